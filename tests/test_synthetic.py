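import filecmp

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_overlaps
from triomix import diffexp, methylation
from triomix.io_formats import SampleMetadata
from triomix.methylation import promoter_intervals
from triomix.synthetic import (
    Geometry,
    SimConfig,
    SyntheticTruth,
    build_geometry,
    generate_cohort,
    make_interactions,
    make_metadata,
    make_truth,
    simulate_counts,
    simulate_methylation,
)


def tiny_config(**kw):
    base = dict(n_genes=40, n_mirnas=12, n_islands=30, seed=11)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            tiny_config(frac_class={"MIR": 0.5, "DM": 0.5, "BOTH": 0.5, "NONE": 0.0})

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            tiny_config(n_tumour=2)

    def test_beta_shift_must_keep_means_inside_unit_interval(self):
        with pytest.raises(ValueError):
            tiny_config(base_methylation=0.8, beta_shift=0.3)

    def test_yaml_dict_round_trip(self):
        cfg = tiny_config()
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestTruth:
    def test_partner_fields_match_class(self):
        truth = make_truth(tiny_config())
        g = truth.genes.set_index("gene_id")
        for _, row in g.iterrows():
            assert (row["partner_mirna_id"] is not None) == (row["class"] in ("MIR", "BOTH"))
            assert (row["partner_island_id"] is not None) == (row["class"] in ("DM", "BOTH"))

    def test_inconsistent_truth_rejected(self):
        truth = make_truth(tiny_config())
        bad = truth.genes.copy()
        bad.loc[bad["class"] == "MIR", "partner_mirna_id"] = None
        with pytest.raises(ValueError):
            SyntheticTruth(genes=bad, mirnas=truth.mirnas)

    def test_canonical_partner_direction_is_opposite(self):
        truth = make_truth(tiny_config(frac_noncanonical=0.0))
        mir_dir = truth.mirnas.set_index("mirna_id")["direction"]
        g = truth.genes.dropna(subset=["partner_mirna_id"])
        for rec in g.itertuples(index=False):
            assert mir_dir[rec.partner_mirna_id] != rec.direction


class TestGeometry:
    def test_uniform_four_gene_config_plants_two_islands(self):
        cfg = tiny_config(n_genes=4, n_islands=4, n_mirnas=6)
        truth = make_truth(cfg)
        geo = build_geometry(cfg, truth)
        assert len(geo.island_to_gene) == 2  # one DM + one BOTH gene

    def test_promoter_map_matches_brute_force_oracle(self):
        cfg = tiny_config()
        truth = make_truth(cfg)
        geo = build_geometry(cfg, truth)
        promoters = promoter_intervals(geo.genes)
        oracle = brute_force_overlaps(promoters, geo.islands)
        expected = sorted(
            (gene, island) for island, gene in geo.island_to_gene.items()
        )
        assert oracle == expected

    def test_cpg_count_per_island(self):
        cfg = tiny_config(cpgs_per_island=7)
        geo = build_geometry(cfg, make_truth(cfg))
        assert len(geo.cpgs) == 7 * len(geo.islands)
        oracle = brute_force_overlaps(geo.cpgs, geo.islands)
        assert len(oracle) == len(geo.cpgs)  # every CpG in exactly one island


class TestCounts:
    def test_identical_seed_identical_matrices(self):
        cfg = tiny_config()
        truth = make_truth(cfg)
        a = simulate_counts(cfg, truth, "mrna")
        b = simulate_counts(cfg, truth, "mrna")
        assert a.counts.equals(b.counts)

    def test_replicate_offsets_differ(self):
        cfg = tiny_config()
        truth = make_truth(cfg)
        a = simulate_counts(cfg, truth, "mrna", seed_offset=1)
        b = simulate_counts(cfg, truth, "mrna", seed_offset=2)
        assert not a.counts.equals(b.counts)

    def test_unaffected_genes_have_vanishing_group_ratio(self):
        # law of large numbers at 50 samples per group
        cfg = tiny_config(
            n_genes=200,
            n_islands=10,
            n_tumour=50,
            n_control=50,
            frac_class={"MIR": 0, "DM": 0, "BOTH": 0, "NONE": 1.0},
        )
        truth = make_truth(cfg)
        cm = simulate_counts(cfg, truth, "mrna")
        meta = SampleMetadata(make_metadata(cfg))
        norm = diffexp.normalized_counts(cm)
        ratio = np.log2(
            norm[meta.group_samples("tumour")].mean(axis=1)
            / norm[meta.group_samples("control")].mean(axis=1)
        )
        assert np.abs(ratio).mean() < 0.1


class TestMethylation:
    def test_betas_inside_unit_interval(self, small_cohort):
        values = small_cohort.beta.to_numpy()
        assert values.min() > 0 and values.max() < 1

    def test_zero_shift_gives_unit_quotients(self):
        cfg = tiny_config(beta_shift=0.0)
        truth = make_truth(cfg)
        geo = build_geometry(cfg, truth)
        beta = simulate_methylation(cfg, truth, geo)
        meta = SampleMetadata(make_metadata(cfg))
        dm = methylation.aggregate_islands(
            methylation.site_dm_test(beta, meta), geo.islands, geo.cpgs
        )
        assert np.abs(dm["log2_quotient"]).max() < 0.3
        assert np.abs(dm["log2_quotient"]).mean() < 0.1

    def test_planted_hypermethylation_quotient_recovered(self):
        # hyper islands move 0.3 -> 0.6, so log2 quotient should be near 1
        cfg = tiny_config(n_genes=60, n_islands=40, cpgs_per_island=20, frac_noncanonical=0.0)
        truth = make_truth(cfg)
        geo = build_geometry(cfg, truth)
        beta = simulate_methylation(cfg, truth, geo)
        meta = SampleMetadata(make_metadata(cfg))
        dm = methylation.aggregate_islands(
            methylation.site_dm_test(beta, meta), geo.islands, geo.cpgs
        ).set_index("island_id")
        hyper = truth.genes.query("direction == 'down'").dropna(subset=["partner_island_id"])
        values = dm.loc[hyper["partner_island_id"], "log2_quotient"]
        assert len(values) > 5
        assert np.allclose(values, 1.0, atol=0.2)


class TestCohort:
    def test_rerun_is_byte_identical(self, small_config, small_cohort, tmp_path):
        again = generate_cohort(small_config, tmp_path / "again")
        for key, path in small_cohort.paths.items():
            assert filecmp.cmp(path, again.paths[key], shallow=False), key

    def test_interactions_contain_every_partner_pair(self, small_cohort):
        truth = small_cohort.truth.genes.dropna(subset=["partner_mirna_id"])
        have = set(zip(small_cohort.interactions["mirna_id"], small_cohort.interactions["gene_id"]))
        for rec in truth.itertuples(index=False):
            assert (rec.partner_mirna_id, rec.gene_id) in have

    def test_decoy_fraction_scales_validated_rows(self, small_cohort):
        n_partners = small_cohort.truth.genes["partner_mirna_id"].notna().sum()
        validated = (small_cohort.interactions["evidence"] == "validated").sum()
        assert validated == pytest.approx(1.5 * n_partners, rel=0.02)
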