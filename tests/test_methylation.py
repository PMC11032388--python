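import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_overlaps, random_intervals
from triomix import methylation
from triomix.io_formats import GenomicInterval, SampleMetadata


def make_meta(samples, groups):
    return SampleMetadata(pd.DataFrame({"sample_id": samples, "group": groups}))


SAMPLES = [f"T{i}" for i in range(4)] + [f"C{i}" for i in range(4)]
META = make_meta(SAMPLES, ["tumour"] * 4 + ["control"] * 4)


class TestMValues:
    def test_known_values(self):
        beta = pd.DataFrame({"s1": [0.5, 0.8], "s2": [0.5, 0.8]}, index=["c1", "c2"])
        m = methylation.mvalue_transform(beta)
        assert m.loc["c1", "s1"] == pytest.approx(0.0)
        assert m.loc["c2", "s1"] == pytest.approx(2.0)  # log2(0.8/0.2)

    def test_strictly_increasing(self):
        grid = np.linspace(0.01, 0.99, 200)
        m = methylation.mvalue_transform(pd.DataFrame({"a": grid, "b": grid}))
        assert np.all(np.diff(m["a"]) > 0)

    def test_boundary_betas_rejected(self):
        with pytest.raises(ValueError):
            methylation.mvalue_transform(pd.DataFrame({"a": [0.0], "b": [0.5]}))


class TestSiteTest:
    def test_group_label_swap_leaves_p_unchanged(self):
        rng = np.random.default_rng(8)
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, size=(30, 8)), columns=SAMPLES)
        beta.index = [f"c{i}" for i in range(30)]
        swapped = make_meta(SAMPLES, ["control"] * 4 + ["tumour"] * 4)
        a = methylation.site_dm_test(beta, META)
        b = methylation.site_dm_test(beta, swapped)
        assert np.allclose(a["p"], b["p"])
        assert np.allclose(a["mean_beta_tumour"], b["mean_beta_control"])

    def test_planted_shift_is_detected(self):
        # 0.3 -> 0.6 shift at 8 vs 8 samples
        rng = np.random.default_rng(9)
        samples = [f"T{i}" for i in range(8)] + [f"C{i}" for i in range(8)]
        meta = make_meta(samples, ["tumour"] * 8 + ["control"] * 8)
        n_sites = 100
        mean = np.full((n_sites, 16), 0.3)
        mean[:, :8] = 0.6  # tumour columns shifted
        prec = 50
        beta = pd.DataFrame(
            rng.beta(mean * prec, (1 - mean) * prec),
            index=[f"c{i}" for i in range(n_sites)],
            columns=samples,
        )
        res = methylation.site_dm_test(beta, meta)
        assert (res["p"] < 0.01).mean() >= 0.90

    def test_zero_variance_floored_and_logged(self, caplog):
        beta = pd.DataFrame(
            np.tile([[0.4], [0.6]], (1, 8)), index=["c1", "c2"], columns=SAMPLES
        )
        with caplog.at_level("WARNING"):
            res = methylation.site_dm_test(beta, META)
        assert np.isfinite(res["p"]).all()
        assert "variance floor" in caplog.text


class TestIslandAggregation:
    def _geometry(self):
        islands = [GenomicInterval("chr1", 0, 100, ".", "isl1"),
                   GenomicInterval("chr1", 200, 300, ".", "isl2")]
        cpgs = [
            GenomicInterval("chr1", 10, 11, ".", "c1"),
            GenomicInterval("chr1", 20, 21, ".", "c2"),
            GenomicInterval("chr1", 250, 251, ".", "c3"),
        ]
        return islands, cpgs

    def test_equal_group_means_give_unit_quotient(self):
        islands, cpgs = self._geometry()
        sites = pd.DataFrame(
            {
                "cpg_id": ["c1", "c2", "c3"],
                "mean_beta_tumour": [0.3, 0.5, 0.7],
                "mean_beta_control": [0.3, 0.5, 0.7],
                "p": [0.4, 0.6, 0.9],
            }
        )
        res = methylation.aggregate_islands(sites, islands, cpgs).set_index("island_id")
        assert res.loc["isl1", "quotient"] == pytest.approx(1.0)
        assert res.loc["isl1", "log2_quotient"] == pytest.approx(0.0)
        assert res.loc["isl1", "n_sites"] == 2

    def test_single_site_island_p_equals_site_p(self):
        islands, cpgs = self._geometry()
        sites = pd.DataFrame(
            {
                "cpg_id": ["c1", "c2", "c3"],
                "mean_beta_tumour": [0.3, 0.4, 0.6],
                "mean_beta_control": [0.3, 0.4, 0.3],
                "p": [0.5, 0.5, 0.0123],
            }
        )
        res = methylation.aggregate_islands(sites, islands, cpgs).set_index("island_id")
        assert res.loc["isl2", "p"] == pytest.approx(0.0123, rel=1e-9)

    def test_island_without_tested_cpg_dropped(self, caplog):
        islands, cpgs = self._geometry()
        sites = pd.DataFrame(
            {"cpg_id": ["c1"], "mean_beta_tumour": [0.3], "mean_beta_control": [0.3], "p": [0.5]}
        )
        with caplog.at_level("WARNING"):
            res = methylation.aggregate_islands(sites, islands, cpgs)
        assert list(res["island_id"]) == ["isl1"]
        assert "no tested CpG" in caplog.text

    def test_membership_matches_brute_force(self):
        rng = np.random.default_rng(10)
        islands = random_intervals(rng, 30, max_len=300, prefix="isl")
        cpgs = [
            GenomicInterval(c.chrom, p, p + 1, ".", f"cg{i}")
            for i, (c, p) in enumerate(
                (islands[int(rng.integers(30))], int(rng.integers(0, 20_000)))
                for _ in range(200)
            )
        ]
        sites = pd.DataFrame(
            {
                "cpg_id": [c.id for c in cpgs],
                "mean_beta_tumour": 0.5,
                "mean_beta_control": 0.5,
                "p": rng.uniform(size=len(cpgs)),
            }
        )
        res = methylation.aggregate_islands(sites, islands, cpgs)
        oracle = brute_force_overlaps(cpgs, islands)
        counts = {}
        for _, isl in oracle:
            counts[isl] = counts.get(isl, 0) + 1
        assert dict(zip(res["island_id"], res["n_sites"])) == counts


class TestPromoters:
    GENES = pd.DataFrame(
        {
            "gene_id": ["gp", "gm", "gclip"],
            "chrom": ["chr1"] * 3,
            "strand": ["+", "-", "+"],
            "tss": [10_000, 10_000, 100],
        }
    )

    def test_windows(self):
        plus, minus, clipped = methylation.promoter_intervals(self.GENES)
        assert (plus.start, plus.end) == (8_500, 10_500)
        assert (minus.start, minus.end) == (9_500, 11_500)
        assert (clipped.start, clipped.end) == (0, 600)

    def test_strand_reflection(self):
        plus, minus, _ = methylation.promoter_intervals(self.GENES)
        tss = 10_000
        assert (tss - minus.end, tss - minus.start) == (plus.start - tss, plus.end - tss)


class TestAssignment:
    PROMOTER = [GenomicInterval("chr1", 8_500, 10_500, "+", "gene1")]

    def test_partial_overlap_assigned(self):
        island = [GenomicInterval("chr1", 8_400, 8_600, ".", "cgi1")]
        assert methylation.assign_cgi_to_genes(island, self.PROMOTER) == {"gene1": ["cgi1"]}

    def test_half_open_abutment_not_assigned(self):
        island = [GenomicInterval("chr1", 8_000, 8_500, ".", "cgi1")]
        assert methylation.assign_cgi_to_genes(island, self.PROMOTER) == {}

    def test_random_geometry_matches_oracle(self):
        rng = np.random.default_rng(11)
        islands = random_intervals(rng, 40, prefix="isl")
        promoters = random_intervals(rng, 25, prefix="gene")
        got = methylation.assign_cgi_to_genes(islands, promoters)
        pairs = sorted((g, i) for g, ids in got.items() for i in ids)
        assert pairs == brute_force_overlaps(promoters, islands)
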