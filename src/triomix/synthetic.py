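"""Synthetic tumour/control tri-omics cohorts with planted regulatory truth.

The generator emits a matched mRNA count matrix, miRNA count matrix and
CpG beta-value matrix for one cohort of tumour and control samples,
together with the genomic geometry (gene TSSs, promoter CpG islands,
CpG positions), a validated-interaction table with decoys, sample
metadata, gene sets and a per-gene truth table.  Each gene is planted
with one of four regulatory architectures:

* ``MIR``  — differentially expressed, coupled to a differentially
  expressed partner miRNA (anti-correlated when canonical);
* ``DM``   — differentially expressed, with a differentially methylated
  CpG island inside its promoter (hypermethylated for down-regulated
  genes when canonical);
* ``BOTH`` — both couplings;
* ``NONE`` — no planted effect at all.

Counts follow a negative-binomial model with per-sample size factors;
a per-sample latent miRNA-activity term is shared between each partner
miRNA and its target gene so that true pairs correlate more strongly
than decoy pairs within groups.  Betas follow a Beta distribution with
a common precision.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from triomix import intervals
from triomix.io_formats import (
    CountMatrix,
    GeneSetCollection,
    GenomicInterval,
    SampleMetadata,
    write_bed_intervals,
    write_count_matrix,
    write_gmt,
    write_table,
)
from triomix.methylation import promoter_intervals

CLASSES = ("MIR", "DM", "BOTH", "NONE")

# deterministic layout constants
CHROM = "chr1"
GENE_SPACING = 10_000
LAYOUT_OFFSET = 100_000
CPG_SPACING = 10

# rng stream tags (combined with the config seed)
_TAG_TRUTH = 1
_TAG_GEOMETRY = 2
_TAG_LATENT = 3
_TAG_BASELINE_MRNA = 4
_TAG_BASELINE_MIRNA = 5
_TAG_COUNTS_MRNA = 6
_TAG_COUNTS_MIRNA = 7
_TAG_METHYLATION = 8
_TAG_METADATA = 9
_TAG_INTERACTIONS = 10
_TAG_GENESETS = 11


@dataclass
class SimConfig:
    """Stated world of one synthetic cohort.

    Defaults describe a desk-scale cohort: 1000 genes, 100 miRNAs, the
    four regulatory classes in equal proportion, |log2FC| 2 for planted
    genes and miRNAs, a 0.3 beta shift on planted promoter islands, and
    8 tumour versus 8 control samples.
    """

    n_genes: int = 1000
    n_mirnas: int = 100
    n_islands: int = 600
    cpgs_per_island: int = 10
    n_tumour: int = 8
    n_control: int = 8
    frac_class: dict[str, float] = field(
        default_factory=lambda: {"MIR": 0.25, "DM": 0.25, "BOTH": 0.25, "NONE": 0.25}
    )
    frac_noncanonical: float = 0.1
    lfc_gene: float = 2.0
    lfc_mirna: float = 2.0
    beta_shift: float = 0.3
    base_methylation: float = 0.3
    beta_precision: float = 50.0
    nb_dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    mirna_coupling_sd: float = 0.75
    decoy_fraction: float = 0.5
    frac_predicted: float = 0.1
    frac_null_mirnas: float = 0.2
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        frac = {c: float(self.frac_class.get(c, 0.0)) for c in CLASSES}
        if abs(sum(frac.values()) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if any(v < 0 for v in frac.values()):
            raise ValueError("class fractions must be non-negative")
        self.frac_class = frac
        if min(self.n_genes, self.n_mirnas, self.n_islands, self.cpgs_per_island) < 1:
            raise ValueError("all feature counts must be >= 1")
        if self.n_tumour < 3 or self.n_control < 3:
            raise ValueError("need at least 3 samples per group")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must satisfy 0 < lo <= hi")
        if not 0 <= self.frac_noncanonical <= 1:
            raise ValueError("frac_noncanonical must lie in [0, 1]")
        if not 0 <= self.beta_shift < 1:
            raise ValueError("beta_shift must lie in [0, 1)")
        for m in (self.base_methylation, self.base_methylation + self.beta_shift):
            if not 0 < m < 1:
                raise ValueError(
                    f"base_methylation +/- beta_shift must stay inside (0, 1); got {m}"
                )
        if self.cpgs_per_island * CPG_SPACING >= 2000:
            raise ValueError("cpgs_per_island too large for a promoter-contained island")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_factor_range"] = list(self.size_factor_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "size_factor_range" in d:
            d["size_factor_range"] = tuple(d["size_factor_range"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted per-gene architecture plus the miRNA effect table."""

    genes: pd.DataFrame  # gene_id, class, direction, canonical, partners, true_lfc
    mirnas: pd.DataFrame  # mirna_id, direction, lfc

    def __post_init__(self):
        g = self.genes
        needs_mirna = g["class"].isin(["MIR", "BOTH"])
        if (g.loc[needs_mirna, "partner_mirna_id"].isna()).any():
            raise ValueError("MIR/BOTH genes must have a partner miRNA")
        if (~g.loc[~needs_mirna, "partner_mirna_id"].isna()).any():
            raise ValueError("only MIR/BOTH genes may have a partner miRNA")
        needs_island = g["class"].isin(["DM", "BOTH"])
        if (g.loc[needs_island, "partner_island_id"].isna()).any():
            raise ValueError("DM/BOTH genes must have a partner island")
        if (~g.loc[~needs_island, "partner_island_id"].isna()).any():
            raise ValueError("only DM/BOTH genes may have a partner island")


@dataclass
class Geometry:
    genes: pd.DataFrame  # gene_id, chrom, strand, tss
    islands: list[GenomicInterval]
    cpgs: list[GenomicInterval]
    island_to_gene: dict[str, str]  # planted promoter islands only


def _class_counts(config: SimConfig) -> dict[str, int]:
    """Largest-remainder apportionment of genes to classes."""
    raw = {c: config.frac_class[c] * config.n_genes for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = config.n_genes - sum(counts.values())
    for c in sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def make_truth(config: SimConfig) -> SyntheticTruth:
    """Draw the planted regulatory architecture for one cohort."""
    rng = np.random.default_rng([config.seed, _TAG_TRUTH])
    counts = _class_counts(config)
    classes = np.repeat(list(counts.keys()), list(counts.values()))
    classes = rng.permutation(classes)

    width = len(str(config.n_mirnas))
    mirna_ids = [f"mir_{i:0{width}d}" for i in range(config.n_mirnas)]
    n_null = int(round(config.frac_null_mirnas * config.n_mirnas))
    n_reg = config.n_mirnas - n_null
    directions = ["up" if i % 2 == 0 else "down" for i in range(n_reg)] + ["none"] * n_null
    mirnas = pd.DataFrame({"mirna_id": mirna_ids, "direction": directions})
    mirnas["lfc"] = np.select(
        [mirnas["direction"] == "up", mirnas["direction"] == "down"],
        [config.lfc_mirna, -config.lfc_mirna],
        default=0.0,
    )
    up_pool = list(mirnas.loc[mirnas["direction"] == "up", "mirna_id"])
    down_pool = list(mirnas.loc[mirnas["direction"] == "down", "mirna_id"])

    gwidth = len(str(config.n_genes))
    rows = []
    n_island = 0
    for i, cls in enumerate(classes):
        gene_id = f"gene_{i:0{gwidth}d}"
        direction = rng.choice(["up", "down"])
        canonical = bool(rng.random() >= config.frac_noncanonical)
        partner_mirna = None
        partner_island = None
        if cls in ("MIR", "BOTH"):
            # canonical inhibition: partner miRNA moves opposite to the gene
            want = {"up": "down", "down": "up"}[direction] if canonical else direction
            pool = down_pool if want == "down" else up_pool
            if not pool:
                raise ValueError(f"no {want}-regulated miRNA available as a partner")
            partner_mirna = pool[int(rng.integers(len(pool)))]
        if cls in ("DM", "BOTH"):
            partner_island = f"cgi_{n_island:0{gwidth}d}"
            n_island += 1
        true_lfc = 0.0 if cls == "NONE" else (config.lfc_gene if direction == "up" else -config.lfc_gene)
        rows.append(
            {
                "gene_id": gene_id,
                "class": cls,
                "direction": direction,
                "canonical": canonical,
                "partner_mirna_id": partner_mirna,
                "partner_island_id": partner_island,
                "true_lfc": true_lfc,
            }
        )
    genes = pd.DataFrame(rows)
    if n_island > config.n_islands:
        raise ValueError(
            f"{n_island} promoter islands required but n_islands={config.n_islands}"
        )
    return SyntheticTruth(genes=genes, mirnas=mirnas)


def build_geometry(config: SimConfig, truth: SyntheticTruth) -> Geometry:
    """Lay out genes, promoter CpG islands and CpG positions.

    Every DM/BOTH gene gets exactly one island fully inside its promoter
    window; NONE/MIR promoters contain no island; background islands
    land in intergenic space.  The emitted promoter map is verified
    against a brute-force interval check and the build fails if the
    planted containment is violated.
    """
    rng = np.random.default_rng([config.seed, _TAG_GEOMETRY])
    g = truth.genes
    strands = rng.choice(["+", "-"], size=len(g))
    tss = LAYOUT_OFFSET + np.arange(len(g)) * GENE_SPACING
    genes = pd.DataFrame(
        {"gene_id": g["gene_id"], "chrom": CHROM, "strand": strands, "tss": tss}
    )

    promoters = promoter_intervals(genes)
    promoter_by_gene = {p.id: p for p in promoters}
    island_width = config.cpgs_per_island * CPG_SPACING

    islands: list[GenomicInterval] = []
    cpgs: list[GenomicInterval] = []
    island_to_gene: dict[str, str] = {}

    def add_island(island_id: str, start: int) -> None:
        islands.append(GenomicInterval(CHROM, start, start + island_width, ".", island_id))
        for j in range(config.cpgs_per_island):
            pos = start + j * CPG_SPACING
            cpgs.append(GenomicInterval(CHROM, pos, pos + 1, ".", f"cg_{island_id}_{j:03d}"))

    for rec in g.itertuples(index=False):
        if rec.partner_island_id is None:
            continue
        p = promoter_by_gene[rec.gene_id]
        start = p.start + (p.end - p.start - island_width) // 2
        add_island(rec.partner_island_id, start)
        island_to_gene[rec.partner_island_id] = rec.gene_id

    n_background = config.n_islands - len(island_to_gene)
    gwidth = len(str(config.n_genes))
    for b in range(n_background):
        start = LAYOUT_OFFSET + (len(g) + 5 + b) * GENE_SPACING
        add_island(f"cgi_bg_{b:0{gwidth}d}", start)

    _check_geometry(truth, promoters, islands, island_to_gene)
    return Geometry(genes=genes, islands=islands, cpgs=cpgs, island_to_gene=island_to_gene)


def _check_geometry(truth, promoters, islands, island_to_gene) -> None:
    """Brute-force post-condition check of the planted layout."""
    planted = {rec.gene_id: rec.partner_island_id for rec in truth.genes.itertuples(index=False)}
    by_id = {iv.id: iv for iv in islands}
    for p in promoters:
        overlapping = [iv.id for iv in islands if p.overlap_len(iv) > 0]
        want = planted.get(p.id)
        if want is None:
            if overlapping:
                raise RuntimeError(f"promoter of {p.id} unexpectedly overlaps {overlapping}")
        else:
            iv = by_id[want]
            contained = p.start <= iv.start and iv.end <= p.end
            if overlapping != [want] or not contained:
                raise RuntimeError(f"promoter of {p.id} must contain exactly {want}")
    for island_id, gene_id in island_to_gene.items():
        if planted.get(gene_id) != island_id:
            raise RuntimeError("island-to-gene map disagrees with the truth table")


def sample_ids(config: SimConfig) -> list[str]:
    wt = len(str(config.n_tumour))
    wc = len(str(config.n_control))
    return [f"T{i + 1:0{wt}d}" for i in range(config.n_tumour)] + [
        f"C{i + 1:0{wc}d}" for i in range(config.n_control)
    ]


def _latent_activity(config: SimConfig, seed_offset: int) -> np.ndarray:
    """Per-sample miRNA-activity deviations shared by both count layers."""
    rng = np.random.default_rng([config.seed, _TAG_LATENT, seed_offset])
    n_samples = config.n_tumour + config.n_control
    return rng.normal(0.0, config.mirna_coupling_sd, size=(config.n_mirnas, n_samples))


def simulate_counts(
    config: SimConfig,
    truth: SyntheticTruth,
    layer: str,
    seed_offset: int = 0,
) -> CountMatrix:
    """Negative-binomial counts for the mRNA or miRNA layer.

    ``mean = s_j * q_i * 2^(lfc_i * [tumour] + coupling)`` with log-uniform
    per-sample size factors ``s_j``, log-uniform baselines ``q_i`` and a
    shared latent miRNA-activity term coupling each MIR/BOTH gene to its
    partner miRNA (sign flipped for canonical inhibition).  Different
    ``seed_offset`` values draw independent replicate cohorts from the
    same truth.
    """
    if layer not in ("mrna", "mirna"):
        raise ValueError("layer must be 'mrna' or 'mirna'")
    n_samples = config.n_tumour + config.n_control
    is_tumour = np.array([1.0] * config.n_tumour + [0.0] * config.n_control)
    latent = _latent_activity(config, seed_offset)
    mirna_index = {m: i for i, m in enumerate(truth.mirnas["mirna_id"])}

    base_tag = _TAG_BASELINE_MRNA if layer == "mrna" else _TAG_BASELINE_MIRNA
    count_tag = _TAG_COUNTS_MRNA if layer == "mrna" else _TAG_COUNTS_MIRNA
    rng = np.random.default_rng([config.seed, count_tag, seed_offset])

    if layer == "mrna":
        feature_ids = list(truth.genes["gene_id"])
        lfc = truth.genes["true_lfc"].to_numpy(dtype=float)
        coupling = np.zeros((len(feature_ids), n_samples))
        for i, rec in enumerate(truth.genes.itertuples(index=False)):
            if rec.partner_mirna_id is not None:
                sign = -1.0 if rec.canonical else 1.0
                coupling[i] = sign * latent[mirna_index[rec.partner_mirna_id]]
    else:
        feature_ids = list(truth.mirnas["mirna_id"])
        lfc = truth.mirnas["lfc"].to_numpy(dtype=float)
        coupling = latent

    baseline_rng = np.random.default_rng([config.seed, base_tag])
    q = 2.0 ** baseline_rng.uniform(5.0, 10.0, size=len(feature_ids))

    lo, hi = config.size_factor_range
    s = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    mu = s[None, :] * q[:, None] * 2.0 ** (lfc[:, None] * is_tumour[None, :] + coupling)

    n_nb = 1.0 / config.nb_dispersion
    p_nb = n_nb / (n_nb + mu)
    counts = rng.negative_binomial(n_nb, p_nb)
    df = pd.DataFrame(counts, index=feature_ids, columns=sample_ids(config))
    df.index.name = "feature_id"
    return CountMatrix(df)


def simulate_methylation(
    config: SimConfig,
    truth: SyntheticTruth,
    geometry: Geometry,
    seed_offset: int = 0,
) -> pd.DataFrame:
    """Beta-value matrix (CpG x sample) with planted promoter-island shifts.

    CpGs in DM/BOTH promoter islands shift their tumour-group mean by
    ``beta_shift`` — hypermethylation for down-regulated genes when the
    coupling is canonical, flipped when noncanonical.  All other CpGs
    share one group-independent mean drawn uniformly from (0.1, 0.9).
    Betas are Beta-distributed around the target mean with common
    precision and clipped to (0.001, 0.999).
    """
    rng = np.random.default_rng([config.seed, _TAG_METHYLATION, seed_offset])
    genes = truth.genes.set_index("gene_id")
    n_samples = config.n_tumour + config.n_control
    is_tumour = np.array([True] * config.n_tumour + [False] * config.n_control)

    island_of_cpg = {}
    for iv in geometry.cpgs:
        island_of_cpg[iv.id] = iv.id.split("_", 1)[1].rsplit("_", 1)[0]

    m_lo = config.base_methylation
    m_hi = config.base_methylation + config.beta_shift

    mean_control = np.empty(len(geometry.cpgs))
    mean_tumour = np.empty(len(geometry.cpgs))
    for i, iv in enumerate(geometry.cpgs):
        island_id = island_of_cpg[iv.id]
        gene_id = geometry.island_to_gene.get(island_id)
        if gene_id is None:
            mean_control[i] = mean_tumour[i] = rng.uniform(0.1, 0.9)
        else:
            rec = genes.loc[gene_id]
            hyper = (rec["direction"] == "down") == bool(rec["canonical"])
            mean_control[i], mean_tumour[i] = (m_lo, m_hi) if hyper else (m_hi, m_lo)

    mean = np.where(is_tumour[None, :], mean_tumour[:, None], mean_control[:, None])
    prec = config.beta_precision
    betas = rng.beta(mean * prec, (1.0 - mean) * prec)
    betas = np.clip(betas, 0.001, 0.999)
    df = pd.DataFrame(betas, index=[iv.id for iv in geometry.cpgs], columns=sample_ids(config))
    df.index.name = "cpg_id"
    return df


def make_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: group, with HPV status and location for tumours."""
    rng = np.random.default_rng([config.seed, _TAG_METADATA])
    rows = []
    for sid in sample_ids(config):
        tumour = sid.startswith("T")
        rows.append(
            {
                "sample_id": sid,
                "group": "tumour" if tumour else "control",
                "hpv": rng.choice(["positive", "negative"]) if tumour else None,
                "location": rng.choice(["oral", "oropharyngeal"]) if tumour else None,
            }
        )
    return pd.DataFrame(rows)


def make_interactions(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Validated truth-partner interactions plus decoys.

    Decoys are validated rows that must not create spurious regulatory
    classes: half link a differentially expressed miRNA to a MIR/BOTH
    gene other than its partner (exercising max-|rho| reduction), half
    link an unaffected miRNA to a random gene (exercising the
    significance filter).  A further ``frac_predicted`` share of rows
    carries 'predicted' evidence and must be filtered out upstream.
    """
    rng = np.random.default_rng([config.seed, _TAG_INTERACTIONS])
    g = truth.genes
    partners = [
        (rec.partner_mirna_id, rec.gene_id)
        for rec in g.itertuples(index=False)
        if rec.partner_mirna_id is not None
    ]
    partner_set = set(partners)
    rows = [{"mirna_id": m, "gene_id": t, "evidence": "validated"} for m, t in partners]

    reg_mirnas = list(truth.mirnas.loc[truth.mirnas["direction"] != "none", "mirna_id"])
    null_mirnas = list(truth.mirnas.loc[truth.mirnas["direction"] == "none", "mirna_id"])
    mir_genes = list(g.loc[g["class"].isin(["MIR", "BOTH"]), "gene_id"])
    all_genes = list(g["gene_id"])

    n_decoys = int(round(config.decoy_fraction * len(partners)))
    seen = set(partner_set)
    made = 0
    for attempt in range(50 * max(1, n_decoys)):
        if made >= n_decoys:
            break
        if made % 2 == 0 and reg_mirnas and mir_genes:
            pair = (
                reg_mirnas[int(rng.integers(len(reg_mirnas)))],
                mir_genes[int(rng.integers(len(mir_genes)))],
            )
        elif null_mirnas:
            pair = (
                null_mirnas[int(rng.integers(len(null_mirnas)))],
                all_genes[int(rng.integers(len(all_genes)))],
            )
        else:
            break
        if pair in seen:
            continue
        seen.add(pair)
        rows.append({"mirna_id": pair[0], "gene_id": pair[1], "evidence": "validated"})
        made += 1

    n_predicted = int(round(config.frac_predicted * len(partners)))
    all_mirnas = list(truth.mirnas["mirna_id"])
    for _ in range(n_predicted):
        rows.append(
            {
                "mirna_id": all_mirnas[int(rng.integers(len(all_mirnas)))],
                "gene_id": all_genes[int(rng.integers(len(all_genes)))],
                "evidence": "predicted",
            }
        )
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


def make_gene_sets(
    config: SimConfig, truth: SyntheticTruth, n_random_terms: int = 10, term_size: int = 30
) -> GeneSetCollection:
    """One term per planted class plus random terms, for enrichment runs."""
    rng = np.random.default_rng([config.seed, _TAG_GENESETS])
    sets: dict[str, tuple[str, list[str]]] = {}
    for cls in CLASSES:
        members = list(truth.genes.loc[truth.genes["class"] == cls, "gene_id"])
        if members:
            sets[f"SET_{cls}"] = (f"planted {cls}-class genes", members)
    all_genes = list(truth.genes["gene_id"])
    size = min(term_size, len(all_genes))
    for t in range(n_random_terms):
        members = sorted(rng.choice(all_genes, size=size, replace=False))
        sets[f"RANDOM_{t:02d}"] = ("random gene set", members)
    return GeneSetCollection(sets)


@dataclass
class Cohort:
    """In-memory handles plus on-disk paths for one generated cohort."""

    config: SimConfig
    truth: SyntheticTruth
    geometry: Geometry
    mrna: CountMatrix
    mirna: CountMatrix
    beta: pd.DataFrame
    metadata: SampleMetadata
    interactions: pd.DataFrame
    paths: dict[str, Path]


def generate_cohort(config: SimConfig, outdir) -> Cohort:
    """Generate and write the full tri-omics fixture set for one cohort.

    Writes mRNA/miRNA counts, the beta matrix, CpG and island BEDs, gene
    annotation, interaction table, sample metadata, gene sets and the
    truth table; re-running with the same config is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = make_truth(config)
    geometry = build_geometry(config, truth)
    mrna = simulate_counts(config, truth, "mrna")
    mirna = simulate_counts(config, truth, "mirna")
    beta = simulate_methylation(config, truth, geometry)
    metadata_df = make_metadata(config)
    interactions = make_interactions(config, truth)
    gene_sets = make_gene_sets(config, truth)

    paths = {
        "mrna_counts": outdir / "mrna_counts.tsv",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "beta": outdir / "beta.tsv",
        "cpgs": outdir / "cpgs.bed",
        "islands": outdir / "islands.bed",
        "genes": outdir / "genes.tsv",
        "samples": outdir / "samples.tsv",
        "interactions": outdir / "interactions.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_count_matrix(mrna, paths["mrna_counts"])
    write_count_matrix(mirna, paths["mirna_counts"])
    write_table(beta.reset_index(), paths["beta"])
    write_bed_intervals(geometry.cpgs, paths["cpgs"])
    write_bed_intervals(geometry.islands, paths["islands"])
    write_table(geometry.genes, paths["genes"])
    write_table(metadata_df, paths["samples"])
    write_table(interactions, paths["interactions"])
    write_gmt(gene_sets, paths["gene_sets"])
    write_table(truth.genes, paths["truth"])

    return Cohort(
        config=config,
        truth=truth,
        geometry=geometry,
        mrna=mrna,
        mirna=mirna,
        beta=beta,
        metadata=SampleMetadata(metadata_df),
        interactions=interactions,
        paths=paths,
    )
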