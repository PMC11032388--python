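"""Differential DNA methylation on CpG sites and islands.

Site-level testing uses Welch's t-test on M-values (logit-transformed
beta values); sites are aggregated to CpG islands as a tumour/control
methylation quotient with a Fisher (or Stouffer) combination of member
p-values and BH adjustment across islands.  Promoters are strand-aware
windows around the TSS (1500 bp upstream, 500 bp downstream) and an
island is assigned to a gene when it overlaps the promoter by at least
one base.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from triomix import intervals
from triomix.diffexp import bh_adjust
from triomix.io_formats import GenomicInterval, SampleMetadata

logger = logging.getLogger(__name__)

#: variance floor used when a site has zero within-group variance
VARIANCE_FLOOR = 1e-12
#: offset guarding the methylation quotient against near-zero denominators
QUOTIENT_EPS = 0.01

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


def mvalue_transform(beta: pd.DataFrame) -> pd.DataFrame:
    """M = log2(beta / (1 - beta)), elementwise; betas must lie in (0, 1)."""
    values = beta.to_numpy(dtype=float)
    if np.any(values <= 0) or np.any(values >= 1):
        raise ValueError("beta values must be strictly inside (0, 1); clip on import")
    return pd.DataFrame(np.log2(values / (1.0 - values)), index=beta.index, columns=beta.columns)


def site_dm_test(beta: pd.DataFrame, meta: SampleMetadata) -> pd.DataFrame:
    """Welch two-sample test per CpG site on M-values.

    Returns a DataFrame with columns (cpg_id, mean_beta_tumour,
    mean_beta_control, p).  Group means are reported on the beta scale.
    Sites with zero within-group variance are tested with a variance
    floor and logged.
    """
    tumour = meta.group_samples("tumour")
    control = meta.group_samples("control")
    if len(tumour) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 samples for the site test")

    m = mvalue_transform(beta)
    mt, mc = m[tumour].to_numpy(), m[control].to_numpy()
    nt, nc = mt.shape[1], mc.shape[1]

    mean_t, mean_c = mt.mean(axis=1), mc.mean(axis=1)
    var_t, var_c = mt.var(axis=1, ddof=1), mc.var(axis=1, ddof=1)
    floored = (var_t < VARIANCE_FLOOR) | (var_c < VARIANCE_FLOOR)
    if floored.any():
        logger.warning("variance floor applied at %d CpG site(s)", int(floored.sum()))
    var_t = np.maximum(var_t, VARIANCE_FLOOR)
    var_c = np.maximum(var_c, VARIANCE_FLOOR)

    se2 = var_t / nt + var_c / nc
    t = (mean_t - mean_c) / np.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    df = se2**2 / ((var_t / nt) ** 2 / (nt - 1) + (var_c / nc) ** 2 / (nc - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    return pd.DataFrame(
        {
            "cpg_id": beta.index,
            "mean_beta_tumour": beta[tumour].mean(axis=1).to_numpy(),
            "mean_beta_control": beta[control].mean(axis=1).to_numpy(),
            "p": p,
        }
    ).reset_index(drop=True)


def _combine_pvalues(p: np.ndarray, method: str) -> float:
    p = np.clip(p, 1e-300, 1.0)
    if method == "fisher":
        stat = -2.0 * np.sum(np.log(p))
        return float(stats.chi2.sf(stat, 2 * p.size))
    if method == "stouffer":
        z = stats.norm.isf(p)
        return float(stats.norm.sf(z.sum() / np.sqrt(p.size)))
    raise ValueError(f"unknown combination method {method!r}")


def aggregate_islands(
    site_results: pd.DataFrame,
    islands: list[GenomicInterval],
    cpg_coords: list[GenomicInterval],
    eps: float = QUOTIENT_EPS,
    method: str = "fisher",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Aggregate site statistics to CpG-island methylation quotients.

    quotient = (mean over member sites of tumour mean beta + eps) /
    (mean over member sites of control mean beta + eps); the island
    p-value combines member-site p-values (Fisher by default) and is BH
    adjusted across islands.  Membership is coordinate containment of the
    CpG in the island (half-open).  Islands without any tested CpG are
    dropped with a warning.
    """
    site = site_results.set_index("cpg_id")
    tested = [iv for iv in cpg_coords if iv.id in site.index]
    membership = intervals.overlap_map(tested, islands)

    members_by_island: dict[str, list[str]] = {}
    for cpg_id, island_ids in membership.items():
        for island_id in island_ids:
            members_by_island.setdefault(island_id, []).append(cpg_id)

    rows = []
    for iv in islands:
        member_ids = members_by_island.get(iv.id)
        if not member_ids:
            logger.warning("island %s has no tested CpG site; dropped", iv.id)
            continue
        sub = site.loc[member_ids]
        mean_t = float(sub["mean_beta_tumour"].mean())
        mean_c = float(sub["mean_beta_control"].mean())
        quotient = (mean_t + eps) / (mean_c + eps)
        p = _combine_pvalues(sub["p"].to_numpy(), method)
        rows.append(
            {
                "island_id": iv.id,
                "n_sites": len(member_ids),
                "quotient": quotient,
                "log2_quotient": float(np.log2(quotient)),
                "p": p,
            }
        )
    result = pd.DataFrame(rows, columns=["island_id", "n_sites", "quotient", "log2_quotient", "p"])
    if len(result):
        result["padj"] = bh_adjust(result["p"].to_numpy())
    else:
        result["padj"] = pd.Series(dtype=float)
    result["significant"] = result["padj"] < alpha
    return result


def promoter_intervals(
    genes: pd.DataFrame,
    up: int = PROMOTER_UPSTREAM,
    down: int = PROMOTER_DOWNSTREAM,
) -> list[GenomicInterval]:
    """Strand-aware promoter windows around each TSS, clipped at zero.

    Plus strand: ``[tss - up, tss + down)``; minus strand the mirror
    image, ``[tss - down, tss + up)``.
    """
    out = []
    for rec in genes.itertuples(index=False):
        if rec.strand == "+":
            start, end = rec.tss - up, rec.tss + down
        elif rec.strand == "-":
            start, end = rec.tss - down, rec.tss + up
        else:
            raise ValueError(f"gene {rec.gene_id!r}: strand must be + or -")
        out.append(GenomicInterval(rec.chrom, max(0, start), end, rec.strand, rec.gene_id))
    return out


def assign_cgi_to_genes(
    islands: list[GenomicInterval],
    promoters: list[GenomicInterval],
    min_overlap: int = 1,
) -> dict[str, list[str]]:
    """Map gene id -> island ids whose CGI overlaps the gene's promoter.

    Any overlap of at least ``min_overlap`` bases assigns the island; a
    CGI may map to several genes and a gene may own several CGIs.
    """
    return intervals.overlap_map(promoters, islands, min_overlap=min_overlap)
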