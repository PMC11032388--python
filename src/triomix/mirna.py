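"""Candidate miRNA-gene pairs and their reduction to one miRNA per gene.

Pairs are built from experimentally validated interactions whose miRNA
and target gene are both significant in their respective differential
expression tables; each pair is scored by the Spearman correlation of
normalised counts over shared samples, and multiple candidate miRNAs per
gene are reduced to the single one with the highest absolute correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["gene_id", "mirna_id", "mirna_log2fc", "rho", "rho_p", "n_shared_samples"]


def candidate_pairs(
    deg: pd.DataFrame,
    demir: pd.DataFrame,
    interactions: pd.DataFrame,
) -> pd.DataFrame:
    """One record per validated interaction with both members significant.

    ``deg`` and ``demir`` are differential-expression tables carrying
    ``feature_id``/``log2fc``/``significant`` columns; ``interactions``
    has (mirna_id, gene_id, evidence).  Correlation columns are left NaN
    for :func:`spearman_fill`.
    """
    if interactions.empty:
        logger.warning("interaction table is empty; no candidate pairs")
        return pd.DataFrame(columns=PAIR_COLUMNS)
    sig_genes = set(deg.loc[deg["significant"], "feature_id"])
    sig_mirnas = set(demir.loc[demir["significant"], "feature_id"])
    mirna_lfc = demir.set_index("feature_id")["log2fc"]

    mask = (
        (interactions["evidence"] == "validated")
        & interactions["gene_id"].isin(sig_genes)
        & interactions["mirna_id"].isin(sig_mirnas)
    )
    kept = interactions.loc[mask, ["gene_id", "mirna_id"]].drop_duplicates()
    out = kept.reset_index(drop=True).copy()
    out["mirna_log2fc"] = out["mirna_id"].map(mirna_lfc)
    out["rho"] = np.nan
    out["rho_p"] = np.nan
    out["n_shared_samples"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out[PAIR_COLUMNS]


def spearman_fill(
    pairs: pd.DataFrame,
    mrna_norm: pd.DataFrame,
    mirna_norm: pd.DataFrame,
) -> pd.DataFrame:
    """Fill Spearman rho and two-sided p for each pair over shared samples.

    Correlations are computed on log2(x + 1) of the normalised counts;
    Spearman is rank-based so the log transform is cosmetic.  Ties get
    average ranks.
    """
    shared = [s for s in mrna_norm.columns if s in set(mirna_norm.columns)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, found {len(shared)}")
    gx = np.log2(mrna_norm[shared] + 1.0)
    mx = np.log2(mirna_norm[shared] + 1.0)

    out = pairs.copy()
    rhos, ps = [], []
    for rec in out.itertuples(index=False):
        rho, p = stats.spearmanr(gx.loc[rec.gene_id], mx.loc[rec.mirna_id])
        rhos.append(rho)
        ps.append(p)
    out["rho"] = rhos
    out["rho_p"] = ps
    out["n_shared_samples"] = len(shared)
    return out


def reduce_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Keep, per gene, the pair maximising ``|rho|``.

    Ties are broken by smaller ``rho_p``, then lexicographically smaller
    ``mirna_id``; the result has exactly one row per gene present in the
    input and is deterministic.
    """
    if pairs.empty:
        return pairs.copy()
    if pairs["rho"].isna().any():
        raise ValueError("rho must be filled before reduction")
    ranked = pairs.assign(_abs_rho=pairs["rho"].abs()).sort_values(
        ["gene_id", "_abs_rho", "rho_p", "mirna_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = ranked.groupby("gene_id", sort=True).head(1).drop(columns="_abs_rho")
    return best.reset_index(drop=True)
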