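"""Tri-omics join, regulatory classification, co-clustering and concordance.

Every significant differentially expressed gene is joined with its best
miRNA partner (from pair reduction) and the lowest-p significant
differentially methylated island overlapping its promoter, then labelled
MIR / DM / BOTH / NONE by which epigenetic signals are present.  The
scaled three-channel fold-change profiles (gene log2FC, partner miRNA
log2FC, island log2 methylation quotient) are co-clustered by k-means,
and a per-cluster channel-dominance score summarises whether clusters
are driven by one epigenetic modality or both — the exclusivity index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

REG_CLASSES = ("MIR", "DM", "BOTH", "NONE")

INTEGRATED_COLUMNS = [
    "gene_id",
    "gene_log2fc",
    "mirna_id",
    "mirna_log2fc",
    "rho",
    "island_id",
    "log2_quotient",
    "reg_class",
]

#: channel-dominance scores below this magnitude count as "no signal"
DOMINANCE_FLOOR = 0.05


def build_integrated_table(
    deg: pd.DataFrame,
    reduced_pairs: pd.DataFrame,
    island_dm: pd.DataFrame,
    cgi_gene_map: dict[str, list[str]],
) -> pd.DataFrame:
    """One record per significant DEG with its miRNA and/or CGI partner.

    The island is the significant DM island overlapping the gene's
    promoter with minimal p (ties: larger ``|log2_quotient|``, then
    lexicographic island id).  The regulatory class follows from which
    partners are present.
    """
    pair_by_gene = reduced_pairs.set_index("gene_id") if len(reduced_pairs) else None
    dm_sig = island_dm.loc[island_dm["significant"]].set_index("island_id")

    rows = []
    for rec in deg.loc[deg["significant"]].itertuples(index=False):
        gene = rec.feature_id
        row = {
            "gene_id": gene,
            "gene_log2fc": rec.log2fc,
            "mirna_id": None,
            "mirna_log2fc": np.nan,
            "rho": np.nan,
            "island_id": None,
            "log2_quotient": np.nan,
        }
        if pair_by_gene is not None and gene in pair_by_gene.index:
            pair = pair_by_gene.loc[gene]
            row["mirna_id"] = pair["mirna_id"]
            row["mirna_log2fc"] = pair["mirna_log2fc"]
            row["rho"] = pair["rho"]
        candidates = [i for i in cgi_gene_map.get(gene, []) if i in dm_sig.index]
        if candidates:
            sub = dm_sig.loc[candidates]
            order = sorted(
                candidates,
                key=lambda i: (sub.at[i, "p"], -abs(sub.at[i, "log2_quotient"]), i),
            )
            best = order[0]
            row["island_id"] = best
            row["log2_quotient"] = dm_sig.at[best, "log2_quotient"]
        has_mir = row["mirna_id"] is not None
        has_dm = row["island_id"] is not None
        row["reg_class"] = (
            "BOTH" if has_mir and has_dm else "MIR" if has_mir else "DM" if has_dm else "NONE"
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=INTEGRATED_COLUMNS)


def classify_regulation(table: pd.DataFrame) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Partition DEGs into the four regulatory classes.

    Returns (counts per class, gene lists per class); the partition is
    exhaustive and exclusive, so counts sum to the number of DEGs.
    """
    counts = {c: 0 for c in REG_CLASSES}
    genes: dict[str, list[str]] = {c: [] for c in REG_CLASSES}
    for rec in table.itertuples(index=False):
        counts[rec.reg_class] += 1
        genes[rec.reg_class].append(rec.gene_id)
    assert sum(counts.values()) == len(table), "class partition must be exhaustive"
    return counts, genes


@dataclass
class ClusterModel:
    """Fitted k-means co-clustering of scaled tri-omics profiles."""

    gene_ids: list[str]
    matrix: np.ndarray  # genes x 3 scaled channels
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    inertia: float  # total within-cluster sum of squares
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    def within_ss(self) -> float:
        """Recompute the within-cluster SS from assignments and data."""
        total = 0.0
        for c in range(self.k):
            members = self.matrix[self.assignments == c]
            if len(members):
                total += float(((members - members.mean(axis=0)) ** 2).sum())
        return total

    def cluster_channel_means(self) -> np.ndarray:
        """Per-cluster means of the scaled channels (k x 3)."""
        return np.vstack(
            [self.matrix[self.assignments == c].mean(axis=0) for c in range(self.k)]
        )


def fit_kmeans(
    matrix: np.ndarray,
    k_range: Sequence[int],
    restarts: int = 100,
    seed: int = 0,
    force_k: int | None = None,
    gene_ids: list[str] | None = None,
) -> ClusterModel:
    """Lloyd's k-means, best of ``restarts`` random initialisations per k.

    Initial centres are drawn uniformly among the data points (the
    classic ``nstart`` semantics); k is chosen from ``k_range`` by
    maximal mean silhouette unless ``force_k`` is given.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    ks = [force_k] if force_k is not None else sorted(k_range)
    if max(ks) > n:
        raise ValueError(f"k={max(ks)} exceeds the number of profiles ({n})")
    if gene_ids is None:
        gene_ids = [f"row_{i}" for i in range(n)]

    fits: dict[int, KMeans] = {}
    silhouettes: dict[int, float] = {}
    for k in ks:
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=restarts,
            algorithm="lloyd",
            random_state=seed,
        ).fit(matrix)
        fits[k] = km
        if 1 < k < n:
            silhouettes[k] = float(silhouette_score(matrix, km.labels_))
        else:
            silhouettes[k] = float("nan")

    if force_k is not None:
        best_k = force_k
    else:
        best_k = max(ks, key=lambda k: (silhouettes[k], -k))
    km = fits[best_k]
    return ClusterModel(
        gene_ids=gene_ids,
        matrix=matrix,
        k=best_k,
        assignments=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
        silhouette_by_k=silhouettes,
    )


def _zscore_columns(matrix: np.ndarray) -> np.ndarray:
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant channel stays at zero
    return (matrix - mean) / sd


def cluster_features(
    table: pd.DataFrame,
    k_range: Sequence[int] = range(8, 13),
    restarts: int = 100,
    seed: int = 0,
    force_k: int | None = None,
    impute_missing: bool = True,
) -> ClusterModel:
    """Co-cluster DEG profiles over the three scaled channels.

    Channels are (gene_log2fc, mirna_log2fc, log2_quotient); a missing
    modality is imputed as 0 ("no measured epigenetic change") unless
    ``impute_missing`` is False, in which case incomplete genes are
    dropped.  Each channel is z-scored over genes before clustering.
    """
    sub = table.copy()
    if not impute_missing:
        sub = sub.dropna(subset=["mirna_log2fc", "log2_quotient"])
    channels = sub[["gene_log2fc", "mirna_log2fc", "log2_quotient"]].fillna(0.0).to_numpy()
    scaled = _zscore_columns(channels)
    return fit_kmeans(
        scaled,
        k_range,
        restarts=restarts,
        seed=seed,
        force_k=force_k,
        gene_ids=list(sub["gene_id"]),
    )


def exclusivity_index(
    model: ClusterModel, theta: float = 0.25, floor: float = DOMINANCE_FLOOR
) -> tuple[np.ndarray, float]:
    """Per-cluster miRNA-vs-methylation dominance and a global index.

    For each cluster, dominance = |m| / (|m| + |q|) where m and q are the
    cluster means of the scaled miRNA and methylation channels (0.5 by
    convention when both magnitudes are below ``floor``).  The global
    index is the gene-weighted fraction of clusters whose dominance lies
    outside [0.5 - theta, 0.5 + theta]: 1 means every gene sits in a
    single-modality cluster, 0 means no cluster is modality-exclusive.
    """
    means = model.cluster_channel_means()
    m, q = np.abs(means[:, 1]), np.abs(means[:, 2])
    with np.errstate(invalid="ignore"):
        dominance = np.where((m < floor) & (q < floor), 0.5, m / np.where(m + q > 0, m + q, 1.0))
    exclusive = (dominance < 0.5 - theta) | (dominance > 0.5 + theta)
    sizes = np.bincount(model.assignments, minlength=model.k)
    index = float(sizes[exclusive].sum() / sizes.sum())
    return dominance, index


class FoldChangeConcordance(NamedTuple):
    n_shared: int
    pearson_r: float
    slope: float
    intercept: float


def compare_fold_changes(table_a: pd.DataFrame, table_b: pd.DataFrame) -> FoldChangeConcordance:
    """Pearson concordance of log2 fold changes over jointly significant genes."""
    a = table_a.loc[table_a["significant"]].set_index("feature_id")["log2fc"]
    b = table_b.loc[table_b["significant"]].set_index("feature_id")["log2fc"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 jointly significant genes, found {len(shared)}")
    fit = stats.linregress(a.loc[shared], b.loc[shared])
    return FoldChangeConcordance(
        n_shared=len(shared),
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
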