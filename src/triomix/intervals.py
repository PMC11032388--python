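"""Interval-overlap joins on 0-based half-open coordinates.

Thin wrapper around pyranges; every public function takes and returns the
package's :class:`~triomix.io_formats.GenomicInterval` lists so callers
never touch the pyranges API directly.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr

from triomix.io_formats import GenomicInterval


def _to_pyranges(intervals: Sequence[GenomicInterval], id_col: str) -> pr.PyRanges:
    df = pd.DataFrame(
        {
            "Chromosome": [iv.chrom for iv in intervals],
            "Start": [iv.start for iv in intervals],
            "End": [iv.end for iv in intervals],
            id_col: [iv.id for iv in intervals],
        }
    )
    return pr.PyRanges(df)


def overlap_pairs(
    queries: Sequence[GenomicInterval],
    subjects: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> list[tuple[str, str]]:
    """All (query_id, subject_id) pairs overlapping by >= ``min_overlap`` bases.

    Half-open semantics: ``[0, 10)`` and ``[10, 20)`` do not overlap.
    Output order is deterministic (sorted by query id then subject id).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not queries or not subjects:
        return []
    joined = _to_pyranges(queries, "_query_id").join(_to_pyranges(subjects, "_subject_id"))
    df = joined.df
    if df.empty:
        return []
    width = df[["End", "End_b"]].min(axis=1) - df[["Start", "Start_b"]].max(axis=1)
    df = df[width >= min_overlap]
    pairs = sorted(zip(df["_query_id"], df["_subject_id"]))
    return pairs


def overlap_map(
    queries: Sequence[GenomicInterval],
    subjects: Sequence[GenomicInterval],
    min_overlap: int = 1,
) -> dict[str, list[str]]:
    """Map each query id to the sorted list of subject ids it overlaps."""
    out: dict[str, list[str]] = {}
    for qid, sid in overlap_pairs(queries, subjects, min_overlap=min_overlap):
        out.setdefault(qid, []).append(sid)
    return out
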