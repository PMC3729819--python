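"""Interval sweep primitives used by overlap and landscape modules.

All coordinates are 0-based, half-open. Interval tables are pandas
DataFrames with at least ``chrom``, ``start`` and ``end`` columns.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ValidationError


def percent(n: int, total: int, decimals: int = 1) -> float:
    """Percentage ``100*n/total`` rounded half-up to ``decimals`` places.

    Half-up rounding matches how published tables format percentages
    (e.g. 546/13,445 -> 4.1).
    """
    if total <= 0:
        raise ValidationError("percentage denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(n) * 100 / Decimal(total)).quantize(q, ROUND_HALF_UP))


def fold_change(a: float, b: float) -> float:
    """Ratio a/b, e.g. between PAR fragment fractions of two conditions."""
    if b == 0:
        raise ValidationError("fold change undefined for zero denominator")
    return a / b


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome.

    Returns a sorted DataFrame with columns chrom, start, end whose rows
    are pairwise disjoint.
    """
    if len(intervals) == 0:
        return pd.DataFrame({"chrom": [], "start": [], "end": []})
    out = []
    df = intervals.sort_values(["chrom", "start"], kind="stable")
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it intersect (>= 1 bp) any subject?

    Subject intervals may overlap each other; a prefix-maximum of sorted
    ends handles that without an interval tree.
    """
    flags = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return flags
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in subject.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = np.maximum.accumulate(sub["end"].to_numpy(dtype=np.int64))
        by_chrom[chrom] = (starts, ends)
    qc = query["chrom"].to_numpy()
    qs = query["start"].to_numpy(dtype=np.int64)
    qe = query["end"].to_numpy(dtype=np.int64)
    for chrom, (starts, prefmax_ends) in by_chrom.items():
        sel = np.flatnonzero(qc == chrom)
        if sel.size == 0:
            continue
        # subject candidates: start < query end
        idx = np.searchsorted(starts, qe[sel], side="left")
        has = idx > 0
        hit = np.zeros(sel.size, dtype=bool)
        hit[has] = prefmax_ends[idx[has] - 1] > qs[sel[has]]
        flags[sel] = hit
    return flags


def points_in_intervals(
    chroms: np.ndarray, positions: np.ndarray, regions: pd.DataFrame
) -> np.ndarray:
    """Boolean per point: does it fall inside any region ``[start, end)``?"""
    flags = np.zeros(len(positions), dtype=bool)
    if len(positions) == 0 or len(regions) == 0:
        return flags
    merged = merge_intervals(regions)
    for chrom, sub in merged.groupby("chrom", sort=False):
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(starts, positions[sel], side="right")
        has = idx > 0
        hit = np.zeros(sel.size, dtype=bool)
        hit[has] = positions[sel[has]] < ends[idx[has] - 1]
        flags[sel] = hit
    return flags
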