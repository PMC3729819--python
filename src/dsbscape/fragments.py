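"""Read, validate, filter, duplicate-cap and pool ssDNA fragment records.

A fragment collection is a pandas DataFrame with columns

    chrom, start, end, strand, q1, q2, replicate

(0-based, half-open coordinates; q1/q2 are the per-end read quality
scores of the paired reads the fragment derives from). Two filters
precede all downstream analysis: fragments where *either* end read has
quality below the threshold are discarded, and at most ``max_duplicates``
identical-coordinate fragments are retained at any locus to limit PCR
duplicate inflation. Replicate datasets are then pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "q1", "q2", "replicate"]


class FragmentRecord(NamedTuple):
    """Row view of one aligned ssDNA fragment."""

    chrom: str
    start: int
    end: int
    strand: str
    q1: int
    q2: int
    replicate: str


@dataclass(frozen=True)
class FilterParams:
    """Quality and duplicate-cap thresholds.

    min_quality: a fragment is discarded when either end read's quality
    is strictly below this (default 30). max_duplicates: cap on
    identical (chrom, start, end, strand) fragments per locus (default 20).
    """

    min_quality: int = 30
    max_duplicates: int = 20

    def __post_init__(self):
        if self.min_quality < 0 or self.max_duplicates < 0:
            raise ValidationError("filter thresholds must be non-negative")


def empty_fragments() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str),
        "start": pd.Series(dtype=np.int64),
        "end": pd.Series(dtype=np.int64),
        "strand": pd.Series(dtype=str),
        "q1": pd.Series(dtype=np.int64),
        "q2": pd.Series(dtype=np.int64),
        "replicate": pd.Series(dtype=str),
    })


def validate_fragments(
    frags: pd.DataFrame, chrom_lengths: dict[str, int] | None = None
) -> None:
    """Raise ValidationError on malformed records."""
    missing = [c for c in FRAGMENT_COLUMNS if c not in frags.columns]
    if missing:
        raise ValidationError(f"fragment table missing columns: {missing}")
    if len(frags) == 0:
        return
    start = frags["start"].to_numpy()
    end = frags["end"].to_numpy()
    if (start < 0).any() or (end <= start).any():
        raise ValidationError("fragments must satisfy end > start >= 0")
    if (frags["q1"].to_numpy() < 0).any() or (frags["q2"].to_numpy() < 0).any():
        raise ValidationError("quality scores must be non-negative")
    if not frags["strand"].isin(["+", "-"]).all():
        raise ValidationError("strand must be '+' or '-'")
    if chrom_lengths is not None:
        for chrom, sub in frags.groupby("chrom", sort=False):
            if chrom not in chrom_lengths:
                raise ValidationError(f"unknown chromosome {chrom!r}")
            if (sub["end"].to_numpy() > chrom_lengths[chrom]).any():
                raise ValidationError(
                    f"fragment beyond end of chromosome {chrom!r}"
                )


def filter_by_quality(
    frags: pd.DataFrame, params: FilterParams | None = None
) -> pd.DataFrame:
    """Keep fragments where both end-read qualities are >= min_quality.

    The discard is disjunctive: one failing end is enough to drop the
    fragment. Order is preserved; the input is not mutated. Idempotent.
    """
    params = params or FilterParams()
    if len(frags) == 0:
        return frags.copy()
    if (frags["q1"].to_numpy() < 0).any() or (frags["q2"].to_numpy() < 0).any():
        raise ValidationError("quality scores must be non-negative")
    keep = (frags["q1"].to_numpy() >= params.min_quality) & (
        frags["q2"].to_numpy() >= params.min_quality
    )
    return frags.loc[keep].reset_index(drop=True)


def cap_duplicates(
    frags: pd.DataFrame, params: FilterParams | None = None
) -> pd.DataFrame:
    """Retain at most max_duplicates fragments per identical locus.

    A locus is the exact (chrom, start, end, strand) tuple; records
    beyond the cap are dropped deterministically, keeping first-seen
    file order. Idempotent.
    """
    params = params or FilterParams()
    if len(frags) == 0:
        return frags.copy()
    rank = frags.groupby(
        ["chrom", "start", "end", "strand"], sort=False
    ).cumcount()
    return frags.loc[rank.to_numpy() < params.max_duplicates].reset_index(drop=True)


def pool_replicates(
    replicate_sets: Iterable[pd.DataFrame],
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Concatenate replicate fragment sets; pooled size is the sum of inputs.

    When a chromosome-length table is supplied, every replicate is
    validated against it (inconsistent chromosome namespaces raise).
    """
    sets = list(replicate_sets)
    if not sets:
        return empty_fragments()
    if chrom_lengths is not None:
        for s in sets:
            validate_fragments(s, chrom_lengths)
    return pd.concat(sets, ignore_index=True)


def apply_filters(
    frags: pd.DataFrame, params: FilterParams | None = None
) -> pd.DataFrame:
    """Pipeline filter order: quality filter first, then duplicate cap."""
    return cap_duplicates(filter_by_quality(frags, params), params)


def iter_records(frags: pd.DataFrame):
    """Yield FragmentRecord row views (convenience for small tables)."""
    for row in frags.itertuples(index=False):
        yield FragmentRecord(
            row.chrom, int(row.start), int(row.end), row.strand,
            int(row.q1), int(row.q2), str(row.replicate),
        )
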