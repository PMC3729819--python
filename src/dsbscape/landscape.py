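"""Chromosome-scale in-hotspot coverage landscapes.

Signal fragments whose midpoints fall inside reference hotspot regions
are counted in fixed-width (default 1 Mb) bins per chromosome and
normalized to percent of the genome-wide in-region total, after masking
the first ``end_mask`` bp of each chromosome (mouse centromeric ends,
whose sequence is unavailable, default 3 Mb). Subtelomeric depletion is
quantified as the ratio of mean query/reference bin ratios in the
non-centromeric end bins versus interior bins, with a within-chromosome
circular-rotation permutation p-value. The PAR statistic is the percent
of genome-wide fragments whose midpoints fall inside the PAR cluster
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedResultError, ValidationError
from .hotspots import fragment_midpoints
from .intervals import points_in_intervals


@dataclass(frozen=True)
class ParDefinition:
    """The PAR hotspot-cluster interval (~40 kb at a chromosome end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValidationError("PAR interval must satisfy end > start >= 0")


@dataclass
class BinProfile:
    """Per-chromosome binned values as percent of total in-hotspot coverage.

    ``values[chrom]`` holds percents (NaN where masked); unmasked values
    sum to 100 across all chromosomes. ``counts`` keeps the raw in-region
    fragment counts behind the percentages.
    """

    bin_width: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray] = field(default_factory=dict)
    masked: dict[str, np.ndarray] = field(default_factory=dict)
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def total_percent(self) -> float:
        return float(sum(np.nansum(v) for v in self.values.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, v in self.values.items():
            for i in range(len(v)):
                rows.append((
                    chrom,
                    i * self.bin_width,
                    min((i + 1) * self.bin_width, self.chrom_lengths[chrom]),
                    v[i],
                    bool(self.masked[chrom][i]),
                ))
        return pd.DataFrame(
            rows, columns=["chrom", "bin_start", "bin_end", "percent", "masked"]
        )


def in_hotspot_window_profile(
    signal: pd.DataFrame,
    regions: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin: int = 1_000_000,
    end_mask: int = 3_000_000,
) -> BinProfile:
    """Percent of total in-region signal per fixed-width bin.

    Only signal fragments whose midpoints fall inside a reference region
    enter the numerator and denominator; bins starting within
    ``end_mask`` of the chromosome start (centromeric end) are masked and
    excluded from both.
    """
    if bin <= 0:
        raise ValidationError("bin width must be positive")
    profile = BinProfile(bin_width=bin, chrom_lengths=dict(chrom_lengths))
    mids = fragment_midpoints(signal) if len(signal) else np.zeros(0, dtype=np.int64)
    chroms = signal["chrom"].to_numpy() if len(signal) else np.array([], dtype=object)
    inside = points_in_intervals(chroms, mids, regions)
    for chrom, L in chrom_lengths.items():
        nbins = -(-L // bin)
        counts = np.zeros(nbins, dtype=np.int64)
        sel = inside & (chroms == chrom)
        if sel.any():
            counts = np.bincount(mids[sel] // bin, minlength=nbins)
        starts = np.arange(nbins, dtype=np.int64) * bin
        profile.counts[chrom] = counts
        profile.masked[chrom] = starts < end_mask
    total = sum(
        int(profile.counts[c][~profile.masked[c]].sum()) for c in chrom_lengths
    )
    if total == 0:
        raise UndefinedResultError("no in-region signal outside masked bins")
    for chrom in chrom_lengths:
        vals = 100.0 * profile.counts[chrom] / total
        vals[profile.masked[chrom]] = np.nan
        profile.values[chrom] = vals
    return profile


def _end_interior_split(
    profile: BinProfile, end_width: int
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-chromosome boolean index arrays: non-centromeric end bins vs
    interior bins (both over unmasked bins only)."""
    end_sel, int_sel = {}, {}
    for chrom, v in profile.values.items():
        L = profile.chrom_lengths[chrom]
        nbins = len(v)
        starts = np.arange(nbins, dtype=np.int64) * profile.bin_width
        ends = np.minimum(starts + profile.bin_width, L)
        unmasked = ~profile.masked[chrom]
        is_end = (ends > L - end_width) & unmasked
        end_sel[chrom] = is_end
        int_sel[chrom] = unmasked & ~is_end
    return end_sel, int_sel


def subtelomere_depletion_stat(
    profile_query: BinProfile,
    profile_reference: BinProfile,
    end_width: int = 5_000_000,
    n_permutations: int = 1_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Depletion ratio R and one-sided permutation p-value.

    R = mean(query/reference bin ratio over non-centromeric end bins) /
    mean(same over interior bins); R < 1 indicates end depletion of the
    query landscape relative to the reference. The null distribution
    comes from circular rotations of the per-bin ratios within each
    chromosome; p = P(R_perm <= R_observed) with add-one correction.
    """
    if (
        profile_query.bin_width != profile_reference.bin_width
        or profile_query.chrom_lengths != profile_reference.chrom_lengths
    ):
        raise ValidationError("profiles must share binning and chromosomes")
    end_sel, int_sel = _end_interior_split(profile_query, end_width)
    ratios, is_end = [], []
    for chrom in profile_query.values:
        q = profile_query.values[chrom]
        r = profile_reference.values[chrom]
        ok = (~profile_query.masked[chrom]) & np.isfinite(r) & (r > 0)
        usable = ok & (end_sel[chrom] | int_sel[chrom])
        if not usable.any():
            continue
        ratios.append((q[usable] / r[usable]))
        is_end.append(end_sel[chrom][usable])
    if not ratios:
        raise UndefinedResultError("no usable bins")
    flat_end = np.concatenate(is_end)
    if not flat_end.any() or flat_end.all():
        raise UndefinedResultError("need both end and interior bins after masking")

    def stat(ratio_list):
        num = np.concatenate([r[e] for r, e in zip(ratio_list, is_end)])
        den = np.concatenate([r[~e] for r, e in zip(ratio_list, is_end)])
        return float(num.mean() / den.mean())

    R = stat(ratios)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        rotated = [np.roll(r, int(rng.integers(len(r)))) for r in ratios]
        if stat(rotated) <= R:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return R, p


def par_cluster_fraction(frags: pd.DataFrame, par: ParDefinition) -> float:
    """Percent of genome-wide fragments with midpoint inside the PAR
    cluster interval, to two decimals (half-up)."""
    if len(frags) == 0:
        raise UndefinedResultError("empty fragment set")
    mids = fragment_midpoints(frags)
    sel = (
        (frags["chrom"].to_numpy() == par.chrom)
        & (mids >= par.start)
        & (mids < par.end)
    )
    from .intervals import percent

    return percent(int(sel.sum()), len(frags), decimals=2)
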