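"""Central-window overlap classification of hotspots.

Overlap calls are restricted to fixed-width windows centered on the
hotspot center: 400 nt for hotspot-hotspot comparisons, 1 kb for
hotspot-H3K4me3, 2 kb for hotspot-motif. A hotspot "overlaps" a set when
its central window intersects (>= 1 bp) the central window of any
element; motif sites are used as raw 17-bp intervals against the
hotspot's central 2 kb. Each query hotspot is counted once regardless of
how many subjects it touches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedResultError, ValidationError
from .intervals import overlaps_any, percent


@dataclass(frozen=True)
class OverlapParams:
    """Central-window widths (bp) for each comparison type."""

    hotspot_window: int = 400     # hotspot vs hotspot
    h3k4me3_window: int = 1_000   # hotspot vs H3K4me3 peak
    motif_window: int = 2_000     # hotspot vs motif site (site used raw)
    tss_window: int = 2_000       # TSS expanded to a +-1 kb interval

    def __post_init__(self):
        for w in (self.hotspot_window, self.h3k4me3_window,
                  self.motif_window, self.tss_window):
            if w <= 0 or w % 2:
                raise ValidationError("windows must be positive even integers")


def interval_centers(intervals: pd.DataFrame) -> np.ndarray:
    """Explicit ``center`` column if present, else floor((start+end)/2)."""
    if "center" in intervals.columns:
        return intervals["center"].to_numpy(dtype=np.int64)
    return (
        intervals["start"].to_numpy(np.int64) + intervals["end"].to_numpy(np.int64)
    ) // 2


def central_window(
    intervals: pd.DataFrame,
    width: int,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """[center - width/2, center + width/2) per interval, clipped to the
    chromosome (never to the interval itself: the window may exceed a
    narrow interval)."""
    if width <= 0:
        raise ValidationError("window width must be positive")
    if width == 0 or len(intervals) == 0:
        return intervals[["chrom", "start", "end"]].copy()
    centers = interval_centers(intervals)
    starts = centers - width // 2
    ends = centers + width // 2
    starts = np.maximum(starts, 0)
    if chrom_lengths is not None:
        lens = intervals["chrom"].map(chrom_lengths).to_numpy(dtype=np.int64)
        ends = np.minimum(ends, lens)
    return pd.DataFrame({
        "chrom": intervals["chrom"].to_numpy(),
        "start": starts,
        "end": ends,
    })


def _windowed(intervals: pd.DataFrame, width: int,
              chrom_lengths: dict[str, int] | None) -> pd.DataFrame:
    if width == 0:
        return intervals[["chrom", "start", "end"]]
    return central_window(intervals, width, chrom_lengths)


def overlap_flags(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    window_a: int,
    window_b: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> np.ndarray:
    """Boolean per element of A: central window (window_a) intersects the
    central window of any element of B (window_b; 0 = raw interval)."""
    if len(set_a) == 0:
        return np.zeros(0, dtype=bool)
    if len(set_b) == 0:
        return np.zeros(len(set_a), dtype=bool)
    return overlaps_any(
        _windowed(set_a, window_a, chrom_lengths),
        _windowed(set_b, window_b, chrom_lengths),
    )


def overlap_fraction(
    set_a: pd.DataFrame,
    set_b: pd.DataFrame,
    window_a: int,
    window_b: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[int, int, float]:
    """(n_overlapping, n_total, percent to one decimal, half-up)."""
    flags = overlap_flags(set_a, set_b, window_a, window_b, chrom_lengths)
    n = int(flags.sum())
    total = len(set_a)
    return n, total, percent(n, total) if total else 0.0


def classify_hotspots(
    query: pd.DataFrame,
    reference: pd.DataFrame | None = None,
    motifs: pd.DataFrame | None = None,
    h3k4me3: pd.DataFrame | None = None,
    tss: pd.DataFrame | None = None,
    params: OverlapParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-hotspot overlap flags against each annotation set.

    Returns the query table with boolean columns ``shared`` (present in
    the reference hotspot set, central 400 nt), ``has_motif`` (motif site
    within the central 2 kb), ``h3k4me3`` (central 1 kb vs peak central
    1 kb) and ``tss`` (central 1 kb vs TSS point expanded +-1 kb).
    Category counts (shared & motif, specific & motif, ...) are derivable
    from the flags and partition correctly.
    """
    params = params or OverlapParams()
    out = query.copy().reset_index(drop=True)
    n = len(out)

    def flags(subject, wa, wb):
        if subject is None or len(subject) == 0:
            return np.zeros(n, dtype=bool)
        return overlap_flags(out, subject, wa, wb, chrom_lengths)

    out["shared"] = flags(reference, params.hotspot_window, params.hotspot_window)
    out["has_motif"] = flags(motifs, params.motif_window, 0)
    out["h3k4me3"] = flags(h3k4me3, params.h3k4me3_window, params.h3k4me3_window)
    if tss is not None and len(tss):
        pts = interval_centers(tss)
        tss_iv = pd.DataFrame({
            "chrom": tss["chrom"].to_numpy(),
            "start": np.maximum(pts - params.tss_window // 2, 0),
            "end": pts + params.tss_window // 2,
        })
        out["tss"] = overlap_flags(out, tss_iv, params.h3k4me3_window, 0, chrom_lengths)
    else:
        out["tss"] = np.zeros(n, dtype=bool)
    return out


def classification_summary(classified: pd.DataFrame) -> dict:
    """Counts of the Table-1-style categories from per-hotspot flags."""
    shared = classified["shared"].to_numpy()
    motif = classified["has_motif"].to_numpy()
    n = len(classified)
    return {
        "n_hotspots": n,
        "n_motif": int(motif.sum()),
        "pct_motif": percent(int(motif.sum()), n) if n else None,
        "n_shared": int(shared.sum()),
        "pct_shared": percent(int(shared.sum()), n) if n else None,
        "n_shared_motif": int((shared & motif).sum()),
        "n_specific_motif": int((~shared & motif).sum()),
        "n_specific_h3k4me3": int((~shared & classified["h3k4me3"]).sum()),
        "n_specific_tss": int((~shared & classified["tss"]).sum()),
    }


def strength_correlation(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    params: OverlapParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> float:
    """Spearman rho of log10 strength over shared hotspot pairs.

    Query hotspots are matched to reference hotspots whose central
    400-nt windows intersect; among multiple candidates the reference
    with the closest center wins. Requires >= 3 matched pairs.
    """
    params = params or OverlapParams()
    if len(query) == 0 or len(reference) == 0:
        raise UndefinedResultError("need non-empty hotspot sets")
    half = params.hotspot_window // 2
    qc = interval_centers(query)
    rc = interval_centers(reference)
    rstr = reference["strength"].to_numpy(dtype=float)
    pairs_q, pairs_r = [], []
    for chrom in np.unique(query["chrom"].to_numpy()):
        qsel = np.flatnonzero(query["chrom"].to_numpy() == chrom)
        rsel = np.flatnonzero(reference["chrom"].to_numpy() == chrom)
        if rsel.size == 0:
            continue
        rcent = np.sort(rc[rsel])
        order = np.argsort(rc[rsel], kind="stable")
        rstr_sorted = rstr[rsel][order]
        for qi in qsel:
            # windows intersect iff |center difference| < hotspot_window
            j = np.searchsorted(rcent, qc[qi])
            best, bestd = -1, None
            for k in (j - 1, j):
                if 0 <= k < len(rcent):
                    d = abs(int(rcent[k]) - int(qc[qi]))
                    if d < 2 * half and (bestd is None or d < bestd):
                        best, bestd = k, d
            if best >= 0:
                pairs_q.append(float(query["strength"].iloc[qi]))
                pairs_r.append(float(rstr_sorted[best]))
    if len(pairs_q) < 3:
        raise UndefinedResultError("fewer than 3 shared hotspot pairs")
    rho = stats.spearmanr(np.log10(pairs_q), np.log10(pairs_r)).statistic
    return float(rho)


def motif_center_profile(
    hotspots: pd.DataFrame,
    sites: pd.DataFrame,
    halfwidth: int = 2_500,
    bin: int = 50,
) -> pd.DataFrame:
    """Mean motif-site base coverage per offset bin around hotspot centers.

    For each hotspot, motif-site base pairs falling at offsets in
    [-halfwidth, +halfwidth) relative to the hotspot center are
    accumulated into fixed-width bins; values are per-hotspot means
    (base pairs of site coverage per hotspot per bin).
    """
    if len(hotspots) == 0:
        raise ValidationError("need a non-empty hotspot set")
    nbins = (2 * halfwidth) // bin
    offsets = np.arange(nbins) * bin - halfwidth
    acc = np.zeros(nbins, dtype=float)
    centers = interval_centers(hotspots)
    hchrom = hotspots["chrom"].to_numpy()
    for chrom in np.unique(hchrom):
        sub = sites.loc[sites["chrom"] == chrom] if len(sites) else sites
        if sub is None or len(sub) == 0:
            continue
        raw_start = sub["start"].to_numpy(np.int64)
        raw_end = sub["end"].to_numpy(np.int64)
        max_len = int((raw_end - raw_start).max())
        order = np.argsort(raw_start, kind="stable")
        s_start = raw_start[order]
        s_end = raw_end[order]
        for c in centers[hchrom == chrom]:
            lo = np.searchsorted(s_start, c - halfwidth - max_len)
            hi = np.searchsorted(s_start, c + halfwidth)
            for ss, se in zip(s_start[lo:hi], s_end[lo:hi]):
                a = max(int(ss) - int(c), -halfwidth)
                b = min(int(se) - int(c), halfwidth)
                if a >= b:
                    continue
                first = (a + halfwidth) // bin
                last = (b - 1 + halfwidth) // bin
                for bi in range(first, last + 1):
                    blo = bi * bin - halfwidth
                    acc[bi] += min(b, blo + bin) - max(a, blo)
    return pd.DataFrame({
        "offset": offsets,
        "coverage": acc / len(hotspots),
    })
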