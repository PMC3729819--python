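"""DSB hotspot calling from filtered, pooled ssDNA fragments.

The caller scores sliding windows of fragment-midpoint counts against a
Poisson null whose rate is the larger of the local flanking background
and the genome-wide background, applies Benjamini-Hochberg FDR control
across all candidate windows, merges significant windows separated by at
most ``merge_gap``, and reports each merged interval as a hotspot with

* ``strength``: the number of fragment midpoints inside the interval
  (the ssDNA fragment count assigned to the hotspot);
* ``center``: the floor of the mean midpoint of those fragments;
* ``qvalue``: the smallest adjusted p-value among member windows.

Output hotspots within a sample are pairwise disjoint and deterministic
for fixed input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

HOTSPOT_COLUMNS = ["chrom", "start", "end", "center", "strength", "qvalue"]


@dataclass(frozen=True)
class CallerParams:
    window: int = 1_000        # sliding window width, bp
    step: int = 100            # window step, bp
    flank: int = 10_000        # local-background flank on each side, bp
    fdr: float = 0.05          # Benjamini-Hochberg level
    merge_gap: int = 200       # merge significant windows closer than this
    min_fragments: int = 5     # minimum window count to be a candidate

    def __post_init__(self):
        if min(self.window, self.step, self.flank, self.merge_gap) <= 0:
            raise ValidationError("window, step, flank and merge gap must be positive")
        if not 0 < self.fdr < 1:
            raise ValidationError("FDR level must lie in (0, 1)")
        if self.min_fragments < 1:
            raise ValidationError("min_fragments must be >= 1")
        if self.window % self.step:
            raise ValidationError("window must be a multiple of step")


def empty_hotspots() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str),
        "start": pd.Series(dtype=np.int64),
        "end": pd.Series(dtype=np.int64),
        "center": pd.Series(dtype=np.int64),
        "strength": pd.Series(dtype=np.int64),
        "qvalue": pd.Series(dtype=float),
    })


def fragment_midpoints(frags: pd.DataFrame) -> np.ndarray:
    return (frags["start"].to_numpy(np.int64) + frags["end"].to_numpy(np.int64)) // 2


def compute_coverage(
    frags: pd.DataFrame, chrom_lengths: dict[str, int], bin: int = 100
) -> dict[str, np.ndarray]:
    """Per-bin fragment-midpoint counts; bin counts sum to the input size."""
    if bin <= 0:
        raise ValidationError("bin width must be positive")
    cov = {
        chrom: np.zeros(-(-L // bin), dtype=np.int64)
        for chrom, L in chrom_lengths.items()
    }
    if len(frags) == 0:
        return cov
    mids = fragment_midpoints(frags)
    chroms = frags["chrom"].to_numpy()
    for chrom in cov:
        sel = chroms == chrom
        if not sel.any():
            continue
        m = mids[sel]
        if (m < 0).any() or (m >= chrom_lengths[chrom]).any():
            raise ValidationError(f"fragment beyond length of chromosome {chrom!r}")
        cov[chrom] = np.bincount(m // bin, minlength=len(cov[chrom]))
    unknown = set(np.unique(chroms)) - set(cov)
    if unknown:
        raise ValidationError(f"fragments on unknown chromosomes: {sorted(unknown)}")
    return cov


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adj = np.empty(n)
    adj[order] = pvals[order] * n / np.arange(1, n + 1)
    adj[order] = np.minimum.accumulate(adj[order][::-1])[::-1]
    return np.minimum(adj, 1.0)


def call_hotspots(
    frags: pd.DataFrame,
    chrom_lengths: dict[str, int],
    params: CallerParams | None = None,
) -> pd.DataFrame:
    """Call hotspots from filtered, pooled fragments.

    Windows of width ``params.window`` advance by ``params.step``; each
    candidate window (count >= min_fragments) gets a Poisson upper-tail
    p-value against max(local flank rate, genome-wide rate) x window.
    Candidates passing BH-FDR are merged when their gap <= merge_gap.
    """
    params = params or CallerParams()
    if len(frags) == 0:
        return empty_hotspots()
    step, window = params.step, params.window
    wbins = window // step
    cov = compute_coverage(frags, chrom_lengths, bin=step)
    genome_len = sum(chrom_lengths.values())
    genome_rate = len(frags) / genome_len  # fragments per bp

    cand_chrom, cand_pos, cand_count, cand_p = [], [], [], []
    for chrom, c in cov.items():
        nb = len(c)
        if nb < wbins or c.sum() == 0:
            continue
        csum = np.concatenate([[0], np.cumsum(c)])
        # window i covers bins [i, i+wbins), i.e. bp [i*step, i*step+window)
        wcount = csum[wbins:] - csum[:-wbins]
        nwin = len(wcount)
        fb = max(params.flank // step, 1)
        i = np.arange(nwin)
        lo = np.maximum(i - fb, 0)
        hi = np.minimum(i + wbins + fb, nb)
        flank_count = (csum[hi] - csum[lo]) - wcount
        flank_bins = (hi - lo) - wbins
        local_rate = flank_count / (flank_bins * step)  # per bp
        lam = np.maximum(local_rate, genome_rate) * window
        sel = wcount >= params.min_fragments
        if not sel.any():
            continue
        p = stats.poisson.sf(wcount[sel] - 1, lam[sel])
        cand_chrom.append(np.full(int(sel.sum()), chrom, dtype=object))
        cand_pos.append(i[sel] * step)
        cand_count.append(wcount[sel])
        cand_p.append(p)

    if not cand_p:
        return empty_hotspots()
    chroms = np.concatenate(cand_chrom)
    pos = np.concatenate(cand_pos)
    pvals = np.concatenate(cand_p)
    qvals = _bh_adjust(pvals)
    sig = qvals <= params.fdr
    if not sig.any():
        return empty_hotspots()

    mids_all = fragment_midpoints(frags)
    frag_chroms = frags["chrom"].to_numpy()
    rows = []
    for chrom in cov:
        csel = sig & (chroms == chrom)
        if not csel.any():
            continue
        starts = np.sort(pos[csel])
        q_by_start = dict(zip(pos[csel], qvals[csel]))
        ends = np.minimum(starts + window, chrom_lengths[chrom])
        # merge windows with gap <= merge_gap
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and s - merged[-1][1] <= params.merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = min(merged[-1][2], q_by_start[s])
            else:
                merged.append([int(s), int(e), q_by_start[s]])
        m = np.sort(mids_all[frag_chroms == chrom])
        for s, e, q in merged:
            lo_i, hi_i = np.searchsorted(m, [s, e])
            inside = m[lo_i:hi_i]
            strength = len(inside)
            center = int(inside.mean()) if strength else (s + e) // 2
            rows.append((chrom, s, e, center, strength, float(q)))
    if not rows:
        return empty_hotspots()
    out = pd.DataFrame(rows, columns=HOTSPOT_COLUMNS)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def rank_and_truncate(hotspots: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-n hotspots by descending strength; ties broken by (chrom, start)."""
    if n < 0:
        raise ValidationError("n must be non-negative")
    ordered = hotspots.sort_values(
        ["strength", "chrom", "start"],
        ascending=[False, True, True],
        kind="stable",
    )
    return ordered.head(n).reset_index(drop=True)
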