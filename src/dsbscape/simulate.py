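"""Synthetic genomes, planted truth sets and ssDNA fragment datasets.

The generator emulates the statistical structure of DMC1 SSDS data so
every downstream stage can be exercised against known ground truth:

* hotspots with heavy-tailed (Pareto) strengths whose fragments cluster
  around the hotspot center with truncated-Gaussian offsets;
* uniform background fragments;
* PCR-style duplicates (exact coordinate/strand copies, geometric
  multiplicity) carrying independently drawn per-end quality scores with
  a configurable low-quality tail;
* a minority of hotspots centered on planted Gal4 consensus sites
  (CGGN11CCG written into the sequence at the hotspot center);
* a ~40 kb PAR-like cluster of overlapping hotspots at one chromosome
  end, simulated as 20 evenly spaced hotspots sharing a total strength;
* condition-specific multiplicative suppression of hotspot strength
  near chromosome ends (subtelomeric depletion).

Matching H3K4me3 tag data is generated at every planted hotspot with no
subtelomeric suppression, so the dissociation between the DSB and
H3K4me3 chromosomal landscapes can be reproduced.

Base composition is i.i.d. uniform A/C/G/T, which makes the analytic
motif-count null exact. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SizingError, ValidationError
from .fragments import empty_fragments
from .motifs import GAL4_PATTERN, ConsensusPattern, scan_sequence

_PATTERN_LEN = len(GAL4_PATTERN)
# offsets of the fixed (non-N) positions within the Gal4 pattern
_FIXED_OFFSETS = [i for i, c in enumerate(GAL4_PATTERN) if c != "N"]


@dataclass(frozen=True)
class ParSpec:
    """A PAR-like cluster of overlapping hotspots at a chromosome end."""

    chrom: str
    start: int
    width: int = 40_000
    total_strength: float = 400.0
    n_hotspots: int = 20


_DEFAULT_PAR = ParSpec(
    chrom="chr4", start=19_950_000, width=40_000, total_strength=300.0
)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic dataset.

    Strengths are expected fragment counts at unit condition efficiency.
    ``subtelomere_factor`` is the multiplicative suppression applied (in
    conditions that enable it) to hotspots whose center lies within
    ``subtelomere_end_width`` of a chromosome end.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 20_000_000 for i in range(1, 5)}
    )
    n_hotspots: int = 100              # per chromosome
    strength_shape: float = 1.5        # Pareto tail index (heavy-tailed)
    strength_scale: float = 30.0       # minimum hotspot strength
    fragment_dispersion: int = 500     # sigma of center offsets, bp
    fragment_length_mean: int = 300
    fragment_length_sd: int = 60
    background_per_mb: float = 30.0    # background fragments per Mb
    duplicate_rate: float = 0.2        # expected extra copies per fragment
    low_quality_fraction: float = 0.15  # per-end chance of a q<30 score
    gal4_fraction: float = 0.04        # fraction of hotspots on Gal4 sites
    gal4_jitter: int = 0               # bp jitter of site midpoint vs center
    # a ~40 kb cluster of 20 overlapping hotspots at the end of the last
    # default chromosome; the default is dropped automatically when a
    # custom genome cannot host it (pass None to disable explicitly)
    par: ParSpec | None = field(default_factory=lambda: _DEFAULT_PAR)
    subtelomere_end_width: int = 5_000_000
    subtelomere_factor: float = 0.2
    min_hotspot_separation: int = 3_000
    reject_accidental_sites: bool = False  # scrub chance Gal4 matches near
    #                                        non-flagged hotspot centers (+-1 kb)
    seed: int = 0

    def __post_init__(self):
        if not self.chrom_lengths or any(
            length <= 0 for length in self.chrom_lengths.values()
        ):
            raise ValidationError("chromosome lengths must be positive")
        if self.n_hotspots < 0 or self.strength_scale <= 0 or self.strength_shape <= 0:
            raise ValidationError("hotspot counts and strength law must be positive")
        if not 0 < self.subtelomere_factor <= 1:
            raise ValidationError("subtelomere factor must lie in (0, 1]")
        if not 0 <= self.gal4_fraction <= 1:
            raise ValidationError("gal4 fraction must lie in [0, 1]")
        if not 0 <= self.low_quality_fraction <= 1:
            raise ValidationError("low-quality fraction must lie in [0, 1]")
        if self.duplicate_rate < 0:
            raise ValidationError("duplicate rate must be non-negative")
        if self.par is _DEFAULT_PAR and (
            self.par.chrom not in self.chrom_lengths
            or self.par.start + self.par.width
            > self.chrom_lengths[self.par.chrom]
        ):
            object.__setattr__(self, "par", None)
        if self.par is not None:
            if self.par.chrom not in self.chrom_lengths:
                raise ValidationError("PAR chromosome not in genome")
            if not (
                0 <= self.par.start
                and self.par.start + self.par.width
                <= self.chrom_lengths[self.par.chrom]
            ):
                raise ValidationError("PAR interval must lie inside its chromosome")


@dataclass(frozen=True)
class ConditionParams:
    """Per-condition multipliers applied to planted hotspot strengths.

    efficiency scales everything including background (sequencing depth
    proxy); signal_factor scales every hotspot but not background;
    subtelomere_factor applies only to hotspots near chromosome ends;
    par_factor only to hotspots inside the PAR cluster; gal4_factor only
    to Gal4-flagged hotspots (0 removes them, as in a strain whose
    targeting protein lacks the Gal4 DNA-binding domain).
    """

    name: str = "sample"
    efficiency: float = 1.0
    signal_factor: float = 1.0
    subtelomere_factor: float = 1.0
    par_factor: float = 1.0
    gal4_factor: float = 1.0


@dataclass
class TruthSet:
    """Planted ground truth for parameter-recovery tests.

    hotspots: DataFrame (chrom, center, strength, has_gal4, in_par);
    motif_sites: DataFrame (chrom, start, end) of planted Gal4 sites,
    with midpoint at the hotspot center (+- configured jitter);
    par: the PAR interval, if any.
    """

    hotspots: pd.DataFrame
    motif_sites: pd.DataFrame
    par: ParSpec | None = None

    def expected_fragments(self, config: SimConfig, condition: ConditionParams) -> np.ndarray:
        """Per-hotspot Poisson mean under a condition (no background)."""
        return hotspot_means(self.hotspots, config, condition)


def hotspot_means(
    hotspots: pd.DataFrame, config: SimConfig, condition: ConditionParams
) -> np.ndarray:
    """Expected fragment count per hotspot under a condition."""
    if len(hotspots) == 0:
        return np.zeros(0, dtype=float)
    mean = (
        hotspots["strength"].to_numpy(dtype=float)
        * condition.efficiency
        * condition.signal_factor
    )
    lengths = hotspots["chrom"].map(config.chrom_lengths).to_numpy(dtype=np.int64)
    centers = hotspots["center"].to_numpy(dtype=np.int64)
    near = (centers < config.subtelomere_end_width) | (
        centers >= lengths - config.subtelomere_end_width
    )
    mean[near] *= condition.subtelomere_factor
    mean[hotspots["in_par"].to_numpy()] *= condition.par_factor
    mean[hotspots["has_gal4"].to_numpy()] *= condition.gal4_factor
    return mean


def plant_truth(config: SimConfig) -> TruthSet:
    """Draw hotspot positions, strengths and flags (no sequence needed).

    Hotspot centers are uniform with a minimum pairwise separation (so
    planted peaks are resolvable); strengths follow a shifted Pareto law;
    a fixed fraction of hotspots (rounded) is flagged to carry a Gal4
    consensus site at its center. PAR hotspots are added on top of the
    per-chromosome count.
    """
    rng = np.random.default_rng(config.seed)
    margin = 3 * config.fragment_dispersion + 2_000
    rows = []
    for chrom in config.chrom_lengths:
        L = config.chrom_lengths[chrom]
        n = config.n_hotspots
        if n == 0:
            continue
        # spacing transform: sorted uniforms in a shrunken range plus an
        # arithmetic offset guarantee the minimum pairwise separation
        sep = config.min_hotspot_separation
        hi = L - margin - (n - 1) * sep
        if hi <= margin:
            raise SizingError(
                f"chromosome {chrom!r} ({L} bp) too short for {n} hotspots"
            )
        centers = np.sort(rng.integers(margin, hi, size=n))
        centers = centers + np.arange(n, dtype=np.int64) * sep
        strengths = config.strength_scale * (
            1.0 + rng.pareto(config.strength_shape, size=n)
        )
        has_gal4 = np.zeros(n, dtype=bool)
        k = int(round(config.gal4_fraction * n))
        if k > 0:
            has_gal4[rng.choice(n, size=k, replace=False)] = True
        for c, s, g in zip(centers, strengths, has_gal4):
            rows.append((chrom, int(c), float(s), bool(g), False))
    if config.par is not None:
        par = config.par
        spacing = par.width / par.n_hotspots
        for i in range(par.n_hotspots):
            c = int(par.start + (i + 0.5) * spacing)
            rows.append(
                (par.chrom, c, par.total_strength / par.n_hotspots, False, True)
            )
    hotspots = pd.DataFrame(
        rows, columns=["chrom", "center", "strength", "has_gal4", "in_par"]
    )
    # planted Gal4 sites: 17-bp interval whose midpoint is the hotspot center
    sites = []
    for row in hotspots.loc[hotspots["has_gal4"]].itertuples(index=False):
        jitter = (
            int(rng.integers(-config.gal4_jitter, config.gal4_jitter + 1))
            if config.gal4_jitter
            else 0
        )
        start = row.center + jitter - _PATTERN_LEN // 2
        sites.append((row.chrom, start, start + _PATTERN_LEN))
    motif_sites = pd.DataFrame(sites, columns=["chrom", "start", "end"])
    return TruthSet(hotspots=hotspots, motif_sites=motif_sites, par=config.par)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def generate_genome(config: SimConfig) -> tuple[dict[str, str], TruthSet]:
    """Synthesize an i.i.d. uniform-base genome with planted Gal4 sites.

    Returns the genome (chromosome name -> sequence) and the TruthSet.
    Guarantees: every flagged truth position carries an exact CGGN11CCG
    match; no accidental second match collides inside a planted site
    (colliding chance matches are scrubbed by mutating one fixed position
    outside the planted interval). With ``reject_accidental_sites`` set,
    chance matches within +-1 kb of non-flagged hotspot centers are
    scrubbed the same way.
    """
    truth = plant_truth(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    pattern = ConsensusPattern()
    genome: dict[str, str] = {}
    for chrom, length in config.chrom_lengths.items():
        arr = _random_sequence(rng, length)
        planted = truth.motif_sites.loc[truth.motif_sites["chrom"] == chrom]
        for site in planted.itertuples(index=False):
            if site.start < 0 or site.end > length:
                raise SizingError(f"planted site outside chromosome {chrom!r}")
            # write the fixed positions; the 11 N positions stay random
            for off in _FIXED_OFFSETS:
                arr[site.start + off] = ord(GAL4_PATTERN[off])
        _scrub_collisions(arr, planted, pattern)
        if config.reject_accidental_sites:
            centers = truth.hotspots.loc[
                (truth.hotspots["chrom"] == chrom)
                & ~truth.hotspots["has_gal4"],
                "center",
            ].to_numpy()
            _scrub_windows(arr, centers, planted, pattern)
        genome[chrom] = arr.tobytes().decode("ascii")
    return genome, truth


def _scrub_match(arr: np.ndarray, start: int, keep: pd.DataFrame) -> None:
    """Destroy the match at ``start`` by mutating one fixed position that
    lies outside every interval in ``keep``."""
    keep_iv = list(zip(keep["start"], keep["end"]))
    for off in _FIXED_OFFSETS:
        pos = start + off
        if all(not (s <= pos < e) for s, e in keep_iv):
            arr[pos] = ord("T") if arr[pos] in (ord("C"), ord("G")) else ord("A")
            return
    raise RuntimeError("no scrubbable position outside planted sites")


def _scrub_collisions(
    arr: np.ndarray, planted: pd.DataFrame, pattern: ConsensusPattern
) -> None:
    """Remove chance matches that overlap a planted site interval."""
    if len(planted) == 0:
        return
    planted_starts = set(planted["start"].tolist())
    for _ in range(10):
        dirty = False
        for site in planted.itertuples(index=False):
            lo = max(0, site.start - _PATTERN_LEN + 1)
            hi = min(len(arr), site.end + _PATTERN_LEN - 1)
            seq = arr[lo:hi].tobytes().decode("ascii")
            for s in scan_sequence(seq, pattern):
                g = lo + int(s)
                if g != site.start and g < site.end and g + _PATTERN_LEN > site.start:
                    _scrub_match(arr, g, planted)
                    dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub colliding matches")


def _scrub_windows(
    arr: np.ndarray,
    centers: np.ndarray,
    planted: pd.DataFrame,
    pattern: ConsensusPattern,
    halfwidth: int = 1_000,
) -> None:
    """Remove every chance match within +-halfwidth of the given centers."""
    for _ in range(10):
        dirty = False
        for c in centers:
            lo = max(0, int(c) - halfwidth)
            hi = min(len(arr), int(c) + halfwidth)
            seq = arr[lo:hi].tobytes().decode("ascii")
            for s in scan_sequence(seq, pattern):
                _scrub_match(arr, lo + int(s), planted)
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not scrub window matches")


def _draw_qualities(
    rng: np.random.Generator, n: int, low_fraction: float
) -> np.ndarray:
    """Integer 0-60 quality scores: uniform 30-60 with a 0-29 low tail."""
    low = rng.random(n) < low_fraction
    q = rng.integers(30, 61, size=n)
    n_low = int(low.sum())
    if n_low:
        q[low] = rng.integers(0, 30, size=n_low)
    return q


def simulate_fragments(
    config: SimConfig,
    truth: TruthSet,
    condition: ConditionParams | None = None,
    seed: int = 0,
    replicate: str = "rep1",
) -> tuple[pd.DataFrame, dict]:
    """Draw one SSDS fragment dataset for a condition.

    Per hotspot the fragment count is Poisson with mean
    strength x condition multipliers; fragment centers are the hotspot
    center plus Gaussian noise truncated at +-3 sigma; background
    fragments are uniform over chromosomes at ``background_per_mb`` x
    efficiency; each distinct fragment is emitted with geometric
    multiplicity (mean 1 + duplicate_rate) as exact coordinate/strand
    copies; every emitted fragment carries two independently drawn
    quality scores. Fragments are clipped to chromosome bounds.

    Returns (fragments, bookkeeping); bookkeeping records the per-hotspot
    draws so fragment-count conservation can be asserted:
    n_distinct == n_background + sum(hotspot_draws), and
    n_emitted == len(fragments).
    """
    condition = condition or ConditionParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    hs = truth.hotspots
    means = hotspot_means(hs, config, condition)
    draws = rng.poisson(means)
    total_sig = int(draws.sum())

    chroms_sig = np.repeat(hs["chrom"].to_numpy(), draws)
    centers_sig = np.repeat(hs["center"].to_numpy(dtype=np.int64), draws)
    if total_sig:
        offsets = stats.truncnorm.rvs(
            -3, 3, scale=config.fragment_dispersion, size=total_sig,
            random_state=rng,
        )
        mids_sig = centers_sig + np.rint(offsets).astype(np.int64)
    else:
        mids_sig = centers_sig

    # background, uniform per chromosome
    bg_chroms, bg_mids = [], []
    for chrom, L in config.chrom_lengths.items():
        lam = config.background_per_mb * condition.efficiency * L / 1e6
        n_bg = int(rng.poisson(lam))
        if n_bg:
            bg_chroms.append(np.full(n_bg, chrom, dtype=object))
            bg_mids.append(rng.integers(0, L, size=n_bg))
    n_background = int(sum(len(a) for a in bg_mids))
    chroms = np.concatenate([chroms_sig] + bg_chroms) if bg_chroms else chroms_sig
    mids = np.concatenate([mids_sig] + bg_mids) if bg_mids else mids_sig

    n_distinct = len(mids)
    if n_distinct == 0:
        return empty_fragments(), {
            "hotspot_draws": draws, "n_background": 0,
            "n_distinct": 0, "n_emitted": 0,
        }

    lengths = np.rint(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, n_distinct)
    ).astype(np.int64)
    lengths = np.maximum(lengths, 50)
    starts = mids - lengths // 2
    ends = starts + lengths
    # clip to chromosome bounds
    chrlen = np.array([config.chrom_lengths[c] for c in chroms], dtype=np.int64)
    starts = np.clip(starts, 0, None)
    ends = np.minimum(ends, chrlen)
    starts = np.minimum(starts, ends - 1)  # keep end > start
    strands = np.where(rng.random(n_distinct) < 0.5, "+", "-")

    # duplicate multiplicity ~ geometric on {1,2,...} with mean 1+rate
    if config.duplicate_rate > 0:
        mult = rng.geometric(1.0 / (1.0 + config.duplicate_rate), size=n_distinct)
    else:
        mult = np.ones(n_distinct, dtype=np.int64)
    n_emitted = int(mult.sum())
    rep = np.repeat
    frags = pd.DataFrame({
        "chrom": rep(chroms, mult),
        "start": rep(starts, mult),
        "end": rep(ends, mult),
        "strand": rep(strands, mult),
        "q1": _draw_qualities(rng, n_emitted, config.low_quality_fraction),
        "q2": _draw_qualities(rng, n_emitted, config.low_quality_fraction),
        "replicate": replicate,
    })
    bookkeeping = {
        "hotspot_draws": draws,
        "n_background": n_background,
        "n_distinct": n_distinct,
        "n_emitted": n_emitted,
    }
    return frags, bookkeeping


def simulate_h3k4me3_tags(
    truth: TruthSet,
    seed: int = 0,
    tags_per_strength: float = 1.0,
    dispersion: int = 300,
    tag_length: int = 50,
    peak_halfwidth: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """H3K4me3 tags clustered at every planted hotspot, plus peak calls.

    Tag counts are Poisson in the *true* hotspot strength with no
    subtelomeric or PAR suppression — the chromatin mark is deposited
    whether or not breaks form there — so DSB and H3K4me3 landscapes can
    dissociate. Background is disabled: zero hotspots yield zero tags.

    Returns (tags, peaks): tags share the fragment-table schema (q=60);
    peaks are center +- peak_halfwidth intervals (one per hotspot).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    hs = truth.hotspots
    if len(hs) == 0:
        return empty_fragments(), pd.DataFrame({"chrom": [], "start": [], "end": []})
    counts = rng.poisson(tags_per_strength * hs["strength"].to_numpy())
    total = int(counts.sum())
    chroms = np.repeat(hs["chrom"].to_numpy(), counts)
    centers = np.repeat(hs["center"].to_numpy(dtype=np.int64), counts)
    if total:
        offsets = stats.truncnorm.rvs(
            -3, 3, scale=dispersion, size=total, random_state=rng
        )
        mids = centers + np.rint(offsets).astype(np.int64)
    else:
        mids = centers
    starts = np.maximum(mids - tag_length // 2, 0)
    tags = pd.DataFrame({
        "chrom": chroms,
        "start": starts,
        "end": starts + tag_length,
        "strand": np.where(rng.random(total) < 0.5, "+", "-"),
        "q1": np.full(total, 60, dtype=np.int64),
        "q2": np.full(total, 60, dtype=np.int64),
        "replicate": "h3k4me3",
    })
    peaks = pd.DataFrame({
        "chrom": hs["chrom"],
        "start": np.maximum(hs["center"].to_numpy() - peak_halfwidth, 0),
        "end": hs["center"].to_numpy() + peak_halfwidth,
    })
    return tags, peaks
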