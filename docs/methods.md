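# Methods

## Data model

The pipeline operates on aligned ssDNA fragment records — the output of
an SSDS (DMC1 ChIP + single-stranded DNA sequencing) experiment after
read alignment and ssDNA identification, which are upstream of this
package. A fragment is `(chrom, start, end, strand, q1, q2, replicate)`
with 0-based half-open coordinates; `q1`/`q2` are the quality scores of
the two end reads the fragment derives from, treated as opaque
non-negative integers. Fragment collections are pandas DataFrames;
hotspots, motif sites and peaks are interval DataFrames.

## Fragment filters

Two filters run before any analysis, in this order:

1. **Quality** — a fragment is discarded when *either* end read has
   quality strictly below `min_quality` (default 30). The disjunctive
   form means one bad mate is enough to drop the pair-derived fragment.
2. **Duplicate cap** — at most `max_duplicates` (default 20) fragments
   are retained per locus, where a locus is the exact
   `(chrom, start, end, strand)` tuple — the standard duplicate
   definition for paired-end–derived fragments. Retention is first-seen
   in file order, for reproducibility.

Both operations are idempotent and order-preserving; replicates are
pooled (concatenated, tagged by replicate id) after filtering.

## Hotspot caller

The caller is this package's own design: a windowed Poisson scan with
local background, chosen because it is the simplest model that supports
an FDR-controlled calling contract testable by truth recovery.

* Fragment midpoints are binned at the step resolution (100 bp) and
  summed over sliding windows of 1 kb.
* Each window with at least `min_fragments` (5) midpoints receives a
  Poisson upper-tail p-value with mean
  `max(local flank rate, genome-wide rate) × window`, where the local
  rate comes from 10 kb flanks on each side of the window (truncated at
  chromosome ends, never wrapping).
* Benjamini–Hochberg correction runs across all candidate windows
  genome-wide; windows passing the FDR level (0.05) are merged when
  separated by ≤ 200 bp.
* A merged interval's `strength` is its midpoint count; its `center` is
  the floor of the mean midpoint (deterministic, and robust for the
  central-window overlap conventions); its `qvalue` is the best member
  window's adjusted p.

Restricting the test to windows with ≥ 5 fragments keeps the BH family
to loci that could possibly be called at desk-scale depths; the
threshold also acts as the minimum reportable strength. Empty inputs
yield empty calls; zero-coverage chromosomes are skipped without
division errors. Output intervals are disjoint by construction, and the
summed strengths never exceed the fragment count.

## Consensus motif scan

Patterns are IUPAC strings (run-length syntax `CGGN{11}CCG` accepted);
the default is the 17-bp Gal4 recognition consensus CGG-N₁₁-CCG. The
scan is exhaustive and exact: no mismatches, overlapping occurrences all
reported, case-insensitive (soft-masked sequence is sequence). A pattern
`N` matches A/C/G/T but **not** an ambiguous genome `N`, and fixed
pattern positions never match genome `N` — "no mismatches" is read as
requiring unambiguous evidence at every position. Because the Gal4
consensus equals its own reverse complement, a forward-strand scan is
strand-complete; each palindromic occurrence is counted once as a
genomic interval, not once per strand. When applied to a real genome
this convention counts unique intervals on the scanned chromosomes.

`expected_match_count` supplies the analytic null under i.i.d. bases:
the Gal4 pattern has per-alignment probability (1/4)⁶, i.e. 2,441.4
expected sites per 10 Mb of uniform sequence.

## Overlap classification

Overlap calls use fixed central windows around the hotspot center: 400
nt for hotspot–hotspot sharing, 1 kb for hotspot–H3K4me3, 2 kb for
hotspot–motif. The motif side is the raw 17-bp interval (the window
convention constrains the hotspot side only). "Overlap" is ≥ 1 bp
intersection of the windows; each query hotspot counts once however
many subjects it touches (any-overlap semantics). An explicit `center`
column takes precedence over the interval midpoint. TSS annotations,
which carry no published window, are treated as points expanded to
± 1 kb (configurable).

Percentages are rounded half-up to one decimal to match conventional
table formatting; an exact 100% is rendered without a decimal.

Strength correlations over shared hotspots use Spearman's rho on
log₁₀ strength; pairs are matched by central-400-nt intersection with
the closest-center reference winning ties, and at least 3 pairs are
required.

The motif-centered profile accumulates motif-site base coverage into
50-bp offset bins over ± 2.5 kb around hotspot centers, reported as the
per-hotspot mean. Hotspots targeted to planted sites show a sharp
central peak; hotspots seeing only background sites are flat.

## Chromosomal landscape

In-hotspot coverage is computed per 1 Mb bin: fragments whose midpoints
fall inside any reference hotspot region contribute to the bin of their
midpoint; bins are normalized to percent of the genome-wide in-region
total, which therefore sums to exactly 100 over unmasked bins. The
first 3 Mb of every chromosome (the low-coordinate, centromeric end,
whose sequence mouse assemblies lack) is masked from both numerator and
denominator by default.

Subtelomeric depletion compares a query landscape to a reference on
identical binning: per-bin ratios query/reference (bins with zero
reference value excluded), then
`R = mean(ratio over non-centromeric end bins) / mean(ratio over interior bins)`
where end bins are the unmasked bins within `end_width` (default 5 Mb)
of the high-coordinate chromosome end. Significance comes from ≥ 1,000
circular rotations of the per-bin ratios within each chromosome —
rotation preserves the bin-value autocorrelation that a free shuffle
would destroy — with a one-sided, add-one-corrected
p = P(R_perm ≤ R_obs). The PAR statistic is simply the percent of all
fragments (midpoint rule) inside the user-supplied PAR interval,
reported to two decimals.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with planted
truth for recovery testing:

* **Genome** — i.i.d. uniform A/C/G/T. This makes the analytic motif
  null exact and is a deliberate idealization: real mammalian genomes
  are GC-poor and repeat-rich, so their Gal4-consensus density is about
  an order of magnitude lower (tens of thousands of sites genome-wide
  rather than one per 4 kb). Consequently the *fraction of hotspots
  with a consensus in their central 2 kb* is large (~40%) in synthetic
  runs, whereas real data show a few percent; synthetic tests therefore
  validate the overlap machinery and the shared/specific partition, not
  the absolute consensus-bearing fraction.
* **Hotspots** — per chromosome, centers are uniform with a guaranteed
  minimum separation of 3 kb (a spacing transform on sorted uniforms),
  so planted peaks are resolvable by the 400-nt sharing convention.
  Strengths follow a shifted Pareto law (tail index 1.5, scale 30
  expected fragments) — heavy-tailed like empirical hotspot strengths.
  A configurable fraction of hotspots (deterministically rounded) is
  flagged to carry an exact Gal4 consensus written at the hotspot
  center; chance matches colliding with a planted site are scrubbed by
  mutating one fixed position outside it, and an optional mode also
  scrubs chance matches within ± 1 kb of non-flagged centers (off by
  default, since removing them would carve an artificial central dip in
  the background-site profile of untargeted hotspots).
* **Fragments** — per-hotspot counts are Poisson in
  strength × condition multipliers; offsets from the center are
  Gaussian truncated at ± 3σ with σ = 500 bp, so a hotspot spans
  ~1–2 kb (matching the central-window conventions). The offset shape
  is a stand-in — the empirical SSDS fragment distribution around
  centers is not modeled. Fragment lengths are normal (300 ± 60 bp,
  min 50); background fragments are uniform at 30 per Mb × efficiency;
  duplicates are exact coordinate/strand copies with geometric
  multiplicity (mean 1 + duplicate_rate); each emitted fragment draws
  two independent quality scores, uniform 30–60 with a configurable
  low-quality (0–29) tail of 15% per end, so the quality filter removes
  a predictable ~28% of fragments at defaults.
* **Conditions** — multiplicative factors compose per hotspot:
  `efficiency` (depth proxy, also scales background), `signal_factor`
  (all hotspots), `subtelomere_factor` (hotspots whose center is within
  `subtelomere_end_width`, default 5 Mb, of either chromosome end; a
  single factor, not a smooth ramp), `par_factor` (PAR-cluster
  hotspots) and `gal4_factor` (flagged hotspots; 0 removes them).
* **PAR** — 20 equal-strength overlapping hotspots evenly spaced across
  a 40 kb interval at a chromosome end, since individual hotspots in
  such a cluster are unresolvable. The default configuration places one
  on the last default chromosome; the default is dropped silently when
  a custom genome cannot host it.
* **H3K4me3** — tags Poisson in the *true* strength at every hotspot
  with no subtelomere/PAR suppression, because the chromatin mark is
  deposited regardless of whether breaks form; this is what lets the
  landscape module reproduce the DSB/H3K4me3 dissociation.

Everything is deterministic given the seed (per-purpose child seeds are
derived via `numpy.random.SeedSequence`).

## Problem sizes and defaults

Default synthetic runs use four 20 Mb chromosomes with 100 hotspots
each — dense enough (5 hotspots/Mb, close to the mouse genome-wide
average) for stable statistics while keeping a full pipeline run in
seconds. Landscape validation uses four 30 Mb chromosomes so that the
3 Mb mask, 5 Mb end bins and an interior all coexist; note that at
these desk-scale chromosome lengths the 5 Mb subtelomere zones cover a
far larger *fraction* of the genome than on real ~150 Mb mouse
chromosomes, which depresses cross-condition strength correlations in
suppressed conditions more than real data would. PAR-recovery checks
scale expected totals to 10⁶ fragments, where the binomial standard
error on a 0.33% share is ~0.006 percentage points.

## Limitations

* The hotspot caller is a generic windowed Poisson/BH design validated
  by synthetic-truth recovery; it is not a reimplementation of any
  published SSDS caller, and no strand-asymmetry information is used.
* PWM/MAST-style scoring is out of scope; motif work is exact IUPAC
  consensus matching only.
* Depth-vs-sensitivity behaviour is exercised only qualitatively (the
  low-efficiency condition calls fewer hotspots); no power model is
  fitted.
* The generator does not simulate read-level data (FASTQ), alignment
  artifacts, GC/repeat structure, or the ssDNA-vs-dsDNA classification
  step of the SSDS protocol.
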