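# Methods

This note records the models implemented in `dnaakit`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical choices a maintainer would want to know.

## Box-density analysis (`boxdensity`)

**Model.** A circular replicon of length L with an *oriC* anchor; positions
are mapped to centisomes cs(p) = ((p − ori) mod L)/L × 100, increasing in
the direction of increasing sequence coordinate (the direction convention is
ours; only relative distances from *oriC* matter downstream). Matches to
IUPAC-degenerate motifs are exact: each motif is compiled to a regex of
character classes (so an `N` *in the genome* matches nothing), scanned with
overlapping lookahead on the sequence extended by motif−1 bases across the
coordinate origin, on both strands; a reverse-strand site is located by
scanning the forward sequence with the reverse-complemented motif, so
`position` is always the leftmost forward-coordinate base. Sites matching
several query motifs are deduplicated per (position, strand) with all motifs
annotated; a per-motif count is available from the `motifs_hit` annotations
when totals per motif are wanted instead.

**Windowed density.** Counts per sliding window of width w ∈ {2, 6, 10} cs
at 1-cs steps. A match at centisome x belongs to the window centred at c iff
the signed circular offset of x from c lies in [−w/2, w/2): the left edge is
closed so every match falls in exactly w windows (coverage identity
Σc counts = n·w). Window edges are half-integer multiples, so counting on a
0.5-cs grid is exact, not an approximation.

**Null models.** (i) Uniform: n\_sims (default 1000) replicates of the
observed number of boxes placed uniformly on [0, 100), windowed identically;
(ii) motif permutation: each replicate shuffles the character order of every
query motif (IUPAC codes move as units, letter multisets preserved,
duplicate permutations allowed), rescans the genome and windows the matches.
Envelopes are per-centisome 5th/95th percentiles. The enrichment pseudo
p-value is the rank estimator p(c) = (1 + #{replicates ≥ observed})/(n+1):
one-sided, never exactly zero, unadjusted for multiple comparisons. Note a
degenerate consequence the tests pin down: when every permutation equals the
original motif (a homopolymer), all null counts tie the observation and
p ≡ 1 under this estimator. Significant regions are maximal runs of
consecutive centisomes with p < α, merged circularly across 99→0. An
optional centisome mask excludes an interval (e.g. *oriC* itself) before
windowing, for the enrichment-without-origin variant.

**Circular KDE.** Density at angle θ is the mean of von Mises kernels
exp(κ cos(θ−θi))/(2π I₀(κ)), evaluated via the exponentially scaled Bessel
function for κ up to ~10⁴. Defaults κ = 200 (kernel angular sd
1/√κ rad ≈ 1.1 cs) and a 1000-point grid; both are configurable since the
appropriate bandwidth depends on how sharply localised a density feature one
wants to resolve. The curve is standardised over the grid (mean 0, sd 1); a
numerically flat density (spread ≤ 1e-12 of its mean) standardises to zeros
rather than amplified rounding noise. Extrema are grid points that top their
±5-cs circular neighbourhood *and* whose neighbourhood is non-constant —
the second condition rejects plateaus where the density has underflowed far
from any mass; plateau runs collapse to their first point, the largest
maximum is flagged global, and a constant profile raises a degenerate-profile
error rather than returning fabricated extrema.

**Strand bias.** With a terminus coordinate, each match is assigned a
replichore by modular offset from *oriC* (ties at ori/ter go by the leftmost
base and are logged). On the replichore where the fork travels toward
increasing coordinates, forward-strand matches lie on the lagging-strand
template; the convention reverses on the other replichore.

## Tracking (`tracking`)

Localisation tables are ThunderSTORM-dialect CSVs (`frame`, `x [nm]`,
`y [nm]`; plain `x`/`y` columns require an explicit unit). The first 500
frames are dropped by default, mirroring the acquisition protocol's
pre-bleaching window. Cell regions are either integer label masks (default
pixel size 0.119 µm) or non-overlapping polygons; localisations outside
every cell are discarded and counted.

Linking is per cell, between consecutive frames only (a frame gap always
closes a track — no gap tolerance, since the appropriate tolerance depends
on blinking statistics we do not model): candidate links within
r\_max = 1.0 µm (≈3× the rms 10-ms step at 2.7 µm²/s) are resolved by the
Hungarian algorithm on the displacement matrix, so competition is settled by
global minimal total displacement, not greedy order.

The apparent diffusion coefficient of a track with n+1 localisations is
D\* = (1/n) Σ‖r(i+1)−r(i)‖² / (4 Δt) — the 2-D estimator, since only x, y
are observed. Tracks need ≥3 localisations; 2-loc tracks are kept for
bookkeeping but excluded from D\*. Histograms use 85 logarithmic bins from
0.04 to 10 µm²/s; out-of-range values are dropped (not clamped) and counted,
identically for measured and simulated data so fits compare like with like.
Localisation noise of sd σ per axis inflates D\* by σ²/Δt, so strictly
immobile molecules appear at ≈0.12 µm²/s under the defaults.

## MC-DDA (`mcdda`)

**Forward model.** Particles switch between a free state (D\_free, default
2.7 µm²/s — a configured constant from hydrodynamic estimates) and a bound
state treated as strictly immobile, with first-order rates k\_fb, k\_bf.
Motion is simulated inside a spherocylinder (cylinder 2 µm, radius 0.5 µm)
with sub-steps of t\_step = 0.1 ms: free particles take isotropic 3-D
Gaussian steps with per-axis sd √(2 D t\_step). We read the step law as
per-axis Gaussian (rather than a fixed step magnitude) because it makes the
unconfined estimator unbiased, E[D\*] = D. A sub-step landing outside the
cell is redrawn (up to 100 attempts, then the particle stays put). Waiting
times between switches are exponential, t = −ln U/k; the waiting-time clock
is decremented every sub-step and a switch takes effect from the next
sub-step. Every t\_frame = 10 ms the (x, y) position is recorded plus
Gaussian noise of sd σ\_loc = 0.035 µm per axis. Track lengths are 1–8
steps with P(n) ∝ exp(−n/τ), τ solved numerically so the truncated mean is
3 (matching the photoactivatable label's bleaching behaviour). Initial
positions are uniform in the cell; initial states follow the stationary law
p\_bound = k\_fb/(k\_fb+k\_bf) unless forced. Motion blur from stroboscopic
excitation is not modelled; recorded positions are instantaneous.

**Fit.** `DiffusionKineticsModel.fit()` minimises the squared difference
between measured and simulated bin fractions over (k\_fb, k\_bf) with
`scipy.optimize.least_squares` (Levenberg–Marquardt). The objective uses
common random numbers — every evaluation re-simulates with the same seed —
so it is a deterministic, piecewise-smooth function of the rates and a
finite-difference Jacobian (relative step 0.05) is meaningful. Rates are
optimised on a log scale to enforce positivity. 95% CIs come from the
linearised covariance s²(JᵀJ)⁻¹ at the optimum (the delta method maps them
to the natural scale and to the bound fraction). Defaults: 50,000 particles
per evaluation, 250,000 for display renders. Monte-Carlo noise between the
data and the fit simulation biases boundary fits (true bound fraction 0)
slightly upward; at the default particle counts the bias is below 0.03.

## Cell cycle (`cellcycle`)

Per-cell mobility is the unweighted mean D\* over the cell's eligible
tracks; cells without eligible tracks are omitted from mobility profiles
(they still appear in area distributions). Profiles over the cell cycle are
centred rolling medians and quartiles of mean D\* over area-ordered cells
with window k = 75, truncated at the edges (partial windows allowed).
Geometry uses the spherocylinder relations r = √(A/(π + 4·AR − 4)) and
V = (2·AR − 0.7)·π·r³ with aspect-ratio presets per growth regime (slow
3.43, intermediate 4.14, fast 4.3); the initiation volume is
V\* = ⟨V⟩/(ln 2 · n\_ori), with the inverse volume→area conversion done
numerically (Brent bracketing, relative tolerance 1e-14). Turbidostat
arithmetic: F = V\_ss/t\_ss, µ = D = F/V\_culture (default 20 mL),
Td = ln 2/µ.

## Flow cytometry (`flowcyto`)

Event intensities are histogrammed at 25 A.U. resolution over the data
range, smoothed with a Gaussian of sd 100 A.U. (clamped at the range edges
so a featureless sample smooths to a plateau, not an artificial dome), and
peaks above a prominence floor of 1% of the modal value are kept. The
reference population's most populated peak is two chromosome equivalents;
an experimental peak at intensity I gets n = round(2·I/reference), with
n = 0 flagged sub-genomic and excluded. Statistics count events within
±250 A.U. of each peak (overlapping windows split events to the nearer
peak): average origins Σnᵢcᵢ/Σcᵢ, asynchrony index = fraction of counted
cells at non-power-of-two origin numbers (the standard run-out definition;
adopted here since no formula is fixed by convention), and the one-origin
fraction. Events outside all windows are excluded from all three.

## Synthetic data (`synth`)

The generators define the study conditions for every test:

* **Genomes** — i.i.d. background at a chosen GC, with concrete motif
  instances planted at positions from a uniform/von Mises mixture
  (default: 100 boxes, κ = 50 at centisome 0 on 100 kb). Accidental
  background matches are allowed — they are realistic — so recovery tests
  compare scans, not just the planted list. Real genomes' long-range
  composition structure (GC skew, repeats) is *not* emulated; passing tests
  demonstrate correct inference under the stated nulls, not robustness to
  compositional gradients (that is what the motif-permutation null is for
  on real data).
* **Tracking datasets** — the MC-DDA simulator's tracks written into the
  ThunderSTORM dialect, one active track per cell at a time on a grid of
  square cells, so linking is unambiguous by construction. Real data's
  localisation gaps, overlapping activations and segmentation errors are
  not emulated; end-to-end tests therefore validate the estimator and
  bookkeeping, not linking robustness.
* **Flow cytometry** — integer chromosome-equivalent peaks at
  2000 A.U./equivalent with 3% lognormal CV, plus a 2N reference. The unit
  is chosen so integer peaks are far apart relative to the 500 A.U.
  counting window while each peak's sd stays well inside it, matching the
  regime the fixed-width window method presumes.

All generators are deterministic given a seed.

## Problem sizes in the test suite

The quantitative checks run at the sizes stated with each method: 10⁵
particles for the noise floor, 250k/50k particle histograms for the 3×3
bound-fraction recovery grid, 100 genomes up to 50 kb for scanner/oracle
equivalence, 1000-replicate nulls over 20 seeds for calibration and
planted-enrichment recovery. These are the package's reference workloads;
the recovery grid is the most expensive (a few minutes on one core).

## Known limitations

* The MC-DDA confidence intervals are linearised; they do not account for
  the multinomial sampling noise of the *data* histogram, only for the
  local curvature of the common-random-numbers objective.
* Bound molecules are strictly immobile; slow bound-state diffusion (e.g.
  chromosome motion) folds into the fitted rates.
* The track linker has no gap closing or blinking model.
* Native FCS parsing, image segmentation and spot detection are out of
  scope; the package consumes tables these upstream tools produce.
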