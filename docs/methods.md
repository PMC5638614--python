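# Methods

This note documents the models implemented in `terloss`, their
assumptions, the defaults and why, and what the synthetic data do and do
not emulate.

## Coordinates and chromosome maps

Positions are 0-based on a circle of `length_bp` bases; intervals are
half-open and all arithmetic is modulo the length. Published coordinates
are usually 1-based kilobases; conversion happens only at I/O boundaries.
Rearrangements are applied on the linearization cut at *oriC*: a deletion
removes loci inside its interval and shifts downstream positions, an
inversion mirrors positions (p → start + end − 1 − p) and flips the
blocking direction of inverted *Ter* sites, and intervals containing
*oriC* are rejected rather than silently rotated. Inversion is an
involution, which the tests exercise.

The bundled scenario maps use rounded, documented approximations of an
MG1655-like chromosome (length 4,641,652 bp; *oriC* 3,925 kb; *dif* 1,588
kb; *TerE/D/A* at 1,100/1,279/1,340 kb blocking counter-clockwise forks;
*TerC/B* at 1,609/1,682 kb blocking clockwise forks). Only *dif* and the
terminus-deletion endpoints (1,379,810–1,617,226) are treated as exact;
real coordinates for analyses of real data are user-supplied through the
map config. On these maps the wild-type forks merge at ~1,604 kb (between
*dif* and *TerC*), the ectopic-*Ter* strain merges at the ectopic site,
the deletion strain's new trap spans ~105 kb between *TerA* and the
shifted *TerB* with the arm junction ~65 kb from the merge point, and the
*Ter* inversion moves the merge ~320 kb from *dif* into the flipped
region.

## Fork-trap replication schedule

Both forks leave *oriC* at t = 0 with equal speed v (default 50 kb/min)
and travel in opposite directions. The clockwise fork replicates clockwise
offsets up to its first clockwise-blocking *Ter*; the counter-clockwise
fork symmetrically. Arrest is permanent until the opposing fork arrives,
so the first-replication time of a window is simply the minimum of the two
single-fork arrival times, each restricted to its reachable arc; a
configuration whose blocking sites leave an unreachable gap raises an
error. m(x) is evaluated at window starts so that a map whose *oriC* lies
on the grid attains m = 0 exactly, and the reported effective C period is
the span max m − min m; with the default 60 min doubling time (slow growth
in minimal medium) C_eff ≈ 46 min < τ, so no overlapping replication
rounds arise and the relative-frequency law n = 2^(−m/τ) is used directly
— only profile ratios are ever interpreted, so D-period and
overlapping-round bookkeeping add nothing. On the grid, max n / min n
equals 2^(C_eff/τ) to machine precision, a tested invariant.

Sub-unit *Ter* efficiency is modeled as a mixture over arrest outcomes
(weighted average of the arrest and pass-through profiles), limited to one
partial site per blocking direction so the mixture stays enumerable and
deterministic.

## Degradation mixture and read sampling

Broken cells carry exactly one fully replicated, non-replicating
chromosome (weight c = max n): breakage happens at division, after
replication completion. Per-side resection extents are independent
Exponential(L), giving retained fraction r(x) = 1 − e^(−d(x,b)/L),
symmetric about the break. Multiple break subpopulations compose
additively — the ectopic-*Ter* and inverted-*Ter* scenarios add a weaker
Tus-dependent break (f = 0.12, L = 40 kb) at the new trap beside the main
dif-centred component; the secondary fractions are this package's choice
of a visibly-weaker-than-primary peak, as no number for them is published.
Finite sequencing depth is a seeded multinomial draw over windows
(defaults: 1 kb windows, 2×10⁶ reads ≈ 30× in 75 bp read equivalents;
qualitative secondary-dip checks use 10⁷ reads, near the study-scale
~217× coverage). Windows are nominally equal; a genome length that is not
a multiple of the window leaves one short final window whose density is
still evaluated at its start with no width weighting — the error is below
one window's read share and far below multinomial noise, and the
convention keeps the dynamic-range identity exact.

Because broken chromosomes are complete outside the resected zone while
intact cells carry the replication gradient, the mutant/reference ratio is
not flat away from the dip: it is tilted upward toward the terminus and
has a broad shallow minimum at *oriC*. This is a real property of the
mixture, and the peak detector must not mistake it for noise (below).

## Peak detection and fitting

The ratio profile is smoothed with a circular moving average (half-width 5
windows) that ignores masked windows. The primary dip is the global argmin
of the smoothed ratio (ties: smallest coordinate); the baseline is the
median of the raw ratio over windows more than 700 kb from it (outside a
Ter-macrodomain-sized neighbourhood; the radius exceeds the widest
degraded region the analyses consider) and the dip is reported only if its
depth exceeds 3× a robust per-window noise scale. Two details matter and
are deliberate choices: the noise scale comes from the *raw* ratio (so
smoothing cannot promote flat noise into a dip — the extreme minimum of a
few thousand smoothed windows would otherwise always clear a
smoothed-value MAD) and it is computed on first differences of adjacent
baseline windows divided by √2 (so the genuine copy-number tilt does not
inflate it). The 3×MAD rule is a robust default, not a published value.

Secondary dips (ectopic or inverted *Ter* breaks) ride on the primary
dip's flanks and on the tilt, so they are found as local minima of the
smoothed curve by prominence (scipy `find_peaks`, same 3×MAD threshold on
the prominence) after claiming the primary's half-depth region plus a
quarter-width margin; each accepted dip claims at most 150 kb around
itself. The broad *oriC* minimum of the tilt is a genuine minimum of the
ratio and may legitimately appear in the list; callers interested in
terminus loss filter by position.

The (f, b, L) fit minimizes least squares between the observed ratio and
the analytic mixture-over-intact curve, with the copy-number gradient
computed from the map. Initialization: b at the detected center, f at
depth/baseline, L at half the half-depth width; bounds f ∈ (0,1), b within
half a genome of the center (parametrized as an offset to avoid circular
wrap at the optimizer boundary), L log-parametrized between half a window
and a quarter genome. Noise-free data are recovered to optimizer
tolerance; at 2×10⁶ reads the fit recovers f within 0.03 and b within
10 kb in 100/100 test seeds.

## Lineage counting scheme

Divisions are classified as NORMAL, INITIAL, INHERITED, DOUBLE_LOSS or
EXCLUDED. A single-loss division is INITIAL only if no ancestor division
(necessarily reached through focus-retaining daughters, since focus-less
cells do not divide) is itself a single-loss division; otherwise it is
INHERITED. Roots whose first observed division is already a loss are
excluded with their subtree — the time-lapse rule that only cells starting
with a normal division are counted. For simulated forests whose roots are
normal by construction this rule is optionally disabled
(`assume_roots_normal=True`); without the flag a deterministic q = 1 chain
has no countable divisions at all. By default, normal divisions on the
retaining branch after an initial event are excluded from the denominator
(they are part of the affected lineage's bookkeeping, not fresh trials);
`count_retaining_normals=True` implements the alternative. The
initial-event fraction is #INITIAL / (#NORMAL + #INITIAL).

Transmission follows the retaining daughter of each initial event: an
event is observable if at least one further division is seen; *full* if
every observed division of the chain again produces a focus-less daughter;
*interrupted* if the loss pattern resumes after normal division(s) (the
walk continues into whichever daughter of a normal division next shows a
loss); *single* otherwise. `pct_transmitted` counts full events only;
interrupted events are reported separately and never folded in.

## Branching steady state

With λ = 2 − q(1+h), the stable ratios relative to normal cells are
affected = qh/(λ−1) and focus-less = (q + affected)/(λ−1), which
normalizes to a focus-less population share of exactly q(1+h); at h = 0
this reduces to q. The solver rejects q(1+h) ≥ 1 (the dividing population
would shrink; no steady state among growing cells). Note that a
back-of-envelope halving argument — each loss division also produces one
focus-containing cell, so without transmission the focus-less share should
be half the division rate — does not hold under this model, because
arrested cells accumulate across generations while dividers multiply; the
explicit compartment recursion is the package's accounting, and the tests
verify the closed form against both the recursion and stochastic
simulation. Simulated populations approach the steady state through a
deterministic transient (all founders are normal) that decays by 1/λ per
generation; consistency tests therefore compare simulation against the
recursion at the simulated horizon, and the sampling band uses a
cluster-robust SE with founder subtrees as the independent units —
shared ancestry inflates fluctuations about 1.5-fold over the naive
binomial SE, which is why the naive band is not used.

## Parameter estimation

q̂ is the initial-event fraction. For h, the descriptive full-heredity
percentage is biased upward under observation truncation: a non-transmitted
retainer whose only observed division happens to be a fresh loss event
(probability ≈ q per division) is indistinguishable from transmission, and
exponential growth concentrates events near the horizon where observed
chains are short (measured bias ≈ +0.04 at q = 0.177, h = 0.745, 8
generations). `estimate_parameters` therefore uses the first-transition
moment estimator: the probability that the first observed division of the
retaining daughter is a loss is p₁ = h + (1−h)q, so ĥ = (p̂₁ − q̂)/(1 − q̂),
which is truncation-independent; the uncorrected percentage remains
available as `h_full_fraction` and in `transmission_stats`. Confidence
intervals resample founder cells with replacement (default 1000 draws);
the default interval is the normal-theory bootstrap (estimate ± z·SD of
the bootstrap replicates), chosen after a 150-replicate calibration in
which it covered at ~95/97% for q/h versus ~95/95% for the percentile
interval, which is also available.

## Motif and GC-skew scanning

IUPAC motifs are matched on both strands with overlapping occurrences
reported; positions are forward-strand coordinates of the leftmost matched
base for both strands, and a circular mode wraps the origin. The
orientation convergence point maximizes the polarization score P(x) =
(# '+' hits on the clockwise arc oriC→x) + (# '−' hits on the arc
x→oriC), evaluated at hit boundaries (the score is piecewise constant)
with ties broken by the smallest clockwise distance from the antipode of
*oriC*; a brute-force scan over every position is the test oracle. GC skew
is (G−C)/(G+C) per window (0 where G+C = 0) and its cumulative sum
clockwise from *oriC* peaks at the replichore junction estimate.

## What the synthetic data do not emulate

No read-level simulation (no FASTQ, mapping errors or coverage biases
beyond multinomial noise), no amplification subpopulations such as those
seen in some *tus*- or *ftsK*-deficient backgrounds, no copy-number
breakpoint artifacts near *TerA* in the rearranged strains, and no growth
arrest mechanism beyond "focus-less cells do not divide" (the regime where
focus-less cells keep dividing after loss of the *hipAB* toxin locus is a
config variant of the branching process, not fitted). Degradation extents
are unbounded exponentials; a hard cap at the nearest essential-gene
boundary would be a straightforward extension but is off by default.
Passing tests therefore demonstrate correctness of the analysis machinery
under the stated generative model, not robustness to the full complexity
of real sequencing or imaging data.

## Problem sizes used in the test suite

Parameter-recovery studies run at 2×10⁶ reads over the full 4.64 Mb map
(100 seeds) and 500 founders × 8 generations (50 replicates, 1000
bootstrap draws each); the steady-state consistency check uses 800
founders × 11 generations (~4.5×10⁵ alive cells); oracle equivalences use
1000 random trees and exhaustive scans over small circles. These sizes
were chosen to make the statistical assertions sharp while keeping the
default suite comfortably fast.
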