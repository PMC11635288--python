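# Methods

## The measurement model

A FRAP series is a single-channel time-lapse `T × H × W` stack with four
pre-bleach frames, one bleach frame, and 50–200 post-bleach frames at a
575 ms frame period (the package defaults; all are configurable). The bleach
frame itself carries no usable intensity: quantification uses only the
frames around it. "Frame −1" is the last pre-bleach frame and "Frame 1" the
first post-bleach frame; the timestamp gap between the bleach frame and
Frame 1 is widened by the bleach-pulse duration (default 0.4 s).

ROI quantification is the arithmetic mean over pixels whose centers fall
inside the region (boundary inclusive), with pixel centers at integer
(row, col) coordinates and the origin top-left. Circles are rasterized
analytically; polygons through shapely's `covers`, which is independent of
vertex order and winding.

## Recovery fitting

The bleached-area trace is divided by the mean of all pre-bleach frames, so
the pre-bleach level is 1 by construction, and time is reset to t = 0 at
Frame 1. The model

    I(t) = I0 + (Iinf − I0)(1 − e^(−k t))

is fit by bounded least squares (`scipy.optimize.curve_fit`) with
k ∈ [1e−4, 1e3] s⁻¹ and deterministic initialization: I0 from the first
post-bleach value, Iinf from the mean of the last 10% of frames, and k from
the first time the trace crosses halfway between them. Reported quantities
are t½ = ln2/k and the mobile fraction (Iinf − I0)/(1 − I0), i.e. the
recovered amplitude as a fraction of what the bleach removed relative to
the pre-bleach level. A failed optimization returns `converged=False` with
half-time and mobile fraction absent; classification treats this as no
recovery. No acquisition-photobleaching correction is applied.

Two systematic effects are worth knowing. First, recovery occurring between
the bleach pulse and Frame 1 is invisible, so for exchange fast relative to
the frame period the fitted mobile fraction underestimates the true mobile
pool (the amplitude has partly recovered before the first usable frame).
Second, a true half-time below the frame period is at the edge of what the
sampling can identify: in the noisy parameter-recovery sweep (Poisson noise
at SNR 20, 100 post-bleach frames), the median relative error of t½ is
well under 10% across the grid of true t½ ∈ {0.5…8} s × mobile fraction
∈ {0.3, 0.6, 0.9}, but the single hardest cell (t½ = 0.5 s with mobile
fraction 0.3) reaches ≈14% — an information limit of 575 ms sampling, not a
property of the optimizer.

## Classification

Strict boundary semantics, taken from the printed inequalities: fast if
t½ < 2 s, medium if 2 ≤ t½ < 5 s, slow if t½ ≥ 5 s; mobile fraction
strictly below 30% (or a failed fit) is no recovery, so exactly 30% still
counts as recovering.

## Connectivity Index

With percent changes ΔI_x between Frame −1 and Frame 1 for the bleached
area *a*, distant same-vacuole area *b*, and neighbor-cell control *c*:
Rel = ΔI_a − ΔI_b, Ref = ΔI_a − ΔI_c, CI = (Ref − Rel)/Ref.

**Denominator convention.** The percent change can be taken relative to the
Frame −1 intensity (the natural reading of a drop "as % of this area
intensity before photobleaching") or relative to the Frame 1 intensity.
Both are implemented; `pre_frame` is the default and the choice never
affects the defining limits (CI is exactly 1 under perfect mixing and
exactly 0 when *b* behaves like *c*, under either convention — covered by
tests).

**Frame −1 intensity** is the single last pre-bleach frame by default; a
`mean` mode averages all pre-bleach frames for extra noise robustness at the
cost of deviating from the strict two-frame definition.

**QC.** CI < 0 (the non-bleached area *gained* signal relative to the
chain) is flagged `drift_negative`, CI > 1 `drift_above_one`; both usually
indicate sample drift between the two frames. A bleached-area drop shallower
than 10 percentage points — including the pathological case of swapped
frames, where ΔI_a is positive — is flagged `weak_bleach`. Flagged results
keep their CI value but are excluded from summaries by default, with
excluded counts reported. Note that for a well-connected vacuole the ideal
CI is 1, so measurement noise alone pushes a fraction of honest
measurements slightly above 1 into the flagged range; this costs sample
size, never correctness.

**Cut-off.** The pipeline default separating connected from disconnected is
CI = 0.1. `calibrate_cutoff` re-estimates it as the 95th percentile of
negative-control CIs (disconnected structures) and warns when that quantile
reaches the median of the positive controls (controls not separable). On
clean simulated controls the empirical cut-off lands near 0.01, an order of
magnitude below the default, which is therefore kept.

## The simulator

Ground truth is a `CompartmentNetwork`: non-overlapping 2D masks in a
single optical plane (matching equatorial-plane imaging), one volume per
compartment (its pixel count), and symmetric exchange edges with
conductance k_ij in amount · concentration⁻¹ · s⁻¹. Concentrations follow

    dC_i/dt = (1/V_i) Σ_j k_ij (C_j − C_i),

which conserves total amount Σ V_i C_i globally and within every graph
component. The propagator over each frame interval is the matrix
exponential for networks of ≤ 50 compartments (exact to machine precision;
verified against the closed-form two-compartment solution at < 1e−6
relative error, in practice ~1e−14) and fixed-step RK4 with step
≤ frame_period/20 above that.

The bleach is instantaneous at the bleach frame — the target compartment's
concentration is multiplied by (1 − bleach_depth) — and the 0.3–0.5 s pulse
duration only widens the following timestamp gap, since only pre/post
frames are analyzed. Rendering adds a uniform background (default 50 a.u.
against an initial concentration of 1000 a.u.), then noise, then an integer
per-frame drift shift; output is quantized to unsigned 16-bit on write with
clipping counted. Default noise is Poisson on (signal + background) scaled
by a photon gain (counts per intensity unit, default 1), matching
photon-limited confocal detection: at the defaults the per-pixel SNR inside
a vacuole is √1050 ≈ 32. Gaussian noise is available for simple tests.

Three morphology styles emulate the phenotypes of interest. `tubular` is a
thin tube (half-width 4 px) split into chain segments with fast exchange;
the default per-edge relaxation half-time of 0.02 s makes even the slowest
chain mode relax well within one frame period, the regime where connected
vacuoles approach CI = 1. `constricted` is a chain of round lobes joined by
low-conductance bottlenecks (default pairwise half-time 3 s), producing
medium/slow recovery. `fragmented` is isolated blobs with no edges. An
optional neighbor-cell compartment (separate cell label, no edges) hosts
the CI control area *c*. ROIs are placed from ground truth at the deepest
interior point of each mask: *a* in the bleach target, *b* in the same-cell
compartment farthest from it, *c* in the neighbor cell. For tubular
networks the ROI radius is capped by the tube half-width, which is the same
constraint a microscopist faces and the main driver of CI noise (±0.04 at
the defaults).

What the simulator deliberately omits: point-spread-function blur,
z-structure, tonoplast rendering, acquisition photobleaching, and vacuole
motility. Passing tests therefore demonstrate that the quantification chain
is correct and discriminates connectivity under realistic photon noise and
drift — not that it is robust to every artifact of live-cell imaging (in
particular, the rapid vacuole movement that motivated the CI in the first
place is represented only by its rigid-drift component).

## Statistics

Recovery half-times are compared pairwise with the two-sided Mann–Whitney
rank-sum test: exact enumeration when min(n₁, n₂) ≤ 8 and there are no
ties (verified against brute-force enumeration over all rank splits),
otherwise the tie-corrected normal approximation. Results are summarized as
a compact letter display: each maximal clique of the non-significance graph
gets one letter, so two groups share a letter exactly when their pairwise
p ≥ α. Connectivity indices across groups are compared with the two-sided
two-sample t-test (pooled variance by default). No multiple-testing
correction is applied by default, matching per-pair reporting; a Holm
option would be a one-line addition but is deliberately not a default.
Non-recovering vacuoles are excluded from half-time statistics but included
in class percentages; QC-flagged CIs are excluded from statistics with
counts reported.

## Problem sizes

The simulated validation study uses cohorts of 10–20 series of 105 frames
at 512 × 512 px with 2–4 compartments per network — enough for the
ground-truth separation (fragmented maximum CI ≈ 0.02 vs connected minimum
CI ≈ 0.9, with zero overlap over 20 + 20 seeded series) while keeping a
full pipeline run in the low minutes on one CPU. Unit tests use 160 × 160
images for speed; nothing in the pipeline depends on image size.
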