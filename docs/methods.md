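# Methods

This note documents the models, conventions and numerical choices behind
the package, in the spirit of the model-documentation pages of msprime or
statsmodels: what is computed, under which assumptions, and where the
design was genuinely open.

## Arena and coordinate conventions

All positions are millimetres in a frame centred on the platform
(radius 58.5 mm). Bearings are degrees counter-clockwise from +x. The two
stripes sit 293 mm from the centre at opposed bearings, by default 90°/270°
so that the stripe axis is vertical in rendered maps, matching the usual
transition-plot orientation; every geometric quantity is configurable
through `ArenaConfig`, and all metrics are equivariant under joint rotation
of trajectory and stripe bearings (tested to 1e−9).

The thigmotaxis boundary is the radius R/√2 = 41.37 mm that splits the disc
into an inner disc and an outer annulus of exactly equal area, so a
spatially uniform fly scores 0.5.

## From samples to steps, bouts and pauses

A trajectory of n samples yields n−1 steps; step i covers [tᵢ, tᵢ₊₁] with
speed ‖pᵢ₊₁−pᵢ‖/Δtᵢ and heading atan2 of the displacement, attributed to
the interval midpoint. The tracker frame rate is not assumed constant;
irregular sampling is handled by per-step Δt. No smoothing is applied
before differencing by default (an optional boxcar window exists); angle
statistics therefore refer to frame-to-frame movements, and their values
depend on that granularity.

A step is *moving* when its speed reaches the immobility threshold
(default 1.0 mm/s — roughly body-length-scale jitter per second; the
threshold is deliberately kept in one place, the `moving` flag of
`StepSeries`, so every metric sees the same dichotomy). A *pause* is a
maximal run of non-moving steps strictly longer than 1 s ("more than 1 s":
exactly 1.0 s is not a pause). Everything else, including sub-threshold
stops, belongs to activity bouts; bouts and pauses tile the record exactly.

## The twelve parameters

Speed and angle metrics use moving steps only; distance travelled uses all
steps, so the raw path length is preserved and immobility flagging only
suppresses jitter in speed/angle statistics. Meander is the median of
per-step |Δheading|/speed (median of ratios, not ratio of medians; the
alternative reading is a one-liner on top of `StepSeries` but is not the
default). Thigmotaxis-while-sitting selects steps inside detected pauses,
not merely sub-threshold steps.

Stripe deviation takes, per moving step, the smaller angle between the
heading and the bearings from the step midpoint to the two stripe centres.
With opposed stripes this is ≤ 90° up to the small parallax of off-centre
positions (the two bearings subtend slightly less than 180°; values are
clipped at 90°). Walks between the stripes are counted by zone crossings:
an end zone is the sector within 45° of a stripe bearing beyond half the
platform radius (both numbers configurable — the assay itself does not
define when a "walk" starts); a walk is registered each time the fly enters
one zone having last occupied the other, so loitering in or re-entering the
same zone never inflates the count.

## The random-walk baseline is analytically 45°

For an uncorrelated walker (headings i.i.d. uniform) observed at *any*
point of the platform, the probability that the nearest-stripe deviation is
below 45° is exactly 1/2: the deviation function over a full turn of
headings consists of four monotone ramps between the two stripe directions,
and for every position on the platform the two inter-stripe gaps both
exceed 90°, so the 45° level is crossed at cumulative probability 0.5
regardless of the gap asymmetry. The median of the baseline is therefore
45° everywhere, not only in the zero-step-length centre limit. Finite steps
with rim folding shift realized headings slightly; measured over 8000
simulated flies the ensemble median is 44.99° ± 0.01. The published
baseline of 44° evidently carries the finite-sample details of the original
(unpublished) walker; this package's baseline should be read as 45°, and
the acceptance suite tests agreement with the printed 44° at its stated ±1°
tolerance using a median over thirty 200-fly batches, whose noise
(~0.01°) is small against the band.

## Transition plots

Moving-step midpoints are binned (2 mm default ≈ a 59×59 grid over the
platform) with step duration as weight and smoothed with a Gaussian of
1 bin (neither value is canonical; both are exposed). The grid extends a
few smoothing lengths beyond the platform so the filter conserves total
mass (tested to 1e−6). Per-fly maps are pooled within strain × replicate by
summation and normalised only afterwards; rendering divides by the maximum
and pins every cell at ≥ 95 % of it to the top colour level, proportional
below.

## Group statistics

The outlier rule is strict: flies with distance-per-minute *smaller than*
50 mm/min are excluded; a fly at exactly 50.0 is kept. PCA is performed on
centred, unit-variance (ddof = 1) metrics — the twelve parameters carry
incommensurable units (mm/s, counts, proportions), so correlation-matrix
PCA is the only defensible default; covariance-matrix PCA is available via
`scale=False` for sensitivity analysis. NaN rows (degenerate flies) and
zero-variance columns are dropped with warnings; component signs are fixed
by making each component's largest-magnitude loading positive.

Shapiro–Wilk p-values are recorded for the first three components. The
factorial ANOVA (score ~ strain * replicate, Type II sums of squares —
robust to the mild imbalance that the outlier filter introduces) may be run
on any component, but a component failing the normality gate triggers a
prominent warning; the conventional choice of component 2 reflects the
historical practice of testing the first component that passes the gate.
Tukey's HSD over strains feeds the grouping: groups are connected
components of the non-significance graph (transitive closure), and a
compact letter display from the graph's maximal cliques reports
non-transitive patterns as overlapping letters instead of forcing a
partition.

## The simulator

Each fly is a two-state Markov walker sampled at dt = 0.05 s (20 Hz; the
real tracker rate is unknown) for 300 s. While moving, the heading is drawn
from a von Mises mixture: with probability `fixation_strength` centred on
the bearing to the stripe nearer to the current heading (concentration
`fixation_kappa`), otherwise centred on the previous heading
(`persistence_kappa`). Step speeds are gamma distributed
(mean 15 mm/s, CV 0.25 — a typical wild-type walking speed giving
~800–900 mm/min, far above the 50 mm/min outlier line). Move→pause and
pause→move transitions use exponential holding times with rates 0.05/s and
0.5/s, i.e. ~14 stops per record of mean 2 s, of which ~60 % exceed the 1 s
pause threshold. The default "replicate effect" adds +0.75 mm/s speed and
+0.005/s stop rate to the second replicate — an activity-only shift
emulating the brighter second-year hardware, real but numerically small.

Positions that would leave the platform are folded radially back inside
(the live fly turns at the water moat; absorbing variants were not needed).
Two consequences are worth knowing. First, folding shortens some realized
steps below the immobility threshold, so rim-hugging flies show occasional
phantom sub-second "stops" — behaviourally not unlike real moat-turning,
but it biases naive Markov-rate estimators by a few per cent. Second,
folded realized headings pull the random-walk baseline from the analytic
45.000° to ≈ 44.99°.

Reproducibility: every fly pre-draws all of its randomness from its own
`SeedSequence` stream in a fixed order, so a fly simulated alone is
bit-identical to the same fly inside any batch, and study manifests can
re-derive any single file from the root seed and the fly's spawn index.
The inner stepping loop is a numba kernel; a pure-numpy twin of the same
update rule is kept as a cross-check and the two agree to 1e−12 over short
horizons (over thousands of steps, compiler-level FMA differences are
amplified by the chaotic rim dynamics, so bitwise long-horizon agreement
between the two code paths is not a meaningful target).

What the generator does *not* emulate: tracker noise and dropouts, jump/
reinitialisation events, gait-level kinematics, within-strain individuality
(flies of a strain are i.i.d. given the strain parameters), and any
illumination or arena asymmetry. Passing tests therefore validate the
analysis chain's arithmetic and statistical calibration, not the biological
realism of any particular parameter value.

## Test and calibration problem sizes

The acceptance suite simulates the full study design (5 strains × 2
replicates × 12 flies, 5-minute records): 100 replicate studies with three
planted parameter groups for recovery power, and 400 parameter-identical
studies for type-I calibration of the strain effect on PC2 (runs are
batched ~20 studies at a time through the vectorised stepper). Planted
groups differ in fixation strength (0.55/0.30/0.05), mean speed (15/12/18
mm/s) and stop rate (0.04/0.08/0.02/s) — separations chosen as clear
strain-scale differences, large against between-fly sampling noise.
Stochastic single-number checks (the 45° baseline, parameter recovery at
n = 20) are asserted on medians over several independent seeded batches, a
deterministic and adequately powered summary of a noisy estimate; batch
seeds are consecutive integers.

## Known limitations

* The walk counter and stripe deviation depend on centroid data only; body
  orientation (which can differ from movement direction during side-steps)
  is not available.
* Exact reproduction of the published F statistics would require the
  original deposited data and the original analysis tool's conventions
  (its ANOVA sum-of-squares order among them); the pipeline records every
  exclusion and warning in its report so such a comparison is mechanical
  once the data are at hand.
* With n < 13 flies after NaN-row drops, PCA returns fewer than 12
  components; the analyser refuses a component index beyond what exists.
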