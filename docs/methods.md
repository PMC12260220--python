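# Methods

This note documents the models, estimators and design choices behind
`rootkin`, the assumptions they rest on, and what the synthetic-data tests
do and do not establish about real trajectories.

## Data model and conventions

A trajectory is an ordered sequence of `(t, x, y, z)` root-tip samples in
seconds and centimetres, nominally one sample per 180 s for 7 days
(3361 samples). Timestamps must be strictly increasing and coordinates
finite; at least three samples are required (the minimum for one turning
angle). Gaps longer than 30 min are tolerated but logged as tracking
dropouts; all step-wise quantities operate on the consecutive samples that
exist. The first sample defines t = 0.

The vertical (growth) axis defaults to `y`; the other two axes span the
horizontal *interaction plane* in which neighbour geometry, hourly
displacements and the growth angles are measured. The axis naming is
configurable (`PlaneConvention`) and recorded in the file sidecar, so data
acquired in a different frame only need the right declaration.

Turning angles follow the arccos-of-normalized-dot-product definition:
0° is a straight continuation and 180° an exact reversal, so *larger*
angles mean sharper turns. The cosine is clamped to [−1, 1] before arccos
to absorb rounding; zero-length segments yield a missing value rather than
an arbitrary angle.

## Main growth component and nutation

Circumnutation is separated from net growth by smoothing the 3-D path with
a centered moving average over a time window. At the edges the half-window
shrinks symmetrically, so the smoothed path has the trajectory's length
and coincides with it at the endpoints. The window defaults to one
nutation period, estimated in two passes: a 2 h bootstrap window, a first
period estimate, then re-smoothing at that period. Averaging over exactly
one period cancels the orbit and leaves the growth axis; the window is
configurable for sensitivity analyses.

Nutation amplitude is the per-sample Euclidean distance between the raw
tip and the smoothed path. The dominant period is read from the plain FFT
power spectrum of the mean-removed amplitude series (no taper, no
zero-padding, period resolution limited to Fourier bins); the reported
"amplitude of the main frequency" is the |X(f)|² power at the argmax bin.
Two numerical guards matter in practice:

* **Edge trimming.** Because the shrink-window smoother pins the smoothed
  path to the raw endpoints, the amplitude series ramps from zero at both
  ends. One window width is trimmed from each edge before the FFT;
  otherwise the ramp dominates the lowest bins.
* **Search band.** The argmax excludes the zero frequency and, by
  default, periods longer than 12 h. Slow residual drift of the amplitude
  series otherwise wins the argmax with multi-day "periods" no root
  nutates at; 12 h is far above reported circumnutation periods for the
  species of interest (tens of minutes to a few hours). Pass
  `max_period=None` to search every non-zero bin.

Spectral entropy uses the horizontal-plane distance between the raw tip
and the smoothed path as the signal, Welch's method (segment length
min(256, N/2), 50 % overlap, Hann taper, constant detrend) for the PSD,
and Shannon entropy in bits of the PSD normalized to sum 1. Zero-power
bins contribute nothing; an all-zero signal has entropy 0 by convention.
With 256-sample segments the flat-spectrum bound is log₂ 129 ≈ 7.0 bits.
Note that even a pure sinusoid keeps ≈ 1.3 bits under a Hann taper (the
main lobe spans three bins), so "low" entropy means *small relative to the
bound*, not literally zero.

## Growth rates

Tip-path arc length stands in for root elongation: the root grows at the
tip, so the deposited root approximately follows the tip's path. This is
an over-estimate when the tip oscillates laterally (the nutation loops
count toward "elongation") and the relative rate inherits that bias; both
rates are therefore comparative features, not absolute physiology.
Cumulative arc length is interpolated at whole days; the absolute rate is
the mean daily increment (cm/day) and the relative rate the mean of
increments divided by the running root length, seeded with the measured
initial root length (default 4 cm, the typical seedling length at the
start of acquisition).

## Condition classification

The feature table (one row per plant, condition label individual/social)
is standardized to z-scores with the population SD; constant features are
dropped with a warning. Outliers are winsorized at |z| = 3 rather than
removed — with cohorts of ~37 plants, deleting rows costs too much power,
and winsorizing is idempotent and logged. Correlated features are pruned
iteratively: while any pair exceeds |r| = 0.7, the member with the larger
mean |r| against the remaining features is dropped (ties broken by column
order); a `force_retain` list can protect named features, e.g. to fix the
retained set across studies.

Both classifiers are linear with default unit regularization (logistic
regression, linear-kernel SVM): with tens of plants and ten features,
anything more flexible overfits. Cross-validation is stratified 5-fold,
seeded; accuracy is the reported metric, and the signed coefficients of a
fit on the full table give feature importance (positive pushes toward the
social class). Standardization and pruning are fit once globally rather
than per fold — with the inferential (not predictive) goal, the slight
optimism of global preprocessing is accepted for interpretability of a
single retained feature set; per-fold preprocessing can be emulated by
calling the pieces directly.

The chance level of the pipeline is verified by label permutation:
accuracy over 100 permutations is compared with 0.5 by a binomial test on
the pooled correct-classification count.

## Behaviour calling

The plant-to-neighbour direction is PN = rn₀ − rp₀ in the horizontal
plane (0° = growing exactly toward the neighbour). Hourly displacements
are taken on the *smoothed* main component — on the raw path, nutation
loops of a perfectly stationary axis would rack up spurious displacement.
Each hourly step is signed with its full magnitude (+|PPh| if the growth
angle is below 90°, −|PPh| above, zero at exactly 90°); a configurable
projection mode (|PPh| cos θ) is available but off by default, keeping the
magnitude semantics of the displacement threshold. The cumulative sum is
scanned in time order; the first crossing of ±1.2 cm fixes the call and
its onset hour (only the first behaviour counts when a root later switches
direction). Without a crossing, the fraction of hours toward must exceed
the fraction away by more than 0.35 (margin reading of the dominance rule;
zero-displacement hours count in the denominator) for a directional call,
otherwise the plant is neutral. 1.2 cm is roughly one quarter of the 5 cm
inter-plant distance of the experimental design.

## Directional statistics

For each aggregative plant, the global growth angle θg is the *signed*
angle from PN to the horizontal displacement between the initial tip
position and the position where the behaviour was identified (the
threshold-crossing hour, or the last sample for dominance calls). The sign
comes from the 2-D cross product (counter-clockwise positive viewed from
above; the −180° boundary maps to +180°). Because the setup is mirror
symmetric about the inter-plant axis, the handedness choice cannot bias a
normality test centred at 0°. Normality of the pooled θg (and per species
when at least three values exist) is tested with Shapiro–Wilk (3 ≤ n ≤
5000, non-constant input required); histogram (10 bins over ±180°) and
Blom-position QQ data are emitted for plotting.

The aggregation-by-identity association is a 2×2 χ² with Yates'
continuity correction, Σ (|O − E| − ½)² / E with df = 1, implemented
directly from the formula (and cross-checked in the test suite against an
independent hand-coded oracle and `scipy.stats.chi2_contingency`).

## Synthetic generator

The generator is phenomenological: it produces trajectories with the
statistical structure the estimators assume, not a mechanistic growth
model (no gravitropism, auxin transport or root–root signalling).

Tip position = vertical growth at `axial_rate` + a horizontal nutation
orbit + optional lateral drift + small-scale waviness + measurement noise.
The orbit has radius `nutation_amplitude` and period `nutation_period`
with log-normal multiplicative jitter drawn once per revolution (so both
stay positive), and a once-per-revolution radial asymmetry,
r(φ) = A·(1 + ε·cos φ). The asymmetry matters: for a *perfect* circle the
distance between the tip and the smoothed axis is constant, so the
nutation period is information-theoretically absent from the amplitude
signal; real orbits swing wider to one side, and ε > 0 reproduces exactly
the once-per-revolution amplitude modulation that makes the spectral
estimator work. The default is ε = 0 (a clean circle, the simplest
geometry for oracle tests); cohort conditions use ε = 0.3.

`waviness_sd` adds i.i.d. per-sample erratic tip motion *before* noise: a
biological property of the plant (sub-resolution exploratory wiggle) that
lengthens the true path, as opposed to `noise_sd`, which is instrument
error. Separating the two lets path-raggedness features (tortuosity, TVC)
vary between plants independently of orbit geometry — without such a
channel, tortuosity is a near-deterministic function of amplitude, period
and axial rate, and its multivariate coefficient is unidentifiable.

Seeding: every plant draws from one `numpy` generator seeded by a stable
SHA-256-derived child seed (< 2³¹) of the master seed, so cohorts
regenerate byte-identically.

### Study conditions

Cohorts default to the study design sizes: 19 individually grown plants
and 18 social plants (10 conspecific + 8 heterospecific pairs at 5 cm).
Condition-level parameters (chosen once as plausible for maize-scale
primary roots, since no effect magnitudes are published for these
features):

| parameter | individual | social |
|---|---|---|
| axial rate (cm/day) | 1.0 | 1.5 |
| nutation amplitude (cm) | 0.15 | 0.25 |
| nutation period (min) | 100 | 70 |
| amplitude jitter (CV/rev) | 0.10 | 0.15 |
| period jitter (CV/rev) | 0.05 | 0.05 |
| radial asymmetry ε | 0.3 | 0.3 |
| waviness SD (cm) | 0.010 | 0.035 |
| measurement noise SD (cm) | 0.01 | 0.01 |

Plant-to-plant spread is log-normal with CV 0.15 on rates, amplitude,
period, jitters and waviness. The social column plants the qualitative
effect pattern the classifier should recover — more main-frequency power,
faster relative growth, higher tortuosity, shorter period — with enough
overlap that discrimination is a statistical question rather than a
lookup. Planted behaviours use a 0.5 cm/day lateral drift (3.5 cm over
7 days, comfortably past the 1.2 cm threshold).

## What the synthetic tests show — and do not

Passing tests establish that every estimator recovers the quantity it
targets from data satisfying its assumptions (circular-ish, coherent
nutation; piecewise-stationary parameters; additive Gaussian noise), that
the behaviour rule and the statistics are implemented exactly, and that
the classification pipeline finds planted multivariate structure at the
study's sample sizes while staying at chance on permuted labels. They do
*not* show that real roots satisfy those assumptions: real nutation is
intermittent and elliptical, tracking dropouts are structured rather than
absent, and published cross-validated accuracies or normality statistics
on deposited trajectories depend on acquisition details (including the
exact smoothing of the main component) that a synthetic emulation cannot
pin down. Reproducing those numbers requires the deposited data and is
out of scope for the test suite.

## Known limitations

* The main-component smoother is a moving average; splines or
  Savitzky–Golay filters would track curved axes with less lag near the
  edges.
* Period estimation is argmax-on-FFT-bins; no interpolation between bins
  and no significance test on the peak.
* The relative growth rate inherits the tip-path-as-elongation
  approximation (see Growth rates).
* Circular statistics (Rayleigh test, von Mises fits) for θg are not
  implemented; the normality test treats angles as linear values, which
  is adequate only because observed spreads are well inside ±180°.
* Only the primary root is modelled; secondary roots and simultaneous
  two-plant responses are out of scope.
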