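# rootkin

Kinematic and behavioural analysis of 3-D root-tip trajectories.

Growing primary roots circumnutate — the tip traces a helical path about
the main growth axis — and when two plants share a substrate, each root may
grow toward its neighbour (*aggregative*), away from it (*avoidant*), or
with no clear direction (*neutral*). `rootkin` is a library and CLI for
plant scientists who track root tips in 3-D (e.g. with time-lapse stereo
imaging at one frame per 3 min over ~7 days) and want to quantify how a
neighbour changes root movement. It covers four stages:

1. **Feature extraction** — per-plant kinematic and oscillatory features
   from a `(t, x, y, z)` trajectory: step distance/velocity/acceleration,
   turning (segmentation) angles θ = arccos(v̂ₚᵣₑᵥ · v̂ₙₑₓₜ), absolute and
   relative daily growth rates, average hourly tip velocity, nutation
   amplitude relative to the smoothed main growth component, dominant
   nutation period and its FFT power, spectral entropy
   H = −Σᵢ Pᵢ log₂ Pᵢ of the Welch PSD of the horizontal oscillation,
   curvature k = |r′ × r″| / |r′|³, its total variation
   TVC = Σᵢ |k(tᵢ) − k(tᵢ₋₁)|, and tortuosity (path length / chord length).
2. **Condition discrimination** — do individually vs socially grown plants
   differ? Features are z-scored, winsorized at |z| = 3, pruned at
   |r| > 0.7, then classified (logistic regression and linear SVM) under
   stratified 5-fold cross-validation; signed coefficients give feature
   importance.
3. **Behaviour calling** — per social plant, hourly displacement of the
   smoothed main component is signed by the growth angle θg,h to the
   plant-to-neighbour direction (+ toward if θg,h < 90°). The first
   crossing of the cumulative signed displacement past ±1.2 cm (about a
   quarter of the 5 cm inter-plant distance) fixes the call; without a
   crossing, a direction must dominate by more than 35 % of the hours,
   else the plant is neutral.
4. **Directional statistics** — for aggregative plants, the signed global
   growth angle θg ∈ (−180°, 180°] between the plant-to-neighbour axis and
   the overall displacement, tested for normality around 0° with
   Shapiro–Wilk; plus a 2×2 χ² test with Yates' continuity correction for
   the association of aggregation with neighbour identity (conspecific vs
   heterospecific).

A seeded synthetic-trajectory generator (helical nutation with
per-revolution jitter and radial asymmetry, axial growth, optional lateral
bias toward/away from a neighbour, measurement noise) makes the whole
pipeline testable end to end with planted ground truth.

## Worked example

```python
import rootkin as rk
from dataclasses import replace

# a social pair 5 cm apart; the focal plant drifts toward its neighbour
params = replace(rk.SOCIAL_PARAMS, lateral_bias=0.5)   # cm/day
pair = rk.generate_pair(params, rk.SOCIAL_PARAMS, behaviour="aggregative",
                        separation=5.0, seed=11, pair_id="demo")

feats = rk.extract_features(pair.plant)
call = rk.call_pair(pair)
theta = rk.global_growth_angle(pair, call)
res = rk.chi_square_yates([[15, 7], [3, 13]])
```

Printing these values gives:

```
period of main nutation: 70.0 min
mean nutation amplitude: 0.250 cm
tortuosity:              32.3
spectral entropy:        5.85 bits
behaviour: aggregative (rule threshold_positive, onset hour 56)
global growth angle theta_g: -17.7 deg
chi2 (Yates) = 7.204, p = 0.007
```

The generator planted a 70 min nutation period and a 0.25 cm orbit radius,
and the spectral estimator recovers both. The 0.5 cm/day drift pushes the
cumulative signed displacement past +1.2 cm at hour 56, so the plant is
called aggregative, and its overall growth direction deviates −17.7° from
the axis to the neighbour. The 2×2 table is the kind of
aggregative/non-aggregative by conspecific/heterospecific contingency the
behaviour stage produces over a cohort; χ² = 7.204 (df = 1, p ≈ .007)
indicates a significant association.

## Command line

```bash
rootkin simulate --spec spec.yaml --out cohort/ --seed 42
rootkin validate cohort/*.csv
rootkin features cohort/manifest.json --out features.csv
rootkin classify-condition features.csv --model svm --out report.json
rootkin behaviour cohort/manifest.json --out calls.csv
rootkin directional cohort/manifest.json --out directional.json
```

Trajectory files are plain CSV (`time_s,x_cm,y_cm,z_cm`) with a JSON
metadata sidecar; cohorts are described by a JSON manifest.

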