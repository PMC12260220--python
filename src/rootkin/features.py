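"""Kinematic and oscillatory feature extraction from root-tip trajectories.

Implements the full per-plant feature battery: step kinematics (distance,
velocity, acceleration), segmentation (turning) angles, absolute/relative
daily growth rates, average hourly tip velocity, nutation amplitude relative
to the smoothed main growth component, the dominant nutation period and its
spectral power, Welch-PSD spectral entropy, curvature and its total
variation, and tortuosity.

Conventions
-----------
* The segmentation angle between consecutive segments is 0° for a straight
  continuation and 180° for an exact reversal — i.e. larger angles mean
  sharper turns under the arccos-of-dot-product definition used here.
* Curvature uses the time parameterization, k = |r' x r''| / |r'|^3, with
  derivatives by central finite differences.
* The "main growth component" is a centered moving average of the 3-D path;
  the window defaults to one estimated nutation period (fallback 2 h).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .trajectory import PlaneConvention, Trajectory

logger = logging.getLogger("rootkin")

DAY_S = 86400.0

#: The ten features used for condition classification, in the order they
#: are reported.
CLASSIFIER_FEATURES = [
    "mean speed",
    "minimum speed",
    "tortuosity",
    "mean nutation amplitude",
    "period of main nutation",
    "total variation of curvature",
    "average relative daily growth rate",
    "amplitude of the main frequency in the power spectrum",
    "spectral entropy",
    "mean segmentation angle",
]

#: The four features with the largest discriminative weight between
#: individually and socially grown plants (sign of the planted effect in
#: parentheses refers to the social class).
HEADLINE_FEATURES = [
    "amplitude of the main frequency in the power spectrum",  # (+)
    "average relative daily growth rate",                     # (+)
    "tortuosity",                                             # (+)
    "period of main nutation",                                # (-)
]


@dataclass
class FeatureConfig:
    """Tunable knobs of the feature extraction stage."""

    #: Smoothing window for the main growth component, seconds; ``None``
    #: means one estimated nutation period (two-pass), fallback 2 h.
    main_component_window: float | None = None
    #: Welch segment length cap for spectral entropy.
    welch_nperseg: int = 256
    welch_window: str = "hann"
    #: Initial root length fallback, cm (used for relative growth rate).
    initial_root_length: float = 4.0
    convention: PlaneConvention = field(default_factory=PlaneConvention)


# ---------------------------------------------------------------------------
# Step kinematics
# ---------------------------------------------------------------------------

def step_kinematics(traj: Trajectory) -> dict[str, np.ndarray]:
    """Per-step distance (cm), velocity (cm/s) and acceleration (cm/s^2)
    between consecutive samples (forward differences)."""
    dt = np.diff(traj.t)
    if np.any(dt == 0):
        raise ValueError("zero time step encountered")
    dist = traj.step_lengths()
    vel = dist / dt
    acc = np.diff(vel) / dt[1:]
    return {"distance": dist, "velocity": vel, "acceleration": acc}


def segmentation_angles(traj: Trajectory) -> np.ndarray:
    """Turning angle (degrees, in [0, 180]) at each interior sample.

    0° = straight continuation; 180° = exact reversal. Zero-length
    segments yield NaN at that index.
    """
    seg = np.diff(traj.xyz, axis=0)
    vprev, vnext = seg[:-1], seg[1:]
    nprev = np.linalg.norm(vprev, axis=1)
    nnext = np.linalg.norm(vnext, axis=1)
    denom = nprev * nnext
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", vprev, vnext) / denom
    cosang = np.clip(cosang, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    bad = denom == 0
    if bad.any():
        logger.warning("segmentation_angles: %d zero-length segment(s); "
                       "angle undefined there", int(bad.sum()))
        angles[bad] = np.nan
    return angles


# ---------------------------------------------------------------------------
# Growth rates and hourly velocity
# ---------------------------------------------------------------------------

def growth_rates(
    traj: Trajectory, initial_root_length: float | None = None
) -> tuple[float, float]:
    """Absolute (cm/day) and relative (1/day) daily growth rates.

    Tip path length approximates root elongation. Cumulative elongation is
    interpolated at whole days; the absolute rate is the mean daily
    increment and the relative rate the mean of increments divided by the
    running root length (initial length + elongation so far), seeded by the
    plant's measured initial root length (default 4 cm).
    """
    if traj.span < 2 * DAY_S:
        raise ValueError("growth_rates needs a span of at least 2 days")
    L0 = (traj.initial_root_length if initial_root_length is None
          else float(initial_root_length))
    rel_t = traj.t - traj.t[0]
    cum = traj.cumulative_path_length()
    n_days = int(rel_t[-1] // DAY_S)
    day_marks = np.arange(n_days + 1) * DAY_S
    L = np.interp(day_marks, rel_t, cum)
    daily = np.diff(L)
    absolute = float(np.mean(daily))
    relative = float(np.mean(daily / (L0 + L[:-1])))
    return absolute, relative


def average_hourly_tip_velocity(traj: Trajectory) -> float:
    """Average distance travelled by the tip per hour, cm/h."""
    if traj.span < 3600:
        raise ValueError("average_hourly_tip_velocity needs a span of >= 1 h")
    return traj.path_length() / (traj.span / 3600.0)


# ---------------------------------------------------------------------------
# Main growth component and nutation
# ---------------------------------------------------------------------------

def main_growth_component(traj: Trajectory, window: float) -> np.ndarray:
    """Smoothed 3-D path: centered time-window moving average.

    ``window`` is the full window width in seconds; at the edges the
    half-window shrinks symmetrically so the output has the same length as
    the input and the endpoints coincide with the raw endpoints.
    """
    if window < 3 * np.median(np.diff(traj.t)):
        raise ValueError("window must cover at least 3 samples")
    t = traj.t
    half = window / 2.0
    # Symmetric shrink keeps the average centered on t_i near the edges.
    eff_half = np.minimum(half, np.minimum(t - t[0], t[-1] - t))
    lo = np.searchsorted(t, t - eff_half, side="left")
    hi = np.searchsorted(t, t + eff_half, side="right")
    csum = np.vstack([np.zeros(3), np.cumsum(traj.xyz, axis=0)])
    counts = (hi - lo).astype(float)
    return (csum[hi] - csum[lo]) / counts[:, None]


def nutation_amplitude(traj: Trajectory, mc: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean displacement of the raw tip position from the
    main growth component, cm."""
    mc = np.asarray(mc, dtype=float)
    if mc.shape != traj.xyz.shape:
        raise ValueError("main component and trajectory lengths differ")
    return np.linalg.norm(traj.xyz - mc, axis=1)


def main_nutation_period(
    amp: np.ndarray, dt: float, max_period: float | None = 720.0
) -> tuple[float, float]:
    """Dominant nutation period (minutes) and its spectral power.

    The mean-removed amplitude series is Fourier transformed (no window,
    no zero-padding); the period is the reciprocal of the frequency with
    maximum power, excluding the zero frequency. Power is |X(f)|^2.

    ``max_period`` (minutes) bounds the search to the circumnutation band:
    residual slow drift of the amplitude series otherwise dominates the
    lowest bins and the argmax returns a multi-day "period" that no root
    nutates at. The default 12 h cap is far above any reported
    circumnutation period; pass ``None`` to search all non-zero bins.
    """
    amp = np.asarray(amp, dtype=float)
    if amp.size < 32:
        raise ValueError("main_nutation_period needs at least 32 samples")
    x = amp - amp.mean()
    if np.allclose(x, 0):
        raise ValueError("constant amplitude series: period undefined")
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(amp.size, d=dt)
    searchable = freqs > 0
    if max_period is not None:
        in_band = freqs >= 1.0 / (max_period * 60.0)
        if in_band.any():
            searchable &= in_band
    k = int(np.argmax(np.where(searchable, power, -np.inf)))
    return float(1.0 / freqs[k] / 60.0), float(power[k])


def horizontal_excursion(
    traj: Trajectory, mc: np.ndarray, convention: PlaneConvention
) -> np.ndarray:
    """Distance in the horizontal interaction plane between each raw sample
    and the main growth component — the oscillation signal used for
    spectral entropy."""
    delta = convention.horizontal(traj.xyz) - convention.horizontal(mc)
    return np.linalg.norm(delta, axis=1)


def spectral_entropy_of(
    x: np.ndarray, fs: float, nperseg: int = 256, window: str = "hann"
) -> float:
    """Shannon entropy (bits) of the Welch PSD of ``x``, normalized to a
    probability distribution over frequency bins. Zero-power bins
    contribute nothing; an all-zero signal has entropy 0."""
    x = np.asarray(x, dtype=float)
    if x.size < 64:
        raise ValueError("spectral entropy needs at least 64 samples")
    nper = min(nperseg, x.size // 2)
    _, psd = sp_signal.welch(
        x, fs=fs, window=window, nperseg=nper, noverlap=nper // 2,
        detrend="constant",
    )
    total = psd.sum()
    if total <= 0:
        logger.warning("spectral entropy of an all-zero signal defined as 0")
        return 0.0
    p = psd / total
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def spectral_entropy(
    traj: Trajectory, mc: np.ndarray, convention: PlaneConvention | None = None,
    nperseg: int = 256, window: str = "hann",
) -> float:
    """Spectral entropy (bits) of the tip's horizontal-plane oscillation
    about the main growth component."""
    convention = convention or PlaneConvention()
    sig = horizontal_excursion(traj, mc, convention)
    fs = 1.0 / float(np.median(np.diff(traj.t)))
    return spectral_entropy_of(sig, fs, nperseg=nperseg, window=window)


# ---------------------------------------------------------------------------
# Curvature and tortuosity
# ---------------------------------------------------------------------------

def curvature_series(traj: Trajectory) -> np.ndarray:
    """Curvature k(t) = |r' x r''| / |r'|^3 (1/cm) at each sample, with
    derivatives by central finite differences on the time grid. Samples
    where the speed vanishes get NaN."""
    if len(traj) < 5:
        raise ValueError("curvature_series needs at least 5 samples")
    r1 = np.gradient(traj.xyz, traj.t, axis=0)
    r2 = np.gradient(r1, traj.t, axis=0)
    cross = np.cross(r1, r2)
    speed = np.linalg.norm(r1, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.linalg.norm(cross, axis=1) / speed ** 3
    bad = speed == 0
    if bad.any():
        logger.warning("curvature: %d stationary sample(s); value undefined",
                       int(bad.sum()))
        k[bad] = np.nan
    return k


def total_variation_curvature(k: np.ndarray) -> float:
    """Sum of absolute successive curvature differences over valid
    consecutive pairs, 1/cm."""
    k = np.asarray(k, dtype=float)
    if k.size < 2:
        raise ValueError("total variation needs at least 2 curvature values")
    diffs = np.abs(np.diff(k))
    return float(np.nansum(diffs))


def tortuosity(traj: Trajectory) -> float:
    """Path length over straight-line start-to-end distance; >= 1."""
    chord = float(np.linalg.norm(traj.xyz[-1] - traj.xyz[0]))
    if chord == 0:
        raise ValueError("tortuosity undefined: start equals end")
    return traj.path_length() / chord


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _describe(name: str, values: np.ndarray, out: dict) -> None:
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    for stat, fn in (("mean", np.mean), ("median", np.median),
                     ("maximum", np.max), ("minimum", np.min)):
        out[f"{stat} {name}"] = float(fn(vals)) if vals.size else np.nan


def extract_features(
    traj: Trajectory, config: FeatureConfig | None = None
) -> dict[str, float]:
    """Compute the full feature vector for one plant.

    Returns a flat mapping of feature name to value, including the ten
    classifier features plus mean/median/max/min of every step series,
    both growth rates and the average hourly tip velocity.
    """
    cfg = config or FeatureConfig()
    conv = cfg.convention
    out: dict[str, float] = {"plant_id": traj.plant_id}  # type: ignore[dict-item]

    kin = step_kinematics(traj)
    _describe("distance", kin["distance"], out)
    _describe("speed", kin["velocity"], out)
    _describe("acceleration", kin["acceleration"], out)
    _describe("segmentation angle", segmentation_angles(traj), out)

    # Main growth component: when no window is given, bootstrap with a 2 h
    # window, estimate the nutation period, then re-smooth at one period.
    dt_med = float(np.median(np.diff(traj.t)))

    def _spectral(mc_arr: np.ndarray, window_s: float):
        """Period/power of the nutation-amplitude series for a given main
        component. The shrink-window smoother pins the main component to
        the raw path at the ends, so the amplitude series ramps from zero
        there; one window width is trimmed from each edge to keep that
        ramp out of the low-frequency bins."""
        amp_full = nutation_amplitude(traj, mc_arr)
        trim = max(1, int(round(window_s / dt_med)))
        interior = amp_full[trim:-trim] if amp_full.size > 2 * trim + 32 else amp_full
        return amp_full, main_nutation_period(interior, dt_med)

    if cfg.main_component_window is not None:
        window_used = cfg.main_component_window
        mc = main_growth_component(traj, window_used)
        try:
            amp, (period, peak_power) = _spectral(mc, window_used)
        except ValueError:
            amp, period, peak_power = nutation_amplitude(traj, mc), np.nan, 0.0
    else:
        # Two-pass: bootstrap with a 2 h window, estimate the period, then
        # re-smooth with one estimated period.
        window_used = 7200.0
        mc = main_growth_component(traj, window_used)
        try:
            amp, (period, peak_power) = _spectral(mc, window_used)
            if 0 < period * 60.0 <= traj.span / 4:
                window_used = period * 60.0
                mc = main_growth_component(traj, window_used)
                amp, (period, peak_power) = _spectral(mc, window_used)
        except ValueError:  # constant amplitude (straight path): keep fallback
            amp, period, peak_power = nutation_amplitude(traj, mc), np.nan, 0.0

    _describe("nutation amplitude", amp, out)
    out["period of main nutation"] = period
    out["amplitude of the main frequency in the power spectrum"] = peak_power
    out["spectral entropy"] = spectral_entropy(
        traj, mc, conv, nperseg=cfg.welch_nperseg, window=cfg.welch_window
    )

    k = curvature_series(traj)
    _describe("curvature", k, out)
    out["total variation of curvature"] = total_variation_curvature(k)
    out["tortuosity"] = tortuosity(traj)

    absolute, relative = growth_rates(traj, cfg.initial_root_length
                                      if "initial_root_length_cm" not in traj.metadata
                                      else None)
    out["average absolute daily growth rate"] = absolute
    out["average relative daily growth rate"] = relative
    out["average hourly tip velocity"] = average_hourly_tip_velocity(traj)
    return out


def feature_table(
    trajectories: Mapping[str, Trajectory] | list[Trajectory],
    labels: Mapping[str, str] | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Assemble a per-plant feature DataFrame (index plant_id), optionally
    with a ``condition`` label column."""
    if isinstance(trajectories, Mapping):
        trajectories = list(trajectories.values())
    rows = [extract_features(t, config) for t in trajectories]
    df = pd.DataFrame(rows).set_index("plant_id")
    if labels is not None:
        df["condition"] = [labels.get(pid) for pid in df.index]
    return df
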