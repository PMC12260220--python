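"""Synthetic root-tip trajectory generator.

Emulates the phenomenology of hydroponically grown primary roots as seen by
a 3-min time-lapse stereo rig: monotone axial growth along the vertical
axis, circular circumnutation of controllable amplitude and period in the
horizontal plane, an optional constant lateral drift toward or away from a
neighbour, and additive per-axis Gaussian measurement noise.

The generator is purely phenomenological — no gravitropism or hormone
transport — but it plants known ground truth (nutation period/amplitude,
growth rate, approach/avoid bias) that the downstream estimators and
classifiers must recover.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .trajectory import (
    DEFAULT_DT,
    PlaneConvention,
    PlantPair,
    Trajectory,
    write_trajectory,
)

DAY_S = 86400.0

BEHAVIOURS = ("aggregative", "avoidant", "neutral")
CONDITIONS = ("individual", "social_conspecific", "social_heterospecific")


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one synthetic root.

    Attributes
    ----------
    duration : float
        Acquisition span, seconds (default 7 days).
    dt : float
        Sampling interval, seconds (default 180 s, the rig's cadence).
    axial_rate : float
        Vertical elongation speed, cm/day.
    nutation_amplitude : float
        Radius of the circumnutation circle, cm.
    nutation_period : float
        Period of one revolution, minutes.
    amplitude_jitter, period_jitter : float
        Coefficient of variation of per-revolution log-normal multiplicative
        jitter on amplitude and period (0 = perfectly regular helix).
    radial_asymmetry : float
        Once-per-revolution modulation of the orbit radius,
        r(phase) = amplitude * (1 + radial_asymmetry * cos(phase)); 0 gives
        a perfect circle. Real circumnutation orbits swing wider to one
        side, and this asymmetry is what makes the nutation period visible
        in the tip's distance-to-main-component signal: for a perfect
        circle that distance is constant and carries no period at all.
    lateral_bias : float
        Horizontal drift speed, cm/day, applied along ``bias_direction``.
    bias_direction : (float, float)
        Unit-normalized direction of the drift in the horizontal plane.
    waviness_sd : float
        SD (cm) of small-scale erratic tip motion per axis per sample —
        sub-resolution exploratory wiggle of the growing tip, independent
        of the nutation orbit. This is a biological property of the plant
        (it lengthens the true path and drives tortuosity and curvature
        variation), unlike ``noise_sd`` which is instrument error.
    noise_sd : float
        SD of i.i.d. Gaussian measurement noise per axis per sample, cm.
    """

    duration: float = 7 * DAY_S
    dt: float = DEFAULT_DT
    axial_rate: float = 1.0
    nutation_amplitude: float = 0.15
    nutation_period: float = 90.0
    amplitude_jitter: float = 0.0
    period_jitter: float = 0.0
    radial_asymmetry: float = 0.0
    lateral_bias: float = 0.0
    bias_direction: tuple[float, float] = (1.0, 0.0)
    waviness_sd: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "duration", "dt", "axial_rate", "nutation_amplitude",
            "nutation_period", "amplitude_jitter", "period_jitter",
            "waviness_sd", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.radial_asymmetry < 1:
            raise ValueError("radial_asymmetry must be in [0, 1)")
        if self.nutation_period * 60.0 <= 2 * self.dt:
            raise ValueError(
                "nutation_period must exceed 2*dt (Nyquist) to be resolvable"
            )


def _revolution_phase(
    n: int, dt: float, period_s: float, period_jitter: float,
    amplitude: float, amplitude_jitter: float, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Phase (radians) and amplitude (cm) per sample, with log-normal
    multiplicative jitter drawn once per revolution so both stay positive."""
    t = np.arange(n) * dt
    if period_jitter == 0 and amplitude_jitter == 0:
        phase = 2 * np.pi * t / period_s
        return phase, np.full(n, amplitude)

    # Build revolution boundaries until they cover the full span.
    sig_p = np.sqrt(np.log1p(period_jitter ** 2))
    sig_a = np.sqrt(np.log1p(amplitude_jitter ** 2))
    bounds = [0.0]
    amps = []
    while bounds[-1] < t[-1] + period_s:
        factor = float(np.exp(rng.normal(-sig_p ** 2 / 2, sig_p))) if sig_p else 1.0
        bounds.append(bounds[-1] + period_s * factor)
        amp_f = float(np.exp(rng.normal(-sig_a ** 2 / 2, sig_a))) if sig_a else 1.0
        amps.append(amplitude * amp_f)
    bounds_arr = np.array(bounds)
    rev = np.searchsorted(bounds_arr, t, side="right") - 1
    # Piecewise-linear phase: 2*pi per revolution.
    frac = (t - bounds_arr[rev]) / np.diff(bounds_arr)[rev]
    phase = 2 * np.pi * (rev + frac)
    return phase, np.asarray(amps)[rev]


def generate_trajectory(
    params: GrowthParams,
    plant_id: str = "synthetic",
    convention: PlaneConvention | None = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    metadata: dict | None = None,
) -> Trajectory:
    """Simulate one tip trajectory; deterministic given ``params.seed``."""
    convention = convention or PlaneConvention()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration / params.dt)) + 1
    t = np.arange(n) * params.dt

    phase, amp = _revolution_phase(
        n, params.dt, params.nutation_period * 60.0, params.period_jitter,
        params.nutation_amplitude, params.amplitude_jitter, rng,
    )

    radius = amp * (1.0 + params.radial_asymmetry * np.cos(phase))
    h1 = radius * np.cos(phase)
    h2 = radius * np.sin(phase)
    days = t / DAY_S
    bias = np.asarray(params.bias_direction, dtype=float)
    norm = np.linalg.norm(bias)
    if norm > 0:
        bias = bias / norm
    h1 = h1 + params.lateral_bias * days * bias[0]
    h2 = h2 + params.lateral_bias * days * bias[1]
    vertical = -params.axial_rate * days  # tip grows downward

    xyz = np.empty((n, 3))
    i1, i2 = convention.horizontal_indices
    xyz[:, i1] = h1
    xyz[:, i2] = h2
    xyz[:, convention.vertical_index] = vertical
    # Start exactly at the origin: the nutation circle otherwise offsets t=0.
    if params.waviness_sd > 0:
        xyz = xyz + rng.normal(0.0, params.waviness_sd, size=xyz.shape)
    xyz -= xyz[0]
    xyz += np.asarray(origin, dtype=float)
    if params.noise_sd > 0:
        xyz = xyz + rng.normal(0.0, params.noise_sd, size=xyz.shape)

    meta = {
        "condition": "individual",
        "vertical_axis": convention.vertical_axis,
        "planted_nutation_period_min": params.nutation_period,
        "planted_nutation_amplitude_cm": params.nutation_amplitude,
        "planted_axial_rate_cm_per_day": params.axial_rate,
        "planted_lateral_bias_cm_per_day": params.lateral_bias,
    }
    if metadata:
        meta.update(metadata)
    return Trajectory(
        plant_id=plant_id,
        species=meta.get("species", "synthetic"),
        t=t,
        xyz=xyz,
        dt_nominal=params.dt,
        metadata=meta,
    )


def generate_pair(
    params_a: GrowthParams,
    params_b: GrowthParams,
    behaviour: str = "neutral",
    separation: float = 5.0,
    seed: int | None = None,
    convention: PlaneConvention | None = None,
    pair_id: str = "pair",
) -> PlantPair:
    """Simulate a focal plant and its neighbour at a horizontal separation.

    The planted behaviour orients the focal plant's lateral drift: toward
    the neighbour for ``aggregative``, away for ``avoidant``, and zero for
    ``neutral``. The neighbour keeps ``params_b`` as given (zero bias unless
    specified).
    """
    if behaviour not in BEHAVIOURS:
        raise ValueError(f"behaviour must be one of {BEHAVIOURS}")
    if separation <= 0:
        raise ValueError("separation must be positive")
    convention = convention or PlaneConvention()
    if seed is not None:
        params_a = replace(params_a, seed=_child_seed(seed, 0))
        params_b = replace(params_b, seed=_child_seed(seed, 1))

    # Focal plant at the origin; neighbour offset along the first
    # horizontal axis, so the plant->neighbour direction is (+1, 0).
    if behaviour == "aggregative":
        params_a = replace(params_a, bias_direction=(1.0, 0.0))
    elif behaviour == "avoidant":
        params_a = replace(
            params_a, bias_direction=(-1.0, 0.0),
        )
    else:
        params_a = replace(params_a, lateral_bias=0.0)

    i1, i2 = convention.horizontal_indices
    origin_b = np.zeros(3)
    origin_b[i1] = separation

    meta_common = {"separation_cm": separation, "pair_id": pair_id}
    plant = generate_trajectory(
        params_a, plant_id=f"{pair_id}_a", convention=convention,
        metadata={**meta_common, "condition": "social_conspecific",
                  "planted_behaviour": behaviour,
                  "neighbour_id": f"{pair_id}_b"},
    )
    neighbour_behaviour = "neutral" if params_b.lateral_bias == 0 else None
    neighbour = generate_trajectory(
        params_b, plant_id=f"{pair_id}_b", convention=convention,
        origin=origin_b,
        metadata={**meta_common, "condition": "social_conspecific",
                  "planted_behaviour": neighbour_behaviour,
                  "neighbour_id": f"{pair_id}_a"},
    )
    return PlantPair(plant, neighbour, separation=separation)


def _child_seed(master: int, index: int) -> int:
    """Stable, collision-resistant per-plant seed below 2**31."""
    h = hashlib.sha256(f"{master}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


#: Default condition-level growth parameters for simulated cohorts. The
#: social condition plants the qualitative effects seen in socially grown
#: roots — faster relative growth, larger and less regular nutations with a
#: shorter period (hence more main-frequency power and higher tortuosity).
INDIVIDUAL_PARAMS = GrowthParams(
    axial_rate=1.0, nutation_amplitude=0.15, nutation_period=100.0,
    radial_asymmetry=0.3, amplitude_jitter=0.10, period_jitter=0.05,
    waviness_sd=0.01, noise_sd=0.01,
)
SOCIAL_PARAMS = GrowthParams(
    axial_rate=1.5, nutation_amplitude=0.25, nutation_period=70.0,
    radial_asymmetry=0.3, amplitude_jitter=0.15, period_jitter=0.05,
    waviness_sd=0.035, noise_sd=0.01,
)


def draw_plant_params(
    base: GrowthParams, cv: float, rng: np.random.Generator
) -> GrowthParams:
    """Per-plant biological variability: log-normal multiplicative draws
    (coefficient of variation ``cv``) around the condition-level means of
    axial rate, nutation amplitude and period, and of the regularity
    parameters (jitter, measurement noise). Varying the regularity
    independently of the orbit geometry keeps path-raggedness features
    (tortuosity, curvature variation) from being deterministic functions of
    amplitude and period across plants."""
    if cv <= 0:
        return base
    sig = np.sqrt(np.log1p(cv ** 2))
    factor = lambda: float(np.exp(rng.normal(-sig ** 2 / 2, sig)))
    return replace(
        base,
        axial_rate=base.axial_rate * factor(),
        nutation_amplitude=base.nutation_amplitude * factor(),
        nutation_period=base.nutation_period * factor(),
        amplitude_jitter=base.amplitude_jitter * factor(),
        period_jitter=base.period_jitter * factor(),
        waviness_sd=base.waviness_sd * factor(),
    )


@dataclass
class CohortSpec:
    """Counts and per-condition growth parameters for a simulated study.

    Defaults mirror the maize arm of the study design: 19 plants grown
    alone and 18 grown socially (10 with a conspecific, 8 with a
    heterospecific neighbour), pairs at 5 cm separation. ``between_plant_cv``
    adds log-normal plant-to-plant spread around each condition's mean
    growth parameters so the two conditions overlap realistically.
    """

    n_individual: int = 19
    n_social_conspecific: int = 10
    n_social_heterospecific: int = 8
    individual_params: GrowthParams = field(
        default_factory=lambda: INDIVIDUAL_PARAMS)
    social_params: GrowthParams = field(default_factory=lambda: SOCIAL_PARAMS)
    behaviour_mix: dict[str, float] = field(
        default_factory=lambda: {"aggregative": 0.4, "avoidant": 0.3, "neutral": 0.3}
    )
    separation: float = 5.0
    between_plant_cv: float = 0.15
    #: Lateral drift speed (cm/day) planted in the focal plant of each
    #: non-neutral social pair; over 7 days 0.5 cm/day crosses the 1.2 cm
    #: displacement threshold comfortably.
    planted_bias: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_individual, self.n_social_conspecific,
               self.n_social_heterospecific) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_individual + self.n_social_conspecific + \
                self.n_social_heterospecific == 0:
            raise ValueError("cohort must contain at least one plant")
        total = sum(self.behaviour_mix.get(b, 0.0) for b in BEHAVIOURS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("behaviour_mix proportions must sum to 1")


def generate_cohort(spec: CohortSpec, out_dir: str | Path, seed: int = 0) -> Path:
    """Write a full synthetic cohort to ``out_dir`` and return the manifest
    path.

    One CSV + sidecar per plant; the manifest is a JSON array of
    ``{trajectory_path, condition, pair_id}`` entries. Per-plant seeds are
    derived deterministically from the master seed, so regeneration with the
    same seed is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_child_seed(seed, 10 ** 6))
    entries: list[dict] = []
    plant_index = 0

    for i in range(spec.n_individual):
        p = draw_plant_params(spec.individual_params, spec.between_plant_cv, rng)
        p = replace(p, seed=_child_seed(seed, plant_index))
        traj = generate_trajectory(
            p, plant_id=f"ind_{i:03d}",
            metadata={"condition": "individual"},
        )
        path = out_dir / f"ind_{i:03d}.csv"
        write_trajectory(traj, path)
        entries.append({"trajectory_path": path.name, "condition": "individual",
                        "pair_id": None})
        plant_index += 1

    behaviours = list(BEHAVIOURS)
    probs = np.array([spec.behaviour_mix.get(b, 0.0) for b in behaviours])
    for condition, count in (
        ("social_conspecific", spec.n_social_conspecific),
        ("social_heterospecific", spec.n_social_heterospecific),
    ):
        for i in range(count):
            behaviour = behaviours[int(rng.choice(len(behaviours), p=probs))]
            pair_id = f"{condition[len('social_'):][:3]}_{i:03d}"
            pa = draw_plant_params(spec.social_params, spec.between_plant_cv, rng)
            pb = draw_plant_params(spec.social_params, spec.between_plant_cv, rng)
            if behaviour != "neutral":
                pa = replace(pa, lateral_bias=spec.planted_bias)
            pair = generate_pair(
                pa, pb, behaviour=behaviour,
                separation=spec.separation,
                seed=_child_seed(seed, plant_index), pair_id=pair_id,
            )
            for traj in (pair.plant, pair.neighbour):
                traj.metadata["condition"] = condition
                path = out_dir / f"{traj.plant_id}.csv"
                write_trajectory(traj, path)
                entries.append({"trajectory_path": path.name,
                                "condition": condition, "pair_id": pair_id})
            plant_index += 1

    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(entries, indent=1))
    return manifest


def simulate_condition_trajectories(
    n_individual: int = 19,
    n_social: int = 18,
    seed: int = 0,
    individual_params: GrowthParams = INDIVIDUAL_PARAMS,
    social_params: GrowthParams = SOCIAL_PARAMS,
    between_plant_cv: float = 0.15,
) -> tuple[list[Trajectory], dict[str, str]]:
    """In-memory cohort for the individual-vs-social analysis.

    Returns one trajectory per plant (no neighbour geometry — only the
    growth phenotype matters for condition classification) and a plant-id
    to condition-label mapping. Default counts mirror the study's feature
    table: 19 individually grown and 18 socially grown plants.
    """
    rng = np.random.default_rng(_child_seed(seed, 424242))
    trajectories: list[Trajectory] = []
    labels: dict[str, str] = {}
    for condition, base, count in (
        ("individual", individual_params, n_individual),
        ("social", social_params, n_social),
    ):
        for i in range(count):
            p = draw_plant_params(base, between_plant_cv, rng)
            p = replace(p, seed=int(rng.integers(2 ** 31)))
            pid = f"{condition[:3]}_{i:03d}"
            trajectories.append(
                generate_trajectory(p, plant_id=pid,
                                    metadata={"condition": condition})
            )
            labels[pid] = condition
    return trajectories, labels
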