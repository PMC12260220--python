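"""Neutral / avoidant / aggregative behaviour calling for social plants.

A social plant's primary-root response to its neighbour is read from the
hourly horizontal displacement of the smoothed main growth component.
Each hour's movement is signed positive when the growth angle to the
plant-to-neighbour direction is below 90° (movement toward the neighbour)
and negative above 90°. The running sum of signed hourly displacements is
scanned in time order:

* first crossing of +1.2 cm  -> aggregative (onset at that hour);
* first crossing of -1.2 cm  -> avoidant;
* no crossing: the direction whose hourly incidence exceeds the other's by
  more than 35% of the total hours wins; otherwise the call is neutral.

Only the first behaviour is kept when the root later switches direction.
The 1.2 cm threshold is roughly one-quarter of the 5 cm inter-plant
distance of the study design.

Vector orientation: the plant-to-neighbour vector is PN = rn0 - rp0 and the
hourly displacement is rp(t+1h) - rp(t), so that 0° means growth exactly
toward the neighbour. (The jointly negated convention gives identical
angles.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import main_growth_component
from .trajectory import PlaneConvention, PlantPair, Trajectory, hourly_indices

BEHAVIOUR_LABELS = ("neutral", "avoidant", "aggregative")

DEFAULT_THRESHOLD_CM = 1.2
DEFAULT_DOMINANCE = 0.35


@dataclass
class HourlyMotion:
    """Per-hour horizontal motion of the main growth component."""

    hours: np.ndarray           # hour index of each step start
    pph: np.ndarray             # (n, 2) horizontal displacement vectors, cm
    theta_gh: np.ndarray        # unsigned growth angle, degrees in [0, 180]
    signed_displacement: np.ndarray  # +|PPh| toward, -|PPh| away, cm
    cumulative: np.ndarray      # running sum of signed displacement, cm
    tip_positions: np.ndarray   # (n+1, 3) raw tip position at each hour, cm


@dataclass
class BehaviourCall:
    """Outcome of the behaviour-calling rule for one plant."""

    label: str
    onset_hour: int | None
    rp_end: np.ndarray          # tip position when the behaviour was identified
    rule_fired: str             # threshold_positive | threshold_negative |
                                # dominance | neutral_default
    fraction_toward: float
    fraction_away: float


def neighbour_vector(
    pair: PlantPair, convention: PlaneConvention | None = None
) -> np.ndarray:
    """Horizontal-plane vector from the focal plant's initial tip to the
    neighbour's initial tip."""
    convention = convention or PlaneConvention()
    pn = convention.horizontal(pair.rn0) - convention.horizontal(pair.rp0)
    if np.linalg.norm(pn) == 0:
        raise ValueError("initial tips coincide: neighbour direction undefined")
    return pn


def hourly_motion(
    pair: PlantPair,
    mc: np.ndarray | None = None,
    convention: PlaneConvention | None = None,
    mc_window: float = 7200.0,
    signed_mode: str = "magnitude",
) -> HourlyMotion:
    """Hourly growth angles and signed displacements of the focal plant.

    ``mc`` is the focal plant's main growth component (computed with a 2 h
    moving average when omitted); hour boundaries are taken on the smoothed
    path, so circumnutation loops do not inflate the displacement.

    ``signed_mode`` selects how each hourly step is signed: ``magnitude``
    (default) uses the full step length +/-|PPh| switched at 90°;
    ``projection`` uses the component along the neighbour direction,
    |PPh| cos θ.
    """
    if signed_mode not in ("magnitude", "projection"):
        raise ValueError("signed_mode must be 'magnitude' or 'projection'")
    convention = convention or PlaneConvention()
    traj = pair.plant
    if traj.span < 2 * 3600:
        raise ValueError("hourly motion needs a span of at least 2 h")
    if mc is None:
        mc = main_growth_component(traj, mc_window)
    pn = neighbour_vector(pair, convention)

    idx = hourly_indices(traj.t)
    mc_h = np.asarray(mc)[idx]
    tips = traj.xyz[idx]
    steps = np.diff(convention.horizontal(mc_h), axis=0)
    norms = np.linalg.norm(steps, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = steps @ pn / (norms * np.linalg.norm(pn))
    cosang = np.clip(cosang, -1.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    theta[norms == 0] = np.nan

    if signed_mode == "projection":
        signed = norms * cosang
    else:
        signed = np.where(theta < 90.0, norms,
                          np.where(theta > 90.0, -norms, 0.0))
    signed[norms == 0] = 0.0
    return HourlyMotion(
        hours=np.arange(steps.shape[0]),
        pph=steps,
        theta_gh=theta,
        signed_displacement=signed,
        cumulative=np.cumsum(signed),
        tip_positions=tips,
    )


def classify_behaviour(
    hm: HourlyMotion,
    threshold: float = DEFAULT_THRESHOLD_CM,
    dominance: float = DEFAULT_DOMINANCE,
) -> BehaviourCall:
    """Apply the displacement-threshold / dominance rule to hourly motion.

    The cumulative signed displacement is scanned in time order and the
    first threshold crossing fixes the call; with no crossing, the dominant
    hourly direction must beat the other by more than ``dominance`` of the
    total hours, else the plant is neutral.
    """
    if hm.signed_displacement.size < 2:
        raise ValueError("behaviour calling needs at least 2 hourly steps")
    cum = hm.cumulative
    n = cum.size
    f_toward = float(np.sum(hm.signed_displacement > 0)) / n
    f_away = float(np.sum(hm.signed_displacement < 0)) / n

    pos = np.nonzero(cum > threshold)[0]
    neg = np.nonzero(cum < -threshold)[0]
    first_pos = int(pos[0]) if pos.size else None
    first_neg = int(neg[0]) if neg.size else None

    if first_pos is not None and (first_neg is None or first_pos <= first_neg):
        onset = first_pos
        return BehaviourCall("aggregative", onset, hm.tip_positions[onset + 1],
                             "threshold_positive", f_toward, f_away)
    if first_neg is not None:
        onset = first_neg
        return BehaviourCall("avoidant", onset, hm.tip_positions[onset + 1],
                             "threshold_negative", f_toward, f_away)

    if abs(f_toward - f_away) > dominance:
        label = "aggregative" if f_toward > f_away else "avoidant"
        return BehaviourCall(label, None, hm.tip_positions[-1],
                             "dominance", f_toward, f_away)
    return BehaviourCall("neutral", None, hm.tip_positions[-1],
                         "neutral_default", f_toward, f_away)


def call_pair(
    pair: PlantPair,
    convention: PlaneConvention | None = None,
    threshold: float = DEFAULT_THRESHOLD_CM,
    dominance: float = DEFAULT_DOMINANCE,
    mc_window: float = 7200.0,
) -> BehaviourCall:
    """Convenience: hourly motion + behaviour call for the focal plant."""
    hm = hourly_motion(pair, convention=convention, mc_window=mc_window)
    return classify_behaviour(hm, threshold=threshold, dominance=dominance)


def behaviour_contingency(
    calls: list[tuple[str, str]],
) -> np.ndarray:
    """2x2 contingency counts from (label, neighbour_identity) tuples.

    Rows: conspecific, heterospecific neighbour; columns: aggregative,
    non-aggregative (avoidant + neutral pooled).
    """
    table = np.zeros((2, 2), dtype=int)
    for label, identity in calls:
        if identity not in ("conspecific", "heterospecific"):
            raise ValueError(
                f"neighbour identity must be conspecific/heterospecific, "
                f"got {identity!r}"
            )
        if label not in BEHAVIOUR_LABELS:
            raise ValueError(f"unknown behaviour label {label!r}")
        row = 0 if identity == "conspecific" else 1
        col = 0 if label == "aggregative" else 1
        table[row, col] += 1
    return table
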