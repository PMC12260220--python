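"""Directional-growth statistics for aggregative plants.

For every plant called aggregative, the global growth angle θg is the
signed angle, in the horizontal interaction plane, between the
plant-to-neighbour direction PN and the overall displacement of the root
tip from its initial position to the position where the behaviour was
identified. θg = 0° means the root grew exactly along the axis toward the
neighbour; the sign is positive counter-clockwise viewed from above, and
the ±180° boundary maps to +180°.

If aggregative roots target the neighbour geometrically, the θg values
should scatter normally around 0°; normality is tested with Shapiro–Wilk.
The association of aggregative behaviour with neighbour identity
(conspecific vs heterospecific) is tested with a 2x2 chi-square with
Yates' continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .behaviour import BehaviourCall, neighbour_vector
from .trajectory import PlaneConvention, PlantPair


@dataclass
class ContingencyStat:
    """Chi-square test with Yates' correction on a 2x2 table (df = 1)."""

    table: np.ndarray
    chi2_yates: float
    p_value: float
    df: int = 1


@dataclass
class DirectionalResult:
    """θg distribution summary plus normality diagnostics."""

    theta_g: dict[str, float]                  # plant_id -> degrees
    shapiro_W: float | None
    shapiro_p: float | None
    shapiro_by_species: dict[str, tuple[float, float]] = field(default_factory=dict)
    histogram_counts: np.ndarray | None = None
    histogram_edges: np.ndarray | None = None
    qq_points: np.ndarray | None = None        # (n, 2): theoretical, sample


def signed_planar_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Signed angle (degrees) from 2-vector ``a`` to 2-vector ``b`` in
    (-180, 180], counter-clockwise positive; the -180° boundary maps to
    +180°."""
    cross = a[0] * b[1] - a[1] * b[0]
    dot = float(np.dot(a, b))
    ang = float(np.degrees(np.arctan2(cross, dot)))
    if ang == -180.0:
        ang = 180.0
    return ang


def global_growth_angle(
    pair: PlantPair,
    call: BehaviourCall,
    convention: PlaneConvention | None = None,
) -> float:
    """Signed global growth angle θg (degrees) for one plant.

    The global displacement runs from the initial tip position to the tip
    position at which the behaviour was identified (threshold-crossing hour
    for threshold calls, last sample otherwise).
    """
    convention = convention or PlaneConvention()
    pn = neighbour_vector(pair, convention)
    p0pend = (convention.horizontal(np.asarray(call.rp_end))
              - convention.horizontal(pair.rp0))
    if np.linalg.norm(p0pend) == 0:
        raise ValueError("zero horizontal displacement: θg undefined")
    return signed_planar_angle(pn, p0pend)


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W statistic, p-value)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or values.size > 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro–Wilk undefined for constant input")
    res = sp_stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


def chi_square_yates(table: np.ndarray) -> ContingencyStat:
    """Chi-square statistic with Yates' continuity correction for a 2x2
    table of counts: sum over cells of (|O - E| - 0.5)^2 / E, with expected
    counts from the marginals and p from the chi-square distribution with
    one degree of freedom."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    n = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("all marginals must be positive")
    expected = np.outer(rows, cols) / n
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    stat = float(np.sum(adj ** 2 / expected))
    p = float(sp_stats.chi2.sf(stat, df=1))
    return ContingencyStat(table=obs.astype(int), chi2_yates=stat, p_value=p)


def directional_report(
    pairs: dict[str, PlantPair],
    calls: dict[str, BehaviourCall],
    neighbour_identity: dict[str, str],
    species: dict[str, str] | None = None,
    convention: PlaneConvention | None = None,
    n_bins: int = 10,
) -> tuple[DirectionalResult, ContingencyStat]:
    """θg statistics over aggregative plants + behaviour-identity association.

    ``pairs``, ``calls`` and ``neighbour_identity`` are keyed by plant id.
    θg is computed only for aggregative calls; Shapiro–Wilk runs on the
    pooled θg values (and per species when given) whenever at least three
    non-constant values are available. The contingency test covers all
    social plants.
    """
    convention = convention or PlaneConvention()
    theta: dict[str, float] = {}
    for pid, call in calls.items():
        if call.label == "aggregative":
            theta[pid] = global_growth_angle(pairs[pid], call, convention)

    w = p = None
    hist_counts = hist_edges = qq = None
    by_species: dict[str, tuple[float, float]] = {}
    vals = np.array(list(theta.values()))
    if vals.size >= 3 and np.ptp(vals) > 0:
        w, p = shapiro_wilk(vals)
        hist_counts, hist_edges = np.histogram(vals, bins=n_bins,
                                               range=(-180.0, 180.0))
        # Blom plotting positions against the fitted normal.
        order = np.sort(vals)
        n = vals.size
        probs = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
        theo = sp_stats.norm.ppf(probs, loc=vals.mean(), scale=vals.std(ddof=1))
        qq = np.column_stack([theo, order])
        if species:
            for sp in sorted(set(species.values())):
                sub = np.array([theta[pid] for pid in theta
                                if species.get(pid) == sp])
                if sub.size >= 3 and np.ptp(sub) > 0:
                    by_species[sp] = shapiro_wilk(sub)
    else:
        import logging
        logging.getLogger("rootkin").warning(
            "fewer than 3 distinct θg values: normality test skipped"
        )

    counts = np.zeros((2, 2), dtype=int)
    for pid, call in calls.items():
        ident = neighbour_identity[pid]
        row = 0 if ident == "conspecific" else 1
        col = 0 if call.label == "aggregative" else 1
        counts[row, col] += 1
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        import logging
        logging.getLogger("rootkin").warning(
            "degenerate contingency table (zero marginal): test undefined"
        )
        contingency = ContingencyStat(table=counts, chi2_yates=float("nan"),
                                      p_value=float("nan"))
    else:
        contingency = chi_square_yates(counts)

    result = DirectionalResult(
        theta_g=theta, shapiro_W=w, shapiro_p=p,
        shapiro_by_species=by_species,
        histogram_counts=hist_counts, histogram_edges=hist_edges,
        qq_points=qq,
    )
    return result, contingency
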