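"""Duration selectivity: interval tuning of presaccadic firing.

Each neuron's mean rate in the 200 ms before the saccade is measured per
mandatory-interval condition, normalized to sum to one, and embedded in an
equilateral triangle: x = n_medium - n_long, y = n_short * sqrt(3).  Pure
preference for short/medium/long maps to the vertices (0, sqrt3), (1, 0),
(-1, 0); a neuron indifferent to interval sits at the centroid
(0, sqrt3/3).  The distance from the centroid quantifies selectivity, and
structures are compared by a two-sample Kolmogorov-Smirnov test on the
distance distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import SessionData

logger = logging.getLogger(__name__)

CONDITIONS = ("short", "medium", "long")
CENTROID = (0.0, np.sqrt(3.0) / 3.0)
PRESACCADIC_MS = 200.0

__all__ = [
    "SelectivityResult",
    "presaccadic_rates",
    "presaccadic_trial_rates",
    "triangle_embed",
    "classify_duration_selective",
    "distance_cdf_compare",
]


@dataclass(frozen=True)
class SelectivityResult:
    rates: dict[str, float]  # mean presaccadic rate per condition
    normalized: tuple[float, float, float]  # (n_s, n_m, n_l), sums to 1
    xy: tuple[float, float]
    distance_from_center: float
    anova_p: float
    preferred: str  # short | medium | long | none


def presaccadic_trial_rates(
    session: SessionData, direction: str
) -> dict[str, np.ndarray]:
    """Trial-wise rate (spikes/s) in [-200, 0) ms before the saccade, per condition."""
    out: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        trials = session.valid_trials(cond, direction)
        if not trials:
            raise ValueError(f"{session.neuron_id}: no trials for condition {cond!r}")
        rates = []
        for tr in trials:
            train = session.spikes.get(tr.trial_id, np.empty(0))
            n = np.count_nonzero(
                (train >= tr.saccade_ms - PRESACCADIC_MS) & (train < tr.saccade_ms)
            )
            rates.append(n / PRESACCADIC_MS * 1000.0)
        out[cond] = np.asarray(rates)
    return out


def presaccadic_rates(session: SessionData, direction: str) -> dict[str, float]:
    """Mean presaccadic rate per condition (>=6 trials each required)."""
    trial_rates = presaccadic_trial_rates(session, direction)
    for cond, r in trial_rates.items():
        if r.size < 6:
            raise ValueError(
                f"{session.neuron_id}: {r.size} trials in {cond!r}; need >= 6"
            )
    return {cond: float(r.mean()) for cond, r in trial_rates.items()}


def triangle_embed(rates: dict[str, float]) -> tuple[tuple[float, float], float]:
    """Map per-condition rates to the triangle and its centroid distance.

    Rates are normalized to sum to one; x = n_m - n_l, y = n_s * sqrt(3);
    the distance is Euclidean from the centroid (0, sqrt3/3).  All-zero
    rates are undefined (ValueError; caller excludes the neuron).
    """
    r = np.array([rates[c] for c in CONDITIONS], dtype=float)
    total = r.sum()
    if total <= 0:
        raise ValueError("all-zero presaccadic rates: embedding undefined")
    n_s, n_m, n_l = r / total
    x = n_m - n_l
    y = n_s * np.sqrt(3.0)
    dist = float(np.hypot(x - CENTROID[0], y - CENTROID[1]))
    return (float(x), float(y)), dist


def classify_duration_selective(
    trial_rates: dict[str, np.ndarray], alpha: float = 0.01
) -> tuple[float, str]:
    """One-way ANOVA across conditions on trial-wise presaccadic rates.

    Returns (p, preferred); preferred is the argmax-mean condition when
    p < alpha, else 'none'.  Degenerate zero within-condition variance with
    unequal means hits the exact F limit (p -> 0).
    """
    groups = [np.asarray(trial_rates[c], dtype=float) for c in CONDITIONS]
    if any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 trials per condition")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        return 1.0, "none"
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.f_oneway(*groups)
    if np.isnan(p):
        p = 1.0
    p = float(p)
    if p < alpha:
        means = [g.mean() for g in groups]
        return p, CONDITIONS[int(np.argmax(means))]
    return p, "none"


def analyze_neuron(
    session: SessionData, direction: str, alpha: float = 0.01
) -> SelectivityResult:
    """Full per-neuron selectivity analysis for one saccade direction."""
    trial_rates = presaccadic_trial_rates(session, direction)
    rates = {c: float(r.mean()) for c, r in trial_rates.items()}
    xy, dist = triangle_embed(rates)
    p, preferred = classify_duration_selective(trial_rates, alpha)
    total = sum(rates[c] for c in CONDITIONS)
    normalized = tuple(rates[c] / total for c in CONDITIONS)
    return SelectivityResult(
        rates=rates, normalized=normalized, xy=xy,
        distance_from_center=dist, anova_p=p, preferred=preferred,
    )


def distance_cdf_compare(
    distances_a: np.ndarray, distances_b: np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of centroid-distance CDFs."""
    a = np.asarray(distances_a, dtype=float)
    b = np.asarray(distances_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need >= 5 neurons per group")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
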