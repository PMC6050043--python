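"""Pre/post inactivation behavioral statistics.

Muscimol sessions compare saccade-latency distributions before and during
inactivation, per (condition x direction x task) cell: median shift with a
two-sided Wilcoxon rank-sum test, dispersion change with a two-sided
variance-ratio F test, both Bonferroni-corrected within session across the
cells tested.  Population-level effects are paired t-tests across sessions
on the per-session median (and SD, CV) changes, with 95% confidence
intervals.  Saline sessions run through the identical statistics as the
volume-effect control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "InactivationSession",
    "CellStats",
    "PopulationEffect",
    "session_latency_shift",
    "session_variance_change",
    "analyze_session",
    "population_effect",
    "saline_control",
]

AGENTS = {"muscimol", "saline"}


@dataclass
class InactivationSession:
    """One injection experiment: pre/post latencies per analysis cell.

    ``cells`` maps (condition, direction, task) to (pre, post) latency
    arrays (ms).
    """

    site: str  # striatum | cerebellum
    agent: str  # muscimol | saline
    cells: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]]
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.agent not in AGENTS:
            raise ValueError(f"unknown agent {self.agent!r}")
        for key, (pre, post) in self.cells.items():
            if len(pre) == 0 or len(post) == 0:
                raise ValueError(f"empty pre/post sample in cell {key}")
            if np.any(np.asarray(pre) <= 0) or np.any(np.asarray(post) <= 0):
                raise ValueError(f"non-positive latency in cell {key}")


@dataclass(frozen=True)
class CellStats:
    delta_median: float
    ranksum_p: float
    ranksum_p_adj: float
    f_stat: float
    f_p: float
    f_p_adj: float
    delta_sd: float
    delta_cv: float
    flags: tuple[str, ...] = ()


def session_latency_shift(
    pre: np.ndarray, post: np.ndarray
) -> tuple[float, float, tuple[str, ...]]:
    """Post-minus-pre median latency shift and two-sided rank-sum p.

    Uses the exact Mann-Whitney null when both samples are small and
    untied; all-tied samples return p = 1 with a flag.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size < 5 or post.size < 5:
        raise ValueError("need >= 5 trials in each of pre and post")
    delta = float(np.median(post) - np.median(pre))
    flags: tuple[str, ...] = ()
    if np.ptp(np.concatenate([pre, post])) == 0:
        return delta, 1.0, ("all_tied",)
    method = "exact" if (pre.size <= 60 and post.size <= 60) else "asymptotic"
    p = float(stats.mannwhitneyu(post, pre, alternative="two-sided", method=method).pvalue)
    return delta, p, flags


def session_variance_change(
    pre: np.ndarray, post: np.ndarray
) -> tuple[float, float, float, float, tuple[str, ...]]:
    """Two-sided variance-ratio F test plus SD and CV changes.

    F = var(post)/var(pre) with df (n_post-1, n_pre-1); the two-sided p is
    2*min(P(F >= f), P(F <= f)).  Zero pre-variance is flagged and yields
    an undefined (inf) ratio.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size < 5 or post.size < 5:
        raise ValueError("need >= 5 trials in each of pre and post")
    v_pre = pre.var(ddof=1)
    v_post = post.var(ddof=1)
    d_sd = float(post.std(ddof=1) - pre.std(ddof=1))
    d_cv = float(post.std(ddof=1) / post.mean() - pre.std(ddof=1) / pre.mean())
    if v_pre == 0:
        if v_post == 0:
            return 1.0, 1.0, d_sd, d_cv, ("zero_variance",)
        return float("inf"), 0.0, d_sd, d_cv, ("zero_pre_variance",)
    f = float(v_post / v_pre)
    dfn, dfd = post.size - 1, pre.size - 1
    p = 2.0 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
    return f, float(min(p, 1.0)), d_sd, d_cv, ()


def analyze_session(session: InactivationSession) -> dict[tuple[str, str, str], CellStats]:
    """Per-cell statistics with per-session Bonferroni correction.

    The Bonferroni family is the set of (condition x direction x task) cells
    tested in this session; adjusted p = min(1, m * p).
    """
    m = len(session.cells)
    out: dict[tuple[str, str, str], CellStats] = {}
    for key, (pre, post) in session.cells.items():
        delta, p_rs, flags1 = session_latency_shift(pre, post)
        f, p_f, d_sd, d_cv, flags2 = session_variance_change(pre, post)
        out[key] = CellStats(
            delta_median=delta,
            ranksum_p=p_rs,
            ranksum_p_adj=min(1.0, m * p_rs),
            f_stat=f,
            f_p=p_f,
            f_p_adj=min(1.0, m * p_f),
            delta_sd=d_sd,
            delta_cv=d_cv,
            flags=flags1 + flags2,
        )
    return out


@dataclass(frozen=True)
class PopulationEffect:
    mean_change: float
    ci95: tuple[float, float]
    t_stat: float
    p: float
    n_sessions: int
    degenerate: bool = False  # zero spread with nonzero mean change


def _paired_t(deltas: np.ndarray) -> PopulationEffect:
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.size
    if n < 3:
        raise ValueError("population test needs >= 3 sessions")
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1))
    if sd == 0:
        # zero spread: t undefined; nonzero mean flagged significant-by-degeneracy
        return PopulationEffect(
            mean_change=mean, ci95=(mean, mean), t_stat=float("nan"),
            p=0.0 if mean != 0 else 1.0, n_sessions=n, degenerate=True,
        )
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    half = float(stats.t.ppf(0.975, n - 1) * se)
    return PopulationEffect(
        mean_change=mean, ci95=(mean - half, mean + half),
        t_stat=float(t), p=p, n_sessions=n,
    )


def population_effect(
    sessions: list[InactivationSession],
) -> dict[tuple[str, str, str], dict[str, PopulationEffect]]:
    """Paired t-tests across sessions on median, SD and CV changes per cell.

    Only cells present in >= 3 sessions are tested; each returns effects
    keyed 'median', 'sd' and 'cv' with mean change and 95% CI.
    """
    by_cell: dict[tuple[str, str, str], dict[str, list[float]]] = {}
    for s in sessions:
        for key, (pre, post) in s.cells.items():
            d = by_cell.setdefault(key, {"median": [], "sd": [], "cv": []})
            d["median"].append(float(np.median(post) - np.median(pre)))
            d["sd"].append(float(post.std(ddof=1) - pre.std(ddof=1)))
            d["cv"].append(
                float(post.std(ddof=1) / post.mean() - pre.std(ddof=1) / pre.mean())
            )
    out: dict[tuple[str, str, str], dict[str, PopulationEffect]] = {}
    for key, deltas in by_cell.items():
        if len(deltas["median"]) < 3:
            logger.info("cell %s skipped: <3 sessions", key)
            continue
        out[key] = {
            stat: _paired_t(np.asarray(vals)) for stat, vals in deltas.items()
        }
    return out


def saline_control(
    sessions: list[InactivationSession],
) -> dict[tuple[str, str, str], dict[str, PopulationEffect]] | None:
    """The same population statistics restricted to saline sessions.

    Returns None (an explicit absence report is logged) when no saline
    sessions exist; mislabeled agents raise at session construction.
    """
    saline = [s for s in sessions if s.agent == "saline"]
    if not saline:
        logger.info("no saline sessions: control analysis absent")
        return None
    return population_effect(saline)
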