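"""Epoch firing rates, task-related classification, baseline variability.

Epochs (all relative to each trial's own events):

* baseline -- 300 ms just before fixation-point onset
* visual   -- 200 ms after cue onset
* delay    -- 350 ms starting 500 ms before the saccade
* saccade  -- 150 ms before saccade initiation

A neuron is task-related when a one-way ANOVA across the four epochs is
significant (p < 0.05) and Scheffe's post-hoc contrast of delay vs baseline
is too (p < 0.05).  The Scheffe criterion is computed from its F-based
definition: for contrast L with estimated variance V(L), the statistic
L^2 / ((k-1) V(L)) is referred to F(k-1, N-k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SessionData

logger = logging.getLogger(__name__)

EPOCHS = ("baseline", "visual", "delay", "saccade")

__all__ = [
    "epoch_rates",
    "classify_task_related",
    "baseline_cv",
    "TaskRelatedLabel",
    "scheffe_contrast",
]


@dataclass(frozen=True)
class TaskRelatedLabel:
    is_task_related: bool
    anova_p: float
    scheffe_p_delay_vs_baseline: float
    direction_p: float | None = None


def _window_rate(train: np.ndarray, start: float, end: float) -> float:
    n = int(np.count_nonzero((train >= start) & (train < end)))
    return n / (end - start) * 1000.0


def epoch_rates(session: SessionData) -> pd.DataFrame:
    """Per-trial firing rate (spikes/s) in the four task epochs.

    Trials whose baseline window would start before the recording are
    dropped with a log entry.  Returns one row per valid trial with columns
    trial_id, condition, direction and the four epoch rates.
    """
    rows = []
    n_dropped = 0
    for trial in session.valid_trials():
        if trial.fp_on_ms - 300.0 < 0:
            n_dropped += 1
            continue
        train = session.spikes.get(trial.trial_id, np.empty(0))
        rows.append(
            {
                "trial_id": trial.trial_id,
                "condition": trial.condition,
                "direction": trial.direction,
                "baseline": _window_rate(train, trial.fp_on_ms - 300.0, trial.fp_on_ms),
                "visual": _window_rate(train, trial.cue_on_ms, trial.cue_on_ms + 200.0),
                "delay": _window_rate(
                    train, trial.saccade_ms - 500.0, trial.saccade_ms - 150.0
                ),
                "saccade": _window_rate(
                    train, trial.saccade_ms - 150.0, trial.saccade_ms
                ),
            }
        )
    if n_dropped:
        logger.info(
            "%s: dropped %d trials with baseline before recording start",
            session.neuron_id, n_dropped,
        )
    return pd.DataFrame(rows, columns=["trial_id", "condition", "direction", *EPOCHS])


def scheffe_contrast(
    groups: list[np.ndarray], coeffs: np.ndarray
) -> tuple[float, float]:
    """Scheffe test of a contrast among k group means.

    Returns (F_scheffe, p) where F_scheffe = L^2 / ((k-1) * V(L)) with
    V(L) = MSE * sum(c_j^2 / n_j), referred to F(k-1, N-k).  Significance at
    level alpha is equivalent to L^2/V(L) exceeding (k-1) F_alpha(k-1, N-k),
    the classical Scheffe criterion.
    """
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    if np.any(n < 2):
        raise ValueError("each epoch needs at least 2 trials")
    means = np.array([g.mean() for g in groups])
    big_n = n.sum()
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_err = big_n - k
    mse = sse / df_err
    contrast = float(coeffs @ means)
    var_l = mse * float((coeffs**2 / n).sum())
    if var_l == 0:
        return (np.inf, 0.0) if contrast != 0 else (0.0, 1.0)
    f_scheffe = contrast**2 / ((k - 1) * var_l)
    p = float(stats.f.sf(f_scheffe, k - 1, df_err))
    return float(f_scheffe), p


def classify_task_related(
    rates: pd.DataFrame, alpha: float = 0.05
) -> TaskRelatedLabel:
    """Task-related label from the four-epoch rate table of one neuron.

    One-way ANOVA across the four epochs over trials, then the Scheffe
    delay-vs-baseline contrast; the label is true iff both p < alpha.  The
    direction p-value is a Wilcoxon rank-sum of contra vs ipsi delay rates
    (None when one direction is absent).
    """
    if len(rates) < 2:
        raise ValueError("need at least 2 trials per epoch")
    groups = [rates[e].to_numpy(dtype=float) for e in EPOCHS]
    if np.ptp(np.concatenate(groups)) == 0:
        anova_p = 1.0  # all epochs identical: F = 0 by convention
    else:
        with np.errstate(invalid="ignore"):
            _, anova_p = stats.f_oneway(*groups)
        if np.isnan(anova_p):
            anova_p = 1.0
    coeffs = np.array([-1.0, 0.0, 1.0, 0.0])  # delay - baseline
    _, scheffe_p = scheffe_contrast(groups, coeffs)
    contra = rates.loc[rates["direction"] == "contra", "delay"].to_numpy()
    ipsi = rates.loc[rates["direction"] == "ipsi", "delay"].to_numpy()
    if len(contra) and len(ipsi):
        direction_p = float(
            stats.mannwhitneyu(contra, ipsi, alternative="two-sided").pvalue
        )
    else:
        direction_p = None
    return TaskRelatedLabel(
        is_task_related=bool(anova_p < alpha and scheffe_p < alpha),
        anova_p=float(anova_p),
        scheffe_p_delay_vs_baseline=float(scheffe_p),
        direction_p=direction_p,
    )


def baseline_cv(
    sessions_a: list[SessionData], sessions_b: list[SessionData]
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-neuron baseline CV for two structures and their unpaired t-test.

    CV is the across-trial sd/mean of baseline-epoch rates; neurons with
    fewer than 5 trials or zero mean baseline are excluded with a log entry.
    Returns (cv_a, cv_b, t, p).
    """

    def cvs(sessions: list[SessionData]) -> np.ndarray:
        out = []
        for s in sessions:
            rates = epoch_rates(s)
            if len(rates) < 5:
                logger.info("%s excluded from CV: <5 trials", s.neuron_id)
                continue
            base = rates["baseline"].to_numpy(dtype=float)
            if base.mean() == 0:
                logger.info("%s excluded from CV: zero mean baseline", s.neuron_id)
                continue
            out.append(base.std(ddof=1) / base.mean())
        return np.asarray(out)

    cv_a, cv_b = cvs(sessions_a), cvs(sessions_b)
    if (
        cv_a.size
        and cv_b.size
        and cv_a.mean() == cv_b.mean()
        and np.concatenate([cv_a, cv_b]).var() == 0
    ):
        return cv_a, cv_b, 0.0, 1.0  # degenerate symmetric null
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(cv_a, cv_b)
    return cv_a, cv_b, float(t), float(p)
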