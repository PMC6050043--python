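"""Delayed-ramp regression of population activity and its neuron bootstrap.

The population trace over the delay period is fit with two lines sharing a
knot: f(t) = b for t < t0 and f(t) = b + k (t - t0) afterwards.  The onset
t0 is profiled over every 1-ms grid point in the fit window; conditional on
t0 the (b, k) solution is closed-form least squares, so the minimizer is
found exactly (earliest t0 on ties).  The fit window runs from 300 ms before
cue onset (configurable to 400) to the mean saccade latency, excluding the
200 ms that start 50 ms after the cue to remove the visual transient.

Confidence intervals come from resampling neurons with replacement: each
resample is re-normalized, re-averaged and re-fit, and the 2.5/50/97.5
percentiles are reported.  Cross-structure comparisons use the paired
difference distribution over resample index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .preprocess import DensityTrace, PopulationTrace, normalize_neuron

logger = logging.getLogger(__name__)

DEFAULT_PRECUE_MS = 300.0
EXCLUSION_MS = (50.0, 250.0)

__all__ = [
    "RampFitResult",
    "BootstrapSummary",
    "fit_ramp",
    "fit_two_line",
    "bootstrap_ramp",
    "compare_structures",
]


@dataclass(frozen=True)
class RampFitResult:
    baseline: float  # b, normalized units
    onset: float  # t0, ms in the trace's alignment frame
    slope: float  # k, normalized units per ms
    r2: float
    fit_window: tuple[float, float]
    excluded_window: tuple[float, float]


@dataclass
class BootstrapSummary:
    onset_samples: np.ndarray
    slope_samples: np.ndarray
    onset_percentiles: tuple[float, float, float]  # 2.5, 50, 97.5
    slope_percentiles: tuple[float, float, float]
    n_neurons: int
    seed: int
    n_refit: int = 0
    point: RampFitResult | None = None


def fit_two_line(
    t: np.ndarray, y: np.ndarray, include: np.ndarray
) -> tuple[float, float, float, float]:
    """Exact profiled least squares for f(t) = b + k relu(t - t0).

    ``include`` masks the samples entering the residual; t0 candidates range
    over every grid point (masked ones too).  Conditional on t0 the normal
    equations are solved from suffix sums in O(len(t)).  Returns
    (b, t0, k, r2); a flat trace falls back to the convention t0 = window
    end, k = 0, r2 = 0.
    """
    ti = t[include]
    yi = y[include]
    n = ti.size
    if n < 10:
        raise ValueError(f"only {n} included samples; need >= 10")
    sy = yi.sum()
    syy = float(yi @ yi)
    sst = syy - sy**2 / n
    # constant trace (up to roundoff): every t0 is optimal; take window end
    if sst <= 1e-12 * max(syy, 1e-300):
        return float(sy / n), float(t[-1]), 0.0, 0.0

    # suffix sums over included samples with time >= each candidate t0
    idx = np.searchsorted(ti, t)  # ti sorted ascending
    c1 = np.concatenate([np.cumsum(np.ones(n)[::-1])[::-1], [0.0]])
    ct = np.concatenate([np.cumsum(ti[::-1])[::-1], [0.0]])
    ct2 = np.concatenate([np.cumsum((ti**2)[::-1])[::-1], [0.0]])
    cy = np.concatenate([np.cumsum(yi[::-1])[::-1], [0.0]])
    cty = np.concatenate([np.cumsum((ti * yi)[::-1])[::-1], [0.0]])
    cnt, st, st2, sy_s, sty = c1[idx], ct[idx], ct2[idx], cy[idx], cty[idx]

    su = st - t * cnt
    su2 = st2 - 2.0 * t * st + t**2 * cnt
    syu = sty - t * sy_s
    det = n * su2 - su**2
    ok = det > 1e-10 * np.maximum(1.0, n * su2)
    b = np.where(ok, (su2 * sy - su * syu) / np.where(det == 0, 1.0, det), sy / n)
    k = np.where(ok, (n * syu - su * sy) / np.where(det == 0, 1.0, det), 0.0)
    sse = syy - b * sy - k * syu
    j = int(np.argmin(sse))  # argmin takes the earliest t0 on exact ties
    r2 = 1.0 - float(sse[j]) / sst
    return float(b[j]), float(t[j]), float(k[j]), float(min(max(r2, 0.0), 1.0))


def _fit_window(
    align: str, mean_latency: float, precue_ms: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Fit and exclusion windows in the alignment frame."""
    if align == "cue":
        win = (-precue_ms, mean_latency)
        excl = EXCLUSION_MS
    elif align == "saccade":
        win = (-(mean_latency + precue_ms), 0.0)
        excl = (-mean_latency + EXCLUSION_MS[0], -mean_latency + EXCLUSION_MS[1])
    else:
        raise ValueError(f"unknown alignment {align!r}")
    return win, excl


def fit_ramp(
    pop: PopulationTrace,
    mean_latency: float,
    align: str,
    *,
    precue_ms: float = DEFAULT_PRECUE_MS,
) -> RampFitResult:
    """Two-line delayed-ramp fit of a population trace.

    Cue-aligned: window [-precue_ms, mean_latency], excluding
    [cue+50, cue+250).  Saccade-aligned: the same span mapped through the
    mean latency so the window ends at the saccade (t = 0).
    """
    win, excl = _fit_window(align, mean_latency, precue_ms)
    if pop.t[0] > win[0] + 1.0 or pop.t[-1] < win[1] - 1.0:
        raise ValueError("trace does not cover the fit window")
    m = (pop.t >= win[0]) & (pop.t <= win[1])
    t = pop.t[m]
    y = pop.value[m]
    include = ~((t >= excl[0]) & (t < excl[1]))
    b, t0, k, r2 = fit_two_line(t, y, include)
    return RampFitResult(
        baseline=b, onset=t0, slope=k, r2=r2, fit_window=win, excluded_window=excl
    )


def _population_for(
    normalized: Sequence[Mapping[object, DensityTrace]],
    key: object,
    take: np.ndarray,
) -> PopulationTrace:
    stack = np.stack([normalized[i][key].rate for i in take])
    ref = normalized[take[0]][key]
    return PopulationTrace(
        t=ref.t, value=stack.mean(axis=0), align=ref.align,
        condition=ref.condition, direction=ref.direction, n_neurons=len(take),
    )


def bootstrap_ramp(
    neuron_traces: Sequence[Mapping[object, DensityTrace]],
    key: object,
    mean_latency: float,
    align: str,
    *,
    B: int = 1000,
    seed: int = 0,
    precue_ms: float = DEFAULT_PRECUE_MS,
    scales: Sequence[tuple[float, float]] | None = None,
) -> BootstrapSummary:
    """Neuron-level bootstrap of the ramp fit.

    ``neuron_traces`` holds each neuron's raw traces keyed by (condition,
    align); ``key`` selects the trace being fit.  Each of the B resamples
    draws neurons with replacement, re-normalizes (normalization is
    per-neuron, so cached per neuron), re-averages and re-fits.  ``scales``
    optionally supplies per-neuron (baseline, modulation depth) pairs for
    the normalization.  Resamples that fail to fit are redrawn and counted.
    Per-resample RNG streams are derived from (seed, resample counter), so
    results do not depend on evaluation order.
    """
    if len(neuron_traces) < 2:
        raise ValueError("bootstrap needs >= 2 neurons")
    if scales is None:
        normalized = [normalize_neuron(tr) for tr in neuron_traces]
    else:
        normalized = [
            normalize_neuron(tr, scale=sc) for tr, sc in zip(neuron_traces, scales)
        ]
    normalized = [n for n in normalized if n is not None]
    n = len(normalized)
    onsets = np.empty(B)
    slopes = np.empty(B)
    n_refit = 0
    for i in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        for _attempt in range(100):
            take = rng.integers(0, n, size=n)
            pop = _population_for(normalized, key, take)
            try:
                res = fit_ramp(pop, mean_latency, align, precue_ms=precue_ms)
            except ValueError:
                n_refit += 1
                continue
            onsets[i], slopes[i] = res.onset, res.slope
            break
        else:
            raise RuntimeError("bootstrap resample failed to fit 100 times")
    if n_refit:
        logger.info("bootstrap: %d resamples redrawn after fit failure", n_refit)
    point = fit_ramp(
        _population_for(normalized, key, np.arange(n)),
        mean_latency, align, precue_ms=precue_ms,
    )
    return BootstrapSummary(
        onset_samples=onsets,
        slope_samples=slopes,
        onset_percentiles=tuple(np.percentile(onsets, [2.5, 50, 97.5])),
        slope_percentiles=tuple(np.percentile(slopes, [2.5, 50, 97.5])),
        n_neurons=n,
        seed=seed,
        n_refit=n_refit,
        point=point,
    )


def compare_structures(
    a: BootstrapSummary, b: BootstrapSummary
) -> dict[str, bool]:
    """Flag parameters whose bootstrap difference distribution excludes 0.

    Differences are paired by resample index; a parameter is significant
    when the central 95% interval of (a - b) excludes zero.
    """
    if a.onset_samples.size != b.onset_samples.size:
        raise ValueError("bootstrap summaries have mismatched B")
    out = {}
    for name, xa, xb in (
        ("onset", a.onset_samples, b.onset_samples),
        ("slope", a.slope_samples, b.slope_samples),
    ):
        lo, hi = np.percentile(xa - xb, [2.5, 97.5])
        out[name] = bool(lo > 0 or hi < 0)
    return out
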