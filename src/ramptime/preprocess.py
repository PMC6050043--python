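"""Alignment, filtering and kernel smoothing of raw spike/eye sessions.

Turns per-neuron session files into event-aligned firing-rate traces:
saccade detection from 1-kHz eye velocity (40 deg/s threshold with a >3 deg
displacement gate), landing-error trial exclusion (>5 deg), spike-density
estimation with a Gaussian kernel (sigma = 15 ms) on a 1-ms grid, per-neuron
normalization and population averaging, and translation of saccade-aligned
traces into the cue frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

logger = logging.getLogger(__name__)

KERNEL_SIGMA_MS = 15.0
VELOCITY_THRESHOLD_DEG_S = 40.0
DISPLACEMENT_GATE_DEG = 3.0
LANDING_ERROR_LIMIT_DEG = 5.0

__all__ = [
    "TrialRecord",
    "SessionData",
    "DensityTrace",
    "PopulationTrace",
    "detect_saccade",
    "filter_trials",
    "spike_density",
    "density_from_trains",
    "trial_densities",
    "normalize_neuron",
    "normalize_population",
    "shift_to_cue_frame",
    "EmptyCellError",
]


class EmptyCellError(ValueError):
    """No valid trials in the requested (condition, direction) cell."""


@dataclass(frozen=True)
class TrialRecord:
    trial_id: int
    condition: str  # short | medium | long
    direction: str  # contra | ipsi
    cue_on_ms: float
    saccade_ms: float
    fp_on_ms: float = 0.0
    task: str = "self_timed"
    landing_error_deg: float = 0.0
    valid: bool = True

    def __post_init__(self) -> None:
        if self.condition not in {"short", "medium", "long"}:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.direction not in {"contra", "ipsi"}:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.valid and self.saccade_ms <= self.cue_on_ms:
            raise ValueError("valid trials require saccade after cue onset")

    @property
    def latency_ms(self) -> float:
        """Cue-to-saccade interval for self-timed trials."""
        return self.saccade_ms - self.cue_on_ms


@dataclass
class SessionData:
    """One neuron's trials, per-trial spike trains and optional eye traces.

    Spike times are on the trial clock (ms from trial start), sorted.
    """

    neuron_id: str
    structure: str  # striatum | cerebellum
    trials: list[TrialRecord]
    spikes: dict[int, np.ndarray]
    eye: dict[int, pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        if self.structure not in {"striatum", "cerebellum"}:
            raise ValueError(f"unknown structure {self.structure!r}")
        ids = {t.trial_id for t in self.trials}
        for tid, train in self.spikes.items():
            if tid not in ids:
                raise ValueError(f"spike train for unknown trial_id {tid}")
            if np.any(np.diff(train) < 0):
                raise ValueError(f"spikes not sorted in trial {tid}")

    def valid_trials(
        self, condition: str | None = None, direction: str | None = None
    ) -> list[TrialRecord]:
        return [
            t
            for t in self.trials
            if t.valid
            and (condition is None or t.condition == condition)
            and (direction is None or t.direction == direction)
        ]

    def preferred_direction(self) -> str:
        """Direction with the larger mean delay-period rate.

        The delay epoch is the 350-ms window starting 500 ms before the
        saccade; ties break to 'contra'.
        """
        from .quantify import epoch_rates  # late import: avoid cycle

        rates = epoch_rates(self)
        means = rates.groupby("direction", observed=True)["delay"].mean()
        if "ipsi" in means and means.get("ipsi", 0.0) > means.get("contra", 0.0):
            return "ipsi"
        return "contra"


@dataclass
class DensityTrace:
    """Trial-averaged firing rate on a 1-ms grid relative to an event."""

    t: np.ndarray  # ms relative to alignment event, spacing exactly 1
    rate: np.ndarray  # spikes/s, >= 0
    align: str  # cue | saccade
    condition: str
    direction: str
    n_trials: int
    kernel_sigma_ms: float = KERNEL_SIGMA_MS

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.t.shape != self.rate.shape:
            raise ValueError("t and rate must have the same shape")
        if self.t.size > 1 and not np.allclose(np.diff(self.t), 1.0):
            raise ValueError("grid spacing must be exactly 1 ms")


@dataclass
class PopulationTrace:
    """Average of per-neuron normalized traces; values in roughly [-eps, 1]."""

    t: np.ndarray
    value: np.ndarray
    align: str
    condition: str
    direction: str
    n_neurons: int


def detect_saccade(eye: pd.DataFrame) -> float | None:
    """First saccade onset (ms, trace clock) from a 1-kHz eye trace.

    Velocity is the central difference of position smoothed with a 5-ms
    boxcar; onset is the first threshold crossing (40 deg/s) belonging to a
    movement whose net displacement exceeds 3 deg.  Returns None when no
    suprathreshold movement passes the displacement gate.
    """
    if len(eye) < 50:
        raise ValueError("eye trace shorter than 50 ms")
    t = eye["t_ms"].to_numpy(dtype=float)
    x = eye["x_deg"].to_numpy(dtype=float)
    y = eye["y_deg"].to_numpy(dtype=float)
    vx = np.gradient(x, t) * 1000.0  # deg/s
    vy = np.gradient(y, t) * 1000.0
    speed = np.hypot(uniform_filter1d(vx, 5), uniform_filter1d(vy, 5))
    above = speed > VELOCITY_THRESHOLD_DEG_S
    if not above.any():
        return None
    # contiguous suprathreshold segments
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = np.r_[0, edges + 1][above[np.r_[0, edges + 1]]]
    for i0 in starts:
        i1 = i0
        while i1 + 1 < above.size and above[i1 + 1]:
            i1 += 1
        disp = np.hypot(x[i1] - x[i0], y[i1] - y[i0])
        if disp > DISPLACEMENT_GATE_DEG:
            return float(t[i0])
    return None


def filter_trials(session: SessionData) -> SessionData:
    """Mark trials landing >5 deg from the cue invalid; keep early saccades."""
    out = []
    n_excluded = 0
    for trial in session.trials:
        if trial.landing_error_deg > LANDING_ERROR_LIMIT_DEG:
            out.append(replace(trial, valid=False))
            n_excluded += 1
        else:
            out.append(trial)
    logger.info(
        "%s: excluded %d/%d trials by landing error",
        session.neuron_id, n_excluded, len(session.trials),
    )
    return SessionData(
        neuron_id=session.neuron_id,
        structure=session.structure,
        trials=out,
        spikes=session.spikes,
        eye=session.eye,
    )


def trial_densities(
    trains: Sequence[np.ndarray],
    window: tuple[float, float],
    sigma_ms: float = KERNEL_SIGMA_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial Gaussian-smoothed rates on a 1-ms grid, shape (n_trials, T).

    Each train holds event times already relative to the alignment event.
    The kernel is truncated and renormalized at the window edges, so the
    density of a single spike integrates to one spike away from the edges
    and no mass is invented at the boundary.  Rates are spikes/s.
    """
    t0, t1 = window
    t = np.arange(t0, t1)
    counts = np.zeros((len(trains), t.size))
    for i, train in enumerate(trains):
        sel = train[(train >= t0) & (train < t1)]
        idx = np.floor(sel - t0).astype(int)
        np.add.at(counts[i], idx, 1.0)
    smoothed = gaussian_filter1d(counts, sigma_ms, axis=-1, mode="constant")
    mass = gaussian_filter1d(np.ones(t.size), sigma_ms, mode="constant")
    return t, smoothed / mass * 1000.0


def density_from_trains(
    trains: Sequence[np.ndarray],
    window: tuple[float, float],
    sigma_ms: float = KERNEL_SIGMA_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged spike density; see :func:`trial_densities`."""
    t, rates = trial_densities(trains, window, sigma_ms)
    return t, rates.mean(axis=0)


def spike_density(
    session: SessionData,
    align: str,
    condition: str,
    direction: str,
    *,
    window: tuple[float, float] | None = None,
    sigma_ms: float = KERNEL_SIGMA_MS,
) -> DensityTrace:
    """Spike-density function for one cell of the design.

    Each trial's clock is shifted so the alignment event (cue onset or
    saccade initiation) sits at t = 0, spikes are smoothed with a Gaussian
    kernel (sigma = 15 ms) on a 1-ms grid and averaged across trials.
    Raises :class:`EmptyCellError` for an empty cell rather than returning
    silent zeros.
    """
    if align not in {"cue", "saccade"}:
        raise ValueError(f"unknown alignment {align!r}")
    trials = session.valid_trials(condition, direction)
    if not trials:
        raise EmptyCellError(
            f"{session.neuron_id}: no valid trials for {condition}/{direction}"
        )
    if window is None:
        if align == "cue":
            max_lat = max(t.latency_ms for t in trials)
            window = (-500.0, float(np.ceil(max_lat)) + 300.0)
        else:
            max_lat = max(t.latency_ms for t in trials)
            window = (-float(np.ceil(max_lat)) - 500.0, 300.0)
    trains = []
    for trial in trials:
        anchor = trial.cue_on_ms if align == "cue" else trial.saccade_ms
        trains.append(session.spikes.get(trial.trial_id, np.empty(0)) - anchor)
    t, rate = density_from_trains(trains, window, sigma_ms)
    return DensityTrace(
        t=t, rate=rate, align=align, condition=condition,
        direction=direction, n_trials=len(trials), kernel_sigma_ms=sigma_ms,
    )


def normalize_neuron(
    traces: Mapping[object, DensityTrace],
    baseline_window: tuple[float, float] = (-300.0, 0.0),
    plateau_window: tuple[float, float] = (0.0, 150.0),
    scale: tuple[float, float] | None = None,
) -> dict[object, DensityTrace] | None:
    """Baseline-subtract and normalize one neuron's traces to its modulation.

    The baseline is the neuron's mean rate over ``baseline_window`` in its
    cue-aligned traces (all conditions pooled).  The divisor estimates the
    neuron's peak modulation as the largest, across saccade-aligned traces,
    of the mean baseline-subtracted rate in the perisaccadic hold window
    ``plateau_window`` -- ramping activity in this preparation peaks at
    movement onset, and a window mean is far less biased upward by bin noise
    than the maximum over every 1-ms bin (the bin-wise max is used only as a
    fallback when no saccade-aligned trace covers the window).  Returns None
    for a neuron with no positive modulation (caller logs and excludes it).

    ``scale`` = (baseline, modulation depth) overrides both estimates; the
    pipeline uses it to supply trial-count-debiased values.
    """
    if scale is not None:
        baseline, peak = scale
        if peak <= 0:
            return None
        return {
            key: replace(tr, t=tr.t.copy(), rate=(tr.rate - baseline) / peak)
            for key, tr in traces.items()
        }
    cue_traces = [tr for tr in traces.values() if tr.align == "cue"]
    base_source = cue_traces or list(traces.values())
    baselines = []
    for tr in base_source:
        m = (tr.t >= baseline_window[0]) & (tr.t < baseline_window[1])
        if m.any():
            baselines.append(tr.rate[m].mean())
    baseline = float(np.mean(baselines)) if baselines else 0.0
    plateau = []
    for tr in traces.values():
        if tr.align == "saccade":
            m = (tr.t >= plateau_window[0]) & (tr.t < plateau_window[1])
            if m.any():
                plateau.append(float(tr.rate[m].mean()) - baseline)
    if plateau:
        peak = max(plateau)
    else:
        peak = max(float((tr.rate - baseline).max()) for tr in traces.values())
    if peak <= 0:
        return None
    return {
        key: replace(tr, t=tr.t.copy(), rate=(tr.rate - baseline) / peak)
        for key, tr in traces.items()
    }


def normalize_population(
    neuron_traces: Sequence[Mapping[object, DensityTrace]],
    baseline_window: tuple[float, float] = (-300.0, 0.0),
) -> dict[object, PopulationTrace]:
    """Per-neuron normalization followed by the across-neuron average.

    ``neuron_traces`` holds, per neuron, a mapping from an arbitrary key
    (typically (condition, align)) to that neuron's trace; all neurons must
    share the grid for each key.  Neurons with zero modulation are excluded
    with a log entry.
    """
    normalized: list[Mapping[object, DensityTrace]] = []
    for i, traces in enumerate(neuron_traces):
        norm = normalize_neuron(traces, baseline_window)
        if norm is None:
            logger.info("neuron %d excluded from population: zero modulation", i)
            continue
        normalized.append(norm)
    if not normalized:
        raise ValueError("no neurons with positive modulation")
    keys = normalized[0].keys()
    out: dict[object, PopulationTrace] = {}
    for key in keys:
        stack = np.stack([n[key].rate for n in normalized])
        ref = normalized[0][key]
        out[key] = PopulationTrace(
            t=ref.t.copy(), value=stack.mean(axis=0), align=ref.align,
            condition=ref.condition, direction=ref.direction,
            n_neurons=len(normalized),
        )
    return out


def shift_to_cue_frame(trace: DensityTrace, mean_latency: float) -> DensityTrace:
    """Translate a saccade-aligned trace so t=0 is the (mean) cue onset.

    The saccade marker, at t=0 in the input, lands at t = mean_latency;
    rates are untouched.
    """
    return replace(trace, t=trace.t + mean_latency, rate=trace.rate.copy())
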