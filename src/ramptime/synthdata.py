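"""Synthetic session generator for self-timed saccade experiments.

Emulates the statistical structure the downstream analyses assume: three
mandatory-interval classes (short 400-700 ms, medium 1000-1600 ms, long
2400-3100 ms), two saccade directions, right-skewed latency distributions with
occasional early saccades, and ramping firing under one of two regimes:

* ``tracker`` -- ramp onset fixed relative to the cue; the slope scales with
  the interval so the rate reaches its peak at saccade time (the striatal
  signature: condition-invariant onset, condition-scaled slope).
* ``trigger`` -- ramp onset locked to the upcoming saccade at a fixed lead
  time, so the slope is the same in every condition (the cerebellar
  signature: latency-locked onset, condition-invariant slope).

Spikes are drawn from an inhomogeneous Poisson process by thinning, which is
exact for the piecewise-linear rate profiles used here.  All randomness flows
through explicit integer seeds; identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SessionData, TrialRecord

__all__ = [
    "TaskConfig",
    "NeuronModel",
    "LatencyModel",
    "RateFunction",
    "generate_trials",
    "rate_profile",
    "sample_spikes",
    "generate_eye_trace",
    "generate_session",
    "generate_population",
    "generate_inactivation_latencies",
]

CONDITIONS = ("short", "medium", "long")
DIRECTIONS = ("contra", "ipsi")

#: Trial clock layout (ms): fixation point comes on at FP_ON_MS, the interval
#: cue at CUE_ON_MS; the pre-FP span accommodates the 300-ms baseline epoch
#: and the pre-cue span the 400-ms fit-window margin.
FP_ON_MS = 400
CUE_ON_MS = 1100
POST_SACCADE_MS = 600
#: movement-related activity decays back to baseline over this span after the
#: post-saccadic hold, as preparatory/perisaccadic responses do
DECAY_MS = 300.0


@dataclass(frozen=True)
class TaskConfig:
    """Task structure: mandatory-interval classes, directions, trial counts."""

    interval_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "short": (400.0, 700.0),
            "medium": (1000.0, 1600.0),
            "long": (2400.0, 3100.0),
        }
    )
    cue_duration_ms: float = 100.0
    directions: tuple[str, ...] = DIRECTIONS
    cue_eccentricity_deg: float = 16.0
    trials_per_condition: int = 20

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        prev_hi = -np.inf
        for cond in CONDITIONS:
            lo, hi = self.interval_ranges[cond]
            if not (0 < lo <= hi):
                raise ValueError(f"interval range for {cond!r} must be positive")
            if lo < prev_hi:
                raise ValueError("interval ranges must be ordered and non-overlapping")
            prev_hi = hi


@dataclass(frozen=True)
class LatencyModel:
    """Per-condition latency distributions (lognormal, moment-matched).

    ``early_fraction`` is the probability that a trial's saccade occurs before
    the mandatory minimum; such latencies are drawn from the condition's
    lognormal truncated above at the minimum, so mis-timed saccades cluster
    just below the boundary as real ones do.  ``inactivation_shift_ms`` and
    ``inactivation_sd_scale`` describe the muscimol manipulation used by the
    inactivation simulations.
    """

    #: defaults put the latency mass inside each mandatory window (mean at the
    #: window center, sd a quarter of the window width), matching a subject
    #: rewarded for saccades within the window
    mean_ms: Mapping[str, float] = field(
        default_factory=lambda: {"short": 550.0, "medium": 1300.0, "long": 2750.0}
    )
    sd_ms: Mapping[str, float] = field(
        default_factory=lambda: {"short": 75.0, "medium": 150.0, "long": 175.0}
    )
    early_fraction: float = 0.1
    inactivation_shift_ms: float = 0.0
    inactivation_sd_scale: float = 1.0

    def __post_init__(self) -> None:
        for cond, sd in self.sd_ms.items():
            if sd < 0:
                raise ValueError(f"sd_ms[{cond!r}] must be >= 0")
        if not (0 <= self.early_fraction < 0.5):
            raise ValueError("early_fraction must be in [0, 0.5)")


@dataclass(frozen=True)
class NeuronModel:
    """One simulated neuron's ramping regime and gain structure."""

    archetype: Literal["tracker", "trigger"]
    baseline_rate: float = 10.0
    peak_rate: float = 60.0
    #: tracker: ramp onset in ms after cue; trigger: lead time before saccade.
    t0_ms: float = 100.0
    d_ms: float = 500.0
    direction_gain: float = 1.0
    latency_coupling: Literal["late", "early"] = "late"
    preferred_direction: str = "contra"
    #: lognormal sd of a per-trial excitability gain multiplying the whole
    #: trial's rate (doubly stochastic Poisson); sets the across-trial
    #: baseline CV beyond the Poisson floor
    trial_gain_sd: float = 0.0
    #: optional per-condition multiplicative gain on the peak modulation,
    #: making the neuron duration-selective; None = same peak everywhere
    condition_peak_gain: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.peak_rate <= self.baseline_rate:
            raise ValueError("peak_rate must exceed baseline_rate")
        if not (0 < self.direction_gain <= 1):
            raise ValueError("direction_gain must be in (0, 1]")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_trials(
    task: TaskConfig,
    lat: LatencyModel,
    seed: int,
    *,
    agent: str | None = None,
) -> pd.DataFrame:
    """Draw a trial table: condition, direction, cue onset, saccade latency.

    Latencies are lognormal, moment-matched to the condition's (mean, sd);
    with probability ``early_fraction`` a trial is replaced by an early
    saccade below the mandatory minimum.  Degenerate sd -> 0 gives every
    trial exactly the condition mean.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    trial_id = 0
    shift = lat.inactivation_shift_ms if agent == "muscimol" else 0.0
    sd_scale = lat.inactivation_sd_scale if agent == "muscimol" else 1.0
    for cond in CONDITIONS:
        lo, _hi = task.interval_ranges[cond]
        mean = lat.mean_ms[cond] + shift
        sd = lat.sd_ms[cond] * sd_scale
        for direction in task.directions:
            for _ in range(task.trials_per_condition):
                if sd == 0:
                    latency = mean
                else:
                    mu, sigma = _lognormal_params(mean, sd)
                    latency = float(rng.lognormal(mu, sigma))
                    if lat.early_fraction > 0 and rng.random() < lat.early_fraction:
                        # lognormal upper-truncated at the mandatory minimum
                        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
                        latency = float(dist.ppf(rng.random() * dist.cdf(lo)))
                rows.append(
                    {
                        "trial_id": trial_id,
                        "task": "self_timed",
                        "condition": cond,
                        "direction": direction,
                        "fp_on_ms": FP_ON_MS,
                        "cue_on_ms": CUE_ON_MS,
                        "saccade_ms": CUE_ON_MS + latency,
                        "latency_ms": latency,
                        "landing_error_deg": float(abs(rng.normal(0.0, 1.0))),
                    }
                )
                trial_id += 1
    return pd.DataFrame(rows)


class RateFunction:
    """Piecewise-linear firing-rate profile r(t) on [0, t_end] (ms, spikes/s).

    Stored as knot arrays; evaluation interpolates linearly, the integral is
    the exact trapezoid over knots, and ``max_rate`` bounds thinning.
    """

    def __init__(self, knots_t: np.ndarray, knots_r: np.ndarray, degenerate: bool = False):
        self.knots_t = np.asarray(knots_t, dtype=float)
        self.knots_r = np.maximum(np.asarray(knots_r, dtype=float), 0.0)
        if np.any(np.diff(self.knots_t) < 0):
            raise ValueError("knot times must be non-decreasing")
        self.degenerate = degenerate

    @property
    def t_end(self) -> float:
        return float(self.knots_t[-1])

    @property
    def max_rate(self) -> float:
        return float(self.knots_r.max())

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.interp(t, self.knots_t, self.knots_r)

    def integral(self) -> float:
        """Expected spike count over the whole profile."""
        return float(np.trapezoid(self.knots_r, self.knots_t)) / 1000.0


def rate_profile(
    model: NeuronModel,
    latency_ms: float,
    *,
    direction: str = "contra",
    condition: str | None = None,
    ramp_target_ms: float | None = None,
    d_ms: float | None = None,
) -> RateFunction:
    """Intended rate for one trial: baseline, then a linear ramp to the peak.

    The ramp is clipped at ``peak_rate``, held through saccade + 150 ms, then
    decays linearly back to baseline over 300 ms.  For trackers the onset is cue + t0 and the slope is
    set so the rate reaches the peak at the ramp target (the trial's saccade
    by default; pass ``ramp_target_ms`` to target e.g. the condition mean).
    For triggers the onset leads the saccade by ``d_ms`` at fixed slope
    (peak - baseline) / d_ms.  An onset at/after the saccade yields a flat
    profile flagged ``degenerate``.
    """
    b = model.baseline_rate
    peak = model.peak_rate
    if direction != model.preferred_direction:
        peak = b + (peak - b) * model.direction_gain
    if model.condition_peak_gain is not None and condition is not None:
        peak = b + (peak - b) * model.condition_peak_gain.get(condition, 1.0)
    sacc = CUE_ON_MS + latency_ms
    t_end = sacc + POST_SACCADE_MS
    hold_end = sacc + 150.0

    if model.archetype == "tracker":
        t_on = CUE_ON_MS + model.t0_ms
        target = CUE_ON_MS + (ramp_target_ms if ramp_target_ms is not None else latency_ms)
        if target <= t_on:
            return RateFunction([0.0, t_end], [b, b], degenerate=True)
        k = (peak - b) / (target - t_on)
    else:
        lead = d_ms if d_ms is not None else model.d_ms
        t_on = sacc - lead
        if t_on <= 0 or lead <= 0:
            return RateFunction([0.0, t_end], [b, b], degenerate=True)
        k = (peak - b) / lead
    if t_on >= sacc:
        return RateFunction([0.0, t_end], [b, b], degenerate=True)

    t_peak = t_on + (peak - b) / k
    knots_t = [0.0, t_on]
    knots_r = [b, b]
    if t_peak < hold_end:  # ramp reaches the peak, then holds
        knots_t += [t_peak, hold_end]
        knots_r += [peak, peak]
    else:  # still ramping when the profile is truncated
        knots_t += [hold_end]
        knots_r += [b + k * (hold_end - t_on)]
    # gradual post-movement decay back to baseline
    knots_t += [hold_end + DECAY_MS, t_end]
    knots_r += [b, b]
    return RateFunction(np.array(knots_t), np.array(knots_r))


def sample_spikes(rate: RateFunction, seed: int | np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson spike times (sorted, ms) by thinning.

    Candidates are homogeneous Poisson at the rate's maximum; each is kept
    with probability r(t)/max.  Exact for any bounded rate.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = rate.max_rate / 1000.0  # spikes per ms
    if lam <= 0:
        return np.empty(0)
    n = rng.poisson(lam * rate.t_end)
    if n == 0:
        return np.empty(0)
    cand = rng.uniform(0.0, rate.t_end, size=n)
    keep = rng.uniform(0.0, rate.max_rate, size=n) < rate(cand)
    return np.sort(cand[keep])


def generate_eye_trace(
    latency_ms: float,
    amplitude_deg: float,
    seed: int | np.random.Generator,
    *,
    direction: str = "contra",
    noise_sd_deg: float = 0.05,
    t_end_ms: float | None = None,
) -> pd.DataFrame:
    """1-kHz horizontal/vertical eye position with one saccade.

    Fixation noise, then a smoothstep displacement of ``amplitude_deg``
    starting at cue + latency.  Movement duration follows the main sequence
    (2A + 20 ms), which keeps the peak velocity above the 40 deg/s detection
    threshold for amplitudes >= 3 deg.  Contraversive saccades go positive.
    """
    if amplitude_deg <= 0:
        raise ValueError("amplitude_deg must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sacc = CUE_ON_MS + latency_ms
    t_end = t_end_ms if t_end_ms is not None else sacc + POST_SACCADE_MS
    t = np.arange(0.0, t_end)
    dur = 2.0 * amplitude_deg + 20.0
    u = np.clip((t - sacc) / dur, 0.0, 1.0)
    step = amplitude_deg * (3.0 * u**2 - 2.0 * u**3)
    sign = 1.0 if direction == "contra" else -1.0
    x = sign * step + rng.normal(0.0, noise_sd_deg, size=t.size)
    y = rng.normal(0.0, noise_sd_deg, size=t.size)
    return pd.DataFrame({"t_ms": t.astype(int), "x_deg": x, "y_deg": y})


def _trial_rate(model: NeuronModel, trial: TrialRecord, rng: np.random.Generator,
                mean_latency: Mapping[str, float],
                mandatory_min: Mapping[str, float] | None = None) -> RateFunction:
    """Per-trial rate with the archetype's trial-by-trial coupling.

    trigger: the lead time D is jittered per trial (sd 8% of D) and the ramp
    tracks the trial's actual saccade, so variation enters at ramp onset.
    tracker/late: every trial -- early saccades included -- ramps toward
    the condition's mean latency and gain noise (sd 15%) is injected only
    over the final 200 ms before the saccade, so within-condition trial
    variation appears late in the delay.  (Giving early-saccade trials
    steeper own-latency ramps would concentrate trigger-like trials in the
    fast tercile and destroy the regime's late-variation signature.)
    """
    if model.archetype == "trigger":
        d = model.d_ms * float(np.exp(rng.normal(0.0, 0.08)))
        return rate_profile(
            model, trial.latency_ms, direction=trial.direction,
            condition=trial.condition, d_ms=d,
        )
    target = (
        mean_latency[trial.condition]
        if model.latency_coupling == "late"
        else trial.latency_ms
    )
    rate = rate_profile(
        model, trial.latency_ms, direction=trial.direction,
        condition=trial.condition, ramp_target_ms=target,
    )
    if model.latency_coupling == "late" and not rate.degenerate:
        gain = float(np.exp(rng.normal(0.0, 0.15)))
        sacc = CUE_ON_MS + trial.latency_ms
        t0, t1 = sacc - 200.0, sacc + 150.0
        grid = np.unique(np.concatenate([rate.knots_t, [t0, t1]]))
        r = np.asarray(rate(grid), dtype=float)
        in_win = (grid > t0) & (grid <= t1)
        base = model.baseline_rate
        r[in_win] = base + (r[in_win] - base) * gain
        rate = RateFunction(grid, r)
    return rate


def generate_session(
    model: NeuronModel,
    task: TaskConfig,
    lat: LatencyModel,
    seed: int,
    *,
    neuron_id: str = "sim0",
    structure: str = "striatum",
    with_eye: bool = False,
) -> SessionData:
    """One neuron's full synthetic session (trials, spikes, optional eye)."""
    trials_df = generate_trials(task, lat, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, model.seed, 7]))
    mean_lat = trials_df.groupby("condition", observed=True)["latency_ms"].mean().to_dict()
    mins = {c: lo for c, (lo, _hi) in task.interval_ranges.items()}
    trials: list[TrialRecord] = []
    spikes: dict[int, np.ndarray] = {}
    eye: dict[int, pd.DataFrame] = {}
    for row in trials_df.itertuples(index=False):
        rec = TrialRecord(
            trial_id=int(row.trial_id),
            task=row.task,
            condition=row.condition,
            direction=row.direction,
            fp_on_ms=float(row.fp_on_ms),
            cue_on_ms=float(row.cue_on_ms),
            saccade_ms=float(row.saccade_ms),
            landing_error_deg=float(row.landing_error_deg),
        )
        trials.append(rec)
        rate = _trial_rate(model, rec, rng, mean_lat, mins)
        if model.trial_gain_sd > 0:
            g = float(np.exp(rng.normal(0.0, model.trial_gain_sd)))
            rate = RateFunction(rate.knots_t, rate.knots_r * g, rate.degenerate)
        spikes[rec.trial_id] = sample_spikes(rate, rng)
        if with_eye:
            eye[rec.trial_id] = generate_eye_trace(
                rec.latency_ms, task.cue_eccentricity_deg, rng, direction=rec.direction
            )
    return SessionData(
        neuron_id=neuron_id,
        structure=structure,
        trials=trials,
        spikes=spikes,
        eye=eye or None,
    )


def generate_population(
    archetype: Literal["tracker", "trigger"],
    n_neurons: int,
    seed: int,
    *,
    task: TaskConfig | None = None,
    lat: LatencyModel | None = None,
    structure: str | None = None,
    model: NeuronModel | None = None,
    rate_jitter: float = 0.15,
    onset_jitter_ms: float = 75.0,
) -> list[SessionData]:
    """A population of independent synthetic neurons of one archetype.

    Baseline and peak rates are jittered across neurons (lognormal, sd
    ``rate_jitter``), and the onset rule varies across neurons as real
    preparatory populations do: tracker post-cue onsets get Gaussian jitter
    (sd ``onset_jitter_ms``, so the population-mean onset stays at the
    template's ``t0_ms``), trigger lead times lognormal jitter of matched
    relative spread.  Each neuron gets its own trial realization.
    """
    task = task or TaskConfig()
    lat = lat or LatencyModel()
    if model is None:
        # structure-typical templates: caudate projection neurons are nearly
        # silent at rest (~2 Hz) and burst to tens of Hz, so their baseline
        # CV (~1.5) is mostly the Poisson floor at a near-empty count window
        # plus modest excitability noise; dentate neurons fire tonically
        # (~30 Hz) with steadier baselines (CV ~0.5)
        if archetype == "tracker":
            template = NeuronModel(
                archetype=archetype,
                baseline_rate=2.0,
                peak_rate=50.0,
                trial_gain_sd=0.5,
            )
        else:
            template = NeuronModel(
                archetype=archetype,
                baseline_rate=30.0,
                peak_rate=80.0,
                trial_gain_sd=0.385,
            )
    else:
        template = model
    if structure is None:
        structure = "striatum" if archetype == "tracker" else "cerebellum"
    ss = np.random.SeedSequence(seed)
    sessions = []
    for i, child in enumerate(ss.spawn(n_neurons)):
        rng = np.random.default_rng(child)
        m = replace(
            template,
            archetype=archetype,
            baseline_rate=template.baseline_rate * float(np.exp(rng.normal(0, rate_jitter))),
            peak_rate=template.peak_rate * float(np.exp(rng.normal(0, rate_jitter))),
            t0_ms=max(0.0, template.t0_ms + float(rng.normal(0, onset_jitter_ms))),
            d_ms=template.d_ms
            * float(np.exp(rng.normal(0, onset_jitter_ms / max(template.d_ms, 1.0)))),
            seed=int(rng.integers(2**31)),
        )
        sessions.append(
            generate_session(
                m,
                task,
                lat,
                seed=int(rng.integers(2**31)),
                neuron_id=f"{archetype}{i:03d}",
                structure=structure,
            )
        )
    return sessions


def generate_inactivation_latencies(
    lat: LatencyModel,
    n_pre: int,
    n_post: int,
    condition: str,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre/post latency samples for one condition of an inactivation session.

    The post sample is shifted by ``inactivation_shift_ms`` and its sd scaled
    by ``inactivation_sd_scale`` (both zero-effect for saline simulations).
    """
    rng = np.random.default_rng(seed)
    mean, sd = lat.mean_ms[condition], lat.sd_ms[condition]
    mu, sigma = _lognormal_params(mean, sd)
    pre = rng.lognormal(mu, sigma, size=n_pre)
    mu2, sigma2 = _lognormal_params(
        mean + lat.inactivation_shift_ms, sd * lat.inactivation_sd_scale
    )
    post = rng.lognormal(mu2, sigma2, size=n_post)
    return pre, post
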