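"""High-level orchestration: sessions -> population analyses.

These helpers glue the stage modules together on common time grids so the
CLI, the tests and batch scripts all run the identical path: per-neuron
spike densities for each condition, per-neuron normalization, population
ramp fits with neuron bootstrap, and the latency-tercile divergence
analysis.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .divergence import (
    DivergenceResult,
    divergence_onset,
    ms_rm_anova,
    split_terciles,
)
from .preprocess import (
    DensityTrace,
    SessionData,
    density_from_trains,
    normalize_neuron,
    normalize_population,
    trial_densities,
)
from .rampfit import BootstrapSummary, bootstrap_ramp

logger = logging.getLogger(__name__)

CONDITIONS = ("short", "medium", "long")

__all__ = [
    "pooled_mean_latencies",
    "neuron_condition_traces",
    "ramp_analysis",
    "divergence_analysis",
]


def pooled_mean_latencies(
    sessions: Sequence[SessionData], direction: str
) -> dict[str, float]:
    """Mean saccade latency per condition, pooled over all valid trials."""
    out = {}
    for cond in CONDITIONS:
        lats = [
            t.latency_ms
            for s in sessions
            for t in s.valid_trials(cond, direction)
        ]
        if not lats:
            raise ValueError(f"no valid trials for condition {cond!r}")
        out[cond] = float(np.mean(lats))
    return out


def neuron_condition_traces(
    sessions: Sequence[SessionData],
    direction: str,
    aligns: Sequence[str] = ("cue",),
    *,
    sigma_ms: float = 15.0,
    precue_ms: float = 300.0,
) -> tuple[
    list[dict[tuple[str, str], DensityTrace]],
    dict[str, float],
    list[SessionData],
]:
    """Per-neuron spike-density traces on common per-condition grids.

    Returns (per-neuron dicts keyed (condition, align), pooled mean
    latencies, retained sessions).  Cue-aligned windows run from before the
    cue to the pooled mean latency (+50 ms margin); saccade-aligned windows
    mirror that span ending 50 ms after the saccade.
    """
    mean_lat = pooled_mean_latencies(sessions, direction)
    windows = {}
    pre = max(precue_ms, 400.0) + 100.0
    for cond in CONDITIONS:
        end = float(np.ceil(mean_lat[cond])) + 50.0
        windows[(cond, "cue")] = (-pre, end)
        windows[(cond, "saccade")] = (-end - pre, 50.0)
    per_neuron = []
    kept: list[SessionData] = []
    for s in sessions:
        traces: dict[tuple[str, str], DensityTrace] = {}
        for cond in CONDITIONS:
            trials = s.valid_trials(cond, direction)
            if not trials:
                traces = {}
                break
            for align in aligns:
                trains = []
                for tr in trials:
                    anchor = tr.cue_on_ms if align == "cue" else tr.saccade_ms
                    trains.append(s.spikes.get(tr.trial_id, np.empty(0)) - anchor)
                t, rate = density_from_trains(trains, windows[(cond, align)], sigma_ms)
                traces[(cond, align)] = DensityTrace(
                    t=t, rate=rate, align=align, condition=cond,
                    direction=direction, n_trials=len(trials),
                    kernel_sigma_ms=sigma_ms,
                )
        if traces:
            per_neuron.append(traces)
            kept.append(s)
        else:
            logger.info("%s skipped: missing a condition", s.neuron_id)
    if not per_neuron:
        raise ValueError("no usable neurons")
    return per_neuron, mean_lat, kept


#: expected maximum of three iid standard normals, used to remove the
#: small-sample upward bias of a max over three noisy plateau means
_EMAX3 = 0.8463


def modulation_scale(
    session: SessionData, direction: str
) -> tuple[float, float]:
    """Per-neuron (baseline, modulation depth) from trial-wise counts.

    Baseline is the mean pre-cue ([-300, 0) ms) rate over the direction's
    valid trials.  The depth is the largest across conditions of the mean
    perisaccadic ([0, 150) ms after saccade onset) rate, minus the expected
    maximum of three centered Gaussians with the empirical standard errors
    -- without that correction the max over noisy condition means
    overestimates the depth and deflates every normalized quantity.
    """
    base_rates = []
    plateau: dict[str, list[float]] = {c: [] for c in CONDITIONS}
    for tr in session.valid_trials(direction=direction):
        train = session.spikes.get(tr.trial_id, np.empty(0))
        nb = np.count_nonzero((train >= tr.cue_on_ms - 300.0) & (train < tr.cue_on_ms))
        npl = np.count_nonzero(
            (train >= tr.saccade_ms) & (train < tr.saccade_ms + 150.0)
        )
        base_rates.append(nb / 0.3)
        if tr.condition in plateau:
            plateau[tr.condition].append(npl / 0.15)
    baseline = float(np.mean(base_rates)) if base_rates else 0.0
    means, ses = [], []
    for c in CONDITIONS:
        v = np.asarray(plateau[c], dtype=float)
        if v.size == 0:
            continue
        means.append(v.mean())
        ses.append(v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0)
    if not means:
        return baseline, 0.0
    depth = float(max(means) - _EMAX3 * np.mean(ses) - baseline)
    return baseline, depth


def ramp_analysis(
    sessions: Sequence[SessionData],
    direction: str,
    align: str = "cue",
    *,
    B: int = 1000,
    seed: int = 0,
    precue_ms: float = 300.0,
    sigma_ms: float = 15.0,
) -> dict[str, BootstrapSummary]:
    """Population two-line ramp fit with neuron bootstrap, per condition."""
    # both alignments are always computed: the cue frame anchors the baseline
    # and the saccade frame anchors the normalization plateau
    per_neuron, mean_lat, kept = neuron_condition_traces(
        sessions, direction, aligns=("cue", "saccade"),
        sigma_ms=sigma_ms, precue_ms=precue_ms,
    )
    scales = [modulation_scale(s, direction) for s in kept]
    out = {}
    for cond in CONDITIONS:
        out[cond] = bootstrap_ramp(
            per_neuron,
            key=(cond, align),
            mean_latency=mean_lat[cond],
            align=align,
            B=B,
            seed=seed,
            precue_ms=precue_ms,
            scales=scales,
        )
    return out


def divergence_analysis(
    sessions: Sequence[SessionData],
    condition: str,
    direction: str | None = None,
    align: str = "cue",
    *,
    B: int = 1000,
    seed: int = 0,
    sigma_ms: float = 15.0,
    alpha: float = 0.01,
    persistence_ms: int = 40,
) -> DivergenceResult:
    """Latency-tercile divergence onset for one condition.

    Per neuron: terciles by latency (preferred direction unless given),
    group spike densities, joint per-neuron normalization anchored to the
    pre-cue baseline and perisaccadic plateau, then the per-ms
    repeated-measures ANOVA with the p < 0.01 / 40-ms persistence rule.
    The analysis window is cue onset to the pooled mean latency (cue frame)
    or the mirror span ending at the saccade (saccade frame).

    Percentiles come from a hierarchical bootstrap: neurons are resampled
    with replacement and each drawn neuron's trials are resampled within
    tercile.  Resampling trials keeps duplicated neurons from injecting the
    same noise pattern coherently into the repeated-measures F, which would
    otherwise produce spurious early onsets in the resamples.
    """
    per_neuron = []  # (trial traces per group, baseline scalars, plateau scalars)
    mean_lats = []
    for s in sessions:
        d = direction or s.preferred_direction()
        try:
            groups = split_terciles(s, condition, d)
        except ValueError:
            logger.info("%s skipped in divergence: too few trials", s.neuron_id)
            continue
        mean_lats.append(np.mean([t.latency_ms for g in groups for t in g]))
        per_neuron.append((s, d, groups))
    if len(per_neuron) < 3:
        raise ValueError("divergence analysis needs >= 3 usable neurons")
    mean_lat = float(np.mean(mean_lats))
    end = float(np.ceil(mean_lat))
    win = (-500.0, end + 50.0) if align == "cue" else (-end - 500.0, 50.0)

    neurons = []
    for s, d, groups in per_neuron:
        # modulation scale is a per-neuron property, estimated once from all
        # of the direction's trials; per-resample re-estimation from small
        # trial chunks is unstable enough to distort the bootstrap F
        baseline, depth = modulation_scale(s, d)
        if depth <= 0:
            logger.info("%s excluded in divergence: zero modulation", s.neuron_id)
            continue
        group_rates = []  # per tercile: (n_trials, T) smoothed rates
        for grp in groups:
            trains = [
                s.spikes.get(tr.trial_id, np.empty(0))
                - (tr.cue_on_ms if align == "cue" else tr.saccade_ms)
                for tr in grp
            ]
            _, rates = trial_densities(trains, win, sigma_ms)
            group_rates.append(rates)
        neurons.append((group_rates, baseline, depth))
    if len(neurons) < 3:
        raise ValueError("divergence analysis needs >= 3 normalized neurons")

    t_grid = np.arange(win[0], win[1])
    if align == "cue":
        mask = (t_grid >= 0.0) & (t_grid <= mean_lat)
    else:
        mask = (t_grid >= -mean_lat) & (t_grid <= 0.0)
    t_win = t_grid[mask]

    def _row(i, sels):
        """One subject row from per-group trial index selections."""
        group_rates, baseline, depth = neurons[i]
        traces = [
            group_rates[g][sels[g] if sels is not None else slice(None)].mean(axis=0)
            for g in range(3)
        ]
        return (np.stack(traces)[:, mask] - baseline) / depth

    def normalized_stack(take, rng=None):
        """(n, 3, T) normalized group traces for one (re)sample.

        When a neuron is drawn several times, its trials are partitioned
        into disjoint chunks, one per copy, so the copies are conditionally
        independent given the neuron; exact duplicates (or copies built
        from shared trials) would push the same noise pattern into the
        repeated-measures F coherently and inflate it.
        """
        rows = []
        if rng is None:
            for i in take:
                rows.append(_row(i, None))
        else:
            uniq, counts = np.unique(np.asarray(take), return_counts=True)
            for i, m in zip(uniq, counts):
                group_rates = neurons[i][0]
                perms = [
                    rng.permutation(group_rates[g].shape[0]) for g in range(3)
                ]
                for c in range(m):
                    sels = []
                    for g in range(3):
                        chunk = perms[g][c::m]
                        if chunk.size == 0:  # more copies than trials
                            chunk = rng.integers(
                                0, group_rates[g].shape[0], size=1
                            )
                        sels.append(chunk)
                    rows.append(_row(i, sels))
        return np.stack(rows)

    arr = normalized_stack(range(len(neurons)))
    pvals = ms_rm_anova(arr)
    onset = divergence_onset(pvals, t_win, alpha=alpha, persistence_ms=persistence_ms)

    n = len(neurons)
    samples = np.empty(B)
    n_none = 0
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        take = rng.integers(0, n, size=n)
        stack = normalized_stack(take, rng)
        o = divergence_onset(
            ms_rm_anova(stack), t_win, alpha=alpha, persistence_ms=persistence_ms
        )
        if o is None:
            n_none += 1
            o = float(t_win[-1])
        samples[b] = o
    if n_none:
        logger.info("divergence bootstrap: %d resamples without onset", n_none)
    return DivergenceResult(
        onset_ms=onset,
        align=align,
        condition=condition,
        pvals=pvals,
        t=t_win,
        alpha=alpha,
        persistence_ms=persistence_ms,
        onset_percentiles=tuple(np.percentile(samples, [2.5, 50, 97.5])),
        onset_samples=samples,
    )
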