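import numpy as np
import pandas as pd
import pytest

from ramptime.preprocess import (
    DensityTrace,
    EmptyCellError,
    detect_saccade,
    density_from_trains,
    filter_trials,
    normalize_neuron,
    normalize_population,
    shift_to_cue_frame,
    spike_density,
)
from ramptime.synthdata import CUE_ON_MS, generate_eye_trace, generate_session
from ramptime.synthdata import LatencyModel, NeuronModel, TaskConfig

from conftest import make_session


class TestDetectSaccade:
    def test_flat_trace_none(self):
        t = np.arange(2000)
        df = pd.DataFrame({"t_ms": t, "x_deg": np.zeros(2000), "y_deg": np.zeros(2000)})
        assert detect_saccade(df) is None

    def test_recovers_injected_saccade(self):
        df = generate_eye_trace(900.0, 16.0, seed=4)
        onset = detect_saccade(df)
        assert onset is not None
        assert abs(onset - (CUE_ON_MS + 900.0)) <= 10.0

    def test_small_displacement_gated_out(self):
        # 2 deg step in ~30 ms: velocity ~66 deg/s but displacement < 3 deg
        t = np.arange(1000, dtype=float)
        x = np.clip((t - 500) / 30.0, 0, 1) * 2.0
        df = pd.DataFrame({"t_ms": t, "x_deg": x, "y_deg": np.zeros_like(t)})
        assert detect_saccade(df) is None

    def test_short_trace_rejected(self):
        df = pd.DataFrame({"t_ms": np.arange(30), "x_deg": np.zeros(30), "y_deg": np.zeros(30)})
        with pytest.raises(ValueError):
            detect_saccade(df)

    def test_latency_round_trip(self):
        """Generator latencies recovered with median abs error < 10 ms."""
        m = NeuronModel(archetype="tracker")
        s = generate_session(
            m, TaskConfig(trials_per_condition=4), LatencyModel(), seed=8,
            with_eye=True,
        )
        errs = []
        for tr in s.trials:
            onset = detect_saccade(s.eye[tr.trial_id])
            assert onset is not None
            errs.append(abs((onset - tr.cue_on_ms) - tr.latency_ms))
        assert np.median(errs) < 10.0


class TestFilterTrials:
    def test_landing_error_rule(self, tracker_session):
        clean = filter_trials(tracker_session)
        assert all(t.valid for t in clean.trials if t.landing_error_deg <= 5)
        # force one bad trial
        from dataclasses import replace

        s2 = make_session(lambda tr: [])
        s2.trials[0] = replace(s2.trials[0], landing_error_deg=6.0)
        out = filter_trials(s2)
        flags = [t.valid for t in out.trials]
        assert flags.count(False) == 1 and not out.trials[0].valid


class TestSpikeDensity:
    def test_single_spike_peak(self):
        s = make_session(lambda tr: [tr.cue_on_ms] if tr.trial_id == 0 else [],
                         n_per_cell=1, conditions=("short",), directions=("contra",))
        trace = spike_density(s, "cue", "short", "contra", window=(-200, 200))
        peak = 1000.0 / (15.0 * np.sqrt(2 * np.pi))
        assert trace.rate[trace.t == 0][0] == pytest.approx(peak, rel=1e-3)

    def test_two_identical_trials_average_identity(self):
        s1 = make_session(lambda tr: [tr.cue_on_ms + 50], n_per_cell=1,
                          conditions=("short",), directions=("contra",))
        s2 = make_session(lambda tr: [tr.cue_on_ms + 50], n_per_cell=2,
                          conditions=("short",), directions=("contra",))
        t1 = spike_density(s1, "cue", "short", "contra", window=(-200, 300))
        t2 = spike_density(s2, "cue", "short", "contra", window=(-200, 300))
        assert np.allclose(t1.rate, t2.rate)

    def test_empty_cell_raises(self):
        s = make_session(lambda tr: [], conditions=("short",), directions=("contra",))
        with pytest.raises(EmptyCellError):
            spike_density(s, "cue", "long", "contra")

    def test_kernel_mass_one_spike(self):
        """The density of one spike integrates to one spike away from edges."""
        t, rate = density_from_trains([np.array([500.0])], (0, 1000))
        assert np.trapezoid(rate, t) / 1000.0 == pytest.approx(1.0, abs=1e-6)

    def test_homogeneous_rate_recovered(self):
        rng = np.random.default_rng(2)
        trains = [np.sort(rng.uniform(0, 1000, rng.poisson(50))) for _ in range(500)]
        t, rate = density_from_trains(trains, (0, 1000))
        interior = rate[(t > 100) & (t < 900)]
        assert np.all(np.abs(interior - 50.0) < 3.0)


class TestNormalization:
    @staticmethod
    def _traces(gain=1.0, shape_shift=0.0):
        t_cue = np.arange(-400.0, 600.0)
        t_sac = np.arange(-600.0, 200.0)
        cue_rate = gain * np.clip((t_cue - shape_shift) / 50.0, 0, 10.0)
        sac_rate = gain * np.full(t_sac.size, 10.0)
        mk = lambda t, r, al: DensityTrace(
            t=t, rate=r, align=al, condition="short", direction="contra", n_trials=5
        )
        return {
            ("short", "cue"): mk(t_cue, cue_rate, "cue"),
            ("short", "saccade"): mk(t_sac, sac_rate, "saccade"),
        }

    def test_self_normalization_plateau_is_one(self):
        norm = normalize_neuron(self._traces())
        sac = norm[("short", "saccade")]
        m = (sac.t >= 0) & (sac.t < 150)
        assert sac.rate[m].mean() == pytest.approx(1.0)

    def test_gain_invariance(self):
        a = normalize_neuron(self._traces(gain=1.0))
        b = normalize_neuron(self._traces(gain=7.3))
        for key in a:
            assert np.allclose(a[key].rate, b[key].rate)

    def test_population_permutation_invariance(self):
        neurons = [self._traces(gain=g) for g in (1.0, 2.0, 5.0)]
        p1 = normalize_population(neurons)
        p2 = normalize_population(neurons[::-1])
        for key in p1:
            assert np.allclose(p1[key].value, p2[key].value)

    def test_identical_shapes_average_to_common_shape(self):
        neurons = [self._traces(gain=1.0), self._traces(gain=3.0)]
        pop = normalize_population(neurons)
        single = normalize_neuron(self._traces(gain=1.0))
        assert np.allclose(
            pop[("short", "cue")].value, single[("short", "cue")].rate
        )

    def test_zero_modulation_excluded(self):
        t = np.arange(-400.0, 600.0)
        flat = {
            ("short", "cue"): DensityTrace(
                t=t, rate=np.zeros(t.size), align="cue", condition="short",
                direction="contra", n_trials=5,
            )
        }
        assert normalize_neuron(flat) is None


class TestShiftToCueFrame:
    def test_identity_and_inverse(self):
        t = np.arange(-500.0, 100.0)
        tr = DensityTrace(t=t, rate=np.random.default_rng(0).random(t.size),
                          align="saccade", condition="short", direction="contra",
                          n_trials=3)
        assert np.allclose(shift_to_cue_frame(tr, 0.0).t, tr.t)
        back = shift_to_cue_frame(shift_to_cue_frame(tr, 550.0), -550.0)
        assert np.allclose(back.t, tr.t) and np.allclose(back.rate, tr.rate)

    def test_saccade_marker_maps_to_mean_latency(self):
        t = np.arange(-500.0, 100.0)
        tr = DensityTrace(t=t, rate=np.zeros(t.size), align="saccade",
                          condition="short", direction="contra", n_trials=3)
        shifted = shift_to_cue_frame(tr, 550.0)
        assert shifted.t[tr.t == 0.0][0] == 550.0

    def test_alignment_consistency_zero_variance(self):
        """With identical latencies, cue-aligned and shifted saccade-aligned
        traces coincide exactly."""
        spikes = lambda tr: tr.cue_on_ms + np.array([100.0, 300.0, 500.0])
        s = make_session(spikes, latency=550.0, conditions=("short",),
                         directions=("contra",))
        cue = spike_density(s, "cue", "short", "contra", window=(-200, 600))
        sac = spike_density(s, "saccade", "short", "contra", window=(-750, 50))
        shifted = shift_to_cue_frame(sac, 550.0)
        common = np.intersect1d(cue.t, shifted.t)
        a = cue.rate[np.isin(cue.t, common)]
        b = shifted.rate[np.isin(shifted.t, common)]
        assert np.allclose(a, b, atol=1e-9)
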