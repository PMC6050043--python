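import numpy as np
import pytest
from scipy import integrate, stats

from ramptime.synthdata import (
    CUE_ON_MS,
    LatencyModel,
    NeuronModel,
    RateFunction,
    TaskConfig,
    generate_eye_trace,
    generate_session,
    generate_trials,
    rate_profile,
    sample_spikes,
)


class TestGenerateTrials:
    def test_same_seed_identical(self):
        task = TaskConfig(trials_per_condition=5)
        a = generate_trials(task, LatencyModel(), seed=7)
        b = generate_trials(task, LatencyModel(), seed=7)
        assert a.equals(b)

    def test_zero_dispersion_gives_condition_means(self):
        lat = LatencyModel(sd_ms={"short": 0, "medium": 0, "long": 0})
        df = generate_trials(TaskConfig(trials_per_condition=4), lat, seed=1)
        for cond, mean in lat.mean_ms.items():
            assert (df.loc[df.condition == cond, "latency_ms"] == mean).all()

    def test_moment_match_monte_carlo(self):
        """Lognormal moment matching: empirical mean within 3 SE of target."""
        lat = LatencyModel(
            mean_ms={"short": 600, "medium": 1300, "long": 2750},
            sd_ms={"short": 100, "medium": 150, "long": 175},
            early_fraction=0.0,
        )
        task = TaskConfig(trials_per_condition=2500, directions=("contra", "ipsi"))
        df = generate_trials(task, lat, seed=3)
        lats = df.loc[df.condition == "short", "latency_ms"]
        se = 100 / np.sqrt(len(lats))
        assert abs(lats.mean() - 600) < 3 * se

    def test_early_fraction_lands_below_minimum(self):
        lat = LatencyModel(early_fraction=0.25)
        task = TaskConfig(trials_per_condition=1000, directions=("contra",))
        df = generate_trials(task, lat, seed=4)
        longs = df.loc[df.condition == "long", "latency_ms"]
        frac_early = (longs < 2400).mean()
        # binomial 3-sigma band around 0.25 plus natural lognormal tail mass
        assert 0.2 < frac_early < 0.33

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(trials_per_condition=0)
        with pytest.raises(ValueError):
            LatencyModel(early_fraction=0.7)


class TestRateProfile:
    def test_trigger_closed_form(self):
        """Lead 500 ms, baseline 50, peak 100, latency 1200: onset at
        cue+700 with slope 0.1 spikes/s/ms."""
        m = NeuronModel(archetype="trigger", baseline_rate=50, peak_rate=100, d_ms=500)
        r = rate_profile(m, 1200.0)
        t_on = CUE_ON_MS + 700.0
        assert r(t_on - 1) == pytest.approx(50.0)
        k = (r(t_on + 100) - r(t_on)) / 100.0
        assert k == pytest.approx(0.1, abs=1e-12)

    def test_tracker_slope_scales_with_interval(self):
        m = NeuronModel(archetype="tracker", t0_ms=100)
        r_short = rate_profile(m, 400.0)
        r_long = rate_profile(m, 2400.0)
        t_on = CUE_ON_MS + 100.0
        k_short = (r_short(t_on + 50) - r_short(t_on)) / 50.0
        k_long = (r_long(t_on + 50) - r_long(t_on)) / 50.0
        assert k_short > k_long > 0

    def test_integral_matches_quadrature(self):
        m = NeuronModel(archetype="trigger", baseline_rate=20, peak_rate=90, d_ms=400)
        r = rate_profile(m, 1500.0)
        num, _ = integrate.quad(lambda t: float(r(t)), 0, r.t_end, limit=500)
        assert r.integral() == pytest.approx(num / 1000.0, abs=1e-9)

    def test_onset_after_saccade_degenerate(self):
        m = NeuronModel(archetype="tracker", t0_ms=800)
        r = rate_profile(m, 400.0)  # onset would be after the saccade target
        assert r.degenerate
        assert float(r(CUE_ON_MS + 600)) == pytest.approx(m.baseline_rate)


class TestSampleSpikes:
    def test_zero_rate_empty(self):
        r = RateFunction([0.0, 1000.0], [0.0, 0.0])
        assert sample_spikes(r, seed=1).size == 0

    def test_constant_rate_poisson_moments(self):
        """100 spikes/s over 1 s: mean count within 3 SE of 100."""
        r = RateFunction([0.0, 1000.0], [100.0, 100.0])
        rng = np.random.default_rng(5)
        counts = [sample_spikes(r, rng).size for _ in range(1000)]
        se = np.sqrt(100 / 1000)
        assert abs(np.mean(counts) - 100) < 3 * se

    def test_time_rescaling(self):
        """Rescaled inter-spike intervals are unit-rate exponential."""
        m = NeuronModel(archetype="trigger", baseline_rate=40, peak_rate=100, d_ms=600)
        prof = rate_profile(m, 1400.0)
        rng = np.random.default_rng(6)
        rescaled = []
        for _ in range(200):
            sp = sample_spikes(prof, rng)
            # cumulative intensity at spike times (exact for piecewise linear)
            cum = np.array(
                [np.trapezoid(prof(np.linspace(0, s, 400)), np.linspace(0, s, 400))
                 for s in sp]
            ) / 1000.0
            rescaled.extend(np.diff(cum))
        p = stats.kstest(rescaled, "expon").pvalue
        assert p > 0.01

    def test_deterministic_under_seed(self):
        r = RateFunction([0.0, 2000.0], [50.0, 50.0])
        assert np.array_equal(sample_spikes(r, 9), sample_spikes(r, 9))


class TestEyeTrace:
    def test_zero_noise_flat_before_saccade(self):
        df = generate_eye_trace(900.0, 16.0, seed=1, noise_sd_deg=0.0)
        pre = df[df.t_ms < CUE_ON_MS + 900].x_deg.to_numpy()
        assert np.allclose(np.diff(pre), 0.0)

    def test_final_amplitude(self):
        df = generate_eye_trace(900.0, 16.0, seed=2)
        assert abs(df.x_deg.tail(50).mean() - 16.0) < 0.5

    @pytest.mark.parametrize("amp", [3.0, 8.0, 16.0])
    def test_peak_velocity_exceeds_threshold(self, amp):
        df = generate_eye_trace(700.0, amp, seed=3, noise_sd_deg=0.0)
        v = np.abs(np.diff(df.x_deg.to_numpy())) * 1000.0
        assert v.max() > 40.0


class TestSessionGeneration:
    def test_deterministic(self, small_task):
        m = NeuronModel(archetype="tracker")
        a = generate_session(m, small_task, LatencyModel(), seed=21)
        b = generate_session(m, small_task, LatencyModel(), seed=21)
        assert len(a.trials) == len(b.trials)
        for tid in a.spikes:
            assert np.array_equal(a.spikes[tid], b.spikes[tid])

    def test_spike_rates_reflect_baseline(self, trigger_session):
        """Pre-cue firing matches the model baseline (30 sp/s) within 3 SE."""
        counts, dur = [], 0.8
        for tr in trigger_session.trials:
            sp = trigger_session.spikes[tr.trial_id]
            counts.append(np.count_nonzero((sp >= 300) & (sp < 1100)))
        lam = np.mean(counts) / dur
        se = np.sqrt(np.mean(counts)) / dur / np.sqrt(len(counts))
        assert abs(lam - 30.0) < 4 * se
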