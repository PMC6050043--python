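import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramptime.selectivity import (
    classify_duration_selective,
    distance_cdf_compare,
    presaccadic_rates,
    triangle_embed,
)

from conftest import make_session

SQRT3 = np.sqrt(3.0)


def brute_force_ks(a, b):
    """Direct sup over all thresholds of |F_a - F_b|."""
    pts = np.concatenate([a, b])
    return max(
        abs((a <= x).mean() - (b <= x).mean()) for x in pts
    )


class TestPresaccadicRates:
    def test_count_over_window(self):
        # 4 spikes in the 200-ms presaccadic window every trial -> 20 sp/s
        s = make_session(
            lambda tr: tr.saccade_ms - np.array([170.0, 120.0, 70.0, 20.0]),
            n_per_cell=6,
        )
        rates = presaccadic_rates(s, "contra")
        assert all(v == pytest.approx(20.0) for v in rates.values())

    def test_empty_trains_zero(self):
        s = make_session(lambda tr: [], n_per_cell=6)
        rates = presaccadic_rates(s, "contra")
        assert all(v == 0.0 for v in rates.values())

    def test_trigger_neuron_rates_similar_across_conditions(
        self, trigger_session
    ):
        """A saccade-locked neuron reaches the same presaccadic rate in
        every interval condition."""
        rates = presaccadic_rates(trigger_session, "contra")
        vals = np.array(list(rates.values()))
        assert vals.std() / vals.mean() < 0.35


class TestTriangleEmbed:
    def test_balanced_input_at_centroid(self):
        xy, d = triangle_embed({"short": 3.0, "medium": 3.0, "long": 3.0})
        assert xy[0] == pytest.approx(0.0)
        assert xy[1] == pytest.approx(SQRT3 / 3)
        assert d == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "rates, vertex",
        [
            ({"short": 1, "medium": 0, "long": 0}, (0.0, SQRT3)),
            ({"short": 0, "medium": 1, "long": 0}, (1.0, 0.0)),
            ({"short": 0, "medium": 0, "long": 1}, (-1.0, 0.0)),
        ],
    )
    def test_pure_conditions_map_to_vertices(self, rates, vertex):
        xy, d = triangle_embed(rates)
        assert xy == pytest.approx(vertex)

    def test_medium_vertex_distance(self):
        _, d = triangle_embed({"short": 0, "medium": 1, "long": 0})
        assert d == pytest.approx(np.sqrt(1 + 1 / 3))

    @given(
        st.tuples(
            st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 100)
        ),
        st.floats(0.01, 50),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_invariance(self, triple, c):
        rates = dict(zip(("short", "medium", "long"), triple))
        scaled = {k: v * c for k, v in rates.items()}
        xy1, d1 = triangle_embed(rates)
        xy2, d2 = triangle_embed(scaled)
        assert xy1 == pytest.approx(xy2, rel=1e-9, abs=1e-12)
        assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            triangle_embed({"short": 0.0, "medium": 0.0, "long": 0.0})


class TestClassifySelective:
    def test_identical_distributions_none(self):
        rng = np.random.default_rng(1)
        base = rng.normal(20, 2, 30)
        trial_rates = {c: base.copy() for c in ("short", "medium", "long")}
        p, pref = classify_duration_selective(trial_rates)
        assert pref == "none"

    def test_strong_short_preference(self):
        rng = np.random.default_rng(2)
        trial_rates = {
            "short": rng.normal(50, 2, 20),
            "medium": rng.normal(10, 2, 20),
            "long": rng.normal(10, 2, 20),
        }
        p, pref = classify_duration_selective(trial_rates)
        assert p < 1e-6 and pref == "short"

    def test_permutation_type_one_rate(self):
        """Permuting condition labels of a selective neuron yields ~1%
        selective calls at alpha = 0.01."""
        rng = np.random.default_rng(3)
        pooled = np.concatenate([
            rng.normal(50, 5, 20), rng.normal(10, 5, 20), rng.normal(10, 5, 20)
        ])
        calls = 0
        n_perm = 400
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            tr = {"short": perm[:20], "medium": perm[20:40], "long": perm[40:]}
            p, _ = classify_duration_selective(tr)
            calls += p < 0.01
        # 99% binomial band around 0.01
        band = 2.576 * np.sqrt(0.01 * 0.99 / n_perm)
        assert calls / n_perm < 0.01 + 3 * band


class TestDistanceCdfCompare:
    def test_identical_samples_zero_d(self):
        x = np.linspace(0, 1, 20)
        d, p = distance_cdf_compare(x, x)
        assert d == pytest.approx(0.0)

    def test_disjoint_supports_full_d(self):
        d, _ = distance_cdf_compare(np.linspace(0, 1, 10), np.linspace(5, 6, 10))
        assert d == pytest.approx(1.0)

    def test_matches_brute_force_sup(self):
        rng = np.random.default_rng(4)
        a = rng.exponential(1.0, 40)
        b = rng.exponential(2.0, 35)
        d, _ = distance_cdf_compare(a, b)
        assert d == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            distance_cdf_compare(np.ones(3), np.ones(10))

    def test_interval_tuned_population_dominates(self):
        """Neurons with condition-specific peaks sit farther from the
        centroid than untuned neurons: the distance CDFs differ (K-S)."""
        from ramptime.selectivity import analyze_neuron
        from ramptime.synthdata import (
            LatencyModel, NeuronModel, TaskConfig, generate_session,
        )

        task = TaskConfig(trials_per_condition=10)
        conds = ("short", "medium", "long")
        tuned_d, flat_d = [], []
        for i in range(15):
            pref = conds[i % 3]
            gains = {c: (1.0 if c == pref else 0.35) for c in conds}
            m_tuned = NeuronModel(
                archetype="tracker", baseline_rate=10, peak_rate=60,
                condition_peak_gain=gains,
            )
            m_flat = NeuronModel(
                archetype="trigger", baseline_rate=30, peak_rate=80
            )
            s_t = generate_session(m_tuned, task, LatencyModel(), seed=500 + i)
            s_f = generate_session(m_flat, task, LatencyModel(), seed=700 + i)
            tuned_d.append(analyze_neuron(s_t, "contra").distance_from_center)
            flat_d.append(analyze_neuron(s_f, "contra").distance_from_center)
        d, p = distance_cdf_compare(np.array(tuned_d), np.array(flat_d))
        assert np.median(tuned_d) > np.median(flat_d)
        assert p < 0.01
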