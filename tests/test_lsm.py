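"""Liquid State Machine: structure, LIF dynamics, readout, determinism."""

import numpy as np
import pytest

from lfpdecode.lsm import (
    LSMClassifier,
    ReservoirConfig,
    build_reservoir,
    clear_state_cache,
    encode_input,
    fit_readout,
    lsm_predict,
    simulate_reservoir,
)


def isolated_neuron_config(**kw):
    kw.setdefault("grid_shape", (1, 1, 1))
    kw.setdefault("excitatory_fraction", 0.5)
    kw.setdefault("connection_C", {"EE": 0, "EI": 0, "IE": 0, "II": 0})
    return ReservoirConfig(**kw)


class TestBuildReservoir:
    def test_seeded_determinism(self):
        a = build_reservoir(ReservoirConfig(seed=3))
        b = build_reservoir(ReservoirConfig(seed=3))
        assert np.array_equal(a.recurrent_weights, b.recurrent_weights)
        assert np.array_equal(a.input_gains, b.input_gains)

    def test_no_self_connections(self):
        st = build_reservoir(ReservoirConfig(seed=0))
        assert np.all(np.diag(st.recurrent_weights) == 0.0)

    def test_sign_convention_by_presynaptic_identity(self):
        st = build_reservoir(ReservoirConfig(seed=0))
        # column j holds outgoing weights of neuron j
        for j in range(st.config.n_neurons):
            col = st.recurrent_weights[:, j]
            if st.is_excitatory[j]:
                assert np.all(col >= 0)
            else:
                assert np.all(col <= 0)

    def test_zero_lambda_disconnects(self):
        st = build_reservoir(ReservoirConfig(lambda_=1e-9, seed=0))
        assert np.count_nonzero(st.recurrent_weights) == 0

    def test_full_connectivity_limit(self):
        cfg = ReservoirConfig(
            grid_shape=(2, 2, 2),
            lambda_=1e9,
            connection_C={"EE": 1, "EI": 1, "IE": 1, "II": 1},
            seed=0,
        )
        st = build_reservoir(cfg)
        n = cfg.n_neurons
        assert np.count_nonzero(st.recurrent_weights) == n * n - n

    def test_excitatory_fraction(self):
        st = build_reservoir(ReservoirConfig(seed=5))
        assert st.is_excitatory.sum() == round(0.8 * 135)


class TestEncodeInput:
    def test_zero_trace_zero_current(self):
        st = build_reservoir(ReservoirConfig(seed=0))
        assert np.all(encode_input(np.zeros(50), st) == 0.0)

    def test_linearity_in_input(self):
        st = build_reservoir(ReservoirConfig(seed=0))
        x = np.random.default_rng(1).standard_normal(30)
        assert np.allclose(encode_input(3.0 * x, st), 3.0 * encode_input(x, st))

    def test_deterministic(self):
        st = build_reservoir(ReservoirConfig(seed=0))
        x = np.random.default_rng(2).standard_normal(30)
        assert np.array_equal(encode_input(x, st), encode_input(x, st))

    def test_static_mode_holds_constant(self):
        st = build_reservoir(ReservoirConfig(seed=0))
        cur = encode_input(np.ones(10), st, mode="static", hold_steps=25)
        assert cur.shape == (25, st.config.n_neurons)
        assert np.allclose(cur, cur[0][None, :])


class TestSimulate:
    def test_zero_current_no_spikes(self):
        cfg = ReservoirConfig(seed=0)
        st = build_reservoir(cfg)
        out = simulate_reservoir(np.zeros((40, cfg.n_neurons)), st, cfg)
        assert out.spikes.sum() == 0
        assert np.allclose(out.filtered, 0.0)

    def test_nonfinite_current_rejected(self):
        cfg = ReservoirConfig(seed=0)
        st = build_reservoir(cfg)
        cur = np.zeros((10, cfg.n_neurons))
        cur[3, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            simulate_reservoir(cur, st, cfg)

    @pytest.mark.parametrize("current", [1.2, 1.5, 2.0, 3.0])
    def test_interspike_interval_matches_closed_form(self, current):
        """Constant suprathreshold drive: ISI = tau_m ln(I/(I-theta)) + refractory,
        within one simulation step."""
        cfg = isolated_neuron_config(seed=0)
        st = build_reservoir(cfg)
        out = simulate_reservoir(np.full((600, 1), current), st, cfg)
        isis = np.diff(np.flatnonzero(out.spikes[:, 0]))
        closed = cfg.tau_m_ms * np.log(current / (current - cfg.threshold)) + cfg.refractory_ms
        assert np.all(np.abs(isis - closed) <= cfg.dt_ms)

    def test_subthreshold_membrane_matches_analytic_solution(self):
        """No-spike regime: v_t = I (1 - (1 - dt/tau)^t), the exact solution
        of the discretized leaky integrator, to 1e-6 relative error."""
        cfg = isolated_neuron_config(seed=0, threshold=10.0)
        st = build_reservoir(cfg)
        current = 0.5
        out = simulate_reservoir(
            np.full((100, 1), current), st, cfg, record_voltage=True
        )
        alpha = cfg.dt_ms / cfg.tau_m_ms
        t = np.arange(1, 101)
        analytic = current * (1.0 - (1.0 - alpha) ** t)
        assert np.max(np.abs(out.voltage[:, 0] - analytic) / analytic) < 1e-6

    def test_spike_count_monotone_in_drive(self):
        cfg = isolated_neuron_config(seed=0)
        st = build_reservoir(cfg)
        sub = simulate_reservoir(np.full((200, 1), 0.9), st, cfg).spikes.sum()
        supra = simulate_reservoir(np.full((200, 1), 1.8), st, cfg).spikes.sum()
        assert sub == 0 and supra > 0

    def test_batch_matches_single(self):
        cfg = ReservoirConfig(seed=1)
        st = build_reservoir(cfg)
        rng = np.random.default_rng(0)
        cur = rng.uniform(0, 2, size=(3, 50, cfg.n_neurons))
        batch = simulate_reservoir(cur, st, cfg)
        for i in range(3):
            single = simulate_reservoir(cur[i], st, cfg)
            assert np.array_equal(batch.spikes[i], single.spikes)
            assert np.allclose(batch.sampled[i], single.sampled)


class TestReadout:
    def test_separable_states_fit_perfectly(self, rng):
        states = np.vstack([rng.normal(0, 0.1, (50, 5)), rng.normal(3, 0.1, (50, 5))])
        labels = np.repeat([0, 1], 50)
        clf = fit_readout(states, labels, regularization_C=100.0)
        assert clf.score(states, labels) == 1.0

    def test_permuted_labels_are_chance(self):
        """States carry no label information: CV accuracy ~ 0.5 at n=500."""
        from sklearn.model_selection import cross_val_score
        from sklearn.linear_model import LogisticRegression

        r = np.random.default_rng(7)
        states = r.standard_normal((500, 20))
        labels = np.repeat([0, 1], 250)
        acc = cross_val_score(
            LogisticRegression(max_iter=2000), states, labels, cv=5
        ).mean()
        assert abs(acc - 0.5) <= 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_readout(np.zeros((5, 3)), np.zeros(5))

    def test_duplicated_columns_well_defined(self, rng):
        """Ridge-penalized readout stays well-defined under collinearity:
        duplicating every column changes no decision and refits exactly."""
        states = rng.standard_normal((60, 4))
        labels = np.repeat([0, 1], 30)
        states[:, 0] = np.where(labels, 1.5, -1.5) + 0.1 * rng.standard_normal(60)
        a = fit_readout(states, labels).predict_proba(states)
        dup = np.hstack([states, states])
        b = fit_readout(dup, labels).predict_proba(dup)
        b2 = fit_readout(dup, labels).predict_proba(dup)
        assert np.array_equal(b, b2)
        assert np.array_equal(a.argmax(axis=1), b.argmax(axis=1))


class TestClassifierFacade:
    def _toy(self, rng, n=40, T=60):
        base = rng.uniform(0.3, 0.7, size=(n, T))
        labels = np.repeat([0, 1], n // 2)
        base[labels == 1, 10:30] -= 0.5  # evoked-like dip
        return np.clip(base, 0, 1), labels

    def test_probabilities_valid_and_deterministic(self, rng):
        X, y = self._toy(rng)
        clear_state_cache()
        clf = LSMClassifier(C=1.0).fit(X, y)
        p1 = clf.predict_proba(X)
        p2 = clf.predict_proba(X)
        assert np.array_equal(p1, p2)
        assert np.allclose(p1.sum(axis=1), 1.0)
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_learns_dip_pattern(self, rng):
        X, y = self._toy(rng, n=60)
        clf = LSMClassifier(C=1.0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.9

    def test_untrained_prediction_rejected(self):
        with pytest.raises(RuntimeError, match="not trained"):
            LSMClassifier().predict_proba(np.zeros((2, 10)))

    def test_lsm_predict_is_positive_class_probability(self, rng):
        X, y = self._toy(rng)
        clf = LSMClassifier().fit(X, y)
        assert np.allclose(lsm_predict(clf, X), clf.predict_proba(X)[:, 1])

    def test_state_cache_transparent(self, rng):
        X, y = self._toy(rng, n=20)
        clear_state_cache()
        s1 = LSMClassifier().states(X)
        s2 = LSMClassifier().states(X)  # second call hits the cache
        assert np.array_equal(s1, s2)

    def test_firing_rate_stability_band(self, small_cohort):
        """Default dynamics keep the mean rate inside 1-100 Hz on real-ish input."""
        import warnings
        from lfpdecode.experiments import ScenarioSpec, build_features
        from lfpdecode.features import apply_minmax, fit_minmax

        sc = ScenarioSpec(task="SD", window="PERI", feature_type="RAW",
                          layer="L4", intensity_subset=(0, 100))
        mat, _, _ = build_features(small_cohort, sc)
        X = apply_minmax(fit_minmax(mat), mat).values[:30]
        clear_state_cache()
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # stability warning would fail here
            LSMClassifier().states(X)
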