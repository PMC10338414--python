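import numpy as np
import pytest

from spikecube._kernels import stdp_delta_kernel
from spikecube.reservoir import (
    LIFConfig,
    STDPConfig,
    SWCConfig,
    connection_probabilities,
    init_reservoir,
    simulate,
    stdp_train,
    subtract,
)

from conftest import make_line_template, make_manual_cube, trains_from_events


class TestSmallWorldInit:
    def test_probability_zero_beyond_threshold(self):
        tpl = make_line_template(frac=0.5)
        p = connection_probabilities(tpl, SWCConfig(C=0.8, lam=0.2, d_thresh=0.3))
        # pair (0,2) has d_norm = 1 > d_thresh; (0,1) has d_norm = 0.5 > 0.3 too
        assert p[0, 2] == 0.0 and p[0, 1] == 0.0
        assert np.all(np.diag(p) == 0.0)

    def test_probability_formula_values(self):
        tpl = make_line_template(frac=0.5)
        cfg = SWCConfig(C=0.6, lam=0.5, d_thresh=1.0)
        p = connection_probabilities(tpl, cfg)
        assert p[0, 1] == pytest.approx(0.6 * np.exp(-1.0))          # d = λ
        assert p[0, 2] == pytest.approx(0.6 * np.exp(-(1 / 0.5) ** 2))

    def test_no_connections_beyond_threshold_in_cube(self, reduced_template):
        cfg = SWCConfig(seed=5)
        cube = init_reservoir(reduced_template, cfg)
        coords = reduced_template.coords
        diff = coords[:, None] - coords[None]
        dn = np.sqrt((diff**2).sum(-1))
        dn /= dn.max()
        rows = np.repeat(np.arange(cube.n_neurons), np.diff(cube.indptr))
        assert np.all(dn[rows, cube.indices] <= cfg.d_thresh + 1e-12)
        assert np.all(cube.d >= 1)

    def test_monte_carlo_frequency_matches_closed_form(self):
        # empirical connection frequency at d_norm = λ over many inits
        cfg = SWCConfig(C=0.5, lam=0.4, d_thresh=0.9)
        tpl = make_line_template(frac=0.4)
        trials = 2000
        hits = 0
        for s in range(trials):
            cube = init_reservoir(tpl, SWCConfig(C=0.5, lam=0.4, d_thresh=0.9, seed=s))
            hits += cube.weights[0, 1] != 0
        p = cfg.C * np.exp(-1.0)
        sd = np.sqrt(p * (1 - p) * trials)
        assert abs(hits - trials * p) <= 3 * sd

    def test_determinism(self, reduced_template):
        a = init_reservoir(reduced_template, SWCConfig(seed=7))
        b = init_reservoir(reduced_template, SWCConfig(seed=7))
        assert a.init_id == b.init_id
        np.testing.assert_array_equal(a.w, b.w)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_inhibitory_sign_is_per_presynaptic_neuron(self, reduced_template):
        cube = init_reservoir(reduced_template, SWCConfig(seed=3, p_inhibitory=0.5))
        w = cube.weights
        for i in range(cube.n_neurons):
            row = w.data[w.indptr[i] : w.indptr[i + 1]]
            if row.size:
                assert np.all(row > 0) or np.all(row < 0)


class TestLIFSimulation:
    def make_two_neuron(self, weight, delay, lif=None):
        tpl = make_line_template(n=2, frac=0.5, channels=("A",))
        return make_manual_cube(tpl, [(0, 1, weight, delay)], lif=lif)

    def test_no_input_no_firing(self):
        cube = self.make_two_neuron(1.0, 1)
        rec = simulate(cube, trains_from_events(np.zeros((1, 20)), ["A"]))
        assert not rec.any()

    def test_suprathreshold_synapse_fires_after_delay(self):
        lif = LIFConfig(v_threshold=0.5, leak=0.0, refractory=0, delay_max=5)
        cube = self.make_two_neuron(0.6, 3, lif)
        ev = np.zeros((1, 20), dtype=np.int8)
        ev[0, [2, 10]] = 1
        rec = simulate(cube, trains_from_events(ev, ["A"]))
        assert np.flatnonzero(rec[1]).tolist() == [5, 13]

    def test_subthreshold_with_leak_never_fires(self):
        lif = LIFConfig(v_threshold=1.0, leak=0.9, refractory=0)
        cube = self.make_two_neuron(0.6, 1, lif)
        ev = np.zeros((1, 50), dtype=np.int8)
        ev[0, ::10] = 1  # isolated spikes, potential decays in between
        rec = simulate(cube, trains_from_events(ev, ["A"]))
        assert not rec[1].any()

    def test_refractory_suppresses_firing(self):
        lif = LIFConfig(v_threshold=0.5, leak=0.0, refractory=3, delay_max=5)
        cube = self.make_two_neuron(1.0, 1, lif)
        ev = np.ones((1, 10), dtype=np.int8)
        rec = simulate(cube, trains_from_events(ev, ["A"]))
        fires = np.flatnonzero(rec[1])
        assert np.all(np.diff(fires) >= 4)  # 3 silent steps after each fire

    def test_inhibitory_input_lowers_potential(self):
        lif = LIFConfig(v_threshold=0.5, leak=0.0, refractory=0)
        cube = self.make_two_neuron(0.6, 1, lif)
        ev = np.zeros((1, 10), dtype=np.int8)
        ev[0, 2] = -1  # inhibitory event drives potential negative
        rec = simulate(cube, trains_from_events(ev, ["A"]))
        assert not rec[1].any()

    def test_unknown_channel_rejected(self):
        cube = self.make_two_neuron(1.0, 1)
        with pytest.raises(KeyError):
            simulate(cube, trains_from_events(np.zeros((1, 5)), ["NOPE"]))


class TestSTDP:
    def paired_delta(self, t_pre, t_post, T=20, a=0.05, tp=3.0):
        rec = np.zeros((2, T), dtype=np.int8)
        rec[0, t_pre] = 1
        rec[1, t_post] = 1
        indptr = np.array([0, 1, 1])       # single connection 0 → 1
        indices = np.array([1])
        dw = stdp_delta_kernel(indptr, indices, rec, a, a, tp, 9)
        return dw[0]

    def test_causal_pair_potentiates(self):
        assert self.paired_delta(5, 7) > 0

    def test_anticausal_pair_depresses(self):
        assert self.paired_delta(7, 5) < 0

    def test_magnitude_decays_with_gap(self):
        gaps = [self.paired_delta(5, 5 + s) for s in (1, 2, 3, 4)]
        assert all(a > b > 0 for a, b in zip(gaps, gaps[1:]))

    def test_simultaneous_spikes_no_change(self):
        assert self.paired_delta(5, 5) == 0.0

    def test_pairs_outside_window_ignored(self):
        assert self.paired_delta(0, 15) == 0.0  # gap 15 > window 9

    def test_uncorrelated_trains_near_zero_mean_drift(self):
        rng = np.random.default_rng(11)
        indptr = np.array([0, 1, 1])
        indices = np.array([1])
        deltas = [
            stdp_delta_kernel(
                indptr, indices,
                (rng.random((2, 400)) < 0.1).astype(np.int8), 0.05, 0.05, 3.0, 9,
            )[0]
            for _ in range(200)
        ]
        single = 0.05 * np.exp(-1 / 3.0)
        assert abs(np.mean(deltas)) < single  # mean drift ≪ one pairing update

    def test_train_changes_only_weights(self, reduced_template):
        cube = init_reservoir(reduced_template, SWCConfig(seed=1))
        rng = np.random.default_rng(0)
        ev = (rng.random((32, 100)) < 0.3).astype(np.int8)
        tr = trains_from_events(ev, reduced_template.channels)
        trained = stdp_train(cube, [tr], STDPConfig())
        np.testing.assert_array_equal(trained.indices, cube.indices)
        np.testing.assert_array_equal(trained.d, cube.d)
        assert trained.init_id == cube.init_id
        assert not np.array_equal(trained.w, cube.w)

    def test_empty_sample_list_rejected(self, reduced_template):
        cube = init_reservoir(reduced_template, SWCConfig(seed=1))
        with pytest.raises(ValueError):
            stdp_train(cube, [])


class TestSubtraction:
    def trained_pair(self, reduced_template, same_init=True):
        cube = init_reservoir(reduced_template, SWCConfig(seed=2))
        rng = np.random.default_rng(5)
        mk = lambda: trains_from_events(
            (rng.random((32, 80)) < 0.3).astype(np.int8), reduced_template.channels
        )
        a = stdp_train(cube, [mk()], STDPConfig(), label="a")
        if not same_init:
            cube2 = init_reservoir(reduced_template, SWCConfig(seed=3))
            return a, stdp_train(cube2, [mk()], STDPConfig(), label="b")
        return a, stdp_train(cube, [mk()], STDPConfig(), label="b")

    def test_self_subtraction_is_zero(self, reduced_template):
        a, _ = self.trained_pair(reduced_template)
        assert np.all(subtract(a, a).w == 0.0)

    def test_antisymmetry(self, reduced_template):
        a, b = self.trained_pair(reduced_template)
        np.testing.assert_allclose(subtract(a, b).w, -subtract(b, a).w)

    def test_mismatched_init_rejected(self, reduced_template):
        a, b = self.trained_pair(reduced_template, same_init=False)
        with pytest.raises(ValueError):
            subtract(a, b)
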