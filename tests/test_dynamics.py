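"""Membrane/synapse integration tests and engine cross-validation.

The fused numba kernel used for whole trials must agree with the plain
numpy reference (`integrate_step` / `update_conductances`) when noise is
disabled, since both implement the same update order.
"""

import dataclasses

import numpy as np
import pytest

from colseq.architecture import CH_EXC, CH_INH, build_network
from colseq.config import NetworkConfig, NeuronParams
from colseq.dynamics import N_CHANNELS, SimState, SpikeRecord, integrate_step, run_window, update_conductances


def _neuron():
    return NeuronParams()


def _vth(n, v=np.inf):
    return np.full(n, v)


class TestIntegrateStep:
    def test_rest_is_fixed_point(self):
        p = _neuron()
        state = SimState.initial(5, p.v_rest)
        for _ in range(100):
            integrate_step(state, _vth(5, p.v_th_exc), p, dt=0.1)
        np.testing.assert_allclose(state.v, p.v_rest)

    def test_monotone_convergence_to_rest(self):
        p = _neuron()
        state = SimState.initial(2, p.v_rest)
        state.v[:] = [-60.0, -80.0]
        prev = state.v.copy()
        for _ in range(2000):
            integrate_step(state, _vth(2), p, dt=0.1)
            assert state.v[0] <= prev[0] + 1e-12 and state.v[1] >= prev[1] - 1e-12
            prev = state.v.copy()
        np.testing.assert_allclose(state.v, p.v_rest, atol=1e-3)

    def test_constant_current_matches_closed_form(self):
        # V(t) = V_rest + (I/g_L)(1 - exp(-t g_L / C_m)) for constant I
        p = _neuron()
        current = 100.0  # pA, keeps V below threshold
        dt, steps = 0.1, 3000
        state = SimState.initial(1, p.v_rest)
        for _ in range(steps):
            integrate_step(state, _vth(1), p, dt=dt, noise=current)
        t = steps * dt
        tau = p.c_m / p.g_l
        expected = p.v_rest + (current / p.g_l) * (1 - np.exp(-t / tau))
        assert state.v[0] == pytest.approx(expected, abs=0.02)

    def test_spike_resets_and_enforces_refractory(self):
        p = _neuron()
        state = SimState.initial(1, p.v_rest)
        spikes = []
        for k in range(1000):
            out = integrate_step(state, _vth(1, p.v_th_exc), p, dt=0.1, noise=1500.0)
            if len(out):
                spikes.append(state.t)
                assert state.v[0] == p.v_reset
        isis = np.diff(spikes)
        assert len(spikes) > 3
        assert np.all(isis >= p.t_ref)

    def test_nonfinite_state_aborts(self):
        p = _neuron()
        state = SimState.initial(1, p.v_rest)
        state.v[0] = np.nan
        with pytest.raises(FloatingPointError):
            integrate_step(state, _vth(1), p, dt=0.1)


class TestUpdateConductances:
    tau = np.array([80.0, 10.0, 10.0, 80.0])
    sat = np.array([9.0, 150.0, 200.0, 12.0])

    def test_pure_decay(self):
        state = SimState.initial(3, -70.0)
        state.g[:, 0] = 5.0
        for _ in range(800):
            update_conductances(state, None, self.tau, self.sat, dt=0.1)
        assert state.g[0, 0] == pytest.approx(5.0 * np.exp(-80.0 / 80.0), rel=1e-3)

    def test_saturated_channel_ignores_increment(self):
        state = SimState.initial(1, -70.0)
        state.g[0, 0] = self.sat[0]
        arr = (np.array([0]), np.array([3.0]), np.array([0]))
        update_conductances(state, arr, self.tau, self.sat, dt=0.0)
        assert state.g[0, 0] == pytest.approx(self.sat[0])

    def test_increment_respects_headroom(self):
        state = SimState.initial(1, -70.0)
        state.g[0, 0] = 4.5  # half of saturation
        arr = (np.array([0]), np.array([2.0]), np.array([0]))
        update_conductances(state, arr, self.tau, self.sat, dt=0.0)
        assert state.g[0, 0] == pytest.approx(4.5 + 2.0 * 0.5)

    def test_negative_weight_rejected(self):
        state = SimState.initial(1, -70.0)
        arr = (np.array([0]), np.array([-1.0]), np.array([0]))
        with pytest.raises(ValueError):
            update_conductances(state, arr, self.tau, self.sat, dt=0.1)

    def test_trajectory_matches_tenfold_refinement(self):
        # single spike, then pure decay: dt vs dt/10 brute force
        coarse = SimState.initial(1, -70.0)
        fine = SimState.initial(1, -70.0)
        arr = (np.array([0]), np.array([1.0]), np.array([0]))
        update_conductances(coarse, arr, self.tau, self.sat, dt=0.0)
        update_conductances(fine, arr, self.tau, self.sat, dt=0.0)
        for _ in range(1000):
            update_conductances(coarse, None, self.tau, self.sat, dt=0.1)
        for _ in range(10000):
            update_conductances(fine, None, self.tau, self.sat, dt=0.01)
        assert coarse.g[0, 0] == pytest.approx(fine.g[0, 0], rel=1e-6)


@pytest.fixture(scope="module")
def quiet_model():
    """Small noiseless single-column network with STD disabled."""
    cfg = NetworkConfig(n_columns=1, n_per_pop=30)
    cfg = cfg.replace(
        noise=dataclasses.replace(cfg.noise, xi_gain=0.0),
        synapse=dataclasses.replace(cfg.synapse, u_dep=0.0),
    )
    return build_network(cfg, seed=21)


def _reference_run(model, in_times, in_tgt, duration):
    """Plain-python mirror of the fused kernel (no noise, no STD)."""
    cfg = model.config
    p, syn = cfg.neuron, cfg.synapse
    dt = cfg.sim.dt
    n_steps = int(round(duration / dt))
    delay_steps = int(round(syn.delay / dt))
    tau = np.array([syn.tau_exc, syn.tau_inh, syn.tau_input, syn.tau_exc])
    sat = np.array([syn.g_sat_exc, syn.g_sat_inh, syn.g_sat_input, syn.g_sat_exc_inh])
    v_th = np.where(model.is_exc, p.v_th_exc, p.v_th_inh)

    order = np.argsort(model.st_src, kind="stable")
    by_src: dict[int, list[int]] = {}
    for e in order:
        by_src.setdefault(int(model.st_src[e]), []).append(e)
    porder = np.argsort(model.pl_pre, kind="stable")
    pl_by_src: dict[int, list[int]] = {}
    for e in porder:
        pl_by_src.setdefault(int(model.pl_pre[e]), []).append(e)

    in_step = np.round(np.asarray(in_times) / dt).astype(int) + delay_steps
    state = SimState.initial(model.n_neurons, p.v_rest)
    pending: dict[int, list[int]] = {}
    spikes_t, spikes_i = [], []
    for step in range(n_steps):
        tgt, w, ch = [], [], []
        for src in pending.pop(step, []):
            for e in by_src.get(src, []):
                tgt.append(model.st_tgt[e])
                w.append(model.st_w[e])
                ch.append(model.st_ch[e])
            for e in pl_by_src.get(src, []):
                tgt.append(model.pl_post[e])
                w.append(model.pl_w[e])
                ch.append(CH_EXC)
        for k in np.flatnonzero(in_step == step):
            tgt.append(in_tgt[k])
            w.append(model.input_w)
            ch.append(2)
        arr = (np.array(tgt, int), np.array(w, float), np.array(ch, int)) if tgt else None
        update_conductances(state, arr, tau, sat, dt)
        out = integrate_step(state, v_th, p, dt)
        for i in out:
            spikes_t.append(state.t)
            spikes_i.append(i)
            pending.setdefault(step + 1 + delay_steps, []).append(int(i))
    return np.array(spikes_t), np.array(spikes_i), state


class TestEngineEquivalence:
    def test_kernel_matches_reference_without_noise(self, quiet_model):
        m = quiet_model
        rng = np.random.default_rng(3)
        targets = np.flatnonzero(m.input_mask)
        in_tgt = rng.choice(targets, size=60)
        in_times = np.sort(rng.uniform(0.0, 50.0, size=60))
        ref_t, ref_i, ref_state = _reference_run(m, in_times, in_tgt, 200.0)
        state, spikes, _ = run_window(m, None, (in_times, in_tgt), 200.0, seed=0)
        assert len(spikes) == len(ref_t) and len(ref_t) > 20
        np.testing.assert_allclose(spikes.times, ref_t, atol=1e-9)
        np.testing.assert_array_equal(spikes.ids, ref_i)
        np.testing.assert_allclose(state.v, ref_state.v, atol=1e-9)
        np.testing.assert_allclose(state.g, ref_state.g, atol=1e-9)


class TestRunWindow:
    def test_zero_duration_empty_record(self, small_model):
        _, spikes, _ = run_window(small_model, None, None, 0.0, seed=1)
        assert len(spikes) == 0

    def test_duration_off_grid_rejected(self, small_model):
        with pytest.raises(ValueError):
            run_window(small_model, None, None, 100.05, seed=1)

    def test_identical_seeds_bit_identical(self, small_model):
        _, a, _ = run_window(small_model, None, None, 500.0, seed=42)
        _, b, _ = run_window(small_model, None, None, 500.0, seed=42)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.ids, b.ids)

    def test_refractory_contract_in_noise_driven_window(self, small_model):
        _, spikes, _ = run_window(small_model, None, None, 1000.0, seed=5)
        isis = spikes.isis()
        assert len(isis) > 50
        assert isis.min() >= 3.0

    def test_conductances_bounded_after_stimulus(self, small_model):
        rng = np.random.default_rng(0)
        targets = np.flatnonzero(small_model.input_mask & (small_model.column == 1))
        times = np.sort(rng.uniform(0, 50, 150))
        tgt = rng.choice(targets, 150)
        state, _, _ = run_window(small_model, None, (times, tgt), 300.0, seed=2)
        syn = small_model.config.synapse
        sat = np.array([syn.g_sat_exc, syn.g_sat_inh, syn.g_sat_input, syn.g_sat_exc_inh])
        assert np.all(state.g >= 0.0)
        assert np.all(state.g <= sat[None, :] + 1e-9)

    def test_halving_dt_changes_counts_mildly(self, small_model):
        counts = {}
        for dt in (0.1, 0.05):
            m = small_model.copy()
            m.config = m.config.replace(sim=dataclasses.replace(m.config.sim, dt=dt))
            _, spikes, _ = run_window(m, None, None, 1000.0, seed=11)
            counts[dt] = len(spikes)
        assert counts[0.1] > 200
        assert abs(counts[0.1] - counts[0.05]) / counts[0.1] < 0.10


class TestSpikeRecordIO:
    def test_gdf_round_trip(self, tmp_path):
        rec = SpikeRecord(np.array([1.5, 2.5, 9.0]), np.array([4, 2, 7]), (0.0, 10.0), 10)
        path = tmp_path / "spikes.gdf"
        rec.to_gdf(path)
        back = SpikeRecord.from_gdf(path)
        np.testing.assert_allclose(back.times, rec.times)
        np.testing.assert_array_equal(back.ids, rec.ids)
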