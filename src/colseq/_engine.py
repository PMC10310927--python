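"""Fused simulation loop (numba) for whole trials.

One compiled kernel advances membranes, conductances, the per-neuron
exponential rate filter, eligibility traces and the reward gate for a full
trial.  The update order per integration step is identical to the reference
implementations in :mod:`colseq.dynamics` and :mod:`colseq.plasticity`
(decay conductances -> deliver delayed spikes -> integrate/threshold ->
trace step -> reward accumulation), which the test suite verifies.

Spike propagation is event-driven over CSR adjacency; eligibility traces
advance on a coarser grid (``traces.trace_dt``, default 1 ms) since both the
rate filter (tau_r = 40 ms) and the traces (tau ~ 1-2 s) are slow compared
to the 0.1 ms membrane step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .architecture import NetworkModel
from .dynamics import SimState, SpikeRecord

__all__ = ["PackedNet", "pack_network", "run_trial", "TrialOutput"]

STATUS_OK = 0
STATUS_SPIKE_OVERFLOW = 1
STATUS_NONFINITE = 2
STATUS_RUNAWAY = 3


@dataclass
class PackedNet:
    """CSR adjacency and per-neuron parameter arrays for the kernel.

    Plastic weights live in ``p_w`` (CSR order); ``perm`` maps model order
    to CSR order (``p_w == model.pl_w[perm]``).  ``sync_from_model`` /
    ``sync_to_model`` move weights between the two layouts.
    """

    n: int
    v_th: np.ndarray
    s_ptr: np.ndarray
    s_tgt: np.ndarray
    s_w: np.ndarray
    s_ch: np.ndarray
    p_ptr: np.ndarray
    p_tgt: np.ndarray
    p_w: np.ndarray
    p_pre: np.ndarray
    p_kind: np.ndarray
    p_class: np.ndarray
    perm: np.ndarray
    pop_of: np.ndarray
    n_pops: int
    pop_size: np.ndarray

    @property
    def n_plastic(self) -> int:
        return len(self.p_w)

    def sync_from_model(self, model: NetworkModel) -> None:
        self.p_w[:] = model.pl_w[self.perm]

    def sync_to_model(self, model: NetworkModel) -> None:
        model.pl_w[self.perm] = self.p_w


def pack_network(model: NetworkModel) -> PackedNet:
    n = model.n_neurons
    neuron = model.config.neuron
    v_th = np.where(model.is_exc, neuron.v_th_exc, neuron.v_th_inh).astype(np.float64)

    def to_csr(src, tgt, *cols):
        order = np.argsort(src, kind="stable")
        src_s = src[order]
        ptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(ptr, src_s + 1, 1)
        np.cumsum(ptr, out=ptr)
        return order, ptr, tgt[order], [c[order] for c in cols]

    s_order, s_ptr, s_tgt, (s_w, s_ch) = to_csr(model.st_src, model.st_tgt, model.st_w, model.st_ch)
    p_order, p_ptr, p_tgt, (p_w, p_kind, p_class) = to_csr(
        model.pl_pre, model.pl_post, model.pl_w, model.pl_kind, model.pl_class
    )
    pop_of = model.pop_index().astype(np.int64)
    n_pops = 4 * model.config.n_columns
    pop_size = np.bincount(pop_of, minlength=n_pops).astype(np.float64)
    return PackedNet(
        n=n,
        v_th=v_th,
        s_ptr=s_ptr,
        s_tgt=s_tgt.astype(np.int64),
        s_w=s_w.astype(np.float64),
        s_ch=s_ch.astype(np.int64),
        p_ptr=p_ptr,
        p_tgt=p_tgt.astype(np.int64),
        p_w=p_w.astype(np.float64),
        p_pre=model.pl_pre[p_order].astype(np.int64),
        p_kind=p_kind.astype(np.int64),
        p_class=p_class.astype(np.int64),
        perm=p_order,
        pop_of=pop_of,
        n_pops=n_pops,
        pop_size=pop_size,
    )


@dataclass
class TrialOutput:
    state: SimState
    spikes: SpikeRecord
    pop_rates: np.ndarray | None     # (n_rec, n_pops), spks/sec
    rate_times: np.ndarray | None    # ms
    traces_tp: np.ndarray | None
    traces_td: np.ndarray | None
    pending_dw: np.ndarray | None    # CSR order
    class_traces: np.ndarray | None  # (n_rec, 2*n_classes) mean LTP/LTD per class
    status: int


@njit(cache=True)
def _sim_loop(
    dt, n_steps, delay_steps, noise_steps, trace_stride, rec_stride, seed,
    v, g, ref_until, rate, rate_h, v_th,
    c_m, g_l, v_rest, v_reset, t_ref, e_exc, e_inh,
    rate_decay, rate_jump, rateh_decay, rateh_jump, sigma_step, ch_decay, g_sat,
    x, is_exc, u_dep, dep_rec, dep_ref,
    s_ptr, s_tgt, s_w, s_ch,
    p_ptr, p_tgt, p_w, p_kind_csr,
    in_step, in_tgt, w_in,
    plastic_on, p_pre, p_kind,
    tp, td, trf, pending,
    k_tau_p, k_tau_d, k_eta_p, k_eta_d, k_tmax_p, k_tmax_d, k_rth, k_lr, k_wmax,
    mode_each, rw_start, rw_end, trace_ref_steps,
    pop_of, pop_size, pop_rate_out,
    p_class, n_pl_class, trace_rec, record_traces,
    spk_t, spk_id, max_rate,
):
    n = v.shape[0]
    np.random.seed(seed)
    ring_size = delay_steps + 2
    ring_ids = np.empty((ring_size, n), dtype=np.int64)
    ring_x = np.empty((ring_size, n))
    ring_cnt = np.zeros(ring_size, dtype=np.int64)
    noise = np.zeros(n)
    last_dep = np.full(n, -1e9)
    nsyn = tp.shape[0]
    n_rw = rw_start.shape[0]
    cap = spk_t.shape[0]
    nspk = 0
    in_ptr = 0
    n_in = in_step.shape[0]
    rw_idx = 0
    check_last_nspk = 0

    for step in range(n_steps):
        t = step * dt
        t_next = t + dt
        if step % noise_steps == 0:
            for i in range(n):
                noise[i] = sigma_step * np.random.standard_normal()
        # 1. conductance decay + resource recovery
        for i in range(n):
            g[i, 0] *= ch_decay[0]
            g[i, 1] *= ch_decay[1]
            g[i, 2] *= ch_decay[2]
            g[i, 3] *= ch_decay[3]
            x[i] += dep_rec * (1.0 - x[i])
        # 2. delayed spike delivery (saturating increments)
        slot = step % ring_size
        for k in range(ring_cnt[slot]):
            src = ring_ids[slot, k]
            xs = ring_x[slot, k]
            for e in range(s_ptr[src], s_ptr[src + 1]):
                tgt = s_tgt[e]
                c = s_ch[e]
                g0 = g[tgt, c]
                g[tgt, c] = g0 + s_w[e] * (1.0 - g0 / g_sat[c])
            for e in range(p_ptr[src], p_ptr[src + 1]):
                tgt = p_tgt[e]
                g0 = g[tgt, 0]
                # the adaptation resource applies to recurrent T->T synapses
                f = xs if p_kind_csr[e] == 0 else 1.0
                g[tgt, 0] = g0 + p_w[e] * f * (1.0 - g0 / g_sat[0])
        ring_cnt[slot] = 0
        while in_ptr < n_in and in_step[in_ptr] == step:
            tgt = in_tgt[in_ptr]
            g0 = g[tgt, 2]
            g[tgt, 2] = g0 + w_in * (1.0 - g0 / g_sat[2])
            in_ptr += 1
        # 3. integrate membranes, register threshold crossings at t + dt
        half_dt = 0.5 * dt
        for i in range(n):
            rate[i] *= rate_decay
            rate_h[i] *= rateh_decay
            if t >= ref_until[i] - half_dt:
                vi = v[i]
                isyn = (g[i, 0] + g[i, 2] + g[i, 3]) * (e_exc - vi) + g[i, 1] * (e_inh - vi)
                vi = vi + (dt / c_m) * (g_l * (v_rest - vi) + isyn + noise[i])
                if vi >= v_th[i]:
                    if nspk >= cap:
                        return nspk, 1
                    spk_t[nspk] = t_next
                    spk_id[nspk] = i
                    nspk += 1
                    rate[i] += rate_jump
                    rate_h[i] += rateh_jump
                    v[i] = v_reset
                    ref_until[i] = t_next + t_ref
                    aslot = (step + 1 + delay_steps) % ring_size
                    ring_ids[aslot, ring_cnt[aslot]] = i
                    if is_exc[i]:
                        ring_x[aslot, ring_cnt[aslot]] = x[i]
                        # depletion is refractory-limited: high-rate volleys
                        # consume no more resource than a moderate burst
                        if t_next - last_dep[i] >= dep_ref:
                            x[i] *= 1.0 - u_dep
                            last_dep[i] = t_next
                    else:
                        ring_x[aslot, ring_cnt[aslot]] = 1.0
                    ring_cnt[aslot] += 1
                else:
                    v[i] = vi
            else:
                v[i] = v_reset
        # 4. eligibility traces + reward gate on the coarse grid
        if plastic_on and step % trace_stride == 0:
            dtt = trace_stride * dt
            if rw_idx < n_rw and step >= rw_end[rw_idx]:
                # reward window closed: consume traces, start trace refractory
                for s in range(nsyn):
                    tp[s] = 0.0
                    td[s] = 0.0
                    trf[s] = step + trace_ref_steps
                rw_idx += 1
            in_rw = rw_idx < n_rw and rw_start[rw_idx] <= step < rw_end[rw_idx]
            for s in range(nsyn):
                if step < trf[s]:
                    continue
                kk = p_kind[s]
                # feedforward gate uses the slower rate filter
                if kk == 1:
                    ri = rate_h[p_pre[s]]
                    rj = rate_h[p_tgt[s]]
                else:
                    ri = rate[p_pre[s]]
                    rj = rate[p_tgt[s]]
                if mode_each:
                    act = ri > k_rth[kk] and rj > k_rth[kk]
                else:
                    act = ri * rj > k_rth[kk]
                h = ri * rj if act else 0.0
                ap = tp[s]
                ap = ap + (dtt / k_tau_p[kk]) * (-ap + k_eta_p[kk] * h * (k_tmax_p[kk] - ap))
                if ap < 0.0:
                    ap = 0.0
                elif ap > k_tmax_p[kk]:
                    ap = k_tmax_p[kk]
                tp[s] = ap
                ad = td[s]
                ad = ad + (dtt / k_tau_d[kk]) * (-ad + k_eta_d[kk] * h * (k_tmax_d[kk] - ad))
                if ad < 0.0:
                    ad = 0.0
                elif ad > k_tmax_d[kk]:
                    ad = k_tmax_d[kk]
                td[s] = ad
                if in_rw:
                    dw = k_lr[kk] * (ap - ad) * dtt
                    if dw > 0.0:
                        # soft upper bound on potentiation
                        bound = 1.0 - p_w[s] / k_wmax[kk]
                        dw *= bound if bound > 0.0 else 0.0
                    pending[s] += dw
        # 5. population rates (and optionally class-mean traces) on the grid
        if (step + 1) % rec_stride == 0:
            ridx = (step + 1) // rec_stride - 1
            for i in range(n):
                pop_rate_out[ridx, pop_of[i]] += rate[i]
            for p in range(pop_rate_out.shape[1]):
                pop_rate_out[ridx, p] /= pop_size[p]
            if record_traces:
                for s in range(nsyn):
                    c = p_class[s]
                    trace_rec[ridx, 2 * c] += tp[s]
                    trace_rec[ridx, 2 * c + 1] += td[s]
        # 6. sanity checks every 100 ms
        if (step + 1) % 1000 == 0:
            ok = True
            for i in range(n):
                if not np.isfinite(v[i]):
                    ok = False
            if not ok:
                return nspk, 2
            # mean network rate (spks/sec) over the last 1000 steps
            window_rate = (nspk - check_last_nspk) / (n * 1000.0 * dt / 1000.0)
            if window_rate > max_rate:
                return nspk, 3
            check_last_nspk = nspk
    return nspk, 0


def run_trial(
    packed: PackedNet,
    model: NetworkModel,
    state: SimState,
    input_times: np.ndarray,
    input_targets: np.ndarray,
    duration: float,
    seed: int,
    plasticity: bool,
    traces: dict | None = None,
    reward_windows: np.ndarray | None = None,
    record_rates: bool = True,
    rate: np.ndarray | None = None,
    rate_h: np.ndarray | None = None,
    record_traces: bool = False,
) -> TrialOutput:
    """Advance the network one trial (or window) with the fused kernel.

    ``input_times``/``input_targets`` are stimulus afferent spikes (ms,
    neuron id); the conduction delay is applied here.  ``reward_windows`` is
    an (n, 2) array of [start, end) times in ms.  Trace state is allocated
    fresh (trial-boundary reset) unless ``traces`` provides the arrays.
    """
    cfg = model.config
    dt = cfg.sim.dt
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    delay_steps = int(round(cfg.synapse.delay / dt))
    if abs(delay_steps * dt - cfg.synapse.delay) > 1e-9:
        raise ValueError("conduction delay must sit on the dt grid")
    noise_steps = max(1, int(round(cfg.noise.update_interval / dt)))
    trace_stride = max(1, int(round(cfg.traces.trace_dt / dt)))
    rec_stride = max(1, int(round(cfg.sim.rate_record_dt / dt)))

    syn = cfg.synapse
    ch_decay = np.exp(-dt / np.array([syn.tau_exc, syn.tau_inh, syn.tau_input, syn.tau_exc]))
    g_sat = np.array([syn.g_sat_exc, syn.g_sat_inh, syn.g_sat_input, syn.g_sat_exc_inh])

    # stimulus arrivals on the step grid, shifted by the conduction delay
    steps = np.round(np.asarray(input_times, dtype=float) / dt).astype(np.int64) + delay_steps
    ok = (steps >= 0) & (steps < n_steps)
    steps = steps[ok]
    tgts = np.asarray(input_targets, dtype=np.int64)[ok]
    order = np.argsort(steps, kind="stable")
    in_step, in_tgt = steps[order], tgts[order]

    nsyn = packed.n_plastic
    if traces is None:
        traces = {
            "tp": np.zeros(nsyn),
            "td": np.zeros(nsyn),
            "trf": np.full(nsyn, -1.0),
            "pending": np.zeros(nsyn),
        }
    if reward_windows is None or len(reward_windows) == 0:
        rw_start = np.empty(0, dtype=np.int64)
        rw_end = np.empty(0, dtype=np.int64)
    else:
        rw = np.asarray(reward_windows, dtype=float)
        if np.any(rw[1:, 0] < rw[:-1, 1]):
            raise ValueError("reward windows overlap")
        rw_start = np.round(rw[:, 0] / dt).astype(np.int64)
        rw_end = np.round(rw[:, 1] / dt).astype(np.int64)

    tr = cfg.traces
    rw_p = cfg.reward
    k_tau_p = np.array([tr.tau_p, tr.tau_ffp])
    k_tau_d = np.array([tr.tau_d, tr.tau_ffd])
    k_eta_p = np.array([tr.eta_p, tr.eta_ffp]) * tr.eta_scale
    k_eta_d = np.array([tr.eta_d, tr.eta_ffd]) * tr.eta_scale
    k_tmax_p = np.array([tr.tmax_p, tr.tmax_ffp])
    k_tmax_d = np.array([tr.tmax_d, tr.tmax_ffd])
    k_rth = np.array([tr.r_th, tr.r_th_ff])
    k_lr = np.array([rw_p.eta, rw_p.eta_ff])
    k_wmax = np.array([rw_p.w_max, rw_p.w_max_ff])

    n_rec = n_steps // rec_stride
    pop_rate_out = np.zeros((max(n_rec, 1), packed.n_pops))
    n_pl_class = int(packed.p_class.max()) + 1 if packed.n_plastic else 1
    class_counts = np.bincount(packed.p_class, minlength=n_pl_class) if packed.n_plastic else np.ones(1, dtype=int)
    trace_rec = np.zeros((max(n_rec, 1) if record_traces else 1, 2 * n_pl_class))
    cap = cfg.sim.spike_buffer
    spk_t = np.empty(cap)
    spk_id = np.empty(cap, dtype=np.int64)
    if rate is None:
        rate = np.zeros(packed.n)
    if rate_h is None:
        rate_h = np.zeros(packed.n)

    neuron = cfg.neuron
    # kernel time is window-local; shift refractory clocks accordingly
    t0 = state.t
    if t0 != 0.0:
        state.ref_until -= t0
    nspk, status = _sim_loop(
        dt, n_steps, delay_steps, noise_steps, trace_stride, rec_stride,
        int(seed) % (2**31),
        state.v, state.g, state.ref_until, rate, rate_h, packed.v_th,
        neuron.c_m, neuron.g_l, neuron.v_rest, neuron.v_reset, neuron.t_ref,
        neuron.e_exc, neuron.e_inh,
        np.exp(-dt / tr.tau_rate), 1000.0 / tr.tau_rate,
        np.exp(-dt / tr.tau_rate_hebb), 1000.0 / tr.tau_rate_hebb,
        cfg.noise.sigma_xi * cfg.noise.xi_gain, ch_decay, g_sat,
        state.x, model.is_exc.astype(np.bool_), syn.u_dep, dt / syn.tau_dep,
        syn.dep_refractory,
        packed.s_ptr, packed.s_tgt, packed.s_w, packed.s_ch,
        packed.p_ptr, packed.p_tgt, packed.p_w, packed.p_kind,
        in_step, in_tgt, float(model.input_w),
        bool(plasticity), packed.p_pre, packed.p_kind,
        traces["tp"], traces["td"], traces["trf"], traces["pending"],
        k_tau_p, k_tau_d, k_eta_p, k_eta_d, k_tmax_p, k_tmax_d, k_rth, k_lr, k_wmax,
        tr.threshold_mode == "each", rw_start, rw_end,
        float(round(rw_p.trace_refractory / dt)),
        packed.pop_of, packed.pop_size, pop_rate_out,
        packed.p_class, n_pl_class, trace_rec, bool(record_traces),
        spk_t, spk_id, cfg.sim.max_rate,
    )
    if status == STATUS_SPIKE_OVERFLOW:
        raise RuntimeError("spike buffer overflow; raise sim.spike_buffer or check for runaway excitation")
    if status == STATUS_NONFINITE:
        raise FloatingPointError("non-finite membrane potential during simulation")
    if status == STATUS_RUNAWAY:
        raise RuntimeError(f"runaway excitation: sustained network rate above {cfg.sim.max_rate} spks/sec")

    if t0 != 0.0:
        state.ref_until += t0
    state.t += duration
    spikes = SpikeRecord(
        times=spk_t[:nspk] + t0,
        ids=spk_id[:nspk].copy(),
        window=(t0, state.t),
        n_neurons=packed.n,
    )
    rate_times = t0 + (np.arange(n_rec) + 1) * rec_stride * dt if record_rates else None
    return TrialOutput(
        state=state,
        spikes=spikes,
        pop_rates=pop_rate_out[:n_rec] if record_rates else None,
        rate_times=rate_times,
        traces_tp=traces["tp"],
        traces_td=traces["td"],
        pending_dw=traces["pending"],
        class_traces=(trace_rec[:n_rec] / np.maximum(class_counts, 1)[None].repeat(2, 0).T.reshape(1, -1))
        if record_traces else None,
        status=status,
    )
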