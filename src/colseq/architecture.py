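"""Construction of the columnar network.

Each of the ``n_columns`` columns holds four populations of ``n_per_pop``
LIF neurons: Timer (T) and Messenger (M) excitatory cells (L5 / L2/3
analogues) and their paired inhibitory populations I_T and I_M.  All
connection classes share the density ``phi``; static weights are drawn
N(mean, sd) and clipped at zero, plastic weights start near zero.

Variants
--------
baseline
    Intra-column T->I_T, T->M, M->I_M, I_T->M and plastic recurrent T->T;
    cross-column inhibition I_T^i->T^j and I_M^i->M^j (i != j); plastic
    feedforward M^i->T^{i+1} only (sequence order hard-wired).
all_to_all
    Baseline plus plastic M^i->T^j for every ordered pair i != j.
local_inhibition
    Inhibition strictly local (I_T^i->T^i, I_M^i->M^i); feedforward
    inhibition replaced by excitatory cross-projections T^i->I_T^j and
    M^i->I_M^j; T^i additionally drives its local I_M^i; stimulus targets
    Timers only.
scaled
    Baseline wiring with larger populations; static weights multiplied by
    sqrt(N/N') and the noise dial halved when N'/N = 4.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import NetworkConfig

__all__ = [
    "ROLES",
    "PopulationSpec",
    "NetworkModel",
    "sample_connections",
    "build_network",
    "scale_static_weights",
    "apply_weight_overrides",
]

# role codes
T, M, IT, IM = 0, 1, 2, 3
ROLES = {"T": T, "M": M, "IT": IT, "IM": IM}
ROLE_NAMES = {v: k for k, v in ROLES.items()}

# conductance channels on the target neuron
CH_EXC, CH_INH, CH_INPUT, CH_EXC_I = 0, 1, 2, 3

KIND_REC, KIND_FF = 0, 1


@dataclass(frozen=True)
class PopulationSpec:
    role: str
    column: int          # 1-based, matching the stimulus element indexing
    size: int
    start: int           # first neuron id

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.size)


@dataclass
class NetworkModel:
    """Populations plus static and plastic connectivity of one instance."""

    config: NetworkConfig
    variant: str
    seed: int
    populations: list[PopulationSpec]
    n_neurons: int
    role: np.ndarray          # per-neuron role code
    column: np.ndarray        # per-neuron column (1-based)
    is_exc: np.ndarray        # bool
    # static connections (COO)
    st_src: np.ndarray
    st_tgt: np.ndarray
    st_w: np.ndarray          # nS, >= 0; sign carried by channel
    st_ch: np.ndarray         # conductance channel at the target
    st_class: np.ndarray      # index into st_class_names
    st_class_names: list[str]
    st_class_means: np.ndarray  # nominal config mean per class, for overrides
    # plastic connections
    pl_pre: np.ndarray
    pl_post: np.ndarray
    pl_w: np.ndarray
    pl_kind: np.ndarray       # KIND_REC or KIND_FF
    pl_class: np.ndarray      # index into pl_class_names
    pl_class_names: list[str]
    # stimulus afferents: mask of neurons that receive an input train when
    # their column is stimulated
    input_mask: np.ndarray
    input_w: float

    def pop(self, role: str, column: int) -> PopulationSpec:
        for p in self.populations:
            if p.role == role and p.column == column:
                return p
        raise KeyError(f"no population {role}^{column}")

    def pop_index(self) -> np.ndarray:
        """Per-neuron population index (column-major, 4 pops per column)."""
        return (self.column - 1) * 4 + self.role

    def plastic_class_mean(self, name: str) -> float:
        idx = self.pl_class_names.index(name)
        mask = self.pl_class == idx
        return float(self.pl_w[mask].mean())

    def copy(self) -> "NetworkModel":
        out = dataclasses.replace(self)
        for f in dataclasses.fields(self):
            v = getattr(out, f.name)
            if isinstance(v, np.ndarray):
                setattr(out, f.name, v.copy())
            elif isinstance(v, list):
                setattr(out, f.name, list(v))
        return out

    def to_edge_list(self) -> pd.DataFrame:
        """Full connectivity as a tidy edge table (CSV-friendly)."""
        delay = self.config.synapse.delay
        frames = [
            pd.DataFrame(
                {
                    "source": self.st_src,
                    "target": self.st_tgt,
                    "weight_ns": self.st_w,
                    "delay_ms": delay,
                    "plastic": False,
                    "klass": [self.st_class_names[i] for i in self.st_class],
                    "inhibitory": self.st_ch == CH_INH,
                }
            ),
            pd.DataFrame(
                {
                    "source": self.pl_pre,
                    "target": self.pl_post,
                    "weight_ns": self.pl_w,
                    "delay_ms": delay,
                    "plastic": True,
                    "klass": [self.pl_class_names[i] for i in self.pl_class],
                    "inhibitory": False,
                }
            ),
        ]
        return pd.concat(frames, ignore_index=True)


def sample_connections(
    n_pre: int,
    n_post: int,
    phi: float,
    rng: np.random.Generator,
    allow_autapse: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli(phi) adjacency between two populations.

    Each ordered (pre, post) pair is connected independently with
    probability ``phi``; the diagonal is excluded when ``allow_autapse`` is
    False (recurrent connections within one population).
    """
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must be a probability")
    mask = rng.random((n_pre, n_post)) < phi
    if not allow_autapse:
        np.fill_diagonal(mask, False)
    pre, post = np.nonzero(mask)
    return pre.astype(np.int64), post.astype(np.int64)


def _draw_static(n: int, mean: float, w, rng: np.random.Generator) -> np.ndarray:
    sd = w.sd * mean if w.sd_mode == "relative" else w.sd
    return np.clip(rng.normal(mean, sd, size=n), 0.0, None)


def build_network(config: NetworkConfig, seed: int) -> NetworkModel:
    """Construct populations and wiring for the configured variant."""
    variant = config.variant
    nc, n = config.n_columns, config.n_per_pop
    rng = np.random.default_rng(seed)
    w = config.weights

    populations = []
    for col in range(1, nc + 1):
        for role_name, role in ROLES.items():
            start = ((col - 1) * 4 + role) * n
            populations.append(PopulationSpec(role_name, col, n, start))
    n_neurons = 4 * nc * n

    role = np.empty(n_neurons, dtype=np.int8)
    column = np.empty(n_neurons, dtype=np.int16)
    for p in populations:
        role[p.start : p.start + p.size] = ROLES[p.role]
        column[p.start : p.start + p.size] = p.column
    is_exc = (role == T) | (role == M)

    def ids(r: int, col: int) -> int:
        # start id of population
        return ((col - 1) * 4 + r) * n

    st_src, st_tgt, st_w, st_ch, st_cls = [], [], [], [], []
    st_names: list[str] = []
    st_means: list[float] = []

    def add_static(r_src: int, c_src: int, r_tgt: int, c_tgt: int, mean: float, ch: int, name: str) -> None:
        pre, post = sample_connections(n, n, config.phi, rng, allow_autapse=True)
        st_src.append(pre + ids(r_src, c_src))
        st_tgt.append(post + ids(r_tgt, c_tgt))
        st_w.append(_draw_static(len(pre), mean, w, rng))
        st_ch.append(np.full(len(pre), ch, dtype=np.int8))
        if name not in st_names:
            st_names.append(name)
            st_means.append(mean)
        st_cls.append(np.full(len(pre), st_names.index(name), dtype=np.int16))

    pl_pre, pl_post, pl_w, pl_kind, pl_cls = [], [], [], [], []
    pl_names: list[str] = []

    def add_plastic(r_src: int, c_src: int, r_tgt: int, c_tgt: int, kind: int, name: str) -> None:
        autapse_ok = not (r_src == r_tgt and c_src == c_tgt)
        pre, post = sample_connections(n, n, config.phi, rng, allow_autapse=autapse_ok)
        pl_pre.append(pre + ids(r_src, c_src))
        pl_post.append(post + ids(r_tgt, c_tgt))
        pl_w.append(rng.uniform(0.0, w.plastic_init_max, size=len(pre)))
        pl_kind.append(np.full(len(pre), kind, dtype=np.int8))
        if name not in pl_names:
            pl_names.append(name)
        pl_cls.append(np.full(len(pre), pl_names.index(name), dtype=np.int16))

    cols = range(1, nc + 1)
    if variant in ("baseline", "all_to_all", "scaled"):
        for i in cols:
            add_plastic(T, i, T, i, KIND_REC, f"T{i}->T{i}")
            add_static(T, i, IT, i, w.t_to_it, CH_EXC_I, "t_to_it")
            add_static(T, i, M, i, w.t_to_m, CH_EXC, "t_to_m")
            add_static(M, i, IM, i, w.m_to_im, CH_EXC_I, "m_to_im")
            add_static(IT, i, M, i, w.it_to_m, CH_INH, "it_to_m")
            for j in cols:
                if j != i:
                    add_static(IT, i, T, j, w.it_to_t, CH_INH, "it_to_t")
                    add_static(IM, i, M, j, w.im_to_m, CH_INH, "im_to_m")
        if variant == "all_to_all":
            for i in cols:
                for j in cols:
                    if j != i:
                        add_plastic(M, i, T, j, KIND_FF, f"M{i}->T{j}")
        else:
            for i in cols:
                if i < nc:
                    add_plastic(M, i, T, i + 1, KIND_FF, f"M{i}->T{i + 1}")
    elif variant == "local_inhibition":
        for i in cols:
            add_plastic(T, i, T, i, KIND_REC, f"T{i}->T{i}")
            add_static(T, i, M, i, w.t_to_m, CH_EXC, "t_to_m")
            add_static(T, i, IM, i, w.t_to_im, CH_EXC_I, "t_to_im")
            add_static(M, i, IM, i, w.m_to_im, CH_EXC_I, "m_to_im")
            add_static(IT, i, T, i, w.it_to_t, CH_INH, "it_to_t")
            add_static(IM, i, M, i, w.im_to_m, CH_INH, "im_to_m")
            for j in cols:
                if j != i:
                    add_static(T, i, IT, j, w.t_to_it, CH_EXC_I, "t_to_it")
                    add_static(M, i, IM, j, w.m_to_im, CH_EXC_I, "m_to_im_cross")
            if i < nc:
                add_plastic(M, i, T, i + 1, KIND_FF, f"M{i}->T{i + 1}")
    else:
        raise ValueError(f"unknown variant {variant!r}")

    # stimulus afferents: Bernoulli(phi) mask over the stimulated populations
    stim_roles = (T,) if variant == "local_inhibition" else (T, IT)
    input_mask = np.zeros(n_neurons, dtype=bool)
    for p in populations:
        if ROLES[p.role] in stim_roles:
            m = rng.random(p.size) < config.stimulus.input_density
            input_mask[p.start : p.start + p.size] = m

    model = NetworkModel(
        config=config,
        variant=variant,
        seed=seed,
        populations=populations,
        n_neurons=n_neurons,
        role=role,
        column=column,
        is_exc=is_exc,
        st_src=np.concatenate(st_src),
        st_tgt=np.concatenate(st_tgt),
        st_w=np.concatenate(st_w),
        st_ch=np.concatenate(st_ch).astype(np.int8),
        st_class=np.concatenate(st_cls),
        st_class_names=st_names,
        st_class_means=np.asarray(st_means, dtype=float),
        pl_pre=np.concatenate(pl_pre),
        pl_post=np.concatenate(pl_post),
        pl_w=np.concatenate(pl_w),
        pl_kind=np.concatenate(pl_kind),
        pl_class=np.concatenate(pl_cls),
        pl_class_names=pl_names,
        input_mask=input_mask,
        input_w=w.w_in,
    )
    if variant == "scaled":
        model = scale_static_weights(model, 100, config.n_per_pop)
    return model


def scale_static_weights(model: NetworkModel, n_ref: int, n_new: int) -> NetworkModel:
    """Rescale static weights for a population size change n_ref -> n_new.

    Every static weight is multiplied by sqrt(n_ref / n_new), keeping the
    input variance constant; when the size grows fourfold the noise dial
    sigma_xi is additionally halved.  Plastic weights are untouched.  The
    returned model carries the rescaling; calling it again with
    ``n_ref == n_new`` is the identity.
    """
    if n_new < n_ref:
        raise ValueError("n_new must be >= n_ref")
    out = model.copy()
    factor = np.sqrt(n_ref / n_new)
    out.st_w = out.st_w * factor
    out.input_w = out.input_w * factor
    if n_new == 4 * n_ref:
        noise = dataclasses.replace(out.config.noise, sigma_xi=out.config.noise.sigma_xi / 2.0)
        out.config = out.config.replace(noise=noise)
    return out


def apply_weight_overrides(
    model: NetworkModel,
    overrides: dict[str, float],
    mode: str = "rescale",
    rng: np.random.Generator | None = None,
) -> NetworkModel:
    """Shift static class means, by percent or to an absolute value.

    ``overrides`` maps a static class name (e.g. ``"t_to_it"``) to either
    ``("pct", delta_percent)`` / a bare float interpreted as a percent delta,
    or ``("abs", new_mean_ns)``.  The special name ``"w_in"`` rescales the
    stimulus weight.  With ``mode="rescale"`` (default) the realized draws
    are multiplied by new_mean/old_mean, preserving the topology and relative
    spread across sweep points; ``mode="redraw"`` redraws from
    N(new_mean, sd) with a fresh clip at zero.
    """
    if mode not in ("rescale", "redraw"):
        raise ValueError("mode must be 'rescale' or 'redraw'")
    out = model.copy()
    wcfg = out.config.weights
    for name, spec in overrides.items():
        if isinstance(spec, tuple):
            how, value = spec
        else:
            how, value = "pct", float(spec)
        if name == "w_in":
            old = out.input_w
            new = old * (1.0 + value / 100.0) if how == "pct" else float(value)
            out.input_w = new
            continue
        if name not in out.st_class_names:
            raise KeyError(f"unknown static class {name!r}")
        idx = out.st_class_names.index(name)
        old = out.st_class_means[idx]
        new = old * (1.0 + value / 100.0) if how == "pct" else float(value)
        mask = out.st_class == idx
        if mode == "rescale":
            if old == 0.0:
                raise ValueError(f"cannot rescale class {name!r} with zero mean")
            out.st_w[mask] = out.st_w[mask] * (new / old)
        else:
            if rng is None:
                rng = np.random.default_rng(out.seed + 1)
            sd = wcfg.sd * new if wcfg.sd_mode == "relative" else wcfg.sd
            out.st_w[mask] = np.clip(rng.normal(new, sd, size=int(mask.sum())), 0.0, None)
        out.st_class_means[idx] = new
    return out
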