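"""Conductance-based LIF network simulation.

Every non-glomerulus cell is a leaky integrate-and-fire point neuron with
exponential conductance synapses:

    C_m dV/dt = -(C_m/tau_m)(V - E_L) + I_e + g_exc (E_exc - V) + g_inh (E_inh - V)

with g_exc, g_inh decaying exponentially (tau_exc, tau_inh per type) and
incremented by |w| on delayed presynaptic spike arrival; the sign of the
table weight selects the channel.  Integration uses exact exponential decay
for the conductances and exponential-Euler for the membrane at a fixed
0.1 ms step; threshold crossings are detected at step boundaries, the spike
is stamped at the end of the step, V is reset to V_r and clamped for the
refractory period.

Glomeruli are parrot relays: their output spike trains equal the imposed
stimulus exactly, so the engine injects those (known) trains directly into
the delayed delivery queue and copies them to the output record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import ScaffoldConfig, LIFParams
from .connectivity import Connectome
from .placement import PlacementTable

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkInstance",
    "SpikeRecord",
    "StimulusSet",
    "assemble",
    "simulate",
    "intrinsic_rate",
]


@dataclass
class SpikeRecord:
    """All spike events of a run: (neuron id, time ms), sorted by time."""

    ids: np.ndarray
    times: np.ndarray
    T: float  # ms

    def __len__(self) -> int:
        return len(self.ids)

    def of(self, neuron_ids) -> np.ndarray:
        """Spike times of one neuron or of a set of neurons (sorted)."""
        mask = np.isin(self.ids, neuron_ids)
        return np.sort(self.times[mask])

    def count_in(self, neuron_ids, t0: float, t1: float) -> int:
        m = np.isin(self.ids, neuron_ids) & (self.times >= t0) & (self.times < t1)
        return int(m.sum())


@dataclass
class StimulusSet:
    """Imposed glomerulus spike trains: parallel arrays of (glom id, time ms)."""

    glom_ids: np.ndarray
    times: np.ndarray
    T: float

    def __post_init__(self):
        order = np.lexsort((self.glom_ids, self.times))
        self.glom_ids = np.asarray(self.glom_ids, dtype=np.int64)[order]
        self.times = np.asarray(self.times, dtype=float)[order]
        if len(self.times) and (self.times.min() < 0 or self.times.max() > self.T):
            raise ValueError("stimulus times outside [0, T]")


class NetworkInstance:
    """Assembled network: per-neuron LIF parameter arrays plus a CSR
    adjacency (by presynaptic *global* cell id) of weighted, delayed,
    channel-routed synapses.

    Weights are held per edge together with their connection-type code so
    protocol manipulations (switch-off, weight overrides) are exact and
    reversible.
    """

    def __init__(self, placement: PlacementTable, cfg: ScaffoldConfig):
        self.cfg = cfg
        self.dt = cfg.sim.dt
        self.E_exc = cfg.sim.E_exc
        self.E_inh = cfg.sim.E_inh
        # local neuron set: every non-parrot cell
        parrot_types = {cfg.neurons[n].type_code
                        for n in cfg.neurons if cfg.neurons[n].is_parrot}
        mask = ~np.isin(placement.type_code, list(parrot_types))
        self.neuron_ids = placement.cell_id[mask]
        n = len(self.neuron_ids)
        n_global = int(placement.cell_id.max()) + 1 if len(placement) else 0
        self.local_of = np.full(n_global, -1, dtype=np.int64)
        self.local_of[self.neuron_ids] = np.arange(n)
        self.glom_ids = placement.ids_of("Glom")
        # per-neuron parameters
        code_to_name = {v: k for k, v in placement.type_names.items()}
        self.type_name = np.array([code_to_name[c]
                                   for c in placement.type_code[mask]])
        def arr(get):
            return np.array([get(cfg.lif[t]) for t in self.type_name])
        self.C_m = arr(lambda p: p.C_m)
        self.g_L = arr(lambda p: p.C_m / p.tau_m)
        self.E_L = arr(lambda p: p.E_L)
        self.I_e = arr(lambda p: p.I_e)
        self.V_r = arr(lambda p: p.V_r)
        self.V_th = arr(lambda p: p.V_th)
        self.ref_steps = np.maximum(
            np.rint(arr(lambda p: p.dt_ref) / self.dt), 1).astype(np.int64)
        self.decay_e = np.exp(-self.dt / arr(lambda p: p.tau_exc))
        self.decay_i = np.exp(-self.dt / arr(lambda p: p.tau_inh))
        # synapse arrays, filled by assemble()
        self.indptr = np.zeros(n_global + 1, dtype=np.int64)
        self.targets = np.empty(0, dtype=np.int64)
        self.weight = np.empty(0)          # effective |w|, nS (0 if off)
        self.base_weight = np.empty(0)     # configured |w|
        self.is_inh = np.empty(0, dtype=bool)
        self.delay_steps = np.empty(0, dtype=np.int64)
        self.conn_code = np.empty(0, dtype=np.int16)
        self.conn_names: list[str] = []
        self._off: set[str] = set()
        self._overrides: dict[str, float] = {}

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_ids)

    @property
    def n_synapses(self) -> int:
        return len(self.targets)

    # -- protocol manipulations ----------------------------------------

    def _refresh_weights(self) -> None:
        w = self.base_weight.copy()
        for name, value in self._overrides.items():
            w[self.conn_code == self.conn_names.index(name)] = abs(value)
        for name in self._off:
            w[self.conn_code == self.conn_names.index(name)] = 0.0
        self.weight = w

    def switch_off(self, names) -> None:
        """Zero the weights of whole connection types (structure kept)."""
        for name in names:
            if name not in self.conn_names:
                raise KeyError(f"unknown connection type {name!r}")
        self._off |= set(names)
        self._refresh_weights()

    def switch_on(self, names=None) -> None:
        """Undo switch_off (all types when names is None)."""
        self._off -= set(self.conn_names if names is None else names)
        self._refresh_weights()

    def override_weight(self, name: str, value: float) -> None:
        if name not in self.conn_names:
            raise KeyError(f"unknown connection type {name!r}")
        self._overrides[name] = value
        self._refresh_weights()

    def clear_overrides(self) -> None:
        self._overrides.clear()
        self._refresh_weights()


def assemble(placement: PlacementTable, connectome: Connectome,
             cfg: ScaffoldConfig) -> NetworkInstance:
    """Bind LIF parameters and synapses to the placed, connected cells.

    One synapse per connectome edge, carrying its connection type's weight
    (absolute value routed to the excitatory or inhibitory channel by sign)
    and delay (rounded to the nearest integration step, minimum one step).
    """
    net = NetworkInstance(placement, cfg)
    pres, posts, codes = [], [], []
    net.conn_names = sorted(connectome.names())
    for code, name in enumerate(net.conn_names):
        edges = connectome[name]
        if len(edges) == 0:
            continue
        pre = edges[:, 0].astype(np.int64)
        post = edges[:, 1].astype(np.int64)
        bad = (pre >= len(net.local_of)) | (post >= len(net.local_of))
        if bad.any() or (net.local_of[post] < 0).any():
            offending = np.flatnonzero(bad | (net.local_of[np.minimum(
                post, len(net.local_of) - 1)] < 0))[:10]
            raise ValueError(
                f"{name}: edges reference ids absent from placement "
                f"(first offending rows {offending.tolist()})")
        pres.append(pre)
        posts.append(post)
        codes.append(np.full(len(pre), code, dtype=np.int16))
    if pres:
        pre = np.concatenate(pres)
        post = np.concatenate(posts)
        code = np.concatenate(codes)
    else:
        pre = post = np.empty(0, dtype=np.int64)
        code = np.empty(0, dtype=np.int16)
    order = np.argsort(pre, kind="stable")
    pre, post, code = pre[order], post[order], code[order]
    n_global = len(net.local_of)
    net.indptr = np.zeros(n_global + 1, dtype=np.int64)
    np.add.at(net.indptr, pre + 1, 1)
    np.cumsum(net.indptr, out=net.indptr)
    net.targets = net.local_of[post]
    w = np.array([cfg.synapses[net.conn_names[c]].weight for c in code])
    d = np.array([cfg.synapses[net.conn_names[c]].delay for c in code])
    net.base_weight = np.abs(w)
    net.is_inh = w < 0
    net.delay_steps = np.maximum(np.rint(d / net.dt), 1).astype(np.int64)
    net.conn_code = code
    net._refresh_weights()
    logger.info("assembled %d neurons, %d synapses",
                net.n_neurons, net.n_synapses)
    return net


def intrinsic_rate(p: LIFParams, dt_ref: float | None = None) -> float:
    """Closed-form firing rate (Hz) of an isolated LIF neuron driven only by
    its constant bias current.

    0 when the asymptotic potential E_L + I_e R stays below threshold, else
    1000 / (dt_ref + tau_m ln((E_L + I_e R - V_r) / (E_L + I_e R - V_th)))
    with R = tau_m / C_m.
    """
    R = p.tau_m / p.C_m
    v_inf = p.E_L + p.I_e * R
    if v_inf <= p.V_th:
        return 0.0
    ref = p.dt_ref if dt_ref is None else dt_ref
    isi = ref + p.tau_m * math.log((v_inf - p.V_r) / (v_inf - p.V_th))
    return 1000.0 / isi


def _gather_edges(indptr, sources):
    """Flat edge indices of the CSR rows in ``sources``."""
    starts = indptr[sources]
    counts = indptr[sources + 1] - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    rep = np.repeat(starts - np.r_[0, np.cumsum(counts)[:-1]], counts)
    return rep + np.arange(total)


def simulate(net: NetworkInstance, stimulus: StimulusSet | None,
             T: float, record: bool = True) -> SpikeRecord:
    """Run the network for ``T`` ms and return the full spike record
    (parrot glomerulus events included verbatim).

    The engine itself is deterministic; all randomness lives in the
    stimulus construction.
    """
    dt = net.dt
    n_steps = int(round(T / dt))
    n = net.n_neurons
    L = int(net.delay_steps.max()) + 1 if net.n_synapses else 2
    ring = np.zeros((L, n, 2))
    V = net.E_L.copy()
    ge = np.zeros(n)
    gi = np.zeros(n)
    ref = np.zeros(n, dtype=np.int64)
    rec_ids: list[np.ndarray] = []
    rec_t: list[np.ndarray] = []

    # imposed glomerulus events, by step
    if stimulus is not None and len(stimulus.times):
        stim_steps = np.minimum((stimulus.times / dt).astype(np.int64),
                                n_steps - 1)
        stim_order = np.argsort(stim_steps, kind="stable")
        stim_steps = stim_steps[stim_order]
        stim_gloms = stimulus.glom_ids[stim_order]
        stim_ptr = 0
        if record:  # parrot relays reproduce the imposed times verbatim
            rec_ids.append(stim_gloms.copy())
            rec_t.append(stimulus.times[stim_order])
    else:
        stim_steps = np.empty(0, dtype=np.int64)
        stim_gloms = np.empty(0, dtype=np.int64)
        stim_ptr = 0

    flat_ring = ring.reshape(-1)
    two_n = 2 * n
    for t in range(n_steps):
        slot = t % L
        arr = ring[slot]
        ge += arr[:, 0]
        gi += arr[:, 1]
        arr[:] = 0.0
        # membrane update (exponential Euler, conductances frozen over dt)
        g_tot = net.g_L + ge + gi
        v_inf = (net.g_L * net.E_L + net.I_e
                 + ge * net.E_exc + gi * net.E_inh) / g_tot
        active = ref == 0
        V = np.where(active,
                     v_inf + (V - v_inf) * np.exp(-dt * g_tot / net.C_m),
                     net.V_r)
        ref = np.maximum(ref - 1, 0)
        ge *= net.decay_e
        gi *= net.decay_i
        spk = active & (V >= net.V_th)
        sources = []
        if spk.any():
            idx = np.flatnonzero(spk)
            if not np.isfinite(V[idx]).all():
                bad = idx[~np.isfinite(V[idx])][0]
                raise FloatingPointError(
                    f"non-finite membrane potential at neuron "
                    f"{net.neuron_ids[bad]}")
            V[idx] = net.V_r[idx]
            ref[idx] = net.ref_steps[idx]
            if record:
                rec_ids.append(net.neuron_ids[idx])
                rec_t.append(np.full(len(idx), (t + 1) * dt))
            sources.append(net.neuron_ids[idx])
        # parrot relays emitting this step
        start = stim_ptr
        while stim_ptr < len(stim_steps) and stim_steps[stim_ptr] == t:
            stim_ptr += 1
        if start < stim_ptr:
            sources.append(stim_gloms[start:stim_ptr])
        if sources:
            src = np.concatenate(sources)
            eidx = _gather_edges(net.indptr, src)
            if len(eidx):
                tgt = net.targets[eidx]
                w = net.weight[eidx]
                chan = net.is_inh[eidx].astype(np.int64)
                slot_arr = (t + net.delay_steps[eidx]) % L
                np.add.at(flat_ring, slot_arr * two_n + tgt * 2 + chan, w)
    if rec_ids:
        ids = np.concatenate(rec_ids)
        times = np.concatenate(rec_t)
        order = np.lexsort((ids, times))
        return SpikeRecord(ids[order], times[order], T)
    return SpikeRecord(np.empty(0, dtype=np.int64), np.empty(0), T)
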