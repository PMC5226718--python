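"""Conductance-based spiking network of the three-choice decision model.

1000 leaky integrate-and-fire neurons in five populations (selective
pools L, R, S; nonspecific excitatory; inhibitory), all-to-all
connected without synaptic delays.  Excitatory synapses carry AMPA
(external and recurrent) and NMDA components, inhibitory synapses
GABA; NMDA channels are voltage-gated by extracellular magnesium and
saturate through an auxiliary rise variable.  Each neuron receives an
independent Poisson external drive aggregated over N_ext sources.

Because connectivity is all-to-all with weights that depend only on
the (presynaptic pool, postsynaptic pool) pair, the recurrent input is
accumulated per pool: the per-step cost is O(N), not O(N^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .params import NetworkSpec, NeuronParams, SynapseParams
from .protocol import StimulationProtocol

__all__ = [
    "Network",
    "SpikeRecord",
    "build_network",
    "nmda_voltage_gate",
    "simulate_trial",
]

POOLS = ("L", "R", "S", "ns", "I")


def nmda_voltage_gate(V: float | np.ndarray, mg_conc: float = 1.0) -> float | np.ndarray:
    """Magnesium-block factor of the NMDA conductance:
    1 / (1 + [Mg2+] exp(-0.062 V) / 3.57)."""
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + mg_conc * np.exp(-0.062 * V) / 3.57)
    return float(out) if out.ndim == 0 else out


@dataclass
class SpikeRecord:
    """Spikes of one trial plus pool membership.

    ``neuron_ids`` and ``times`` (ms) are sorted by time; ``pool_of``
    maps neuron index to pool index in (L, R, S, ns, I) order.
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    pool_of: np.ndarray
    pool_sizes: dict[str, int]
    duration: float
    seed: int | None = None

    @property
    def n_neurons(self) -> int:
        return int(self.pool_of.shape[0])

    def pool_slice(self, pool: str) -> np.ndarray:
        """Boolean mask of spikes emitted by the given pool."""
        p = POOLS.index(pool)
        return self.pool_of[self.neuron_ids] == p

    def write(self, path: str | Path) -> None:
        """Two-column text (neuron_id, time_ms) with a pool-membership
        sidecar ``<path>.pools``."""
        path = Path(path)
        np.savetxt(path, np.column_stack([self.neuron_ids, self.times]),
                   fmt=["%d", "%.3f"], header="neuron_id time_ms")
        sidecar = path.with_suffix(path.suffix + ".pools")
        with open(sidecar, "w") as fh:
            fh.write(f"# duration_ms {self.duration}\n")
            fh.write(f"# seed {self.seed if self.seed is not None else -1}\n")
            for i, p in enumerate(self.pool_of):
                fh.write(f"{i} {POOLS[p]}\n")

    @classmethod
    def read(cls, path: str | Path) -> "SpikeRecord":
        path = Path(path)
        data = np.loadtxt(path, ndmin=2)
        sidecar = path.with_suffix(path.suffix + ".pools")
        duration = 0.0
        seed = None
        pools = []
        with open(sidecar) as fh:
            for line in fh:
                if line.startswith("# duration_ms"):
                    duration = float(line.split()[-1])
                elif line.startswith("# seed"):
                    s = int(line.split()[-1])
                    seed = None if s < 0 else s
                elif line.strip():
                    pools.append(POOLS.index(line.split()[1]))
        pool_of = np.asarray(pools, dtype=np.int64)
        sizes = {p: int(np.sum(pool_of == i)) for i, p in enumerate(POOLS)}
        ids = data[:, 0].astype(np.int64) if data.size else np.empty(0, np.int64)
        times = data[:, 1] if data.size else np.empty(0)
        return cls(neuron_ids=ids, times=times, pool_of=pool_of,
                   pool_sizes=sizes, duration=duration, seed=seed)


@dataclass
class Network:
    """Built network: per-neuron parameter arrays and pool structure."""

    spec: NetworkSpec
    neuron: NeuronParams
    syn: SynapseParams
    pool_of: np.ndarray       # int64 (N,)
    is_exc: np.ndarray        # bool (N,)
    weights: np.ndarray       # (5, 5) pre-pool x post-pool
    C_m: np.ndarray           # nF (N,)
    g_L: np.ndarray           # nS (N,)
    tau_rp: np.ndarray        # ms (N,)
    g_ext: np.ndarray         # nS (N,)
    g_rec: np.ndarray         # nS (N,)
    g_nmda: np.ndarray        # nS (N,)
    g_gaba: np.ndarray        # nS (N,)

    @property
    def pool_sizes(self) -> dict[str, int]:
        return self.spec.pool_sizes


def build_network(
    spec: NetworkSpec | None = None,
    neuron: NeuronParams | None = None,
    syn: SynapseParams | None = None,
) -> Network:
    """Assemble the five-population network.

    Structured weights: w+ within a selective pool, w- from any other
    excitatory pool onto a selective pool, 1 elsewhere; no autapses.
    With ``spec.scale_recurrent`` the recurrent conductances are scaled
    by the reference population sizes (N_E=800, N_I=200) over the
    actual ones, preserving total recurrent drive in reduced networks.
    """
    spec = spec or NetworkSpec()
    neuron = neuron or NeuronParams()
    syn = syn or SynapseParams()

    sizes = [spec.N_sel, spec.N_sel, spec.N_sel, spec.N_ns, spec.N_I]
    pool_of = np.repeat(np.arange(5, dtype=np.int64), sizes)
    N = pool_of.shape[0]
    assert N == spec.N
    is_exc = pool_of < 4

    wp, wm = spec.w_plus, spec.w_minus
    W = np.ones((5, 5))
    for x in range(3):
        for j in range(4):
            W[j, x] = wp if j == x else wm

    exc_scale = 1.0
    inh_scale = 1.0
    if spec.scale_recurrent:
        exc_scale = 800.0 / spec.N_E
        inh_scale = 200.0 / spec.N_I

    def per_neuron(v_exc: float, v_inh: float) -> np.ndarray:
        return np.where(is_exc, v_exc, v_inh)

    return Network(
        spec=spec, neuron=neuron, syn=syn,
        pool_of=pool_of, is_exc=is_exc, weights=W,
        C_m=per_neuron(neuron.C_m_exc, neuron.C_m_inh),
        g_L=per_neuron(neuron.g_L_exc, neuron.g_L_inh),
        tau_rp=per_neuron(neuron.tau_rp_exc, neuron.tau_rp_inh),
        g_ext=per_neuron(syn.g_AMPA_ext_exc, syn.g_AMPA_ext_inh),
        g_rec=per_neuron(syn.g_AMPA_rec_exc, syn.g_AMPA_rec_inh) * exc_scale,
        g_nmda=per_neuron(syn.g_NMDA_exc, syn.g_NMDA_inh) * exc_scale,
        g_gaba=per_neuron(syn.g_GABA_exc, syn.g_GABA_inh) * inh_scale,
    )


@njit(cache=True)
def _run(seed, n_steps, dt,
         pool_of, is_exc, W,
         C_m, g_L, tau_rp, g_ext, g_rec, g_nmda, g_gaba,
         V_L, V_thr, V_reset, V_E, V_I, mg_conc,
         tau_ampa, tau_gaba, tau_rise, tau_decay, alpha,
         ext_rate,  # (n_steps, 5) total aggregated external rate, Hz
         spike_ids, spike_times):
    """Forward-Euler integration of the full network for one trial.

    Gating variables use exact exponential decay between spikes; the
    membrane equation uses forward Euler.  Returns the number of spikes
    recorded (-1 on buffer overflow, -2 on non-finite state).
    """
    np.random.seed(seed)
    N = pool_of.shape[0]

    V = V_L + (V_thr - V_L) * np.random.random(N)
    s_ext = np.zeros(N)
    s_rec = np.zeros(N)
    s_nmda = np.zeros(N)
    x_nmda = np.zeros(N)
    s_gaba = np.zeros(N)
    last_spike = np.full(N, -1e9)

    d_ampa = math.exp(-dt / tau_ampa)
    d_gaba = math.exp(-dt / tau_gaba)
    d_rise = math.exp(-dt / tau_rise)

    # exp(-rate*dt) per pool, refreshed when the step's rates change
    p_zero = np.zeros(5)
    lam_dt = np.zeros(5)
    for p in range(5):
        lam_dt[p] = -1.0

    n_spikes = 0
    cap = spike_ids.shape[0]

    for step in range(n_steps):
        t = step * dt

        # -- decay gating, NMDA saturation ---------------------------------
        for i in range(N):
            s_ext[i] *= d_ampa
            if is_exc[i]:
                s_rec[i] *= d_ampa
                s = s_nmda[i]
                s += dt * (-s / tau_decay + alpha * x_nmda[i] * (1.0 - s))
                s_nmda[i] = s
                x_nmda[i] *= d_rise
            else:
                s_gaba[i] *= d_gaba

        # -- external Poisson input ----------------------------------------
        for p in range(5):
            ld = ext_rate[step, p] * dt * 1e-3
            if ld != lam_dt[p]:
                lam_dt[p] = ld
                p_zero[p] = math.exp(-ld)
        for i in range(N):
            thr = p_zero[pool_of[i]]
            prod = np.random.random()
            while prod > thr:
                s_ext[i] += 1.0
                prod *= np.random.random()

        # -- pool-aggregated recurrent gating ------------------------------
        SA = np.zeros(5)
        SN = np.zeros(5)
        SG = 0.0
        for i in range(N):
            p = pool_of[i]
            if is_exc[i]:
                SA[p] += s_rec[i]
                SN[p] += s_nmda[i]
            else:
                SG += s_gaba[i]

        # -- membrane update, threshold, reset -----------------------------
        for i in range(N):
            if t < last_spike[i] + tau_rp[i]:
                V[i] = V_reset
                continue
            p = pool_of[i]
            da = 0.0
            dn = 0.0
            for q in range(4):
                da += W[q, p] * SA[q]
                dn += W[q, p] * SN[q]
            if is_exc[i]:  # no autapses
                da -= W[p, p] * s_rec[i]
                dn -= W[p, p] * s_nmda[i]
            dg = W[4, p] * SG
            if not is_exc[i]:
                dg -= W[4, 4] * s_gaba[i]

            v = V[i]
            gate = 1.0 / (1.0 + mg_conc * math.exp(-0.062 * v) / 3.57)
            I_syn = (g_ext[i] * (v - V_E) * s_ext[i]
                     + g_rec[i] * (v - V_E) * da
                     + g_nmda[i] * (v - V_E) * gate * dn
                     + g_gaba[i] * (v - V_I) * dg)
            v += dt * 1e-3 * (-g_L[i] * (v - V_L) - I_syn) / C_m[i]
            if not math.isfinite(v):
                return -2

            if v >= V_thr:
                if n_spikes >= cap:
                    return -1
                spike_ids[n_spikes] = i
                spike_times[n_spikes] = t
                n_spikes += 1
                last_spike[i] = t
                v = V_reset
                if is_exc[i]:
                    s_rec[i] += 1.0
                    x_nmda[i] += 1.0
                else:
                    s_gaba[i] += 1.0
            V[i] = v

    return n_spikes


def simulate_trial(
    network: Network,
    protocol: StimulationProtocol,
    seed: int,
    dt: float = 0.05,
) -> SpikeRecord:
    """Integrate one full trial; bit-reproducible for a given seed."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    extra = protocol.rate_table(dt)
    ext_rate = extra + network.spec.nu_ext_total
    n_steps = ext_rate.shape[0]

    cap = max(200_000, int(network.spec.N * protocol.trial_end * 1e-3 * 120))
    spike_ids = np.empty(cap, dtype=np.int64)
    spike_times = np.empty(cap, dtype=np.float64)

    syn, neuron = network.syn, network.neuron
    n = _run(
        seed, n_steps, dt,
        network.pool_of, network.is_exc, network.weights,
        network.C_m, network.g_L, network.tau_rp,
        network.g_ext, network.g_rec, network.g_nmda, network.g_gaba,
        neuron.V_L, neuron.V_thr, neuron.V_reset, syn.V_E, syn.V_I,
        syn.mg_conc,
        syn.tau_AMPA, syn.tau_GABA, syn.tau_NMDA_rise, syn.tau_NMDA_decay,
        syn.alpha,
        np.ascontiguousarray(ext_rate),
        spike_ids, spike_times,
    )
    if n == -1:
        raise RuntimeError("spike buffer overflow; network is runaway-active")
    if n == -2:
        raise FloatingPointError("non-finite membrane potential during integration")

    return SpikeRecord(
        neuron_ids=spike_ids[:n].copy(),
        times=spike_times[:n].copy(),
        pool_of=network.pool_of,
        pool_sizes=network.pool_sizes,
        duration=protocol.trial_end,
        seed=seed,
    )
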