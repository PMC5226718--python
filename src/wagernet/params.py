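"""Model parameters for the three-choice attractor decision network.

All quantities are kept in the units used throughout the package:
mV, ms, nF, nS and Hz.  The default values reproduce the published
parameter table of the conductance-based network (1000 leaky
integrate-and-fire neurons, three selective pools L/R/S, one
nonspecific excitatory pool and one inhibitory pool).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "NetworkSpec",
    "default_neuron_params",
    "default_synapse_params",
    "default_network_spec",
    "load_profile",
    "save_profile",
]

# Excitatory pool order used everywhere: L, R, S, nonspecific.
EXC_POOLS = ("L", "R", "S", "ns")
POOLS = ("L", "R", "S", "ns", "I")


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire cell parameters (per class).

    The membrane leak conductance ``g_L`` is not part of the published
    table; the values used here (25 nS excitatory, 20 nS inhibitory)
    are the standard ones of the model family this network belongs to,
    giving membrane time constants of 20 ms and 10 ms.
    """

    C_m_exc: float = 0.5     # nF
    C_m_inh: float = 0.2     # nF
    g_L_exc: float = 25.0    # nS
    g_L_inh: float = 20.0    # nS
    V_L: float = -70.0       # mV, leak reversal
    V_thr: float = -50.0     # mV, spike threshold
    V_reset: float = -55.0   # mV
    tau_rp_exc: float = 2.0  # ms, refractory period
    tau_rp_inh: float = 1.0  # ms

    def __post_init__(self) -> None:
        if not self.V_reset < self.V_thr:
            raise ValueError("V_reset must be below V_thr")
        if self.C_m_exc <= 0 or self.C_m_inh <= 0:
            raise ValueError("capacitances must be positive")
        if self.tau_rp_exc <= 0 or self.tau_rp_inh <= 0:
            raise ValueError("refractory periods must be positive")

    @property
    def tau_m_exc(self) -> float:
        """Membrane time constant of excitatory cells (ms): C_m/g_L."""
        return self.C_m_exc * 1e3 / self.g_L_exc

    @property
    def tau_m_inh(self) -> float:
        return self.C_m_inh * 1e3 / self.g_L_inh


@dataclass(frozen=True)
class SynapseParams:
    """Conductance-based synapse parameters.

    AMPA and GABA synapses jump instantaneously on a presynaptic spike
    and decay exponentially; NMDA channels rise through an auxiliary
    variable ``x`` and saturate (``alpha * x * (1 - s)``).
    """

    g_AMPA_ext_exc: float = 2.08    # nS
    g_AMPA_ext_inh: float = 1.62
    g_AMPA_rec_exc: float = 0.104
    g_AMPA_rec_inh: float = 0.081
    g_NMDA_exc: float = 0.327
    g_NMDA_inh: float = 0.258
    g_GABA_exc: float = 1.287
    g_GABA_inh: float = 1.002
    tau_AMPA: float = 2.0           # ms
    tau_GABA: float = 10.0
    tau_NMDA_rise: float = 2.0
    tau_NMDA_decay: float = 100.0
    alpha: float = 0.5              # ms^-1, NMDA saturation rate
    V_E: float = 0.0                # mV
    V_I: float = -70.0              # mV
    mg_conc: float = 1.0            # mM

    def __post_init__(self) -> None:
        for name in (
            "g_AMPA_ext_exc", "g_AMPA_ext_inh", "g_AMPA_rec_exc",
            "g_AMPA_rec_inh", "g_NMDA_exc", "g_NMDA_inh",
            "g_GABA_exc", "g_GABA_inh",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_AMPA", "tau_GABA", "tau_NMDA_rise", "tau_NMDA_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.V_I < self.V_E:
            raise ValueError("V_I must be below V_E")


@dataclass(frozen=True)
class NetworkSpec:
    """Population sizes, structured weights and external drive.

    ``w_plus`` strengthens recurrent connections within a selective
    pool; ``w_minus`` weakens excitatory connections from any other
    excitatory pool onto a selective pool; every remaining connection
    has weight 1.  Connectivity is all-to-all without autapses or
    synaptic delays.
    """

    N: int = 1000
    f: float = 0.2                     # selective-pool fraction of N_E
    w_plus: float = 1.500
    w_minus: float = 0.878
    N_ext: int = 800                   # external Poisson sources per neuron
    nu_ext_per_source: float = 3.0     # Hz background per source
    scale_recurrent: bool = False      # rescale recurrent g for reduced N

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        n_e = 0.8 * self.N
        n_sel = self.f * n_e
        if n_sel < 1:
            raise ValueError("selective pools must contain at least one neuron")
        for val, name in ((n_e, "N_E"), (n_sel, "selective pool size"),
                          (0.2 * self.N, "N_I"), (n_e - 3 * n_sel, "nonspecific pool size")):
            if abs(val - round(val)) > 1e-9:
                raise ValueError(f"{name} = {val} is not an integer; choose N, f accordingly")
        if n_e - 3 * n_sel < 1:
            raise ValueError("nonspecific pool must contain at least one neuron")

    @property
    def N_E(self) -> int:
        return round(0.8 * self.N)

    @property
    def N_I(self) -> int:
        return round(0.2 * self.N)

    @property
    def N_sel(self) -> int:
        """Neurons per selective pool (L, R or S)."""
        return round(self.f * self.N_E)

    @property
    def N_ns(self) -> int:
        return self.N_E - 3 * self.N_sel

    @property
    def pool_sizes(self) -> dict[str, int]:
        return {"L": self.N_sel, "R": self.N_sel, "S": self.N_sel,
                "ns": self.N_ns, "I": self.N_I}

    @property
    def nu_ext_total(self) -> float:
        """Aggregated background external rate per neuron (Hz)."""
        return self.N_ext * self.nu_ext_per_source


def default_neuron_params() -> NeuronParams:
    return NeuronParams()


def default_synapse_params() -> SynapseParams:
    return SynapseParams()


def default_network_spec() -> NetworkSpec:
    return NetworkSpec()


_SECTIONS = {"neuron": NeuronParams, "synapse": SynapseParams, "network": NetworkSpec}


def load_profile(path: str | Path) -> dict:
    """Load a network profile from a YAML file.

    The file may contain ``neuron``, ``synapse`` and ``network``
    sections; omitted sections (or keys) fall back to the defaults.
    Unknown keys are rejected so typos do not silently vanish.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown profile sections: {sorted(unknown)}")
    out = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - valid
        if bad:
            raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
        out[name] = cls(**section)
    return out


def save_profile(path: str | Path, neuron: NeuronParams | None = None,
                 synapse: SynapseParams | None = None,
                 network: NetworkSpec | None = None) -> None:
    """Write the (possibly default) profile next to generated outputs."""
    payload = {
        "neuron": dataclasses.asdict(neuron or NeuronParams()),
        "synapse": dataclasses.asdict(synapse or SynapseParams()),
        "network": dataclasses.asdict(network or NetworkSpec()),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
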