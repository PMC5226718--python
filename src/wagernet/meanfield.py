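"""Mean-field reduction of the three-choice attractor network.

The stationary activity of each population is described by a Gaussian
white/coloured-noise approximation of the membrane potential: a mean
``mu_x``, a fluctuation amplitude ``sigma_x`` and an effective membrane
time constant ``tau_x`` determine the population output rate through
the first-passage-time transfer function ``phi``.  Fixed points of the
coupled self-consistency system

    nu_x = phi(mu_x(nu), sigma_x(nu))        for all populations x

are found by integrating the relaxation dynamics

    tau_x dnu_x/dt = -nu_x + phi(mu_x, sigma_x)

with a forward-Euler routine (0.1 ms step).  A fixed point reached by
this flow is operationally stable; the module enumerates attractors
from grids of initial conditions, scans the common stimulus input
``lambda`` for bifurcations, and locates basin boundaries in the
(nu_L, nu_R) plane with a bisection algorithm.

Five populations are tracked: the three selective pools L, R, S, the
nonspecific excitatory pool and the single inhibitory pool, closed
self-consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _mfcore
from ._mfcore import ALPHA_CUTOFF as _ALPHA_CUTOFF_K
from .params import NetworkSpec, NeuronParams, SynapseParams

__all__ = [
    "MeanFieldParams",
    "MeanFieldState",
    "FixedPoint",
    "AttractorLandscape",
    "psi",
    "drives",
    "mu_sigma",
    "transfer",
    "solve_fixed_point",
    "enumerate_attractors",
    "bifurcation_scan",
    "basin_boundary",
    "condition_rates",
    "classify_state",
]

POOLS = ("L", "R", "S", "ns", "I")
N_EXC = 4  # L, R, S, nonspecific

# Gauss-Legendre rule used for the transfer-function integral.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)

# Above this value of the upper integration bound the rate is
# numerically indistinguishable from zero (integrand ~ 2 exp(u^2)).
_ALPHA_CUTOFF = 12.0


@dataclass(frozen=True)
class MeanFieldParams:
    """Derived constants of the reduction, one entry per population.

    Arrays are ordered (L, R, S, ns, I).  ``weights[j, x]`` is the
    structured synaptic weight from population j onto population x;
    ``r`` holds the excitatory population fractions (of N_E).
    """

    r: np.ndarray
    weights: np.ndarray
    g_m: np.ndarray            # nS
    C_m: np.ndarray            # nF
    tau_m: np.ndarray          # ms
    tau_rp: np.ndarray         # ms
    g_ext: np.ndarray          # nS
    T_ext: np.ndarray          # ms
    T_AMPA: np.ndarray         # ms
    T_I: np.ndarray            # ms
    gN_NE_over_gm: np.ndarray  # dimensionless
    tau_AMPA: float
    tau_NMDA: float            # ms, alpha * tau_rise * tau_decay
    tau_NMDA_rise: float
    tau_NMDA_decay: float
    alpha: float
    beta: float                # mV^-1, NMDA voltage-gate steepness
    gamma: float               # [Mg2+]/3.57
    V_E: float
    V_I: float
    V_L: float
    V_thr: float
    V_reset: float
    nu_ext: float              # Hz, aggregated background rate per neuron

    @classmethod
    def from_network(
        cls,
        spec: NetworkSpec | None = None,
        neuron: NeuronParams | None = None,
        syn: SynapseParams | None = None,
    ) -> "MeanFieldParams":
        spec = spec or NetworkSpec()
        neuron = neuron or NeuronParams()
        syn = syn or SynapseParams()

        f = spec.f
        r = np.array([f, f, f, 1.0 - 3.0 * f])

        wp, wm = spec.w_plus, spec.w_minus
        # weights[j, x]: from j onto x.  Selective pools favour
        # themselves (w+), are depressed from every other excitatory
        # pool (w-); all remaining connections are unstructured (1).
        W = np.ones((5, 5))
        for x in range(3):                    # onto L, R, S
            for j in range(N_EXC):            # from excitatory pools
                W[j, x] = wp if j == x else wm

        exc = np.array([True, True, True, True, False])
        g_m = np.where(exc, neuron.g_L_exc, neuron.g_L_inh)
        C_m = np.where(exc, neuron.C_m_exc, neuron.C_m_inh)
        tau_m = C_m * 1e3 / g_m
        tau_rp = np.where(exc, neuron.tau_rp_exc, neuron.tau_rp_inh)
        g_ext = np.where(exc, syn.g_AMPA_ext_exc, syn.g_AMPA_ext_inh)
        g_rec = np.where(exc, syn.g_AMPA_rec_exc, syn.g_AMPA_rec_inh)
        g_nmda = np.where(exc, syn.g_NMDA_exc, syn.g_NMDA_inh)
        g_gaba = np.where(exc, syn.g_GABA_exc, syn.g_GABA_inh)

        return cls(
            r=r,
            weights=W,
            g_m=g_m,
            C_m=C_m,
            tau_m=tau_m,
            tau_rp=tau_rp,
            g_ext=g_ext,
            T_ext=g_ext * syn.tau_AMPA / g_m,
            T_AMPA=g_rec * spec.N_E * syn.tau_AMPA / g_m,
            T_I=g_gaba * spec.N_I * syn.tau_GABA / g_m,
            gN_NE_over_gm=g_nmda * spec.N_E / g_m,
            tau_AMPA=syn.tau_AMPA,
            tau_NMDA=syn.alpha * syn.tau_NMDA_rise * syn.tau_NMDA_decay,
            tau_NMDA_rise=syn.tau_NMDA_rise,
            tau_NMDA_decay=syn.tau_NMDA_decay,
            alpha=syn.alpha,
            beta=0.062,
            gamma=syn.mg_conc / 3.57,
            V_E=syn.V_E,
            V_I=syn.V_I,
            V_L=neuron.V_L,
            V_thr=neuron.V_thr,
            V_reset=neuron.V_reset,
            nu_ext=spec.nu_ext_total,
        )


@dataclass(eq=False)
class MeanFieldState:
    """Rates and derived quantities of all five populations."""

    nu: np.ndarray          # Hz
    mu: np.ndarray          # mV
    sigma: np.ndarray       # mV
    S: np.ndarray           # total effective conductance (units of g_m)
    tau: np.ndarray         # ms
    V_avg: np.ndarray       # mV
    n_AMPA: np.ndarray
    n_NMDA: np.ndarray
    n_GABA: np.ndarray

    def rate(self, pool: str) -> float:
        return float(self.nu[POOLS.index(pool)])


@dataclass(eq=False)
class FixedPoint:
    state: MeanFieldState
    stable: bool
    classification: str
    residual: float
    steps: int

    @property
    def nu(self) -> np.ndarray:
        return self.state.nu


@dataclass
class AttractorLandscape:
    condition: str
    lam: float
    dlam: float
    fixed_points: list[FixedPoint]
    boundaries: dict[str, np.ndarray] = field(default_factory=dict)

    def of_class(self, name: str) -> FixedPoint | None:
        for fp in self.fixed_points:
            if fp.classification == name:
                return fp
        return None

    @property
    def classes(self) -> set[str]:
        return {fp.classification for fp in self.fixed_points}


def _pack(params: MeanFieldParams) -> tuple:
    """Arguments of the numba kernels, in their positional order."""
    return (
        params.r, params.weights, params.g_m, params.C_m, params.tau_m,
        params.tau_rp, params.g_ext, params.T_ext, params.T_AMPA,
        params.T_I, params.gN_NE_over_gm,
        params.tau_AMPA, params.tau_NMDA_rise, params.tau_NMDA_decay,
        params.tau_NMDA, params.alpha, params.beta, params.gamma,
        params.V_E, params.V_I, params.V_L, params.V_thr, params.V_reset,
        params.nu_ext,
    )


# ---------------------------------------------------------------------------
# Elementary pieces of the reduction
# ---------------------------------------------------------------------------

def psi(nu: float | np.ndarray, params: MeanFieldParams) -> float | np.ndarray:
    """Effective stationary NMDA activation for a presynaptic rate.

    Implements the saturating series

        psi(nu) = (nu tau_N / (1 + nu tau_N))
                  * [1 + 1/(1 + nu tau_N) * sum_n (-alpha tau_r)^n T_n / (n+1)!]

    The alternating-binomial coefficient T_n admits the closed product
    form T_n/(n+1)! = 1 / [(n+1) prod_{j=1..n} (x + j)] with
    x = tau_r (1 + nu tau_N) / tau_d, which is what is summed here (the
    naive binomial sum cancels catastrophically in floating point).
    Terms are accumulated to n = 64 with early stop below 1e-12.
    """
    nu_arr = np.atleast_1d(np.asarray(nu, dtype=float)) / 1e3  # Hz -> ms^-1
    out = np.array([
        _mfcore.psi_nb(v, params.tau_NMDA_rise, params.tau_NMDA_decay,
                       params.tau_NMDA, params.alpha)
        for v in nu_arr
    ])
    return out if np.ndim(nu) else float(out[0])


def drives(nu: np.ndarray, params: MeanFieldParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recurrent synaptic drives onto each population.

    AMPA and GABA drives are weighted rate sums (in ms^-1); the NMDA
    drive is the weighted sum of saturated activations psi(nu_j).
    """
    nu_ms = np.asarray(nu, dtype=float) / 1e3
    W = params.weights
    r = params.r
    nu_exc = nu_ms[:N_EXC]
    psi_exc = np.asarray(psi(np.asarray(nu)[:N_EXC], params))
    n_ampa = (r * nu_exc) @ W[:N_EXC]
    n_nmda = (r * psi_exc) @ W[:N_EXC]
    n_gaba = W[4] * nu_ms[4]
    return n_ampa, n_nmda, n_gaba


def mu_sigma(
    nu: np.ndarray,
    V_avg: np.ndarray,
    params: MeanFieldParams,
    lam: np.ndarray | None = None,
) -> MeanFieldState:
    """Evaluate mean and fluctuation of the membrane potential.

    ``lam`` holds the extra external input rate per population (Hz,
    added to the aggregated background drive).  The mean potential is
    the conductance-weighted average of the reversal potentials divided
    by the total effective conductance ``S_x`` (so that with no input
    mu_x = V_L), and ``V_avg`` feeds back through the linearised NMDA
    voltage dependence.
    """
    nu = np.asarray(nu, dtype=float)
    V_avg = np.asarray(V_avg, dtype=float)
    if lam is None:
        lam = np.zeros(5)
    lam = np.asarray(lam, dtype=float)

    n_ampa, n_nmda, n_gaba = drives(nu, params)

    mu = np.zeros(5)
    sigma = np.zeros(5)
    tau = np.zeros(5)
    S = np.zeros(5)
    ok = _mfcore.mf_eval(nu, V_avg, lam, *_pack(params),
                         mu, sigma, tau, S)
    if not ok:
        raise FloatingPointError("total effective conductance S_x <= 0")

    return MeanFieldState(
        nu=nu.copy(), mu=mu, sigma=sigma, S=S, tau=tau,
        V_avg=np.asarray(V_avg, dtype=float).copy(),
        n_AMPA=n_ampa, n_NMDA=n_nmda, n_GABA=n_gaba,
    )


def transfer(
    mu: np.ndarray | float,
    sigma: np.ndarray | float,
    tau_x: np.ndarray | float,
    tau_rp: np.ndarray | float,
    tau_AMPA: float,
    V_thr: float,
    V_reset: float,
) -> np.ndarray | float:
    """First-passage-time population transfer function (rate in Hz).

    phi = [tau_rp + tau_x * sqrt(pi) * int_{beta}^{alpha} erfcx(-u) du]^-1

    with the coloured-noise-corrected bound
    alpha = (V_thr - mu)/sigma * (1 + 0.5 k) + 1.03 sqrt(k) - 0.5 k,
    k = tau_AMPA/tau_x, and beta = (V_reset - mu)/sigma.  The integral
    is evaluated with a fixed Gauss-Legendre rule; far below threshold
    (alpha beyond the cutoff) the rate is indistinguishable from zero.
    """
    scalar = np.ndim(mu) == 0
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    tau_x = np.broadcast_to(np.atleast_1d(np.asarray(tau_x, dtype=float)), mu.shape)
    tau_rp = np.broadcast_to(np.atleast_1d(np.asarray(tau_rp, dtype=float)), mu.shape)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")

    out = np.array([
        _mfcore.transfer_nb(mu[i], sigma[i], tau_x[i], tau_rp[i],
                            tau_AMPA, V_thr, V_reset,
                            _GL_NODES, _GL_WEIGHTS)
        for i in range(mu.shape[0])
    ])
    return float(out[0]) if scalar else out


# Residual drive to the direction pools (Hz) entering the stationary
# conditions, standing in for the slowly decaying target input (the
# targets stay visible throughout a trial).  These are mean-field
# configuration constants, not derived from the spiking protocol: the
# reduction linearizes the network around its stationary states and
# its effective operating point differs from the finite-size spiking
# network's (see docs/methods.md).
TARGET_RESIDUAL_STIMULUS = 3.08
TARGET_RESIDUAL_DELAY = 2.21


def condition_rates(condition: str, lam: float, dlam: float,
                    lam_S: float = 5.0,
                    target_residual: float | None = None) -> np.ndarray:
    """Extra external rates per pool for one stimulation condition.

    ``stimulus``: pools L/R receive lam +/- dlam on top of the residual
    target input; ``delay``: residual target input only; ``sure``: pool
    S additionally receives the sustained sure-target asymptote (5 Hz
    by default).
    """
    rates = np.zeros(5)
    if condition == "stimulus":
        if lam - abs(dlam) < 0:
            raise ValueError("lam - |dlam| must be nonnegative")
        resid = TARGET_RESIDUAL_STIMULUS if target_residual is None else target_residual
        rates[0] = lam + dlam + resid
        rates[1] = lam - dlam + resid
    elif condition == "delay":
        resid = TARGET_RESIDUAL_DELAY if target_residual is None else target_residual
        rates[0] = resid
        rates[1] = resid
    elif condition == "sure":
        resid = TARGET_RESIDUAL_DELAY if target_residual is None else target_residual
        rates[0] = resid
        rates[1] = resid
        rates[2] = lam_S
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return rates


# ---------------------------------------------------------------------------
# Fixed points
# ---------------------------------------------------------------------------

def classify_state(nu: np.ndarray,
                   spont_thr: float = 10.0,
                   decision_thr: float = 20.0,
                   mixed_range: tuple[float, float] = (10.0, 40.0),
                   mixed_gap: float = 2.0) -> str:
    """Label a converged rate vector by its selective-pool pattern."""
    L, R, S = nu[0], nu[1], nu[2]
    sel = np.array([L, R, S])
    if np.all(sel < spont_thr):
        return "spontaneous"
    for idx, name in ((0, "decision_L"), (1, "decision_R"), (2, "decision_S")):
        others = np.delete(sel, idx)
        if sel[idx] > decision_thr and np.all(others < spont_thr):
            return name
    lo, hi = mixed_range
    if lo <= L <= hi and lo <= R <= hi and abs(L - R) < mixed_gap:
        return "mixed"
    return "other"


def solve_fixed_point(
    initial_rates: np.ndarray | list[float],
    params: MeanFieldParams,
    lam: np.ndarray | None = None,
    tol: float = 1e-6,
    dt: float = 0.1,
    max_steps: int = 1_000_000,
) -> FixedPoint:
    """Relax the self-consistency dynamics to a fixed point.

    Integrates tau_x dnu_x/dt = -nu_x + phi(mu_x, sigma_x) with forward
    Euler (default step 0.1 ms) until the largest per-step rate change
    drops below ``tol`` (Hz, quoted at the 0.1 ms reference step and
    rescaled proportionally when ``dt`` changes, so the stopping point
    is a rate-of-change criterion independent of the step size).  The
    population-average potential is updated self-consistently alongside
    the rates.  Non-convergence within ``max_steps`` is flagged
    (possible limit cycle), never silently returned as stable.
    """
    nu = np.asarray(initial_rates, dtype=float).copy()
    if nu.shape != (5,):
        raise ValueError("initial_rates must contain 5 population rates")
    if np.any(nu < 0) or np.any(nu > 1e3 / params.tau_rp + 1e-9):
        raise ValueError("initial rates must lie in [0, 1/tau_rp]")
    if lam is None:
        lam = np.zeros(5)
    lam = np.asarray(lam, dtype=float)

    V_avg = np.full(5, 0.5 * (params.V_thr + params.V_reset))
    state = mu_sigma(nu, V_avg, params, lam)
    V_avg = state.mu - (params.V_thr - params.V_reset) * (nu / 1e3) * state.tau

    nu_out, V_out, steps, status = _mfcore.mf_solve(
        nu, V_avg, lam, *_pack(params), _GL_NODES, _GL_WEIGHTS,
        dt, tol * (dt / 0.1), max_steps)
    if status == -1:
        raise FloatingPointError("mean-field integration diverged")
    converged = status == 1

    state = mu_sigma(nu_out, V_out, params, lam)
    phi = transfer(state.mu, state.sigma, state.tau, params.tau_rp,
                   params.tau_AMPA, params.V_thr, params.V_reset)
    residual = float(np.max(np.abs(nu_out - phi)))
    return FixedPoint(
        state=state,
        stable=converged,
        classification=classify_state(nu_out) if converged else "non_convergent",
        residual=residual,
        steps=int(steps),
    )


# Seeds near each candidate attractor.  Symmetric states (spontaneous,
# mixed) are probed with a small L/R asymmetry: the instability that
# destroys them is transverse to the nu_L = nu_R diagonal, which an
# exactly symmetric relaxation can never detect.
_SEED_PERTURBATION = 0.1  # Hz

_DEFAULT_SEEDS = (
    (3.0 + _SEED_PERTURBATION, 3.0 - _SEED_PERTURBATION, 3.0),   # spontaneous
    (45.0, 2.0, 2.0),                                            # decision L
    (2.0, 45.0, 2.0),                                            # decision R
    (25.0 + _SEED_PERTURBATION, 25.0 - _SEED_PERTURBATION, 2.0),  # mixed
)

# Probed only under the sure-target condition, where an S-dominant
# attractor is part of the landscape of interest.
_S_DOMINANT_SEED = (2.0, 2.0, 45.0)


def enumerate_attractors(
    params: MeanFieldParams,
    lam: float,
    dlam: float = 0.0,
    condition: str = "stimulus",
    init_grid: list[tuple[float, float, float]] | None = None,
    ns_init: float = 3.0,
    inh_init: float = 9.0,
    dedup_tol: float = 0.1,
    **solve_kwargs,
) -> AttractorLandscape:
    """Collect the stable fixed points reachable from a seed grid.

    Two converged states count as the same attractor when every
    population rate agrees within ``dedup_tol`` (0.1 Hz).
    """
    rates = condition_rates(condition, lam, dlam)
    if init_grid is not None:
        seeds = init_grid
    else:
        seeds = list(_DEFAULT_SEEDS)
        if condition == "sure":
            seeds.append(_S_DOMINANT_SEED)

    found: list[FixedPoint] = []
    for (nl, nr, ns_sel) in seeds:
        fp = solve_fixed_point(
            np.array([nl, nr, ns_sel, ns_init, inh_init]),
            params, lam=rates, **solve_kwargs)
        if not fp.stable:
            continue
        if any(np.max(np.abs(fp.nu - g.nu)) < dedup_tol for g in found):
            continue
        found.append(fp)
    return AttractorLandscape(condition=condition, lam=lam, dlam=dlam,
                              fixed_points=found)


def bifurcation_scan(
    params: MeanFieldParams,
    lam_grid: np.ndarray | list[float],
    dlam: float = 0.0,
    condition: str = "stimulus",
    **kwargs,
) -> list[AttractorLandscape]:
    """Enumerate attractors along a grid of the common input lambda.

    Bifurcations show up as grid points where the set of attractor
    classes changes; callers read them off the returned landscapes
    (see :func:`bifurcation_points`).
    """
    return [enumerate_attractors(params, lam, dlam, condition, **kwargs)
            for lam in lam_grid]


def bifurcation_points(scan: list[AttractorLandscape]) -> list[tuple[float, set, set]]:
    """(lambda, classes_before, classes_after) where the set changes."""
    out = []
    for prev, cur in zip(scan, scan[1:]):
        if prev.classes != cur.classes:
            out.append((cur.lam, prev.classes, cur.classes))
    return out


def _same_attractor(fp: FixedPoint, target: FixedPoint, tol: float = 1.0) -> bool:
    return fp.stable and np.max(np.abs(fp.nu - target.nu)) < tol


def basin_boundary(
    params: MeanFieldParams,
    landscape: AttractorLandscape,
    attractor: FixedPoint,
    n_rays: int = 16,
    precision: float = 0.1,
    plane_max: float = 80.0,
    **solve_kwargs,
) -> np.ndarray:
    """Bisect the basin boundary of one attractor in the nu_L-nu_R plane.

    Rays fan out from the attractor's (nu_L, nu_R) position; the
    non-probed pools start at their rates in the attractor.  Along each
    ray the boundary between in-basin and out-of-basin initial points
    is located by bisection to ``precision`` (0.1 Hz).  Rays that never
    leave the basin contribute no point.  Returns an (n, 2) array of
    ordered boundary points.
    """
    if attractor not in landscape.fixed_points:
        raise ValueError("attractor must belong to the landscape")
    rates = condition_rates(landscape.condition, landscape.lam, landscape.dlam)
    base = attractor.nu.copy()
    solve_kwargs.setdefault("max_steps", 400_000)

    def converges_to_attractor(nl: float, nr: float) -> bool:
        init = base.copy()
        init[0], init[1] = nl, nr
        fp = solve_fixed_point(init, params, lam=rates, **solve_kwargs)
        return _same_attractor(fp, attractor)

    points = []
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    for theta in angles:
        d = np.array([math.cos(theta), math.sin(theta)])
        # Farthest point of the ray inside the [0, plane_max]^2 box.
        ts = []
        for i in (0, 1):
            if d[i] > 1e-12:
                ts.append((plane_max - base[i]) / d[i])
            elif d[i] < -1e-12:
                ts.append((0.0 - base[i]) / d[i])
        t_hi = min(ts)
        if t_hi <= 0:
            continue
        if converges_to_attractor(*(base[:2] + t_hi * d)):
            continue  # ray exits the box without leaving the basin
        t_lo = 0.0
        while t_hi - t_lo > precision:
            t_mid = 0.5 * (t_lo + t_hi)
            if converges_to_attractor(*(base[:2] + t_mid * d)):
                t_lo = t_mid
            else:
                t_hi = t_mid
        points.append(base[:2] + 0.5 * (t_lo + t_hi) * d)
    return np.array(points)
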