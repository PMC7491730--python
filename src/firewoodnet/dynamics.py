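"""Coupled pest–social dynamics on a travel network.

Each patch ``i`` carries five state variables:

* ``S_i`` — susceptible host trees, logistic growth to carrying capacity K;
* ``I_i`` — infested trees, dying at rate gamma;
* ``B_i`` — infested firewood present in the patch (same within-patch
  transmission potential as infested trees);
* ``L_i`` — fraction of visitors who buy firewood locally ("local
  strategists"), evolving by replicator dynamics under social learning;
* ``T_i`` — cumulative infestations, the running integral of the infection
  term (damage metric; never decreases).

Per patch::

    dS_i/dt = r S_i (1 - (S_i + I_i)/K) - A S_i (I_i + B_i) theta_k(I_i - I_a)
    dI_i/dt = -gamma I_i + A S_i (I_i + B_i) theta_k(I_i - I_a) - export_i
    dB_i/dt = -gamma B_i + import_i
    dL_i/dt = sigma L_i (1 - L_i) (U + s (2 L_i - 1) + f I_i)
    dT_i/dt = A S_i (I_i + B_i) theta_k(I_i - I_a)

with density-dependent transmission ``theta_k(x) = 1 / (1 + exp(-k x))``
(half-speed at ``I_i = I_a``) and firewood transport::

    export_i = d (1 - C_e) (1 - L_i) I_i * sum_{j != i} P[j, i] * q_ij(t)
    import_i = d (1 - C_e) * sum_{j != i} P[i, j] (1 - L_j) I_j * q_ij(t)

``P[i, j]`` is the fraction of trips leaving patch j that arrive at i, C_e is
the checkpoint interception fraction applied on every route, and ``q_ij(t)``
is a quarantine gate: 1 normally, but an upside-down boxcar (0 inside the
window ``[t0, t0 + delta_t]``) on any route with an endpoint in the
quarantined set V.  With no quarantine active, total import equals total
export: interception removes wood from every route symmetrically, and all
remaining wood leaving a patch arrives somewhere as firewood B.

The replicator equation for L derives from strategy payoffs
``P_l - P_t = U + s (2 L_i - 1) + f I_i``: U is the net social cost of
transporting firewood (the outreach-campaign lever), s the strength of
conformity pressure, and f the behavioural response to visible local
infestation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.special import expit

from .travel_network import TravelNetwork


class DynamicsError(ValueError):
    """Invalid state, parameters, or state/network dimension mismatch."""


@dataclass(frozen=True)
class ModelParams:
    """Scalar model parameters (defaults are the baseline values).

    Units: r, gamma, sigma, d are per year; A is per susceptible-infested
    contact per year; K, Ia are trees; U, f, s are utilities; Ce, k unitless.
    """

    r: float = 0.02
    A: float = 0.001
    gamma: float = 1.4
    K: float = 5000.0
    U: float = 0.0
    Ce: float = 0.0
    f: float = 0.1
    s: float = 0.1
    sigma: float = 0.1
    d: float = 0.1
    Ia: float = 1.0
    k: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r", "A", "gamma", "f", "s", "sigma", "d"):
            if getattr(self, name) < 0:
                raise DynamicsError(f"{name} must be nonnegative")
        if not 0.0 <= self.Ce <= 1.0:
            raise DynamicsError(f"Ce must be in [0, 1], got {self.Ce}")
        if self.K <= 0:
            raise DynamicsError(f"K must be positive, got {self.K}")
        if self.k <= 0:
            raise DynamicsError(f"k must be positive, got {self.k}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ModelParams":
        """Build from a flat config mapping; unknown keys are rejected."""
        valid = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - valid)
        if unknown:
            raise DynamicsError(
                f"unknown parameter names {unknown}; valid names: {sorted(valid)}"
            )
        return cls(**{k: float(v) for k, v in mapping.items()})

    def with_overrides(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


PARAM_NAMES = tuple(f.name for f in fields(ModelParams))


@dataclass
class SystemState:
    """Per-patch state vectors (S, I, B, L, T), all length N."""

    S: np.ndarray
    I: np.ndarray
    B: np.ndarray
    L: np.ndarray
    T: np.ndarray

    VARIABLES = ("S", "I", "B", "L", "T")

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, v), dtype=float) for v in self.VARIABLES]
        n = arrays[0].shape
        if any(a.shape != n or a.ndim != 1 for a in arrays):
            raise DynamicsError("state vectors must be 1-D and of equal length")
        for v, a in zip(self.VARIABLES, arrays):
            setattr(self, v, a)

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def validate(self, tol: float = 0.0) -> None:
        for v in ("S", "I", "B", "T"):
            if np.any(getattr(self, v) < -tol):
                raise DynamicsError(f"{v} has negative components")
        if np.any(self.L < -tol) or np.any(self.L > 1 + tol):
            raise DynamicsError("L components must lie in [0, 1]")

    def pack(self) -> np.ndarray:
        return np.concatenate([getattr(self, v) for v in self.VARIABLES])

    @classmethod
    def unpack(cls, y: np.ndarray, n: int) -> "SystemState":
        return cls(*(y[i * n : (i + 1) * n] for i in range(5)))


@dataclass(frozen=True)
class QuarantinePolicy:
    """Quarantined node set V with activation window [t0, t0 + delta_t].

    Patches in V neither import nor export firewood while the window is
    active.  An empty V means no quarantine.
    """

    nodes: tuple = ()
    t0: float = 0.0
    delta_t: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if self.t0 < 0:
            raise DynamicsError(f"t0 must be >= 0, got {self.t0}")
        if self.delta_t < 0:
            raise DynamicsError(f"delta_t must be >= 0, got {self.delta_t}")

    @property
    def is_empty(self) -> bool:
        return len(self.nodes) == 0 or self.delta_t == 0

    def member_mask(self, network: TravelNetwork) -> np.ndarray:
        mask = np.zeros(network.n, dtype=bool)
        for v in self.nodes:
            mask[network.index_of(v)] = True
        return mask

    def key(self) -> tuple:
        return (tuple(sorted(map(str, self.nodes))), self.t0, self.delta_t)


def sigmoid_theta(x, k: float = 1.0):
    """Density-dependent transmission factor ``1 / (1 + exp(-k x))``."""
    if k <= 0:
        raise DynamicsError(f"sigmoid steepness k must be positive, got {k}")
    return expit(k * np.asarray(x, dtype=float))


def boxcar_off_window(x, delta_t: float):
    """Upside-down boxcar: 0 for ``0 <= x <= delta_t``, 1 outside.

    Acts as the quarantine switch on transport terms, with ``x = t - t0``.
    """
    if delta_t < 0:
        raise DynamicsError(f"delta_t must be >= 0, got {delta_t}")
    x = np.asarray(x, dtype=float)
    inside = (x >= 0) & (x <= delta_t)
    out = np.where(inside, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def utility_difference(L_i, I_i, params: ModelParams):
    """Payoff advantage of buying locally over transporting, P_l - P_t.

    Equals ``U + s (2 L_i - 1) + f I_i``: the net transport cost U, conformity
    with the local majority, and aversion driven by visible infestation.
    """
    L_i = np.asarray(L_i, dtype=float)
    I_i = np.asarray(I_i, dtype=float)
    out = params.U + params.s * (2.0 * L_i - 1.0) + params.f * I_i
    return float(out) if out.ndim == 0 else out


def _route_gate(network, params, policy):
    """Precompute off-diagonal P and the mask of quarantine-gated routes."""
    P0 = network.trip_fraction.copy()
    np.fill_diagonal(P0, 0.0)
    gated = None
    if policy is not None and not policy.is_empty:
        v = policy.member_mask(network)
        gated = v[:, None] | v[None, :]
    return P0, gated


def transport_fluxes(t, state, params, network, quarantine_policy=None):
    """Per-patch firewood import and export rates at time ``t``.

    Returns ``(imports, exports)``; both scale every route by
    ``d (1 - C_e)`` and by the quarantine gate on routes with an endpoint
    in V.  Exposed separately so conservation (sum of imports equals sum of
    exports when no quarantine is active) can be checked directly.
    """
    _check_dims(state, network)
    P0, gated = _route_gate(network, params, quarantine_policy)
    PG = P0
    if gated is not None:
        h = boxcar_off_window(t - quarantine_policy.t0, quarantine_policy.delta_t)
        if h == 0.0:
            PG = np.where(gated, 0.0, P0)
    flow = params.d * (1.0 - params.Ce) * (1.0 - state.L) * state.I
    exports = flow * PG.sum(axis=0)
    imports = PG @ flow
    return imports, exports


def _check_dims(state: SystemState, network: TravelNetwork) -> None:
    if state.n != network.n:
        raise DynamicsError(
            f"state has {state.n} patches but network has {network.n}"
        )


def coupled_rhs(t, state, params, network, quarantine_policy=None):
    """Time derivative of the full coupled system at time ``t``.

    Returns a :class:`SystemState` whose fields hold (dS, dI, dB, dL, dT).
    """
    _check_dims(state, network)
    imports, exports = transport_fluxes(t, state, params, network, quarantine_policy)
    theta = sigmoid_theta(state.I - params.Ia, params.k)
    infection = params.A * state.S * (state.I + state.B) * theta
    dS = params.r * state.S * (1.0 - (state.S + state.I) / params.K) - infection
    dI = -params.gamma * state.I + infection - exports
    dB = -params.gamma * state.B + imports
    dL = (
        params.sigma
        * state.L
        * (1.0 - state.L)
        * utility_difference(state.L, state.I, params)
    )
    dT = infection
    return SystemState(dS, dI, dB, dL, dT)


def make_packed_rhs(network, params, quarantine_policy=None, gate_value=None):
    """Compile a flat-vector RHS ``f(t, y)`` for the ODE integrator.

    Route masks are precomputed once.  If ``gate_value`` is given (0 or 1)
    the quarantine gate is held fixed at that value, which the integrator
    uses to keep each segment between window boundaries smooth.
    """
    n = network.n
    P0, gated = _route_gate(network, params, quarantine_policy)
    P_closed = P0 if gated is None else np.where(gated, 0.0, P0)
    colsum_open = P0.sum(axis=0)
    colsum_closed = P_closed.sum(axis=0)
    d_eff = params.d * (1.0 - params.Ce)
    r, A, gamma, K = params.r, params.A, params.gamma, params.K
    sigma, U, s, f = params.sigma, params.U, params.s, params.f
    Ia, k = params.Ia, params.k
    policy = quarantine_policy

    def rhs(t, y):
        S, I, B, L = y[:n], y[n : 2 * n], y[2 * n : 3 * n], y[3 * n : 4 * n]
        if gated is None:
            PG, colsum = P0, colsum_open
        else:
            h = (
                gate_value
                if gate_value is not None
                else boxcar_off_window(t - policy.t0, policy.delta_t)
            )
            if h == 0.0:
                PG, colsum = P_closed, colsum_closed
            else:
                PG, colsum = P0, colsum_open
        flow = d_eff * (1.0 - L) * I
        theta = expit(k * (I - Ia))
        infection = A * S * (I + B) * theta
        dS = r * S * (1.0 - (S + I) / K) - infection
        dI = -gamma * I + infection - flow * colsum
        dB = -gamma * B + PG @ flow
        dL = sigma * L * (1.0 - L) * (U + s * (2.0 * L - 1.0) + f * I)
        return np.concatenate([dS, dI, dB, dL, infection])

    return rhs
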