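"""Time integration of the coupled system and trajectory summaries.

Integration uses an adaptive stiff-capable solver (LSODA via
``scipy.integrate.solve_ivp``).  Quarantine windows introduce a step
discontinuity in the transport terms, so runs are segmented at the window
boundaries ``t0`` and ``t0 + delta_t`` and the gate is held constant within
each segment — the adaptive stepper never straddles the switch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import (
    DynamicsError,
    ModelParams,
    QuarantinePolicy,
    SystemState,
    make_packed_rhs,
)
from .travel_network import TravelNetwork

#: Sampled components may undershoot zero by at most this much (then clamped).
UNDERSHOOT_TOL = 1e-6


class SolverError(RuntimeError):
    """Adaptive integration failed; carries the failure time."""

    def __init__(self, message: str, failure_time: float):
        super().__init__(f"{message} (at t = {failure_time:g})")
        self.failure_time = failure_time


@dataclass
class InitialConditions:
    """Focal-seed scenario: one heavily infested patch, uniform background.

    ``focal_infested_fraction`` of the focal patch's carrying capacity starts
    infested (default 1: the bulk host population of the seeded urban centre);
    every patch starts with local-strategist fraction ``background_L``
    (default 0.5, the neutral replicator point at U = 0, I = 0) and firewood
    stock ``background_B``.
    """

    focal_node: object = None
    focal_infested_fraction: float = 1.0
    background_L: float = 0.5
    background_B: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.focal_infested_fraction <= 1.0:
            raise DynamicsError("focal_infested_fraction must be in [0, 1]")
        if not 0.0 <= self.background_L <= 1.0:
            raise DynamicsError("background_L must be in [0, 1]")
        if self.background_B < 0:
            raise DynamicsError("background_B must be >= 0")


def build_initial_state(
    network: TravelNetwork,
    initial_conditions: InitialConditions | None = None,
    params: ModelParams | None = None,
) -> SystemState:
    """Construct the seeded initial state.

    Every patch starts at carrying capacity; at the focal node (explicit id,
    else the network's flagged focal node) a fraction of K is moved from S to
    I.  T starts at I so seeded infestations are counted in the cumulative
    damage metric.
    """
    ic = initial_conditions or InitialConditions()
    params = params or ModelParams()
    n = network.n
    S = np.full(n, params.K)
    I = np.zeros(n)
    if ic.focal_infested_fraction > 0:
        focal = ic.focal_node if ic.focal_node is not None else network.focal_node
        if focal is None:
            raise DynamicsError(
                "no focal node: give InitialConditions.focal_node or flag one "
                "in the network metadata"
            )
        i = network.index_of(focal)
        I[i] = ic.focal_infested_fraction * params.K
        S[i] = params.K - I[i]
    B = np.full(n, ic.background_B)
    L = np.full(n, ic.background_L)
    return SystemState(S, I, B, L, I.copy())


@dataclass
class Trajectory:
    """Time-indexed record of all patch states plus provenance.

    ``S, I, B, L, T`` are arrays of shape (n_times, n_patches) aligned with
    ``times`` and ``node_ids``.
    """

    times: np.ndarray
    S: np.ndarray
    I: np.ndarray
    B: np.ndarray
    L: np.ndarray
    T: np.ndarray
    node_ids: list
    provenance: dict = field(default_factory=dict)

    VARIABLES = ("S", "I", "B", "L", "T")

    @property
    def n_patches(self) -> int:
        return len(self.node_ids)

    def state_at(self, index: int) -> SystemState:
        return SystemState(*(getattr(self, v)[index] for v in self.VARIABLES))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per (time, patch)."""
        nt, n = len(self.times), self.n_patches
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "patch_id": np.tile(np.asarray(self.node_ids, dtype=object), nt),
                **{v: getattr(self, v).ravel() for v in self.VARIABLES},
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        times = np.unique(df["time"].to_numpy())
        node_ids = df["patch_id"].iloc[: len(df) // len(times)].tolist()
        n = len(node_ids)
        arrays = {v: df[v].to_numpy().reshape(len(times), n) for v in cls.VARIABLES}
        return cls(times=times, node_ids=node_ids, **arrays)

    def summary(self) -> dict:
        """Compact JSON-ready summary: network averages plus provenance."""
        means = network_averages(self)
        return {
            "times": self.times.tolist(),
            "network_averages": {
                v: means[v].tolist() for v in self.VARIABLES
            },
            "n_patches": self.n_patches,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)


def _sample_times(t_end: float, sample_every: float) -> np.ndarray:
    n = int(np.floor(t_end / sample_every + 1e-9))
    times = np.arange(n + 1) * sample_every
    if times[-1] < t_end - 1e-9 * max(1.0, t_end):
        times = np.append(times, t_end)
    return times


def run_simulation(
    network: TravelNetwork,
    params: ModelParams | None = None,
    quarantine_policy: QuarantinePolicy | None = None,
    initial_conditions: InitialConditions | None = None,
    t_end: float = 20.0,
    sample_every: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "LSODA",
    initial_state: SystemState | None = None,
) -> Trajectory:
    """Integrate the coupled system and sample it on a regular grid.

    The run is split at quarantine-window boundaries so the transport gate is
    constant within every solver segment.  After each segment L is clamped to
    [0, 1] (the replicator form keeps the interval invariant in exact
    arithmetic; this guards float excursions).  Sampled components below
    ``-UNDERSHOOT_TOL`` abort the run; smaller undershoots are clamped to 0.

    ``initial_state`` bypasses the focal-seed construction entirely when a
    fully custom starting state is needed.
    """
    if t_end <= 0:
        raise DynamicsError(f"t_end must be positive, got {t_end}")
    if sample_every <= 0:
        raise DynamicsError(f"sample_every must be positive, got {sample_every}")
    params = params or ModelParams()
    policy = quarantine_policy
    if initial_state is not None:
        if initial_state.n != network.n:
            raise DynamicsError(
                f"initial state has {initial_state.n} patches, network {network.n}"
            )
        initial_state.validate()
        state0 = initial_state
    else:
        state0 = build_initial_state(network, initial_conditions, params)
    n = network.n

    breaks = {0.0, float(t_end)}
    if policy is not None and not policy.is_empty:
        for b in (policy.t0, policy.t0 + policy.delta_t):
            if 0.0 < b < t_end:
                breaks.add(float(b))
    edges = sorted(breaks)

    times = _sample_times(t_end, sample_every)
    y = state0.pack()
    out = np.empty((len(times), 5 * n))
    out[0] = y
    filled = np.zeros(len(times), dtype=bool)
    filled[0] = True

    for a, b in zip(edges[:-1], edges[1:]):
        if policy is not None and not policy.is_empty:
            mid = 0.5 * (a + b)
            gate = 0.0 if policy.t0 <= mid <= policy.t0 + policy.delta_t else 1.0
        else:
            gate = None
        rhs = make_packed_rhs(network, params, policy, gate_value=gate)
        inside = np.flatnonzero((times > a + 1e-12) & (times <= b + 1e-12))
        t_eval = np.unique(np.append(times[inside], b))
        sol = solve_ivp(
            rhs, (a, b), y, method=method, t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            t_fail = float(sol.t[-1]) if sol.t.size else a
            raise SolverError(f"integration failed: {sol.message}", t_fail)
        for idx in inside:
            col = int(np.argmin(np.abs(sol.t - times[idx])))
            out[idx] = sol.y[:, col]
            filled[idx] = True
        y = sol.y[:, -1].copy()
        y[3 * n : 4 * n] = np.clip(y[3 * n : 4 * n], 0.0, 1.0)

    assert filled.all()
    if out.min() < -UNDERSHOOT_TOL:
        t_bad = times[int(np.argmax(out.min(axis=1) < -UNDERSHOOT_TOL))]
        raise SolverError(
            f"state undershot zero by more than {UNDERSHOOT_TOL}", float(t_bad)
        )
    arrays = {}
    for vi, v in enumerate(Trajectory.VARIABLES):
        block = out[:, vi * n : (vi + 1) * n]
        block = np.clip(block, 0.0, 1.0) if v == "L" else np.maximum(block, 0.0)
        arrays[v] = block

    provenance = {
        "params": params.as_dict(),
        "quarantine": None
        if policy is None or not policy.nodes
        else {
            "nodes": [str(v) for v in policy.nodes],
            "t0": policy.t0,
            "delta_t": policy.delta_t,
        },
        "initial_conditions": "custom state"
        if initial_state is not None
        else vars(initial_conditions or InitialConditions()),
        "network_fingerprint": network.fingerprint(),
        "solver": {"method": method, "rtol": rtol, "atol": atol},
        "t_end": t_end,
        "sample_every": sample_every,
    }
    return Trajectory(
        times=times, node_ids=list(network.node_ids), provenance=provenance, **arrays
    )


def network_averages(trajectory: Trajectory) -> pd.DataFrame:
    """Unweighted patch means of every state variable at each sample time."""
    if len(trajectory.times) == 0:
        raise DynamicsError("empty trajectory")
    data = {"time": trajectory.times}
    for v in Trajectory.VARIABLES:
        data[v] = getattr(trajectory, v).mean(axis=1)
    return pd.DataFrame(data)


def infested_patch_count(trajectory: Trajectory, threshold: float = 1.0) -> np.ndarray:
    """Number of patches with at least ``threshold`` infested trees over time."""
    if threshold < 0:
        raise DynamicsError(f"threshold must be >= 0, got {threshold}")
    return (trajectory.I >= threshold).sum(axis=1)
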