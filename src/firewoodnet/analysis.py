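"""Assessment statistics and intervention sweep experiments.

The damage metric throughout is the mean cumulative infested population,
``(1/N) sum_i T_i(t_bar)`` — every tree ever infested up to the evaluation
horizon, averaged over patches.  On top of it the module provides:

* the marginal benefit of outreach: a least-squares slope of the damage
  metric against the net transport cost U over a grid (negative slope means
  raising U helps);
* 2-D parameter sweeps (heatmap surfaces) over any pair of model parameters
  or the horizon itself;
* quarantine sweeps over quarantine size |V| and duration delta_t, with V
  picked by betweenness centrality;
* a bisection search for the interception fraction C_e that halves the
  baseline damage metric.

A :class:`Scenario` bundles the fixed ingredients of an experiment (network,
baseline parameters, seeding, horizon) and caches simulations by parameter
hash so sweep cells sharing a run never re-integrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import DynamicsError, ModelParams, QuarantinePolicy, PARAM_NAMES
from .simulate import InitialConditions, Trajectory, run_simulation
from .travel_network import TravelNetwork, quarantine_node_selection


class AnalysisError(ValueError):
    """Invalid sweep/search request."""


class NonMonotoneMetricError(AnalysisError):
    """The halving search requires a metric nonincreasing in C_e."""


_UNSET = object()


@dataclass
class Scenario:
    """A reusable simulation setup; runs are cached by parameter hash."""

    network: TravelNetwork
    params: ModelParams = field(default_factory=ModelParams)
    initial_conditions: InitialConditions | None = None
    quarantine_policy: QuarantinePolicy | None = None
    t_end: float = 20.0
    sample_every: float = 0.1
    rtol: float = 1e-6
    atol: float = 1e-8
    _cache: dict = field(default_factory=dict, repr=False)

    def run(self, overrides=None, policy=_UNSET, t_end=None) -> Trajectory:
        """Simulate with parameter overrides, reusing cached trajectories."""
        params = self.params.with_overrides(**(overrides or {}))
        pol = self.quarantine_policy if policy is _UNSET else policy
        horizon = self.t_end if t_end is None else float(t_end)
        key = (
            tuple(params.as_dict().items()),
            None if pol is None else pol.key(),
            horizon,
        )
        if key not in self._cache:
            self._cache[key] = run_simulation(
                self.network,
                params,
                quarantine_policy=pol,
                initial_conditions=self.initial_conditions,
                t_end=horizon,
                sample_every=self.sample_every,
                rtol=self.rtol,
                atol=self.atol,
            )
        return self._cache[key]


def mean_cumulative_infestation(trajectory: Trajectory, t_bar: float) -> float:
    """Mean cumulative infested population ``(1/N) sum_i T_i(t_bar)``.

    Linearly interpolated between stored sample times.
    """
    times = trajectory.times
    if not times[0] <= t_bar <= times[-1] + 1e-9:
        raise AnalysisError(
            f"t_bar = {t_bar} outside trajectory span [{times[0]}, {times[-1]}]"
        )
    return float(np.interp(t_bar, times, trajectory.T.mean(axis=1)))


def default_u_grid() -> np.ndarray:
    """11 evenly spaced utility values spanning the explored range [-5, 5]."""
    return np.linspace(-5.0, 5.0, 11)


def marginal_benefit_slope(
    scenario: Scenario,
    U_grid=None,
    t_bar: float = 10.0,
    overrides=None,
    metric=None,
) -> float:
    """Least-squares slope of the damage metric against the utility U.

    Runs the full simulation for every U in the grid, evaluates the mean
    cumulative infestation at ``t_bar``, and fits a line.  A negative slope
    means raising the social cost of transport reduces damage; a positive
    slope means outreach is neutral or detrimental.  ``metric`` may replace
    the simulation-backed evaluation (signature ``metric(U) -> float``).
    """
    grid = np.asarray(default_u_grid() if U_grid is None else U_grid, dtype=float)
    if grid.size < 2 or np.unique(grid).size < 2:
        raise AnalysisError("U_grid needs at least 2 distinct values")
    if metric is None:
        def metric(u):
            traj = scenario.run(
                {**(overrides or {}), "U": float(u)},
                t_end=max(scenario.t_end, t_bar),
            )
            return mean_cumulative_infestation(traj, t_bar)
    values = np.array([metric(u) for u in grid])
    slope, _ = np.polyfit(grid, values, 1)
    return float(slope)


@dataclass
class SweepResult:
    """Metric surface over a 2-D parameter grid, with provenance."""

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    metric_name: str
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis1_values = np.asarray(self.axis1_values, dtype=float)
        self.axis2_values = np.asarray(self.axis2_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.axis1_values.size, self.axis2_values.size):
            raise AnalysisError("sweep matrix shape does not match axis lengths")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values,
            index=pd.Index(self.axis1_values, name=self.axis1_name),
            columns=pd.Index(self.axis2_values, name=self.axis2_name),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def plot_heatmap(self, path=None, ax=None):
        """Render the surface as a heatmap (requires matplotlib)."""
        import matplotlib

        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(
            self.axis2_values, self.axis1_values, self.values, shading="nearest"
        )
        ax.set_xlabel(self.axis2_name)
        ax.set_ylabel(self.axis1_name)
        ax.figure.colorbar(mesh, ax=ax, label=self.metric_name)
        if path is not None:
            ax.figure.savefig(path, dpi=150)
            plt.close(ax.figure)
        return ax


VALID_AXES = PARAM_NAMES + ("t_bar",)
METRICS = ("mean_cumulative_infestation", "marginal_benefit_slope")


def parameter_sweep_2d(
    scenario: Scenario,
    axis1,
    axis2,
    metric: str = "mean_cumulative_infestation",
    t_bar: float = 10.0,
    U_grid=None,
) -> SweepResult:
    """Evaluate a metric over the Cartesian grid of two parameter axes.

    Each axis is ``(name, values)`` where name is a model parameter or
    ``"t_bar"`` (the evaluation horizon).  Cells are independent: the result
    does not depend on evaluation order, and repeated sweeps with identical
    inputs are bit-identical.
    """
    (name1, vals1), (name2, vals2) = axis1, axis2
    for name in (name1, name2):
        if name not in VALID_AXES:
            raise AnalysisError(
                f"invalid axis {name!r}; valid axes: {list(VALID_AXES)}"
            )
    if metric not in METRICS:
        raise AnalysisError(f"invalid metric {metric!r}; valid: {list(METRICS)}")
    if metric == "marginal_benefit_slope" and "U" in (name1, name2):
        raise AnalysisError("U cannot be a sweep axis for the slope metric")
    vals1 = np.atleast_1d(np.asarray(vals1, dtype=float))
    vals2 = np.atleast_1d(np.asarray(vals2, dtype=float))
    if vals1.size == 0 or vals2.size == 0:
        raise AnalysisError("sweep axes must be nonempty")

    M = np.empty((vals1.size, vals2.size))
    for i, a in enumerate(vals1):
        for j, b in enumerate(vals2):
            over, tb = {}, t_bar
            for name, val in ((name1, a), (name2, b)):
                if name == "t_bar":
                    tb = float(val)
                else:
                    over[name] = float(val)
            if metric == "mean_cumulative_infestation":
                traj = scenario.run(over, t_end=max(scenario.t_end, tb))
                M[i, j] = mean_cumulative_infestation(traj, tb)
            else:
                M[i, j] = marginal_benefit_slope(
                    scenario, U_grid=U_grid, t_bar=tb, overrides=over
                )
    return SweepResult(
        axis1_name=name1,
        axis1_values=vals1,
        axis2_name=name2,
        axis2_values=vals2,
        metric_name=metric,
        values=M,
        provenance={
            "t_bar": t_bar,
            "params": scenario.params.as_dict(),
            "network_fingerprint": scenario.network.fingerprint(),
        },
    )


@dataclass(frozen=True)
class HalvingResult:
    """Smallest interception fraction halving the baseline damage metric."""

    Ce: float
    attained: bool
    baseline: float
    achieved: float

    def __float__(self) -> float:
        return self.Ce


def halving_interception_fraction(
    scenario: Scenario,
    t_bar: float = 5.0,
    tol: float = 0.005,
    metric=None,
) -> HalvingResult:
    """Bisect for the C_e that halves the mean cumulative infestation.

    Searches ``C_e in [0, 1]`` for the smallest interception fraction whose
    damage metric at ``t_bar`` is at most half the uncontrolled (C_e = 0)
    value.  The metric must be nonincreasing in C_e (it is, in this model:
    every transport term scales by ``1 - C_e``); a violation beyond 0.1%
    raises :class:`NonMonotoneMetricError`.  If even full interception cannot
    halve the damage, returns ``Ce = 1.0`` flagged ``attained=False``.
    """
    if metric is None:
        def metric(ce):
            traj = scenario.run({"Ce": float(ce)}, t_end=max(scenario.t_end, t_bar))
            return mean_cumulative_infestation(traj, t_bar)
    m0 = metric(0.0)
    if m0 <= 0:
        raise AnalysisError("baseline metric at Ce = 0 must be positive")
    m_half = metric(0.5)
    m1 = metric(1.0)
    slack = 1e-3 * m0
    if m_half > m0 + slack or m1 > m_half + slack:
        raise NonMonotoneMetricError(
            "damage metric is not nonincreasing in Ce "
            f"(M(0)={m0:.6g}, M(0.5)={m_half:.6g}, M(1)={m1:.6g})"
        )
    target = 0.5 * m0
    if m1 > target:
        warnings.warn(
            "halving unattainable even at full interception", stacklevel=2
        )
        return HalvingResult(1.0, False, m0, m1)
    # invariant: metric(lo) > target >= metric(hi)
    if m_half <= target:
        lo, hi, m_hi = 0.0, 0.5, m_half
    else:
        lo, hi, m_hi = 0.5, 1.0, m1
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        m_mid = metric(mid)
        if m_mid <= target:
            hi, m_hi = mid, m_mid
        else:
            lo = mid
    return HalvingResult(float(hi), True, m0, float(m_hi))


def quarantine_sweep(
    scenario: Scenario,
    V_sizes,
    delta_t_values,
    t0: float = 1.0,
    t_bar_list=(5.0, 10.0, 15.0),
) -> dict:
    """Damage surfaces over quarantine size |V| and duration delta_t.

    For each size the quarantined set is the top-|V| betweenness-centrality
    nodes.  Returns ``{t_bar: SweepResult}``, one surface per horizon; a
    single simulation per (|V|, delta_t) cell serves all horizons.
    """
    V_sizes = [int(v) for v in V_sizes]
    delta_t_values = [float(dt) for dt in delta_t_values]
    if t0 < 0:
        raise AnalysisError(f"t0 must be >= 0, got {t0}")
    for size in V_sizes:
        if not 0 <= size <= scenario.network.n:
            raise AnalysisError(
                f"|V| = {size} exceeds network size {scenario.network.n}"
            )
    horizon = max(max(t_bar_list), scenario.t_end)
    surfaces = {
        tb: np.empty((len(V_sizes), len(delta_t_values))) for tb in t_bar_list
    }
    for i, size in enumerate(V_sizes):
        V = quarantine_node_selection(scenario.network, size)
        for j, dt in enumerate(delta_t_values):
            policy = (
                None
                if size == 0 or dt == 0
                else QuarantinePolicy(nodes=tuple(V), t0=t0, delta_t=dt)
            )
            traj = scenario.run(policy=policy, t_end=horizon)
            for tb in t_bar_list:
                surfaces[tb][i, j] = mean_cumulative_infestation(traj, tb)
    prov = {
        "t0": t0,
        "params": scenario.params.as_dict(),
        "network_fingerprint": scenario.network.fingerprint(),
    }
    return {
        tb: SweepResult(
            axis1_name="V_size",
            axis1_values=np.asarray(V_sizes, dtype=float),
            axis2_name="delta_t",
            axis2_values=np.asarray(delta_t_values, dtype=float),
            metric_name=f"mean_cumulative_infestation(t={tb})",
            values=surfaces[tb],
            provenance=dict(prov, t_bar=tb),
        )
        for tb in t_bar_list
    }
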