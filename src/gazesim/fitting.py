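"""Grid-search fitting of the three free parameters.

The fit measure is the mean squared error between the start and end points
of the regression lines summarizing simulated and measured learning curves
(anticipatory-window Eyes-Mouth scores over trials).  The grid search
simulates a full experiment at every (beta, gamma, theta) combination of
predefined value lists and records the MSE; the optimum is the grid point
minimizing it, with lexicographic tie-breaking (lowest beta, then gamma,
then theta).

One pseudo-random uniform schedule, derived from the protocol's master
seed, is shared by every grid point (common random numbers), so MSE
differences across the grid reflect the parameters rather than sampling
noise, and results are independent of evaluation order.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import experiment_endpoints, mse_endpoints
from .core import Params
from .simulator import Protocol, experiment_uniforms, simulate_experiment

#: Default parameter value lists explored by the grid search.
DEFAULT_BETA = (0.1, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_GAMMA = (0.1, 0.5, 1.0, 1.5, 2.0)
DEFAULT_THETA = (0.0, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class ParameterGrid:
    """Value lists for beta, gamma and theta."""

    beta_values: tuple = DEFAULT_BETA
    gamma_values: tuple = DEFAULT_GAMMA
    theta_values: tuple = DEFAULT_THETA

    def __post_init__(self):
        for name, values, lo, hi in (
            ("beta", self.beta_values, 0.0, np.inf),
            ("gamma", self.gamma_values, 0.0, np.inf),
            ("theta", self.theta_values, 0.0, 1.0),
        ):
            arr = tuple(float(v) for v in values)
            if not arr:
                raise ValueError(f"{name}_values must be non-empty")
            if any(b <= a for a, b in zip(arr, arr[1:])):
                raise ValueError(f"{name}_values must be strictly increasing")
            if arr[0] < lo or arr[-1] > hi:
                raise ValueError(f"{name}_values outside [{lo}, {hi}]")
            object.__setattr__(self, f"{name}_values", arr)

    def __len__(self) -> int:
        return (
            len(self.beta_values) * len(self.gamma_values) * len(self.theta_values)
        )

    def points(self):
        """Grid points in canonical order (beta outermost, theta innermost)."""
        return itertools.product(
            self.beta_values, self.gamma_values, self.theta_values
        )

    @classmethod
    def from_json(cls, path) -> "ParameterGrid":
        data = json.loads(Path(path).read_text())
        return cls(
            beta_values=tuple(data.get("beta", DEFAULT_BETA)),
            gamma_values=tuple(data.get("gamma", DEFAULT_GAMMA)),
            theta_values=tuple(data.get("theta", DEFAULT_THETA)),
        )


@dataclass(frozen=True)
class FitResult:
    """Grid-search outcome: the full MSE surface and its minimizer."""

    table: pd.DataFrame
    best_params: Params
    best_mse: float
    grid: ParameterGrid
    conditions: tuple

    def best_endpoints(self) -> dict:
        row = self.table[
            (self.table["beta"] == self.best_params.beta)
            & (self.table["gamma"] == self.best_params.gamma)
            & (self.table["theta"] == self.best_params.theta)
        ].iloc[0]
        return {
            cond: (row[f"start_{cond}"], row[f"end_{cond}"])
            for cond in self.conditions
        }


def grid_search(
    data_endpoints: dict,
    grid: ParameterGrid,
    protocol: Protocol,
    streams: dict,
    window: str = "anticipatory",
    baseline: str = "none",
) -> FitResult:
    """Evaluate the MSE at every grid point and locate the minimum.

    ``data_endpoints`` maps condition labels to the measured
    :class:`~gazesim.analysis.EndpointSummary`; its conditions must match
    the protocol's.  By default both sides of the comparison summarize the
    *raw* group-mean preference series (``baseline="none"``): the series
    level carries most of the information about theta, which baseline
    correction removes by construction.  Pass ``baseline="participant"`` or
    ``"group"`` to fit corrected learning curves instead — the data
    endpoints must then be computed the same way.
    """
    from .analysis import ComparisonError

    if set(data_endpoints) != set(protocol.conditions):
        raise ComparisonError(
            f"data conditions {sorted(data_endpoints)} do not match protocol "
            f"conditions {sorted(protocol.conditions)}"
        )
    uniforms = experiment_uniforms(protocol)
    rows = []
    best = None
    for beta, gamma, theta in grid.points():
        params = replace(protocol.params, beta=beta, gamma=gamma, theta=theta)
        result = simulate_experiment(protocol, streams, uniforms=uniforms,
                                     params=params)
        sim_ep = experiment_endpoints(result, window=window, baseline=baseline)
        mse = mse_endpoints(sim_ep, data_endpoints)
        row = {"beta": beta, "gamma": gamma, "theta": theta, "mse": mse}
        for cond, ep in sim_ep.items():
            row[f"start_{cond}"] = ep.start
            row[f"end_{cond}"] = ep.end
        rows.append(row)
        if best is None or mse < best[0]:
            best = (mse, params)
    table = pd.DataFrame(rows)
    return FitResult(
        table=table,
        best_params=best[1],
        best_mse=float(best[0]),
        grid=grid,
        conditions=tuple(sorted(protocol.conditions)),
    )


def export_fit_surface(result: FitResult) -> pd.DataFrame:
    """Long-format fit surface sorted by (beta, gamma, theta).

    Emits a "no sensitivity" warning when every grid point has the same MSE.
    """
    table = result.table.sort_values(["beta", "gamma", "theta"]).reset_index(drop=True)
    if np.ptp(table["mse"].to_numpy()) == 0:
        warnings.warn("flat fit surface: no sensitivity to the parameters")
    return table


def best_params_from_surface(table: pd.DataFrame) -> Params:
    """Re-derive the optimal parameters from an exported surface table."""
    ordered = table.sort_values(["mse", "beta", "gamma", "theta"], kind="stable")
    row = ordered.iloc[0]
    return Params(beta=float(row["beta"]), gamma=float(row["gamma"]),
                  theta=float(row["theta"]))


def fit_diagnostics(result: FitResult, tolerance: float = 0.10) -> dict:
    """Sensitivity, robustness and smoothness of the fit surface.

    sensitivity
        Ratio of the maximum to the minimum MSE over the grid (1 = flat).
    robustness_region_size
        Number of grid points in the connected lattice region (6-neighbor
        adjacency in grid-index space) around the minimizer whose MSE is
        within ``tolerance`` of the best (relative), and the region itself.
    smoothness
        Mean absolute MSE difference between adjacent grid points.
    """
    grid = result.grid
    nb, ng, nt = (len(grid.beta_values), len(grid.gamma_values),
                  len(grid.theta_values))
    mse = np.empty((nb, ng, nt))
    table = result.table.set_index(["beta", "gamma", "theta"])["mse"]
    for i, b in enumerate(grid.beta_values):
        for j, g in enumerate(grid.gamma_values):
            for k, t in enumerate(grid.theta_values):
                mse[i, j, k] = table.loc[(b, g, t)]
    best = mse.min()
    # sensitivity
    sensitivity = float(mse.max() / best) if best > 0 else np.inf
    if np.ptp(mse) == 0:
        sensitivity = 1.0
    # robustness: flood fill from the argmin over points within tolerance
    within = mse <= best * (1.0 + tolerance) + 1e-15
    seed = np.unravel_index(np.argmin(mse), mse.shape)
    region = {seed}
    frontier = [seed]
    while frontier:
        i, j, k = frontier.pop()
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < nb and 0 <= nj < ng and 0 <= nk < nt:
                if within[ni, nj, nk] and (ni, nj, nk) not in region:
                    region.add((ni, nj, nk))
                    frontier.append((ni, nj, nk))
    # smoothness: mean |difference| over all lattice edges
    diffs = []
    for axis in range(3):
        diffs.append(np.abs(np.diff(mse, axis=axis)).ravel())
    smoothness = float(np.concatenate(diffs).mean()) if any(
        d.size for d in diffs) else 0.0
    return {
        "sensitivity": sensitivity,
        "robustness_region_size": len(region),
        "robustness_region": sorted(region),
        "smoothness": smoothness,
        "best_mse": float(best),
    }
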