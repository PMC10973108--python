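"""Grid-search fitting: recover known generating parameters.

Generates a synthetic behavioral dataset at (beta=2, gamma=1, theta=0.25)
with one random seed, then fits the model with a different seed over a
reduced grid, and prints the recovered optimum and fit diagnostics.
"""

from gazesim import Params, Protocol, simulate_experiment
from gazesim.analysis import experiment_endpoints
from gazesim.fitting import ParameterGrid, fit_diagnostics, grid_search
from gazesim.synth import protocol_streams

gen = Params(beta=2.0, gamma=1.0, theta=0.25)
data_protocol = Protocol(master_seed=123, params=gen)
data_endpoints = experiment_endpoints(
    simulate_experiment(data_protocol, protocol_streams(data_protocol)),
    baseline="none",
)

grid = ParameterGrid(beta_values=(0.5, 1.0, 2.0, 3.0, 5.0),
                     gamma_values=(0.5, 1.0, 1.5, 2.0),
                     theta_values=(0.0, 0.1, 0.25, 0.5, 1.0))
fit_protocol = Protocol(master_seed=456)
result = grid_search(data_endpoints, grid, fit_protocol,
                     protocol_streams(fit_protocol))

bp = result.best_params
print(f"generating point: beta={gen.beta} gamma={gen.gamma} theta={gen.theta}")
print(f"recovered optimum: beta={bp.beta} gamma={bp.gamma} theta={bp.theta} "
      f"(mse={result.best_mse:.6f} over {len(grid)} grid points)")
diag = fit_diagnostics(result)
print(f"fit surface: sensitivity={diag['sensitivity']:.1f}, "
      f"{diag['robustness_region_size']} grid points within 10% of the "
      f"minimum, smoothness={diag['smoothness']:.5f}")

print("\nThe minimum of the MSE surface sits at (or next to) the generating")
print("parameters. Sensitivity is max/min error over the grid (1 would mean")
print("a flat, uninformative surface); the robustness region counts grid")
print("points within 10% of the minimum (tight here because the minimum is")
print("near zero); smoothness is the mean error step between neighbors.")
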