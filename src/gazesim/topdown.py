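"""Top-down component: task knowledge and anticipatory learning.

The base task knowledge is a fixed preference for the communicative zones of
a talking face: probability .45 each for Eyes and Mouth, .05 each for the
rest of the face and elsewhere.  In the eyebrow-raise condition the model
additionally expresses the *result* of learning that a visual event recurs
in the eyes region at the end of every sentence: with T prior exposures the
unnormalized Eyes mass grows to (beta * T + 1) * 0.45, and this learned
preference switches on at t_a = t_ER - gamma * T, i.e. increasingly *before*
the event as exposures accumulate.  beta is thus the strength and gamma the
speed of anticipatory learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import N_ZONES, ParameterError, Params, Role, ZoneDistribution, normalize

#: Base zone preferences (Eyes, Mouth, RoF, Other).
BASE_PRIORS = (0.45, 0.45, 0.05, 0.05)


@dataclass(frozen=True)
class TopDownConfig:
    """Configuration of the top-down component.

    ``learning_enabled`` is true only for the eyebrow-raise condition: the
    lip-protrusion event happens in the mouth region, which the base priors
    already favor, so no learned redistribution is modeled there.

    ``count_first_trial`` selects the alternative exposure convention
    T = trial index (instead of the default T = trial index - 1, under which
    the first trial shows neither learning nor anticipation).  It exists for
    sensitivity checks only.
    """

    base_priors: tuple = BASE_PRIORS
    learning_enabled: bool = True
    count_first_trial: bool = False

    def __post_init__(self):
        arr = np.asarray(self.base_priors, dtype=float)
        if arr.shape != (N_ZONES,) or np.any(arr < 0) or abs(arr.sum() - 1) > 1e-9:
            raise ParameterError("base_priors must be 4 non-negative values summing to 1")
        object.__setattr__(self, "base_priors", tuple(float(x) for x in arr))

    def exposures(self, trial: int) -> int:
        """Number of prior exposures to the event at a 1-based trial index."""
        return trial if self.count_first_trial else trial - 1

    def prior_distribution(self) -> ZoneDistribution:
        return ZoneDistribution(np.asarray(self.base_priors), Role.TOP_DOWN)


def learned_eyes_mass(beta: float, exposures: int, base: float = BASE_PRIORS[0]) -> float:
    """Unnormalized Eyes mass after learning: ``(beta * exposures + 1) * base``.

    The result is a mass, not a probability — it may exceed 1 and is
    renormalized against the other zones' base masses downstream.
    """
    if beta < 0:
        raise ParameterError(f"beta must be >= 0, got {beta}")
    if exposures < 0:
        raise ParameterError(f"exposures must be >= 0, got {exposures}")
    return (beta * exposures + 1.0) * base


def anticipation_onset(t_er: float, gamma: float, exposures: int) -> float:
    """Time step at which the learned Eyes preference switches on.

    ``t_a = max(0, t_er - gamma * exposures)``: with gamma = 0 the switch
    coincides with the event onset (no anticipation); larger gamma moves it
    earlier by gamma steps per exposure, floored at the trial start.
    """
    if gamma < 0:
        raise ParameterError(f"gamma must be >= 0, got {gamma}")
    if exposures < 0:
        raise ParameterError(f"exposures must be >= 0, got {exposures}")
    return max(0.0, t_er - gamma * exposures)


def top_down_distribution(
    t: float,
    trial: int,
    config: TopDownConfig,
    params: Params,
    t_er: float,
) -> ZoneDistribution:
    """Top-down zone distribution at time step ``t`` of a 1-based ``trial``.

    Before the anticipation onset (or whenever learning is disabled) this is
    the base priors; from the onset on, the Eyes mass is replaced by the
    learned mass and the vector renormalized.
    """
    if not config.learning_enabled:
        return config.prior_distribution()
    exposures = config.exposures(trial)
    if exposures <= 0:
        return config.prior_distribution()
    if t < anticipation_onset(t_er, params.gamma, exposures):
        return config.prior_distribution()
    masses = np.asarray(config.base_priors, dtype=float).copy()
    masses[0] = learned_eyes_mass(params.beta, exposures, config.base_priors[0])
    return normalize(masses, Role.TOP_DOWN)


def top_down_table(
    n_trials: int,
    n_steps: int,
    t_er: float,
    config: TopDownConfig,
    params: Params,
) -> np.ndarray:
    """Precomputed top-down probabilities, shape (n_trials, n_steps, 4).

    Row ``[T-1, t]`` equals :func:`top_down_distribution` at trial T, step t;
    used by the vectorized simulator.
    """
    base = np.asarray(BASE_PRIORS if config is None else config.base_priors)
    table = np.broadcast_to(base, (n_trials, n_steps, N_ZONES)).copy()
    if not config.learning_enabled:
        return table
    for trial in range(1, n_trials + 1):
        exposures = config.exposures(trial)
        if exposures <= 0:
            continue
        onset = anticipation_onset(t_er, params.gamma, exposures)
        start = int(np.ceil(onset))
        if start >= n_steps:
            continue
        masses = base.copy()
        masses[0] = learned_eyes_mass(params.beta, exposures, base[0])
        table[trial - 1, start:] = masses / masses.sum()
    return table
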