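"""Selection-history (memory) component.

A belief over which zones were recently visually processed, maintained as a
discrete Bayesian filter: a dilution step (the temporal model — a small,
symmetric leak toward the uniform resting state) followed by an observation
step (the viewed zone gains probability).  The belief tracks zones to
*avoid*; the inversion operator (1 - b_i) / (z - 1) converts it into a
distribution over zones to *visit*, so recently visited zones become less
attractive (inhibition of return at the zone level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    N_ZONES,
    NORM_TOL,
    ParameterError,
    Role,
    Zone,
    ZoneDistribution,
    _as_probs,
)


@dataclass(frozen=True)
class MemoryState:
    """Normalized belief over recently visited zones."""

    belief: np.ndarray

    def __post_init__(self):
        arr = _as_probs(self.belief)
        if np.any(arr < 0):
            raise ValueError("belief entries must be non-negative")
        total = arr.sum()
        if abs(total - 1.0) > NORM_TOL:
            raise ValueError(f"belief sums to {total}, not 1")
        arr = arr / total
        arr.flags.writeable = False
        object.__setattr__(self, "belief", arr)

    @classmethod
    def uniform(cls) -> "MemoryState":
        return cls(np.full(N_ZONES, 1.0 / N_ZONES))


# Array-level kernels shared with the vectorized simulator. They operate on
# arrays whose last axis has length 4 and assume validated parameters.

def dilute_array(belief: np.ndarray, epsilon: float) -> np.ndarray:
    # M b with M = (1-3e) I + e (1 - I)  ==  (1 - 4e) b + e  (row sums kept at 1)
    return belief * (1.0 - N_ZONES * epsilon) + epsilon


def observe_array(belief: np.ndarray, viewed: np.ndarray, p_hit: float) -> np.ndarray:
    miss = (1.0 - p_hit) / (N_ZONES - 1)
    lik = np.full(belief.shape, miss)
    np.put_along_axis(lik, np.asarray(viewed)[..., None], p_hit, axis=-1)
    post = belief * lik
    return post / post.sum(axis=-1, keepdims=True)


def invert_array(belief: np.ndarray) -> np.ndarray:
    return (1.0 - belief) / (N_ZONES - 1)


def dilute(state: MemoryState, epsilon: float) -> MemoryState:
    """One step of memory decay toward the uniform resting state.

    Applies the symmetric transition matrix with off-diagonal entries
    ``epsilon`` and diagonal ``1 - 3 * epsilon``.
    """
    if not 0.0 < epsilon < 1.0 / N_ZONES:
        raise ParameterError(f"epsilon must be in (0, {1.0 / N_ZONES}), got {epsilon}")
    return MemoryState(dilute_array(state.belief, epsilon))


def observe(state: MemoryState, viewed: Zone, p_hit: float) -> MemoryState:
    """Bayes update of the belief with the currently viewed zone.

    The observation model puts probability ``p_hit`` on the viewed zone and
    spreads the remainder evenly over the other three zones.
    """
    if not 1.0 / N_ZONES < p_hit <= 1.0:
        raise ParameterError(f"p_hit must be in ({1.0 / N_ZONES}, 1], got {p_hit}")
    return MemoryState(observe_array(state.belief, np.array(int(viewed)), p_hit))


def invert(state: MemoryState) -> ZoneDistribution:
    """Map the visited-zones belief to a zones-to-visit distribution.

    Entry i is ``(1 - belief_i) / (z - 1)``, which sums to one automatically
    and reverses the order of the belief: the more recently a zone was
    visited, the less attractive it becomes.
    """
    return ZoneDistribution(invert_array(state.belief), Role.MEMORY_INVERTED)


def filter_step(
    state: MemoryState, viewed: Zone, epsilon: float, p_hit: float
) -> MemoryState:
    """Full filter update: dilute, then observe the viewed zone."""
    return observe(dilute(state, epsilon), viewed, p_hit)
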