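"""Shared domain types.

The visual scene is partitioned into four areas of interest (AOIs) of a
talking face: the eyes, the mouth, the rest of the face (RoF) and everything
else (Other).  Every component of the attention model emits a probability
distribution over these four zones, stating how attractive each zone is to
the eye at the current instant.  This module holds the zone vocabulary, the
normalized probability vector over zones, the model parameters, and the two
elementary probability-vector operations (normalization and multiplicative
fusion) that everything else builds on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Number of zones; the model is defined for exactly four.
N_ZONES = 4

#: Normalization tolerance accepted on construction.
NORM_TOL = 1e-9

ZONE_LABELS = ("Eyes", "Mouth", "RoF", "Other")


class Zone(enum.IntEnum):
    """The four areas of interest, in canonical order."""

    EYES = 0
    MOUTH = 1
    ROF = 2
    OTHER = 3

    @property
    def label(self) -> str:
        return ZONE_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Zone":
        try:
            return cls(ZONE_LABELS.index(label))
        except ValueError:
            raise ValueError(f"unknown zone label {label!r}") from None


class Role(str, enum.Enum):
    """Provenance tag of a zone distribution within the model."""

    BOTTOM_UP = "bottom_up"
    TOP_DOWN = "top_down"
    MEMORY_INVERTED = "memory_inverted"
    FUSED = "fused"
    HISTORY = "history"


class InvalidMassError(ValueError):
    """Raised when a mass vector is all-zero or contains negative entries."""


class DegenerateFusionError(ValueError):
    """Raised when fused distributions have disjoint supports."""


class ParameterError(ValueError):
    """Raised when a model parameter is outside its domain."""


def _as_probs(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_ZONES,):
        raise ValueError(f"expected {N_ZONES} entries, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ZoneDistribution:
    """A normalized probability vector over the four zones.

    Probabilities are stored in linear space: with only four zones the
    magnitudes involved never underflow.  Vectors are defensively
    re-normalized on construction (the accepted input tolerance is 1e-9).
    """

    probs: np.ndarray
    role: Role = Role.FUSED

    def __post_init__(self):
        arr = _as_probs(self.probs)
        if np.any(arr < 0):
            raise InvalidMassError("probabilities must be non-negative")
        total = arr.sum()
        if abs(total - 1.0) > NORM_TOL:
            raise ValueError(f"probabilities sum to {total}, not 1")
        arr = arr / total
        arr.flags.writeable = False
        object.__setattr__(self, "probs", arr)
        object.__setattr__(self, "role", Role(self.role))

    def __getitem__(self, zone) -> float:
        return float(self.probs[int(zone)])

    def as_dict(self) -> dict:
        return {label: float(p) for label, p in zip(ZONE_LABELS, self.probs)}

    @classmethod
    def uniform(cls, role: Role = Role.FUSED) -> "ZoneDistribution":
        return cls(np.full(N_ZONES, 1.0 / N_ZONES), role)


@dataclass(frozen=True)
class InferenceSettings:
    """Fixed states of the three coherence variables used during inference.

    The memory connector is opened (0, yielding the inversion mechanism)
    while the bottom-up and top-down connectors are closed (1, yielding
    multiplicative fusion).  Any other configuration is rejected: the model's
    inference equations are derived for exactly this setting.
    """

    lambda_ij: int = 0
    lambda_bu: int = 1
    lambda_td: int = 1

    def __post_init__(self):
        if (self.lambda_ij, self.lambda_bu, self.lambda_td) != (0, 1, 1):
            raise ParameterError(
                "inference requires lambda_ij=0, lambda_bu=1, lambda_td=1"
            )


@dataclass(frozen=True)
class Params:
    """Free and fixed parameters of the attention model.

    beta
        Strength of top-down learning (>= 0): scales how fast the learned
        preference for the event zone grows with exposures.
    gamma
        Speed of anticipation (>= 0), in normalized time steps advanced per
        trial of exposure.
    theta
        Weight of the static saliency map in the bottom-up mixture, in [0, 1];
        1 - theta weights the motion map.
    epsilon
        Memory dilution leak per step, in (0, 1/4): per-step probability mass
        leaking from each zone of the selection history to each other zone.
    p_hit
        Observation-model probability assigned to the currently viewed zone,
        in (1/4, 1]; the remaining mass is spread over the other zones.
    """

    beta: float = 1.0
    gamma: float = 1.0
    theta: float = 0.5
    epsilon: float = 0.05
    p_hit: float = 0.9

    def __post_init__(self):
        if self.beta < 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            raise ParameterError(f"gamma must be >= 0, got {self.gamma}")
        if not 0.0 <= self.theta <= 1.0:
            raise ParameterError(f"theta must be in [0, 1], got {self.theta}")
        if not 0.0 < self.epsilon < 1.0 / N_ZONES:
            raise ParameterError(
                f"epsilon must be in (0, {1.0 / N_ZONES}), got {self.epsilon}"
            )
        if not 1.0 / N_ZONES < self.p_hit <= 1.0:
            raise ParameterError(
                f"p_hit must be in ({1.0 / N_ZONES}, 1], got {self.p_hit}"
            )


def normalize(masses, role: Role = Role.FUSED) -> ZoneDistribution:
    """Divide non-negative masses by their sum.

    Raises :class:`InvalidMassError` on all-zero or negative input.
    """
    arr = _as_probs(masses)
    if np.any(arr < 0):
        raise InvalidMassError("masses must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise InvalidMassError("masses must not be all zero")
    return ZoneDistribution(arr / total, role)


def distribution_product(
    a: ZoneDistribution, b: ZoneDistribution, c: ZoneDistribution
) -> ZoneDistribution:
    """Multiplicative fusion of three zone distributions.

    Elementwise product of the three probability vectors, re-normalized;
    this is how closed coherence connectors combine the component votes.
    Commutative in its arguments.  Raises
    :class:`DegenerateFusionError` when the supports are disjoint (the
    product is identically zero).
    """
    prod = a.probs * b.probs * c.probs
    total = prod.sum()
    if total <= 0:
        raise DegenerateFusionError("fused distributions have disjoint supports")
    return ZoneDistribution(prod / total, Role.FUSED)
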