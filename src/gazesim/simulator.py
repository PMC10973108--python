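"""Gaze-trajectory simulation.

At each normalized time step the three components each vote with a zone
distribution — top-down task knowledge, bottom-up saliency of the current
frame, and the inverted selection-history belief — and the fused
(multiplicative) distribution is sampled to obtain the next eye position.
The memory belief then assimilates the newly drawn position (dilute, then
observe), so that at step t it summarizes positions X^0..X^t.

Time is discretized into normalized steps: by default 100 steps per Speech
Event and 100 per Non-speech Event (1% of each event per step), aligning
trials whose real durations differ.  A trial starts with the eye on the
Eyes zone and a uniform memory belief; trials are independent (memory does
not carry over across the inter-trial attention-getter).

Experiments are simulated with one pseudo-random stream per (condition,
participant, trial), derived deterministically from the protocol's master
seed, so results are bit-reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    N_ZONES,
    Params,
    Role,
    Zone,
    ZoneDistribution,
    distribution_product,
)
from .memory import (
    MemoryState,
    dilute_array,
    invert_array,
    observe_array,
)
from .saliency import AOISaliencyStream, bottom_up_distribution, bottom_up_table
from .topdown import TopDownConfig, top_down_distribution, top_down_table

CONDITIONS = ("ER", "LP")
_COND_CODE = {"ER": 0, "LP": 1}


class ProtocolError(ValueError):
    """Raised on inconsistent protocol / stream configurations."""


@dataclass(frozen=True)
class TrialTimeline:
    """Discretized, normalized time axis of one trial.

    ``t_er`` (the Non-speech Event onset) equals ``n_speech_steps``; the
    anticipatory analysis window is the last 50% of the Speech Event,
    ``[n_speech_steps // 2, n_speech_steps)``, and the detection window is
    the whole Non-speech Event, ``[t_er, n_steps)``.
    """

    n_speech_steps: int = 100
    n_nonspeech_steps: int = 100
    condition: str = "ER"
    trial: int = 1
    speech_duration_ms: float = 1800.0
    nonspeech_duration_ms: float = 1880.0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ProtocolError(f"unknown condition {self.condition!r}")
        if self.n_speech_steps < 2 or self.n_nonspeech_steps < 1:
            raise ProtocolError("timeline too short")

    @property
    def t_er(self) -> int:
        return self.n_speech_steps

    @property
    def n_steps(self) -> int:
        return self.n_speech_steps + self.n_nonspeech_steps

    @property
    def anticipatory_window(self) -> range:
        return range(self.n_speech_steps // 2, self.n_speech_steps)

    @property
    def detection_window(self) -> range:
        return range(self.t_er, self.n_steps)

    def window(self, name: str) -> range:
        if name == "anticipatory":
            return self.anticipatory_window
        if name == "detection":
            return self.detection_window
        raise ValueError(f"unknown window {name!r}")


@dataclass(frozen=True)
class GazeState:
    """Current eye position plus the memory belief that produced it."""

    position: Zone
    memory: MemoryState


@dataclass(frozen=True)
class Trajectory:
    """Zone visited at each time step of one trial (zones[0] is X^0)."""

    zones: np.ndarray
    trial: int
    condition: str
    participant_id: str = "sim"
    seed: int | None = None

    def __post_init__(self):
        arr = np.asarray(self.zones, dtype=np.int8)
        arr.flags.writeable = False
        object.__setattr__(self, "zones", arr)

    def __len__(self) -> int:
        return len(self.zones)


@dataclass(frozen=True)
class Protocol:
    """Experiment design: conditions, trials, virtual participants, seeds."""

    n_trials: int = 19
    conditions: tuple = CONDITIONS
    n_virtual_participants: int = 20
    params: Params = field(default_factory=Params)
    master_seed: int = 0
    timeline: TrialTimeline = field(default_factory=TrialTimeline)

    def __post_init__(self):
        if self.n_trials < 2:
            raise ProtocolError("need >= 2 trials (trial 1 is the baseline)")
        conds = tuple(self.conditions)
        for c in conds:
            if c not in CONDITIONS:
                raise ProtocolError(f"unknown condition {c!r}")
        object.__setattr__(self, "conditions", conds)

    def td_config(self, condition: str) -> TopDownConfig:
        """Learning is enabled only in the eyebrow-raise condition."""
        return TopDownConfig(learning_enabled=(condition == "ER"))


@dataclass(frozen=True)
class ExperimentResult:
    """Simulated zone trajectories per condition.

    ``zones[cond]`` has shape (n_participants, n_trials, n_steps) with
    integer zone indices.
    """

    zones: dict
    protocol: Protocol

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: participant, condition, trial, step, zone."""
        rows = []
        for cond, arr in self.zones.items():
            n_pp, n_trials, n_steps = arr.shape
            pp, tr, st = np.meshgrid(
                np.arange(n_pp), np.arange(1, n_trials + 1),
                np.arange(n_steps), indexing="ij",
            )
            rows.append(pd.DataFrame({
                "participant": [f"{cond}{i:02d}" for i in pp.ravel()],
                "condition": cond,
                "trial": tr.ravel(),
                "step": st.ravel(),
                "zone": arr.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)


def fused_distribution(
    state: GazeState,
    saliency_step,
    t: int,
    timeline: TrialTimeline,
    params: Params,
    td_config: TopDownConfig,
) -> ZoneDistribution:
    """Fused zone distribution at step ``t`` given the current gaze state.

    The memory factor is the inversion of the dilute-then-observe posterior
    of ``state.memory`` given ``state.position``; it multiplies the top-down
    and bottom-up distributions, renormalized.
    """
    static_means, dynamic_means = saliency_step
    td = top_down_distribution(t, timeline.trial, td_config, params, timeline.t_er)
    bu = bottom_up_distribution(static_means, dynamic_means, params.theta)
    posterior = observe_array(
        dilute_array(state.memory.belief, params.epsilon),
        np.array(int(state.position)),
        params.p_hit,
    )
    mem = ZoneDistribution(invert_array(posterior), Role.MEMORY_INVERTED)
    return distribution_product(td, bu, mem)


def draw_next_position(dist: ZoneDistribution, rng: np.random.Generator) -> Zone:
    """Sample one zone from a fused distribution."""
    u = rng.random()
    cum = np.cumsum(dist.probs)
    cum[-1] = 1.0
    return Zone(int(np.searchsorted(cum, u, side="right")))


def _run_batch(
    td_table: np.ndarray,
    bu_table: np.ndarray,
    uniforms: np.ndarray,
    params: Params,
) -> np.ndarray:
    """Simulate a batch of independent trials sharing saliency input.

    td_table: (n_trials, n_steps, 4) top-down probabilities.
    bu_table: (n_steps, 4) bottom-up probabilities.
    uniforms: (n_pp, n_trials, n_steps) pre-drawn uniform variates; column t
        drives the draw of X^t (column 0 is unused, X^0 being fixed to Eyes).

    Returns zone indices, shape (n_pp, n_trials, n_steps).
    """
    n_pp, n_trials, n_steps = uniforms.shape
    if td_table.shape != (n_trials, n_steps, N_ZONES):
        raise ProtocolError(
            f"top-down table shape {td_table.shape} does not match "
            f"(n_trials={n_trials}, n_steps={n_steps})"
        )
    if bu_table.shape != (n_steps, N_ZONES):
        raise ProtocolError(
            f"saliency stream length {bu_table.shape[0]} does not match "
            f"timeline steps {n_steps}"
        )
    eps, p_hit = params.epsilon, params.p_hit
    zones = np.empty((n_pp, n_trials, n_steps), dtype=np.int8)
    zones[:, :, 0] = int(Zone.EYES)
    x = np.zeros((n_pp, n_trials), dtype=np.int64)
    belief = np.full((n_pp, n_trials, N_ZONES), 1.0 / N_ZONES)
    belief = observe_array(dilute_array(belief, eps), x, p_hit)
    for t in range(1, n_steps):
        # distributions of step t-1 generate X^t (one-step-ahead draw)
        fused = td_table[None, :, t - 1, :] * bu_table[t - 1] * invert_array(belief)
        fused /= fused.sum(axis=-1, keepdims=True)
        cum = np.cumsum(fused, axis=-1)
        cum[..., -1] = 1.0
        x = (uniforms[:, :, t, None] >= cum).sum(axis=-1)
        zones[:, :, t] = x
        belief = observe_array(dilute_array(belief, eps), x, p_hit)
    return zones


def trial_seed(master_seed: int, condition: str, participant: int, trial: int):
    """Deterministic, platform-stable seed words for one trial's RNG stream."""
    return np.random.SeedSequence(
        (int(master_seed), _COND_CODE[condition], int(participant), int(trial))
    )


def experiment_uniforms(protocol: Protocol) -> dict:
    """Pre-drawn uniforms per condition, shape (n_pp, n_trials, n_steps).

    Drawing these once and reusing them across parameter settings implements
    common random numbers: fit-measure differences between settings then
    reflect the parameters, not fresh sampling noise.
    """
    n_steps = protocol.timeline.n_steps
    out = {}
    for cond in protocol.conditions:
        arr = np.empty(
            (protocol.n_virtual_participants, protocol.n_trials, n_steps)
        )
        for p in range(protocol.n_virtual_participants):
            for tr in range(1, protocol.n_trials + 1):
                rng = np.random.Generator(np.random.PCG64(
                    trial_seed(protocol.master_seed, cond, p, tr)
                ))
                arr[p, tr - 1] = rng.random(n_steps)
        out[cond] = arr
    return out


def simulate_trial(
    timeline: TrialTimeline,
    saliency: AOISaliencyStream,
    params: Params,
    td_config: TopDownConfig,
    rng: np.random.Generator,
    participant_id: str = "sim",
) -> Trajectory:
    """Simulate a single trial and return its zone sequence.

    X^0 is the Eyes zone and the memory belief starts uniform; each step
    fuses the three components, draws the next position, and assimilates it
    into the memory.
    """
    if len(saliency) != timeline.n_steps:
        raise ProtocolError(
            f"saliency stream length {len(saliency)} != timeline steps "
            f"{timeline.n_steps}"
        )
    td = top_down_table(
        timeline.trial, timeline.n_steps, timeline.t_er, td_config, params
    )[timeline.trial - 1][None, :, :]
    bu = bottom_up_table(saliency, params.theta)
    uniforms = rng.random(timeline.n_steps)[None, None, :]
    zones = _run_batch(td, bu, uniforms, params)[0, 0]
    return Trajectory(zones, timeline.trial, timeline.condition, participant_id)


def simulate_experiment(
    protocol: Protocol,
    streams: dict,
    uniforms: dict | None = None,
    params: Params | None = None,
) -> ExperimentResult:
    """Simulate every condition x virtual participant x trial of a protocol.

    ``streams`` maps condition labels to :class:`AOISaliencyStream` objects
    (one per condition, replayed on every trial).  ``uniforms`` optionally
    supplies pre-drawn variates from :func:`experiment_uniforms`; ``params``
    optionally overrides ``protocol.params`` (used by the grid search, which
    pairs one uniform draw with many parameter settings).
    """
    params = protocol.params if params is None else params
    for cond in protocol.conditions:
        if cond not in streams:
            raise ProtocolError(f"no saliency stream for condition {cond!r}")
    if uniforms is None:
        uniforms = experiment_uniforms(protocol)
    tl = protocol.timeline
    zones = {}
    for cond in protocol.conditions:
        stream = streams[cond]
        if len(stream) != tl.n_steps:
            raise ProtocolError(
                f"stream for {cond} has {len(stream)} steps, timeline has "
                f"{tl.n_steps}"
            )
        td = top_down_table(
            protocol.n_trials, tl.n_steps, tl.t_er, protocol.td_config(cond), params
        )
        bu = bottom_up_table(stream, params.theta)
        zones[cond] = _run_batch(td, bu, uniforms[cond], params)
    return ExperimentResult(zones, replace(protocol, params=params))
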