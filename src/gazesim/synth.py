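"""Synthetic stimuli and behavioral datasets.

The original stimuli are videos of a speaker producing a short sentence
(Speech Event, mean 1800 ms) followed by either an eyebrow raise (ER) or a
lip protrusion (LP; both 1880 ms), shown at 25 frames/s; the infant gaze
recordings are not redistributable.  This module emulates both so that the
whole pipeline is testable without downloads:

* schematic talking-face frames — a geometric face with permanently
  high-contrast eye blobs (the sclera/pupil contrast that makes real eyes
  statically salient), an oscillating mouth during the Speech Event, and
  condition-appropriate motion (eyebrow region for ER, mouth for LP) during
  the Non-speech Event;
* analytic per-AOI saliency streams with the same structure the pixel
  pipeline produces, as a fast path that bypasses rendering;
* model-generated behavioral gaze tables following the experimental
  protocol (19 test trials, 20 participants per condition), with optional
  step-wise Bernoulli "away" lapses to exercise the missing-data paths.

Everything synthetic here is a stand-in for the undeposited originals: only
the saliency *structure* (which zone is statically vs dynamically salient,
and when) matters to the model, not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Params, Zone
from .saliency import AOILayout, AOISaliencyStream
from .simulator import (
    CONDITIONS,
    Protocol,
    TrialTimeline,
    simulate_experiment,
)


def default_layout(image_size=(160, 120)) -> AOILayout:
    """A face layout proportioned like a zoomed-in talking-face video."""
    w, h = image_size
    return AOILayout(
        image_size=(w, h),
        face=(round(w * 0.25), round(h * 0.10), round(w * 0.75), round(h * 0.90)),
        eyes=(round(w * 0.32), round(h * 0.25), round(w * 0.68), round(h * 0.45)),
        mouth=(round(w * 0.38), round(h * 0.60), round(w * 0.62), round(h * 0.78)),
    )


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one synthetic stimulus video.

    Durations and frame rate default to the experimental protocol (Speech
    Event fixed at its 1800 ms mean duration, Non-speech Event 1880 ms,
    25 frames/s).  Motion amplitudes are unitless intensity step sizes;
    ``static_contrast`` scales the permanent eye-region contrast and
    ``motion_floor`` is a small base motion present in every zone (sensor
    and compression noise in real video), which keeps the dynamic saliency
    distribution full-support.
    """

    condition: str = "ER"
    speech_duration_ms: float = 1800.0
    nonspeech_duration_ms: float = 1880.0
    fps: float = 25.0
    image_size: tuple = (160, 120)
    layout: AOILayout | None = None
    mouth_motion: float = 1.0
    eyes_motion: float = 0.0
    event_motion: float = 1.0
    static_contrast: float = 1.0
    motion_floor: float = 0.05

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.layout is None:
            object.__setattr__(self, "layout", default_layout(self.image_size))

    @property
    def n_speech_frames(self) -> int:
        return round(self.fps * self.speech_duration_ms / 1000.0)

    @property
    def n_nonspeech_frames(self) -> int:
        return round(self.fps * self.nonspeech_duration_ms / 1000.0)

    @property
    def n_frames(self) -> int:
        return self.n_speech_frames + self.n_nonspeech_frames

    @property
    def event_zone(self) -> Zone:
        return Zone.EYES if self.condition == "ER" else Zone.MOUTH


def _rect_center(rect):
    x0, y0, x1, y1 = rect
    return (x0 + x1) / 2.0, (y0 + y1) / 2.0


def make_stimulus_frames(spec: StimulusSpec, rng=None) -> list:
    """Render the schematic talking face as a list of gray frames in [0, 1].

    The eye blobs (dark pupils on bright sclera patches) are permanent and
    static; a mouth bar oscillates in intensity during the Speech Event; the
    event region (eyebrows for ER, mouth for LP) oscillates during the
    Non-speech Event.  ``rng`` adds tiny per-pixel noise emulating sensor
    noise; omit it for a fully deterministic sequence.
    """
    layout = spec.layout
    w, h = layout.image_size
    if any((r[2] - r[0]) <= 0 or (r[3] - r[1]) <= 0
           for r in (layout.eyes, layout.mouth, layout.face)):
        raise ValueError("zero-area AOI in the stimulus layout")
    base = np.full((h, w), 0.40)
    fx0, fy0, fx1, fy1 = (int(v) for v in layout.face)
    base[fy0:fy1, fx0:fx1] = 0.55
    # permanent high-contrast eyes: bright sclera patches with dark pupils
    ex0, ey0, ex1, ey1 = (int(v) for v in layout.eyes)
    eh, ew = ey1 - ey0, ex1 - ex0
    for cx_frac in (0.28, 0.72):
        cx = ex0 + cx_frac * ew
        cy = ey0 + 0.62 * eh
        yy, xx = np.mgrid[0:h, 0:w]
        sclera = ((xx - cx) ** 2 / (0.14 * ew) ** 2
                  + (yy - cy) ** 2 / (0.30 * eh) ** 2) <= 1.0
        pupil = ((xx - cx) ** 2 + (yy - cy) ** 2) <= (0.10 * min(ew, eh) * 2) ** 2
        base[sclera] = 0.55 + 0.40 * spec.static_contrast
        base[pupil] = max(0.0, 0.55 - 0.50 * spec.static_contrast)
    mx0, my0, mx1, my1 = (int(v) for v in layout.mouth)
    mcy = (my0 + my1) // 2
    brow_y0 = ey0 + max(1, eh // 8)
    frames = []
    for i in range(spec.n_frames):
        frame = base.copy()
        in_speech = i < spec.n_speech_frames
        # mouth bar: intensity oscillates during speech (articulation), and
        # during the non-speech event in the LP condition only.  The
        # oscillation frequency is incommensurate with the frame rate so no
        # two successive frames are identical while a bar is animated.
        mouth_amp = 0.0
        if in_speech:
            mouth_amp = spec.mouth_motion
        elif spec.condition == "LP":
            mouth_amp = spec.event_motion
        phase = np.sin(2.0 * np.pi * 0.21 * i)  # ~5 Hz articulation at 25 fps
        bar_half = max(1, round((my1 - my0) * 0.18))
        frame[mcy - bar_half:mcy + bar_half, mx0:mx1] = (
            0.40 + 0.30 * mouth_amp * (0.5 + 0.5 * phase)
        )
        # eyebrow bar inside the eyes AOI: moves during the ER event only
        lift = 0.5 + 0.5 * np.sin(2.0 * np.pi * 0.17 * i)
        if not in_speech and spec.condition == "ER":
            frame[brow_y0:brow_y0 + max(1, eh // 6), ex0:ex1] = (
                0.30 + 0.45 * spec.event_motion * lift
            )
        elif in_speech and spec.eyes_motion > 0:
            frame[brow_y0:brow_y0 + max(1, eh // 6), ex0:ex1] = (
                0.30 + 0.45 * spec.eyes_motion * lift
            )
        if rng is not None:
            frame = np.clip(frame + rng.normal(0.0, 0.005, frame.shape), 0.0, 1.0)
        frames.append(frame)
    return frames


def write_frames(frames, directory) -> None:
    """Write frames as 8-bit PNGs named frame_0000.png, frame_0001.png, ..."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        img = Image.fromarray(np.clip(frame * 255, 0, 255).astype(np.uint8))
        img.save(directory / f"frame_{i:04d}.png")


#: Relative static saliency of (Eyes, Mouth, RoF, Other) in the schematic
#: face: the eye blobs carry most of the contrast, mouth and face outline a
#: little, the background almost none.
_STATIC_PROFILE = np.array([1.0, 0.2, 0.2, 0.02])


def make_saliency_streams(spec: StimulusSpec, timeline: TrialTimeline) -> AOISaliencyStream:
    """Analytic per-AOI saliency stream at the timeline's resolution.

    Mirrors the structure the pixel pipeline extracts from the rendered
    frames: static mass concentrated on Eyes throughout; dynamic mass on
    Mouth during Speech-Event steps and on the event zone during
    Non-speech-Event steps, over a uniform motion floor.  Step 0 has no
    previous frame, hence zero dynamic saliency, like the pixel path.
    """
    n = timeline.n_steps
    static = np.tile(_STATIC_PROFILE * spec.static_contrast, (n, 1))
    dynamic = np.full((n, 4), spec.motion_floor)
    speech = slice(0, timeline.n_speech_steps)
    event = slice(timeline.t_er, n)
    dynamic[speech, int(Zone.MOUTH)] += spec.mouth_motion
    dynamic[speech, int(Zone.EYES)] += spec.eyes_motion
    dynamic[event, int(spec.event_zone)] += spec.event_motion
    dynamic[0, :] = 0.0
    return AOISaliencyStream(static, dynamic)


def protocol_streams(protocol: Protocol, spec_kwargs: dict | None = None) -> dict:
    """Analytic streams for every condition of a protocol."""
    spec_kwargs = spec_kwargs or {}
    return {
        cond: make_saliency_streams(
            StimulusSpec(condition=cond, **spec_kwargs), protocol.timeline
        )
        for cond in protocol.conditions
    }


def make_behavioral_dataset(
    protocol: Protocol,
    generating_params: Params | None = None,
    lapse_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    group: str = "SIM",
    spec_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Model-generated gaze records in the behavioral table format.

    Trajectories are simulated under ``generating_params`` (defaulting to
    the protocol's) and converted to one record per (participant, condition,
    trial, step), with columns participant, group, condition, trial, step,
    aoi.  Each step is independently replaced by an off-face ``"away"``
    record with probability ``lapse_rate``, emulating looks away from the
    screen; those samples are excluded from looking-time denominators
    downstream.
    """
    if not 0.0 <= lapse_rate <= 0.5:
        raise ValueError(f"lapse_rate must be in [0, 0.5], got {lapse_rate}")
    result = simulate_experiment(
        protocol, protocol_streams(protocol, spec_kwargs), params=generating_params
    )
    df = result.to_frame()
    if lapse_rate > 0:
        if rng is None:
            rng = np.random.default_rng(protocol.master_seed)
        lapse = rng.random(len(df)) < lapse_rate
        df.loc[lapse, "zone"] = -1
    labels = {int(z): z.label for z in Zone}
    labels[-1] = "away"
    df["aoi"] = df["zone"].map(labels)
    df.insert(1, "group", group)
    return df.drop(columns=["zone"])
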