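"""Bottom-up component: static and dynamic saliency over AOIs.

Static saliency follows the classic intensity-channel center-surround
scheme: the image is smoothed at a set of center and surround scales, the
absolute center-surround differences are max-normalized per scale and
summed.  This gives high values along contrast edges (the high-contrast eye
region of a face) and zero in flat regions; as a difference of linear
filters with unit DC gain it is invariant to adding a constant to the image.
Color, orientation and flicker channels are omitted: the stimuli are
gray-scale image sequences.

Dynamic saliency is the absolute difference of squared pixel intensities
between successive frames, highlighting moving regions (the articulating
mouth during speech, the event region afterwards).

Per-pixel maps are aggregated to the four AOIs by *averaging* inside each
zone, making the per-zone measure independent of zone area, and the two
resulting distributions are mixed with weight ``theta`` on the static part.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import N_ZONES, Role, Zone, ZoneDistribution, normalize

#: Default center-surround scale pairs (center sigma, surround sigma) in px.
#: Three center scales, two surround deltas each (surround = 4x and 8x center).
DEFAULT_SCALES = ((1.0, 4.0), (1.0, 8.0), (2.0, 8.0), (2.0, 16.0), (4.0, 16.0), (4.0, 32.0))


class FormatError(ValueError):
    """Raised on malformed images, layouts or streams."""


@dataclass(frozen=True)
class AOILayout:
    """Pixel-coordinate AOI layout of the face image.

    Rectangles are 0-based, half-open ``(x0, y0, x1, y1)`` with the origin at
    the top-left: a point ``(x, y)`` lies inside iff ``x0 <= x < x1`` and
    ``y0 <= y < y1``.  The four zones partition the image: Eyes and Mouth are
    the two rectangles, RoF is the face rectangle minus both, Other is the
    image minus the face.  A point on a shared boundary belongs to the zone
    with the lower index (Eyes before Mouth before RoF).
    """

    image_size: tuple  # (width, height)
    eyes: tuple
    mouth: tuple
    face: tuple

    def __post_init__(self):
        w, h = self.image_size
        for name, rect in (("eyes", self.eyes), ("mouth", self.mouth), ("face", self.face)):
            x0, y0, x1, y1 = rect
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise FormatError(f"{name} rectangle {rect} not inside image {w}x{h}")
        ex0, ey0, ex1, ey1 = self.eyes
        mx0, my0, mx1, my1 = self.mouth
        if ex0 < mx1 and mx0 < ex1 and ey0 < my1 and my0 < ey1:
            raise FormatError("eyes and mouth rectangles overlap")

    @property
    def shape(self) -> tuple:
        """Array shape (height, width)."""
        w, h = self.image_size
        return (h, w)

    def zone_of_point(self, x: float, y: float):
        """Zone containing pixel (x, y), or ``None`` for off-screen points."""
        w, h = self.image_size
        if not (0 <= x < w and 0 <= y < h):
            return None
        for zone, rect in ((Zone.EYES, self.eyes), (Zone.MOUTH, self.mouth)):
            x0, y0, x1, y1 = rect
            if x0 <= x < x1 and y0 <= y < y1:
                return zone
        x0, y0, x1, y1 = self.face
        if x0 <= x < x1 and y0 <= y < y1:
            return Zone.ROF
        return Zone.OTHER

    def zone_mask(self) -> np.ndarray:
        """Integer zone index per pixel, shape (height, width)."""
        h, w = self.shape
        mask = np.full((h, w), int(Zone.OTHER), dtype=np.int8)
        fx0, fy0, fx1, fy1 = (int(v) for v in self.face)
        mask[fy0:fy1, fx0:fx1] = int(Zone.ROF)
        mx0, my0, mx1, my1 = (int(v) for v in self.mouth)
        mask[my0:my1, mx0:mx1] = int(Zone.MOUTH)
        ex0, ey0, ex1, ey1 = (int(v) for v in self.eyes)
        mask[ey0:ey1, ex0:ex1] = int(Zone.EYES)
        return mask

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"image_size": list(self.image_size), "eyes": list(self.eyes),
             "mouth": list(self.mouth), "face": list(self.face)}, indent=2))

    @classmethod
    def from_json(cls, path) -> "AOILayout":
        data = json.loads(Path(path).read_text())
        try:
            return cls(
                image_size=tuple(data["image_size"]),
                eyes=tuple(data["eyes"]),
                mouth=tuple(data["mouth"]),
                face=tuple(data["face"]),
            )
        except KeyError as exc:
            raise FormatError(f"layout file {path} missing key {exc}") from None


@dataclass(frozen=True)
class AOISaliencyStream:
    """Per-step static and dynamic zone means, each of shape (n_steps, 4)."""

    static: np.ndarray
    dynamic: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.static, dtype=float)
        d = np.asarray(self.dynamic, dtype=float)
        if s.ndim != 2 or s.shape[1] != N_ZONES or s.shape != d.shape:
            raise FormatError(f"stream shapes {s.shape}/{d.shape} invalid")
        if np.any(s < 0) or np.any(d < 0):
            raise FormatError("saliency means must be non-negative")
        object.__setattr__(self, "static", s)
        object.__setattr__(self, "dynamic", d)

    def __len__(self) -> int:
        return self.static.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for kind, arr in (("static", self.static), ("dyn", self.dynamic)):
            for z in Zone:
                cols[f"{kind}_{z.label.lower()}"] = arr[:, int(z)]
        df = pd.DataFrame(cols)
        df.insert(0, "step", np.arange(len(self)))
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AOISaliencyStream":
        df = pd.read_csv(path, sep="\t")
        static = df[[f"static_{z.label.lower()}" for z in Zone]].to_numpy()
        dynamic = df[[f"dyn_{z.label.lower()}" for z in Zone]].to_numpy()
        return cls(static, dynamic)


def _check_image(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(f"expected a non-empty 2-D gray image, got shape {arr.shape}")
    return arr


def static_saliency(frame, scales=DEFAULT_SCALES, normalize_scales: bool = True) -> np.ndarray:
    """Center-surround static saliency map of a gray-scale frame.

    For each ``(center, surround)`` sigma pair the map is
    ``|G_center(frame) - G_surround(frame)|``; per-scale maps are divided by
    their maximum (when positive) and summed.  ``normalize_scales=False``
    skips the per-scale normalization (useful for comparing a single scale
    against a direct convolution).
    """
    arr = _check_image(frame)
    out = np.zeros_like(arr)
    for center, surround in scales:
        diff = np.abs(
            gaussian_filter(arr, center, mode="nearest")
            - gaussian_filter(arr, surround, mode="nearest")
        )
        if normalize_scales:
            peak = diff.max()
            # leave numerically-flat maps alone instead of amplifying noise
            if peak > 1e-12:
                diff = diff / peak
        out += diff
    return out


def dynamic_saliency(frame_t, frame_prev) -> np.ndarray:
    """Motion saliency: absolute difference of squared intensities.

    ``|frame_t**2 - frame_prev**2|`` per pixel; zero wherever the video is
    static.  The squaring emphasizes bright moving structure, the absolute
    value makes the measure sign-free.
    """
    a = _check_image(frame_t)
    b = _check_image(frame_prev)
    if a.shape != b.shape:
        raise FormatError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return np.abs(a * a - b * b)


def aggregate_aoi(saliency_map, layout: AOILayout) -> np.ndarray:
    """Mean map value inside each of the four zones, shape (4,).

    Zones with zero pixel area contribute 0 with a warning.
    """
    arr = _check_image(saliency_map)
    if arr.shape != layout.shape:
        raise FormatError(
            f"map shape {arr.shape} does not match layout {layout.shape}"
        )
    mask = layout.zone_mask()
    means = np.zeros(N_ZONES)
    for z in range(N_ZONES):
        sel = mask == z
        count = sel.sum()
        if count == 0:
            warnings.warn(f"zone {Zone(z).label} has zero area; mean set to 0")
            continue
        means[z] = arr[sel].mean()
    return means


def bottom_up_distribution(static_means, dynamic_means, theta: float) -> ZoneDistribution:
    """Mix normalized static and dynamic zone means with weight ``theta``.

    Each mean vector is normalized to a distribution (an all-zero vector
    falls back to uniform with a warning, so blank frames do not halt a
    simulation) and combined as ``theta * static + (1 - theta) * dynamic``.
    theta near 1 expresses a preference for static contrast (the eyes);
    theta near 0 a preference for movement.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    parts = []
    for means in (static_means, dynamic_means):
        arr = np.asarray(means, dtype=float)
        total = arr.sum()
        if total <= 0:
            warnings.warn("all-zero saliency means; falling back to uniform")
            parts.append(np.full(N_ZONES, 1.0 / N_ZONES))
        else:
            parts.append(arr / total)
    mixed = theta * parts[0] + (1.0 - theta) * parts[1]
    return ZoneDistribution(mixed, Role.BOTTOM_UP)


def bottom_up_table(stream: AOISaliencyStream, theta: float) -> np.ndarray:
    """Vectorized bottom-up probabilities per step, shape (n_steps, 4)."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    parts = []
    for arr in (stream.static, stream.dynamic):
        totals = arr.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(totals > 0, arr / np.where(totals > 0, totals, 1.0),
                            1.0 / N_ZONES)
        parts.append(dist)
    return theta * parts[0] + (1.0 - theta) * parts[1]


def stream_from_frames(frames, layout: AOILayout) -> AOISaliencyStream:
    """Per-step AOI saliency stream from a gray frame sequence.

    The dynamic map of step 0 pairs the first frame with itself and is
    therefore all-zero.
    """
    frames = [_check_image(f) for f in frames]
    if len(frames) < 2:
        raise FormatError("need at least 2 frames")
    shape = frames[0].shape
    for i, f in enumerate(frames):
        if f.shape != shape:
            raise FormatError(f"frame {i} shape {f.shape} differs from {shape}")
    static = np.empty((len(frames), N_ZONES))
    dynamic = np.empty((len(frames), N_ZONES))
    prev = frames[0]
    for i, frame in enumerate(frames):
        static[i] = aggregate_aoi(static_saliency(frame), layout)
        dynamic[i] = aggregate_aoi(dynamic_saliency(frame, prev), layout)
        prev = frame
    return AOISaliencyStream(static, dynamic)


def load_frames(directory) -> list:
    """Read a directory of PNG/PGM frames (sorted by name) as [0, 1] floats."""
    from PIL import Image  # deferred: only needed for the pixel path

    paths = sorted(
        p for p in Path(directory).iterdir() if p.suffix.lower() in (".png", ".pgm")
    )
    if not paths:
        raise FormatError(f"no PNG/PGM frames found in {directory}")
    frames = []
    for p in paths:
        img = np.asarray(Image.open(p).convert("L"), dtype=float) / 255.0
        frames.append(img)
    return frames
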