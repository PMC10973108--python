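"""Reading and writing the package's text formats.

Gaze records are long-format delimited text (tab-separated canonically,
comma accepted on read) with one row per gaze sample: participant, group,
condition, trial, and either a pre-normalized ``step`` index or a
``time_ms`` stamp, plus either an ``aoi`` label (Eyes/Mouth/RoF/Other/away)
or pixel coordinates ``x, y`` resolved through an AOI layout.  Millisecond
time stamps are converted to normalized steps by proportional binning into
the trial timeline (each event normalized separately).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ZONE_LABELS, Zone
from .saliency import AOILayout
from .simulator import CONDITIONS, TrialTimeline


class ParseError(ValueError):
    """Raised on malformed gaze tables, with offending line numbers."""


REQUIRED_COLUMNS = ("participant", "condition", "trial")
AOI_LABELS = set(ZONE_LABELS) | {"away"}


def _read_delimited(path) -> pd.DataFrame:
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    return pd.read_csv(path, sep=sep)


def normalize_time_ms(
    time_ms, timeline: TrialTimeline
) -> np.ndarray:
    """Proportionally bin millisecond stamps into normalized steps.

    Times in ``[0, speech_duration_ms)`` map onto the Speech-Event steps,
    later times onto the Non-speech-Event steps, each event scaled
    separately; results are clipped into the timeline.
    """
    t = np.asarray(time_ms, dtype=float)
    sp_ms = timeline.speech_duration_ms
    ns_ms = timeline.nonspeech_duration_ms
    in_speech = t < sp_ms
    steps = np.where(
        in_speech,
        np.floor(t / sp_ms * timeline.n_speech_steps),
        timeline.n_speech_steps
        + np.floor((t - sp_ms) / ns_ms * timeline.n_nonspeech_steps),
    )
    return np.clip(steps, 0, timeline.n_steps - 1).astype(int)


def read_gaze_table(
    path,
    layout: AOILayout | None = None,
    timeline: TrialTimeline | None = None,
) -> pd.DataFrame:
    """Read and validate a gaze table.

    Returns a DataFrame with columns participant, group, condition, trial,
    step, aoi and zone (integer zone index, -1 for away).  ``layout`` is
    required when rows carry only (x, y); ``timeline`` is required when rows
    carry ``time_ms`` instead of ``step``.
    """
    df = _read_delimited(path)
    # +2: one for the header, one for 1-based line numbering
    lineno = df.index.to_numpy() + 2

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if "step" not in df.columns:
        if "time_ms" not in df.columns:
            raise ParseError(f"{path}: need a 'step' or 'time_ms' column")
        if timeline is None:
            timeline = TrialTimeline()
        df["step"] = normalize_time_ms(df["time_ms"].to_numpy(), timeline)
    if "aoi" not in df.columns and not {"x", "y"} <= set(df.columns):
        raise ParseError(f"{path}: need an 'aoi' column or 'x'/'y' columns")
    if "group" not in df.columns:
        df["group"] = "NA"

    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        lines = lineno[bad_cond.to_numpy()][:5].tolist()
        raise ParseError(
            f"{path}: unknown condition label(s) at line(s) {lines}; "
            f"expected one of {CONDITIONS}"
        )
    dup = df.duplicated(subset=["participant", "condition", "trial", "step"])
    if dup.any():
        lines = lineno[dup.to_numpy()][:5].tolist()
        raise ParseError(
            f"{path}: duplicate (participant, condition, trial, step) at "
            f"line(s) {lines}"
        )

    if "aoi" in df.columns:
        bad_aoi = ~df["aoi"].isin(AOI_LABELS)
        if bad_aoi.any():
            lines = lineno[bad_aoi.to_numpy()][:5].tolist()
            raise ParseError(f"{path}: unknown aoi label(s) at line(s) {lines}")
    else:
        if layout is None:
            raise ParseError(f"{path}: (x, y) records require an AOI layout")
        aois = []
        for x, y in zip(df["x"].to_numpy(float), df["y"].to_numpy(float)):
            zone = layout.zone_of_point(x, y)
            aois.append("away" if zone is None else zone.label)
        df["aoi"] = aois

    zone_code = {label: i for i, label in enumerate(ZONE_LABELS)}
    zone_code["away"] = -1
    df["zone"] = df["aoi"].map(zone_code).astype(int)
    cols = ["participant", "group", "condition", "trial", "step", "aoi", "zone"]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]


def write_gaze_table(df: pd.DataFrame, path) -> None:
    """Write a gaze table as tab-separated text."""
    out = df.copy()
    if "zone" in out.columns and "aoi" in out.columns:
        out = out.drop(columns=["zone"])
    out.to_csv(path, sep="\t", index=False)


def write_manifest(path, **fields) -> None:
    """Write a JSON run manifest (parameters, seeds, version) beside outputs."""
    from . import __version__

    payload = {"gazesim_version": __version__}
    payload.update(fields)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
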