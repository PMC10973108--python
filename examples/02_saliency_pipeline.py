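"""Render a schematic talking-face stimulus and extract its saliency.

Renders the eyebrow-raise stimulus (92 frames at 25 fps: a 1800 ms sentence
then a 1880 ms eyebrow raise), runs the center-surround static and
frame-difference dynamic saliency over it, aggregates per AOI, and prints
which zone dominates each measure in each event phase.
"""

import numpy as np

from gazesim import Zone, stream_from_frames
from gazesim.synth import StimulusSpec, make_stimulus_frames

spec = StimulusSpec(condition="ER")
frames = make_stimulus_frames(spec)
print(f"rendered {len(frames)} frames of size {frames[0].shape[::-1]}"
      f" ({spec.n_speech_frames} speech + {spec.n_nonspeech_frames} event)")

stream = stream_from_frames(frames, spec.layout)
phases = {
    "speech": slice(1, spec.n_speech_frames),
    "event": slice(spec.n_speech_frames + 1, None),
}
for name, sl in phases.items():
    static_zone = Zone(int(np.bincount(stream.static[sl].argmax(1)).argmax()))
    dynamic_zone = Zone(int(np.bincount(stream.dynamic[sl].argmax(1)).argmax()))
    print(f"{name:>6}: most statically salient zone = {static_zone.label}, "
          f"most motion = {dynamic_zone.label}")

print("\nThe eyes dominate static contrast throughout (sclera/pupil blobs);")
print("motion sits on the mouth while the face talks and jumps to the eye")
print("region when the eyebrows move - exactly the structure the bottom-up")
print("component feeds into the model, mixed with weight theta.")
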