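"""Generate an annotated synthetic EEG recording and inspect its structure.

Builds one minute of 8-channel, 256 Hz signal with a seizure between 20 s
and 35 s, writes it in the delimited dialect, reads it back and cuts it into
labeled 5-second windows.
"""

import numpy as np

from rsae import SynthConfig, gen_recording, read_recording, segment_recording, write_recording
from rsae.io import write_intervals

config = SynthConfig(seed=7)
rec = gen_recording(config, duration_s=60.0, seizure_intervals=[(20.0, 35.0)])
write_recording("synthetic_eeg.tsv", rec)
write_intervals("synthetic_eeg.ann", rec.seizure_intervals)

back = read_recording("synthetic_eeg.tsv", "delimited", fs=256.0,
                      intervals="synthetic_eeg.ann")
segments = segment_recording(back, window_s=5.0, seizure_overlap_frac=0.5)
n_seiz = sum(s.label == "seizure" for s in segments)

print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples "
      f"({rec.duration_s:.0f} s at {rec.fs:.0f} Hz)")
print(f"channel RMS amplitude: {rec.data.std(axis=1).mean():.1f} uV "
      f"(background scale {config.background_amp} uV)")
print(f"segments: {len(segments)} total, {n_seiz} seizure / {len(segments) - n_seiz} nonseizure")
# The seizure windows slide with 50% overlap inside the 15 s annotated
# interval; nonseizure windows tile the remaining 45 s without overlap.
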