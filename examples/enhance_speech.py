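"""Envelope-enhance a speech-like signal and show where energy was added.

Builds a synthetic utterance with three abrupt onsets, runs the
envelope-enhancement algorithm, and compares RMS levels in the 50 ms after
each onset against the unprocessed signal. Enhancement should boost the
onsets while leaving steady segments untouched.
"""

import numpy as np

from assrlab import enhance
from assrlab.simulate import synthetic_utterance

utterance, onsets = synthetic_utterance(
    onset_times=[0.3, 1.0, 1.8], segment_levels=[1.0, 0.8, 0.9], seed=2)
enhanced, inter = enhance(utterance, return_intermediates=True)

rate, win = 16000, int(0.05 * 16000)
print("onset   RMS original  RMS enhanced  gain")
for t0 in onsets:
    i = slice(int(t0 * rate), int(t0 * rate) + win)
    r_orig = np.sqrt(np.mean(utterance.samples[i] ** 2))
    r_enh = np.sqrt(np.mean(enhanced.samples[i] ** 2))
    print(f"{t0:5.2f} s  {r_orig:11.4f}  {r_enh:12.4f}  {r_enh / r_orig:5.2f}x")

mid = slice(int(0.6 * rate), int(0.85 * rate))
ratio = (np.sqrt(np.mean(enhanced.samples[mid] ** 2))
         / np.sqrt(np.mean(utterance.samples[mid] ** 2)))
p = inter["p"]
mask = np.zeros(p.size, bool)
for t0 in onsets:
    mask[int(t0 * rate): int(t0 * rate) + win] = True
print(f"\nsteady-state RMS ratio: {ratio:.3f} (1.0 = untouched)")
print(f"fraction of added energy within 50 ms of an onset: "
      f"{np.sum(p[mask]**2) / np.sum(p**2):.3f}")
# Gains > 1 at onsets with a steady-state ratio of 1.0 show the processing
# sharpens amplitude rise times without altering the rest of the signal.
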