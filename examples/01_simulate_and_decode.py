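"""Simulate one subject and decode emotion category over time.

Builds a 20-stimulus design (10 positive / 10 negative scenes, 8
repetitions), injects a category-discriminative pattern at 100-400 ms
with amplitude 3x the noise SD, preprocesses, and runs time-resolved SVM
decoding.  Expected: AUC near 0.5 before stimulus onset and well above
0.5 inside the injected window.
"""

import numpy as np

from empadecode import (
    EffectSpec,
    decode_timecourse,
    make_stimulus_set,
    make_trial_design,
    reject_artifacts,
    rereference_average,
    simulate_epochs,
)
from empadecode.mvpa import category_labels

stimuli = make_stimulus_set(n_per_category=10, seed=0)
design = make_trial_design(stimuli, repetitions=8, task="CE", seed=0)
effects = EffectSpec(category_amplitude=3.0, category_onset=100.0, category_duration=300.0)
epochs = simulate_epochs(design, stimuli, effects, n_channels=32, seed=0)
print(f"simulated {epochs.n_trials} trials x {epochs.n_channels} channels x {epochs.n_samples} samples")

# re-reference and reject, but skip the band-pass here: zero-phase filtering
# smears a boxcar signal backward in time, which would blur the onset this
# demo wants to show crisply
clean, report = reject_artifacts(rereference_average(epochs))
print(f"artifact rejection: {report.n_rejected}/{report.n_input_trials} trials removed")

tc = decode_timecourse(clean, category_labels(clean), n_folds=8, n_repeats=2, seed=1)
pre = tc.values[tc.times < 0].mean()
window = tc.values[(tc.times >= 150) & (tc.times <= 350)].mean()
peak_t = tc.times[np.argmax(tc.values)]
print(f"mean AUC before onset: {pre:.3f}  (chance = 0.5)")
print(f"mean AUC in 150-350 ms: {window:.3f}")
print(f"peak AUC {tc.values.max():.3f} at {peak_t:.0f} ms")
print("-> the classifier finds category information only where it was injected")
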