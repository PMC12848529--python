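"""Group-level cluster-based permutation test against chance.

Simulates a small group of subjects with a category signal at
100-400 ms, decodes each, and runs the sign-flip cluster permutation
test (Wilcoxon point statistics, maxsum cluster mass).  Expected: one
significant cluster covering roughly the injected window.
"""

import numpy as np

from empadecode import (
    EffectSpec,
    decode_timecourse,
    make_stimulus_set,
    make_trial_design,
    permtest_vs_chance,
    simulate_epochs,
)
from empadecode.mvpa import category_labels

n_subjects = 8
effects = EffectSpec(category_amplitude=3.0, category_onset=100.0, category_duration=300.0)
stimuli = make_stimulus_set(seed=0)
courses = []
for i in range(n_subjects):
    design = make_trial_design(stimuli, repetitions=8, seed=100 + i)
    ep = simulate_epochs(design, stimuli, effects, n_channels=16, seed=200 + i, subject_id=i)
    courses.append(decode_timecourse(ep, category_labels(ep), n_folds=4, n_repeats=2, seed=i))

result = permtest_vs_chance(courses, chance=0.5, n_perm=500, seed=0)
print(f"{len(result.clusters)} cluster(s); permutation null from {result.n_permutations} sign-flips")
for c in result.significant_clusters():
    start = result.times[int(c.indices.min())]
    end = result.times[int(c.indices.max())]
    print(f"significant cluster: {start:.0f}-{end:.0f} ms, mass {c.mass:.1f}, p = {c.p_value:.4f}")
print("-> the recovered window tracks the injected 100-400 ms signal;")
print("   p has an add-one floor of 1/(n_perm+1), never exactly 0")
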