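"""Decode two synthetic motor-imagery-like classes with the 3D CNN.

Class 0 couples channels (0, 1), class 1 couples channels (2, 3) — the
location of the phase-locked pair is the only difference.  Each 4-s trial
is cut into nine 2-s windows (0.25-s step); each window's stacked
PCC/COH/PLV matrices form one 8x8x3 training sample.  Trial-level 5-fold
cross-validation keeps all windows of a trial in one fold.

Scaled down (10 trials/class, 30 epochs) so it runs in ~20 s.
"""

import numpy as np

import tfpf

common = dict(n_channels=8, fs=160.0, duration=4.0, noise_sd=1.0)
spec_a = tfpf.SimulationSpec(coupled_pairs=((0, 1, 12.0, 1000.0, 0.5),), **common)
spec_b = tfpf.SimulationSpec(coupled_pairs=((2, 3, 12.0, 1000.0, 0.5),), **common)

trials = tfpf.make_labeled_dataset(spec_a, spec_b, 10, seed=0)
samples = tfpf.trials_to_input_sets(trials)
print(f"{len(trials)} trials -> {len(samples)} samples of shape "
      f"{samples[0].values.shape}")

folds, mean_acc, sd_acc = tfpf.evaluate_cv(samples, k=5, seed=0, epochs=30)
for r in folds:
    print(f"fold {r.fold_index}: {len(r.test_trial_ids)} test trials, "
          f"accuracy {r.accuracy:.2f}")
print(f"\nmean CV accuracy {mean_acc:.2f} +/- {sd_acc:.2f}")
print("Near-perfect accuracy here means the CNN finds the class-specific")
print("PLV/COH/PCC signature; chance (0.5) would mean the features carry")
print("no class information.")
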