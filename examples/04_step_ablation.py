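"""Sliding-window step-size ablation with a one-way ANOVA.

Smaller steps produce more overlapping windows per trial — more training
samples from the same recordings.  The harness reruns the full pipeline
for steps of 0.5, 0.25 and 0.125 s and tests whether mean cross-validated
accuracy differs across steps.
"""

import numpy as np

import tfpf

common = dict(n_channels=8, fs=160.0, duration=4.0, noise_sd=1.0)
spec_a = tfpf.SimulationSpec(coupled_pairs=((0, 1, 12.0, 1000.0, 0.5),), **common)
spec_b = tfpf.SimulationSpec(coupled_pairs=((2, 3, 12.0, 1000.0, 0.5),), **common)


def builder(seed):
    return tfpf.make_labeled_dataset(spec_a, spec_b, 8, seed=seed)


steps = (0.5, 0.25, 0.125)
accs, F, p = tfpf.ablate_step_sizes(builder, steps=steps, repeats=2,
                                    k=4, epochs=25, seed=0)
for s in steps:
    n_windows = int((4.0 - 2.0) / s) + 1
    print(f"step {s:>5} s ({n_windows:2d} windows/trial): "
          f"mean accuracy {np.mean(accs[s]):.2f}")
print(f"\none-way ANOVA across steps: F = {F:.2f}, p = {p:.3f}")
print("A small p would indicate the step size significantly changes")
print("accuracy; on this easily separable task all steps saturate, so the")
print("ANOVA typically finds no difference.")
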