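"""Simulate a phase-coupled channel pair and read off the three features.

Builds a 4-channel trial where channels 0 and 1 share a 12 Hz carrier with
a tight von Mises phase coupling (kappa = 1000) and a linear mixing weight
of 0.5; channels 2 and 3 are pure noise.  The three connectivity matrices
should show the coupled pair standing far above the background.
"""

import numpy as np

import tfpf

spec = tfpf.SimulationSpec(
    n_channels=4, fs=160.0, duration=4.0,
    coupled_pairs=((0, 1, 12.0, 1000.0, 0.5),), noise_sd=1.0, seed=0)
trial = tfpf.bandpass(tfpf.simulate(spec))
segment = trial.data[:, :320]  # one 2-s window

for kind in ("PCC", "COH", "PLV"):
    m = tfpf.connectivity_matrix(segment, trial.fs, (8.0, 30.0), kind).values
    background = np.abs(m[2, 3])
    print(f"{kind}: coupled pair (0,1) = {m[0, 1]:+.3f}   "
          f"uncoupled pair (2,3) = {background:+.3f}")

print()
print("The coupled pair stands above the uncoupled one on every feature;")
print("PLV separates most sharply (phase locking is exactly what kappa")
print("controls), while the uncoupled values show each estimator's noise")
print("floor for a single 2-s window.")
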