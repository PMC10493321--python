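"""Stacking per-window connectivity matrices into 3D feature voxels.

Each sliding window yields three channels x channels matrices (PCC, COH,
PLV); stacked along a third axis they form one C x C x 3 voxel.  A trial's
voxels can either stay separate (``per_segment`` mode — each voxel is one
classifier sample, so windowing acts as data augmentation) or be
concatenated depth-wise into a single C x C x 3N block (``stacked`` mode).
The slice order (PCC, COH, PLV), window-major in stacked mode, is a frozen
contract.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .connectivity import FEATURE_KINDS, connectivity_matrix
from .preprocess import SegmentSet

__all__ = ["TFPFVoxel", "InputSet", "build_tfpf", "assemble_input",
           "save_input_sets", "load_input_sets"]

STACK_MODES = ("per_segment", "stacked")


@dataclass(frozen=True)
class TFPFVoxel:
    """One window's C x C x 3 feature block, slices ordered (PCC, COH, PLV)."""

    values: np.ndarray
    segment_index: int = 0
    trial_id: str = "trial-0"
    label: object = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != v.shape[1] or v.shape[2] != 3:
            raise ValueError(f"voxel must be C x C x 3, got {v.shape}")
        object.__setattr__(self, "values", v)

    def slice(self, feature_kind: str) -> np.ndarray:
        return self.values[:, :, FEATURE_KINDS.index(feature_kind)]


@dataclass(frozen=True)
class InputSet:
    """One classifier sample: a C x C x D array with its label.

    ``D = 3`` in per_segment mode; ``D = 3 * n_segments`` in stacked mode
    (window-major, then PCC/COH/PLV within each window).
    """

    values: np.ndarray
    trial_id: str
    label: object
    stack_mode: str = "per_segment"
    segment_index: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValueError(f"input set must be C x C x D, got {v.shape}")
        if self.stack_mode not in STACK_MODES:
            raise ValueError(f"stack_mode must be one of {STACK_MODES}")
        object.__setattr__(self, "values", v)

    @property
    def depth(self) -> int:
        return self.values.shape[2]


def build_tfpf(segments: SegmentSet, fs: float | None = None,
               band: tuple = (8.0, 30.0)) -> list:
    """One TFPF voxel per sliding window of a trial.

    The windows must already be band-limited (the PLV slice takes the
    analytic-signal phase of the data as given).
    """
    if len(segments) == 0:
        raise ValueError(f"trial {segments.trial_id!r} has no segments")
    fs = segments.fs if fs is None else fs
    voxels = []
    for k, seg in enumerate(segments):
        slices = [
            connectivity_matrix(seg, fs, band, kind, segment_index=k).values
            for kind in FEATURE_KINDS
        ]
        voxels.append(TFPFVoxel(values=np.stack(slices, axis=2), segment_index=k,
                                trial_id=segments.trial_id, label=segments.label))
    return voxels


def assemble_input(voxels: list, stack_mode: str = "per_segment") -> list:
    """Turn one trial's voxels into classifier samples.

    per_segment: N samples of depth 3 sharing the trial label.
    stacked: one sample of depth 3N (window-major slice order).
    """
    if not voxels:
        raise ValueError("no voxels to assemble")
    if stack_mode not in STACK_MODES:
        raise ValueError(f"stack_mode must be one of {STACK_MODES}, got {stack_mode!r}")
    trial_ids = {v.trial_id for v in voxels}
    if len(trial_ids) > 1:
        raise ValueError(f"voxels from multiple trials: {sorted(trial_ids)}")
    voxels = sorted(voxels, key=lambda v: v.segment_index)
    if stack_mode == "per_segment":
        return [
            InputSet(values=v.values, trial_id=v.trial_id, label=v.label,
                     stack_mode=stack_mode, segment_index=v.segment_index)
            for v in voxels
        ]
    stacked = np.concatenate([v.values for v in voxels], axis=2)
    return [InputSet(values=stacked, trial_id=voxels[0].trial_id,
                     label=voxels[0].label, stack_mode=stack_mode)]


def save_input_sets(input_sets: list, directory: str) -> str:
    """Serialize samples to ``arrays.npz`` plus a JSON metadata sidecar."""
    os.makedirs(directory, exist_ok=True)
    arrays = {f"sample_{k:05d}": s.values for k, s in enumerate(input_sets)}
    np.savez_compressed(os.path.join(directory, "arrays.npz"), **arrays)
    meta = [
        {"key": f"sample_{k:05d}", "trial_id": s.trial_id, "label": s.label,
         "stack_mode": s.stack_mode, "segment_index": s.segment_index}
        for k, s in enumerate(input_sets)
    ]
    with open(os.path.join(directory, "metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return directory


def load_input_sets(directory: str) -> list:
    with open(os.path.join(directory, "metadata.json")) as fh:
        meta = json.load(fh)
    with np.load(os.path.join(directory, "arrays.npz")) as npz:
        return [
            InputSet(values=npz[m["key"]], trial_id=m["trial_id"], label=m["label"],
                     stack_mode=m["stack_mode"], segment_index=m["segment_index"])
            for m in meta
        ]
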