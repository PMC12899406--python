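"""HDF5 / CSV persistence for cohorts and scalogram tensors.

Cohort layout: one HDF5 group per trial (``trial_000000`` ...) holding an
``emg`` (8, T_e) dataset and a ``velocity`` (T_k,) dataset with subject,
action, score, stage, parity and sampling rates as attributes; the
manifest is stored alongside as CSV.  Tensor files hold ``scalograms``
(N, 11, H, W), ``labels`` (N,), ``actions`` (N,) and ``subjects`` (N,);
row 0 of each scalogram is the lowest frequency.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cwt import ScalogramDataset
from .synthetic import TrialRecord

__all__ = ["save_cohort", "load_cohort", "save_tensors", "load_tensors"]


def save_cohort(path, trials: list[TrialRecord],
                manifest: pd.DataFrame | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["n_trials"] = len(trials)
        for i, tr in enumerate(trials):
            g = f.create_group(f"trial_{i:06d}")
            g.create_dataset("emg", data=tr.emg, compression="gzip")
            g.create_dataset("velocity", data=tr.velocity, compression="gzip")
            g.attrs.update({
                "subject_id": tr.subject_id, "action_id": tr.action_id,
                "parity": tr.parity, "score": tr.score, "stage": tr.stage,
                "emg_fs": tr.emg_fs, "kine_fs": tr.kine_fs,
                "trial_index": tr.trial_index,
            })
    if manifest is not None:
        manifest.to_csv(path.with_suffix(".manifest.csv"), index=False)


def load_cohort(path) -> tuple[list[TrialRecord], pd.DataFrame | None]:
    path = Path(path)
    trials = []
    with h5py.File(path, "r") as f:
        for key in sorted(k for k in f.keys() if k.startswith("trial_")):
            g = f[key]
            a = g.attrs
            trials.append(TrialRecord(
                subject_id=str(a["subject_id"]), action_id=int(a["action_id"]),
                parity=int(a["parity"]), score=int(a["score"]),
                emg=g["emg"][...], velocity=g["velocity"][...],
                stage=str(a["stage"]), emg_fs=float(a["emg_fs"]),
                kine_fs=float(a["kine_fs"]), trial_index=int(a["trial_index"]),
            ))
    manifest_path = path.with_suffix(".manifest.csv")
    manifest = pd.read_csv(manifest_path) if manifest_path.exists() else None
    return trials, manifest


def save_tensors(path, ds: ScalogramDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("scalograms", data=ds.X, compression="gzip")
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("actions", data=ds.actions)
        f.create_dataset("subjects",
                         data=np.array([str(s) for s in ds.subjects], dtype="S"))
        f.attrs["row0"] = "lowest frequency"


def load_tensors(path) -> ScalogramDataset:
    with h5py.File(path, "r") as f:
        return ScalogramDataset(
            X=f["scalograms"][...],
            labels=f["labels"][...],
            actions=f["actions"][...],
            subjects=np.array([s.decode() for s in f["subjects"][...]], dtype=object),
        )
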