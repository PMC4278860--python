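"""Persistence: HDF5 containers for sessions, features and results.

HDF5 is the canonical on-disk format (float32 datasets, sampling rates and
labels as attributes). CSV is supported as a plain-text interchange format
for both the neural matrix and the kinematics; EDF neural recordings can be
read through MNE when available and paired with CSV kinematics.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import FEATURE_TYPES, FeatureTensor
from .synth import RecordingSession

__all__ = [
    "write_session",
    "read_session",
    "write_features",
    "read_features",
    "session_to_csv",
    "session_from_csv",
    "read_neural_edf",
    "write_results",
]


def _as_str(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


def write_session(session: RecordingSession, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("neural", data=session.neural.astype(np.float32))
        f.create_dataset("kinematics", data=session.kinematics.astype(np.float32))
        f.attrs["fs_neural"] = session.fs_neural
        f.attrs["fs_kin"] = session.fs_kin
        f.attrs["channel_labels"] = [s.encode() for s in session.channel_labels]
        gt = session.ground_truth
        if gt:
            g = f.create_group("ground_truth")
            g.create_dataset("drive", data=np.asarray(gt["drive"], dtype=np.float32))
            info = gt["informative"]
            g.create_dataset("informative_channel", data=info["channel"].to_numpy(dtype=np.int64))
            g.create_dataset(
                "informative_feature_type",
                data=[s.encode() for s in info["feature_type"]],
            )
            g.create_dataset("informative_gain", data=info["gain"].to_numpy(dtype=np.float64))
            g.create_dataset("informative_lag_ms", data=info["lag_ms"].to_numpy(dtype=np.float64))


def read_session(path: str | Path) -> RecordingSession:
    with h5py.File(path, "r") as f:
        for key in ("neural", "kinematics"):
            if key not in f:
                raise ValueError(f"missing dataset {key!r} in {path}")
        for key in ("fs_neural", "fs_kin"):
            if key not in f.attrs:
                raise ValueError(f"missing attribute {key!r} in {path}")
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = {
                "drive": g["drive"][...].astype(float),
                "informative": pd.DataFrame(
                    {
                        "channel": g["informative_channel"][...],
                        "feature_type": [_as_str(s) for s in g["informative_feature_type"][...]],
                        "gain": g["informative_gain"][...],
                        "lag_ms": g["informative_lag_ms"][...],
                    }
                ),
            }
        return RecordingSession(
            neural=f["neural"][...],
            kinematics=f["kinematics"][...],
            fs_neural=float(f.attrs["fs_neural"]),
            fs_kin=float(f.attrs["fs_kin"]),
            channel_labels=[_as_str(s) for s in f.attrs["channel_labels"]],
            ground_truth=gt,
        )


def write_features(ft: FeatureTensor, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=ft.values.astype(np.float32))
        if ft.kinematics is not None:
            f.create_dataset("kinematics", data=ft.kinematics.astype(np.float32))
        f.attrs["fs"] = ft.fs
        f.attrs["trim_margin_s"] = ft.trim_margin_s
        f.attrs["channel_labels"] = [s.encode() for s in ft.channel_labels]
        f.attrs["feature_types"] = [s.encode() for s in ft.feature_types]


def read_features(path: str | Path) -> FeatureTensor:
    with h5py.File(path, "r") as f:
        return FeatureTensor(
            values=f["features"][...].astype(float),
            channel_labels=[_as_str(s) for s in f.attrs["channel_labels"]],
            feature_types=tuple(_as_str(s) for s in f.attrs["feature_types"]),
            fs=float(f.attrs["fs"]),
            trim_margin_s=float(f.attrs["trim_margin_s"]),
            kinematics=f["kinematics"][...].astype(float) if "kinematics" in f else None,
        )


def session_to_csv(session: RecordingSession, neural_path: str | Path, kin_path: str | Path) -> None:
    """Plain-text interchange: one column per channel / axis, row per sample."""
    pd.DataFrame(session.neural.T, columns=session.channel_labels).to_csv(neural_path, index=False)
    pd.DataFrame(session.kinematics.T, columns=["height", "depth", "lateral"]).to_csv(kin_path, index=False)


def session_from_csv(
    neural_path: str | Path, kin_path: str | Path, fs_neural: float = 1000.0, fs_kin: float = 100.0
) -> RecordingSession:
    neural = pd.read_csv(neural_path)
    kin = pd.read_csv(kin_path)
    return RecordingSession(
        neural=neural.to_numpy().T,
        kinematics=kin.to_numpy().T,
        fs_neural=fs_neural,
        fs_kin=fs_kin,
        channel_labels=list(neural.columns),
    )


def read_neural_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read a neural matrix (µV), its rate and labels from an EDF file."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def write_results(results: dict, path: str | Path) -> None:
    """Persist per-target cross-validation results (and nulls) to HDF5."""
    with h5py.File(path, "w") as f:
        for target, block in results.items():
            g = f.create_group(target)
            cv = block["cv"]
            g.attrs["n_inputs"] = cv.n_inputs
            g.attrs["median_r"] = cv.median_r
            g.create_dataset("fold_r", data=cv.fold_r)
            g.create_dataset("fold_z", data=cv.fold_z)
            g.create_dataset("fold_n_test", data=np.array([fr.n_test for fr in cv.folds]))
            for i, fr in enumerate(cv.folds):
                fg = g.create_group(f"fold{i}")
                fg.create_dataset("predicted", data=fr.predicted.astype(np.float32))
                fg.create_dataset("observed", data=fr.observed.astype(np.float32))
                fg.attrs["test_span"] = fr.test_span
                sel = fr.selected
                fg.create_dataset("sel_channel", data=[s.channel.encode() for s in sel])
                fg.create_dataset("sel_feature_type", data=[s.feature_type.encode() for s in sel])
                fg.create_dataset("sel_lag_ms", data=np.array([s.best_lag_ms for s in sel]))
                fg.create_dataset("sel_train_r", data=np.array([s.train_r for s in sel]))
            if block.get("null") is not None:
                null = block["null"]
                ng = g.create_group("null")
                ng.create_dataset("r", data=null.r)
                ng.attrs["mode"] = null.mode
                ng.attrs["seed"] = null.seed
            if "p_corrected" in block:
                g.attrs["p_corrected"] = block["p_corrected"]
                g.attrs["significant"] = block["significant"]
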