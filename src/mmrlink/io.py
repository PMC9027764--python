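"""Shared I/O: cohort containers, TSV exports, checksums, manifests.

Array data live in a single HDF5 container per cohort (documented layout
below); every table also has a lossless long-format TSV twin so a cohort
can be shipped as plain text.  Floats in TSVs are written with ``%.17g``
(round-trip exact for float64).

HDF5 layout (``cohort.h5``)::

    /schema_version        attr, int
    /time_start            attr, seconds
    /sample_rate           attr, Hz
    /label_names           dataset of str
    /evoked/<subject>/<condition>   (n_labels, n_times, 3) float64

``mmr.h5`` holds ``/mmr`` (subjects x labels x times), ``/subject_ids``,
``/label_names`` and the same time attrs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .mmr import LabelEvoked, MMRMatrix

__all__ = [
    "SCHEMA_VERSION",
    "write_tsv",
    "read_tsv",
    "write_evoked_h5",
    "read_evoked_h5",
    "evoked_to_long_frame",
    "long_frame_to_evoked",
    "write_mmr_h5",
    "read_mmr_h5",
    "mmr_to_long_frame",
    "write_adjacency",
    "read_adjacency",
    "file_sha256",
    "write_manifest",
]

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.17g"


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", **kwargs)


def write_evoked_h5(evoked: dict[tuple[str, str], LabelEvoked], path) -> None:
    if not evoked:
        raise ValueError("no evoked responses to write")
    ref = next(iter(evoked.values()))
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["time_start"] = ref.time_start
        f.attrs["sample_rate"] = ref.sample_rate
        f.create_dataset(
            "label_names", data=np.array(ref.label_names, dtype=object),
            dtype=h5py.string_dtype(),
        )
        grp = f.create_group("evoked")
        for (subject_id, condition), ev in sorted(evoked.items()):
            grp.create_dataset(f"{subject_id}/{condition}", data=ev.data)


def read_evoked_h5(path) -> dict[tuple[str, str], LabelEvoked]:
    out: dict[tuple[str, str], LabelEvoked] = {}
    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs:
            raise ValueError(f"{path}: missing schema_version attribute")
        time_start = float(f.attrs["time_start"])
        sample_rate = float(f.attrs["sample_rate"])
        label_names = [s.decode() if isinstance(s, bytes) else str(s) for s in f["label_names"][()]]
        for subject_id in f["evoked"]:
            for condition in f["evoked"][subject_id]:
                out[(subject_id, condition)] = LabelEvoked(
                    subject_id=subject_id,
                    condition=condition,
                    data=f["evoked"][subject_id][condition][()],
                    time_start=time_start,
                    sample_rate=sample_rate,
                    label_names=label_names,
                )
    return out


_EVOKED_COLUMNS = ["subject_id", "condition", "label", "component", "time_index", "value"]


def evoked_to_long_frame(evoked: dict[tuple[str, str], LabelEvoked]) -> pd.DataFrame:
    """Lossless long-format TSV twin of the evoked container."""
    frames = []
    for (subject_id, condition), ev in sorted(evoked.items()):
        L, T, _ = ev.data.shape
        lab_idx, t_idx, comp = np.meshgrid(
            np.arange(L), np.arange(T), np.arange(3), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "condition": condition,
                    "label": np.asarray(ev.label_names)[lab_idx.ravel()],
                    "component": comp.ravel(),
                    "time_index": t_idx.ravel(),
                    "value": ev.data.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def long_frame_to_evoked(
    frame: pd.DataFrame,
    time_start: float,
    sample_rate: float,
    label_names: list[str],
) -> dict[tuple[str, str], LabelEvoked]:
    missing = [c for c in _EVOKED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"evoked table missing column(s): {', '.join(missing)}")
    n_times = int(frame["time_index"].max()) + 1
    label_pos = {name: i for i, name in enumerate(label_names)}
    out: dict[tuple[str, str], LabelEvoked] = {}
    for (subject_id, condition), grp in frame.groupby(
        ["subject_id", "condition"], sort=True
    ):
        data = np.zeros((len(label_names), n_times, 3))
        bad = ~grp["label"].isin(label_pos)
        if bad.any():
            raise ValueError(
                f"unknown label {grp.loc[bad.idxmax(), 'label']!r} in evoked table"
            )
        lab = grp["label"].map(label_pos).to_numpy(dtype=int)
        data[lab, grp["time_index"].to_numpy(int), grp["component"].to_numpy(int)] = (
            grp["value"].to_numpy(float)
        )
        out[(subject_id, condition)] = LabelEvoked(
            subject_id=subject_id,
            condition=condition,
            data=data,
            time_start=time_start,
            sample_rate=sample_rate,
            label_names=list(label_names),
        )
    return out


def write_mmr_h5(mmr: MMRMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["time_start"] = mmr.time_start
        f.attrs["sample_rate"] = mmr.sample_rate
        f.create_dataset("mmr", data=mmr.data)
        f.create_dataset(
            "subject_ids", data=np.array(mmr.subject_ids, dtype=object),
            dtype=h5py.string_dtype(),
        )
        f.create_dataset(
            "label_names", data=np.array(mmr.label_names, dtype=object),
            dtype=h5py.string_dtype(),
        )


def read_mmr_h5(path) -> MMRMatrix:
    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs:
            raise ValueError(f"{path}: missing schema_version attribute")
        decode = lambda xs: [x.decode() if isinstance(x, bytes) else str(x) for x in xs]  # noqa: E731
        return MMRMatrix(
            data=f["mmr"][()],
            subject_ids=decode(f["subject_ids"][()]),
            label_names=decode(f["label_names"][()]),
            time_start=float(f.attrs["time_start"]),
            sample_rate=float(f.attrs["sample_rate"]),
        )


def mmr_to_long_frame(mmr: MMRMatrix) -> pd.DataFrame:
    S, L, T = mmr.data.shape
    s_idx, l_idx, t_idx = np.meshgrid(
        np.arange(S), np.arange(L), np.arange(T), indexing="ij"
    )
    return pd.DataFrame(
        {
            "subject_id": np.asarray(mmr.subject_ids)[s_idx.ravel()],
            "label": np.asarray(mmr.label_names)[l_idx.ravel()],
            "time_index": t_idx.ravel(),
            "mmr": mmr.data.ravel(),
        }
    )


def write_adjacency(edges: np.ndarray, label_names: list[str], path) -> None:
    names = np.asarray(label_names)
    frame = pd.DataFrame(
        {"label_a": names[edges[:, 0]], "label_b": names[edges[:, 1]]}
    )
    write_tsv(frame, path)


def read_adjacency(path, label_names: list[str]) -> np.ndarray:
    frame = read_tsv(path)
    for col in ("label_a", "label_b"):
        if col not in frame.columns:
            raise ValueError(f"adjacency file missing column {col!r}")
    pos = {name: i for i, name in enumerate(label_names)}
    bad = ~frame["label_a"].isin(pos) | ~frame["label_b"].isin(pos)
    if bad.any():
        raise ValueError(
            f"adjacency refers to unknown label: {dict(frame.loc[bad.idxmax()])}"
        )
    a = frame["label_a"].map(pos).to_numpy(dtype=int)
    b = frame["label_b"].map(pos).to_numpy(dtype=int)
    return np.stack([a, b], axis=1)


def file_sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    path,
    *,
    config: dict,
    master_seed: int,
    stage_seeds: dict[str, int],
    outputs: dict[str, str],
    version: str,
    timestamps: dict | None = None,
) -> None:
    """Deterministic JSON run manifest.

    Timestamps are omitted unless explicitly supplied so that two runs
    with the same seed produce byte-identical manifests.
    """
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": version,
        "master_seed": master_seed,
        "stage_seeds": stage_seeds,
        "config": config,
        "outputs": outputs,
        "timestamps": timestamps,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
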