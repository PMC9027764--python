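"""Mismatch-response (MMR) computation from vector source estimates.

The entry point of the pipeline is label-level source activity: for each
subject and condition a ``labels x time x 3`` array of free-orientation
dipole vectors in arbitrary source-estimate units.  The MMR is the
Euclidean magnitude of the deviant-minus-standard difference vector at
each label and time sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelEvoked",
    "MMRMatrix",
    "compute_mmr",
    "compute_mmr_matrix",
    "average_labels",
    "vertex_mmr",
    "roi_window_mean",
    "window_to_samples",
    "log_mmr",
    "select_preceding_standards",
]


@dataclass
class LabelEvoked:
    """Label-level evoked response for one subject and one condition.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    condition : str
        Either ``"standard"`` or ``"deviant"``.
    data : ndarray, shape (n_labels, n_times, 3)
        Free-orientation dipole vector time courses per label.
    time_start : float
        Time of the first sample in seconds (negative = pre-stimulus).
    sample_rate : float
        Sampling rate in Hz.
    label_names : list of str
        Ordered label names; the order is the contract shared by all
        subjects and conditions of a cohort.
    """

    subject_id: str
    condition: str
    data: np.ndarray
    time_start: float
    sample_rate: float
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(
                f"data must be (n_labels, n_times, 3); got {self.data.shape}"
            )
        if self.condition not in ("standard", "deviant"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.label_names and len(self.label_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.label_names)} label names for "
                f"{self.data.shape[0]} labels"
            )
        if not self.label_names:
            self.label_names = [f"label_{i:03d}" for i in range(self.data.shape[0])]

    @property
    def n_labels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.time_start + np.arange(self.n_times) / self.sample_rate


@dataclass
class MMRMatrix:
    """Per-subject MMR magnitudes: ``subjects x labels x time``, all >= 0."""

    data: np.ndarray
    subject_ids: list[str]
    label_names: list[str]
    time_start: float
    sample_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_subjects, n_labels, n_times)")
        if np.any(self.data < 0):
            raise ValueError("MMR magnitudes must be nonnegative")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if len(self.label_names) != self.data.shape[1]:
            raise ValueError("label_names length mismatch")

    @property
    def times(self) -> np.ndarray:
        return self.time_start + np.arange(self.data.shape[2]) / self.sample_rate

    def subset(self, subject_ids: list[str]) -> "MMRMatrix":
        """Return a new matrix restricted to ``subject_ids`` (in that order)."""
        idx = [self.subject_ids.index(s) for s in subject_ids]
        return MMRMatrix(
            data=self.data[idx],
            subject_ids=list(subject_ids),
            label_names=self.label_names,
            time_start=self.time_start,
            sample_rate=self.sample_rate,
        )


def _check_aligned(standard: LabelEvoked, deviant: LabelEvoked) -> None:
    if standard.subject_id != deviant.subject_id:
        raise ValueError(
            f"subject mismatch: {standard.subject_id!r} vs {deviant.subject_id!r}"
        )
    if standard.data.shape != deviant.data.shape:
        raise ValueError(
            f"shape mismatch: {standard.data.shape} vs {deviant.data.shape}"
        )
    for i, (a, b) in enumerate(zip(standard.label_names, deviant.label_names)):
        if a != b:
            raise ValueError(f"label mismatch at index {i}: {a!r} vs {b!r}")
    if standard.sample_rate != deviant.sample_rate or not np.isclose(
        standard.time_start, deviant.time_start
    ):
        raise ValueError(
            "time axis mismatch: "
            f"start {standard.time_start} vs {deviant.time_start}, "
            f"rate {standard.sample_rate} vs {deviant.sample_rate}"
        )


def compute_mmr(standard: LabelEvoked, deviant: LabelEvoked) -> np.ndarray:
    """Magnitude of the deviant-minus-standard vector difference.

    Returns
    -------
    ndarray, shape (n_labels, n_times)
        ``MMR[l, t] = || deviant[l, t, :] - standard[l, t, :] ||_2``.
    """
    _check_aligned(standard, deviant)
    diff = deviant.data - standard.data
    return np.linalg.norm(diff, axis=2)


def compute_mmr_matrix(
    pairs: list[tuple[LabelEvoked, LabelEvoked]],
) -> MMRMatrix:
    """Stack per-subject MMRs from (standard, deviant) pairs into a matrix."""
    if not pairs:
        raise ValueError("no subjects supplied")
    ref = pairs[0][0]
    mats, subject_ids = [], []
    for standard, deviant in pairs:
        if standard.label_names != ref.label_names:
            raise ValueError(
                f"label ordering of {standard.subject_id!r} differs from "
                f"{ref.subject_id!r}"
            )
        mats.append(compute_mmr(standard, deviant))
        subject_ids.append(standard.subject_id)
    return MMRMatrix(
        data=np.stack(mats),
        subject_ids=subject_ids,
        label_names=list(ref.label_names),
        time_start=ref.time_start,
        sample_rate=ref.sample_rate,
    )


def average_labels(
    vertex_data: np.ndarray,
    label_map: np.ndarray,
    label_names: list[str],
) -> np.ndarray:
    """Average vertex-level vector data within labels.

    Parameters
    ----------
    vertex_data : ndarray, shape (n_vertices, n_times, 3)
    label_map : ndarray of int, shape (n_vertices,)
        Label index of each vertex (into ``label_names``).
    label_names : list of str

    Returns
    -------
    ndarray, shape (n_labels, n_times, 3)
        Arithmetic per-component mean over the vertices of each label.
    """
    vertex_data = np.asarray(vertex_data, dtype=float)
    label_map = np.asarray(label_map)
    if vertex_data.ndim != 3 or vertex_data.shape[2] != 3:
        raise ValueError("vertex_data must be (n_vertices, n_times, 3)")
    if label_map.shape != (vertex_data.shape[0],):
        raise ValueError("label_map must assign one label per vertex")
    n_labels = len(label_names)
    if label_map.min() < 0 or label_map.max() >= n_labels:
        raise ValueError("label_map indices out of range")
    out = np.empty((n_labels, vertex_data.shape[1], 3))
    for lab in range(n_labels):
        members = label_map == lab
        if not members.any():
            raise ValueError(f"label {label_names[lab]!r} has no vertices")
        out[lab] = vertex_data[members].mean(axis=0)
    return out


def vertex_mmr(
    standard_vertex: np.ndarray,
    deviant_vertex: np.ndarray,
    label_map: np.ndarray,
    label_names: list[str],
) -> np.ndarray:
    """Label-level MMR from vertex-level vector data.

    When vertex data are supplied, the magnitude is taken per vertex
    *before* label averaging (subtract vectors, then magnitude, then
    average within label), so the result is the label mean of vertex
    MMRs rather than the MMR of label-mean vectors.

    Returns an (n_labels, n_times) array of nonnegative magnitudes.
    """
    standard_vertex = np.asarray(standard_vertex, dtype=float)
    deviant_vertex = np.asarray(deviant_vertex, dtype=float)
    if standard_vertex.shape != deviant_vertex.shape:
        raise ValueError(
            f"shape mismatch: {standard_vertex.shape} vs {deviant_vertex.shape}"
        )
    magnitudes = np.linalg.norm(deviant_vertex - standard_vertex, axis=2)
    label_map = np.asarray(label_map)
    out = np.empty((len(label_names), magnitudes.shape[1]))
    for lab in range(len(label_names)):
        members = label_map == lab
        if not members.any():
            raise ValueError(f"label {label_names[lab]!r} has no vertices")
        out[lab] = magnitudes[members].mean(axis=0)
    return out


def window_to_samples(
    time_start: float, sample_rate: float, n_times: int, window: tuple[float, float]
) -> tuple[int, int]:
    """Map a ``[start, end)`` window in seconds to sample indices.

    The window is closed on the left, open on the right: a sample at time
    ``t`` is included iff ``start <= t < end``.  A small tolerance absorbs
    floating-point representation of grid-aligned boundaries.
    """
    start, end = window
    if end <= start:
        raise ValueError(f"window end {end} must exceed start {start}")
    eps = 1e-9
    lo = int(np.ceil((start - time_start) * sample_rate - eps))
    hi = int(np.ceil((end - time_start) * sample_rate - eps))
    lo = max(lo, 0)
    hi = min(hi, n_times)
    if hi <= lo:
        raise ValueError(
            f"window {window} contains no samples on the "
            f"{sample_rate} Hz grid starting at {time_start}"
        )
    return lo, hi


def roi_window_mean(
    mmr: MMRMatrix, roi_labels: list[str], window: tuple[float, float]
) -> np.ndarray:
    """Mean MMR over an ROI label set and a time window, per subject."""
    if not roi_labels:
        raise ValueError("roi_labels is empty")
    idx = []
    for name in roi_labels:
        try:
            idx.append(mmr.label_names.index(name))
        except ValueError:
            raise ValueError(f"unknown label {name!r}") from None
    lo, hi = window_to_samples(
        mmr.time_start, mmr.sample_rate, mmr.data.shape[2], window
    )
    return mmr.data[:, idx, lo:hi].mean(axis=(1, 2))


def log_mmr(x, floor: float = 1e-12, clamp: bool = False):
    """Natural log of positive MMR values.

    Values below ``floor`` raise by default; with ``clamp=True`` they are
    clamped to the floor first (useful for noisy real data where a window
    mean can be arbitrarily small).
    """
    arr = np.asarray(x, dtype=float)
    if clamp:
        arr = np.maximum(arr, floor)
    elif np.any(arr < floor):
        bad = float(np.min(arr))
        raise ValueError(f"value {bad} below log floor {floor}")
    out = np.log(arr)
    return out if out.ndim else float(out)


def select_preceding_standards(trial_labels) -> np.ndarray:
    """Indices of the standard trials immediately preceding each deviant.

    Exactly one index per deviant; the returned set has the same
    cardinality as the number of deviants.
    """
    labels = list(trial_labels)
    for lab in labels:
        if lab not in ("standard", "deviant"):
            raise ValueError(f"unknown trial label {lab!r}")
    out = []
    for i, lab in enumerate(labels):
        if lab == "deviant":
            if i == 0:
                raise ValueError("deviant at position 0 has no preceding standard")
            if labels[i - 1] != "standard":
                raise ValueError(
                    f"deviant at position {i} not preceded by a standard"
                )
            out.append(i - 1)
    return np.asarray(out, dtype=int)
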