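"""Synthetic cohorts with the statistical structure the analysis assumes.

Two groups of subjects are simulated.  Group ``"nonnative"`` (coded 0)
has a larger post-200 ms mismatch response; group ``"native"`` (coded 1)
carries a log-linear coupling between MMR amplitude and latent
discrimination sensitivity, restricted to left frontal/temporal labels.
Behavior follows equal-variance signal detection theory, so the scored
d' recovers the planted sensitivity in expectation.

Waveform parameterization
-------------------------
Each condition shares two early Gaussian bumps (peaks at 100 and 130 ms,
sigma 20 ms) whose per-label amplitudes are drawn once per subject; the
deviant additionally carries a Gaussian bump centred in the coupling
window (sigma = window width / 6) whose per-label amplitude is

    A[l] = exp(log(base_amp[group]) + delta_i
               + gamma[group] * s_i * 1[l in coupling ROI] + eps_l)

where ``s_i`` is the subject's latent sensitivity, ``delta_i ~
N(0, subject_log_sd[group])`` is a per-subject global amplitude factor
(both groups show between-subject MMR variability; in the coupled group
most of it comes from the coupling itself, in the uncoupled group it is
idiosyncratic) and ``eps_l ~ N(0, amp_log_jitter)`` is per-label jitter.  All label time
courses point along a fixed random unit 3-vector per label per subject,
plus i.i.d. Gaussian component noise.

Seed policy
-----------
One master seed.  Subject-level child seeds are drawn from
``SeedSequence(master).generate_state(...)``; within a subject,
sub-streams are ``SeedSequence((child, k))`` with k = 1 shared waveform,
2 standard-condition noise, 3 deviant-condition noise, 4 behavior.
Truth draws use ``SeedSequence((master, 0))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .mmr import LabelEvoked

__all__ = [
    "SimulationConfig",
    "OddballSequence",
    "SubjectTruth",
    "SimulatedCohort",
    "default_roi_labels",
    "label_adjacency",
    "generate_oddball_sequence",
    "simulate_ax_trials",
    "simulate_subject_evoked",
    "simulate_cohort",
]

GROUPS = ("nonnative", "native")

_STREAM_SHARED = 1
_STREAM_STANDARD = 2
_STREAM_DEVIANT = 3
_STREAM_BEHAVIOR = 4


def default_roi_labels(n_labels: int) -> dict[str, tuple[int, ...]]:
    """Carve the four a-priori ROIs out of ``n_labels`` generic labels.

    The first half of the label list plays the left hemisphere, the
    second half the right; each ROI takes 5 labels (fewer for tiny
    atlases, always >= 1).
    """
    half = n_labels // 2
    size = max(1, min(5, half // 2))
    if half < 2:
        raise ValueError(f"n_labels={n_labels} too small to host 4 disjoint ROIs")
    return {
        "left_IFG": tuple(range(0, size)),
        "left_STG": tuple(range(size, 2 * size)),
        "right_IFG": tuple(range(half, half + size)),
        "right_STG": tuple(range(half + size, half + 2 * size)),
    }


def label_adjacency(n_labels: int, width: int = 5) -> np.ndarray:
    """Synthetic spatial adjacency: one 4-connected grid per hemisphere.

    Labels ``0 .. n//2-1`` form the left hemisphere, the rest the right;
    hemispheres are not connected.  Returns an undirected edge list of
    shape (n_edges, 2) with each pair listed once (a < b).
    """
    edges = []
    half = n_labels // 2
    for offset, size in ((0, half), (half, n_labels - half)):
        for i in range(size):
            r, c = divmod(i, width)
            if c + 1 < width and i + 1 < size:
                edges.append((offset + i, offset + i + 1))
            if i + width < size:
                edges.append((offset + i, offset + i + width))
    return np.asarray(edges, dtype=int)


@dataclass
class SimulationConfig:
    """Knobs for the synthetic cohort generator.

    Per-group fields are mappings keyed by ``"nonnative"`` / ``"native"``.
    Default latent sensitivities are kept moderate: with 10 trials per
    pairing, the scored d' ceiling (all-correct tables) is ~3.9, and
    planting larger latent means just saturates the scale.
    """

    n_per_group: int = 15
    n_labels: int = 150
    roi_label_ids: dict[str, tuple[int, ...]] | None = None
    epoch_window: tuple[float, float] = (-0.100, 0.900)
    sample_rate: float = 200.0
    group_means_dprime: dict[str, float] = field(
        default_factory=lambda: {"nonnative": 1.0, "native": 1.5}
    )
    group_sds_dprime: dict[str, float] = field(
        default_factory=lambda: {"nonnative": 0.3, "native": 1.2}
    )
    criterion_mean: float = 0.75
    criterion_sd: float = 0.05
    mmr_base_amplitude: dict[str, float] = field(
        default_factory=lambda: {"nonnative": 3.0, "native": 1.5}
    )
    coupling_gamma: dict[str, float] = field(
        default_factory=lambda: {"nonnative": 0.0, "native": 0.42}
    )
    coupling_rois: tuple[str, ...] = ("left_IFG", "left_STG")
    coupling_window: tuple[float, float] = (0.200, 0.500)
    amp_log_jitter: float = 0.10
    subject_log_sd: dict[str, float] = field(
        default_factory=lambda: {"nonnative": 0.6, "native": 0.15}
    )
    early_amplitude: float = 2.0
    noise_sd: float = 0.05
    n_trials_per_pairing: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_label_ids is None:
            self.roi_label_ids = default_roi_labels(self.n_labels)
        self.validate()

    def validate(self) -> None:
        problems = []
        if self.n_per_group < 3:
            problems.append("n_per_group must be >= 3")
        if self.sample_rate <= 0:
            problems.append("sample_rate must be > 0")
        start, end = self.epoch_window
        if not (start < 0 < end):
            problems.append("epoch_window must straddle 0 (start < 0 < end)")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if self.n_trials_per_pairing < 1:
            problems.append("n_trials_per_pairing must be >= 1")
        seen: set[int] = set()
        for name, ids in self.roi_label_ids.items():
            ids_set = set(ids)
            if seen & ids_set:
                problems.append(f"ROI {name!r} overlaps another ROI")
            if any(i < 0 or i >= self.n_labels for i in ids_set):
                problems.append(f"ROI {name!r} has label ids outside 0..{self.n_labels - 1}")
            seen |= ids_set
        for roi in self.coupling_rois:
            if roi not in self.roi_label_ids:
                problems.append(f"coupling ROI {roi!r} not in roi_label_ids")
        for grp in GROUPS:
            for mapping, label in (
                (self.group_means_dprime, "group_means_dprime"),
                (self.group_sds_dprime, "group_sds_dprime"),
                (self.mmr_base_amplitude, "mmr_base_amplitude"),
                (self.coupling_gamma, "coupling_gamma"),
                (self.subject_log_sd, "subject_log_sd"),
            ):
                if grp not in mapping:
                    problems.append(f"{label} missing group {grp!r}")
        w0, w1 = self.coupling_window
        if not (start <= w0 < w1 <= end):
            problems.append("coupling_window must lie inside epoch_window")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    @property
    def n_times(self) -> int:
        start, end = self.epoch_window
        return int(round((end - start) * self.sample_rate)) + 1

    @property
    def label_names(self) -> list[str]:
        return [f"label_{i:03d}" for i in range(self.n_labels)]

    def coupling_label_ids(self) -> frozenset[int]:
        ids: set[int] = set()
        for roi in self.coupling_rois:
            ids |= set(self.roi_label_ids[roi])
        return frozenset(ids)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OddballSequence:
    """Ordered standard/deviant trial labels with per-trial SOA in ms."""

    trial_labels: list[str]
    soa_ms: np.ndarray

    def __post_init__(self) -> None:
        self.soa_ms = np.asarray(self.soa_ms, dtype=float)
        if len(self.trial_labels) != len(self.soa_ms):
            raise ValueError("trial_labels and soa_ms lengths differ")

    @property
    def n_deviant(self) -> int:
        return sum(1 for t in self.trial_labels if t == "deviant")


@dataclass
class SubjectTruth:
    """What was planted for one subject, recorded exactly as drawn."""

    subject_id: str
    group: str
    sensitivity: float
    criterion: float
    amplitudes: np.ndarray  # per-label deviant bump amplitude
    evoked_seed: int
    behavior_seed: int


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    evoked: dict[tuple[str, str], LabelEvoked]  # (subject_id, condition)
    behavior: pd.DataFrame
    groups: pd.DataFrame
    truth: list[SubjectTruth]
    adjacency: np.ndarray

    @property
    def subject_ids(self) -> list[str]:
        return list(self.groups["subject_id"])

    def truth_frame(self) -> pd.DataFrame:
        """Long-format truth table (one row per subject x label)."""
        rows = []
        for t in self.truth:
            for lab, amp in enumerate(t.amplitudes):
                rows.append(
                    {
                        "subject_id": t.subject_id,
                        "group": t.group,
                        "sensitivity": t.sensitivity,
                        "criterion": t.criterion,
                        "label": self.config.label_names[lab],
                        "amplitude": amp,
                    }
                )
        return pd.DataFrame(rows)


def generate_oddball_sequence(
    n_standard: int,
    n_deviant: int,
    min_separation: int,
    soa_nominal: float = 800.0,
    soa_jitter: float = 50.0,
    seed: int = 0,
) -> OddballSequence:
    """Random oddball sequence with a minimum standard run before each deviant.

    Each deviant is preceded by at least ``min_separation`` consecutive
    standards (this also holds before the first deviant).  Construction:
    reserve ``min_separation`` standards in front of every deviant, then
    scatter the surplus standards uniformly over the ``n_deviant + 1``
    gaps.
    """
    if n_standard < 0 or n_deviant < 0:
        raise ValueError("trial counts must be nonnegative")
    reserved = min_separation * n_deviant
    if n_standard < reserved:
        raise ValueError(
            f"infeasible separation constraint: need at least "
            f"min_separation*n_deviant = {reserved} standards, got {n_standard}"
        )
    rng = np.random.default_rng(seed)
    surplus = n_standard - reserved
    # multinomial scatter of surplus standards over gaps
    gap_counts = rng.multinomial(surplus, np.full(n_deviant + 1, 1.0 / (n_deviant + 1)))
    labels: list[str] = []
    for i in range(n_deviant):
        labels.extend(["standard"] * (gap_counts[i] + min_separation))
        labels.append("deviant")
    labels.extend(["standard"] * gap_counts[n_deviant])
    n_total = n_standard + n_deviant
    soa = rng.uniform(soa_nominal - soa_jitter, soa_nominal + soa_jitter, size=n_total)
    return OddballSequence(trial_labels=labels, soa_ms=soa)


def simulate_ax_trials(
    sensitivity: float,
    criterion: float,
    n_per_pairing: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """AX same/different responses under equal-variance SDT.

    The decision variable is N(sensitivity, 1) on different-pair trials
    (AB, BA) and N(0, 1) on same-pair trials (AA, BB); the subject
    responds "different" iff it exceeds ``criterion``.
    """
    if n_per_pairing < 1:
        raise ValueError("n_per_pairing must be >= 1")
    rng = np.random.default_rng(seed)
    pairings = ["AA", "AB", "BB", "BA"]
    pair_col = np.repeat(pairings, n_per_pairing)
    order = rng.permutation(len(pair_col))
    pair_col = pair_col[order]
    is_diff = np.isin(pair_col, ["AB", "BA"])
    dv = rng.normal(0.0, 1.0, size=len(pair_col)) + np.where(is_diff, sensitivity, 0.0)
    response = np.where(dv > criterion, "different", "same")
    return pd.DataFrame(
        {
            "pair_type": pair_col,
            "trial_index": np.arange(len(pair_col)),
            "response": response,
        }
    )


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def simulate_subject_evoked(
    config: SimulationConfig,
    truth: SubjectTruth,
    condition: str,
    seed: int | None = None,
) -> LabelEvoked:
    """One subject's label-level evoked response for one condition.

    Both conditions share the early bumps and per-label orientation
    (drawn from the subject seed independently of condition); the deviant
    adds the planted post-200 ms bump with per-label amplitudes from
    ``truth.amplitudes``.  With ``noise_sd = 0`` the magnitude of
    (deviant - standard) at the bump peak equals the planted amplitude
    exactly.
    """
    if condition not in ("standard", "deviant"):
        raise ValueError(f"unknown condition {condition!r}")
    if seed is None:
        seed = truth.evoked_seed
    times = config.epoch_window[0] + np.arange(config.n_times) / config.sample_rate
    L, T = config.n_labels, config.n_times

    shared_rng = np.random.default_rng(np.random.SeedSequence((seed, _STREAM_SHARED)))
    orient = shared_rng.normal(size=(L, 3))
    orient /= np.linalg.norm(orient, axis=1, keepdims=True)
    a1 = config.early_amplitude * shared_rng.uniform(0.8, 1.2, size=L)
    a2 = config.early_amplitude * shared_rng.uniform(0.8, 1.2, size=L)
    wave = a1[:, None] * _gauss(times, 0.100, 0.020) + a2[:, None] * _gauss(
        times, 0.130, 0.020
    )

    if condition == "deviant":
        w0, w1 = config.coupling_window
        center = 0.5 * (w0 + w1)
        sigma = (w1 - w0) / 6.0
        wave = wave + truth.amplitudes[:, None] * _gauss(times, center, sigma)

    data = wave[:, :, None] * orient[None, None, :].reshape(L, 1, 3)

    stream = _STREAM_STANDARD if condition == "standard" else _STREAM_DEVIANT
    noise_rng = np.random.default_rng(np.random.SeedSequence((seed, stream)))
    if config.noise_sd > 0:
        data = data + noise_rng.normal(0.0, config.noise_sd, size=(L, T, 3))

    return LabelEvoked(
        subject_id=truth.subject_id,
        condition=condition,
        data=data,
        time_start=config.epoch_window[0],
        sample_rate=config.sample_rate,
        label_names=config.label_names,
    )


def _draw_truth(config: SimulationConfig) -> list[SubjectTruth]:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
    child = np.random.SeedSequence(config.seed).generate_state(
        4 * config.n_per_group, dtype=np.uint64
    )
    coupling_ids = np.zeros(config.n_labels, dtype=bool)
    coupling_ids[list(config.coupling_label_ids())] = True
    truths = []
    k = 0
    for group in GROUPS:
        mu = config.group_means_dprime[group]
        sd = config.group_sds_dprime[group]
        gamma = config.coupling_gamma[group]
        log_base = np.log(config.mmr_base_amplitude[group])
        for j in range(config.n_per_group):
            # latent sensitivity truncated at 0: d' near 0 is meaningful,
            # negative planted sensitivity is not
            a = (0.0 - mu) / sd
            s = float(
                stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng)
            )
            c = float(rng.normal(config.criterion_mean, config.criterion_sd))
            delta = rng.normal(0.0, config.subject_log_sd[group])
            eps = rng.normal(0.0, config.amp_log_jitter, size=config.n_labels)
            log_amp = log_base + delta + gamma * s * coupling_ids + eps
            truths.append(
                SubjectTruth(
                    subject_id=f"{group}_{j:02d}",
                    group=group,
                    sensitivity=s,
                    criterion=c,
                    amplitudes=np.exp(log_amp),
                    evoked_seed=int(child[2 * k]),
                    behavior_seed=int(child[2 * k + 1]),
                )
            )
            k += 1
    return truths


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full synthetic cohort: evoked pairs, AX behavior, groups, truth.

    Deterministic given ``config.seed`` (bitwise on serialized output).
    """
    config.validate()
    truths = _draw_truth(config)
    evoked: dict[tuple[str, str], LabelEvoked] = {}
    behavior_frames = []
    for t in truths:
        for condition in ("standard", "deviant"):
            evoked[(t.subject_id, condition)] = simulate_subject_evoked(
                config, t, condition
            )
        trials = simulate_ax_trials(
            t.sensitivity,
            t.criterion,
            config.n_trials_per_pairing,
            seed=np.random.SeedSequence((t.behavior_seed, _STREAM_BEHAVIOR)),
        )
        trials.insert(0, "subject_id", t.subject_id)
        trials.insert(1, "group", t.group)
        behavior_frames.append(trials)
    behavior = pd.concat(behavior_frames, ignore_index=True)
    groups = pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in truths],
            "group": [t.group for t in truths],
        }
    )
    return SimulatedCohort(
        config=config,
        evoked=evoked,
        behavior=behavior,
        groups=groups,
        truth=truths,
        adjacency=label_adjacency(config.n_labels),
    )
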