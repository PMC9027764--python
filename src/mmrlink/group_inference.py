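"""Two-sample inference: t tests, Cohen's d, and the TFCE permutation map.

The spatiotemporal cluster test enhances a labels x time |t| map with
threshold-free cluster enhancement (TFCE) and calibrates per-sample
p-values against the max-TFCE distribution over group-label
permutations, giving strong familywise control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TTestResult",
    "TFCEMap",
    "two_sample_t",
    "two_sample_t_from_stats",
    "welch_df",
    "cohen_d_from_t",
    "t_statistic_map",
    "tfce_enhance",
    "tfce_permutation_test",
]


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    tails: int
    variant: str
    cohen_d: float


def _tail_p(t: float, df: float, tails: int) -> float:
    if tails == 1:
        return float(stats.t.sf(abs(t), df))
    if tails == 2:
        return float(2.0 * stats.t.sf(abs(t), df))
    raise ValueError("tails must be 1 or 2")


def welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    """Welch-Satterthwaite degrees of freedom from sample SDs and sizes."""
    v1, v2 = s1**2 / n1, s2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def cohen_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d recovered from an independent-samples t statistic."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both sample sizes must be >= 2")
    return abs(t) * np.sqrt(1.0 / n1 + 1.0 / n2)


def two_sample_t_from_stats(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "pooled",
    tails: int = 2,
) -> TTestResult:
    """Independent two-sample t test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if sd1 == 0.0 and sd2 == 0.0:
        raise ValueError("zero variance in both samples")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if variant == "pooled":
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        se = np.sqrt(sd1**2 / n1 + sd2**2 / n2)
        df = welch_df(sd1, n1, sd2, n2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = (mean1 - mean2) / se
    d = (mean1 - mean2) / np.sqrt(sp2)
    return TTestResult(
        t=float(t), df=df, p=_tail_p(t, df, tails), tails=tails,
        variant=variant, cohen_d=float(d),
    )


def two_sample_t(x, y, variant: str = "pooled", tails: int = 2) -> TTestResult:
    """Independent two-sample t test on raw samples.

    Cohen's d is always the pooled-SD standardized mean difference,
    whichever t variant is requested.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    return two_sample_t_from_stats(
        float(x.mean()), float(x.std(ddof=1)), x.size,
        float(y.mean()), float(y.std(ddof=1)), y.size,
        variant=variant, tails=tails,
    )


def t_statistic_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized pooled two-sample t over the leading (subject) axis."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return t


def _as_edge_list(adjacency, n_labels: int) -> np.ndarray:
    """Accept an (m, 2) edge list or a square adjacency matrix."""
    adjacency = np.asarray(adjacency)
    if adjacency.ndim == 2 and adjacency.shape == (n_labels, n_labels):
        if not np.array_equal(adjacency, adjacency.T):
            raise ValueError("adjacency matrix is not symmetric")
        rows, cols = np.nonzero(np.triu(adjacency, k=1))
        return np.stack([rows, cols], axis=1)
    if adjacency.ndim == 2 and adjacency.shape[1] == 2:
        if adjacency.size and adjacency.max() >= n_labels:
            raise ValueError("adjacency edge refers to a label outside the map")
        return adjacency.astype(int)
    if adjacency.size == 0:
        return np.empty((0, 2), dtype=int)
    raise ValueError("adjacency must be an (m, 2) edge list or a square matrix")


def _spatiotemporal_edges(label_edges: np.ndarray, n_labels: int, n_times: int) -> np.ndarray:
    """Edges over flattened (label, time) nodes: spatial within a time
    sample, temporal between the same label at adjacent samples."""
    parts = []
    if len(label_edges):
        t_idx = np.arange(n_times)
        a = (label_edges[:, 0:1] * n_times + t_idx).ravel()
        b = (label_edges[:, 1:2] * n_times + t_idx).ravel()
        parts.append(np.stack([a, b], axis=1))
    if n_times > 1:
        labs = np.arange(n_labels)
        a = (labs[:, None] * n_times + np.arange(n_times - 1)).ravel()
        parts.append(np.stack([a, a + 1], axis=1))
    if not parts:
        return np.empty((0, 2), dtype=int)
    return np.concatenate(parts)


def _enhance_flat(
    stat: np.ndarray, edges: np.ndarray, n_nodes: int, E: float, H: float, dh: float
) -> np.ndarray:
    out = np.zeros(n_nodes)
    top = stat.max()
    if top <= 0:
        return out
    n_steps = int(np.floor(top / dh + 1e-9))
    src, dst = edges[:, 0], edges[:, 1]
    for k in range(1, n_steps + 1):
        h = k * dh
        mask = stat >= h
        keep = mask[src] & mask[dst]
        g = sp.csr_matrix(
            (np.ones(int(keep.sum())), (src[keep], dst[keep])),
            shape=(n_nodes, n_nodes),
        )
        _, comp = connected_components(g, directed=False)
        sizes = np.bincount(comp[mask])
        out[mask] += sizes[comp[mask]] ** E * h**H * dh
    return out


def tfce_enhance(
    stat: np.ndarray,
    adjacency,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a labels x time statistic map.

    For each sample, sums ``extent(h)^E * h^H * dh`` over thresholds
    ``h = dh, 2*dh, ... <= max(stat)``, where extent is the size of the
    spatiotemporal cluster containing the sample at threshold h
    (connected through label adjacency within a time sample and through
    time-step +/-1 within a label).  Negative stat values contribute
    nothing; enhance ``|stat|`` upstream for a two-sided map.
    """
    stat = np.asarray(stat, dtype=float)
    if stat.ndim == 1:
        stat = stat[:, None]
    if not np.all(np.isfinite(stat)):
        raise ValueError("stat map must be finite")
    n_labels, n_times = stat.shape
    label_edges = _as_edge_list(adjacency, n_labels)
    if dh is None:
        top = float(stat.max())
        dh = top / 50.0 if top > 0 else 1.0
    if dh <= 0:
        raise ValueError("dh must be > 0")
    edges = _spatiotemporal_edges(label_edges, n_labels, n_times)
    flat = _enhance_flat(stat.ravel(), edges, n_labels * n_times, E, H, dh)
    return flat.reshape(n_labels, n_times)


@dataclass
class TFCEMap:
    """Observed statistic map with its TFCE enhancement and permutation p."""

    stat: np.ndarray
    tfce: np.ndarray
    p: np.ndarray
    neg_log10_p: np.ndarray
    n_permutations: int
    E: float
    H: float
    dh: float
    adjacency: np.ndarray


def tfce_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    adjacency,
    n_perm: int = 1024,
    seed: int = 0,
    E: float = 0.5,
    H: float = 2.0,
    statistic: str = "t",
) -> TFCEMap:
    """Spatiotemporal TFCE permutation test between two subject groups.

    The observed per-sample statistic is the two-sided pooled two-sample
    |t| (or t^2 with ``statistic="f"``).  Group labels are permuted
    ``n_perm`` times; each permuted map is enhanced and its maximum
    pooled into the null, so ``p(s) = (1 + #{max TFCE_perm >= TFCE_obs(s)})
    / (n_perm + 1)``.  dh is fixed from the observed map and reused for
    every permutation so enhanced values are comparable.
    """
    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if group_a.ndim != 3 or group_b.ndim != 3 or group_a.shape[1:] != group_b.shape[1:]:
        raise ValueError("groups must be (n_subjects, n_labels, n_times) with equal maps")
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("t", "f"):
        raise ValueError(f"unknown statistic {statistic!r}")

    n_labels, n_times = group_a.shape[1:]
    label_edges = _as_edge_list(adjacency, n_labels)
    edges = _spatiotemporal_edges(label_edges, n_labels, n_times)
    n_nodes = n_labels * n_times

    def enhance(stat_flat: np.ndarray, dh: float) -> np.ndarray:
        return _enhance_flat(stat_flat, edges, n_nodes, E, H, dh)

    def stat_of(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        t = t_statistic_map(a, b)
        return t**2 if statistic == "f" else np.abs(t)

    obs_stat = stat_of(group_a, group_b)
    top = float(obs_stat.max())
    dh = top / 50.0 if top > 0 else 1.0
    obs_tfce = enhance(obs_stat.ravel(), dh)

    pooled = np.concatenate([group_a, group_b], axis=0)
    n_a = group_a.shape[0]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_nodes)
    for _ in range(n_perm):
        order = rng.permutation(pooled.shape[0])
        perm_stat = stat_of(pooled[order[:n_a]], pooled[order[n_a:]])
        perm_max = enhance(perm_stat.ravel(), dh).max()
        exceed += perm_max >= obs_tfce
    p = (1.0 + exceed) / (n_perm + 1.0)
    return TFCEMap(
        stat=obs_stat,
        tfce=obs_tfce.reshape(n_labels, n_times),
        p=p.reshape(n_labels, n_times),
        neg_log10_p=-np.log10(p).reshape(n_labels, n_times),
        n_permutations=n_perm,
        E=E,
        H=H,
        dh=dh,
        adjacency=label_edges,
    )
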