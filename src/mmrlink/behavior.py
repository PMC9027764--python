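"""Scoring of AX discrimination tables into hit/false-alarm rates and d'."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["BehavioralScore", "dprime", "score_ax", "scores_to_frame"]

DIFFERENT_PAIRS = frozenset({"AB", "BA"})
SAME_PAIRS = frozenset({"AA", "BB"})
VALID_RESPONSES = frozenset({"same", "different", "none"})


@dataclass
class BehavioralScore:
    """Per-subject signal-detection summary of an AX table."""

    subject_id: str
    n_hit: int
    n_fa: int
    n_different_trials: int
    n_same_trials: int
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float  # optional SDT bias, c = -(z(h*) + z(f*)) / 2


def _corrected_rate(count: int, n: int, correction: str) -> float:
    if n < 1:
        raise ValueError("cannot edge-correct a rate with 0 trials")
    if correction == "half":
        # 1/(2N) rule: only boundary rates are moved
        if count == 0:
            return 1.0 / (2 * n)
        if count == n:
            return 1.0 - 1.0 / (2 * n)
        return count / n
    if correction == "loglinear":
        return (count + 0.5) / (n + 1.0)
    raise ValueError(f"unknown correction {correction!r}")


def dprime(
    hit_rate: float,
    fa_rate: float,
    n_different: int,
    n_same: int,
    correction: str = "half",
) -> float:
    """Sensitivity d' = Phi^-1(h*) - Phi^-1(f*) with edge correction.

    ``correction="half"`` replaces rates of exactly 0 or 1 by 1/(2N) and
    1 - 1/(2N); ``"loglinear"`` applies (count + 0.5)/(N + 1) to every
    rate.  Antisymmetric: swapping the two rates flips the sign.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_different < 1 or n_same < 1:
        raise ValueError("counts must be >= 1 to apply the edge correction")
    h = _corrected_rate(int(round(hit_rate * n_different)), n_different, correction)
    f = _corrected_rate(int(round(fa_rate * n_same)), n_same, correction)
    return float(norm.ppf(h) - norm.ppf(f))


def _score_one(subject_id: str, trials: pd.DataFrame, correction: str) -> BehavioralScore:
    answered = trials[trials["response"] != "none"]
    is_diff_pair = answered["pair_type"].isin(DIFFERENT_PAIRS)
    said_diff = answered["response"] == "different"
    n_different = int(is_diff_pair.sum())
    n_same = int((~is_diff_pair).sum())
    n_hit = int((is_diff_pair & said_diff).sum())
    n_fa = int((~is_diff_pair & said_diff).sum())
    if n_different < 1 or n_same < 1:
        raise ValueError(
            f"subject {subject_id!r}: needs at least one answered trial of "
            "each pair class to score d'"
        )
    hit_rate = n_hit / n_different
    fa_rate = n_fa / n_same
    h = _corrected_rate(n_hit, n_different, correction)
    f = _corrected_rate(n_fa, n_same, correction)
    zh, zf = norm.ppf(h), norm.ppf(f)
    return BehavioralScore(
        subject_id=subject_id,
        n_hit=n_hit,
        n_fa=n_fa,
        n_different_trials=n_different,
        n_same_trials=n_same,
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        dprime=float(zh - zf),
        criterion=float(-(zh + zf) / 2.0),
    )


def score_ax(trials: pd.DataFrame, correction: str = "half") -> list[BehavioralScore]:
    """Score an AX trial table into one :class:`BehavioralScore` per subject.

    Hits are "different" responses on AB/BA trials; false alarms are
    "different" responses on AA/BB trials.  Trials with response
    ``"none"`` (timeouts) are excluded from numerator and denominator.

    The table needs columns ``pair_type`` and ``response``; an optional
    ``subject_id`` column splits scoring per subject (a single anonymous
    subject is assumed otherwise).
    """
    trials = trials.copy()
    if "subject_id" not in trials.columns:
        trials["subject_id"] = "subject_00"
    bad_pair = ~trials["pair_type"].isin(DIFFERENT_PAIRS | SAME_PAIRS)
    if bad_pair.any():
        row = int(np.flatnonzero(bad_pair.to_numpy())[0])
        raise ValueError(
            f"row {row}: unknown pair_type {trials['pair_type'].iloc[row]!r}"
        )
    bad_resp = ~trials["response"].isin(VALID_RESPONSES)
    if bad_resp.any():
        row = int(np.flatnonzero(bad_resp.to_numpy())[0])
        raise ValueError(
            f"row {row}: unknown response {trials['response'].iloc[row]!r}"
        )
    return [
        _score_one(sid, grp, correction)
        for sid, grp in trials.groupby("subject_id", sort=True)
    ]


def scores_to_frame(scores: list[BehavioralScore]) -> pd.DataFrame:
    """Stable tabular form of scores (column order is part of the contract)."""
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "n_hit": s.n_hit,
                "n_fa": s.n_fa,
                "n_different_trials": s.n_different_trials,
                "n_same_trials": s.n_same_trials,
                "hit_rate": s.hit_rate,
                "fa_rate": s.fa_rate,
                "dprime": s.dprime,
                "criterion": s.criterion,
            }
            for s in scores
        ]
    )
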