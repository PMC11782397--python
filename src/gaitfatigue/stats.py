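"""Interpretation statistics: paired Wilcoxon tests, Bonferroni
correction, and Pearson correlations among selected features.

The Wilcoxon signed-rank test is implemented in-package because the exact
(small-sample) null distribution with midranked ties is needed: zero
differences are dropped, tied absolute differences receive midranks, the
null distribution is enumerated exactly over all sign assignments for
n <= 12, and a normal approximation with tie and continuity corrections is
used for larger n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .io import ContractError
from .features import WindowSample

__all__ = [
    "WilcoxonResult",
    "paired_wilcoxon",
    "bonferroni",
    "feature_correlations",
    "per_participant_state_means",
]

EXACT_N_MAX = 12


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    p_value: float
    n_used: int       # pairs remaining after dropping zero differences
    all_zero: bool = False


def paired_wilcoxon(before, after) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired per-participant means.

    Zero differences are dropped; ties among |differences| are midranked.
    For n <= 12 the p-value is exact: the null distribution of W+ is
    enumerated over all 2^n sign assignments and the two-sided p is the
    probability of a |W+ - n(n+1)/4| at least as large as observed.  For
    larger n a normal approximation with continuity and tie corrections is
    used.  All-zero differences yield p = 1 with a flag.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ContractError("before/after must be equal-length 1-D arrays")
    if before.shape[0] < 5:
        raise ContractError("paired_wilcoxon requires at least 5 pairs")
    d = after - before
    d = d[d != 0.0]
    if d.shape[0] == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, all_zero=True)
    n = d.shape[0]
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= EXACT_N_MAX:
        # enumerate all sign assignments of the ranks (vectorised)
        masks = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        sums = masks @ ranks
        obs = abs(w_plus - mu)
        p = float(np.mean(np.abs(sums - mu) >= obs - 1e-12))
    else:
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        dev = w_plus - mu
        # continuity correction shrinks the deviation toward the mean
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var) if var > 0 else 0.0
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(statistic=min(w_plus, w_minus), p_value=p, n_used=n)


def bonferroni(p_values, alpha: float = 0.05) -> list[bool]:
    """Significance flags at the Bonferroni-corrected level alpha / m."""
    p_values = list(p_values)
    if len(p_values) < 1:
        raise ContractError("bonferroni requires at least one p-value")
    m = len(p_values)
    return [p < alpha / m for p in p_values]


def feature_correlations(
    samples: list[WindowSample],
    feature_subset,
    strong_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r among the subset features, plus a strong-|r| mask.

    Zero-variance features have undefined correlations; those entries are
    reported as flagged 0 (the diagonal stays 1).  |r| above the threshold
    (0.5 by default) is conventionally a strong correlation.
    """
    feature_subset = list(feature_subset)
    if len(samples) < 3:
        raise ContractError("feature_correlations requires >= 3 samples")
    X = np.array(
        [[s.features[n] for n in feature_subset] for s in samples], dtype=float
    )
    sd = X.std(axis=0)
    m = len(feature_subset)
    r = np.zeros((m, m))
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        r[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r, 1.0)
    strong = (np.abs(r) > strong_threshold) & ~np.eye(m, dtype=bool)
    return r, strong


def per_participant_state_means(
    samples: list[WindowSample], feature_name: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-participant mean of one feature in each state.

    Returns (non_fatigue_means, fatigue_means, participant_ids) with one
    entry per participant, the paired inputs for :func:`paired_wilcoxon`.
    """
    pids = sorted({s.participant_id for s in samples})
    before, after = [], []
    for pid in pids:
        nf = [
            s.features[feature_name]
            for s in samples
            if s.participant_id == pid and s.state_label == "non_fatigue"
        ]
        fa = [
            s.features[feature_name]
            for s in samples
            if s.participant_id == pid and s.state_label == "fatigue"
        ]
        if not nf or not fa:
            continue
        before.append(float(np.mean(nf)))
        after.append(float(np.mean(fa)))
    return np.array(before), np.array(after), pids
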