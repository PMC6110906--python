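"""Group inference for gyral vs sulcal accuracy.

One-tailed pooled-variance two-sample t-tests with Bonferroni
correction, a seeded label-permutation test of the gyri-sulci mean
difference, Pearson correlation of FA against accuracy, and
subject-proportion summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

__all__ = [
    "TestResult",
    "SubjectSummary",
    "t_test_one_tailed",
    "bonferroni_adjust",
    "permutation_mean_diff",
    "pearson_correlation",
    "subject_proportion",
]


@dataclass
class TestResult:
    roi_or_network_id: object
    statistic: float
    p_raw: float
    p_adjusted: float
    n_gyri: int
    n_sulci: int
    method: str


@dataclass
class SubjectSummary:
    network_id: object
    n_subjects: int
    n_significant: int

    @property
    def proportion(self) -> float:
        return self.n_significant / self.n_subjects


def t_test_one_tailed(a, b, equal_var: bool = True) -> tuple:
    """Pooled-variance t statistic and upper-tail p for H1: mean(a) > mean(b).

    Welch's correction available via ``equal_var=False``.  Degenerate
    samples (size < 2 or both variances zero) raise ``ValueError``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if a.std() == 0 and b.std() == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, 0.5  # identical degenerate samples: symmetric null
        raise ValueError("zero-variance samples; t-test undefined")
    t, p = sp_stats.ttest_ind(a, b, equal_var=equal_var, alternative="greater")
    return float(t), float(p)


def bonferroni_adjust(p_values, family_size: int) -> list:
    """``min(1, p * family_size)`` per p-value."""
    p_values = list(p_values)
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if family_size < len(p_values):
        raise ValueError("family_size smaller than the number of tests")
    return [min(1.0, p * family_size) for p in p_values]


def permutation_mean_diff(values, labels, n_perm: int = 1000,
                          seed: int = 0) -> tuple:
    """Label-permutation test of mean(gyri) - mean(sulci) > 0.

    ``labels`` is boolean-like: truthy = gyral.  The null is built by
    relabeling with the same group sizes ``n_perm`` times; the one-sided
    p uses the add-one estimator ``(1 + #{null >= observed}) / (n_perm + 1)``
    so p is never exactly 0.  Deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    n_g = int(labels.sum())
    n_s = int(labels.size - n_g)
    if n_g == 0 or n_s == 0:
        raise ValueError("both labels must be present")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = values[labels].mean() - values[~labels].mean()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        diff = perm[:n_g].mean() - perm[n_g:].mean()
        if diff >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return float(observed), float(p)


def pearson_correlation(x, y) -> tuple:
    """Pearson r with the two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


def subject_proportion(flags: dict) -> list:
    """Per-network fraction of subjects flagged significant.

    ``flags`` maps network id -> sequence of per-subject booleans
    (significant after Bonferroni adjustment at alpha = 0.05).
    """
    if not flags:
        raise ValueError("need at least one network")
    out = []
    for net_id, subject_flags in flags.items():
        subject_flags = list(subject_flags)
        if not subject_flags:
            raise ValueError("need at least one subject")
        out.append(SubjectSummary(
            network_id=net_id,
            n_subjects=len(subject_flags),
            n_significant=int(sum(bool(f) for f in subject_flags)),
        ))
    return out
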