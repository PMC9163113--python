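"""Agreement statistics and ischemia classification.

The battery used to compare misaligned against correctly aligned analyses:
relative deviation, Bland-Altman bias and limits of agreement, the two-way
absolute-agreement intraclass correlation ICC(A,1), the Wilcoxon signed-rank
test (exact by sign-pattern enumeration at small n, with midranks for ties),
and threshold-based ischemia classification with false-positive /
false-negative accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ISCHEMIC_THRESHOLDS",
    "DiagnosisChange",
    "relative_deviation",
    "bland_altman",
    "icc_agreement",
    "wilcoxon_signed_rank",
    "classify_ischemia",
    "diagnosis_change",
]

#: Clinical ischemic thresholds, mL/g/min: a stress value *below* the
#: threshold is classified ischemic.  2.3 for washout-based MBF; 1.8 for
#: uptake-based transmural MBFt.
ISCHEMIC_THRESHOLDS = {"mbf": 2.3, "mbft": 1.8}

#: Largest n for which the exact sign-flip null distribution is enumerated.
WILCOXON_EXACT_N = 15


def relative_deviation(ref: float, test: float) -> float:
    """Percent deviation of ``test`` from a positive reference value."""
    if ref <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (test - ref) / ref


def bland_altman(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """Bland-Altman agreement of paired measurements.

    Differences ``d = y - x``; returns ``(bias, sd, loa_low, loa_high)``
    with bias the mean difference, sd the sample standard deviation and the
    limits of agreement ``bias +/- 1.96 sd``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def icc_agreement(x: np.ndarray, y: np.ndarray) -> float:
    """Intraclass correlation ICC(A,1): two-way, single measure, absolute
    agreement (McGraw & Wong), computed from the two-way ANOVA mean squares.

    Subjects are rows, the two measurements (e.g. aligned and misaligned)
    are columns:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR the between-subject, MSC the between-measurement and MSE the
    residual mean square.  Unlike a correlation, a constant offset between
    the measurements lowers the value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three pairs for ICC")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand, rtol=0, atol=0):
        raise ValueError("zero total variance: ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    return float((msr - mse) / denom)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Differences ``d = y - x``; zero differences are dropped, absolute
    differences are ranked with midranks for ties, and the statistic is the
    sum of ranks of positive differences.  For n <= 15 the two-sided p-value
    is exact, by enumeration of all 2^n sign assignments (valid with ties);
    above that a normal approximation with tie-aware variance and continuity
    correction is used.  A degenerate sample (all differences zero) returns
    ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # n(n+1)/2 even with midranks
    if n <= WILCOXON_EXACT_N:
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        dist = signs @ ranks
        hi = max(w_pos, total - w_pos)
        lo = min(w_pos, total - w_pos)
        tol = 1e-9
        p = (np.sum(dist >= hi - tol) + np.sum(dist <= lo + tol)) / dist.size
        return w_pos, float(min(p, 1.0))
    mu = total / 2.0
    sigma = np.sqrt(np.sum(ranks**2) / 4.0)
    if sigma == 0:
        return w_pos, 1.0
    z = (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / sigma
    p = 2.0 * sps.norm.sf(abs(z))
    return w_pos, float(min(p, 1.0))


def classify_ischemia(
    value: float, kind: str, thresholds: dict[str, float] | None = None
) -> bool:
    """True when a flow value falls strictly below the ischemic threshold.

    ``kind`` selects the threshold ("mbf": 2.3 mL/g/min, "mbft": 1.8
    mL/g/min by default); a value exactly on the threshold is not ischemic.
    """
    if value < 0:
        raise ValueError("flow values must be non-negative")
    thr = (thresholds or ISCHEMIC_THRESHOLDS).get(kind)
    if thr is None:
        raise ValueError(f"unknown flow kind {kind!r}")
    return bool(value < thr)


@dataclass(frozen=True)
class DiagnosisChange:
    """Misalignment-induced diagnosis changes over a set of regions.

    ``false_positives``: regions non-ischemic in the aligned reference but
    classified ischemic under misalignment; ``false_negatives``: the
    converse; ``total``: regions compared.
    """

    false_positives: int
    false_negatives: int
    total: int

    def __post_init__(self) -> None:
        if self.false_positives + self.false_negatives > self.total:
            raise ValueError("more diagnosis changes than regions")


def diagnosis_change(
    ref_values: np.ndarray,
    test_values: np.ndarray,
    kind: str,
    thresholds: dict[str, float] | None = None,
) -> DiagnosisChange:
    """Count false-positive and false-negative ischemia calls.

    Each matched (reference, misaligned) value pair is classified against
    the ``kind`` threshold; disagreements are tallied by direction.
    """
    ref = np.asarray(ref_values, dtype=float)
    test = np.asarray(test_values, dtype=float)
    if ref.shape != test.shape or ref.ndim != 1:
        raise ValueError("value lists must be 1-D and matched in length")
    fp = fn = 0
    for r, t in zip(ref, test):
        r_isch = classify_ischemia(r, kind, thresholds)
        t_isch = classify_ischemia(t, kind, thresholds)
        if not r_isch and t_isch:
            fp += 1
        elif r_isch and not t_isch:
            fn += 1
    return DiagnosisChange(false_positives=fp, false_negatives=fn, total=ref.size)
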