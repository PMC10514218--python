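"""Evaluation statistics: ROC/AUC, Youden cut-offs, DeLong tests, and the
classical two-group comparisons (t, rank-sum, chi-square) with Bonferroni
alpha arithmetic.

The AUC is computed as the Mann-Whitney probability (ties counted 1/2)
via midranks, which equals the exhaustive pairwise definition exactly.
The DeLong machinery for paired-AUC comparison is implemented from
placement values; it is the nonparametric covariance-based test used to
compare correlated ROC curves on the same subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateStatisticError, ParameterError


@dataclass
class ROCResult:
    """AUC with DeLong CI and the Youden-optimal operating point.

    Direction convention: the positive class (MCI) is expected to have
    *higher* scores (more subthreshold voxels = more atrophy). A subject
    is called positive when score > cutoff.
    """

    auc: float
    n_pos: int
    n_neg: int
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    auc_se: float
    ci_low: float
    ci_high: float
    direction: str = "higher_score_positive"


def _split(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ParameterError("scores and labels must have equal length")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ParameterError("both classes must be present")
    return pos, neg


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def auc_mann_whitney(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + 1/2 P(tie), exactly, via midranks."""
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    ranks = _midrank(np.concatenate([pos, neg]))
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _placements(scores, labels):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos, neg = _split(scores, labels)
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def auc_variance_delong(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for a single score set."""
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def optimal_cutoff(scores, labels) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximizing Youden's J.

    Candidate cut-offs are the midpoints between adjacent distinct
    observed scores, plus half-step points beyond each end, so integer
    voxel-count scores yield half-integer cut-offs. Ties in J break
    toward higher specificity, then toward the lower cutoff.
    """
    pos, neg = _split(scores, labels)
    distinct = np.unique(np.concatenate([pos, neg]))
    if len(distinct) == 1:
        gap = 1.0
        candidates = np.array([distinct[0] - gap / 2, distinct[0] + gap / 2])
    else:
        mids = (distinct[:-1] + distinct[1:]) / 2
        candidates = np.concatenate([
            [distinct[0] - (distinct[1] - distinct[0]) / 2],
            mids,
            [distinct[-1] + (distinct[-1] - distinct[-2]) / 2],
        ])
    best = None
    for c in candidates:
        sens = float((pos > c).mean())
        spec = float((neg <= c).mean())
        j = sens + spec - 1.0
        key = (j, spec, -c)
        if best is None or key > best[0]:
            best = (key, float(c), sens, spec)
    return best[1], best[2], best[3]


def roc_auc(scores, labels) -> ROCResult:
    """Full ROC summary: Mann-Whitney AUC, DeLong 95% CI, Youden cut-off."""
    pos, neg = _split(scores, labels)
    auc, var = auc_variance_delong(scores, labels)
    se = float(np.sqrt(max(var, 0.0)))
    cutoff, sens, spec = optimal_cutoff(scores, labels)
    zcrit = sps.norm.ppf(0.975)
    return ROCResult(
        auc=auc, n_pos=len(pos), n_neg=len(neg),
        optimal_cutoff=cutoff, sensitivity=sens, specificity=spec,
        auc_se=se,
        ci_low=float(np.clip(auc - zcrit * se, 0.0, 1.0)),
        ci_high=float(np.clip(auc + zcrit * se, 0.0, 1.0)),
    )


def roc_curve_points(scores, labels) -> np.ndarray:
    """(1-specificity, sensitivity) pairs over all candidate cut-offs, for plotting."""
    pos, neg = _split(scores, labels)
    thresholds = np.unique(np.concatenate([pos, neg]))
    pts = [(1.0, 1.0)]
    for c in thresholds:
        pts.append((float((neg > c).mean()), float((pos > c).mean())))
    return np.array(sorted(set(pts)))


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    var_diff: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both score sets must refer to the same subjects in the same order
    (the paired design is what the placement-value covariance assumes).
    A degenerate variance — e.g. identical score vectors — is reported
    with ``degenerate=True`` and p = 1.0 rather than a silent division.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    if scores_a.shape != scores_b.shape:
        raise ParameterError("paired score sets must have equal length")
    v10_a, v01_a = _placements(scores_a, labels)
    v10_b, v01_b = _placements(scores_b, labels)
    auc_a = float(v10_a.mean())
    auc_b = float(v10_b.mean())
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var_diff = float(s[0, 0] + s[1, 1] - 2 * s[0, 1])
    if var_diff <= 1e-15:
        return DeLongResult(auc_a, auc_b, 0.0, 1.0, var_diff, degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, float(z), float(p), var_diff)


def two_sample_t(
    mean1=None, sd1=None, n1=None, mean2=None, sd2=None, n2=None,
    x=None, y=None, variant: str = "pooled",
) -> tuple[float, float, float]:
    """Independent-samples t-test, (t, df, p two-sided).

    Accepts either summary statistics (mean, SD, n per group) — so printed
    table rows can be re-tested — or raw samples via ``x``/``y``.
    ``variant`` selects the pooled-variance or Welch form.
    """
    if x is not None or y is not None:
        if x is None or y is None:
            raise ParameterError("provide both raw samples or neither")
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        mean1, sd1, n1 = x.mean(), x.std(ddof=1), len(x)
        mean2, sd2, n2 = y.mean(), y.std(ddof=1), len(y)
    if None in (mean1, sd1, n1, mean2, sd2, n2):
        raise ParameterError("incomplete summary statistics")
    if n1 < 2 or n2 < 2:
        raise ParameterError("need n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("SDs must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            raise DegenerateStatisticError("zero variance in both groups with equal means")
        raise DegenerateStatisticError("zero variance in both groups: t is unbounded")
    if variant not in ("pooled", "welch"):
        raise ParameterError(f"unknown variant {variant!r}")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2
    else:
        a, b = sd1 ** 2 / n1, sd2 ** 2 / n2
        df = (a + b) ** 2 / (a ** 2 / (n1 - 1) + b ** 2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test, (U, p).

    Exact null enumeration for n1+n2 <= 12 without ties; otherwise the
    normal approximation with tie correction and continuity correction.
    U is the Mann-Whitney statistic of ``x``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ParameterError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= 12 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    ranks = _midrank(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    nn = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (nn * (nn - 1))
    var = n1 * n2 / 12 * (nn + 1 - tie_term)
    if u == mu or var <= 0:
        return float(u), 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    return float(u), float(2.0 * sps.norm.sf(abs(z)))


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction, df=1."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ParameterError("table must be 2x2 with nonnegative counts")
    a, b, c, d = t.ravel()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ParameterError("chi-square undefined with a zero margin")
    n = t.sum()
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def bonferroni_alpha(raw_alpha: float, m: int) -> float:
    """Family-wise alpha implied by a per-test alpha over m comparisons.

    corrected = raw_alpha * m, capped at 1. (E.g. a per-test 0.0001 over a
    6-ROI x 3-threshold x 4-kernel x 3-reference grid of 216 comparisons
    corresponds to a corrected 0.0216.)
    """
    if m < 1:
        raise ParameterError(f"need m >= 1, got {m}")
    if not 0.0 < raw_alpha < 1.0:
        raise ParameterError(f"raw_alpha must be in (0,1), got {raw_alpha}")
    return min(1.0, raw_alpha * m)
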