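"""Statistical toolkit for cohort evaluation.

Normality-gated two-group comparison (t-test vs Mann-Whitney, gated by a
Kolmogorov-Smirnov-type normality test), Pearson correlation, ROC/AUC,
sensitivity/specificity at an AHI screening cutoff, Bland-Altman agreement,
Cohen's kappa, and the closed-form power computation used for two-sample
design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupComparison",
    "AgreementResult",
    "compare_groups",
    "sens_spec",
    "roc_auc",
    "bland_altman",
    "pearson_r",
    "power_two_sample",
    "cohen_kappa",
]

#: AHI at or above this defines disease (OSA) ground truth.
OSA_DISEASE_THRESHOLD = 5.0


@dataclass(frozen=True)
class GroupComparison:
    test_used: str  # "t" | "mann_whitney"
    statistic: float
    p_value: float
    mean_difference: float
    ci95: tuple[float, float] | None  # mean-difference CI, t branch only
    normal_a: bool
    normal_b: bool


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    pairs: int


def _is_normal(x: np.ndarray, alpha: float, method: str) -> bool:
    if np.ptp(x) == 0:
        return True  # degenerate spread: treat as not rejecting normality
    if method == "lilliefors":
        _, p = lilliefors(x, dist="norm")
    elif method == "ks":
        _, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown normality test {method!r}")
    return p > alpha


def compare_groups(
    a,
    b,
    alpha: float = 0.05,
    *,
    normality: str = "lilliefors",
    welch: bool = False,
) -> GroupComparison:
    """Two-group comparison with normality-gated test choice.

    Both groups are tested for normality (Lilliefors-corrected KS by
    default, plain KS with estimated parameters via ``normality="ks"``).
    If both pass at ``alpha``, a two-sided t-test is used (pooled variance
    by default, Welch via ``welch=True``) with a 95% CI for the mean
    difference; otherwise the Mann-Whitney U test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    na, nb = _is_normal(a, alpha, normality), _is_normal(b, alpha, normality)
    mean_diff = float(a.mean() - b.mean())
    if na and nb:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        ci = res.confidence_interval(0.95)
        return GroupComparison(
            test_used="t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            mean_difference=mean_diff,
            ci95=(float(ci.low), float(ci.high)),
            normal_a=na,
            normal_b=nb,
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        test_used="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_difference=mean_diff,
        ci95=None,
        normal_a=na,
        normal_b=nb,
    )


def sens_spec(
    pred_ahi,
    true_ahi,
    cutoff: float,
    disease_threshold: float = OSA_DISEASE_THRESHOLD,
) -> tuple[float, float]:
    """Sensitivity and specificity (percent) of the predicted AHI as a
    screening test.

    Disease ground truth is ``true_ahi >= disease_threshold`` (default 5,
    the OSA definition); test-positive is ``pred_ahi >= cutoff`` — the
    screening cutoff applies to the predicted value only.
    """
    pred = np.asarray(pred_ahi, dtype=float)
    true = np.asarray(true_ahi, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred_ahi and true_ahi must be paired, equal-length vectors")
    disease = true >= disease_threshold
    positive = pred >= cutoff
    n_dis = int(disease.sum())
    n_hea = int((~disease).sum())
    if n_dis == 0:
        raise ValueError("no diseased subjects: sensitivity undefined")
    if n_hea == 0:
        raise ValueError("no healthy subjects: specificity undefined")
    tp = int(np.sum(disease & positive))
    tn = int(np.sum(~disease & ~positive))
    return 100.0 * tp / n_dis, 100.0 * tn / n_hea


def roc_auc(scores, labels) -> float:
    """Tie-aware trapezoidal area under the ROC curve.

    Computed as the normalized Mann-Whitney U statistic (midranks handle
    ties, equivalent to trapezoidal integration with tied score groups
    averaged).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    uniq = np.unique(y)  # positives are the larger of the two label values
    if len(uniq) != 2:
        raise ValueError(f"labels must contain exactly 2 classes, got {len(uniq)}")
    pos = s[y == uniq[1]]
    neg = s[y == uniq[0]]
    ranks = sps.rankdata(s)
    u = ranks[y == uniq[1]].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement: bias (mean difference) and 95% limits of
    agreement at bias +/- 1.96 SD of the paired differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        sd_diff=sd, pairs=len(d),
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def power_two_sample(delta: float, sd: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample comparison of means, normal
    approximation::

        power = Phi(|delta|/(sd*sqrt(1/n1+1/n2)) - z_{1-alpha/2})
              + Phi(-|delta|/(...) - z_{1-alpha/2})

    The second (opposite-tail) term is negligible except under the null,
    where the expression reduces exactly to ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    se = sd * math.sqrt(1.0 / n1 + 1.0 / n2)
    z_crit = sps.norm.ppf(1 - alpha / 2)
    ncp = abs(delta) / se
    return float(sps.norm.cdf(ncp - z_crit) + sps.norm.cdf(-ncp - z_crit))


def cohen_kappa(confusion) -> float:
    """Cohen's kappa from a square confusion-count matrix:
    (p_o - p_e) / (1 - p_e) with marginal-product expected agreement."""
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion counts must be nonnegative")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm) / total
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if abs(1 - pe) < 1e-12:
        raise ValueError("expected agreement is 1: kappa undefined")
    return float((po - pe) / (1 - pe))
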