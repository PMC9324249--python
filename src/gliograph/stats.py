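"""Statistical primitives: normality gate, gated two-sample tests, BH-FDR.

Every group comparison is gated by the Jarque-Bera normality test on both
samples: if both pass (p > alpha), a two-tailed pooled-variance Student
t-test is used; otherwise a two-tailed Mann-Whitney U test (exact
enumeration for small samples without ties, tie-corrected normal
approximation otherwise).  The paired variant gates on the differences and
falls back to the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateSampleError, InvalidArgumentError

logger = logging.getLogger(__name__)

#: Largest n_a * n_b for which the Mann-Whitney p is computed by exact
#: enumeration of orderings (requires untied data).
MW_EXACT_LIMIT = 400


def jarque_bera(sample) -> tuple[float, float]:
    """Jarque-Bera statistic and chi-squared(2) upper-tail p-value.

    JB = (n/6) * (S^2 + (K - 3)^2 / 4) with skewness S and kurtosis K from
    biased central moments.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 8:
        raise InvalidArgumentError("Jarque-Bera requires n >= 8")
    m = x - x.mean()
    m2 = np.mean(m**2)
    if m2 == 0:
        raise DegenerateSampleError("zero-variance sample")
    skew = np.mean(m**3) / m2**1.5
    kurt = np.mean(m**4) / m2**2
    jb = n / 6.0 * (skew**2 + (kurt - 3.0) ** 2 / 4.0)
    return float(jb), float(sps.chi2.sf(jb, df=2))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one gated comparison, including the gate record."""

    test_used: str  # "t", "mann_whitney" or "wilcoxon"
    statistic: float
    p: float
    direction: int  # sign of (mean_a - mean_b), or mean difference if paired
    normal_a: bool | None = None
    normal_b: bool | None = None

    def gate_consistent(self, alpha: float) -> bool:
        if self.normal_a is None or self.normal_b is None:
            return self.test_used in ("mann_whitney", "wilcoxon")
        both_normal = self.normal_a and self.normal_b
        return self.test_used == "t" if both_normal else self.test_used != "t"


def _normality(x: np.ndarray, alpha: float) -> bool | None:
    """True/False from the JB gate, None when the gate cannot run."""
    if x.size < 8:
        return None
    try:
        _, p = jarque_bera(x)
    except DegenerateSampleError:
        return False
    return p > alpha


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= MW_EXACT_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(a, b, alpha_normality: float = 0.05) -> TestResult:
    """Two-tailed gated comparison of two independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InvalidArgumentError("both samples need n >= 3")
    direction = int(np.sign(a.mean() - b.mean()))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # All observations identical: no evidence of any difference.
        logger.warning("compare_groups: all pooled observations identical; p = 1")
        return TestResult("mann_whitney", 0.0, 1.0, 0)
    normal_a = _normality(a, alpha_normality)
    normal_b = _normality(b, alpha_normality)
    if normal_a and normal_b:
        stat, p = sps.ttest_ind(a, b, equal_var=True)
        return TestResult("t", float(stat), float(p), direction, normal_a, normal_b)
    stat, p = _mann_whitney(a, b)
    return TestResult("mann_whitney", stat, p, direction, normal_a, normal_b)


def compare_paired(a, b, alpha_normality: float = 0.05) -> TestResult:
    """Two-tailed gated comparison of paired samples (gate on differences)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise InvalidArgumentError("paired samples must have equal length")
    if a.size < 3:
        raise InvalidArgumentError("paired comparison needs n >= 3")
    diff = a - b
    direction = int(np.sign(diff.mean()))
    if np.all(diff == 0):
        logger.warning("compare_paired: all differences zero; p = 1")
        return TestResult("wilcoxon", 0.0, 1.0, 0)
    normal = _normality(diff, alpha_normality)
    if normal:
        stat, p = sps.ttest_rel(a, b)
        return TestResult("t", float(stat), float(p), direction, normal, normal)
    res = sps.wilcoxon(a, b)
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue),
                      direction, normal, normal)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
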