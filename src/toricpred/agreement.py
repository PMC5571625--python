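"""Agreement and inference statistics for prediction-error components.

* :func:`icc_agreement` — intraclass correlation between estimated and
  measured astigmatism components: two-way model, single measures,
  absolute agreement (McGraw & Wong ICC(A,1); `pingouin`'s ICC2 row).
  Thresholds follow the usual convention: > 0.8 excellent, > 0.6
  substantial agreement.
* :func:`mean_component_test` — one-sample test of a mean error component
  against zero, with a Shapiro–Wilk normality gate selecting between the
  one-sample t test and the Wilcoxon signed-rank test, and Bonferroni
  adjustment for the number of modalities in the comparison family.
* :func:`sample_size` — one-sample normal-approximation sample size for
  detecting a mean shift ``delta`` with known SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = ["ICCEstimate", "TestResult", "icc_agreement", "mean_component_test", "sample_size"]


@dataclass(frozen=True)
class ICCEstimate:
    """ICC point estimate; ``value`` is None when the ICC is undefined."""

    value: Optional[float]
    n: int
    reason: Optional[str] = None


@dataclass(frozen=True)
class TestResult:
    mean: float
    raw_p: float
    adjusted_p: float
    significant: bool
    test_used: str  # "t", "wilcoxon" or "wilcoxon(degenerate)"
    shapiro_p: Optional[float]


def icc_agreement(pairs: Sequence[tuple[float, float]]) -> ICCEstimate:
    """Absolute-agreement single-measures ICC of paired components (D).

    Each pair is ``(estimated, measured)`` for one eye.  Undefined when
    there is no between-eye variance (the ANOVA decomposition collapses);
    such cases return ``value=None`` with a reason instead of a number.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("icc_agreement needs at least two (estimated, measured) pairs")
    if not np.all(np.isfinite(arr)):
        raise ValueError("icc_agreement requires finite values")
    n = arr.shape[0]
    if n < 3:
        return ICCEstimate(None, n, "fewer than 3 pairs: two-way ANOVA decomposition undefined")
    row_means = arr.mean(axis=1)
    if np.ptp(arr) == 0.0:
        return ICCEstimate(None, n, "zero total variance: all ratings identical")
    if np.ptp(row_means) == 0.0 and np.allclose(arr[:, 0], arr[:, 1]):
        return ICCEstimate(None, n, "zero between-pair variance")
    data = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), 2),
            "raters": np.tile(["estimated", "measured"], n),
            "ratings": arr.ravel(),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc = pg.intraclass_corr(data=data, targets="targets", raters="raters",
                                 ratings="ratings", nan_policy="raise")
    value = float(icc.loc[icc["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0])
    if not math.isfinite(value):
        return ICCEstimate(None, n, "ICC undefined for this variance decomposition")
    return ICCEstimate(value, n)


def mean_component_test(
    values: Sequence[float], m_comparisons: int, alpha: float = 0.05
) -> TestResult:
    """Test whether a mean prediction-error component differs from zero.

    Shapiro–Wilk at ``alpha`` gates the choice: normal samples use the
    one-sample t test, non-normal samples the Wilcoxon signed-rank test.
    ``adjusted_p = min(1, raw_p × m_comparisons)`` (Bonferroni).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("mean_component_test needs at least 3 values")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    mean = float(x.mean())

    if np.ptp(x) == 0.0:
        # Degenerate sample: no dispersion, neither test is defined.  All
        # zeros is trivially non-significant; a constant non-zero sample is
        # reported via the exact sign-test bound of the signed-rank test.
        raw_p = 1.0 if x[0] == 0.0 else min(1.0, 2.0 * 0.5 ** x.size)
        adj = min(1.0, raw_p * m_comparisons)
        return TestResult(mean, raw_p, adj, adj < alpha, "wilcoxon(degenerate)", None)

    shapiro_p = float(stats.shapiro(x).pvalue)
    if shapiro_p >= alpha:
        raw_p = float(stats.ttest_1samp(x, 0.0).pvalue)
        used = "t"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw_p = float(stats.wilcoxon(x, zero_method="wilcox").pvalue)
        used = "wilcoxon"
    adjusted = min(1.0, raw_p * m_comparisons)
    return TestResult(mean, raw_p, adjusted, adjusted < alpha, used, shapiro_p)


def sample_size(delta: float, sd: float, power: float = 0.8, alpha: float = 0.05) -> int:
    """One-sample two-sided normal-approximation sample size.

    ``n = ⌈((z_{1−α/2} + z_{power})·sd/delta)²⌉`` — the number of eyes
    needed to detect a mean prediction error of ``delta`` D given SD ``sd``.
    """
    if not (0.0 < power < 1.0 and 0.0 < alpha < 1.0):
        raise ValueError("power and alpha must be in (0, 1)")
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return math.ceil((z * sd / delta) ** 2)
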