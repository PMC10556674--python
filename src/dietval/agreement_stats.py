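"""Agreement statistics: Bland–Altman, paired tests, Pearson, ICC, over/under.

Conventions follow the validation literature for method comparison:

* Bland–Altman differences are test method minus reference; the limits of
  agreement (LoA) use the fixed 1.96 multiplier, while the confidence
  intervals of the bias and of each LoA use the t quantile with n−1 degrees
  of freedom (SE bias = sd/√n, SE LoA = sd·√(3/n), the classical
  approximation).
* Paired difference tests are gated on a Shapiro–Wilk normality check of
  the differences: paired t when normal, Wilcoxon signed-rank otherwise;
  p-values are Bonferroni-adjusted by the number of comparisons.
* The mean percentage difference (MPD) is the mean of the individual
  percentage differences, not the percentage difference of the means.
* The intraclass correlation (ICC) for diet stability is the one-way
  random-effects ratio σ²_between/(σ²_between+σ²_within), estimated by
  REML for unbalanced data (the one-way ANOVA estimator on balanced data,
  where the two coincide for a positive between component), with the exact
  F-based confidence interval.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "PairedEstimates",
    "BlandAltmanResult",
    "PairedTestResult",
    "PearsonResult",
    "ICCResult",
    "OverUnderSummary",
    "bland_altman",
    "bland_altman_from_moments",
    "paired_difference_test",
    "pearson",
    "icc_random_intercept",
    "over_under_summary",
]


@dataclass
class PairedEstimates:
    """Per-participant (test, reference) pairs, e.g. (app TDEI, DLW TDEE)."""

    participant_ids: list[str]
    value_a: np.ndarray  # test method, kcal/day
    value_b: np.ndarray  # reference method, kcal/day
    label_a: str = "test"
    label_b: str = "reference"

    def __post_init__(self) -> None:
        self.value_a = np.asarray(self.value_a, dtype=float)
        self.value_b = np.asarray(self.value_b, dtype=float)
        if self.value_a.shape != self.value_b.shape:
            raise DomainError("value_a and value_b must be aligned")
        if len(self.participant_ids) != self.value_a.size:
            raise DomainError("participant_ids must match the number of pairs")
        if not (np.all(np.isfinite(self.value_a)) and np.all(np.isfinite(self.value_b))):
            raise DomainError("paired estimates must be finite")

    @property
    def n(self) -> int:
        return self.value_a.size

    @property
    def differences(self) -> np.ndarray:
        return self.value_a - self.value_b


@dataclass
class BlandAltmanResult:
    n: int
    bias: float
    bias_ci: tuple[float, float]
    sd_diff: float
    se_bias: float
    loa: tuple[float, float]
    se_loa: float
    loa_ci_lower: tuple[float, float]
    loa_ci_upper: tuple[float, float]
    label_a: str = "test"
    label_b: str = "reference"


@dataclass
class PairedTestResult:
    n: int
    statistic: float | None
    p_raw: float | None
    p_adj: float | None
    test_used: str  # "paired_t", "wilcoxon", or "degenerate"
    shapiro_p: float | None
    mean_difference: float


@dataclass
class PearsonResult:
    n: int
    r: float
    r_squared: float
    p_raw: float
    p_adj: float


@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]
    f_stat: float
    df: tuple[float, float]
    var_between: float
    var_within: float
    within_sd: float
    ms_between: float
    ms_within: float
    method: str


@dataclass
class OverUnderSummary:
    n: int
    n_over: int
    n_under: int
    n_zero: int
    mpd_overall: float
    mpd_over: float | None
    mpd_under: float | None
    mean_delta_over: float | None
    mean_delta_under: float | None
    sd_delta_over: float | None = None
    sd_delta_under: float | None = None


LOA_Z = 1.96  # fixed multiplier of the limits of agreement


def bland_altman_from_moments(
    bias: float, sd_diff: float, n: int, alpha: float = 0.05,
    label_a: str = "test", label_b: str = "reference",
) -> BlandAltmanResult:
    """Bland–Altman internals from the mean difference, its SD, and n."""
    if n < 2:
        raise DomainError("Bland–Altman needs at least 2 pairs")
    if sd_diff < 0:
        raise DomainError("sd_diff must be non-negative")
    t = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))
    se_bias = sd_diff / math.sqrt(n)
    se_loa = sd_diff * math.sqrt(3.0 / n)
    loa = (bias - LOA_Z * sd_diff, bias + LOA_Z * sd_diff)
    return BlandAltmanResult(
        n=n, bias=bias, bias_ci=(bias - t * se_bias, bias + t * se_bias),
        sd_diff=sd_diff, se_bias=se_bias, loa=loa, se_loa=se_loa,
        loa_ci_lower=(loa[0] - t * se_loa, loa[0] + t * se_loa),
        loa_ci_upper=(loa[1] - t * se_loa, loa[1] + t * se_loa),
        label_a=label_a, label_b=label_b,
    )


def bland_altman(pairs: PairedEstimates, alpha: float = 0.05) -> BlandAltmanResult:
    """Bland–Altman agreement of the test method against the reference."""
    if pairs.n < 2:
        raise DomainError("Bland–Altman needs at least 2 pairs")
    d = pairs.differences
    return bland_altman_from_moments(
        float(np.mean(d)), float(np.std(d, ddof=1)), pairs.n, alpha,
        label_a=pairs.label_a, label_b=pairs.label_b,
    )


def paired_difference_test(
    pairs: PairedEstimates, alpha: float = 0.05, bonferroni_factor: int = 1
) -> PairedTestResult:
    """Paired t or Wilcoxon signed-rank, chosen by Shapiro–Wilk on the differences.

    Shapiro–Wilk p ≥ 0.05 selects the paired t test, otherwise the Wilcoxon
    signed-rank test.  Zero-variance differences make every test degenerate;
    the bias is still reported.
    """
    if pairs.n < 3:
        raise DomainError("paired difference test needs n >= 3")
    d = pairs.differences
    mean_diff = float(np.mean(d))
    if np.allclose(d, d[0]):
        return PairedTestResult(n=pairs.n, statistic=None, p_raw=None,
                                p_adj=None, test_used="degenerate",
                                shapiro_p=None, mean_difference=mean_diff)
    sw_stat, sw_p = stats.shapiro(d)
    if sw_p >= 0.05:
        stat, p = stats.ttest_rel(pairs.value_a, pairs.value_b)
        used = "paired_t"
    else:
        stat, p = stats.wilcoxon(pairs.value_a, pairs.value_b)
        used = "wilcoxon"
    return PairedTestResult(
        n=pairs.n, statistic=float(stat), p_raw=float(p),
        p_adj=min(1.0, bonferroni_factor * float(p)), test_used=used,
        shapiro_p=float(sw_p), mean_difference=mean_diff,
    )


def pearson(pairs: PairedEstimates, bonferroni_factor: int = 1) -> PearsonResult:
    """Pearson correlation with both r and r² reported, Bonferroni-adjusted p."""
    if pairs.n < 3:
        raise DomainError("Pearson correlation needs n >= 3")
    if np.std(pairs.value_a) == 0 or np.std(pairs.value_b) == 0:
        raise DomainError("Pearson correlation undefined for zero variance")
    res = stats.pearsonr(pairs.value_a, pairs.value_b)
    r = float(res.statistic)
    p = float(res.pvalue)
    return PearsonResult(n=pairs.n, r=r, r_squared=r * r, p_raw=p,
                         p_adj=min(1.0, bonferroni_factor * p))


def _icc_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """One-way random-effects ANOVA components (MSB, MSW, var_b, var_w).

    Uses n0 = (N − Σn_i²/N)/(k−1) as the effective group size for
    unbalanced layouts (Searle's method-of-moments estimator).
    """
    k = len(groups)
    sizes = np.array([g.size for g in groups], dtype=float)
    N = sizes.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - np.sum(sizes**2) / N) / (k - 1)
    var_w = msw
    var_b = max(0.0, (msb - msw) / n0)
    return msb, msw, var_b, var_w


def _icc_reml(daily: pd.DataFrame) -> tuple[float, float]:
    """REML variance components of a random-intercept model (statsmodels MixedLM)."""
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ 1", daily, groups=daily["participant_id"])
        fit = model.fit(reml=True)
    var_b = float(fit.cov_re.iloc[0, 0])
    var_w = float(fit.scale)
    return var_b, var_w


def icc_random_intercept(
    daily: pd.DataFrame | Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> ICCResult:
    """One-way random-effects ICC of per-participant daily intake.

    Accepts a long DataFrame with columns ``participant_id`` and ``value``
    (a ``tdei_kcal`` column is also recognised) or a mapping of participant
    to daily values.  The confidence interval uses the exact F method on
    the ANOVA representation.
    """
    if isinstance(daily, Mapping):
        daily = pd.DataFrame(
            [(pid, v) for pid, vals in daily.items() for v in vals],
            columns=["participant_id", "value"],
        )
    else:
        daily = daily.rename(columns={"tdei_kcal": "value"})[
            ["participant_id", "value"]].copy()
    groups = [np.asarray(g["value"], dtype=float)
              for _, g in daily.groupby("participant_id", sort=False)]
    k = len(groups)
    if k < 2:
        raise DomainError("ICC needs at least 2 participants")
    if all(g.size < 2 for g in groups):
        raise DomainError("ICC needs repeated days for at least one participant")
    sizes = np.array([g.size for g in groups], dtype=float)
    N = sizes.sum()

    msb, msw, var_b_anova, var_w_anova = _icc_anova(groups)
    balanced = np.all(sizes == sizes[0])
    if balanced:
        var_b, var_w, method = var_b_anova, var_w_anova, "anova"
    else:
        var_b, var_w = _icc_reml(daily)
        method = "reml"
    total = var_b + var_w
    icc = var_b / total if total > 0 else 0.0

    # exact F interval on the ANOVA representation
    df1, df2 = k - 1.0, N - k
    n0 = (N - np.sum(sizes**2) / N) / (k - 1)
    f_stat = msb / msw if msw > 0 else math.inf
    if math.isfinite(f_stat):
        fl = f_stat / stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
        fu = f_stat * stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
        ci = ((fl - 1.0) / (fl + n0 - 1.0), (fu - 1.0) / (fu + n0 - 1.0))
    else:  # zero within-subject variance: degenerate perfect-agreement case
        ci = (1.0, 1.0)

    return ICCResult(
        icc=float(icc), ci=(float(ci[0]), float(ci[1])), f_stat=float(f_stat),
        df=(df1, df2), var_between=float(var_b), var_within=float(var_w),
        within_sd=float(math.sqrt(var_w)), ms_between=float(msb),
        ms_within=float(msw), method=method,
    )


def over_under_summary(pairs: PairedEstimates) -> OverUnderSummary:
    """Split the cohort by the sign of the difference and summarise each side.

    Percentage differences are per-participant, 100·(a−b)/b; the overall
    MPD is their mean.  Exact zero differences form their own count.
    """
    if pairs.n < 1:
        raise DomainError("over/under summary needs at least 1 pair")
    if np.any(pairs.value_b <= 0):
        raise DomainError("reference values must be positive for percentage differences")
    d = pairs.differences
    pct = 100.0 * d / pairs.value_b
    over = d > 0
    under = d < 0
    zero = d == 0

    def _mean(x: np.ndarray) -> float | None:
        return float(np.mean(x)) if x.size else None

    def _sd(x: np.ndarray) -> float | None:
        return float(np.std(x, ddof=1)) if x.size >= 2 else None

    return OverUnderSummary(
        n=pairs.n, n_over=int(over.sum()), n_under=int(under.sum()),
        n_zero=int(zero.sum()), mpd_overall=float(np.mean(pct)),
        mpd_over=_mean(pct[over]), mpd_under=_mean(pct[under]),
        mean_delta_over=_mean(d[over]), mean_delta_under=_mean(d[under]),
        sd_delta_over=_sd(d[over]), sd_delta_under=_sd(d[under]),
    )
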