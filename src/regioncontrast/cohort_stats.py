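"""Cohort-level statistics: Welch tests, non-inferiority, power, MWU, KS, Pearson.

The comparison framework mirrors a standard imaging-cohort analysis:

* Welch two-sample t-tests (unequal variances, alpha = 0.05) with 95%
  confidence intervals on the mean difference;
* one-sided non-inferiority tests of a new acquisition against a
  reference, with the margin expressed in normalized-contrast units
  (default -0.1, i.e. up to a 0.1 drop in contrast is tolerated);
* post-hoc power at the observed effect via the noncentral t;
* nonparametric Mann-Whitney U tests robust to unequal cohort sizes;
* one-sample Kolmogorov-Smirnov normality checks;
* Pearson correlations with Fisher-z 95% confidence intervals.

Welch-Satterthwaite degrees of freedom are used throughout for
consistency with the primary unequal-variance test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedCorrelationError

DEFAULT_NONINFERIORITY_MARGIN = -0.1
DEFAULT_ALPHA_TWO_SIDED = 0.05
DEFAULT_ALPHA_NONINFERIORITY = 0.025

Verdict = Literal["non_inferior", "inferior_not_shown", "inconclusive"]


@dataclass
class GroupSample:
    """A labeled cohort of per-case metric values."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group '{self.label}' contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=1))


@dataclass
class SummaryStats:
    """Sufficient statistics (mean, sd, n) of one group."""

    mean: float
    sd: float
    n: int

    @classmethod
    def of(cls, sample: GroupSample) -> "SummaryStats":
        return cls(mean=sample.mean, sd=sample.sd, n=sample.n)


@dataclass
class WelchResult:
    t: float
    df: float
    p_two_sided: float
    mean_diff: float
    ci95: tuple[float, float]
    se: float
    degenerate: bool = False


@dataclass
class NonInferiorityResult:
    """Outcome of a one-sided non-inferiority test of new vs reference.

    H0: mu_new - mu_ref <= margin (inferior); H1: > margin.
    ``verdict`` is ``non_inferior`` iff ``p_noninferiority < alpha``,
    which coincides exactly with the lower bound of the two-sided
    (1 - 2*alpha) confidence interval lying above the margin.
    """

    metric: str
    mean_diff: float
    ci95: tuple[float, float]
    p_two_sided: float
    p_noninferiority: float
    power_posthoc: float
    noninferiority_margin: float
    alpha_two_sided: float
    alpha_noninf: float
    verdict: Verdict
    t: float = np.nan
    df: float = np.nan
    degenerate: bool = False


def _welch_pieces(a: GroupSample, b: GroupSample) -> tuple[float, float, float]:
    """(mean difference, standard error, Welch-Satterthwaite df)."""
    if a.n < 2 or b.n < 2:
        raise ValueError("Welch test requires n >= 2 in both groups")
    va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
    sa2, sb2 = va / a.n, vb / b.n
    se = float(np.sqrt(sa2 + sb2))
    if se == 0:
        return float(a.mean - b.mean), 0.0, float(a.n + b.n - 2)
    df = (sa2 + sb2) ** 2 / (sa2**2 / (a.n - 1) + sb2**2 / (b.n - 1))
    return float(a.mean - b.mean), se, float(df)


def welch_test(a: GroupSample, b: GroupSample, ci_level: float = 0.95) -> WelchResult:
    """Welch two-sample t-test of mu_a - mu_b with a confidence interval.

    Zero variance in both groups is degenerate: equal means give p = 1,
    distinct means p = 0 (the difference is then known exactly).
    """
    diff, se, df = _welch_pieces(a, b)
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
        t_stat = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
        return WelchResult(
            t=t_stat, df=df, p_two_sided=p, mean_diff=diff, ci95=(diff, diff), se=0.0, degenerate=True
        )
    t_stat = diff / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df)
    return WelchResult(
        t=float(t_stat),
        df=df,
        p_two_sided=float(p),
        mean_diff=diff,
        ci95=(diff - tcrit * se, diff + tcrit * se),
        se=se,
    )


def posthoc_power(
    a: SummaryStats | GroupSample,
    b: SummaryStats | GroupSample,
    alpha: float = DEFAULT_ALPHA_TWO_SIDED,
    sided: Literal["two-sided", "one-sided"] = "two-sided",
    shift: float = 0.0,
    df_mode: Literal["welch", "pooled"] = "welch",
) -> float:
    """Power of the two-sample t-test at the observed effect size.

    Uses the noncentral t distribution with noncentrality
    (mean_a - mean_b - shift) / SE; ``shift`` is the tested null value
    (the margin, for a non-inferiority test; 0 otherwise). For two-sided
    tests the power is evaluated at the observed effect as a descriptive
    quantity only — post-hoc power is a monotone transform of the p-value
    and adds no inferential content.
    """
    if isinstance(a, GroupSample):
        a = SummaryStats.of(a)
    if isinstance(b, GroupSample):
        b = SummaryStats.of(b)
    if a.sd <= 0 and b.sd <= 0:
        raise ValueError("post-hoc power requires a positive standard deviation")
    sa2, sb2 = a.sd**2 / a.n, b.sd**2 / b.n
    se = np.sqrt(sa2 + sb2)
    if df_mode == "welch":
        df = (sa2 + sb2) ** 2 / (sa2**2 / (a.n - 1) + sb2**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    ncp = (a.mean - b.mean - shift) / se

    def _tail(value: float) -> float:
        # scipy's noncentral t returns nan in the extreme far tail, where
        # the probability mass is numerically zero
        return float(value) if np.isfinite(value) else 0.0

    if sided == "one-sided":
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return min(_tail(stats.nct.sf(tcrit, df, ncp)), 1.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    power = _tail(stats.nct.sf(tcrit, df, ncp)) + _tail(stats.nct.cdf(-tcrit, df, ncp))
    return min(power, 1.0)


def noninferiority_test(
    new: GroupSample,
    reference: GroupSample,
    margin: float = DEFAULT_NONINFERIORITY_MARGIN,
    alpha: float = DEFAULT_ALPHA_NONINFERIORITY,
    metric: str = "",
) -> NonInferiorityResult:
    """One-sided non-inferiority test of ``new`` against ``reference``.

    Tests H0: mu_new - mu_ref <= margin against H1: > margin with a
    shifted one-sided Welch t-test at level ``alpha`` (default 0.025).
    The verdict from the p-value rule and from the confidence-interval
    rule (lower bound of the two-sided (1 - 2*alpha) CI above the margin)
    agree by construction. Post-hoc power is computed at the observed
    difference against the margin.
    """
    if margin >= 0:
        raise ValueError(f"non-inferiority margin must be negative, got {margin}")
    diff, se, df = _welch_pieces(new, reference)
    two_sided = welch_test(new, reference, ci_level=1.0 - 2.0 * alpha)
    if se == 0:
        p_ni = 0.0 if diff > margin else 1.0
        verdict: Verdict = "non_inferior" if diff > margin else "inferior_not_shown"
        power = 1.0 if diff != margin else alpha
        return NonInferiorityResult(
            metric=metric,
            mean_diff=diff,
            ci95=two_sided.ci95,
            p_two_sided=two_sided.p_two_sided,
            p_noninferiority=p_ni,
            power_posthoc=power,
            noninferiority_margin=margin,
            alpha_two_sided=DEFAULT_ALPHA_TWO_SIDED,
            alpha_noninf=alpha,
            verdict=verdict,
            t=np.inf if diff > margin else -np.inf,
            df=df,
            degenerate=True,
        )
    t_stat = (diff - margin) / se
    p_ni = float(stats.t.sf(t_stat, df))
    verdict = "non_inferior" if p_ni < alpha else "inferior_not_shown"
    power = posthoc_power(
        SummaryStats.of(new), SummaryStats.of(reference), alpha=alpha, sided="one-sided", shift=margin
    )
    return NonInferiorityResult(
        metric=metric,
        mean_diff=diff,
        ci95=two_sided.ci95,
        p_two_sided=welch_test(new, reference).p_two_sided,
        p_noninferiority=p_ni,
        power_posthoc=power,
        noninferiority_margin=margin,
        alpha_two_sided=DEFAULT_ALPHA_TWO_SIDED,
        alpha_noninf=alpha,
        verdict=verdict,
        t=float(t_stat),
        df=df,
    )


def mwu_test(a: GroupSample, b: GroupSample) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) with U the statistic of group ``a`` (number of (a, b)
    pairs with a > b, ties counted 1/2). Exact enumeration is used for
    small tie-free samples (both n <= 8), a tie-corrected normal
    approximation otherwise.
    """
    has_ties = np.unique(np.concatenate([a.values, b.values])).size < a.n + b.n
    if max(a.n, b.n) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a.values, b.values, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class KSResult:
    statistic: float
    p: float
    degenerate: bool = False


def ks_normality(sample: GroupSample, lilliefors: bool = False) -> KSResult:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample's own mean and SD. With
    estimated parameters the classical KS p-value is conservative
    (too large); set ``lilliefors=True`` for the corrected variant.
    A constant sample has no scale and is flagged degenerate.
    """
    if sample.n < 5:
        raise ValueError("normality check requires n >= 5")
    sd = sample.sd
    if sd == 0:
        return KSResult(statistic=np.nan, p=np.nan, degenerate=True)
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lilliefors

        stat, p = _lilliefors(sample.values, dist="norm")
        return KSResult(statistic=float(stat), p=float(p))
    stat, p = stats.kstest(sample.values, "norm", args=(sample.mean, sd))
    return KSResult(statistic=float(stat), p=float(p))


@dataclass
class PearsonResult:
    r: float
    ci95: tuple[float, float]
    n: int


def pearson_with_ci(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson correlation with a Fisher z-transform 95% CI.

    CI: tanh(arctanh(r) +- z_{0.975} / sqrt(n - 3)). A correlation of
    exactly +-1 has a point CI at +-1.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = int(x.size)
    if n < 4:
        raise ValueError("Pearson CI requires n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("zero variance in x or y; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return PearsonResult(r=r, ci95=(r, r), n=n)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    return PearsonResult(r=r, ci95=(float(np.tanh(z - half)), float(np.tanh(z + half))), n=n)
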