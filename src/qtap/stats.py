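"""Group statistics for absolute-expression comparisons.

Implements the statistical layer used throughout the pipeline: the unpaired
pooled-variance Student's t-test in both raw-data and summary-statistic form,
a robust FDR-controlled outlier screen (a documented univariate variant of
the robust-regression-and-outlier-removal, "ROUT", idea), a Shapiro–Wilk
normality check, fold ratios at table precision, and exact noncentral-t power
and sample-size calculations for a two-sided two-sample design.

The raw and summary t-test forms share one code path by construction, so the
identity ``student_t_summary(summaries of X, Y) == student_t_raw(X, Y)``
holds to machine precision; tests cross-check both against
``scipy.stats.ttest_ind``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = [
    "GroupSummary",
    "TestResult",
    "NormalityResult",
    "PowerSpec",
    "student_t_raw",
    "student_t_summary",
    "rout_outliers",
    "normality_check",
    "fold_ratio",
    "round_sigfig",
    "power_two_sample_t",
    "simulated_power",
    "min_sample_size",
]

T_TEST_NAME = "unpaired two-sided Student's t (pooled variance)"


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SD summary of one group (fmol/μg or % of control)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ConfigurationError(f"group '{self.label}': n must be ≥ 2, got {self.n}")
        if self.sd < 0:
            raise ConfigurationError(f"group '{self.label}': sd must be ≥ 0, got {self.sd}")

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        x = np.asarray(values, dtype=float)
        return cls(label=label, n=x.size, mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)))


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    df: int
    p_value: float
    outliers_removed: tuple = ()
    test_name: str = T_TEST_NAME

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    passed: bool | None  # None marks a degenerate (constant) input
    degenerate: bool = False


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sided two-sample t power calculation.

    ``delta`` is the difference of group means in measurement units; ``sd1``
    and ``sd2`` are the group SDs, pooled as sqrt((sd1²+sd2²)/2).
    """

    delta: float
    sd1: float
    sd2: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.target_power < 1:
            raise ConfigurationError(f"target_power must be in (0, 1), got {self.target_power}")
        if self.delta == 0:
            raise ConfigurationError("delta must be nonzero")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ConfigurationError("group SDs must be nonnegative")

    @property
    def sd_pooled(self) -> float:
        return math.sqrt((self.sd1**2 + self.sd2**2) / 2.0)


def _pooled_t(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int,
              outliers_removed: tuple = ()) -> TestResult:
    """Pooled-variance two-sample t; single code path for raw and summary forms."""
    if n1 < 2 or n2 < 2:
        raise ConfigurationError(f"each group needs n ≥ 2 (got {n1}, {n2})")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return TestResult(t_statistic=t, df=df, p_value=p, outliers_removed=tuple(outliers_removed))


def student_t_raw(group_a, group_b, outliers_removed: tuple = ()) -> TestResult:
    """Unpaired two-sided Student's t-test on raw measurements."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError(f"each group needs n ≥ 2 (got {a.size}, {b.size})")
    return _pooled_t(
        float(np.mean(a)), float(np.std(a, ddof=1)), a.size,
        float(np.mean(b)), float(np.std(b, ddof=1)), b.size,
        outliers_removed,
    )


def student_t_summary(m1: float, sd1: float, n1: int,
                      m2: float, sd2: float, n2: int) -> TestResult:
    """Same test computed from printed (mean, SD, n) summaries.

    Enables re-deriving published table p-values without the raw animals'
    data; identical formulas to :func:`student_t_raw`.
    """
    return _pooled_t(m1, sd1, n1, m2, sd2, n2)


def rout_outliers(values, q: float = 0.01):
    """Robust FDR-controlled outlier screen on one group's measurements.

    A univariate ROUT-style procedure: the robust location is the median, the
    robust scale (RSDR) is the 68.27th percentile of absolute residuals with
    an n/(n−1) small-sample correction, and points are flagged from the most
    extreme inward with Benjamini–Hochberg control of the false discovery
    rate at ``q``.

    Parameters
    ----------
    values : array-like, length ≥ 3
    q : maximum desired FDR, in [0, 0.1]; ``q = 0`` flags nothing.

    Returns
    -------
    (kept, flagged) : kept values as ndarray; flagged as sorted list of
        positional indices into ``values``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ConfigurationError(f"outlier screen needs ≥ 3 values, got {n}")
    if not 0.0 <= q <= 0.1:
        raise ConfigurationError(f"ROUT q must be in [0, 0.1], got {q}")
    if q == 0.0:
        return x.copy(), []
    abs_resid = np.abs(x - np.median(x))
    rsdr = float(np.percentile(abs_resid, 68.27)) * n / (n - 1)
    if rsdr == 0.0:
        # majority of points identical: any deviation is infinitely extreme
        p = np.where(abs_resid > 0, 0.0, 1.0)
    else:
        p = 2.0 * sps.t.sf(abs_resid / rsdr, df=n - 1)
    order = np.argsort(-abs_resid, kind="stable")  # most extreme first
    p_sorted = p[order]
    thresholds = q * (np.arange(1, n + 1) / n)
    qualifying = np.nonzero(p_sorted <= thresholds)[0]
    k = int(qualifying.max()) + 1 if qualifying.size else 0
    flagged = sorted(int(i) for i in order[:k])
    kept = np.delete(x, flagged)
    return kept, flagged


def normality_check(values, alpha: float = 0.05) -> NormalityResult:
    """Shapiro–Wilk test of the normality null; pass ⇔ p ≥ alpha."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ConfigurationError(f"normality check needs ≥ 3 values, got {x.size}")
    if np.ptp(x) == 0.0:
        return NormalityResult(math.nan, math.nan, passed=None, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = sps.shapiro(x)
    return NormalityResult(float(stat), float(p), passed=bool(p >= alpha))


def fold_ratio(mean_treatment: float, mean_control: float) -> float:
    """Treatment/control fold ratio; NaN marks an undefined ratio (control 0).

    Full precision is returned; table rendering rounds to 2 significant
    figures via :func:`round_sigfig`.
    """
    if mean_control == 0 or not math.isfinite(mean_control):
        return math.nan
    return mean_treatment / mean_control


def round_sigfig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (table precision)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def power_two_sample_t(n_per_group: int, spec: PowerSpec) -> float:
    """Exact power of the two-sided two-sample t-test at n per group.

    Noncentrality λ = |delta| / (sd_pooled · sqrt(2/n)) with
    sd_pooled = sqrt((sd1² + sd2²)/2), df = 2n − 2;
    power = P(|T'(df, λ)| > t_crit).
    """
    if n_per_group < 2:
        raise ConfigurationError(f"n_per_group must be ≥ 2, got {n_per_group}")
    df = 2 * n_per_group - 2
    ncp = abs(spec.delta) / (spec.sd_pooled * math.sqrt(2.0 / n_per_group))
    t_crit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))


def simulated_power(n_per_group: int, spec: PowerSpec, n_sims: int = 100_000,
                    rng=None) -> float:
    """Monte-Carlo power of the same test; the simulation route is independent
    of the noncentral-t formula and serves as its cross-check."""
    rng = np.random.default_rng(rng)
    n = n_per_group
    a = rng.normal(0.0, spec.sd1, size=(n_sims, n))
    b = rng.normal(spec.delta, spec.sd2, size=(n_sims, n))
    df = 2 * n - 2
    sp2 = ((n - 1) * a.var(axis=1, ddof=1) + (n - 1) * b.var(axis=1, ddof=1)) / df
    se = np.sqrt(sp2 * (2.0 / n))
    t = (b.mean(axis=1) - a.mean(axis=1)) / se
    t_crit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(np.mean(np.abs(t) > t_crit))


def min_sample_size(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest per-group n with power ≥ target; increment-until-satisfied."""
    n = 2
    while power_two_sample_t(n, spec) < spec.target_power:
        n += 1
        if n > n_max:  # pragma: no cover - unreachable for delta != 0
            raise ConfigurationError("sample-size search did not converge")
    return n
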