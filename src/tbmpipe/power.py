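"""Small-sample power analysis: noncentral-t two-sample power and Fisher-z
Pearson-correlation power, with sample-size inversion and effect sizes."""

from __future__ import annotations

from math import atanh, ceil, sqrt

from scipy import stats

__all__ = [
    "ttest_power",
    "ttest_sample_size",
    "pearson_power",
    "pearson_sample_size",
    "cohens_d",
    "power_curve_ttest",
    "power_curve_pearson",
]


def _validate_alpha(alpha: float, tails: int) -> None:
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")


def ttest_power(d: float, n1: int, n2: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of a two-sample t-test at standardized effect size ``d``.

    Noncentral-t: df = n1 + n2 - 2, noncentrality d * sqrt(n1 n2 / (n1+n2)),
    power = P(|T'| > t_crit) for the two-tailed test.
    """
    _validate_alpha(alpha, tails)
    if d < 0:
        raise ValueError("d must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    from math import isnan

    df = n1 + n2 - 2
    nc = d * sqrt(n1 * n2 / (n1 + n2))
    if tails == 2:
        crit = stats.t.ppf(1 - alpha / 2, df)
        upper = float(stats.nct.sf(crit, df, nc))
        lower = float(stats.nct.cdf(-crit, df, nc))
        if isnan(lower):  # scipy far-tail issue at large noncentrality
            lower = 0.0
        return upper + lower
    crit = stats.t.ppf(1 - alpha, df)
    return float(stats.nct.sf(crit, df, nc))


def ttest_sample_size(
    d: float,
    alpha: float = 0.05,
    tails: int = 2,
    power: float = 0.8,
    allocation_ratio: float = 1.0,
    max_n: int = 1_000_000,
) -> int:
    """Smallest total N reaching the target power, with group sizes split by
    ``allocation_ratio`` = n2 / n1 (each group at least 2)."""
    if d <= 0:
        raise ValueError("d must be > 0")
    if not (0 < power < 1):
        raise ValueError("target power must be in (0, 1)")
    if allocation_ratio <= 0:
        raise ValueError("allocation ratio must be > 0")
    n1 = 2
    while True:
        n2 = max(2, round(n1 * allocation_ratio))
        if ttest_power(d, n1, n2, alpha, tails) >= power:
            return n1 + n2
        n1 += 1
        if n1 + n1 * allocation_ratio > max_n:
            raise RuntimeError("target power unreachable within max_n")


def pearson_power(r: float, n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Power to detect a Pearson correlation via the Fisher-z approximation:
    power = Phi(|z_r| sqrt(n-3) - z_crit) (+ the opposite tail when
    two-tailed)."""
    _validate_alpha(alpha, tails)
    if not (0 < abs(r) < 1):
        raise ValueError("|r| must be in (0, 1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    zr = abs(atanh(r)) * sqrt(n - 3)
    z_crit = stats.norm.ppf(1 - alpha / tails)
    power = stats.norm.cdf(zr - z_crit)
    if tails == 2:
        power += stats.norm.cdf(-zr - z_crit)
    return float(power)


def pearson_sample_size(
    r: float, alpha: float = 0.05, tails: int = 2, power: float = 0.8
) -> int:
    """Smallest n whose Fisher-z power reaches the target.

    Closed form n ~= ((z_crit + z_power) / atanh(r))^2 + 3 seeds the search;
    the returned n is the exact inverse of :func:`pearson_power`.
    """
    if not (0 < abs(r) < 1):
        raise ValueError("|r| must be in (0, 1)")
    if not (0 < power < 1):
        raise ValueError("target power must be in (0, 1)")
    z_crit = stats.norm.ppf(1 - alpha / tails)
    z_pow = stats.norm.ppf(power)
    n = max(4, ceil(((z_crit + z_pow) / abs(atanh(r))) ** 2 + 3) - 2)
    while pearson_power(r, n, alpha, tails) < power:
        n += 1
    return n


def cohens_d(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Standardized mean difference |mean_a - mean_b| / pooled sd."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("sds must be >= 0")
    pooled = sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    if pooled == 0:
        raise ZeroDivisionError("pooled sd is zero")
    return abs(mean_a - mean_b) / pooled


def power_curve_ttest(d_values, n1: int, n2: int, alpha: float = 0.05, tails: int = 2):
    """(d, power) rows for CSV export of a power curve."""
    return [(float(d), ttest_power(float(d), n1, n2, alpha, tails)) for d in d_values]


def power_curve_pearson(r_values, n: int, alpha: float = 0.05, tails: int = 2):
    """(r, power) rows for CSV export of a correlation power curve."""
    return [(float(r), pearson_power(float(r), n, alpha, tails)) for r in r_values]
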