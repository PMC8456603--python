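"""Growth-curve analysis and multiple-comparison statistics.

Doubling times come from the slope of ln(OD_t / OD_0) against time
(doubling time = ln 2 / slope).  Group comparisons follow the standard
stack for this kind of data: Kolmogorov–Smirnov normality screening,
Box-Cox transformation when normality is rejected, one-way ANOVA, and
simultaneous post-hoc comparisons — Dunnett's method against a designated
control and Tukey's method for all pairs.

The Dunnett equicoordinate critical value is computed here by direct
numerical integration of the equicorrelated multivariate-t
representation: with a balanced design the treatment-vs-control t
statistics share correlation 1/2 and can be written
T_i = (Z_i − Z_0) / (√2 S), Z's iid N(0,1), ν S² ~ χ²_ν, so

    P(max_i |T_i| ≤ c) = E_{S,Z_0} [Φ(Z_0 + √2 c S) − Φ(Z_0 − √2 c S)]^k

which is evaluated with Gauss–Hermite (Z_0) × Gauss–Legendre (the χ
quantile scale) quadrature and inverted for c by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from numpy.polynomial.legendre import leggauss
from scipy import optimize, stats

__all__ = [
    "GrowthCurve",
    "GroupTable",
    "DunnettResult",
    "NoGrowthError",
    "doubling_time",
    "ks_normality",
    "boxcox_transform",
    "anova_oneway",
    "dunnett_critical",
    "dunnett_test",
    "tukey_hsd",
]


class NoGrowthError(ValueError):
    """Raised when a culture's OD does not increase (no finite doubling time)."""


@dataclass
class GrowthCurve:
    times_min: np.ndarray
    od: np.ndarray
    od0: float | None = None  # defaults to the first OD value

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.od.size < 3:
            raise ValueError("growth curve needs at least 3 points")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be increasing")
        if np.any(self.od <= 0):
            raise ValueError("OD values must be positive")
        if self.od0 is None:
            self.od0 = float(self.od[0])


@dataclass
class GroupTable:
    """Tidy group/value data with an optional designated control group."""

    groups: dict[str, np.ndarray]
    control: str | None = None

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for name, v in self.groups.items():
            if v.size == 0:
                raise ValueError(f"group {name!r} is empty")
        if self.control is not None and self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} not present")

    @property
    def n_total(self) -> int:
        return sum(v.size for v in self.groups.values())

    def pooled_variance(self) -> tuple[float, int]:
        """Within-group (error) variance and its degrees of freedom."""
        df = self.n_total - len(self.groups)
        if df < 1:
            raise ValueError("no degrees of freedom for the pooled variance")
        ss = sum(
            float(np.sum((v - v.mean()) ** 2)) for v in self.groups.values()
        )
        return ss / df, df


@dataclass
class DunnettResult:
    comparisons: list[str]          # treatment group names
    statistics: np.ndarray          # t vs control
    critical_value: float
    significant: np.ndarray         # |t| > critical
    error_df: int
    n_comparisons: int
    alpha: float


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def doubling_time(curve: GrowthCurve) -> float:
    """Doubling time (min) = ln 2 / slope of ln(OD_t / OD_0) vs t."""
    y = np.log(curve.od / curve.od0)
    slope = float(np.polyfit(curve.times_min, y, 1)[0])
    if slope <= 0:
        raise NoGrowthError("culture is not growing (slope <= 0)")
    return math.log(2) / slope


# ---------------------------------------------------------------------------
# Normality and transformation
# ---------------------------------------------------------------------------

def ks_normality(values) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated mean and sd.

    With parameters estimated from the same sample the nominal p-value is
    conservative (the Lilliefors situation); it is reported as-is.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("KS normality screen needs n >= 5")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("constant data: normality test degenerate")
    res = stats.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return float(res.statistic), float(res.pvalue)


def boxcox_transform(values) -> tuple[np.ndarray, float]:
    """Box-Cox transform at the profile-likelihood-optimal λ.

    y = (x^λ − 1)/λ, or ln x at λ = 0; requires strictly positive input.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    lam = float(stats.boxcox_normmax(x, method="mle"))
    y = stats.boxcox(x, lmbda=lam)
    return np.asarray(y, dtype=float), lam


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_oneway(table: GroupTable) -> tuple[float, int, int]:
    """One-way ANOVA F with (between, within) degrees of freedom."""
    values = list(table.groups.values())
    k = len(values)
    n = table.n_total
    res = stats.f_oneway(*values)
    return float(res.statistic), k - 1, n - k


# ---------------------------------------------------------------------------
# Dunnett's method
# ---------------------------------------------------------------------------

_GH_NODES = 120
_GL_NODES = 400


@lru_cache(maxsize=256)
def _quad_nodes(df: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    zh, wh = hermegauss(_GH_NODES)
    wh = wh / math.sqrt(2 * math.pi)
    # Gauss-Legendre over the scale S = sqrt(chi2_df / df), weighted by its
    # density 2 df s chi2pdf(df s^2; df), on a bracket covering all but
    # ~1e-12 of the mass.
    s_lo = math.sqrt(stats.chi2.ppf(1e-12, df) / df)
    s_hi = math.sqrt(stats.chi2.ppf(1.0 - 1e-12, df) / df)
    xg, wg = leggauss(_GL_NODES)
    s = 0.5 * (s_hi - s_lo) * (xg + 1.0) + s_lo
    ws = 0.5 * (s_hi - s_lo) * wg * 2.0 * df * s * stats.chi2.pdf(df * s * s, df)
    return zh, wh, s, ws


def _dunnett_coverage(c: float, k: int, df: int, two_sided: bool) -> float:
    zh, wh, s, ws = _quad_nodes(df)
    a = math.sqrt(2.0) * c * s[:, None]
    upper = stats.norm.cdf(zh[None, :] + a)
    if two_sided:
        inner = (upper - stats.norm.cdf(zh[None, :] - a)) ** k
    else:
        inner = upper**k
    return float((inner @ wh * ws).sum())


@lru_cache(maxsize=1024)
def dunnett_critical(
    df: int, k: int, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """Equicoordinate critical point of Dunnett's many-to-one comparison.

    The value c solves P(max_i |T_i| ≤ c) = 1 − alpha (or max T_i for the
    one-sided test) for the k-variate t distribution with common
    correlation 1/2 — the balanced-design case — and ``df`` error degrees
    of freedom.  Accuracy is better than ±0.005.  For k = 1 this is the
    ordinary Student-t quantile.
    """
    if df < 2 or k < 1 or not (0 < alpha < 1):
        raise ValueError("require df >= 2, k >= 1, 0 < alpha < 1")
    if k == 1:
        q = 1 - alpha / 2 if two_sided else 1 - alpha
        return float(stats.t.ppf(q, df))
    return float(
        optimize.brentq(
            lambda c: _dunnett_coverage(c, k, df, two_sided) - (1 - alpha),
            0.5,
            15.0,
            xtol=1e-6,
        )
    )


def dunnett_test(table: GroupTable, alpha: float = 0.05) -> DunnettResult:
    """Simultaneous treatment-vs-control comparisons by Dunnett's method.

    T_i = (mean_i − mean_control) / sqrt(s² (1/n_i + 1/n_c)) with the
    pooled within-group variance s²; each |T_i| is compared with the
    balanced-design equicoordinate critical value at the familywise level
    ``alpha``.
    """
    if table.control is None:
        raise ValueError("table has no designated control group")
    s2, df = table.pooled_variance()
    ctrl = table.groups[table.control]
    names = [g for g in table.groups if g != table.control]
    t_stats = np.array(
        [
            (table.groups[g].mean() - ctrl.mean())
            / math.sqrt(s2 * (1.0 / table.groups[g].size + 1.0 / ctrl.size))
            for g in names
        ]
    )
    crit = dunnett_critical(df, len(names), alpha=alpha, two_sided=True)
    return DunnettResult(
        comparisons=names,
        statistics=t_stats,
        critical_value=crit,
        significant=np.abs(t_stats) > crit,
        error_df=df,
        n_comparisons=len(names),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Tukey's HSD
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


def tukey_hsd(table: GroupTable, alpha: float = 0.05) -> dict:
    """All-pairwise comparisons with the studentized-range (Tukey-Kramer) rule.

    Pair (i, j) is significant when
    |mean_i − mean_j| / sqrt(s²/2 (1/n_i + 1/n_j)) exceeds the
    1 − alpha studentized-range quantile q(k, df).
    """
    if len(table.groups) < 3:
        raise ValueError("Tukey HSD needs at least 3 groups")
    s2, df = table.pooled_variance()
    names = list(table.groups)
    qc = _q_crit(alpha, len(names), df)
    pairs, qs, sig = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = table.groups[names[i]], table.groups[names[j]]
            q = abs(a.mean() - b.mean()) / math.sqrt(
                s2 / 2.0 * (1.0 / a.size + 1.0 / b.size)
            )
            pairs.append((names[i], names[j]))
            qs.append(q)
            sig.append(q > qc)
    return {
        "pairs": pairs,
        "q_statistics": np.array(qs),
        "critical_value": qc,
        "significant": np.array(sig),
        "error_df": df,
        "alpha": alpha,
    }
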