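"""Inferential battery for pre/post two-group intervention studies.

Every statistic here is computed from its defining formula (sums of squares,
cell means, the Fisher transform, the Benjamini-Hochberg step-up) rather than
delegated to a model-fitting library; scipy supplies only the reference
distributions (t, F, chi-square, normal, noncentral t) for p-values and power.

Sign conventions
----------------
* Two-sample t: numerator is ``group2 - group1`` (pooled Student variance by
  default, Welch optional).
* Paired t: differences are ``pre - post``, so an improvement on a
  higher-is-better measure yields a negative t; Cohen's d is ``t / sqrt(n)``
  exactly.
* Fisher r-to-z comparison: ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) +
  1/(n2-3))``; swapping the arguments negates z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CorrelationComparison",
    "two_sample_t",
    "two_sample_t_from_stats",
    "paired_t",
    "mixed_anova_2x2",
    "partial_eta_squared",
    "pearson_change_correlation",
    "fisher_z_compare",
    "benjamini_hochberg",
    "chi_square_2x2",
    "paired_t_power",
    "power_paired_n",
    "tmt_b_minus_a",
]


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis test: statistic, df, p, effect size, sample sizes."""

    family: str
    statistic: float
    df: float | tuple[float, float]
    p_two_sided: float
    p_one_sided: float | None = None
    effect_size: float | None = None
    n: int | tuple[int, int] | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p_two_sided": self.p_two_sided,
            "p_one_sided": self.p_one_sided,
            "effect_size": self.effect_size,
            "n": list(self.n) if isinstance(self.n, tuple) else self.n,
        }
        d.update(self.extra)
        return d


@dataclass(frozen=True)
class CorrelationComparison:
    """Fisher r-to-z test of equality of two independent correlations."""

    r1: float
    r2: float
    n1: int
    n2: int
    z: float
    p_one_sided: float
    p_two_sided: float


def _sd(x: np.ndarray, ddof: int = 1) -> float:
    return float(np.std(x, ddof=ddof))


def two_sample_t_from_stats(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    *,
    welch: bool = False,
) -> TestResult:
    """Independent two-sample t from summary statistics (group2 - group1)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    diff = mean2 - mean1
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both group SDs are zero; t is undefined")
    v1, v2 = sd1 ** 2, sd2 ** 2
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)
    t = diff / math.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    # Cohen's d with the pooled SD, even under Welch, as the descriptive effect
    sp = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = diff / sp if sp > 0 else float("nan")
    return TestResult(
        family="two_sample_t",
        statistic=float(t),
        df=df,
        p_two_sided=float(p),
        p_one_sided=float(sps.t.sf(abs(t), df)),
        effect_size=float(d),
        n=(n1, n2),
    )


def two_sample_t(group1=None, group2=None, *, welch: bool = False, **summary) -> TestResult:
    """Two-sample t from raw vectors, or from summary stats via keywords.

    ``two_sample_t(x, y)`` uses the raw-vector path; the summary-statistic path
    is ``two_sample_t(mean1=..., sd1=..., n1=..., mean2=..., sd2=..., n2=...)``.
    """
    if group2 is None and summary:
        return two_sample_t_from_stats(welch=welch, **summary)
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    return two_sample_t_from_stats(
        float(x.mean()), _sd(x), x.size, float(y.mean()), _sd(y), y.size, welch=welch
    )


def paired_t(pre: Sequence[float], post: Sequence[float]) -> TestResult:
    """Paired-samples t on ``pre - post`` differences; d = t / sqrt(n) exactly."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post length mismatch")
    n = pre.size
    if n < 2:
        raise ValueError("paired t needs n >= 2")
    d = pre - post
    sd = _sd(d)
    if sd == 0:
        if d.mean() == 0:
            t = 0.0
        else:
            raise ValueError("zero variance of differences with nonzero mean: t is infinite")
    else:
        t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    return TestResult(
        family="paired_t",
        statistic=t,
        df=float(df),
        p_two_sided=float(2.0 * sps.t.sf(abs(t), df)),
        p_one_sided=float(sps.t.sf(abs(t), df)),
        effect_size=t / math.sqrt(n),
        n=n,
        extra={"mean_difference": float(d.mean()), "sd_difference": sd},
    )


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """ANOVA effect size: F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive dfs")
    return F * df1 / (F * df1 + df2)


def mixed_anova_2x2(frame: pd.DataFrame, measure: str) -> TestResult:
    """Time-by-Group interaction of a 2 (group) x 2 (pre/post) mixed ANOVA.

    Computed from the within-subject error decomposition: the time contrast
    per subject is ``(post - pre) / 2``; the interaction sum of squares is the
    between-group spread of its group means and the error term is its pooled
    within-group variation, giving F with df (1, N - 2).  Algebraically this F
    equals the squared pooled two-sample t on raw change scores.

    ``frame`` is a long CohortFrame (participant, group, time, measure, value);
    participants missing either timepoint are dropped with a recorded count.
    """
    sub = frame[frame["measure"] == measure]
    if sub.empty:
        raise ValueError(f"measure {measure!r} not present")
    wide = sub.pivot_table(
        index=["participant", "group"], columns="time", values="value", aggfunc="first"
    )
    for col in ("pre", "post"):
        if col not in wide.columns:
            raise ValueError(f"measure {measure!r} lacks timepoint {col!r}")
    n_dropped = int(wide[["pre", "post"]].isna().any(axis=1).sum())
    wide = wide.dropna(subset=["pre", "post"])
    groups = wide.index.get_level_values("group")
    names = sorted(set(groups))
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {names}")
    g1 = wide[groups == names[0]]
    g2 = wide[groups == names[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 complete cases")

    # within-subject time contrast, one value per subject
    c1 = ((g1["post"] - g1["pre"]) / 2.0).to_numpy()
    c2 = ((g2["post"] - g2["pre"]) / 2.0).to_numpy()
    n1, n2 = c1.size, c2.size
    n_total = n1 + n2
    grand = (c1.sum() + c2.sum()) / n_total
    # interaction SS: group spread of contrast means (x2 for the two time cells)
    ss_int = 2.0 * (n1 * (c1.mean() - grand) ** 2 + n2 * (c2.mean() - grand) ** 2)
    ss_err = 2.0 * (((c1 - c1.mean()) ** 2).sum() + ((c2 - c2.mean()) ** 2).sum())
    df1, df2 = 1.0, float(n_total - 2)
    if ss_err == 0:
        raise ValueError("zero within-group change variance; F is undefined")
    F = (ss_int / df1) / (ss_err / df2)
    return TestResult(
        family="anova_interaction",
        statistic=float(F),
        df=(df1, df2),
        p_two_sided=float(sps.f.sf(F, df1, df2)),
        effect_size=partial_eta_squared(F, df1, df2),
        n=(n1, n2),
        extra={
            "ss_interaction": float(ss_int),
            "ss_error": float(ss_err),
            "n_dropped_incomplete": n_dropped,
            "group_order": names,
        },
    )


def pearson_change_correlation(dx: Sequence[float], dy: Sequence[float]) -> TestResult:
    """Pearson r between two change-score vectors with the exact-null t test.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) on df = n - 2.
    """
    x = np.asarray(dx, dtype=float)
    y = np.asarray(dy, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 4:
        raise ValueError("correlation test needs n >= 4")
    if _sd(x) == 0 or _sd(y) == 0:
        raise ValueError("constant input; correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc * yc).sum() / math.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t, p = math.inf, 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        family="pearson_r",
        statistic=float(t),
        df=float(df),
        p_two_sided=float(p),
        p_one_sided=float(p / 2.0),
        effect_size=r,
        n=n,
        extra={"r": r},
    )


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two independent correlations via the Fisher transform.

    Note on sidedness: both tails are reported.  The study context this
    battery reproduces quotes one-sided normal tail probabilities alongside a
    two-sided significance rule; downstream reports flag that discrepancy.
    """
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError(f"correlations must be strictly inside (-1, 1), got {r}")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("Fisher comparison needs n >= 4 per group")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return CorrelationComparison(
        r1=r1,
        r2=r2,
        n1=n1,
        n2=n2,
        z=float(z),
        p_one_sided=float(sps.norm.sf(abs(z))),
        p_two_sided=float(2.0 * sps.norm.sf(abs(z))),
    )


def benjamini_hochberg(pvals: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Standard BH step-up: adjusted p-values and rejection flags at level q.

    adjusted_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order; rejection means adjusted <= q.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    n = counts.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(mg == 0 for mg in margins):
        raise ValueError("zero margin; chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / math.prod(margins)
    return TestResult(
        family="chi_square",
        statistic=float(chi2),
        df=1.0,
        p_two_sided=float(sps.chi2.sf(chi2, 1)),
        n=int(n),
        extra={"phi": math.copysign(math.sqrt(chi2 / n), a * d - b * c)},
    )


def paired_t_power(n: int, d: float, alpha: float = 0.05, two_sided: bool = True) -> float:
    """Power of the paired/one-sample t-test via the noncentral t distribution."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = d * math.sqrt(n)
    if two_sided:
        tcrit = sps.t.isf(alpha / 2.0, df)
        return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    tcrit = sps.t.isf(alpha, df)
    return float(sps.nct.sf(tcrit, df, ncp))


def power_paired_n(
    d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    *,
    two_sided: bool = True,
    n_max: int = 1_000_000,
) -> int:
    """Smallest n whose paired-t power reaches the target (noncentral t)."""
    if d == 0:
        raise ValueError("effect size must be nonzero")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie strictly in (0, 1)")
    d = abs(d)
    lo, hi = 2, 2
    while paired_t_power(hi, d, alpha, two_sided) < power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power unattainable below n = {n_max}")
    # power is nondecreasing in n here; bisect for the threshold
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if paired_t_power(mid, d, alpha, two_sided) >= power:
            hi = mid
        else:
            lo = mid
    n = hi if paired_t_power(lo, d, alpha, two_sided) < power else lo
    return max(n, 2)


def tmt_b_minus_a(b_sec, a_sec):
    """Trail-making derived score: Part B time minus Part A time.

    Accepts scalars or aligned vectors; inputs must be positive completion
    times in seconds.
    """
    b = np.asarray(b_sec, dtype=float)
    a = np.asarray(a_sec, dtype=float)
    if np.any(b <= 0) or np.any(a <= 0):
        raise ValueError("completion times must be positive")
    out = b - a
    return float(out) if out.ndim == 0 else out
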