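"""Group and longitudinal statistics for thickness data.

The battery mirrors standard practice for this kind of longitudinal design:

* normality screening per sample (Lilliefors-type Kolmogorov-Smirnov with
  estimated mean/SD; the null distribution of the statistic is obtained by
  seeded Monte-Carlo, m = 2000, since the classical KS table is invalid once
  parameters are estimated), at a 10% significance level;
* two-group comparisons with Welch's t-test when both samples pass the
  normality screen, Mann-Whitney U otherwise, Bonferroni-corrected across
  the layers compared at each time point;
* one-way repeated-measures ANOVA (subjects as blocks) over age, replaced by
  the Friedman test when any time point fails normality, on complete cases
  only (eyes measured at every age);
* mixed-design (two-way repeated-measures) ANOVA for group, time and
  group x time effects;
* Tukey-Kramer pairwise age comparisons on the repeated-measures error term,
  using the studentized-range distribution.

Significance is reported at the 5%, 1% and 0.1% levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "LongitudinalTable",
    "PairwiseMatrix",
    "normality",
    "compare_groups",
    "welch_from_summary",
    "complete_cases",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "tukey_kramer",
]

ALPHA_LEVELS = (0.05, 0.01, 0.001)


def stars(p: float, levels: Sequence[float] = ALPHA_LEVELS) -> str:
    """Significance stars: '*' < 0.05, '**' < 0.01, '***' < 0.001."""
    if not np.isfinite(p):
        return ""
    return "*" * sum(p < lv for lv in sorted(levels, reverse=True))


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p: float
    df: Optional[tuple] = None
    p_adj: Optional[float] = None
    n: Optional[tuple] = None
    extra: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return stars(self.p_adj if self.p_adj is not None else self.p)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p out of range: {self.p}")


@dataclass
class LongitudinalTable:
    """Complete-case subjects x time points matrix for one stratum."""

    values: np.ndarray  # (n_subjects, n_times)
    subjects: list
    times: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (subjects x times)")
        if np.isnan(v).any():
            raise ValueError("complete-case table must have no missing cells")
        if v.shape != (len(self.subjects), len(self.times)):
            raise ValueError("values shape must match subjects x times")
        self.values = v

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    def to_long(self) -> pd.DataFrame:
        n, k = self.values.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(self.subjects, k),
                "time": np.tile(self.times, n),
                "value": self.values.ravel(),
            }
        )


@dataclass
class PairwiseMatrix:
    """Symmetric time x time matrix of adjusted p-values (diagonal 1)."""

    p: pd.DataFrame

    def __post_init__(self) -> None:
        a = self.p.to_numpy()
        if not np.allclose(a, a.T, equal_nan=True):
            raise ValueError("pairwise matrix must be symmetric")

    def stars(self) -> pd.DataFrame:
        return self.p.map(stars)


# ------------------------------------------------------------- normality


@lru_cache(maxsize=256)
def _lilliefors_null(n: int, m: int, seed: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors KS statistic."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((m, n))
    x.sort(axis=1)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf((x - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.sort(np.maximum(d_plus, d_minus))


def lilliefors_statistic(values: np.ndarray) -> float:
    x = np.sort(np.asarray(values, float))
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))


def normality(
    values, alpha: float = 0.10, m: int = 2000, seed: int = 0
) -> tuple[bool, TestResult]:
    """Kolmogorov-Smirnov normality screen with estimated parameters.

    The null distribution of the statistic is simulated (m replicates,
    seeded), so the test is correctly calibrated despite the estimated mean
    and SD. Returns (is_normal, result); normal iff p >= alpha. Zero-variance
    input is never normal.
    """
    x = np.asarray(values, float)
    if x.size < 4:
        raise ValueError("need at least 4 values for the normality screen")
    if x.std(ddof=1) == 0:
        return False, TestResult("lilliefors-mc", np.inf, 0.0, n=(x.size,))
    d = lilliefors_statistic(x)
    null = _lilliefors_null(x.size, m, seed)
    p = float((1 + (null >= d).sum()) / (m + 1))
    return p >= alpha, TestResult("lilliefors-mc", d, p, n=(x.size,))


# ------------------------------------------------------- group comparisons


def welch_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Welch's t-test from summary statistics (Satterthwaite df, two-sided)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sds must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("ns must be >= 2")
    t, p = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    se2 = sd1**2 / n1 + sd2**2 / n2
    df = se2**2 / (
        (sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1)
    )
    return TestResult("welch-t", float(t), float(p), df=(df,), n=(n1, n2))


def compare_groups(
    a,
    b,
    m_comparisons: int = 1,
    alpha_normality: float = 0.10,
    seed: int = 0,
    force: Optional[str] = None,
) -> TestResult:
    """Two-group comparison with normality gating and Bonferroni correction.

    Welch's t-test when both samples pass the normality screen, Mann-Whitney
    U otherwise (exact distribution for small tie-free samples, normal
    approximation with tie correction beyond n = 20). The adjusted p-value is
    min(1, m * p) for ``m_comparisons`` simultaneous tests. ``force`` may be
    'welch' or 'mannwhitney' to skip the gate.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 4 or b.size < 4:
        return TestResult(
            "insufficient-data", np.nan, np.nan, n=(a.size, b.size)
        )
    if force is None:
        norm_a, _ = normality(a, alpha_normality, seed=seed)
        norm_b, _ = normality(b, alpha_normality, seed=seed)
    elif force in ("welch", "mannwhitney"):
        norm_a = norm_b = force == "welch"
    else:
        raise ValueError(f"unknown force {force!r}")
    if norm_a and norm_b:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:  # unreachable via gate
            res = TestResult("welch-t", 0.0, 1.0, n=(a.size, b.size))
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
            df = sps.ttest_ind(a, b, equal_var=False).df
            res = TestResult(
                "welch-t", float(t), float(p), df=(float(df),), n=(a.size, b.size)
            )
    else:
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 20 and not ties) else "asymptotic"
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        res = TestResult("mann-whitney", float(u), float(p), n=(a.size, b.size))
    res.p_adj = min(1.0, m_comparisons * res.p) if np.isfinite(res.p) else np.nan
    res.extra["normal"] = (norm_a, norm_b)
    return res


# --------------------------------------------------------- repeated measures


def complete_cases(
    records: pd.DataFrame,
    times: Sequence | None = None,
    subject_col: str = "subject",
    time_col: str = "time",
    value_col: str = "value",
) -> tuple[LongitudinalTable, list]:
    """Keep only subjects measured at every requested time point.

    Returns the complete-case table plus the dropped subject ids. Duplicate
    (subject, time) records are averaged.
    """
    wide = records.pivot_table(
        index=subject_col, columns=time_col, values=value_col, aggfunc="mean"
    )
    if times is not None:
        missing_t = [t for t in times if t not in wide.columns]
        for t in missing_t:
            wide[t] = np.nan
        wide = wide[list(times)]
    keep = wide.dropna()
    dropped = sorted(set(wide.index) - set(keep.index))
    if keep.empty:
        raise ValueError("no subject was measured at every requested time point")
    return (
        LongitudinalTable(keep.to_numpy(), list(keep.index), list(keep.columns)),
        dropped,
    )


def _rm_ss(x: np.ndarray) -> tuple[float, float, float, float]:
    """Sums of squares of the one-way repeated-measures decomposition."""
    n, k = x.shape
    grand = x.mean()
    ss_time = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    return ss_time, ss_subj, ss_err, ss_total


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor."""
    k = x.shape[1]
    s = np.cov(x, rowvar=False)
    s_c = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(s_c) ** 2
    den = (k - 1) * (s_c**2).sum()
    return float(num / den) if den > 0 else 1.0


def rm_anova_oneway(
    table: LongitudinalTable,
    alpha_normality: float = 0.10,
    seed: int = 0,
    force: Optional[str] = None,
    greenhouse_geisser: bool = False,
) -> TestResult:
    """Within-subject effect of time: repeated-measures ANOVA or Friedman.

    The parametric F (subjects as blocks) is used when every time point
    passes the normality screen; otherwise the Friedman test. ``force`` may
    be 'ranova' or 'friedman' to skip the gate. No sphericity correction is
    applied by default; ``greenhouse_geisser=True`` adjusts the F-test df.
    """
    x = table.values
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 time points and >= 3 subjects")
    if force is None:
        # the screen needs n >= 4; smaller tables default to the parametric F
        normal = n < 4 or all(
            x[:, j].std(ddof=1) == 0 or normality(x[:, j], alpha_normality, seed=seed)[0]
            for j in range(k)
        )
        method = "ranova" if normal else "friedman"
    else:
        method = force
    if method == "ranova":
        ss_time, _, ss_err, ss_total = _rm_ss(x)
        df1, df2 = k - 1, (k - 1) * (n - 1)
        if ss_time <= 1e-12 * max(ss_total, 1.0):
            return TestResult("ranova", 0.0, 1.0, df=(df1, df2), n=(n, k))
        ms_time = ss_time / df1
        ms_err = ss_err / df2
        f = ms_time / ms_err if ms_err > 0 else np.inf
        if greenhouse_geisser:
            eps = _gg_epsilon(x)
            p = float(sps.f.sf(f, df1 * eps, df2 * eps))
        else:
            p = float(sps.f.sf(f, df1, df2))
        return TestResult(
            "ranova", float(f), p, df=(df1, df2), n=(n, k),
            extra={"ms_err": ms_err},
        )
    if method == "friedman":
        if k < 3:
            raise ValueError("Friedman test needs >= 3 time points")
        if np.allclose(x, x[:, [0]]):
            return TestResult("friedman", 0.0, 1.0, df=(k - 1,), n=(n, k))
        stat, p = sps.friedmanchisquare(*(x[:, j] for j in range(k)))
        return TestResult("friedman", float(stat), float(p), df=(k - 1,), n=(n, k))
    raise ValueError(f"unknown method {method!r}")


def rm_anova_twoway(
    tables: dict[str, LongitudinalTable],
) -> dict[str, TestResult]:
    """Mixed-design ANOVA: between-subject group, within-subject time, and
    group x time interaction. Both groups must be complete-case tables over
    the same time points."""
    if len(tables) < 2:
        raise ValueError("need at least two groups")
    if any(t.n_times < 2 for t in tables.values()):
        raise ValueError("need at least two time points")
    times = None
    frames = []
    for g, t in tables.items():
        if times is None:
            times = list(t.times)
        elif list(t.times) != times:
            raise ValueError("groups must share the same time points")
        d = t.to_long()
        d["group"] = g
        d["subject"] = [f"{g}:{s}" for s in d["subject"]]
        frames.append(d)
    long = pd.concat(frames, ignore_index=True)
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(
            data=long, dv="value", within="time", subject="subject", between="group"
        )
    aov = aov.set_index("Source")
    out = {}
    for src, name in (("group", "group"), ("time", "time"),
                      ("Interaction", "interaction")):
        row = aov.loc[src]
        f = float(row.F)
        p = float(row["p_unc"])
        if not np.isfinite(f):  # degenerate (e.g. identical groups)
            f, p = 0.0, 1.0
        out[name] = TestResult(
            f"mixed-anova-{name}", f, p, df=(float(row.DF1), float(row.DF2))
        )
    return out


def tukey_kramer(
    table: LongitudinalTable,
) -> PairwiseMatrix:
    """All pairwise time comparisons on the repeated-measures error term.

    q = |mean_i - mean_j| / sqrt(MS_error / n), referred to the studentized
    range distribution with k groups and (k-1)(n-1) df. With k = 2 this
    reduces to the paired comparison on the same error term.
    """
    x = table.values
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 time points")
    _, _, ss_err, _ = _rm_ss(x)
    df_err = (k - 1) * (n - 1)
    ms_err = ss_err / df_err
    means = x.mean(axis=0)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if ms_err <= 0:
                pij = 1.0 if means[i] == means[j] else 0.0
            else:
                q = abs(means[i] - means[j]) / np.sqrt(ms_err / n)
                pij = float(sps.studentized_range.sf(q, k, df_err))
            p[i, j] = p[j, i] = min(1.0, pij)
    return PairwiseMatrix(pd.DataFrame(p, index=table.times, columns=table.times))
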