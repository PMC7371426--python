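"""Group summaries and the hypothesis tests used in the reporting layer.

Defaults mirror the analysis conventions of the study design this package
serves: probability-of-firing comparisons are nonparametric (Mann-Whitney /
Kruskal-Wallis + Dunn), other metrics parametric (t-test / ANOVA + Tukey or
Sidak), repeated measures get Greenhouse-Geisser corrected degrees of
freedom. All tests are two-sided; no significance gating is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float
    median: float
    q1: float
    q3: float
    units: str = ""


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    comparison: str = ""
    family: str = ""
    df: tuple = ()
    extras: dict = field(default_factory=dict)


def summarize(values, group: str = "", units: str = "") -> GroupSummary:
    """Mean +/- SEM (sample sd, n-1) and linear-interpolation quartiles."""
    x = np.asarray(list(values), dtype=float)
    if len(x) < 1:
        raise ValueError("need at least one value")
    n = len(x)
    sem = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return GroupSummary(group=group, n=n, mean=float(x.mean()), sem=sem,
                        median=float(med), q1=float(q1), q3=float(q3),
                        units=units)


# ------------------------------------------------------------------ two-group
EXACT_MW_MAX_N = 8


def compare_two_unpaired(a, b, mode: str = "mann_whitney",
                         comparison: str = "", welch: bool = False) -> TestResult:
    """Two-sample unpaired comparison.

    Mann-Whitney is exact (full enumeration) when min(n) <= 8 and the pooled
    data are tie-free, otherwise a tie-corrected normal approximation. The
    t-test is Student (pooled variance) by default with a Welch option.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both samples must be nonempty")
    if mode == "mann_whitney":
        pooled = np.concatenate([a, b])
        ties = len(np.unique(pooled)) < len(pooled)
        if np.ptp(pooled) == 0:
            # fully tied data: U sits at its mean, p = 1 by symmetry
            u = len(a) * len(b) / 2.0
            return TestResult(test="mann_whitney", statistic=u, p_value=1.0,
                              comparison=comparison,
                              extras={"method": "degenerate-all-tied"})
        method = "exact" if (min(len(a), len(b)) <= EXACT_MW_MAX_N and not ties) \
            else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return TestResult(test="mann_whitney", statistic=float(res.statistic),
                          p_value=float(res.pvalue), comparison=comparison,
                          extras={"method": method})
    if mode == "t_test":
        res = sps.ttest_ind(a, b, equal_var=not welch)
        return TestResult(test="welch_t" if welch else "student_t",
                          statistic=float(res.statistic),
                          p_value=float(res.pvalue), comparison=comparison,
                          df=(float(res.df),))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------- multi-group
def _dunn_pairwise(groups: dict) -> list:
    """Dunn's rank-based multiple comparisons with tie correction.

    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)),
    T = sum(t^3 - t); two-sided p values Bonferroni-adjusted over the family.
    """
    labels = sorted(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    ns = np.array([len(d) for d in data])
    pooled = np.concatenate(data)
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g, n in zip(labels, ns):
        mean_ranks[g] = float(np.mean(ranks[start:start + n]))
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term / (12.0 * (n_tot - 1))
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(max(var_base, 0.0)
                     * (1.0 / len(groups[g1]) + 1.0 / len(groups[g2])))
        if se == 0.0:  # all observations tied: no evidence either way
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[g1] - mean_ranks[g2]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
        out.append(TestResult(test="dunn", statistic=float(z),
                              p_value=float(min(1.0, p_raw * m)),
                              comparison=f"{g1} vs {g2}", family="dunn",
                              extras={"p_unadjusted": float(p_raw)}))
    return out


def _tukey_pairwise(groups: dict) -> list:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = sorted(groups)
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    codes = np.concatenate([[g] * len(groups[g]) for g in labels])
    res = pairwise_tukeyhsd(values, codes)
    out = []
    for row in res.summary().data[1:]:
        g1, g2, meandiff, p_adj = row[0], row[1], float(row[2]), float(row[3])
        out.append(TestResult(test="tukey", statistic=meandiff, p_value=p_adj,
                              comparison=f"{g1} vs {g2}", family="tukey"))
    return out


def _sidak_pairwise(groups: dict) -> list:
    labels = sorted(groups)
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for g1, g2 in combinations(labels, 2):
        res = sps.ttest_ind(groups[g1], groups[g2], equal_var=True)
        p_adj = 1.0 - (1.0 - float(res.pvalue)) ** m
        out.append(TestResult(test="sidak_t", statistic=float(res.statistic),
                              p_value=min(1.0, p_adj),
                              comparison=f"{g1} vs {g2}", family="sidak",
                              extras={"p_unadjusted": float(res.pvalue)}))
    return out


def compare_many(groups: dict, mode: str = "kruskal_dunn") -> dict:
    """Omnibus test + post-hoc pairwise comparisons for >= 2 groups.

    ``groups`` maps label -> 1-D values. Returns {"omnibus": TestResult,
    "pairwise": [TestResult, ...]}. Post-hoc adjusted p-values are never
    smaller than their unadjusted counterparts.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(list(v), dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if not len(v):
            raise ValueError(f"group {g!r} is empty")
    if mode == "kruskal_dunn":
        pooled = np.concatenate(list(arrays.values()))
        if np.ptp(pooled) == 0:  # every observation tied (e.g. ceiling data)
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*[arrays[g] for g in sorted(arrays)])
        omnibus = TestResult(test="kruskal_wallis", statistic=float(h),
                             p_value=float(p), df=(len(arrays) - 1,))
        pairwise = _dunn_pairwise(arrays)
    elif mode in ("anova_tukey", "anova_sidak"):
        f, p = sps.f_oneway(*[arrays[g] for g in sorted(arrays)])
        n_tot = sum(len(v) for v in arrays.values())
        omnibus = TestResult(test="anova", statistic=float(f),
                             p_value=float(p),
                             df=(len(arrays) - 1, n_tot - len(arrays)))
        pairwise = _tukey_pairwise(arrays) if mode == "anova_tukey" \
            else _sidak_pairwise(arrays)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"omnibus": omnibus, "pairwise": pairwise}


# ------------------------------------------------ repeated measures (mixed)
def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """GG epsilon from the covariance matrix of the repeated measures."""
    b = cov.shape[0]
    centered = cov - cov.mean(axis=0, keepdims=True) \
        - cov.mean(axis=1, keepdims=True) + cov.mean()
    num = np.trace(centered) ** 2
    den = (b - 1) * np.sum(centered ** 2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (b - 1), 1.0))


def repeated_measures_anova(values, between=None) -> dict:
    """One within-factor (columns) ANOVA, optional between-group factor.

    ``values`` is subjects x levels (balanced within-factor: every subject
    has every level; NaNs = missing cells are rejected). Returns F tests for
    the within factor, the between factor, and their interaction, with
    Greenhouse-Geisser sphericity-corrected degrees of freedom for the
    within-subject effects.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be a subjects x levels matrix")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells: values must be complete")
    s, b = x.shape
    if b < 2 or s < 2:
        raise ValueError("need >= 2 subjects and >= 2 within levels")

    if between is None:
        labels = np.zeros(s, dtype=int)
    else:
        labels = np.asarray(between)
        if len(labels) != s:
            raise ValueError("between labels must match subject count")
    uniq = np.unique(labels)
    a = len(uniq)
    if s - a < 1:
        raise ValueError("need more subjects than groups")

    grand = x.mean()
    subj_mean = x.mean(axis=1)
    time_mean = x.mean(axis=0)
    ss_total = float(np.sum((x - grand) ** 2))
    ss_between_subj = float(b * np.sum((subj_mean - grand) ** 2))
    ss_within_subj = ss_total - ss_between_subj

    group_mean = {g: x[labels == g].mean() for g in uniq}
    ng = {g: int(np.sum(labels == g)) for g in uniq}
    ss_a = float(b * sum(ng[g] * (group_mean[g] - grand) ** 2 for g in uniq))
    ss_subj_err = ss_between_subj - ss_a

    ss_t = float(s * np.sum((time_mean - grand) ** 2))
    ss_axt = 0.0
    for g in uniq:
        cell = x[labels == g].mean(axis=0)
        ss_axt += ng[g] * np.sum((cell - group_mean[g] - time_mean + grand) ** 2)
    ss_axt = float(ss_axt)
    ss_err_w = ss_within_subj - ss_t - ss_axt

    # pooled within-group covariance of the repeated measures, for epsilon
    resid = np.vstack([x[labels == g] - x[labels == g].mean(axis=0)
                       for g in uniq])
    cov = resid.T @ resid / (s - a)
    eps = greenhouse_geisser_epsilon(cov)

    df_t, df_err_w = (b - 1), (s - a) * (b - 1)
    df_axt = (a - 1) * (b - 1)
    ms_err_w = ss_err_w / df_err_w

    out = {}
    f_t = (ss_t / df_t) / ms_err_w
    out["within"] = TestResult(
        test="rm_anova_within", statistic=float(f_t),
        p_value=float(sps.f.sf(f_t, df_t * eps, df_err_w * eps)),
        df=(df_t * eps, df_err_w * eps), extras={"epsilon": eps,
                                                 "p_uncorrected": float(sps.f.sf(f_t, df_t, df_err_w))})
    if a > 1:
        df_a, df_subj_err = a - 1, s - a
        f_a = (ss_a / df_a) / (ss_subj_err / df_subj_err)
        out["between"] = TestResult(
            test="rm_anova_between", statistic=float(f_a),
            p_value=float(sps.f.sf(f_a, df_a, df_subj_err)),
            df=(df_a, df_subj_err))
        f_i = (ss_axt / df_axt) / ms_err_w
        out["interaction"] = TestResult(
            test="rm_anova_interaction", statistic=float(f_i),
            p_value=float(sps.f.sf(f_i, df_axt * eps, df_err_w * eps)),
            df=(df_axt * eps, df_err_w * eps), extras={"epsilon": eps})
    return out


# -------------------------------------------------------------------- pearson
def pearson(x, y, comparison: str = "") -> TestResult:
    """Pearson r with two-sided p from the t transform."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    return TestResult(test="pearson", statistic=float(r), p_value=float(p),
                      comparison=comparison, df=(len(x) - 2,))
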