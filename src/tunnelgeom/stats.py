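"""Cohort statistics for tunnel measurement tables.

Implements, from their defining formulas, the statistical layer used on the
measurement tables: one-way fixed-effects ANOVA, pooled-variance independent
t-test, two-way random absolute-agreement single-measure ICC with the
customary poor / fair-to-good / excellent grading (cutoffs 0.40 and 0.75),
compact letter display over a Tukey HSD p-value matrix, noncentral-F power
and minimum-sample-size computation, and the sex/age/height subgroup report.

Only the Tukey HSD p-values are delegated (scipy.stats.tukey_hsd); F, t and
ICC statistics are computed from sums of squares so they can be checked
against brute-force oracles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

__all__ = [
    "StatResult", "one_way_anova", "independent_t_test", "icc_agreement",
    "letter_groups", "tukey_p_matrix", "anova_sample_size", "noncentral_f_power",
    "run_subgroup_analysis",
]

AGE_BINS = ((16.0, 30.0), (31.0, 45.0), (46.0, 60.0))
AGE_LABELS = ("young_16_30", "middle_31_45", "elderly_46_60")
HEIGHT_EDGES = (1.60, 1.70)
HEIGHT_LABELS = ("lt_1.60", "1.60_1.70", "gt_1.70")


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple[float, float] | float
    p_value: float
    groups: dict[str, str] | None = None   # compact letters per level
    extra: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# elementary tests (from sums of squares)
# ---------------------------------------------------------------------------

def one_way_anova(groups: list[np.ndarray]) -> StatResult:
    """Classical fixed-effects one-way ANOVA from sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("every group needs n >= 2")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    grand = np.concatenate(groups).mean()
    means = np.array([g.mean() for g in groups])
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1, df2 = k - 1, N - k
    msb, msw = ssb / df1, ssw / df2
    if msw == 0:
        f = 0.0 if msb == 0 else np.inf
    else:
        f = msb / msw
    p = float(scipy.stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return StatResult(test="anova", statistic=float(f), df=(df1, df2), p_value=p,
                      extra={"ssb": ssb, "ssw": ssw})


def independent_t_test(a, b) -> StatResult:
    """Two-sided pooled-variance independent t-test.

    The report layer prints t, t^2 and p; t^2 equals the one-way ANOVA F of
    the two groups, the form in which such comparisons are often tabulated.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("t-test needs n >= 2 per group")
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            return StatResult(test="t_test", statistic=0.0, df=float(na + nb - 2),
                              p_value=1.0, extra={"t_squared": 0.0})
        raise ValidationError("zero pooled variance with unequal means")
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = float((a.mean() - b.mean()) / se)
    df = na + nb - 2
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return StatResult(test="t_test", statistic=t, df=float(df), p_value=p,
                      extra={"t_squared": t * t})


def icc_agreement(ratings: np.ndarray) -> StatResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is subjects x raters, complete.  Grade: ICC < 0.40 poor,
    0.40-0.75 fair to good, > 0.75 excellent.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 5 or X.shape[1] < 2:
        raise ValidationError("ICC needs >= 5 subjects and >= 2 raters")
    if not np.isfinite(X).all():
        raise ValidationError("ICC matrix must be complete")
    if np.allclose(X, X.flat[0]):
        raise ValidationError("constant rating matrix: ICC undefined")
    n, k = X.shape
    grand = X.mean()
    row_m = X.mean(axis=1)
    col_m = X.mean(axis=0)
    ss_rows = k * ((row_m - grand) ** 2).sum()
    ss_cols = n * ((col_m - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc < 0.40:
        grade = "poor"
    elif icc <= 0.75:
        grade = "fair_to_good"
    else:
        grade = "excellent"
    f = msr / mse if mse > 0 else np.inf
    df = ((n - 1), (n - 1) * (k - 1))
    p = float(scipy.stats.f.sf(f, *df)) if np.isfinite(f) else 0.0
    return StatResult(test="icc", statistic=float(icc), df=df, p_value=p,
                      extra={"grade": grade, "MSR": msr, "MSC": msc, "MSE": mse})


# ---------------------------------------------------------------------------
# compact letter display
# ---------------------------------------------------------------------------

def tukey_p_matrix(groups: list[np.ndarray]) -> np.ndarray:
    """Symmetric Tukey-HSD p-value matrix for the group list."""
    res = scipy.stats.tukey_hsd(*[np.asarray(g, dtype=float) for g in groups])
    return np.asarray(res.pvalue)


def letter_groups(pairwise_p: np.ndarray, alpha: float = 0.05,
                  labels: list[str] | None = None,
                  means: np.ndarray | None = None) -> tuple[dict[str, str], bool]:
    """Compact letter display: levels share a letter iff pairwise p > alpha.

    Insert-and-absorb: start with one letter covering all levels; every
    significant pair splits any letter containing both; subset letters are
    absorbed.  Returns (labels per level, intransitive_flag); the flag marks
    significance patterns that are not unions of cliques (a level then simply
    carries several letters).
    """
    P = np.asarray(pairwise_p, dtype=float)
    k = P.shape[0]
    if P.shape != (k, k) or not np.allclose(P, P.T, equal_nan=True):
        raise ValidationError("pairwise_p must be a symmetric matrix")
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if P[i, j] <= alpha:
                new_sets = []
                for s in sets:
                    if i in s and j in s:
                        new_sets.append(s - {i})
                        new_sets.append(s - {j})
                    else:
                        new_sets.append(s)
                # absorb subsets
                new_sets.sort(key=len, reverse=True)
                kept: list[set[int]] = []
                for s in new_sets:
                    if s and not any(s <= t for t in kept):
                        kept.append(s)
                sets = kept
    # letter order: by descending mean of the first member (presentation only)
    if means is not None:
        sets.sort(key=lambda s: -float(np.max(np.asarray(means)[list(s)])))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, sets):
        for idx in sorted(s):
            out[labels[idx]] += letter
    # intransitive if the sharing relation is not an equivalence on the levels
    share = np.zeros((k, k), dtype=bool)
    for s in sets:
        for i in s:
            for j in s:
                share[i, j] = True
    intransitive = False
    for i in range(k):
        for j in range(k):
            for m in range(k):
                if share[i, j] and share[j, m] and not share[i, m]:
                    intransitive = True
    return out, intransitive


# ---------------------------------------------------------------------------
# power / sample size (noncentral F)
# ---------------------------------------------------------------------------

def noncentral_f_power(k: int, n_total: int, effect_f: float, alpha: float) -> float:
    """Power of the one-way fixed-effects omnibus F test at total N.

    Noncentrality lambda = f^2 * N with df = (k-1, N-k).
    """
    df1, df2 = k - 1, n_total - k
    if df2 < 1:
        return 0.0
    lam = effect_f ** 2 * n_total
    f_crit = scipy.stats.f.isf(alpha, df1, df2)
    return float(scipy.stats.ncf.sf(f_crit, df1, df2, lam))


def anova_sample_size(k: int, effect_f: float, alpha: float = 0.05,
                      power: float = 0.9) -> int:
    """Smallest total N whose noncentral-F power reaches the target."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if effect_f <= 0:
        raise ValidationError(f"effect_f must be > 0, got {effect_f}")
    if power >= 1.0:
        raise ValidationError("power target must be < 1")
    n = k + 1
    while n <= 10**6:
        if noncentral_f_power(k, n, effect_f, alpha) >= power:
            return n
        n += 1
    raise ValidationError("power target unreachable within N <= 1e6")


# ---------------------------------------------------------------------------
# subgroup report
# ---------------------------------------------------------------------------

PARAMS = ("psa_deg", "tth_mm", "ttd_mm")
APPROACH_ORDER = ("T1", "T2", "T3", "T4", "T5")


def _age_group(age: float) -> str | None:
    for (lo, hi), lab in zip(AGE_BINS, AGE_LABELS):
        if lo <= age <= hi:
            return lab
    return None


def _height_group(h: float) -> str:
    if h < HEIGHT_EDGES[0]:
        return HEIGHT_LABELS[0]
    if h <= HEIGHT_EDGES[1]:
        return HEIGHT_LABELS[1]
    return HEIGHT_LABELS[2]


def run_subgroup_analysis(table: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Sex / age / height subgroup statistics of a cohort measurement table.

    ``table`` needs columns subject_id, approach, psa_deg, tth_mm, ttd_mm,
    sex, age, height_m.  Returns the four report tables: per-approach summary
    with compact letters, sex t-tests, age-group and height-group ANOVAs.
    Empty subgroups yield NA rows rather than errors.
    """
    required = {"subject_id", "approach", "sex", "age", "height_m", *PARAMS}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    df = table.copy()
    df["age_group"] = df["age"].map(_age_group)
    df["height_group"] = df["height_m"].map(_height_group)

    # --- per-approach summary with compact letters --------------------------
    rows = []
    for param in PARAMS:
        groups = [df.loc[df.approach == a, param].to_numpy() for a in APPROACH_ORDER]
        present = [g for g in groups if len(g) >= 2]
        if len(present) == len(groups):
            an = one_way_anova(groups)
            P = tukey_p_matrix(groups)
            letters, _ = letter_groups(P, alpha, labels=list(APPROACH_ORDER),
                                       means=np.array([g.mean() for g in groups]))
            for a, g in zip(APPROACH_ORDER, groups):
                rows.append({"parameter": param, "approach": a, "n": len(g),
                             "mean": g.mean(), "sd": g.std(ddof=1),
                             "anova_F": an.statistic, "anova_p": an.p_value,
                             "letters": letters[a]})
    fig_summary = pd.DataFrame(rows)

    def _two_group(sub: pd.DataFrame, col: str, lv0: str, lv1: str, param: str) -> dict:
        a = sub.loc[sub[col] == lv0, param].to_numpy()
        b = sub.loc[sub[col] == lv1, param].to_numpy()
        base = {"parameter": param, f"n_{lv0}": len(a), f"n_{lv1}": len(b),
                f"mean_{lv0}": a.mean() if len(a) else np.nan,
                f"sd_{lv0}": a.std(ddof=1) if len(a) > 1 else np.nan,
                f"mean_{lv1}": b.mean() if len(b) else np.nan,
                f"sd_{lv1}": b.std(ddof=1) if len(b) > 1 else np.nan}
        if len(a) >= 2 and len(b) >= 2 and (a.std() > 0 or b.std() > 0):
            r = independent_t_test(a, b)
            base.update(t=r.statistic, t_squared=r.extra["t_squared"], p=r.p_value)
        else:
            base.update(t=np.nan, t_squared=np.nan, p=np.nan)
        return base

    # --- sex ---------------------------------------------------------------
    sex_rows = []
    for param in PARAMS:
        for a in APPROACH_ORDER:
            sub = df[df.approach == a]
            row = {"approach": a}
            row.update(_two_group(sub, "sex", "male", "female", param))
            sex_rows.append(row)
    table_sex = pd.DataFrame(sex_rows)

    # --- age / height ------------------------------------------------------
    def _multi_group(col: str, levels: tuple[str, ...]) -> pd.DataFrame:
        out = []
        for param in PARAMS:
            for a in APPROACH_ORDER:
                sub = df[df.approach == a]
                gs = [sub.loc[sub[col] == lv, param].to_numpy() for lv in levels]
                row: dict = {"parameter": param, "approach": a}
                for lv, g in zip(levels, gs):
                    row[f"n_{lv}"] = len(g)
                    row[f"mean_{lv}"] = g.mean() if len(g) else np.nan
                    row[f"sd_{lv}"] = g.std(ddof=1) if len(g) > 1 else np.nan
                ok = [g for g in gs if len(g) >= 2]
                if len(ok) >= 2 and any(g.std() > 0 for g in ok):
                    an = one_way_anova(ok)
                    row["anova_F"], row["anova_p"] = an.statistic, an.p_value
                    # pairwise one-way F values, the layout used in clinical tables
                    for (i, j) in ((0, 1), (0, 2), (1, 2)):
                        key = f"F_{levels[i]}_vs_{levels[j]}"
                        if len(gs[i]) >= 2 and len(gs[j]) >= 2 and \
                                (gs[i].std() > 0 or gs[j].std() > 0):
                            row[key] = one_way_anova([gs[i], gs[j]]).statistic
                        else:
                            row[key] = np.nan
                else:
                    row["anova_F"] = row["anova_p"] = np.nan
                out.append(row)
        return pd.DataFrame(out)

    return {
        "fig_summary": fig_summary,
        "table_sex": table_sex,
        "table_age": _multi_group("age_group", AGE_LABELS),
        "table_height": _multi_group("height_group", HEIGHT_LABELS),
    }
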