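"""Statistics layer vs closed-form and brute-force oracles."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tunnelgeom.errors import ValidationError
from tunnelgeom.stats import (anova_sample_size, icc_agreement, independent_t_test,
                              letter_groups, noncentral_f_power, one_way_anova,
                              run_subgroup_analysis, tukey_p_matrix)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_anova_worked_example_from_sums_of_squares():
    res = one_way_anova([np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])])
    assert res.statistic == pytest.approx(3.0, abs=1e-12)
    assert res.df == (2, 6)
    assert res.extra["ssb"] == pytest.approx(6.0)
    assert res.extra["ssw"] == pytest.approx(6.0)


def test_anova_identical_groups_give_zero_f():
    g = np.array([1.0, 2.0, 3.0])
    res = one_way_anova([g, g.copy(), g.copy()])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_two_group_anova_equals_t_squared():
    rng = np.random.default_rng(8)
    a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1.3, 9)
    f = one_way_anova([a, b]).statistic
    t = independent_t_test(a, b)
    assert t.statistic ** 2 == pytest.approx(f, abs=1e-9)
    assert t.extra["t_squared"] == pytest.approx(f, abs=1e-9)


def test_anova_shift_invariant_and_scale_equivariant():
    rng = np.random.default_rng(1)
    groups = [rng.normal(i, 1, 10) for i in range(3)]
    f0 = one_way_anova(groups).statistic
    assert one_way_anova([g + 100.0 for g in groups]).statistic == pytest.approx(f0, rel=1e-9)
    assert one_way_anova([g * 7.0 for g in groups]).statistic == pytest.approx(f0, rel=1e-9)


def test_anova_matches_scipy_reference():
    rng = np.random.default_rng(2)
    groups = [rng.normal(i * 0.3, 1.0, n) for i, n in enumerate((7, 11, 9, 14))]
    mine = one_way_anova(groups)
    ref = scipy.stats.f_oneway(*groups)
    assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def test_t_identical_samples():
    a = np.array([1.0, 2.0, 3.0])
    res = independent_t_test(a, a.copy())
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_t_matches_direct_formula():
    a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
    res = independent_t_test(a, b)
    sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
    t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    assert res.statistic == pytest.approx(t_hand, abs=1e-12)


def test_t_antisymmetric_in_group_order():
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 10)
    r1, r2 = independent_t_test(a, b), independent_t_test(b, a)
    assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


def test_t_zero_pooled_variance_with_unequal_means_errors():
    with pytest.raises(ValidationError):
        independent_t_test([1.0, 1.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def test_icc_identical_raters_is_one_and_excellent():
    rng = np.random.default_rng(0)
    col = rng.normal(50, 10, 20)
    res = icc_agreement(np.column_stack([col, col]))
    assert res.statistic == pytest.approx(1.0)
    assert res.extra["grade"] == "excellent"


def test_icc_independent_noise_is_near_zero():
    rng = np.random.default_rng(0)
    res = icc_agreement(rng.normal(0, 1, size=(200, 2)))
    assert abs(res.statistic) < 0.1
    assert res.extra["grade"] == "poor"


def test_icc_grading_cutoffs():
    rng = np.random.default_rng(3)
    subj = rng.normal(0, 3.0, 300)
    # observer noise tuned around the cutoffs via the theoretical ICC s2/(s2+n2)
    for noise, grade in ((1.0, "excellent"), (3.0, "fair_to_good"), (9.0, "poor")):
        X = subj[:, None] + rng.normal(0, noise, size=(300, 2))
        assert icc_agreement(X).extra["grade"] == grade


def test_icc_matches_pingouin_two_way_absolute_single():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(12)
    X = rng.normal(0, 2, size=(30, 1)) + rng.normal(0, 1, size=(30, 3))
    res = icc_agreement(X)
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(30), 3),
        "rater": np.tile(np.arange(3), 30),
        "score": X.ravel(),
    })
    ref = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    icc2 = float(ref.loc[ref.Type.str.contains("A,1"), "ICC"].iloc[0])
    assert res.statistic == pytest.approx(icc2, abs=1e-6)


def test_icc_constant_matrix_errors():
    with pytest.raises(ValidationError):
        icc_agreement(np.full((10, 2), 3.14))


# ---------------------------------------------------------------------------
# compact letter display
# ---------------------------------------------------------------------------

def test_all_pairs_significant_gives_distinct_letters():
    P = np.full((4, 4), 0.001)
    np.fill_diagonal(P, 1.0)
    letters, flag = letter_groups(P, labels=list("wxyz"))
    assert sorted(letters.values()) == ["a", "b", "c", "d"]
    assert not flag


def test_no_pair_significant_shares_one_letter():
    P = np.ones((5, 5))
    letters, flag = letter_groups(P)
    assert set(letters.values()) == {"a"}
    assert not flag


def test_paired_approach_pattern_yields_three_letter_classes():
    """T1~T2 and T4~T5 non-significant, every other pair significant."""
    labels = ["T1", "T2", "T3", "T4", "T5"]
    P = np.full((5, 5), 0.001)
    np.fill_diagonal(P, 1.0)
    P[0, 1] = P[1, 0] = 0.6
    P[3, 4] = P[4, 3] = 0.4
    means = np.array([58.5, 61.1, 56.1, 52.0, 49.9])
    letters, flag = letter_groups(P, labels=labels, means=means)
    assert letters["T1"] == letters["T2"]
    assert letters["T4"] == letters["T5"]
    assert len({letters["T1"], letters["T3"], letters["T4"]}) == 3
    assert letters == {"T1": "a", "T2": "a", "T3": "b", "T4": "c", "T5": "c"}
    assert not flag


def test_intransitive_pattern_is_flagged_and_consistent():
    # 0~1, 1~2 but 0 vs 2 significant: level 1 needs two letters
    P = np.array([[1.0, 0.9, 0.01],
                  [0.9, 1.0, 0.9],
                  [0.01, 0.9, 1.0]])
    letters, flag = letter_groups(P)
    assert flag
    assert set(letters["g0"]) & set(letters["g1"])
    assert set(letters["g1"]) & set(letters["g2"])
    assert not set(letters["g0"]) & set(letters["g2"])


def test_tukey_matrix_is_symmetric_probability():
    rng = np.random.default_rng(4)
    P = tukey_p_matrix([rng.normal(i, 1, 10) for i in range(4)])
    assert P.shape == (4, 4)
    assert np.allclose(P, P.T)
    assert ((P >= 0) & (P <= 1)).all()


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------

def test_power_target_zero_returns_minimal_design():
    assert anova_sample_size(k=5, effect_f=0.5, alpha=0.05, power=0.0) == 6


def test_two_group_sample_size_matches_noncentral_t_oracle():
    k, f, alpha, power = 2, 0.5, 0.05, 0.9
    n_f = anova_sample_size(k, f, alpha, power)
    # two-sample two-sided t with effect d = 2f, total N, noncentral t oracle
    d = 2 * f
    n = k + 1
    while True:
        n1 = n // 2
        n2 = n - n1
        df = n - 2
        nc = d / np.sqrt(1 / n1 + 1 / n2)
        tcrit = scipy.stats.t.isf(alpha / 2, df)
        pw = scipy.stats.nct.sf(tcrit, df, nc) + scipy.stats.nct.cdf(-tcrit, df, nc)
        if pw >= power:
            break
        n += 1
    assert abs(n_f - n) <= 2


def test_sample_size_power_verified_by_simulation():
    k, f, alpha, power = 5, 0.5, 0.05, 0.9
    N = anova_sample_size(k, f, alpha, power)
    analytic = noncentral_f_power(k, N, f, alpha)
    assert analytic >= power
    # simulate a balanced one-way design with between-group sd = f * sigma
    rng = np.random.default_rng(99)
    n_per = N // k
    n_used = n_per * k
    lam_adjust = np.sqrt(n_used / N)
    means = np.array([-2., -1., 0., 1., 2.])
    means = means / np.sqrt(np.mean(means**2)) * f * lam_adjust
    draws = 10_000
    data = rng.normal(means[None, :, None], 1.0, size=(draws, k, n_per))
    gm = data.mean(axis=2)
    grand = data.mean(axis=(1, 2))
    ssb = n_per * ((gm - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((data - gm[:, :, None]) ** 2).sum(axis=(1, 2))
    F = (ssb / (k - 1)) / (ssw / (n_used - k))
    crit = scipy.stats.f.isf(alpha, k - 1, n_used - k)
    sim_power = (F > crit).mean()
    assert abs(sim_power - noncentral_f_power(k, n_used, f, alpha)) < 0.02


def test_unreachable_power_raises():
    with pytest.raises(ValidationError):
        anova_sample_size(k=3, effect_f=1e-9, alpha=0.05, power=0.9)


# ---------------------------------------------------------------------------
# subgroup report
# ---------------------------------------------------------------------------

def _toy_cohort(n=60, seed=0, scale_by_height=True):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        h = rng.uniform(1.5, 1.85)
        scale = h / 1.66 if scale_by_height else 1.0
        sex = "male" if rng.random() < 0.4 else "female"
        age = rng.uniform(16, 60)
        for j, a in enumerate(("T1", "T2", "T3", "T4", "T5")):
            psa = 60 - 3 * j + rng.normal(0, 2)          # scale-free
            ttd = (70 - 4 * j) * scale + rng.normal(0, 1)
            tth = ttd * np.sin(np.radians(psa))
            rows.append(dict(subject_id=f"S{i}", approach=a, psa_deg=psa,
                             tth_mm=tth, ttd_mm=ttd, sex=sex, age=age, height_m=h))
    return pd.DataFrame(rows)


def test_height_affects_ttd_but_not_psa():
    tables = run_subgroup_analysis(_toy_cohort())
    th = tables["table_height"].set_index(["parameter", "approach"])
    for a in ("T1", "T2", "T3", "T4", "T5"):
        assert th.loc[("ttd_mm", a), "anova_p"] < 0.05
        assert th.loc[("psa_deg", a), "anova_p"] > 0.05


def test_equal_heights_yield_na_height_anova():
    df = _toy_cohort(scale_by_height=False)
    df["height_m"] = 1.65
    tables = run_subgroup_analysis(df)
    th = tables["table_height"]
    assert th["anova_p"].isna().all()


def test_shuffled_covariates_give_uniform_pvalues():
    """Permutation null: sex labels shuffled per subject -> p ~ U(0,1)."""
    df = _toy_cohort(n=40, seed=2)
    rng = np.random.default_rng(10)
    subj = df.drop_duplicates("subject_id")[["subject_id", "sex"]]
    pvals = []
    for _ in range(200):
        perm = dict(zip(subj.subject_id, rng.permutation(subj.sex.to_numpy())))
        d = df[df.approach == "T3"]
        a = d.loc[d.subject_id.map(perm) == "male", "psa_deg"].to_numpy()
        b = d.loc[d.subject_id.map(perm) == "female", "psa_deg"].to_numpy()
        pvals.append(independent_t_test(a, b).p_value)
    ks = scipy.stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_fig_summary_contains_letters_and_all_approaches():
    tables = run_subgroup_analysis(_toy_cohort())
    fig = tables["fig_summary"]
    assert set(fig.approach) == {"T1", "T2", "T3", "T4", "T5"}
    assert fig.letters.str.len().ge(1).all()
    assert (fig.anova_p < 0.05).all()
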