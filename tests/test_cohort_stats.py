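import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from pathpanel.cohort_stats import (
    ClinicalTable, anova_tukey, km_curve, load_clinical, logrank_hr,
    median_split, summarize_cohort, two_group_t,
)


# ---------------------------------------------------------------------------
# median split

def test_median_split_hand_worked_example():
    s = pd.Series({"a": 0.1, "b": 0.4, "c": 0.45, "d": 0.9, "e": 0.95})
    labels = median_split(s)
    # median 0.45 is closer to 0.4 than to 0.9 -> joins low
    assert (labels == "low").sum() == 3 and (labels == "high").sum() == 2
    assert labels["c"] == "low"


def test_median_split_even_and_ties():
    even = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
    lab = median_split(even)
    assert set(lab[lab == "low"].index) == {"a", "b"}
    # equidistant median goes low
    eq = pd.Series({"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0, "e": 4.0})
    assert median_split(eq)["c"] == "low"
    with pytest.raises(ValueError, match="no split possible"):
        median_split(pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}))
    with pytest.raises(ValueError, match=">= 4"):
        median_split(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))


def test_median_split_group_sizes_balanced():
    rng = np.random.default_rng(0)
    for n in (4, 5, 9, 10, 27):
        s = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        lab = median_split(s)
        lo, hi = (lab == "low").sum(), (lab == "high").sum()
        assert abs(lo - hi) <= 1


# ---------------------------------------------------------------------------
# Kaplan-Meier

def test_km_hand_values():
    out = km_curve([1, 2, 3], [1, 1, 1])
    np.testing.assert_allclose(out["survival"], [2 / 3, 1 / 3, 0.0])
    assert km_curve([5, 6, 7], [0, 0, 0]).empty  # all censored: S stays 1
    single = km_curve([5, 9, 9, 9, 9], [1, 0, 0, 0, 0])
    assert single["survival"].iloc[0] == pytest.approx(0.8)
    with pytest.raises(ValueError, match="negative"):
        km_curve([-1, 2], [1, 1])


def test_km_matches_lifelines():
    rng = np.random.default_rng(1)
    t = rng.exponential(10, size=40)
    e = rng.integers(0, 2, size=40)
    e[0] = 1
    ours = km_curve(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for _, row in ours.iterrows():
        assert row["survival"] == pytest.approx(
            float(kmf.survival_function_at_times(row["time"]).iloc[0]),
            rel=1e-9)


# ---------------------------------------------------------------------------
# log-rank / HR

def _toy_cohort(seed=0, n=40, effect=1.0):
    rng = np.random.default_rng(seed)
    hi = rng.integers(0, 2, size=n).astype(bool)
    t = rng.exponential(np.where(hi, 10 / effect, 10))
    c = rng.uniform(0, 25, size=n)
    times = pd.Series(np.minimum(t, c), index=[f"s{i}" for i in range(n)])
    events = pd.Series((t <= c).astype(int), index=times.index)
    labels = pd.Series(np.where(hi, "high", "low"), index=times.index)
    return labels, times, events


def test_logrank_null_identity():
    t = pd.Series([3.0, 5.0, 8.0, 3.0, 5.0, 8.0],
                  index=list("abcdef"))
    e = pd.Series([1, 1, 0, 1, 1, 0], index=t.index)
    labels = pd.Series(["low"] * 3 + ["high"] * 3, index=t.index)
    res = logrank_hr(labels, t, e)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.hr == pytest.approx(1.0)
    assert res.p == pytest.approx(1.0)


def test_logrank_label_swap_inverts_hr():
    labels, t, e = _toy_cohort(seed=2, effect=3.0)
    res = logrank_hr(labels, t, e)
    swapped = labels.map({"low": "high", "high": "low"})
    res2 = logrank_hr(swapped, t, e)
    assert res2.hr == pytest.approx(1.0 / res.hr, rel=1e-9)
    assert res2.chi2 == pytest.approx(res.chi2, rel=1e-9)
    assert res2.p == pytest.approx(res.p, rel=1e-9)
    assert res.ci95[0] <= res.hr <= res.ci95[1]


def test_logrank_matches_lifelines():
    labels, t, e = _toy_cohort(seed=3, effect=2.0)
    res = logrank_hr(labels, t, e)
    hi = labels == "high"
    lt = logrank_test(t[hi], t[~hi], e[hi], e[~hi])
    assert res.chi2 == pytest.approx(lt.test_statistic, rel=1e-6)
    assert res.p == pytest.approx(lt.p_value, rel=1e-6)


def test_logrank_zero_event_group_flagged():
    t = pd.Series([2.0, 4.0, 6.0, 3.0, 5.0, 7.0], index=list("abcdef"))
    e = pd.Series([1, 1, 1, 0, 0, 0], index=t.index)
    labels = pd.Series(["low"] * 3 + ["high"] * 3, index=t.index)
    res = logrank_hr(labels, t, e)
    assert "degenerate_zero_events_one_sided_bound" in res.flags
    assert res.ci95[0] == 0.0


def test_pike_estimator_available():
    labels, t, e = _toy_cohort(seed=4, effect=2.0)
    score = logrank_hr(labels, t, e, hr_estimator="score")
    pike = logrank_hr(labels, t, e, hr_estimator="pike")
    assert score.p == pike.p  # test is estimator-independent
    assert np.sign(np.log(score.hr)) == np.sign(np.log(pike.hr))


# ---------------------------------------------------------------------------
# ANOVA / t-test

def test_anova_hand_computed_f():
    scores = pd.Series([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float,
                       index=[f"s{i}" for i in range(9)])
    groups = pd.Series(["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3,
                       index=scores.index)
    res = anova_tukey(scores, groups)
    assert res["F"] == pytest.approx(3.0)
    assert set(res["tukey"]) == {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
    assert all(0 <= p <= 1 for p in res["tukey"].values())


def test_two_groups_f_equals_t_squared():
    rng = np.random.default_rng(5)
    scores = pd.Series(rng.normal(size=14), index=[f"s{i}" for i in range(14)])
    groups = pd.Series(["a"] * 6 + ["b"] * 8, index=scores.index)
    f_res = anova_tukey(scores, groups)
    t_res = two_group_t(scores, groups)
    assert f_res["F"] == pytest.approx(t_res["t"] ** 2, rel=1e-9)
    assert f_res["p"] == pytest.approx(t_res["p"], rel=1e-9)


def test_t_test_symmetry_and_degeneracy():
    scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                       index=[f"s{i}" for i in range(6)])
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=scores.index)
    r1 = two_group_t(scores, groups)
    r2 = two_group_t(scores, groups.map({"a": "b", "b": "a"}))
    assert r1["t"] == pytest.approx(-r2["t"])
    assert r1["p"] == pytest.approx(r2["p"])
    flat = pd.Series([1.0] * 6, index=scores.index)
    with pytest.raises(ValueError, match="zero pooled variance"):
        two_group_t(flat, groups)
    with pytest.raises(ValueError, match="degenerate ANOVA"):
        anova_tukey(flat, groups)


# ---------------------------------------------------------------------------
# cohort summary

def _cohort_19():
    subtypes = (["mesenchymal"] * 1 + ["mixed_spindle_mesenchymal"] * 2
                + ["mixed_squamous_spindle"] * 3 + ["spindle"] * 7
                + ["squamous"] * 6)
    receptor = ["ER-PR-HER2-"] * 17 + ["ER-PR-HER2unknown"] * 2
    return ClinicalTable(data=pd.DataFrame({
        "sample_id": [f"P{i:02d}" for i in range(19)],
        "subtype": subtypes,
        "receptor_status": receptor,
        "age": np.linspace(35, 86, 19),
    }))


def test_summary_published_percentages():
    summ = summarize_cohort(_cohort_19(),
                            categories=["subtype", "receptor_status"],
                            continuous=["age"])
    assert summ.n == 19
    assert summ.categorical["subtype"]["spindle"] == (7, 36.8)
    assert summ.categorical["receptor_status"]["ER-PR-HER2-"] == (17, 89.5)
    med, lo, hi = summ.continuous["age"]
    assert (lo, hi) == (35.0, 86.0)


def test_summary_edge_cases():
    one = ClinicalTable(data=pd.DataFrame(
        {"sample_id": ["a"], "subtype": ["squamous"]}))
    summ = summarize_cohort(one)
    assert summ.categorical["subtype"]["squamous"] == (1, 100.0)
    with pytest.raises(ValueError, match="unknown field"):
        summarize_cohort(one, categories=["nope"])
    with pytest.raises(ValueError, match="empty cohort"):
        summarize_cohort(ClinicalTable(data=pd.DataFrame(
            {"sample_id": [], "subtype": []})))


def test_clinical_table_validation(tmp_path):
    df = pd.DataFrame({"sample_id": ["a", "b"], "subtype": ["x", "y"],
                       "rfs_months": [5.0, -1.0], "rfs_event": [1, 0],
                       "os_months": [5.0, 6.0], "os_event": [0, 1]})
    with pytest.raises(ValueError, match="negative follow-up"):
        ClinicalTable(data=df)
    df["rfs_months"] = [5.0, 1.0]
    path = tmp_path / "c.tsv"
    df.to_csv(path, sep="\t", index=False)
    clin = load_clinical(path)
    t, e = clin.endpoint("os")
    np.testing.assert_allclose(t, [5.0, 6.0])
    np.testing.assert_allclose(e, [0, 1])
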