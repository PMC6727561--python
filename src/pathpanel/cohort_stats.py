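"""Outcome and group statistics for small cohorts.

Median split with an explicit odd-n tie rule, Kaplan-Meier curves, the
log-rank test with a score-based hazard ratio, one-way ANOVA with
Tukey-Kramer post hoc comparisons, the pooled-variance t-test, and
Table-1-style cohort summaries.

The hazard ratio reported by :func:`logrank_hr` is the score estimator
HR = exp((O1 - E1) / V) with CI exp((O1 - E1)/V +- 1.96/sqrt(V)); the
Pike-style estimator (O1/E1)/(O2/E2) is available behind a switch for
sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ClinicalTable",
    "SurvivalResult",
    "CohortSummary",
    "load_clinical",
    "median_split",
    "km_curve",
    "logrank_hr",
    "anova_tukey",
    "two_group_t",
    "summarize_cohort",
]

CLINICAL_COLUMNS = ["sample_id", "subtype", "rfs_months", "rfs_event",
                    "os_months", "os_event"]


@dataclass
class ClinicalTable:
    """Per-patient clinical records (subtype, follow-up, event flags)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("sample_id", "subtype") if c not in self.data]
        if missing:
            raise ValueError(f"clinical table missing columns {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in clinical table")
        for col in self.data.columns:
            if col.endswith("_months") and (self.data[col] < 0).any():
                raise ValueError(f"negative follow-up time in {col}")
            if col.endswith("_event") and \
                    not self.data[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be binary 0/1")

    def endpoint(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, events) arrays for endpoint 'rfs' or 'os'."""
        t = self.data[f"{name}_months"].to_numpy(dtype=float)
        e = self.data[f"{name}_event"].to_numpy(dtype=int)
        return t, e

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])


def load_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    return ClinicalTable(data=df)


@dataclass
class SurvivalResult:
    """Log-rank O/E/V summary with score-based HR and 95% CI."""

    O1: float
    E1: float
    V: float
    chi2: float
    p: float
    hr: float
    ci95: tuple[float, float]
    n_groups: dict[str, int]
    flags: set[str] = field(default_factory=set)


def median_split(scores: pd.Series) -> pd.Series:
    """Dichotomize at the median; returns 'low'/'high' labels per sample.

    Even n: the lower half of the sorted values is 'low'. Odd n: the median
    sample joins the group whose nearest member value is numerically closer
    (ties go to 'low').
    """
    if len(scores) < 4:
        raise ValueError("median split needs >= 4 samples")
    if scores.nunique() == 1:
        raise ValueError("no split possible: all values identical")
    order = sorted(scores.index, key=lambda s: (scores[s], str(s)))
    n = len(order)
    labels = pd.Series(index=scores.index, dtype=object)
    if n % 2 == 0:
        low, high = order[:n // 2], order[n // 2:]
    else:
        mid = n // 2
        med = scores[order[mid]]
        below = scores[order[mid - 1]]
        above = scores[order[mid + 1]]
        if abs(med - below) <= abs(above - med):
            low, high = order[:mid + 1], order[mid + 1:]
        else:
            low, high = order[:mid], order[mid:]
    labels[low] = "low"
    labels[high] = "high"
    return labels


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate; steps at event times only.

    Returns a DataFrame with columns ``time`` and ``survival`` (S right-
    continuous, S(0) = 1 implicit before the first row).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) != len(e):
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    s = 1.0
    rows = []
    for ti in np.unique(t[e == 1]):
        at_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(ti), s))
    return pd.DataFrame(rows, columns=["time", "survival"])


def logrank_hr(labels: pd.Series, times: pd.Series, events: pd.Series,
               group1: str = "high",
               hr_estimator: str = "score") -> SurvivalResult:
    """Two-group log-rank test with hazard ratio of ``group1`` vs the other.

    At each distinct event time the observed-minus-expected events in group 1
    and the hypergeometric variance are accumulated; chi2 = (O1-E1)^2/V with
    a chi-square(1) p-value. A group with zero events makes the HR degenerate:
    the result is flagged and the CI reported as a one-sided bound.
    """
    common = labels.index
    t = np.asarray(times.loc[common], dtype=float)
    e = np.asarray(events.loc[common], dtype=int)
    g1 = (labels.loc[common] == group1).to_numpy()
    groups = set(labels)
    if len(groups) != 2 or group1 not in groups:
        raise ValueError(f"labels must have two groups including {group1!r}")
    if e.sum() == 0:
        raise ValueError("no events in either group")

    O1 = float(e[g1].sum())
    E1 = 0.0
    V = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = float(at_risk.sum())
        n1 = float((at_risk & g1).sum())
        d = float(((t == ti) & (e == 1)).sum())
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

    flags: set[str] = set()
    if V <= 0:
        raise ValueError("log-rank variance is zero (degenerate risk sets)")
    chi2_stat = (O1 - E1) ** 2 / V
    p = float(sps.chi2.sf(chi2_stat, df=1))
    beta = (O1 - E1) / V
    se = 1.0 / np.sqrt(V)
    if hr_estimator == "score":
        hr = float(np.exp(beta))
        ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    elif hr_estimator == "pike":
        O2 = float(e[~g1].sum())
        E2 = float(e.sum()) - E1
        if O1 == 0 or O2 == 0 or E1 == 0 or E2 == 0:
            hr = float(np.exp(beta))
            ci = (float(np.exp(beta - 1.96 * se)),
                  float(np.exp(beta + 1.96 * se)))
            flags.add("pike_degenerate_fell_back_to_score")
        else:
            hr = (O1 / E1) / (O2 / E2)
            ci = (float(hr * np.exp(-1.96 * se)),
                  float(hr * np.exp(1.96 * se)))
    else:
        raise ValueError(f"unknown hr_estimator {hr_estimator!r}")

    n1_events = O1
    n2_events = float(e[~g1].sum())
    if n1_events == 0 or n2_events == 0:
        flags.add("degenerate_zero_events_one_sided_bound")
        ci = (0.0, ci[1]) if n1_events == 0 else (ci[0], float("inf"))
    sizes = labels.value_counts().to_dict()
    return SurvivalResult(O1=O1, E1=E1, V=V, chi2=float(chi2_stat), p=p,
                          hr=hr, ci95=ci, n_groups=sizes, flags=flags)


def anova_tukey(scores: pd.Series, groups: pd.Series) -> dict:
    """One-way ANOVA F/p plus Tukey-Kramer pairwise adjusted p-values."""
    levels = sorted(groups.unique())
    arrays = [scores.loc[groups.index[groups == g]].to_numpy(dtype=float)
              for g in levels]
    if len(levels) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 samples each")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("degenerate ANOVA: zero within-group variance")
    f_stat, p = sps.f_oneway(*arrays)
    tk = sps.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            pairwise[(levels[i], levels[j])] = float(tk.pvalue[i, j])
    return {"F": float(f_stat), "p": float(p), "tukey": pairwise}


def two_group_t(scores: pd.Series, labels: pd.Series) -> dict:
    """Two-sided pooled-variance Student's t-test between two groups."""
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("t-test needs exactly two groups")
    a = scores.loc[labels.index[labels == levels[0]]].to_numpy(dtype=float)
    b = scores.loc[labels.index[labels == levels[1]]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >=2 samples")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and \
            np.mean(a) == np.mean(b):
        raise ValueError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "p": float(p), "groups": (levels[0], levels[1])}


@dataclass
class CohortSummary:
    """Category counts/percents and continuous median/min/max."""

    n: int
    categorical: dict[str, dict[str, tuple[int, float]]]
    continuous: dict[str, tuple[float, float, float]]


def summarize_cohort(clinical: ClinicalTable,
                     categories: list[str] | None = None,
                     continuous: list[str] | None = None) -> CohortSummary:
    """Per-level counts with percents (1 decimal) and median/min/max."""
    df = clinical.data
    if len(df) == 0:
        raise ValueError("empty cohort")
    categories = categories if categories is not None else ["subtype"]
    continuous = continuous or []
    for c in list(categories) + list(continuous):
        if c not in df.columns:
            raise ValueError(f"unknown field {c!r}")
    n = len(df)
    cat: dict[str, dict[str, tuple[int, float]]] = {}
    for c in categories:
        counts = df[c].value_counts()
        cat[c] = {str(level): (int(cnt), round(100.0 * cnt / n, 1))
                  for level, cnt in counts.items()}
    cont = {c: (float(np.median(df[c])), float(df[c].min()),
                float(df[c].max()))
            for c in continuous}
    return CohortSummary(n=n, categorical=cat, continuous=cont)
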