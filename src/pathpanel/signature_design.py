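"""Signature derivation and the panel design selection procedures.

Covers the panel-design workflow: rank genes by a moderated effect size from
an overexpression-vs-GFP training contrast; form a nested series of candidate
gene lists in 5-gene steps; pick per-pathway lengths under a total gene
budget by exact dynamic programming; pick single signatures by external
anchors (drug EC50 rank correlation, class-separation score); strip a
blocklist (e.g. heat-shock protein genes); and reduce literature signatures
to the top-k genes by expression in a reference cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .panel_core import CountsExperiment
from .normalization import NormalizedMatrix, normalize

__all__ = [
    "Signature",
    "CandidateSeries",
    "DesignConfig",
    "derive_candidates",
    "evaluate_candidates_proteomics",
    "select_lengths_budget",
    "select_by_ec50",
    "select_by_separation",
    "filter_blocklist",
    "reduce_by_expression",
    "default_hsp_blocklist",
]


@dataclass
class Signature:
    """Named gene list with per-gene direction and training effect."""

    pathway: str
    genes: pd.DataFrame  # index: symbol; columns: direction (+-1), effect

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("signature gene list must be nonempty")
        if self.genes.index.duplicated().any():
            raise ValueError("signature symbols must be unique")

    @property
    def symbols(self) -> list[str]:
        return list(self.genes.index)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CandidateSeries:
    """Nested candidate gene lists at lengths step, 2*step, ..., max.

    ``stats`` keeps the per-gene training statistics (effect, mu0, mu1,
    sigma, z) in rank order so any candidate length can be scored without
    re-fitting.
    """

    pathway: str
    stats: pd.DataFrame  # rank-ordered; index: symbol
    step: int = 5
    min_length: int = 5

    @property
    def lengths(self) -> list[int]:
        return list(range(self.min_length, len(self.stats) + 1, self.step))

    def candidate(self, length: int) -> list[str]:
        if length not in self.lengths:
            raise ValueError(
                f"length {length} not on grid "
                f"({self.min_length}..{len(self.stats)} step {self.step})")
        return list(self.stats.index[:length])

    def signature(self, length: int) -> Signature:
        sub = self.stats.iloc[:length]
        genes = pd.DataFrame({
            "direction": np.sign(sub["effect"]).astype(int).replace(0, 1),
            "effect": sub["effect"],
        })
        return Signature(pathway=self.pathway, genes=genes)

    def profiles(self, length: int):
        from .activity import ReferenceProfiles
        sub = self.stats.iloc[:length]
        return ReferenceProfiles(
            pathway=self.pathway,
            table=sub[["mu0", "mu1", "sigma"]].copy(),
        )


@dataclass
class DesignConfig:
    """Panel design constants: budget, grid, literature reduction size."""

    budget: int = 150
    step: int = 5
    min_length: int = 5
    literature_k: int = 25
    hsp_blocklist: str | None = None
    budget_semantics: str = "sum"  # or "union"

    def __post_init__(self) -> None:
        if self.budget_semantics not in ("sum", "union"):
            raise ValueError("budget_semantics must be 'sum' or 'union'")


def derive_candidates(training: CountsExperiment, pathway: str,
                      max_length: int,
                      design: DesignConfig | None = None) -> CandidateSeries:
    """Rank genes by a moderated standardized effect and nest prefixes.

    Per endogenous gene: effect = mean(active) - mean(GFP) on normalized log2
    data, z = effect / (s_g + s0) with s_g the per-gene pooled SD and s0 the
    median pooled SD (shrinkage offset so near-zero-variance genes cannot
    dominate). Genes are ranked by |z| (ties broken by symbol).
    """
    design = design or DesignConfig()
    endo = training.panel.endogenous
    if max_length > len(endo):
        raise ValueError(
            f"max_length {max_length} exceeds {len(endo)} endogenous genes")
    groups = training.groups
    gfp = groups.index[groups == "GFP"]
    act = groups.index[groups == pathway]
    if len(gfp) < 2 or len(act) < 2:
        raise ValueError("need >=2 lanes per training arm")
    norm = normalize(training).data
    y0, y1 = norm.loc[gfp], norm.loc[act]
    mu0, mu1 = y0.mean(axis=0), y1.mean(axis=0)
    effect = mu1 - mu0
    pooled_var = ((y0.var(axis=0, ddof=1) * (len(gfp) - 1)
                   + y1.var(axis=0, ddof=1) * (len(act) - 1))
                  / (len(gfp) + len(act) - 2))
    s = np.sqrt(pooled_var)
    s0 = float(s.median())
    z = effect / (s + s0)
    stats = pd.DataFrame({
        "effect": effect, "mu0": mu0, "mu1": mu1,
        "sigma": s.clip(lower=0.1).fillna(0.1), "z": z,
    })
    # deterministic: |z| descending, then symbol ascending
    order = sorted(stats.index, key=lambda g: (-abs(z[g]), g))
    stats = stats.loc[order].iloc[:max_length]
    return CandidateSeries(pathway=pathway, stats=stats,
                           step=design.step, min_length=design.min_length)


def _default_scorer():
    from .activity import score_activity
    return score_activity


def _score_candidate(series: CandidateSeries, length: int,
                     matrix: NormalizedMatrix, scorer) -> pd.Series:
    res = scorer(series.profiles(length), matrix, False)
    return res.scores[series.pathway]


def evaluate_candidates_proteomics(series: CandidateSeries,
                                   validation: NormalizedMatrix,
                                   proteomics: pd.Series,
                                   scorer=None) -> dict[int, float]:
    """Spearman(activity, proteomics) per candidate length.

    A constant activity vector gives an undefined rank correlation; it is
    recorded as 0 with a warning.
    """
    scorer = scorer or _default_scorer()
    overlap = [s for s in validation.data.index if s in proteomics.index]
    if len(overlap) < 5:
        raise ValueError(
            f"need >=5 overlapping samples, got {len(overlap)}")
    sub = NormalizedMatrix(data=validation.data.loc[overlap])
    prot = proteomics.loc[overlap]
    out: dict[int, float] = {}
    for length in series.lengths:
        act = _score_candidate(series, length, sub, scorer)
        if act.nunique() == 1 or prot.nunique() == 1:
            warnings.warn(
                f"constant activity at length {length}; rho set to 0",
                stacklevel=2)
            out[length] = 0.0
            continue
        out[length] = float(spearmanr(act, prot).statistic)
    return out


def select_lengths_budget(curves: dict[str, dict[int, float]],
                          design: DesignConfig | None = None,
                          gene_lists: dict[str, dict[int, list[str]]] | None = None,
                          ) -> dict[str, int]:
    """Choose one candidate length per pathway under the gene budget.

    "sum" semantics: maximize sum(rho) subject to sum(lengths) <= budget by
    exact dynamic programming over the length grid. "union" semantics: the
    budget caps the number of unique genes across signatures (shared genes
    counted once); greedy forward selection from the minimum lengths,
    stepping the pathway with the largest rho gain while feasible
    (``gene_lists`` must supply the candidate lists). Ties prefer the
    smaller total length, then lexicographic pathway order.
    """
    design = design or DesignConfig()
    if not curves or any(not c for c in curves.values()):
        raise ValueError("every pathway needs a nonempty rho curve")
    pathways = sorted(curves)
    if design.budget_semantics == "sum":
        min_total = sum(min(curves[p]) for p in pathways)
        if min_total > design.budget:
            raise ValueError(
                f"infeasible budget {design.budget}: minimal feasible "
                f"budget is {min_total}")
        # DP over pathways; state = total length used
        best: dict[int, tuple[float, tuple[int, ...]]] = {0: (0.0, ())}
        for p in pathways:
            nxt: dict[int, tuple[float, tuple[int, ...]]] = {}
            for used, (val, assign) in best.items():
                for length, rho in sorted(curves[p].items()):
                    u = used + length
                    if u > design.budget:
                        continue
                    cand = (val + rho, assign + (length,))
                    cur = nxt.get(u)
                    if cur is None or _better(cand, cur):
                        nxt[u] = cand
            best = nxt
        winner = None
        winner_used = None
        for used, (val, assign) in best.items():
            cand = (val, assign)
            if winner is None or _better_total(cand, used, winner, winner_used):
                winner, winner_used = cand, used
        assert winner is not None
        return dict(zip(pathways, winner[1]))

    if gene_lists is None:
        raise ValueError("union semantics requires gene_lists")
    lengths = {p: min(curves[p]) for p in pathways}

    def union_size(assign: dict[str, int]) -> int:
        genes: set[str] = set()
        for p, ln in assign.items():
            genes.update(gene_lists[p][ln])
        return len(genes)

    if union_size(lengths) > design.budget:
        raise ValueError(
            f"infeasible budget {design.budget}: minimal union is "
            f"{union_size(lengths)}")
    while True:
        best_step = None
        for p in pathways:
            grid = sorted(curves[p])
            i = grid.index(lengths[p])
            if i + 1 >= len(grid):
                continue
            nxt_len = grid[i + 1]
            gain = curves[p][nxt_len] - curves[p][lengths[p]]
            if gain <= 0:
                continue
            trial = dict(lengths)
            trial[p] = nxt_len
            if union_size(trial) > design.budget:
                continue
            key = (-gain, union_size(trial), p)
            if best_step is None or key < best_step[0]:
                best_step = (key, p, nxt_len)
        if best_step is None:
            return lengths
        lengths[best_step[1]] = best_step[2]


def _better(a: tuple[float, tuple[int, ...]],
            b: tuple[float, tuple[int, ...]]) -> bool:
    """At equal budget use: higher rho, then shorter total, then lexicographic."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if sum(a[1]) != sum(b[1]):
        return sum(a[1]) < sum(b[1])
    return a[1] < b[1]


def _better_total(a: tuple[float, tuple[int, ...]], a_used: int,
                  b: tuple[float, tuple[int, ...]], b_used: int) -> bool:
    if a[0] != b[0]:
        return a[0] > b[0]
    if a_used != b_used:
        return a_used < b_used
    return a[1] < b[1]


def select_by_ec50(series: CandidateSeries, cellline_matrix: NormalizedMatrix,
                   ec50: pd.Series, scorer=None) -> list[str]:
    """Pick the candidate whose activity is most negatively rank-correlated
    with drug EC50 across cell lines (most-sensitive = most-active).

    Ties prefer the shorter list. If no candidate achieves a negative
    correlation the minimum is still returned, with a warning.
    """
    scorer = scorer or _default_scorer()
    overlap = [s for s in cellline_matrix.data.index if s in ec50.index]
    if len(overlap) < 5:
        raise ValueError(f"need >=5 cell lines with EC50, got {len(overlap)}")
    sub = NormalizedMatrix(data=cellline_matrix.data.loc[overlap])
    e = ec50.loc[overlap]
    best: tuple[float, int] | None = None
    for length in series.lengths:
        act = _score_candidate(series, length, sub, scorer)
        if act.nunique() == 1 or e.nunique() == 1:
            rho = 0.0
        else:
            rho = float(spearmanr(act, e).statistic)
        key = (rho, length)
        if best is None or key < best:
            best = key
    assert best is not None
    if best[0] >= 0:
        warnings.warn("no negative correlation achieved", stacklevel=2)
    return series.candidate(best[1])


def select_by_separation(series: CandidateSeries, labeled: NormalizedMatrix,
                         groups: pd.Series, scorer=None,
                         active_label: str = "active",
                         control_label: str = "control") -> list[str]:
    """Pick the candidate that best separates active from control samples.

    Separation = (mean activity_active - mean activity_control) / pooled SD,
    with the pooled SD floored at 1e-6. Ties prefer the shorter list.
    """
    scorer = scorer or _default_scorer()
    act_ids = groups.index[groups == active_label]
    ctl_ids = groups.index[groups == control_label]
    if len(act_ids) < 2 or len(ctl_ids) < 2:
        raise ValueError("both groups need >=2 samples")
    best: tuple[float, int] | None = None
    for length in series.lengths:
        a = _score_candidate(series, length, labeled, scorer)
        xa, xc = a.loc[act_ids], a.loc[ctl_ids]
        pooled = np.sqrt(
            ((len(xa) - 1) * xa.var(ddof=1) + (len(xc) - 1) * xc.var(ddof=1))
            / (len(xa) + len(xc) - 2))
        diff = xa.mean() - xc.mean()
        if pooled < 1e-6 and diff == 0:
            metric = 0.0
        else:
            metric = float(diff / max(pooled, 1e-6))
        key = (-metric, length)
        if best is None or key < best:
            best = key
    assert best is not None
    return series.candidate(best[1])


def filter_blocklist(signature: Signature,
                     blocklist: set[str]) -> tuple[Signature, int]:
    """Remove blocklisted symbols, preserving order; returns removal count."""
    keep = [g for g in signature.symbols if g not in blocklist]
    removed = len(signature) - len(keep)
    if not keep:
        raise ValueError(
            f"blocklist removes every gene from {signature.pathway!r}")
    return (Signature(pathway=signature.pathway,
                      genes=signature.genes.loc[keep]),
            removed)


def reduce_by_expression(genes: list[str], reference: NormalizedMatrix,
                         k: int = 25) -> list[str]:
    """Top-k genes by mean normalized expression in a reference cohort.

    Genes missing from the reference are dropped with a warning; ties break
    by symbol order. If fewer than k genes remain, all are returned with a
    warning.
    """
    present = [g for g in genes if g in reference.data.columns]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"genes absent from reference dropped: {missing}",
                      stacklevel=2)
    means = reference.data[present].mean(axis=0)
    ranked = sorted(present, key=lambda g: (-means[g], g))
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} genes available for top-{k} reduction",
            stacklevel=2)
        return ranked
    return ranked[:k]


def default_hsp_blocklist(symbols: list[str] | None = None) -> set[str]:
    """Heat-shock-protein symbol blocklist: HSP*/DNAJ* prefixes.

    With ``symbols`` given, returns the matching subset; otherwise a small
    default list of common HSP family symbols.
    """
    if symbols is not None:
        return {s for s in symbols
                if s.upper().startswith(("HSP", "DNAJ"))}
    return {
        "HSPA1A", "HSPA1B", "HSPA4", "HSPA5", "HSPA6", "HSPA8", "HSPA9",
        "HSPB1", "HSPB8", "HSPD1", "HSPE1", "HSPH1", "HSP90AA1", "HSP90AB1",
        "HSP90B1", "DNAJA1", "DNAJB1", "DNAJB6", "DNAJC7",
    }
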