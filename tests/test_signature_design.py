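import itertools

import numpy as np
import pandas as pd
import pytest

from pathpanel.normalization import NormalizedMatrix, normalize
from pathpanel.signature_design import (
    CandidateSeries, DesignConfig, Signature, default_hsp_blocklist,
    derive_candidates, evaluate_candidates_proteomics, filter_blocklist,
    reduce_by_expression, select_by_ec50, select_by_separation,
    select_lengths_budget,
)
from pathpanel.synthetic import (
    SimulationConfig, default_ground_truth,
    simulate_overexpression_experiment, simulate_panel,
)


def _training(n_genes=40, planted=10, delta=2.0, phi=0.01, seed=0,
              n_per_arm=10):
    cfg = SimulationConfig(n_endogenous=n_genes, n_housekeeping=4,
                           neg_ctrl_count=4, nb_dispersion=phi, seed=seed)
    panel = simulate_panel(cfg)
    truth = default_ground_truth(panel, genes_per_pathway=planted,
                                 effect=delta)
    exp = simulate_overexpression_experiment(panel, "PW1", n_per_arm,
                                             n_per_arm, truth, cfg)
    return panel, truth, exp


def test_candidate_series_is_nested():
    _, _, exp = _training()
    series = derive_candidates(exp, "PW1", 30)
    for lo, hi in zip(series.lengths, series.lengths[1:]):
        assert set(series.candidate(lo)) < set(series.candidate(hi))


def test_planted_signature_recovered():
    """30 planted genes at phi=0.01 are nearly all in the length-30 list."""
    recovered = []
    for seed in range(10):
        _, truth, exp = _training(n_genes=60, planted=30, seed=seed)
        series = derive_candidates(exp, "PW1", 30)
        got = set(series.candidate(30)) & set(truth.signature_genes["PW1"])
        recovered.append(len(got))
    assert sum(r >= 27 for r in recovered) >= 9


def test_single_shifted_gene_ranks_first():
    _, truth, exp = _training(n_genes=30, planted=1, delta=4.0, phi=0.0)
    series = derive_candidates(exp, "PW1", 10)
    planted = next(iter(truth.signature_genes["PW1"]))
    assert series.candidate(5)[0] == planted
    assert series.signature(5).genes.loc[planted, "direction"] == 1


def test_off_grid_length_rejected():
    _, _, exp = _training()
    series = derive_candidates(exp, "PW1", 20)
    with pytest.raises(ValueError, match="not on grid"):
        series.candidate(7)
    with pytest.raises(ValueError, match="exceeds"):
        derive_candidates(exp, "PW1", 1000)


def test_budget_hand_example():
    curves = {"a": {5: 0.5, 10: 0.9}, "b": {5: 0.8, 10: 0.81}}
    chosen = select_lengths_budget(curves, DesignConfig(budget=15))
    assert chosen == {"a": 10, "b": 5}


def _brute_force(curves, budget):
    paths = sorted(curves)
    best = None
    for combo in itertools.product(*(sorted(curves[p]) for p in paths)):
        if sum(combo) > budget:
            continue
        val = sum(curves[p][ln] for p, ln in zip(paths, combo))
        key = (-val, sum(combo), combo)
        if best is None or key < best:
            best = key
    return dict(zip(paths, best[2]))


def test_budget_dp_matches_bruteforce():
    rng = np.random.default_rng(7)
    for trial in range(20):
        curves = {}
        for i in range(6):
            lengths = [5, 10, 15, 20]
            rhos = np.sort(rng.uniform(0, 1, size=4))  # concave-ish
            curves[f"pw{i}"] = dict(zip(lengths, np.round(rhos, 6)))
        for budget in (30, 60, 150):
            dp = select_lengths_budget(curves, DesignConfig(budget=budget))
            assert sum(dp.values()) <= budget
            assert dp == _brute_force(curves, budget)


def test_budget_infeasible_reports_minimum():
    curves = {"a": {10: 0.5}, "b": {10: 0.4}}
    with pytest.raises(ValueError, match="20"):
        select_lengths_budget(curves, DesignConfig(budget=15))


def test_budget_slack_gives_argmax_lengths():
    curves = {"a": {5: 0.2, 10: 0.9}, "b": {5: 0.7, 10: 0.3}}
    chosen = select_lengths_budget(curves, DesignConfig(budget=1000))
    assert chosen == {"a": 10, "b": 5}


def test_budget_union_semantics_counts_shared_genes_once():
    curves = {"a": {1: 0.5, 2: 0.9}, "b": {1: 0.5, 2: 0.9}}
    gene_lists = {
        "a": {1: ["g1"], 2: ["g1", "g2"]},
        "b": {1: ["g1"], 2: ["g1", "g2"]},  # fully shared with a
    }
    cfg = DesignConfig(budget=2, step=1, min_length=1,
                       budget_semantics="union")
    chosen = select_lengths_budget(curves, cfg, gene_lists=gene_lists)
    # union of both length-2 lists is still 2 genes -> both can grow
    assert chosen == {"a": 2, "b": 2}


def _matrix_from_scores(series, activities, rng, noise=0.0):
    """Build a normalized matrix whose samples mix mu0/mu1 at given levels."""
    tab = series.stats
    data = {}
    for i, a in enumerate(activities):
        y = (1 - a) * tab["mu0"] + a * tab["mu1"]
        data[f"S{i}"] = y + rng.normal(0, noise, size=len(y))
    return NormalizedMatrix(data=pd.DataFrame(data).T)


def test_proteomics_curve_and_overlap_guard():
    _, _, exp = _training(n_genes=30, planted=10)
    series = derive_candidates(exp, "PW1", 20)
    rng = np.random.default_rng(0)
    acts = np.linspace(0, 1, 12)
    mat = _matrix_from_scores(series, acts, rng, noise=0.05)
    prot = pd.Series(acts, index=mat.data.index)
    curve = evaluate_candidates_proteomics(series, mat, prot)
    assert set(curve) == set(series.lengths)
    assert max(curve.values()) > 0.95

    small = NormalizedMatrix(data=mat.data.iloc[:4])
    with pytest.raises(ValueError, match=">=5"):
        evaluate_candidates_proteomics(series, small, prot)


def test_constant_activity_recorded_as_zero():
    _, _, exp = _training(n_genes=30, planted=10)
    series = derive_candidates(exp, "PW1", 10)
    rng = np.random.default_rng(0)
    mat = _matrix_from_scores(series, np.zeros(6), rng)  # all at baseline
    prot = pd.Series(np.arange(6.0), index=mat.data.index)
    with pytest.warns(UserWarning, match="constant activity"):
        curve = evaluate_candidates_proteomics(series, mat, prot)
    assert all(v == 0.0 for v in curve.values())


def test_ec50_selection_prefers_most_negative_then_shorter():
    _, _, exp = _training(n_genes=30, planted=10)
    series = derive_candidates(exp, "PW1", 10)
    rng = np.random.default_rng(1)
    acts = np.linspace(0, 1, 10)
    mat = _matrix_from_scores(series, acts, rng)
    ec50 = pd.Series(acts, index=mat.data.index)  # positively correlated
    with pytest.warns(UserWarning, match="no negative correlation"):
        chosen = select_by_ec50(series, mat, ec50)
    assert chosen == series.candidate(5)  # tie on rho -> shorter wins

    good = pd.Series(10.0 ** (-acts), index=mat.data.index)
    chosen = select_by_ec50(series, mat, good)
    assert chosen == series.candidate(5)


def test_separation_selection_tie_rule_and_planted_win():
    _, _, exp = _training(n_genes=30, planted=10)
    series = derive_candidates(exp, "PW1", 10)
    rng = np.random.default_rng(2)
    mat = _matrix_from_scores(series, [0, 0, 0, 1, 1, 1], rng)
    groups = pd.Series(["control"] * 3 + ["active"] * 3,
                       index=mat.data.index)
    chosen = select_by_separation(series, mat, groups)
    assert chosen == series.candidate(5)  # identical metrics -> shortest


def test_blocklist_filtering():
    genes = pd.DataFrame({"direction": [1] * 3, "effect": [1.0] * 3},
                         index=["HSPA6", "FN1", "SNAI2"])
    sig = Signature(pathway="p", genes=genes)
    out, removed = filter_blocklist(sig, {"HSPA6"})
    assert removed == 1 and out.symbols == ["FN1", "SNAI2"]
    out2, removed2 = filter_blocklist(sig, {"XYZ"})
    assert removed2 == 0 and out2.symbols == sig.symbols
    with pytest.raises(ValueError, match="every gene"):
        filter_blocklist(sig, {"HSPA6", "FN1", "SNAI2"})


def test_blocklist_arithmetic_133_minus_79():
    hsp = [f"HSPX{i}" for i in range(79)]
    other = [f"G{i}" for i in range(54)]
    genes = pd.DataFrame({"direction": [1] * 133, "effect": [0.5] * 133},
                         index=hsp + other)
    sig = Signature(pathway="p", genes=genes)
    out, removed = filter_blocklist(sig, set(hsp))
    assert removed == 79 and len(out) == 54


def test_default_hsp_blocklist_prefix_screen():
    syms = ["HSPA6", "DNAJB1", "FN1", "hspb8"]
    assert default_hsp_blocklist(syms) == {"HSPA6", "DNAJB1", "hspb8"}


def test_reduce_by_expression_matches_sort_oracle():
    rng = np.random.default_rng(4)
    genes = [f"G{i:02d}" for i in range(30)]
    data = pd.DataFrame(rng.normal(8, 2, size=(5, 30)), columns=genes)
    ref = NormalizedMatrix(data=data)
    out = reduce_by_expression(genes, ref, k=10)
    means = data.mean()
    oracle = sorted(genes, key=lambda g: (-means[g], g))[:10]
    assert out == oracle
    assert reduce_by_expression(out, ref, k=10) == out  # identity at k = n
    with pytest.warns(UserWarning, match="dropped"):
        short = reduce_by_expression(genes + ["MISSING"], ref, k=10)
    assert short == oracle
    with pytest.warns(UserWarning, match="available"):
        assert len(reduce_by_expression(genes[:5], ref, k=10)) == 5
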