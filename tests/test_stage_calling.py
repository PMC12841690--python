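"""Stage-wise calling: signed-rank oracle, gates, BH, presence, LOPO."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from gliopanel.definitions import CALL_HYPER, CALL_HYPO, CALL_NS
from gliopanel.stage_calling import (
    CallingParams,
    build_presence,
    call_stage,
    lopo_stability,
    test_gene_stage as wilcoxon_vs_half,
)


def exact_signed_rank_p(values, null=0.5):
    """Enumeration oracle: two-sided one-sample signed-rank p over all 2^n
    sign patterns of the |differences| (no ties, zeros dropped)."""
    diffs = np.asarray(values) - null
    diffs = diffs[diffs != 0]
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    total = ranks.sum()
    count = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= min(w_obs, total - w_obs):
            count += 1
    return count / 2 ** n


@pytest.mark.parametrize("seed,n", [(0, 6), (1, 8), (2, 10), (3, 12)])
def test_wilcoxon_matches_enumeration(seed, n):
    rng = np.random.default_rng(seed)
    values = np.round(rng.random(n), 3)  # rounding may create ties → regenerate
    while len(np.unique(np.abs(values - 0.5))) < n or (values == 0.5).any():
        values = np.round(rng.random(n), 3)
    _, _, p = wilcoxon_vs_half(values)
    assert p == pytest.approx(exact_signed_rank_p(values), rel=1e-12)


def test_wilcoxon_spec_configurations():
    med, delta, p = wilcoxon_vs_half([0.1, 0.2, 0.15, 0.12, 0.18, 0.22])
    assert p == pytest.approx(exact_signed_rank_p([0.1, 0.2, 0.15, 0.12, 0.18, 0.22]))
    assert p == pytest.approx(2 / 64)  # all-negative configuration, n=6
    # 50 values all below 0.5 with median 0.15 → strong evidence
    rng = np.random.default_rng(4)
    vals = np.clip(rng.normal(0.15, 0.05, 50), 0.01, 0.45)
    med, delta, p = wilcoxon_vs_half(vals)
    assert delta == pytest.approx(np.median(vals) - 0.5)
    assert p < 0.001
    # symmetry about the null → p ≈ 1
    sym = np.concatenate([0.5 - np.linspace(0.01, 0.2, 20), 0.5 + np.linspace(0.01, 0.2, 20)])
    _, _, p_sym = wilcoxon_vs_half(sym)
    assert p_sym > 0.9


def test_wilcoxon_degenerate_inputs():
    with pytest.raises(ValueError):
        wilcoxon_vs_half([])
    med, delta, p = wilcoxon_vs_half([0.5, 0.5, 0.5, 0.5])
    assert p == 1.0 and delta == 0.0  # all at the reference → p=1 by convention
    _, _, p_small = wilcoxon_vs_half([0.1, 0.2])
    assert np.isnan(p_small)  # n < 3 → undefined


def test_bh_equals_brute_force_step_up():
    def brute_force_bh(p):
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        return adj

    rng = np.random.default_rng(11)
    for _ in range(25):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(
            multipletests(p, method="fdr_bh")[1], brute_force_bh(p), rtol=1e-12
        )


def test_effect_gate_blocks_significant_but_shallow_genes(separated_cohort):
    """A gene with β_median just above 0.30 stays NS despite a tiny p-value."""
    c = separated_cohort
    rng = np.random.default_rng(2)
    values = c.summary.values.copy()
    # plant a gene at β ≈ 0.32: clearly ≠ 0.5 but fails the ≤0.30 gate
    values.loc[values.index[0], :] = rng.normal(0.32, 0.01, values.shape[1]).clip(0, 1)
    summary = type(c.summary)(values=values, panel=c.summary.panel,
                              probes_per_gene=c.summary.probes_per_gene)
    calls = call_stage(summary, c.metadata, "Primary").set_index("gene")
    row = calls.loc[values.index[0]]
    assert row["fdr"] < 0.05 and row["call"] == CALL_NS


def test_call_stage_recovers_planted_classes(separated_cohort):
    c = separated_cohort
    calls = call_stage(c.summary, c.metadata, "Primary").set_index("gene")["call"]
    truth = pd.Series(c.truth.gene_class)
    for cls in (CALL_HYPO, CALL_HYPER, CALL_NS):
        genes = truth[truth == cls].index.intersection(calls.index)
        assert (calls.loc[genes] == cls).mean() >= 0.95, cls
    # sign convention: Δβ < 0 for every HYPO call, > 0 for every HYPER call
    table = call_stage(c.summary, c.metadata, "Primary")
    assert (table.loc[table["call"] == CALL_HYPO, "delta_beta"] < 0).all()
    assert (table.loc[table["call"] == CALL_HYPER, "delta_beta"] > 0).all()


def test_recur3_refused_for_inference(separated_cohort):
    c = separated_cohort
    with pytest.raises(ValueError, match="Recur3"):
        call_stage(c.summary, c.metadata, "Recur3")
    with pytest.raises(ValueError, match="unknown stage|not eligible"):
        call_stage(c.summary, c.metadata, "Relapse")


def test_presence_matrix_intersections():
    def table(stage, calls):
        return pd.DataFrame(
            {"gene": list(calls), "stage": stage, "call": list(calls.values())}
        )

    t1 = table("Primary", {"A": CALL_HYPO, "B": CALL_HYPO, "C": CALL_HYPER})
    t2 = table("Recur1", {"A": CALL_HYPO, "B": CALL_HYPO, "C": CALL_HYPER})
    t3 = table("Recur2", {"A": CALL_HYPO, "B": CALL_NS, "C": CALL_HYPER})
    presence = build_presence([t1, t2, t3])
    assert presence.consistent_hypo == ["A"]   # B drops out at Recur2
    assert presence.consistent_hyper == ["C"]
    assert presence.grid.loc["B", "Recur2"] == CALL_NS


def test_presence_recovers_planted_consistency(separated_cohort):
    c = separated_cohort
    tables = {s: call_stage(c.summary, c.metadata, s) for s in ("Primary", "Recur1", "Recur2")}
    presence = build_presence(tables)
    stable_hypo = {g for g, cls in c.truth.gene_class.items()
                   if cls == CALL_HYPO and g in c.report.panel}
    # most planted HYPO genes persist across all three stages (events can flip a few)
    assert len(set(presence.consistent_hypo) & stable_hypo) >= 0.9 * len(stable_hypo)


def test_lopo_retention_well_powered(separated_cohort):
    c = separated_cohort
    lopo = lopo_stability(c.summary, c.metadata, "Primary")
    assert not lopo.empty
    assert lopo["retention"].median() == 1.0
    assert (lopo["retention"] >= 0.95).mean() >= 0.95


def test_lopo_marginal_call_not_retained():
    """A call whose significance depends on every patient (minimal-n
    signed-rank, p = 2/2^6 = 0.031) disappears in every leave-one-out
    resample (p = 2/2^5 = 0.0625), giving retention 0."""
    from gliopanel.promoter_panel import PromoterSummary

    vals = [0.25, 0.27, 0.28, 0.26, 0.29, 0.24]
    values = pd.DataFrame([vals], index=["G1"],
                          columns=[f"P{i:02d}_Primary" for i in range(6)])
    summary = PromoterSummary(values=values, panel=["G1"],
                              probes_per_gene=pd.Series(dtype=int))
    meta = pd.DataFrame({
        "sample_id": values.columns,
        "patient": [s.split("_")[0] for s in values.columns],
        "stage": "Primary",
    })
    base = call_stage(summary, meta, "Primary").set_index("gene")
    assert base.loc["G1", "call"] == CALL_HYPO
    lopo = lopo_stability(summary, meta, "Primary")
    assert lopo.set_index("gene").loc["G1", "retention"] == 0.0


def test_lopo_empty_when_no_significant_calls():
    from gliopanel.promoter_panel import PromoterSummary

    rng = np.random.default_rng(3)
    values = pd.DataFrame(
        rng.uniform(0.4, 0.6, (4, 10)), index=list("ABCD"),
        columns=[f"P{i}_Primary" for i in range(10)],
    )
    summary = PromoterSummary(values=values, panel=list("ABCD"),
                              probes_per_gene=pd.Series(dtype=int))
    meta = pd.DataFrame({
        "sample_id": values.columns,
        "patient": [s.split("_")[0] for s in values.columns],
        "stage": "Primary",
    })
    lopo = lopo_stability(summary, meta, "Primary")
    assert lopo.empty
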