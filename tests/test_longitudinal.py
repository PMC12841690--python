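"""Burden, k-means groups, transition events, binomial imbalance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gliopanel.definitions import GAIN_HYPER, GAIN_HYPO, GAIN_STABLE
from gliopanel.longitudinal_dynamics import (
    binomial_imbalance,
    burden_counts,
    classify_transitions,
    cluster_burden,
    compare_burden,
    patient_calls,
)


def test_patient_call_gates(separated_cohort):
    c = separated_cohort
    calls = patient_calls(c.summary, c.metadata)
    by_beta = calls.set_index(["patient", "stage", "gene"])
    # gates: β ≤ 0.30 → HYPO, β ≥ 0.70 → HYPER (boundary inclusive), else NS
    assert (calls.loc[calls["beta"] <= 0.30, "call"] == "HYPO").all()
    assert (calls.loc[calls["beta"] >= 0.70, "call"] == "HYPER").all()
    mid = calls[(calls["beta"] > 0.30) & (calls["beta"] < 0.70)]
    assert (mid["call"] == "NS").all()
    assert len(by_beta) > 0


def test_patient_call_boundaries():
    from gliopanel.promoter_panel import PromoterSummary

    values = pd.DataFrame(
        {"P1_Primary": [0.12, 0.50, 0.70, 0.30]},
        index=["A", "B", "C", "D"],
    )
    summary = PromoterSummary(values=values, panel=list("ABCD"),
                              probes_per_gene=pd.Series(dtype=int))
    meta = pd.DataFrame(
        {"sample_id": ["P1_Primary"], "patient": ["P1"], "stage": ["Primary"]}
    )
    calls = patient_calls(summary, meta).set_index("gene")["call"]
    assert calls["A"] == "HYPO"
    assert calls["B"] == "NS"
    assert calls["C"] == "HYPER"   # boundary inclusive
    assert calls["D"] == "HYPO"    # boundary inclusive


def test_burden_counts_equal_brute_force(separated_cohort):
    c = separated_cohort
    calls = patient_calls(c.summary, c.metadata)
    burden = burden_counts(calls).set_index(["patient", "stage"])
    sample = calls[(calls["patient"] == calls["patient"].iloc[0])]
    for stage, block in sample.groupby("stage"):
        row = burden.loc[(sample["patient"].iloc[0], stage)]
        assert row["n_hypo"] == (block["call"] == "HYPO").sum()
        assert row["n_hyper"] == (block["call"] == "HYPER").sum()


def _blob_burden(seed=0, n=30):
    rng = np.random.default_rng(seed)
    centers = [(2, 1), (10, 3), (20, 8)]
    rows = []
    for i in range(n):
        cx, cy = centers[i % 3]
        rows.append((f"P{i:03d}", "Primary",
                     max(0, cx + rng.integers(-1, 2)), max(0, cy + rng.integers(-1, 2))))
    return pd.DataFrame(rows, columns=["patient", "stage", "n_hypo", "n_hyper"])


def test_three_planted_blobs_select_k3():
    burden = _blob_burden()
    result = cluster_burden(burden, k=3, seed=0)["Primary"]
    silh = {k: v for k, v in result.silhouettes.items() if np.isfinite(v)}
    assert max(silh, key=silh.get) == 3  # k=3 attains the maximal silhouette
    assert all(-1 <= v <= 1 for v in silh.values())
    # label ordering by ascending centroid sum
    means = result.burden.groupby("group")[["n_hypo", "n_hyper"]].mean().sum(axis=1)
    assert means["Low"] < means["Mid"] < means["High"]


def test_degenerate_identical_counts():
    burden = pd.DataFrame(
        {"patient": [f"P{i}" for i in range(10)], "stage": "Primary",
         "n_hypo": 5, "n_hyper": 2}
    )
    result = cluster_burden(burden, k=3, seed=0)["Primary"]
    assert result.degenerate
    assert all(np.isnan(v) for v in result.silhouettes.values())


def test_compare_burden_power_and_k2_equivalence():
    rng = np.random.default_rng(1)
    burden = pd.DataFrame({
        "patient": [f"P{i}" for i in range(60)],
        "stage": "Primary",
        "group": ["Low"] * 30 + ["High"] * 30,
        "n_hypo": np.concatenate([rng.poisson(5, 30), rng.poisson(10, 30)]),
        "n_hyper": np.concatenate([rng.poisson(2, 30), rng.poisson(7, 30)]),
    })
    res = compare_burden(burden)
    assert res["n_hypo"]["kruskal_p"] < 0.01
    # two groups: KW p equals the rank-sum p up to the continuity correction
    mwu = stats.mannwhitneyu(
        burden.loc[burden["group"] == "Low", "n_hypo"],
        burden.loc[burden["group"] == "High", "n_hypo"],
        alternative="two-sided", method="asymptotic",
    )
    assert res["n_hypo"]["kruskal_p"] == pytest.approx(mwu.pvalue, rel=0.05)
    with pytest.raises(ValueError):
        compare_burden(burden[burden["group"] == "Low"])


def test_transition_classification_rules(separated_cohort):
    c = separated_cohort
    events, totals = classify_transitions(c.summary, c.metadata)
    assert set(events["class"]) <= {GAIN_HYPO, GAIN_HYPER, GAIN_STABLE}
    assert (events.loc[events["class"] == GAIN_HYPER, "delta_beta"] >= 0.20).all()
    assert (events.loc[events["class"] == GAIN_HYPO, "delta_beta"] <= -0.20).all()
    assert (events.loc[events["class"] == GAIN_STABLE, "delta_beta"].abs() < 0.20).all()
    if not totals.empty:
        assert totals.loc[totals["transition"] == "R2→R3", "descriptive"].all()


def test_planted_event_recovery(separated_cohort):
    """≥90% of injected ±0.30 steps are classified as the matching gain."""
    c = separated_cohort
    events, _ = classify_transitions(c.summary, c.metadata)
    idx = events.set_index(["patient", "gene", "transition"])["class"]
    injected = c.truth.injected_events
    assert injected
    hits = 0
    for patient, gene, transition, direction in injected:
        want = GAIN_HYPER if direction > 0 else GAIN_HYPO
        if idx.get((patient, gene, transition)) == want:
            hits += 1
    assert hits / len(injected) >= 0.90


@given(st.lists(st.floats(-0.6, 0.6, allow_nan=False), min_size=1, max_size=30))
@settings(deadline=None, max_examples=50)
def test_event_classification_antisymmetric(deltas):
    """Negating Δβ swaps HypoGain↔HyperGain and fixes Stable."""

    def classify(d):
        if d <= -0.20:
            return GAIN_HYPO
        if d >= 0.20:
            return GAIN_HYPER
        return GAIN_STABLE

    swap = {GAIN_HYPO: GAIN_HYPER, GAIN_HYPER: GAIN_HYPO, GAIN_STABLE: GAIN_STABLE}
    for d in deltas:
        assert classify(-d) == swap[classify(d)]


def test_binomial_exact_tail_values():
    totals = pd.DataFrame({
        "gene": ["A", "A", "B", "B"],
        "transition": ["P→R1"] * 4,
        "class": [GAIN_HYPER, GAIN_HYPO] * 2,
        "count": [20, 3, 5, 5],
    })
    res = binomial_imbalance(totals).set_index("gene")
    # x=20, n=23: two-sided exact p = 2·P(X ≤ 3) = 4096/2^23
    assert res.loc["A", "p"] == pytest.approx(4096 / 2 ** 23, rel=1e-12)
    assert res.loc["B", "p"] == 1.0  # perfectly balanced


def test_binomial_matches_enumeration():
    """Minimum-likelihood two-sided p equals brute-force enumeration over
    all outcomes at small n."""
    from math import comb

    rng = np.random.default_rng(5)
    for _ in range(20):
        n = int(rng.integers(1, 18))
        x = int(rng.integers(0, n + 1))
        pmf = [comb(n, k) / 2 ** n for k in range(n + 1)]
        expected = sum(p for p in pmf if p <= pmf[x] + 1e-12)
        got = stats.binomtest(x, n, 0.5).pvalue
        assert got == pytest.approx(min(expected, 1.0), rel=1e-9)


def test_balanced_generator_yields_no_imbalance(separated_cohort):
    """Events injected with symmetric direction probabilities produce no
    post-BH significant gene-level imbalance."""
    c = separated_cohort
    _, totals = classify_transitions(c.summary, c.metadata)
    res = binomial_imbalance(totals)
    if not res.empty:
        assert (res["fdr"] < 0.05).sum() <= max(1, int(0.05 * len(res)))
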