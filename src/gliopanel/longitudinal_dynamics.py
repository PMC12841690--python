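"""Longitudinal methylation dynamics: patient burden and adjacent-stage gain events.

Two complementary patient-level views of the cohort:

* **Burden** — per patient and stage, the number of panel genes whose
  single-sample promoter β falls in the HYPO (≤ 0.30) or HYPER (≥ 0.70)
  range.  Patients are clustered into Low/Mid/High burden groups with
  k-means in the 2-D (n_hypo, n_hyper) count space, with average
  silhouette widths over k = 2..5 supporting the choice of k.
* **Transition events** — per patient, gene and adjacent-stage pair, the
  β change Δβ = β(later) − β(earlier), classified HypoGain (≤ −0.20),
  HyperGain (≥ +0.20) or Stable.  Per-gene totals feed a two-sided exact
  binomial test of HyperGain vs HypoGain imbalance (BH across genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .definitions import (
    CALL_HYPER,
    CALL_HYPO,
    CALL_NS,
    GAIN_HYPER,
    GAIN_HYPO,
    GAIN_STABLE,
    TRANSITION_LABELS,
    TRANSITIONS,
)
from .promoter_panel import PromoterSummary

__all__ = [
    "patient_calls",
    "burden_counts",
    "BurdenClustering",
    "cluster_burden",
    "compare_burden",
    "classify_transitions",
    "binomial_imbalance",
]

_GROUP_LABELS = ("Low", "Mid", "High")


def patient_calls(
    summary: PromoterSummary,
    metadata: pd.DataFrame,
    beta_lo: float = 0.30,
    beta_hi: float = 0.70,
) -> pd.DataFrame:
    """Per-(patient, stage, gene) HYPO/HYPER/NS call from the β gates alone.

    At n = 1 no test is possible, so the patient-level call uses only the
    β range: β ≤ ``beta_lo`` → HYPO, β ≥ ``beta_hi`` → HYPER (boundaries
    inclusive), else NS.  Multiple samples from one patient at one stage
    are averaged first.
    """
    meta = metadata.set_index("sample_id")
    long = summary.values.T.copy()
    long["patient"] = meta.loc[long.index, "patient"]
    long["stage"] = meta.loc[long.index, "stage"]
    per = long.groupby(["patient", "stage"], sort=True).mean()
    stacked = per.stack(future_stack=True).rename("beta").reset_index()
    stacked.columns = ["patient", "stage", "gene", "beta"]
    stacked = stacked[np.isfinite(stacked["beta"])]
    call = np.full(len(stacked), CALL_NS, dtype=object)
    call[(stacked["beta"] <= beta_lo).to_numpy()] = CALL_HYPO
    call[(stacked["beta"] >= beta_hi).to_numpy()] = CALL_HYPER
    stacked["call"] = call
    return stacked.reset_index(drop=True)


def burden_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Tally HYPO and HYPER patient-level calls per (patient, stage)."""
    grouped = calls.groupby(["patient", "stage"], sort=True)["call"]
    out = grouped.agg(
        n_hypo=lambda c: int((c == CALL_HYPO).sum()),
        n_hyper=lambda c: int((c == CALL_HYPER).sum()),
    ).reset_index()
    return out


@dataclass
class BurdenClustering:
    """Burden grouping for one stage plus the silhouette model-selection trace."""

    stage: str
    burden: pd.DataFrame  # patient, stage, n_hypo, n_hyper, group
    k: int
    silhouettes: dict[int, float] = field(default_factory=dict)
    degenerate: bool = False


def _label_clusters(centroids: np.ndarray) -> list[str]:
    """Order cluster labels Low/Mid/High by ascending centroid count sum.

    Ties on the sum are broken by the n_hypo centroid ascending.
    """
    order = np.lexsort((centroids[:, 0], centroids.sum(axis=1)))
    labels = [""] * len(order)
    names = _GROUP_LABELS[: len(order)] if len(order) <= 3 else [
        f"G{i + 1}" for i in range(len(order))
    ]
    for rank, idx in enumerate(order):
        labels[idx] = names[rank]
    return labels


def cluster_burden(
    burden: pd.DataFrame,
    k: int = 3,
    k_range: tuple[int, int] = (2, 5),
    seed: int = 0,
) -> dict[str, BurdenClustering]:
    """Cluster patients into burden groups per stage; silhouette trace for k_range.

    k-means with 25 restarts on the raw (n_hypo, n_hyper) counts (both
    axes share the count scale, so no standardization).  Stages with
    fewer patients than k are skipped.  When all patients at a stage have
    identical counts the clustering is degenerate and the silhouette is
    reported as NaN.
    """
    results: dict[str, BurdenClustering] = {}
    for stage, block in burden.groupby("stage", sort=True):
        x = block[["n_hypo", "n_hyper"]].to_numpy(dtype=float)
        n_unique = np.unique(x, axis=0).shape[0]
        if len(block) < k or n_unique < k:
            if n_unique == 1:
                out = block.copy()
                out["group"] = _GROUP_LABELS[0]
                results[str(stage)] = BurdenClustering(
                    stage=str(stage), burden=out, k=1,
                    silhouettes={kk: float("nan") for kk in range(k_range[0], k_range[1] + 1)},
                    degenerate=True,
                )
            continue  # too few patients → stage skipped
        silhouettes: dict[int, float] = {}
        for kk in range(k_range[0], k_range[1] + 1):
            if kk > n_unique or kk >= len(block):
                silhouettes[kk] = float("nan")
                continue
            km = KMeans(n_clusters=kk, n_init=25, random_state=seed).fit(x)
            if np.unique(km.labels_).size < 2:
                silhouettes[kk] = float("nan")
            else:
                silhouettes[kk] = float(silhouette_score(x, km.labels_))
        km = KMeans(n_clusters=k, n_init=25, random_state=seed).fit(x)
        names = _label_clusters(km.cluster_centers_)
        out = block.copy()
        out["group"] = [names[l] for l in km.labels_]
        results[str(stage)] = BurdenClustering(
            stage=str(stage), burden=out, k=k, silhouettes=silhouettes
        )
    return results


def compare_burden(
    burden: pd.DataFrame,
    group_col: str = "group",
    outcomes: tuple[str, ...] = ("n_hypo", "n_hyper"),
) -> dict[str, dict]:
    """Kruskal–Wallis across groups plus BH-adjusted pairwise rank-sum tests.

    ``group_col`` may be the burden group label or ``"stage"`` for the
    cross-stage comparison.  Each outcome (n_hypo, n_hyper) is tested
    separately; the pairwise two-sided rank-sum p-values are BH-adjusted
    within each outcome's family.
    """
    groups = sorted(burden[group_col].dropna().unique())
    sized = [g for g in groups if (burden[group_col] == g).sum() >= 2]
    if len(sized) < 2:
        raise ValueError(f"need ≥2 groups with ≥2 observations, found {len(sized)}")
    out: dict[str, dict] = {}
    for outcome in outcomes:
        samples = [burden.loc[burden[group_col] == g, outcome].to_numpy(dtype=float) for g in sized]
        kw_stat, kw_p = stats.kruskal(*samples)
        pairs = []
        for i in range(len(sized)):
            for j in range(i + 1, len(sized)):
                res = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
                pairs.append((sized[i], sized[j], float(res.pvalue)))
        adj = multipletests([p for *_, p in pairs], method="fdr_bh")[1] if pairs else []
        out[outcome] = {
            "kruskal_stat": float(kw_stat),
            "kruskal_p": float(kw_p),
            "pairwise": [
                {"a": a, "b": b, "p": p, "p_adj": float(q)}
                for (a, b, p), q in zip(pairs, adj)
            ],
        }
    return out


def classify_transitions(
    summary: PromoterSummary,
    metadata: pd.DataFrame,
    threshold: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjacent-stage Δβ events per (patient, gene) and per-gene gain totals.

    For every patient with promoter data at both stages of a transition,
    Δβ = β(later) − β(earlier) is classified HypoGain (Δβ ≤ −threshold),
    HyperGain (Δβ ≥ +threshold) or Stable.  Returns ``(events, totals)``:
    ``events`` has one row per (patient, gene, transition);
    ``totals`` counts HypoGain/HyperGain per gene and transition
    (Stable not totalled), with the R2→R3 transition flagged descriptive
    (two patients in the motivating cohort shape).
    """
    meta = metadata.set_index("sample_id")
    long = summary.values.T.copy()
    long["patient"] = meta.loc[long.index, "patient"]
    long["stage"] = meta.loc[long.index, "stage"]
    per = long.groupby(["patient", "stage"], sort=True).mean()
    records = []
    for earlier, later in TRANSITIONS:
        label = TRANSITION_LABELS[(earlier, later)]
        for patient in per.index.get_level_values("patient").unique():
            idx = per.loc[patient].index
            if earlier not in idx or later not in idx:
                continue
            delta = per.loc[(patient, later)] - per.loc[(patient, earlier)]
            for gene, d in delta.items():
                if not np.isfinite(d):
                    continue
                if d <= -threshold:
                    cls = GAIN_HYPO
                elif d >= threshold:
                    cls = GAIN_HYPER
                else:
                    cls = GAIN_STABLE
                records.append((patient, gene, label, float(d), cls))
    events = pd.DataFrame(
        records, columns=["patient", "gene", "transition", "delta_beta", "class"]
    )
    gains = events[events["class"] != GAIN_STABLE]
    if gains.empty:
        totals = pd.DataFrame(columns=["gene", "transition", "class", "count", "descriptive"])
    else:
        totals = (
            gains.groupby(["gene", "transition", "class"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
        totals["descriptive"] = totals["transition"] == TRANSITION_LABELS[("Recur2", "Recur3")]
    return events, totals


def binomial_imbalance(totals: pd.DataFrame) -> pd.DataFrame:
    """Two-sided exact binomial test of HyperGain vs HypoGain per gene.

    Events are summed across transitions; for each gene with ≥1 event,
    x = HyperGain count out of n = HyperGain + HypoGain is tested against
    the balanced null p = 0.5 with the minimum-likelihood two-sided exact
    binomial p (sum of outcome probabilities ≤ that of the observed
    count); BH across the tested genes.
    """
    if totals.empty:
        return pd.DataFrame(columns=["gene", "n_hyper_gain", "n_hypo_gain", "p", "fdr"])
    wide = (
        totals.groupby(["gene", "class"])["count"].sum().unstack(fill_value=0)
    )
    n_hyper = wide.get(GAIN_HYPER, pd.Series(0, index=wide.index))
    n_hypo = wide.get(GAIN_HYPO, pd.Series(0, index=wide.index))
    records = []
    for gene in wide.index:
        x, n = int(n_hyper[gene]), int(n_hyper[gene] + n_hypo[gene])
        if n == 0:
            continue
        p = stats.binomtest(x, n, p=0.5, alternative="two-sided").pvalue
        records.append((gene, x, n - x, float(p)))
    out = pd.DataFrame(records, columns=["gene", "n_hyper_gain", "n_hypo_gain", "p"])
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("gene", ignore_index=True)
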