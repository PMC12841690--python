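"""Stage-wise hypo/hypermethylation calling.

Per gene and stage, the per-sample promoter β values are tested against
the hemi-methylated reference 0.50 with a one-sample Wilcoxon signed-rank
test; p-values are Benjamini–Hochberg adjusted across panel genes within
the stage.  A gene is called

* HYPO  when β_median ≤ 0.30, FDR < 0.05 and |Δβ| ≥ 0.20,
* HYPER when β_median ≥ 0.70, FDR < 0.05 and |Δβ| ≥ 0.20,
* NS otherwise,

with Δβ = β_median − 0.50.  The β gates imply the |Δβ| gate at the
defaults, but both are enforced independently so either can be relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .definitions import CALL_HYPER, CALL_HYPO, CALL_NS, INFERENTIAL_STAGES
from .promoter_panel import PromoterSummary

__all__ = [
    "CallingParams",
    "PresenceMatrix",
    "test_gene_stage",
    "call_stage",
    "build_presence",
    "lopo_stability",
]

#: exact signed-rank distribution up to this n (no ties); normal approx above
_EXACT_N = 25


@dataclass(frozen=True)
class CallingParams:
    """Gates and thresholds for HYPO/HYPER calling."""

    beta_lo: float = 0.30   # β_median ≤ beta_lo eligible for HYPO
    beta_hi: float = 0.70   # β_median ≥ beta_hi eligible for HYPER
    min_delta: float = 0.20  # |β_median − null_beta| gate
    alpha: float = 0.05      # FDR threshold
    null_beta: float = 0.50  # one-sample test reference
    min_samples: int = 3     # below this the p-value is undefined → NS


def test_gene_stage(values, null_beta: float = 0.50) -> tuple[float, float, float]:
    """One-sample Wilcoxon signed-rank test of promoter β against ``null_beta``.

    Returns ``(beta_median, delta_beta, p_value)``.  Values exactly equal
    to the reference are dropped before ranking (Wilcoxon convention);
    ties among the |differences| are mid-ranked.  The exact null
    distribution is used for n ≤ 25 without ties, the normal
    approximation with continuity correction otherwise.  With fewer than
    3 usable values the p-value is NaN (call will be NS with a reason);
    if every value equals the reference, p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite promoter β values supplied")
    beta_median = float(np.median(values))
    delta = beta_median - null_beta
    diffs = values - null_beta
    nonzero = diffs[diffs != 0.0]
    if nonzero.size == 0:
        return beta_median, delta, 1.0
    if values.size < 3:
        return beta_median, delta, float("nan")
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= _EXACT_N and not has_ties) else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return beta_median, delta, float(res.pvalue)


def _collapse_patients(
    summary: PromoterSummary, metadata: pd.DataFrame, stage: str
) -> pd.DataFrame:
    """Per-patient promoter β at one stage (genes × patients).

    Multiple samples from one patient at one stage are averaged so that
    the test operates on independent patient units.
    """
    meta = metadata[metadata["stage"] == stage]
    samples = [s for s in meta["sample_id"] if s in summary.values.columns]
    if not samples:
        raise ValueError(f"no samples at stage {stage!r}")
    block = summary.values[samples]
    patients = meta.set_index("sample_id").loc[samples, "patient"]
    return block.T.groupby(patients.values).mean().T


def call_stage(
    summary: PromoterSummary,
    metadata: pd.DataFrame,
    stage: str,
    params: CallingParams | None = None,
) -> pd.DataFrame:
    """Stage-wise HYPO/HYPER/NS calls for every panel gene.

    BH adjustment is applied across all panel genes with a defined
    p-value within the stage.  ``Recur3`` is refused: with two patients
    it is descriptive only.
    """
    if params is None:
        params = CallingParams()
    if stage not in INFERENTIAL_STAGES:
        raise ValueError(
            f"stage {stage!r} not eligible for inference; expected one of {INFERENTIAL_STAGES}"
        )
    per_patient = _collapse_patients(summary, metadata, stage)
    records = []
    for gene in summary.panel:
        vals = per_patient.loc[gene].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            records.append((gene, 0, np.nan, np.nan, np.nan, "no_data"))
            continue
        med, delta, p = test_gene_stage(vals, params.null_beta)
        reason = "" if np.isfinite(p) else "insufficient_n"
        records.append((gene, vals.size, med, delta, p, reason))
    out = pd.DataFrame(
        records, columns=["gene", "n", "beta_median", "delta_beta", "p", "reason"]
    )
    out.insert(1, "stage", stage)
    out["fdr"] = np.nan
    defined = out["p"].notna()
    if defined.any():
        out.loc[defined, "fdr"] = multipletests(
            out.loc[defined, "p"].to_numpy(), method="fdr_bh"
        )[1]
    sig = defined & (out["fdr"] < params.alpha) & (out["delta_beta"].abs() >= params.min_delta)
    call = np.full(len(out), CALL_NS, dtype=object)
    call[(sig & (out["beta_median"] <= params.beta_lo)).to_numpy()] = CALL_HYPO
    call[(sig & (out["beta_median"] >= params.beta_hi)).to_numpy()] = CALL_HYPER
    out["call"] = call
    return out.sort_values("gene", ignore_index=True)


@dataclass
class PresenceMatrix:
    """Gene × stage grid of calls with the cross-stage consistent sets."""

    grid: pd.DataFrame  # genes × stages, values HYPO/HYPER/NS
    consistent_hypo: list[str]
    consistent_hyper: list[str]


def build_presence(calls: Iterable[pd.DataFrame] | Mapping[str, pd.DataFrame]) -> PresenceMatrix:
    """Compile per-stage call tables into a presence matrix.

    ``consistent_hypo``/``consistent_hyper`` are the genes carrying the
    same significant call in every supplied stage (set intersection).
    """
    if isinstance(calls, Mapping):
        tables = list(calls.values())
    else:
        tables = list(calls)
    if len(tables) < 2:
        raise ValueError("presence matrix needs calls from ≥2 stages")
    grid = pd.concat(tables).pivot(index="gene", columns="stage", values="call")
    stage_order = [s for s in INFERENTIAL_STAGES if s in grid.columns]
    grid = grid[stage_order]
    hypo_sets = [set(t.loc[t["call"] == CALL_HYPO, "gene"]) for t in tables]
    hyper_sets = [set(t.loc[t["call"] == CALL_HYPER, "gene"]) for t in tables]
    return PresenceMatrix(
        grid=grid,
        consistent_hypo=sorted(set.intersection(*hypo_sets)),
        consistent_hyper=sorted(set.intersection(*hyper_sets)),
    )


def lopo_stability(
    summary: PromoterSummary,
    metadata: pd.DataFrame,
    stage: str,
    params: CallingParams | None = None,
) -> pd.DataFrame:
    """Leave-one-patient-out stability of significant stage calls.

    For each patient with samples at the stage, all of that patient's
    samples are dropped and the stage calling re-run; the retention
    proportion of a call is the fraction of resamples reproducing it.
    Only calls significant in the full data are reported.  Returns an
    empty frame when the stage has no significant calls.
    """
    if params is None:
        params = CallingParams()
    meta = metadata[metadata["stage"] == stage]
    patients = sorted(set(meta["patient"]))
    if len(patients) < 4:
        raise ValueError(f"LOPO needs ≥4 patients at stage {stage!r}, found {len(patients)}")
    base = call_stage(summary, metadata, stage, params)
    sig = base[base["call"] != CALL_NS]
    if sig.empty:
        return pd.DataFrame(columns=["gene", "stage", "call", "retention"])
    retained = {gene: 0 for gene in sig["gene"]}
    for patient in patients:
        sub_meta = metadata[~((metadata["patient"] == patient) & (metadata["stage"] == stage))]
        calls = call_stage(summary, sub_meta, stage, params).set_index("gene")["call"]
        for gene, call in zip(sig["gene"], sig["call"]):
            if calls.get(gene) == call:
                retained[gene] += 1
    out = sig[["gene", "stage", "call"]].copy()
    out["retention"] = [retained[g] / len(patients) for g in out["gene"]]
    return out.reset_index(drop=True)
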