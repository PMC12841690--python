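"""M-value models: logit transform, stage-trend mixed models, threshold tests, agreement.

β values are variance-unstable near 0 and 1; modelling is done on the
M scale, M = log2((β + ε) / (1 − β + ε)) with a small offset ε keeping the
transform finite at the boundaries.  The per-gene longitudinal trend model
is a linear mixed model with stage as an ordinal fixed effect
(Primary=0 < Recur1=1 < Recur2=2) and a patient random intercept for the
repeated measures.  Effect sizes can additionally be tested against a
minimum-magnitude threshold τ (the shifted-hypothesis construction used
for threshold testing of fold changes); the default τ = |log2(0.7/0.3)|
is the M-scale image of a β shift of 0.20 about 0.50, matching the β-gate
effect-size rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .definitions import CALL_HYPER, CALL_HYPO, CALL_NS, INFERENTIAL_STAGES
from .promoter_panel import PromoterSummary

__all__ = [
    "DEFAULT_EPSILON",
    "default_tau",
    "beta_to_m",
    "m_to_beta",
    "TrendResult",
    "fit_stage_trend",
    "fit_all_trends",
    "threshold_test",
    "model_stage_calls",
    "calling_agreement",
]

DEFAULT_EPSILON = 1e-6

_STAGE_CODE = {s: i for i, s in enumerate(INFERENTIAL_STAGES)}


def default_tau(beta_lo: float = 0.30, beta_hi: float = 0.70) -> float:
    """M-scale threshold matching the β effect-size gate (≈ 1.2224 at defaults)."""
    return abs(np.log2(beta_hi / beta_lo))


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """log2((β + ε)/(1 − β + ε)); strictly increasing, finite on [0, 1]."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    beta = np.asarray(beta, dtype=float)
    finite = beta[np.isfinite(beta)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("β values must lie in [0, 1]")
    m = np.log2((beta + epsilon) / (1.0 - beta + epsilon))
    return m if m.ndim else float(m)


def m_to_beta(m, epsilon: float = DEFAULT_EPSILON):
    """Inverse of :func:`beta_to_m`."""
    m = np.asarray(m, dtype=float)
    r = np.exp2(m)
    beta = (r * (1.0 + epsilon) - epsilon) / (1.0 + r)
    return beta if beta.ndim else float(beta)


@dataclass
class TrendResult:
    gene: str
    slope: float
    se: float
    p_value: float
    q_value: float = float("nan")
    threshold_p: float = float("nan")
    n_samples: int = 0
    method: str = "mixed"  # "mixed" or "ols" fallback


def _ols_slope(m: np.ndarray, code: np.ndarray) -> tuple[float, float, float]:
    x = np.column_stack([np.ones_like(code, dtype=float), code])
    beta, *_ = np.linalg.lstsq(x, m, rcond=None)
    resid = m - x @ beta
    dof = max(len(m) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = float(np.sqrt(cov[1, 1]))
    t = beta[1] / se if se > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(beta[1]), se, float(p)


def fit_stage_trend(
    m_values: pd.Series,
    metadata: pd.DataFrame,
    gene: str = "",
) -> TrendResult:
    """Per-gene ordinal stage-trend model on the M scale.

    ``m_values`` is indexed by sample id.  Stage enters as 0/1/2; the
    patient random intercept absorbs between-patient level differences.
    REML estimation with a Wald z test on the slope.  When fewer than 3
    patients contribute ≥2 stages (random intercept not identifiable) or
    the fit is singular, an ordinary least-squares fit is used and the
    result flagged ``method="ols"``.
    """
    meta = metadata.set_index("sample_id")
    samples = [s for s in m_values.index if s in meta.index and meta.loc[s, "stage"] in _STAGE_CODE]
    m = m_values.loc[samples].to_numpy(dtype=float)
    keep = np.isfinite(m)
    samples = [s for s, k in zip(samples, keep) if k]
    m = m[keep]
    stage_codes = np.array([_STAGE_CODE[meta.loc[s, "stage"]] for s in samples], dtype=float)
    patients = np.array([meta.loc[s, "patient"] for s in samples])
    if np.unique(stage_codes).size < 2:
        raise ValueError(f"gene {gene!r}: need samples from ≥2 stages to fit a trend")
    counts = pd.Series(stage_codes).groupby(patients).nunique()
    repeated = int((counts >= 2).sum())
    if repeated >= 3:
        try:
            exog = np.column_stack([np.ones_like(stage_codes), stage_codes])
            with warnings.catch_warnings():
                # zero patient variance is a legitimate boundary case here
                warnings.simplefilter("ignore")
                fit = MixedLM(m, exog, groups=patients).fit(reml=True)
            slope = float(fit.params[1])
            se = float(fit.bse[1])
            if np.isfinite(se) and se > 0:
                p = 2.0 * stats.norm.sf(abs(slope / se))
                return TrendResult(gene, slope, se, float(p), n_samples=len(m), method="mixed")
        except Exception:
            pass  # singular / non-converged → OLS fallback below
    slope, se, p = _ols_slope(m, stage_codes)
    return TrendResult(gene, slope, se, p, n_samples=len(m), method="ols")


def fit_all_trends(
    summary: PromoterSummary,
    metadata: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
    tau: float | None = None,
) -> pd.DataFrame:
    """Fit the stage-trend model for every panel gene; BH across genes.

    Adds a threshold-test p-value at τ (default: the M-scale image of the
    |Δβ| ≥ 0.20 gate).
    """
    if tau is None:
        tau = default_tau()
    mvals = pd.DataFrame(
        beta_to_m(summary.values.to_numpy(), epsilon),
        index=summary.values.index,
        columns=summary.values.columns,
    )
    results = [fit_stage_trend(mvals.loc[g], metadata, gene=g) for g in summary.panel]
    out = pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "slope": [r.slope for r in results],
            "se": [r.se for r in results],
            "p": [r.p_value for r in results],
            "n": [r.n_samples for r in results],
            "method": [r.method for r in results],
        }
    )
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["threshold_p"] = [threshold_test(s, se, tau) for s, se in zip(out["slope"], out["se"])]
    return out


def threshold_test(effect: float, se: float, tau: float, df: float | None = None) -> float:
    """Threshold test of H0: |effect| ≤ τ against |effect| > τ.

    Shifted-hypothesis construction on the Wald statistic:
    p = P(T > (|effect| − τ)/se) + P(T > (|effect| + τ)/se), with T
    standard normal (default) or Student-t with ``df`` degrees of
    freedom.  At τ = 0 this reduces to the ordinary two-sided p-value.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if not np.isfinite(se) or se <= 0:
        raise ValueError("standard error must be positive and finite")
    t_right = (abs(effect) - tau) / se
    t_left = (abs(effect) + tau) / se
    dist = stats.norm if df is None else stats.t(df)
    return float(dist.sf(t_right) + dist.sf(t_left))


def model_stage_calls(
    summary: PromoterSummary,
    metadata: pd.DataFrame,
    stage: str,
    tau: float | None = None,
    alpha: float = 0.05,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Model-based HYPO/HYPER/NS calls on the M scale for one stage.

    For each gene, the stage-wise mean M (per-patient units, as in the
    β-gate calling) is tested against M(0.5) = 0 with the threshold test
    at τ; BH across genes.  A gene is called HYPO when the mean is
    negative and the adjusted threshold-test p < α, HYPER when positive
    and significant, NS otherwise.  With τ matched to the β gates this is
    the model-side member of the calling-agreement comparison.
    """
    from .stage_calling import _collapse_patients

    if tau is None:
        tau = default_tau()
    per_patient = _collapse_patients(summary, metadata, stage)
    mvals = beta_to_m(per_patient.to_numpy(), epsilon)
    records = []
    for i, gene in enumerate(per_patient.index):
        row = mvals[i]
        row = row[np.isfinite(row)]
        mean = float(np.mean(row))
        se = float(np.std(row, ddof=1) / np.sqrt(row.size)) if row.size > 1 else np.nan
        if np.isfinite(se) and se > 0:
            p = threshold_test(mean, se, tau, df=row.size - 1)
        else:
            p = np.nan
        records.append((gene, row.size, mean, se, p))
    out = pd.DataFrame(records, columns=["gene", "n", "mean_m", "se", "threshold_p"])
    out.insert(1, "stage", stage)
    out["threshold_q"] = np.nan
    defined = out["threshold_p"].notna()
    if defined.any():
        out.loc[defined, "threshold_q"] = multipletests(
            out.loc[defined, "threshold_p"].to_numpy(), method="fdr_bh"
        )[1]
    sig = defined & (out["threshold_q"] < alpha)
    call = np.full(len(out), CALL_NS, dtype=object)
    call[(sig & (out["mean_m"] < 0)).to_numpy()] = CALL_HYPO
    call[(sig & (out["mean_m"] > 0)).to_numpy()] = CALL_HYPER
    out["call"] = call
    return out.sort_values("gene", ignore_index=True)


def calling_agreement(calls_a, calls_b) -> float:
    """Unweighted multi-category Cohen's κ between two call vectors.

    κ = (p_o − p_e)/(1 − p_e) with observed agreement p_o and chance
    agreement p_e from the marginal label frequencies.  When both vectors
    are the same constant label (p_e = 1), κ is defined as 1.
    """
    a = np.asarray(calls_a, dtype=object)
    b = np.asarray(calls_b, dtype=object)
    if a.shape != b.shape:
        raise ValueError(f"call vectors differ in length: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty call vectors")
    p_o = float(np.mean(a == b))
    labels = np.unique(np.concatenate([a, b]))
    p_e = float(sum(np.mean(a == l) * np.mean(b == l) for l in labels))
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)
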