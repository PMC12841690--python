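"""Prognostic survival modelling for signature scores and single genes.

Cox proportional-hazards models (Efron ties, configurable to Breslow)
relate the per-sample scores to overall survival adjusted for age and
sex; the pre-specified quartile contrast compares the top and bottom
score quartiles with Kaplan–Meier + log-rank and an adjusted Cox HR.
Per-gene analyses dichotomize expression at the cohort median
(High > median vs Low ≤ median) with log-rank p-values BH-adjusted
across genes.  Subtype associations use Kruskal–Wallis with BH-adjusted
pairwise rank-sum tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, proportional_hazard_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxResult",
    "cox_per_sd",
    "quartile_contrast",
    "per_gene_median_split",
    "subtype_association",
]


@dataclass
class CoxResult:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    logrank_p: float = float("nan")
    fdr: float = float("nan")
    ph_p: float = float("nan")  # Schoenfeld-residual proportional-hazards diagnostic
    n: int = 0
    n_events: int = 0
    km: pd.DataFrame | None = field(default=None, repr=False)


def _check_survival(df: pd.DataFrame) -> None:
    if (df["os_time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["os_event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")


def _fit_cox(df: pd.DataFrame, term: str, ties: str = "efron") -> tuple[CoxPHFitter, pd.Series]:
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_time", event_col="os_event", fit_options={"step_size": 0.5})
    except Exception as err:  # non-convergence is reported, not silently swallowed
        raise RuntimeError(f"Cox model failed to converge for term {term!r}: {err}") from err
    return cph, cph.summary.loc[term]


def cox_per_sd(
    score: pd.Series,
    covariates: pd.DataFrame,
    survival: pd.DataFrame,
    ties: str = "efron",
) -> CoxResult:
    """Adjusted Cox model with the score as a per-1-SD continuous covariate.

    The score is standardized to unit SD in-cohort, so the HR is per SD
    increase.  Age and sex enter as adjustment covariates.  Requires ≥20
    events.  A Schoenfeld-residual test on the score term is reported as
    the proportional-hazards diagnostic.
    """
    df = pd.concat([score.rename("score"), covariates, survival], axis=1, join="inner").dropna(
        subset=["score", "os_time", "os_event"]
    )
    _check_survival(df)
    n_events = int(df["os_event"].sum())
    if n_events < 20:
        raise ValueError(f"need ≥20 events, found {n_events}")
    sd = df["score"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("score has zero variance")
    df["score"] = (df["score"] - df["score"].mean()) / sd
    cols = ["score", "age", "sex", "os_time", "os_event"]
    cph, row = _fit_cox(df[cols], "score", ties)
    ph = proportional_hazard_test(cph, df[cols], time_transform="rank")
    ph_p = float(ph.summary.loc["score", "p"])
    return CoxResult(
        term="score_per_sd",
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p_wald=float(row["p"]),
        ph_p=ph_p,
        n=len(df),
        n_events=n_events,
    )


def _km_table(times, events, label: str) -> pd.DataFrame:
    km = KaplanMeierFitter()
    km.fit(times, events, label=label)
    out = km.survival_function_.join(km.confidence_interval_)
    out.columns = ["survival", "ci_low", "ci_high"]
    out["at_risk"] = [km.event_table.loc[:t, "at_risk"].iloc[-1] for t in out.index]
    out["group"] = label
    out.index.name = "time"
    return out.reset_index()


def assign_quartiles(score: pd.Series) -> pd.Series:
    """Quartile 1–4 by score; linear-interpolation cut points, boundary ties low."""
    cuts = np.quantile(score.dropna(), [0.25, 0.5, 0.75])
    q = 1 + np.sum(score.to_numpy()[:, None] > cuts[None, :], axis=1)
    return pd.Series(q, index=score.index, name="quartile")


def quartile_contrast(
    score: pd.Series,
    covariates: pd.DataFrame,
    survival: pd.DataFrame,
    min_per_quartile: int = 10,
) -> CoxResult:
    """Pre-specified Q4-vs-Q1 contrast: KM + log-rank + adjusted Cox HR."""
    df = pd.concat([score.rename("score"), covariates, survival], axis=1, join="inner").dropna(
        subset=["score", "os_time", "os_event"]
    )
    _check_survival(df)
    df["quartile"] = assign_quartiles(df["score"])
    sizes = df["quartile"].value_counts()
    if sizes.min() < min_per_quartile or len(sizes) < 4:
        raise ValueError(f"degenerate quartiles (sizes {sizes.to_dict()})")
    sub = df[df["quartile"].isin([1, 4])].copy()
    q1, q4 = sub["quartile"] == 1, sub["quartile"] == 4
    if sub.loc[q1, "os_event"].sum() + sub.loc[q4, "os_event"].sum() == 0:
        raise ValueError("no events in Q1 ∪ Q4; log-rank undefined")
    lr = logrank_test(
        sub.loc[q4, "os_time"], sub.loc[q1, "os_time"],
        sub.loc[q4, "os_event"], sub.loc[q1, "os_event"],
    )
    sub["q4"] = (sub["quartile"] == 4).astype(float)
    cph, row = _fit_cox(sub[["q4", "age", "sex", "os_time", "os_event"]], "q4")
    km = pd.concat(
        [
            _km_table(sub.loc[q1, "os_time"], sub.loc[q1, "os_event"], "Q1"),
            _km_table(sub.loc[q4, "os_time"], sub.loc[q4, "os_event"], "Q4"),
        ],
        ignore_index=True,
    )
    return CoxResult(
        term="Q4_vs_Q1",
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p_wald=float(row["p"]),
        logrank_p=float(lr.p_value),
        n=len(sub),
        n_events=int(sub["os_event"].sum()),
        km=km,
    )


def per_gene_median_split(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    adjust: bool = False,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene KM/log-rank at the cohort-median expression split, BH across genes.

    High = expression > median, Low = expression ≤ median (values exactly
    at the median go Low).  The per-gene Cox HR (High vs Low) is
    unadjusted by default; ``adjust=True`` adds age and sex.  Genes with
    constant expression are skipped and listed in ``result.attrs["skipped"]``.
    """
    samples = [s for s in expression.columns if s in survival.index]
    surv = survival.loc[samples]
    _check_survival(surv)
    records, skipped = [], []
    for gene in expression.index:
        x = expression.loc[gene, samples].astype(float)
        med = x.median()
        high = x > med
        if high.sum() == 0 or (~high).sum() == 0:
            skipped.append((gene, "constant_expression"))
            continue
        lr = logrank_test(
            surv.loc[high.values, "os_time"], surv.loc[~high.values, "os_time"],
            surv.loc[high.values, "os_event"], surv.loc[~high.values, "os_event"],
        )
        df = surv[["os_time", "os_event"]].copy()
        df["high"] = high.values.astype(float)
        if adjust:
            if covariates is None:
                raise ValueError("adjust=True requires covariates")
            df = df.join(covariates.loc[samples])
        try:
            _, row = _fit_cox(df, "high")
            hr, lo, hi, pw = (
                float(row["exp(coef)"]),
                float(row["exp(coef) lower 95%"]),
                float(row["exp(coef) upper 95%"]),
                float(row["p"]),
            )
        except RuntimeError:
            hr = lo = hi = pw = float("nan")
        records.append((gene, hr, lo, hi, pw, float(lr.p_value)))
    out = pd.DataFrame(
        records, columns=["gene", "hr", "ci_low", "ci_high", "p_wald", "logrank_p"]
    )
    if not out.empty:
        out["fdr"] = multipletests(out["logrank_p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["fdr"] = pd.Series(dtype=float)
    out.attrs["skipped"] = skipped
    return out.sort_values("gene", ignore_index=True)


def subtype_association(
    score: pd.Series,
    subtype: pd.Series,
    min_per_group: int = 5,
) -> dict:
    """Kruskal–Wallis of the score across subtypes + BH pairwise rank-sum tests.

    Samples with missing subtype are excluded.  Returns the omnibus p,
    per-subtype medians, and the BH-adjusted pairwise comparisons.
    """
    df = pd.concat([score.rename("score"), subtype.rename("subtype")], axis=1).dropna()
    groups = sorted(df["subtype"].unique())
    sized = [g for g in groups if (df["subtype"] == g).sum() >= min_per_group]
    if len(sized) < 2:
        raise ValueError(f"need ≥2 subtypes with ≥{min_per_group} samples")
    samples = {g: df.loc[df["subtype"] == g, "score"].to_numpy() for g in sized}
    kw_stat, kw_p = stats.kruskal(*samples.values())
    pairs = []
    for i in range(len(sized)):
        for j in range(i + 1, len(sized)):
            a, b = sized[i], sized[j]
            p = float(stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided").pvalue)
            pairs.append((a, b, p))
    adj = multipletests([p for *_, p in pairs], method="fdr_bh")[1]
    return {
        "kruskal_stat": float(kw_stat),
        "kruskal_p": float(kw_p),
        "medians": {g: float(np.median(samples[g])) for g in sized},
        "pairwise": [
            {"a": a, "b": b, "p": p, "p_adj": float(q)} for (a, b, p), q in zip(pairs, adj)
        ],
    }
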