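"""Expression/methylation signature scores and methylation–expression coupling.

The promoter calls partition the panel into a hypomethylated (HYPO) and a
hypermethylated (HYPER) gene set.  On expression data these sets yield a
per-sample signature score

    ExprScore = mean(Z_HYPO) − mean(Z_HYPER)

where Z is the in-sample standardization of (log-scale) expression, and
on methylation data the complementary

    MethScore = mean(β_HYPER) − mean(β_HYPO).

Set-level coherence (HYPO expressed above HYPER within samples) is tested
with a paired Wilcoxon test; per-gene direction with one-sample Wilcoxon
tests on Z (BH-FDR, significance requiring the set's expected sign).
Per-gene coupling between promoter β and expression is Spearman's ρ with
BH-FDR and a |ρ| ≥ 0.30 effect-size flag; the a-priori expectation for a
repressive promoter mark is ρ < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .definitions import CALL_HYPER, CALL_HYPO

__all__ = [
    "in_sample_z",
    "expr_score",
    "meth_score",
    "build_score_table",
    "CoherenceResult",
    "coherence_tests",
    "meth_expr_coupling",
]

#: below this sample count Spearman p uses a seeded permutation test
_SPEARMAN_EXACT_N = 20


def in_sample_z(
    expression: pd.DataFrame,
    gene_universe=None,
) -> tuple[pd.DataFrame, list[str]]:
    """Standardize expression within each sample (column) over a gene universe.

    Z = (x − mean)/sd per column, computed across the ``gene_universe``
    rows (default: all genes).  Returns ``(Z, flagged)`` where
    ``flagged`` lists samples with zero within-sample variance (their Z
    column is NaN).
    """
    if gene_universe is not None:
        genes = [g for g in gene_universe if g in expression.index]
        expression = expression.loc[genes]
    if expression.shape[0] < 2:
        raise ValueError("in-sample Z needs ≥2 genes in the universe")
    x = expression.to_numpy(dtype=float)
    mean = np.nanmean(x, axis=0, keepdims=True)
    sd = np.nanstd(x, axis=0, ddof=1, keepdims=True)
    flagged = [s for s, ok in zip(expression.columns, (sd[0] > 0)) if not ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / np.where(sd > 0, sd, np.nan)
    return pd.DataFrame(z, index=expression.index, columns=expression.columns), flagged


def _set_means(z: pd.DataFrame, gene_set, label: str) -> pd.Series:
    present = [g for g in gene_set if g in z.index]
    if not present:
        raise ValueError(f"{label} set empty after intersecting with available genes")
    return z.loc[present].mean(axis=0)


def expr_score(z: pd.DataFrame, hypo_set, hyper_set) -> pd.Series:
    """ExprScore = mean(Z over HYPO set) − mean(Z over HYPER set), per sample."""
    score = _set_means(z, hypo_set, CALL_HYPO) - _set_means(z, hyper_set, CALL_HYPER)
    return score.rename("expr_score")


def meth_score(promoter_beta: pd.DataFrame, hyper_set, hypo_set) -> pd.Series:
    """MethScore = mean(promoter β over HYPER set) − mean(over HYPO set)."""
    score = _set_means(promoter_beta, hyper_set, CALL_HYPER) - _set_means(
        promoter_beta, hypo_set, CALL_HYPO
    )
    return score.rename("meth_score")


def build_score_table(
    expression: pd.DataFrame,
    hypo_set,
    hyper_set,
    covariates: pd.DataFrame | None = None,
    promoter_beta: pd.DataFrame | None = None,
    z_universe=None,
) -> pd.DataFrame:
    """Assemble the per-sample score table (ExprScore, quartile, covariates).

    Quartiles 1–4 are assigned by ExprScore with linear-interpolation
    quantile cut points and boundary ties to the lower quartile.  When a
    promoter β summary is supplied, MethScore is added for the samples
    covered by both platforms.
    """
    z, _ = in_sample_z(expression, z_universe)
    table = expr_score(z, hypo_set, hyper_set).to_frame()
    cuts = np.quantile(table["expr_score"].dropna(), [0.25, 0.5, 0.75])
    table["quartile"] = 1 + np.sum(
        table["expr_score"].to_numpy()[:, None] > cuts[None, :], axis=1
    )
    if promoter_beta is not None:
        ms = meth_score(promoter_beta, hyper_set, hypo_set)
        table = table.join(ms, how="left")
    if covariates is not None:
        table = table.join(covariates, how="left")
    table.index.name = "sample_id"
    return table


@dataclass
class CoherenceResult:
    """Set-level and per-gene coherence of expression with the promoter calls."""

    paired_p: float
    pseudo_median: float  # Hodges–Lehmann estimate of the per-sample set difference
    per_gene: pd.DataFrame  # gene, set, shift, p, fdr, significant_expected_direction


def _hodges_lehmann(x: np.ndarray) -> float:
    """Median of the Walsh averages (x_i + x_j)/2, i ≤ j."""
    i, j = np.triu_indices(len(x))
    return float(np.median((x[i] + x[j]) / 2.0))


def coherence_tests(z: pd.DataFrame, hypo_set, hyper_set) -> CoherenceResult:
    """Test that HYPO genes are expressed above HYPER genes, set- and gene-level.

    Paired Wilcoxon on the per-sample difference mean(Z_HYPO) −
    mean(Z_HYPER), with its Hodges–Lehmann pseudo-median; per-gene
    two-sided one-sample Wilcoxon of the gene's Z across samples against
    0, BH across genes, a gene counting as coherent only when FDR < 0.05
    *and* the shift sign matches its set (HYPO > 0, HYPER < 0).
    """
    if z.shape[1] < 10:
        raise ValueError("coherence tests need ≥10 samples")
    diff = (
        (_set_means(z, hypo_set, CALL_HYPO) - _set_means(z, hyper_set, CALL_HYPER))
        .dropna()
        .to_numpy()
    )
    paired_p = float(stats.wilcoxon(diff, zero_method="wilcox").pvalue)
    records = []
    for gene_set, label, sign in ((hypo_set, CALL_HYPO, 1.0), (hyper_set, CALL_HYPER, -1.0)):
        for gene in sorted(set(gene_set) & set(z.index)):
            vals = z.loc[gene].dropna().to_numpy(dtype=float)
            vals = vals[vals != 0.0]
            shift = _hodges_lehmann(vals) if vals.size else 0.0
            p = float(stats.wilcoxon(vals, zero_method="wilcox").pvalue) if vals.size else 1.0
            records.append((gene, label, shift, p, sign))
    per_gene = pd.DataFrame(records, columns=["gene", "set", "shift", "p", "_sign"])
    per_gene["fdr"] = multipletests(per_gene["p"].to_numpy(), method="fdr_bh")[1]
    per_gene["significant_expected_direction"] = (per_gene["fdr"] < 0.05) & (
        np.sign(per_gene["shift"]) == per_gene["_sign"]
    )
    per_gene = per_gene.drop(columns="_sign")
    return CoherenceResult(
        paired_p=paired_p,
        pseudo_median=_hodges_lehmann(diff),
        per_gene=per_gene,
    )


def _spearman(beta: np.ndarray, expr: np.ndarray, seed: int = 0) -> tuple[float, float]:
    n = len(beta)
    if n > _SPEARMAN_EXACT_N:
        res = stats.spearmanr(beta, expr)
        return float(res.statistic), float(res.pvalue)
    # small n: t-approximation is unreliable → seeded Monte-Carlo permutation
    rho = float(stats.spearmanr(beta, expr).statistic)
    rng = np.random.default_rng(seed)
    ranks_b = stats.rankdata(beta)
    ranks_e = stats.rankdata(expr)
    count = 0
    n_perm = 9999
    for _ in range(n_perm):
        r = float(np.corrcoef(ranks_b, rng.permutation(ranks_e))[0, 1])
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    return rho, (count + 1) / (n_perm + 1)


def meth_expr_coupling(
    promoter_beta: pd.DataFrame,
    expression: pd.DataFrame,
    genes=None,
    effect_threshold: float = 0.30,
) -> pd.DataFrame:
    """Spearman coupling of promoter β with expression, per gene.

    Samples are matched by id across the two platforms (≥10 required).
    Genes lacking promoter coverage (absent or all-NaN β) are skipped
    with a logged reason.  Two-sided p with mid-rank ties; BH across
    tested genes; ``effect_flag`` marks |ρ| ≥ ``effect_threshold``.
    """
    samples = [s for s in promoter_beta.columns if s in expression.columns]
    if len(samples) < 10:
        raise ValueError(f"need ≥10 matched samples, found {len(samples)}")
    if genes is None:
        genes = sorted(set(promoter_beta.index) & set(expression.index))
    records, skipped = [], []
    for gene in genes:
        if gene not in promoter_beta.index or gene not in expression.index:
            skipped.append((gene, "missing_on_platform"))
            continue
        b = promoter_beta.loc[gene, samples].to_numpy(dtype=float)
        e = expression.loc[gene, samples].to_numpy(dtype=float)
        ok = np.isfinite(b) & np.isfinite(e)
        if ok.sum() < 10:
            skipped.append((gene, "insufficient_promoter_coverage"))
            continue
        rho, p = _spearman(b[ok], e[ok])
        records.append((gene, int(ok.sum()), rho, p))
    out = pd.DataFrame(records, columns=["gene", "n", "rho", "p"])
    if not out.empty:
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["effect_flag"] = out["rho"].abs() >= effect_threshold
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["effect_flag"] = pd.Series(dtype=bool)
    out.attrs["skipped"] = skipped
    return out.sort_values("gene", ignore_index=True)
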