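# gliopanel

Promoter-methylation panel analysis for longitudinal tumor cohorts, built
around the workflow used to study gliogenesis gene promoters in
*IDH*-wildtype glioblastoma: Illumina-style β values are summarized to
gene promoters, genes are called hypo- or hypermethylated per disease
stage, methylation dynamics are tracked across recurrences, and the
resulting gene sets are carried into expression, enrichment, and survival
analyses.  A synthetic-cohort generator with planted ground truth makes
the entire pipeline testable end to end without access to patient data.

It is aimed at computational biologists analyzing EPIC/450K array data
who want the panel-calling and integration logic as a tested, scriptable
library rather than a collection of one-off analysis scripts.

## The method

**Promoter summarization.** Probes annotated TSS1500, TSS200, 5′UTR or
1stExon define a gene's promoter; genes with ≥2 promoter probes form the
inference-ready panel; promoter methylation per gene × sample is the
median β over those probes.

**Stage calling.** Per gene and stage, per-patient promoter β is tested
against the hemi-methylated reference with a one-sample Wilcoxon
signed-rank test (BH-FDR across genes), and

- HYPO: β_median ≤ 0.30, FDR < 0.05, |Δβ| ≥ 0.20
- HYPER: β_median ≥ 0.70, FDR < 0.05, |Δβ| ≥ 0.20

with Δβ = β_median − 0.50; everything else is NS.  Cross-stage presence
matrices, leave-one-patient-out (LOPO) retention, and subregion
concordance quantify stability of the calls.

**Longitudinal dynamics.** Per patient, HYPO/HYPER counts ("burden") are
clustered into Low/Mid/High groups (k-means, silhouette-supported k);
adjacent-stage changes Δβ ≤ −0.20 / ≥ +0.20 are HypoGain/HyperGain
events, with exact binomial tests for per-gene gain imbalance.

**M-scale models.** β is mapped to M = log₂((β+ε)/(1−β+ε)); per-gene
linear mixed models (ordinal stage fixed effect, patient random
intercept) estimate recurrence trends, and a threshold (minimum effect
size) test at τ = |log₂(0.7/0.3)| mirrors the |Δβ| ≥ 0.20 gate on the M
scale.  Cohen's κ quantifies agreement between β-gate and model-based
calls.

**Integration and prognosis.** With HYPO/HYPER sets in hand:
ExprScore = mean(Z_HYPO) − mean(Z_HYPER) on in-sample-standardized
expression and MethScore = mean(β_HYPER) − mean(β_HYPO); Spearman ρ per
gene measures methylation–expression coupling (FDR < 0.05, |ρ| ≥ 0.30);
Cox models (per-SD and quartile Q4 vs Q1, age/sex-adjusted), per-gene
median-split KM/log-rank with BH, and subtype Kruskal–Wallis tests cover
the prognostic layer.  A local hypergeometric ORA runs called gene sets
against any GMT collection with a configurable background.

## Worked example

```python
from gliopanel import CohortConfig, call_stage, lopo_stability
from gliopanel.synthetic_cohort import generate_manifest, generate_beta
from gliopanel.promoter_panel import map_promoter_probes, derive_panel, summarize_promoter
from gliopanel.mscale_models import model_stage_calls, calling_agreement

config = CohortConfig(n_patients=80, seed=1)          # 60 genes, classes 0.15/0.85/0.50
manifest = generate_manifest(config)
beta, metadata, truth = generate_beta(config, manifest)

mapping = map_promoter_probes(manifest)
summary = summarize_promoter(beta, mapping, derive_panel(mapping).panel)
calls = call_stage(summary, metadata, "Primary")
print(calls["call"].value_counts().to_dict())
# {'HYPO': 32, 'NS': 19, 'HYPER': 9}

print(calls.head(3).round(4).to_string(index=False))
#  gene   stage  n  beta_median  delta_beta      p reason    fdr call
# G0001 Primary 80       0.1478     -0.3522 0.0000        0.0000 HYPO
# G0002 Primary 80       0.4963     -0.0037 0.8161        0.9416   NS
# G0003 Primary 80       0.1533     -0.3467 0.0000        0.0000 HYPO

m_calls = model_stage_calls(summary, metadata, "Primary")
kappa = calling_agreement(calls["call"].to_numpy(),
                          m_calls.set_index("gene").loc[calls["gene"], "call"].to_numpy())
print(kappa)                                  # 1.0

lopo = lopo_stability(summary, metadata, "Primary")
print(lopo["retention"].median(), len(lopo))  # 1.0 41
```

The 41 stage-significant calls (32 HYPO + 9 HYPER) recover the planted
gene classes exactly; on this well-separated cohort the β-gate and
M-scale model decisions agree perfectly (κ = 1.0), and every call
survives leave-one-patient-out re-calling (median retention 1.0).

The same pipeline is available from the shell:

```bash
gliopanel simulate --out sim --seed 3
gliopanel panel --manifest sim/manifest.tsv --beta sim/beta.tsv --out panel
gliopanel call --summary panel/promoter_summary.tsv --meta sim/metadata.tsv --out calls
gliopanel longitudinal --summary panel/promoter_summary.tsv --meta sim/metadata.tsv --out long
```

See `gliopanel --help` for the `trend`, `ora`, `scores`, `coupling`, and
`survival` subcommands.

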