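"""Synthetic longitudinal methylation cohort with known ground truth.

Emulates the data structure of a longitudinal IDH-wildtype glioblastoma
methylation study: an array-style probe manifest, a probes × samples β
matrix over primary and recurrent tumor stages with patient-level
structure, methylation-coupled expression, and survival times whose
hazard depends on a supplied score.  Every quantity a downstream module
estimates is planted here explicitly (gene classes, step events,
coupling coefficients, the true hazard ratio), so recovery can be tested
without external data.

Per-probe β values are Beta-distributed around the gene-class promoter
mean (HYPO ≈ 0.15, HYPER ≈ 0.85, NS ≈ 0.50 by default; gene-body probes
around 0.50) with a concentration parameter controlling array-like
spread.  A per-patient random intercept is applied on the M (log2-odds)
scale and back-transformed, keeping β bounded.  Injected events add a
±`event_magnitude` β step to one (patient, gene) promoter mean from a
given stage transition onward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .definitions import CALL_HYPER, CALL_HYPO, CALL_NS, STAGES, TRANSITIONS, TRANSITION_LABELS
from .mscale_models import beta_to_m, m_to_beta
from .promoter_panel import PromoterSummary

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "generate_manifest",
    "generate_beta",
    "generate_expression",
    "generate_survival",
    "write_cohort",
]

_CLASSES = (CALL_HYPO, CALL_HYPER, CALL_NS)
_PROMOTER_CHOICES = ("TSS1500", "TSS200", "5UTR", "1stExon")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the motivating cohort shape: ~106 patients, every
    patient with a primary tumor, about half with a first recurrence,
    ~18% with a second and two patients with a third; gene classes
    centered at β 0.15 (HYPO), 0.85 (HYPER) and 0.50 (NS) in roughly the
    54/15/31% mix a gliogenesis promoter panel showed.
    """

    n_genes: int = 60
    probes_per_gene_range: tuple[int, int] = (2, 6)
    n_low_coverage_genes: int = 0  # genes forced to <2 promoter probes
    n_patients: int = 106
    #: fraction of patients carrying each stage (nested: Recur2 ⊆ Recur1 ⊆ Primary)
    stage_design: dict = field(
        default_factory=lambda: {"Primary": 1.0, "Recur1": 0.5, "Recur2": 0.18, "Recur3": 0.019}
    )
    class_proportions: dict = field(
        default_factory=lambda: {CALL_HYPO: 0.54, CALL_HYPER: 0.15, CALL_NS: 0.31}
    )
    class_beta_means: dict = field(
        default_factory=lambda: {CALL_HYPO: 0.15, CALL_HYPER: 0.85, CALL_NS: 0.50}
    )
    beta_concentration: float = 50.0
    patient_effect_sd: float = 0.15  # SD of the per-patient intercept, M (log2-odds) scale
    event_rate: float = 0.05  # P(injected Δβ step) per (patient, gene, transition)
    event_magnitude: float = 0.30  # β step size
    coupling_coefficient: float = 1.0  # expression units per −M for coupled genes
    coupling_fraction: float = 0.33
    expr_noise_sd: float = 0.5
    expr_baseline_mean: float = 6.0
    expr_baseline_sd: float = 1.5
    hr_per_sd: float = 0.87  # true hazard ratio per SD of the score
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.probes_per_gene_range
        if lo > hi:
            raise ValueError(f"probes_per_gene_range min > max: {self.probes_per_gene_range}")
        if lo < 1 or self.n_genes < 1 or self.n_patients < 1:
            raise ValueError("all counts must be ≥ 1")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-12:
            raise ValueError("class_proportions must sum to 1")
        for cls, mean in self.class_beta_means.items():
            if not 0.0 < mean < 1.0:
                raise ValueError(f"class mean for {cls} must lie in (0,1), got {mean}")
        if not 0.0 < self.event_magnitude <= 0.5:
            raise ValueError("event_magnitude must lie in (0, 0.5]")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be positive")
        if self.n_low_coverage_genes >= self.n_genes:
            raise ValueError("n_low_coverage_genes must be < n_genes")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    gene_class: dict[str, str]
    #: (patient, gene, transition label, direction ±1)
    injected_events: list[tuple[str, str, str, int]]
    coupled_genes: dict[str, float]
    true_hr: float

    def to_json(self) -> str:
        d = asdict(self)
        d["injected_events"] = [list(e) for e in self.injected_events]
        return json.dumps(d, indent=1)


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([config.seed, stream])


def generate_manifest(config: CohortConfig) -> pd.DataFrame:
    """Synthetic probe manifest: probe_id, gene, region.

    Each gene draws its probe count uniformly from
    ``probes_per_gene_range``; probes are annotated to promoter regions
    with occasional extra gene-body probes.  The first
    ``n_low_coverage_genes`` genes (chosen at random) are forced to a
    single promoter probe so the ≥2-probe panel gate has planted
    failures.
    """
    rng = _rng(config, 0)
    lo, hi = config.probes_per_gene_range
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    low_cov = set(rng.choice(genes, size=config.n_low_coverage_genes, replace=False))
    rows = []
    counter = 1
    for gene in genes:
        n_probes = int(rng.integers(lo, hi + 1))
        if gene in low_cov:
            regions = ["Body"] * max(n_probes - 1, 1) + [str(rng.choice(_PROMOTER_CHOICES))]
        else:
            regions = [str(r) for r in rng.choice(_PROMOTER_CHOICES, size=n_probes)]
            for _ in range(int(rng.integers(0, 3))):
                regions.append("Body")
        for region in regions:
            rows.append((f"cg{counter:08d}", gene, region))
            counter += 1
    return pd.DataFrame(rows, columns=["probe_id", "gene", "region"])


def _assign_classes(config: CohortConfig, genes: list[str], rng) -> dict[str, str]:
    n = len(genes)
    counts = {c: int(round(config.class_proportions[c] * n)) for c in _CLASSES}
    counts[CALL_NS] += n - sum(counts.values())  # rounding remainder → NS
    labels = sum(([c] * counts[c] for c in _CLASSES), [])
    perm = rng.permutation(n)
    return {genes[i]: labels[k] for k, i in enumerate(perm)}


def _stage_sets(config: CohortConfig, patients: list[str], rng) -> dict[str, list[str]]:
    """Nested per-stage patient sets following the stage_design fractions."""
    sets: dict[str, list[str]] = {}
    prev = list(patients)
    for stage in STAGES:
        frac = config.stage_design.get(stage, 0.0)
        size = min(int(round(frac * len(patients))), len(prev))
        if size == 0:
            sets[stage] = []
            prev = []
            continue
        chosen = sorted(rng.choice(prev, size=size, replace=False))
        sets[stage] = chosen
        prev = chosen
    return sets


def generate_beta(
    config: CohortConfig, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """β matrix (probes × samples), sample metadata, and the planted truth.

    Sample ids are ``<patient>_<stage>``.  Metadata columns: sample_id,
    patient, stage, age (patient-level, Normal(60, 10) truncated to
    [18, 90]) and sex (1 = male, Bernoulli 0.6).
    """
    rng = _rng(config, 1)
    genes = sorted(manifest["gene"].unique())
    gene_class = _assign_classes(config, genes, rng)
    patients = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]
    stage_sets = _stage_sets(config, patients, rng)

    meta_rows = []
    age = np.clip(rng.normal(60.0, 10.0, size=len(patients)), 18.0, 90.0)
    sex = (rng.random(len(patients)) < 0.6).astype(int)
    patient_attr = {p: (float(a), int(s)) for p, a, s in zip(patients, age, sex)}
    for stage in STAGES:
        for patient in stage_sets[stage]:
            a, s = patient_attr[patient]
            meta_rows.append((f"{patient}_{stage}", patient, stage, a, s))
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "patient", "stage", "age", "sex"])

    patient_u = {p: rng.normal(0.0, config.patient_effect_sd) for p in patients}

    # injected step events: per (patient, gene, available transition)
    events: list[tuple[str, str, str, int]] = []
    event_delta: dict[tuple[str, str], np.ndarray] = {}  # (patient, gene) → per-stage cum Δβ
    stage_idx = {s: i for i, s in enumerate(STAGES)}
    promoter_genes = [
        g for g in genes
        if (manifest.loc[manifest["gene"] == g, "region"] != "Body").sum() >= 2
    ]
    class_mean = {g: config.class_beta_means[gene_class[g]] for g in genes}
    for earlier, later in TRANSITIONS:
        label = TRANSITION_LABELS[(earlier, later)]
        both = set(stage_sets[earlier]) & set(stage_sets[later])
        for patient in sorted(both):
            hits = rng.random(len(promoter_genes)) < config.event_rate
            dirs = rng.choice([-1, 1], size=len(promoter_genes))
            for gene, hit, direction in zip(promoter_genes, hits, dirs):
                if not hit:
                    continue
                base = class_mean[gene]
                # flip a step that would leave (0.05, 0.95); keeps events recoverable
                if base + direction * config.event_magnitude > 0.95:
                    direction = -1
                elif base + direction * config.event_magnitude < 0.05:
                    direction = 1
                cum = event_delta.setdefault((patient, gene), np.zeros(len(STAGES)))
                cum[stage_idx[later]:] += direction * config.event_magnitude
                events.append((patient, gene, label, int(direction)))

    samples = metadata["sample_id"].tolist()
    sample_patient = metadata["patient"].to_numpy()
    sample_stage_idx = np.array([stage_idx[s] for s in metadata["stage"]])
    u_vec = np.array([patient_u[p] for p in sample_patient])

    c = config.beta_concentration
    blocks, probe_index = [], []
    for gene, sub in manifest.groupby("gene", sort=True):
        base = class_mean[gene]
        m_prom = beta_to_m(base) + u_vec  # promoter mean per sample, M scale
        mean_prom = np.asarray(m_to_beta(m_prom), dtype=float)
        deltas = np.array(
            [
                event_delta.get((p, gene), np.zeros(len(STAGES)))[si]
                for p, si in zip(sample_patient, sample_stage_idx)
            ]
        )
        mean_prom = np.clip(mean_prom + deltas, 0.02, 0.98)
        mean_body = np.clip(np.asarray(m_to_beta(u_vec), dtype=float), 0.02, 0.98)
        for probe, region in zip(sub["probe_id"], sub["region"]):
            mean = mean_body if region == "Body" else mean_prom
            blocks.append(rng.beta(mean * c, (1.0 - mean) * c))
            probe_index.append(probe)
    beta = pd.DataFrame(np.vstack(blocks), index=probe_index, columns=samples)
    beta = beta.loc[manifest["probe_id"]]  # manifest order
    beta.index.name = "probe_id"

    n_coupled = int(round(config.coupling_fraction * len(promoter_genes)))
    coupled = sorted(rng.choice(promoter_genes, size=n_coupled, replace=False))
    truth = SyntheticTruth(
        gene_class=gene_class,
        injected_events=events,
        coupled_genes={g: config.coupling_coefficient for g in coupled},
        true_hr=config.hr_per_sd,
    )
    return beta, metadata, truth


def generate_expression(
    truth: SyntheticTruth,
    beta_summary: PromoterSummary,
    config: CohortConfig,
) -> pd.DataFrame:
    """Log-scale expression matrix coupled to promoter methylation.

    For genes in ``truth.coupled_genes``, expression = baseline +
    coefficient·(−M(promoter β)) + Gaussian noise, so β and expression
    are negatively associated; other genes are independent of β.
    """
    rng = _rng(config, 2)
    values = beta_summary.values
    missing = [g for g in truth.coupled_genes if g not in values.index]
    if missing:
        raise ValueError(f"beta summary does not cover coupled genes: {missing}")
    genes = list(values.index)
    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=len(genes))
    noise = rng.normal(0.0, config.expr_noise_sd, size=values.shape)
    expr = np.tile(baseline[:, None], (1, values.shape[1])) + noise
    m = beta_to_m(np.nan_to_num(values.to_numpy(), nan=0.5))
    for i, gene in enumerate(genes):
        coef = truth.coupled_genes.get(gene)
        if coef:
            expr[i] += coef * (-m[i])
    out = pd.DataFrame(expr, index=genes, columns=values.columns)
    out.index.name = "gene"
    return out


def generate_survival(
    scores: pd.DataFrame,
    config: CohortConfig,
    age_effect: float = 0.02,
    sex_effect: float = 0.1,
    baseline_median: float = 14.0,
) -> pd.DataFrame:
    """Exponential survival times whose log-hazard follows the score.

    ``scores`` needs columns ``score``, ``age``, ``sex`` (index: sample
    id).  log-hazard = ln(hr_per_sd)·z(score) + age_effect·(age − 60) +
    sex_effect·sex over a baseline with median ``baseline_median`` time
    units (months, by convention).  Censoring is an independent
    exponential clock calibrated so that roughly ``censoring_rate`` of
    subjects are censored; at rate 0 every subject has an event.
    """
    if config.hr_per_sd <= 0:
        raise ValueError("hr_per_sd must be positive")
    required = {"score", "age", "sex"}
    if missing := required - set(scores.columns):
        raise ValueError(f"scores table missing columns: {sorted(missing)}")
    if not np.isfinite(scores["score"]).all():
        raise ValueError("scores must be finite")
    rng = _rng(config, 3)
    z = (scores["score"] - scores["score"].mean()) / scores["score"].std(ddof=1)
    lp = (
        np.log(config.hr_per_sd) * z.to_numpy()
        + age_effect * (scores["age"].to_numpy() - 60.0)
        + sex_effect * scores["sex"].to_numpy()
    )
    lam0 = np.log(2.0) / baseline_median
    t_event = rng.exponential(1.0 / (lam0 * np.exp(lp)))
    cr = config.censoring_rate
    if cr > 0:
        lam_c = lam0 * cr / (1.0 - cr)
        t_cens = rng.exponential(1.0 / lam_c, size=len(t_event))
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        os_time = t_event
        os_event = np.ones(len(t_event), dtype=int)
    out = scores.copy()
    out["os_time"] = os_time
    out["os_event"] = os_event
    return out


def write_cohort(
    out_dir,
    manifest: pd.DataFrame,
    beta: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: SyntheticTruth,
    expression: pd.DataFrame | None = None,
    survival: pd.DataFrame | None = None,
) -> None:
    """Write the cohort as plain TSV files + a truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    beta.to_csv(out / "beta.tsv", sep="\t")
    metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    if expression is not None:
        expression.to_csv(out / "expression.tsv", sep="\t")
    if survival is not None:
        survival.to_csv(out / "survival.tsv", sep="\t")
    (out / "truth.json").write_text(truth.to_json())
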