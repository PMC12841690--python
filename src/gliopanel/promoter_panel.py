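"""Promoter probe mapping, panel derivation, and per-gene promoter summarization.

Promoters are defined purely from the array manifest annotation: a probe
belongs to a gene's promoter when its region label is one of TSS1500,
TSS200, 5UTR or 1stExon.  A gene enters the inference-ready panel when it
has at least ``min_probes`` promoter probes; its promoter methylation in a
sample is the median β across those probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .definitions import PROMOTER_REGIONS, REGION_VOCAB, normalize_region

__all__ = [
    "PanelReport",
    "PromoterSummary",
    "map_promoter_probes",
    "derive_panel",
    "summarize_promoter",
    "subregion_concordance",
]


def _validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    required = {"probe_id", "gene", "region"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest.empty:
        raise ValueError("manifest is empty")
    manifest = manifest.copy()
    manifest["region"] = manifest["region"].map(normalize_region)
    unknown = sorted(set(manifest["region"]) - REGION_VOCAB)
    if unknown:
        raise ValueError(f"unknown region labels in manifest: {unknown}")
    return manifest


def map_promoter_probes(
    manifest: pd.DataFrame,
    regions: Iterable[str] | None = None,
) -> dict[str, list[str]]:
    """Map each gene to its promoter probe set.

    Parameters
    ----------
    manifest
        Table with columns ``probe_id``, ``gene``, ``region``.  The 5'UTR
        label dialects (``5'UTR``, ``5′UTR``) are normalized to ``5UTR``.
    regions
        Region labels counted as promoter; defaults to
        TSS1500/TSS200/5UTR/1stExon.

    Returns
    -------
    dict mapping gene symbol to the list of its promoter probe ids (order
    of first appearance, de-duplicated).  Genes with zero promoter probes
    are absent.
    """
    manifest = _validate_manifest(manifest)
    if regions is None:
        regions = PROMOTER_REGIONS
    else:
        regions = {normalize_region(r) for r in regions}
        bad = sorted(regions - REGION_VOCAB)
        if bad:
            raise ValueError(f"regions not in vocabulary: {bad}")
    sub = manifest[manifest["region"].isin(regions)]
    mapping: dict[str, list[str]] = {}
    for gene, probe in zip(sub["gene"], sub["probe_id"]):
        probes = mapping.setdefault(gene, [])
        if probe not in probes:  # de-duplicate multi-category annotations
            probes.append(probe)
    return mapping


@dataclass(frozen=True)
class PanelReport:
    """Panel derivation bookkeeping.

    ``universe_size`` is the size of the full gene universe under study,
    ``represented_size`` the number of universe genes with at least one
    probe on the array (any region), ``panel`` the genes passing the
    promoter-probe gate.
    """

    panel: list[str]
    universe_size: int
    represented_size: int
    min_probes: int

    @property
    def panel_size(self) -> int:
        return len(self.panel)

    @property
    def pct_panel_of_universe(self) -> float:
        return 100.0 * self.panel_size / self.universe_size

    @property
    def pct_panel_of_represented(self) -> float:
        return 100.0 * self.panel_size / self.represented_size

    @property
    def pct_represented_of_universe(self) -> float:
        return 100.0 * self.represented_size / self.universe_size

    def describe(self) -> dict[str, float]:
        return {
            "universe_size": self.universe_size,
            "represented_size": self.represented_size,
            "panel_size": self.panel_size,
            "pct_panel_of_universe": round(self.pct_panel_of_universe, 1),
            "pct_panel_of_represented": round(self.pct_panel_of_represented, 1),
            "pct_represented_of_universe": round(self.pct_represented_of_universe, 1),
        }


def derive_panel(
    mapping: Mapping[str, list[str]],
    min_probes: int = 2,
    universe: Iterable[str] | int | None = None,
    represented: Iterable[str] | int | None = None,
) -> PanelReport:
    """Derive the inference-ready panel: genes with ≥ ``min_probes`` promoter probes.

    ``universe`` and ``represented`` supply the denominators for the
    bookkeeping percentages (gene collections or plain counts); both
    default to the mapped genes when omitted.
    """
    if min_probes < 1:
        raise ValueError(f"min_probes must be ≥ 1, got {min_probes}")
    panel = sorted(g for g, probes in mapping.items() if len(probes) >= min_probes)

    def _size(x, default: int) -> int:
        if x is None:
            return default
        if isinstance(x, int):
            return x
        return len(set(x))

    represented_size = _size(represented, len(mapping))
    universe_size = _size(universe, represented_size)
    return PanelReport(
        panel=panel,
        universe_size=universe_size,
        represented_size=represented_size,
        min_probes=min_probes,
    )


@dataclass
class PromoterSummary:
    """Per-gene × sample promoter methylation (median β over promoter probes)."""

    values: pd.DataFrame  # genes × samples, β in [0, 1] (NaN where uncovered)
    panel: list[str]
    probes_per_gene: pd.Series = field(repr=False)


def summarize_promoter(
    beta: pd.DataFrame,
    mapping: Mapping[str, list[str]],
    panel: Iterable[str] | None = None,
) -> PromoterSummary:
    """Summarize promoter methylation as the median β over promoter probes.

    ``beta`` is a probes × samples matrix.  Missing probe values are
    excluded from each per-sample median; a gene is NaN for a sample when
    all its probes are missing there.
    """
    if panel is None:
        panel = sorted(mapping)
    panel = list(panel)
    rows = {}
    counts = {}
    for gene in panel:
        probes = [p for p in mapping.get(gene, []) if p in beta.index]
        if not probes:
            raise ValueError(f"panel gene {gene!r} has no probes in the β matrix")
        block = beta.loc[probes].to_numpy(dtype=float)
        with np.errstate(all="ignore"):
            rows[gene] = np.nanmedian(block, axis=0)
        counts[gene] = len(probes)
    values = pd.DataFrame(rows, index=beta.columns).T
    values.index.name = "gene"
    return PromoterSummary(
        values=values,
        panel=panel,
        probes_per_gene=pd.Series(counts, name="n_probes"),
    )


def subregion_concordance(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    metadata: pd.DataFrame,
    stages: Iterable[str] | None = None,
    min_probes: int = 2,
    params=None,
):
    """Sensitivity analysis: re-run stage calling per promoter subregion.

    For each region bin (TSS1500, TSS200, 5UTR, 1stExon) the full
    per-gene summarization and stage-calling is repeated using only that
    bin's probes, and the resulting calls are compared with the combined
    promoter definition.  Concordance per bin is the fraction of
    (gene, stage) pairs whose bin call equals the combined call, over the
    pairs callable in both (a gene failing the probe gate in a bin is
    excluded from that bin's denominator).

    Returns a dict with per-bin call tables, per-bin concordance, the mean
    concordance over non-empty bins, and the list of skipped bins.
    """
    from .stage_calling import CallingParams, call_stage
    from .definitions import INFERENTIAL_STAGES

    if params is None:
        params = CallingParams()
    if stages is None:
        present = set(metadata["stage"])
        stages = [s for s in INFERENTIAL_STAGES if s in present]
    stages = list(stages)

    def _calls_for(mapping) -> dict[tuple[str, str], str]:
        report = derive_panel(mapping, min_probes=min_probes)
        if not report.panel:
            return {}
        summary = summarize_promoter(beta, mapping, report.panel)
        out = {}
        for stage in stages:
            calls = call_stage(summary, metadata, stage, params)
            for gene, call in zip(calls["gene"], calls["call"]):
                out[(gene, stage)] = call
        return out

    combined = _calls_for(map_promoter_probes(manifest))
    result = {"bins": {}, "concordance": {}, "skipped": []}
    for region in sorted(PROMOTER_REGIONS):
        mapping = map_promoter_probes(manifest, regions={region})
        bin_calls = _calls_for(mapping)
        if not bin_calls:
            result["skipped"].append(region)
            continue
        shared = [k for k in bin_calls if k in combined]
        if not shared:
            result["skipped"].append(region)
            continue
        agree = sum(bin_calls[k] == combined[k] for k in shared)
        result["bins"][region] = bin_calls
        result["concordance"][region] = agree / len(shared)
    vals = list(result["concordance"].values())
    result["mean_concordance"] = float(np.mean(vals)) if vals else float("nan")
    return result
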