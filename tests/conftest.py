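"""Shared fixtures: synthetic cohorts generated once per session."""

from types import SimpleNamespace

import pytest

from gliopanel.promoter_panel import derive_panel, map_promoter_probes, summarize_promoter
from gliopanel.synthetic_cohort import (
    CohortConfig,
    generate_beta,
    generate_expression,
    generate_manifest,
)


def make_cohort(config: CohortConfig) -> SimpleNamespace:
    manifest = generate_manifest(config)
    beta, metadata, truth = generate_beta(config, manifest)
    mapping = map_promoter_probes(manifest)
    report = derive_panel(mapping)
    summary = summarize_promoter(beta, mapping, report.panel)
    return SimpleNamespace(
        config=config,
        manifest=manifest,
        beta=beta,
        metadata=metadata,
        truth=truth,
        mapping=mapping,
        report=report,
        summary=summary,
    )


@pytest.fixture(scope="session")
def separated_cohort() -> SimpleNamespace:
    """Well-separated cohort: class β means 0.15/0.85/0.50, 80 primaries."""
    return make_cohort(CohortConfig(n_patients=80, seed=1))


@pytest.fixture(scope="session")
def cohort_expression(separated_cohort):
    """Methylation-coupled expression for the separated cohort."""
    c = separated_cohort
    return generate_expression(c.truth, c.summary, c.config)
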