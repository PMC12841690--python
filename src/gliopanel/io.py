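"""Plain-text readers for the pipeline's tabular inputs (TSV/CSV)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_manifest(path) -> pd.DataFrame:
    """Probe manifest with columns probe_id, gene, region."""
    return pd.read_csv(path, sep=_sep(path), dtype=str)


def read_matrix(path) -> pd.DataFrame:
    """Numeric matrix (probes or genes × samples); first column is the row id."""
    return pd.read_csv(path, sep=_sep(path), index_col=0)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata (sample_id, patient, stage, ...)."""
    return pd.read_csv(path, sep=_sep(path))


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
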