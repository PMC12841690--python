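"""Local over-representation analysis against user-supplied gene-set collections.

A query gene set (e.g. the union of stage-significant promoters) is
tested for enrichment in each term of a GMT collection with the
hypergeometric upper-tail test, against a configurable background
universe, with BH-FDR across terms.  Collections are inputs (GMT files);
nothing is bundled.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["read_gmt", "ora"]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into {term name: member genes}."""
    from gseapy.parser import read_gmt as _read_gmt

    return _read_gmt(str(path))


def ora(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    background: Iterable[str],
    min_size: int = 3,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each collection term.

    Each term is intersected with the background before testing; terms
    whose in-background size falls outside [min_size, max_size] (or is
    zero) are skipped.  With universe size N = |background|, term size m,
    query size n and overlap k, p = P(X ≥ k) under Hypergeom(N, m, n);
    BH across the tested terms.

    Raises if the query is not a subset of the background (offenders
    listed) — enrichment against a universe that does not contain the
    query is ill-posed.
    """
    query = set(query)
    background = set(background)
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query genes missing from background: {offenders}")
    n = len(query)
    big_n = len(background)
    records = []
    for term, members in collection.items():
        in_bg = set(members) & background
        m = len(in_bg)
        if m == 0 or m < min_size or m > max_size:
            continue
        overlap = sorted(query & in_bg)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, big_n, m, n))
        records.append((term, m, k, ",".join(overlap), p))
    out = pd.DataFrame(records, columns=["term", "size", "overlap", "genes", "p"])
    if not out.empty:
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["p", "term"], ignore_index=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out
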