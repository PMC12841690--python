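"""Shared vocabulary: disease stages, probe region annotations, call labels.

The pipeline operates on longitudinal tumor cohorts sampled at a primary
resection and up to three recurrences.  The third recurrence is carried
through descriptive operations only and is refused by inferential ones.
"""

from __future__ import annotations

STAGES: tuple[str, ...] = ("Primary", "Recur1", "Recur2", "Recur3")
INFERENTIAL_STAGES: tuple[str, ...] = ("Primary", "Recur1", "Recur2")

#: adjacent-stage transitions, in chronological order
TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("Primary", "Recur1"),
    ("Recur1", "Recur2"),
    ("Recur2", "Recur3"),
)

TRANSITION_LABELS: dict[tuple[str, str], str] = {
    ("Primary", "Recur1"): "P→R1",
    ("Recur1", "Recur2"): "R1→R2",
    ("Recur2", "Recur3"): "R2→R3",
}

#: Illumina-style region annotations counted as "promoter"
PROMOTER_REGIONS: frozenset[str] = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
REGION_VOCAB: frozenset[str] = PROMOTER_REGIONS | {"Body", "other"}

#: manifest dialects for the 5' UTR label, normalized on read
_REGION_ALIASES = {"5'UTR": "5UTR", "5′UTR": "5UTR"}

CALL_HYPO = "HYPO"
CALL_HYPER = "HYPER"
CALL_NS = "NS"
CALLS: tuple[str, ...] = (CALL_HYPO, CALL_HYPER, CALL_NS)

GAIN_HYPO = "HypoGain"
GAIN_HYPER = "HyperGain"
GAIN_STABLE = "Stable"


def normalize_region(region: str) -> str:
    """Map manifest region labels onto the closed vocabulary (5'UTR dialects)."""
    region = region.strip()
    return _REGION_ALIASES.get(region, region)


def stage_index(stage: str) -> int:
    try:
        return STAGES.index(stage)
    except ValueError:
        raise ValueError(f"unknown stage label {stage!r}; expected one of {STAGES}") from None
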