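"""Compact/expanded labels for disordered regions from the Flory exponent.

The apparent Flory scaling exponent nu relates intramolecular distances to
sequence separation in a disordered chain: low nu means a compact ensemble,
high nu a well-solvated, expanded one.  nu values come from an external
sequence-based predictor and are inputs here (TSV: accession, start, end,
nu).  Regions with at least 30 residues are labelled

* ``compact``  when nu <= 0.475,
* ``expanded`` when nu >  0.55,
* ``unlabeled`` otherwise (including every region shorter than 30 residues).

The thresholds correspond to the tails of the human disordered-region nu
distribution (roughly the 5% most compact and 32% most expanded).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .embeddings import SequenceRegion

logger = logging.getLogger(__name__)

COMPACT_MAX_NU = 0.475
EXPANDED_MIN_NU = 0.55  # exclusive
MIN_REGION_LENGTH = 30

COMPACT, EXPANDED, UNLABELED = "compact", "expanded", "unlabeled"

#: MobiDB-style feature keys for the two labels.
FEATURE_KEYS = {
    COMPACT: "prediction-compact-mobidb_lite",
    EXPANDED: "prediction-extended-mobidb_lite",
}


@dataclass(frozen=True)
class NuPrediction:
    region: SequenceRegion
    nu: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.nu):
            raise ValueError(f"non-finite nu for region {self.region.key}")
        if not (0.0 < self.nu < 1.0):
            raise ValueError(
                f"nu={self.nu} for region {self.region.key} outside (0, 1)"
            )
        if not (0.3 <= self.nu <= 0.8):
            logger.warning(
                "nu=%.3f for region %s outside the plausible [0.3, 0.8] band",
                self.nu,
                self.region.key,
            )


def label_region(pred: NuPrediction, min_length: int = MIN_REGION_LENGTH) -> str:
    """Apply the compaction rule to one region; boundary semantics are exact."""
    if pred.region.length < min_length:
        return UNLABELED
    if pred.nu <= COMPACT_MAX_NU:
        return COMPACT
    if pred.nu > EXPANDED_MIN_NU:
        return EXPANDED
    return UNLABELED


def label_table(
    preds: list[NuPrediction], min_length: int = MIN_REGION_LENGTH
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Label every region and summarise per-protein fractions.

    Returns the labelled table and a summary with the fraction of distinct
    proteins carrying at least one compact and at least one expanded region.
    """
    rows = []
    for pred in preds:
        rows.append(
            {
                "accession": pred.region.accession,
                "start": pred.region.start,
                "end": pred.region.end,
                "length": pred.region.length,
                "nu": pred.nu,
                "label": label_region(pred, min_length=min_length),
            }
        )
    table = pd.DataFrame(
        rows, columns=["accession", "start", "end", "length", "nu", "label"]
    )
    if table.empty:
        summary = {
            "n_proteins": 0,
            "fraction_compact_proteins": 0.0,
            "fraction_expanded_proteins": 0.0,
        }
        return table, summary
    proteins = table["accession"].unique()
    compact = table.loc[table["label"] == COMPACT, "accession"].unique()
    expanded = table.loc[table["label"] == EXPANDED, "accession"].unique()
    summary = {
        "n_proteins": int(proteins.size),
        "fraction_compact_proteins": compact.size / proteins.size,
        "fraction_expanded_proteins": expanded.size / proteins.size,
    }
    return table, summary


def read_nu_table(path) -> list[NuPrediction]:
    """Read a nu table TSV with columns accession, start, end, nu."""
    df = pd.read_csv(path, sep="\t")
    return [
        NuPrediction(
            SequenceRegion(str(r.accession), int(r.start), int(r.end)), float(r.nu)
        )
        for r in df.itertuples(index=False)
    ]


def write_labeled_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["nu"] = out["nu"].map(lambda x: f"{x:.6f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
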