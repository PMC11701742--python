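"""Per-residue consensus of disorder/binding tracks from multiple sources.

Each source emits a ternary call per residue: annotated (1), not annotated
(0), or no coverage (-1, written ``-`` in TSV).  Three consensus modes:

* ``merge``    — union: annotated wherever any source annotates;
* ``majority`` — annotated where >= 50% of the votes agree;
* ``strict``   — annotated where >= 90% of the votes agree.

By default the vote denominator counts only the sources *covering* the
residue, so a predictor with partial coverage is not read as a negative
vote; ``denominator="all"`` divides by the number of tracks instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embeddings import SequenceRegion

ANNOTATED, NOT_ANNOTATED, NO_COVERAGE = 1, 0, -1
_STATE_CHARS = {ANNOTATED: "1", NOT_ANNOTATED: "0", NO_COVERAGE: "-"}
_CHAR_STATES = {v: k for k, v in _STATE_CHARS.items()}
_STATE_NAMES = {ANNOTATED: "annotated", NOT_ANNOTATED: "not_annotated",
                NO_COVERAGE: "no_coverage"}
_NAME_STATES = {v: k for k, v in _STATE_NAMES.items()}


@dataclass
class DisorderTrack:
    """Ternary per-residue calls from one source for one protein."""

    accession: str
    feature_key: str
    calls: np.ndarray  # int8 vector of {1, 0, -1}

    def __post_init__(self) -> None:
        if not self.feature_key:
            raise ValueError("feature_key must be nonempty")
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.ndim != 1:
            raise ValueError("calls must be a 1-D vector")
        if not np.isin(calls, [ANNOTATED, NOT_ANNOTATED, NO_COVERAGE]).all():
            raise ValueError("calls must be in {1, 0, -1}")
        self.calls = calls

    @property
    def length(self) -> int:
        return int(self.calls.size)


class VoteMatrix:
    """Stacked tracks for one protein with per-residue vote counts."""

    def __init__(self, accession: str, tracks: list[DisorderTrack]) -> None:
        if not tracks:
            raise ValueError("VoteMatrix needs at least one track")
        lengths = {t.length for t in tracks}
        if len(lengths) > 1:
            raise ValueError(
                f"{accession}: track length mismatch: {sorted(lengths)}"
            )
        self.accession = accession
        self.tracks = list(tracks)
        stack = np.vstack([t.calls for t in tracks])
        self.n_annotated = (stack == ANNOTATED).sum(axis=0)
        self.n_covered = (stack != NO_COVERAGE).sum(axis=0)

    @property
    def length(self) -> int:
        return int(self.n_annotated.size)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


@dataclass
class ConsensusConfig:
    mode: str = "majority"  # merge | majority | strict
    majority_threshold: float = 0.5
    strict_threshold: float = 0.9
    min_region_length: int = 1
    denominator: str = "covered"  # covered | all

    def __post_init__(self) -> None:
        if self.mode not in ("merge", "majority", "strict"):
            raise ValueError(f"unknown consensus mode {self.mode!r}")
        if not (0.0 < self.majority_threshold <= self.strict_threshold <= 1.0):
            raise ValueError("need 0 < majority_threshold <= strict_threshold <= 1")
        if self.denominator not in ("covered", "all"):
            raise ValueError("denominator must be 'covered' or 'all'")
        if self.min_region_length < 1:
            raise ValueError("min_region_length must be >= 1")


def consensus(votes: VoteMatrix, config: ConsensusConfig) -> DisorderTrack:
    """Collapse a vote matrix into one consensus track."""
    n_ann = votes.n_annotated.astype(np.float64)
    n_cov = votes.n_covered.astype(np.float64)
    denom = n_cov if config.denominator == "covered" else float(votes.n_tracks)

    if config.mode == "merge":
        annotated = n_ann >= 1
    else:
        thr = (
            config.majority_threshold
            if config.mode == "majority"
            else config.strict_threshold
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(denom > 0, n_ann / np.where(denom > 0, denom, 1), 0.0)
        annotated = (n_cov > 0) & (frac >= thr)

    calls = np.full(votes.length, NOT_ANNOTATED, dtype=np.int8)
    calls[annotated] = ANNOTATED
    calls[votes.n_covered == 0] = NO_COVERAGE

    if config.min_region_length > 1:
        for run_start, run_end in _runs(calls == ANNOTATED):
            if run_end - run_start < config.min_region_length:
                calls[run_start:run_end] = NOT_ANNOTATED
    return DisorderTrack(
        accession=votes.accession,
        feature_key=f"consensus-{config.mode}",
        calls=calls,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index pairs of maximal True runs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def extract_regions(track: DisorderTrack, min_length: int = 1) -> list[SequenceRegion]:
    """Maximal annotated runs of length >= min_length as 1-based regions."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    regions = []
    for start, end in _runs(track.calls == ANNOTATED):
        if end - start >= min_length:
            regions.append(SequenceRegion(track.accession, start + 1, end))
    return regions


def regions_to_track(
    accession: str,
    regions: list[SequenceRegion],
    length: int,
    feature_key: str = "regions",
) -> DisorderTrack:
    """Rasterise region intervals back into a binary track."""
    calls = np.zeros(length, dtype=np.int8)
    for region in regions:
        if region.end > length:
            raise ValueError(f"region {region.key} exceeds track length {length}")
        calls[region.start - 1 : region.end] = ANNOTATED
    return DisorderTrack(accession, feature_key, calls)


@dataclass
class ContentStat:
    fraction: float
    n_proteins: int
    n_annotated_residues: int = 0
    n_total_residues: int = 0


def content_fraction(tracks: list[DisorderTrack]) -> dict[str, ContentStat]:
    """Annotated-residue fraction per feature, over annotated proteins only.

    For each feature key, the fraction is total annotated residues divided by
    the total length of the proteins that carry at least one annotated
    residue for that feature; proteins with zero annotated residues are
    excluded from the denominator.
    """
    by_feature: dict[str, list[DisorderTrack]] = {}
    for track in tracks:
        by_feature.setdefault(track.feature_key, []).append(track)
    out: dict[str, ContentStat] = {}
    for feature, group in sorted(by_feature.items()):
        n_ann = 0
        n_tot = 0
        n_prot = 0
        for track in group:
            ann = int((track.calls == ANNOTATED).sum())
            if ann >= 1:
                n_ann += ann
                n_tot += track.length
                n_prot += 1
        out[feature] = ContentStat(
            fraction=(n_ann / n_tot) if n_tot else 0.0,
            n_proteins=n_prot,
            n_annotated_residues=n_ann,
            n_total_residues=n_tot,
        )
    return out


# -- I/O ---------------------------------------------------------------------
#
# TSV: accession, feature_key, calls as run-length encoding "<char>:<count>"
# joined by commas, e.g. "1:5,0:3,-:2".  JSON: MobiDB-style regions arrays.


def encode_calls(calls: np.ndarray) -> str:
    parts = []
    prev = None
    count = 0
    for v in calls:
        c = _STATE_CHARS[int(v)]
        if c == prev:
            count += 1
        else:
            if prev is not None:
                parts.append(f"{prev}:{count}")
            prev, count = c, 1
    if prev is not None:
        parts.append(f"{prev}:{count}")
    return ",".join(parts)


def decode_calls(text: str) -> np.ndarray:
    if not text:
        return np.zeros(0, dtype=np.int8)
    chunks = []
    for part in text.split(","):
        char, _, count = part.partition(":")
        chunks.append(np.full(int(count), _CHAR_STATES[char], dtype=np.int8))
    return np.concatenate(chunks)


def write_tracks_tsv(tracks: list[DisorderTrack], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("accession\tfeature_key\tcalls\n")
        for track in sorted(tracks, key=lambda t: (t.accession, t.feature_key)):
            fh.write(f"{track.accession}\t{track.feature_key}\t{encode_calls(track.calls)}\n")


def read_tracks_tsv(path) -> list[DisorderTrack]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        DisorderTrack(rec.accession, rec.feature_key, decode_calls(rec.calls))
        for rec in df.itertuples(index=False)
    ]


def track_to_json_obj(track: DisorderTrack, length_key: str = "length") -> dict:
    """MobiDB-style JSON object: regions as [start, end] pairs."""
    return {
        "accession": track.accession,
        "feature_key": track.feature_key,
        length_key: track.length,
        "regions": [[r.start, r.end] for r in extract_regions(track)],
        "no_coverage": [
            [s + 1, e] for s, e in _runs(track.calls == NO_COVERAGE)
        ],
    }


def track_from_json_obj(obj: dict) -> DisorderTrack:
    calls = np.zeros(int(obj["length"]), dtype=np.int8)
    for start, end in obj.get("no_coverage", []):
        calls[start - 1 : end] = NO_COVERAGE
    for start, end in obj.get("regions", []):
        calls[start - 1 : end] = ANNOTATED
    return DisorderTrack(obj["accession"], obj["feature_key"], calls)
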