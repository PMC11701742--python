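"""Synthetic fixtures with controlled statistical structure.

Every input the toolkit consumes can be generated here, so the full
pipeline runs with no downloads: random ontology DAGs, clustered region
embeddings with planted leaf-term annotations (emulating a curated
DisProt-style reference set), multi-source vote tracks with a known hidden
truth, and nu tables drawn from a mixture straddling the compaction
thresholds.

Determinism: every generator draws from a named substream of the single
fixture seed (``numpy`` ``SeedSequence`` spawn keys), so an identical
:class:`FixtureSpec` yields bit-identical fixtures on any platform.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import idranno.consensus as cns

from .compaction import NuPrediction
from .embeddings import (
    RegionEmbedding,
    ResidueEmbeddingMatrix,
    SequenceRegion,
    write_region_embeddings,
    write_residue_matrices,
)
from .evaluation import GoldStandard
from .ontology import Ontology, OntologyTerm, propagate_true_path, write_obo

_STAGE_IDS = {
    "ontology": 0,
    "embeddings": 1,
    "tracks": 2,
    "nu": 3,
    "sequences": 4,
}

_NS_CODES = {
    "molecular_function": "SMF",
    "biological_process": "SBP",
    "cellular_component": "SCC",
    "disorder_function": "SDF",
}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_IDS[stage], extra))
    )


@dataclass
class FixtureSpec:
    """All knobs of the fixture generators; identical spec => identical bytes.

    The defaults describe the reference study conditions: 16-dimensional
    embeddings, 20 planted leaf terms with 30 reference regions each and 200
    queries, cluster separation ten times the within-cluster spread, five
    vote tracks at 90% agreement, and a nu mixture whose compact-side /
    middle / expanded-side weights (2% / 53% / 45%) mirror the proteome-scale
    compact and expanded protein fractions.
    """

    seed: int = 0
    # ontology
    namespaces: tuple[str, ...] = ("molecular_function", "disorder_function")
    dag_depth: int = 4
    dag_branching: int = 3
    crosslink_prob: float = 0.1
    # embeddings / annotations
    n_terms: int = 20
    n_reference_regions: int = 600
    n_query_regions: int = 200
    dim: int = 16
    cluster_separation: float = 10.0
    noise_sd: float = 1.0
    region_length_range: tuple[int, int] = (30, 80)
    # tracks
    n_tracks: int = 5
    track_length: int = 200
    agreement: float = 0.9
    coverage_gap: float = 0.1
    track_disorder_prob: float = 0.4
    n_track_proteins: int = 20
    # nu table
    n_nu_regions: int = 5000
    nu_means: tuple[float, ...] = (0.42, 0.50, 0.60)
    nu_sds: tuple[float, ...] = (0.01, 0.01, 0.01)
    nu_weights: tuple[float, ...] = (0.02, 0.53, 0.45)
    nu_length_range: tuple[int, int] = (30, 150)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.nu_weights), 1.0):
            raise ValueError("nu mixture weights must sum to 1")
        if not (0.0 <= self.agreement <= 1.0):
            raise ValueError("agreement must be in [0, 1]")
        if self.dag_depth < 1 or self.dag_branching < 1:
            raise ValueError("dag depth and branching must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureSpec":
        data = json.loads(text)
        for key in (
            "namespaces",
            "region_length_range",
            "nu_means",
            "nu_sds",
            "nu_weights",
            "nu_length_range",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# -- ontology ----------------------------------------------------------------


def make_ontology(spec: FixtureSpec) -> Ontology:
    """A rooted random DAG per namespace: a complete tree plus cross-links.

    Level l holds ``branching**l`` terms; each non-root term gets one tree
    parent and, with probability ``crosslink_prob``, one extra parent from a
    strictly shallower level (acyclicity preserved by construction).
    """
    rng = _rng(spec.seed, "ontology")
    terms: dict[str, OntologyTerm] = {}
    for ns in spec.namespaces:
        code = _NS_CODES[ns]
        levels: list[list[str]] = []
        counter = 0
        for depth in range(spec.dag_depth):
            width = spec.dag_branching**depth
            level = []
            for _ in range(width):
                counter += 1
                level.append(f"{code}:{counter:07d}")
            levels.append(level)
        for depth, level in enumerate(levels):
            for j, term_id in enumerate(level):
                parents: set[str] = set()
                if depth > 0:
                    parents.add(levels[depth - 1][j // spec.dag_branching])
                    if depth >= 1 and rng.random() < spec.crosslink_prob:
                        shallow = int(rng.integers(0, depth))
                        cand = levels[shallow][
                            int(rng.integers(0, len(levels[shallow])))
                        ]
                        if cand not in parents:
                            parents.add(cand)
                terms[term_id] = OntologyTerm(
                    id=term_id,
                    name=f"synthetic {ns} term {term_id}",
                    namespace=ns,
                    parents=frozenset(parents),
                )
    return Ontology(terms)


def leaf_terms(ontology: Ontology, namespace: str) -> list[str]:
    """Terms of the namespace with no children, sorted."""
    has_child: set[str] = set()
    for term in ontology.terms.values():
        has_child.update(term.parents)
    return sorted(
        t.id
        for t in ontology.terms.values()
        if t.namespace == namespace and t.id not in has_child
    )


# -- annotated embeddings ----------------------------------------------------


@dataclass
class EmbeddingFixture:
    annotations: pd.DataFrame  # accession, start, end, term, namespace, evidence
    reference_embeddings: list[RegionEmbedding]
    query_embeddings: list[RegionEmbedding]
    gold: dict[str, GoldStandard]  # namespace -> gold standard for the queries
    planted_cluster: dict[tuple[str, int, int], int]  # region key -> cluster id
    centres: np.ndarray  # n_terms x dim
    residue_matrices: dict[str, ResidueEmbeddingMatrix] = field(default_factory=dict)


def make_annotated_embeddings(
    spec: FixtureSpec,
    ontology: Ontology,
    emit_matrices: bool = False,
) -> EmbeddingFixture:
    """Clustered region embeddings with planted leaf-term annotations.

    Each of ``n_terms`` clusters is assigned one leaf term per transfer
    namespace (paired across namespaces, so one embedding geometry serves
    both).  Cluster centres sit on random directions at distance
    ``cluster_separation * noise_sd`` from the origin; member embeddings add
    isotropic noise of scale ``noise_sd``.  Ground truth for a query is its
    planted leaf plus the true-path closure.

    With ``emit_matrices`` each region also gets a per-residue matrix whose
    row mean equals the region vector exactly, to exercise mean pooling
    end-to-end.
    """
    rng = _rng(spec.seed, "embeddings")
    planted_ns = [ns for ns in spec.namespaces if ns in
                  ("molecular_function", "disorder_function")]
    leaves_by_ns = {}
    for ns in planted_ns:
        leaves = leaf_terms(ontology, ns)
        if spec.n_terms > len(leaves):
            raise ValueError(
                f"n_terms={spec.n_terms} exceeds {len(leaves)} leaves in {ns}"
            )
        leaves_by_ns[ns] = [
            leaves[i]
            for i in rng.choice(len(leaves), size=spec.n_terms, replace=False)
        ]

    centres = rng.standard_normal((spec.n_terms, spec.dim))
    norms = np.linalg.norm(centres, axis=1, keepdims=True)
    centres = centres / norms * (spec.cluster_separation * spec.noise_sd)

    lo, hi = spec.region_length_range

    def draw_regions(prefix: str, n: int) -> tuple[list[RegionEmbedding], list[int]]:
        clusters = rng.integers(0, spec.n_terms, size=n)
        lengths = rng.integers(lo, hi + 1, size=n)
        out = []
        for i in range(n):
            acc = f"{prefix}{i+1:05d}"
            region = SequenceRegion(acc, 1, int(lengths[i]))
            vec = centres[clusters[i]] + spec.noise_sd * rng.standard_normal(spec.dim)
            out.append(RegionEmbedding(region, vec))
        return out, [int(c) for c in clusters]

    refs, ref_clusters = draw_regions("SYNREF", spec.n_reference_regions)
    queries, query_clusters = draw_regions("SYNQRY", spec.n_query_regions)

    ann_rows = []
    for emb, cluster in zip(refs, ref_clusters):
        for ns in planted_ns:
            ann_rows.append(
                {
                    "accession": emb.region.accession,
                    "start": emb.region.start,
                    "end": emb.region.end,
                    "term": leaves_by_ns[ns][cluster],
                    "namespace": ns,
                    "evidence": "synthetic",
                }
            )
    annotations = pd.DataFrame(
        ann_rows,
        columns=["accession", "start", "end", "term", "namespace", "evidence"],
    )

    gold = {}
    for ns in planted_ns:
        regions = {
            emb.region.key: frozenset(
                propagate_true_path({leaves_by_ns[ns][cluster]}, ontology)
            )
            for emb, cluster in zip(queries, query_clusters)
        }
        gold[ns] = GoldStandard(namespace=ns, regions=regions)

    planted = {
        emb.region.key: cluster
        for emb, cluster in zip(refs + queries, ref_clusters + query_clusters)
    }

    matrices: dict[str, ResidueEmbeddingMatrix] = {}
    if emit_matrices:
        for emb in refs + queries:
            length = emb.region.length
            deltas = rng.standard_normal((length, spec.dim)) * spec.noise_sd
            deltas -= deltas.mean(axis=0, keepdims=True)
            matrices[emb.region.accession] = ResidueEmbeddingMatrix(
                emb.region.accession, emb.vector[None, :] + deltas
            )

    return EmbeddingFixture(
        annotations=annotations,
        reference_embeddings=refs,
        query_embeddings=queries,
        gold=gold,
        planted_cluster=planted,
        centres=centres,
        residue_matrices=matrices,
    )


# -- tracks ------------------------------------------------------------------


def make_tracks(
    spec: FixtureSpec, accession: str = "SYNTRK00001", stream: int = 0
) -> tuple[list[cns.DisorderTrack], cns.DisorderTrack]:
    """Vote tracks around a hidden truth, with controlled agreement.

    A hidden binary track is sampled; each source copies it per residue with
    probability ``agreement`` and flips it otherwise, then masks coverage
    with probability ``coverage_gap``.  Returns (tracks, hidden truth).
    """
    rng = _rng(spec.seed, "tracks", stream)
    hidden = (rng.random(spec.track_length) < spec.track_disorder_prob).astype(
        np.int8
    )
    tracks = []
    for i in range(spec.n_tracks):
        agree = rng.random(spec.track_length) < spec.agreement
        calls = np.where(agree, hidden, 1 - hidden).astype(np.int8)
        masked = rng.random(spec.track_length) < spec.coverage_gap
        calls[masked] = cns.NO_COVERAGE
        tracks.append(
            cns.DisorderTrack(
                accession=accession,
                feature_key=f"prediction-disorder-src{i+1}",
                calls=calls,
            )
        )
    truth = cns.DisorderTrack(accession, "hidden-truth", hidden)
    return tracks, truth


def make_track_collection(
    spec: FixtureSpec,
) -> tuple[list[cns.DisorderTrack], list[cns.DisorderTrack]]:
    """Tracks for ``n_track_proteins`` proteins (flattened), plus truths."""
    all_tracks: list[cns.DisorderTrack] = []
    truths: list[cns.DisorderTrack] = []
    for p in range(spec.n_track_proteins):
        tracks, truth = make_tracks(
            spec, accession=f"SYNTRK{p+1:05d}", stream=p
        )
        all_tracks.extend(tracks)
        truths.append(truth)
    return all_tracks, truths


# -- nu table ----------------------------------------------------------------


def make_nu_table(spec: FixtureSpec) -> list[NuPrediction]:
    """nu values from a Gaussian mixture around the compaction thresholds."""
    rng = _rng(spec.seed, "nu")
    comps = rng.choice(len(spec.nu_weights), size=spec.n_nu_regions, p=spec.nu_weights)
    means = np.asarray(spec.nu_means)[comps]
    sds = np.asarray(spec.nu_sds)[comps]
    nus = np.clip(rng.normal(means, sds), 0.301, 0.799)
    lo, hi = spec.nu_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_nu_regions)
    preds = []
    for i in range(spec.n_nu_regions):
        region = SequenceRegion(f"SYNNU{i+1:06d}", 1, int(lengths[i]))
        preds.append(NuPrediction(region, float(nus[i])))
    return preds


# -- mock embedder -----------------------------------------------------------


class MockEmbedder:
    """Deterministic stand-in for a protein language model.

    Maps (accession, sequence) to an L x D matrix using a seed derived from
    the accession, so the same protein always embeds identically.  Synthetic:
    the geometry carries no biological signal.
    """

    def __init__(self, dim: int = 16, seed: int = 0) -> None:
        self.dim = dim
        self.seed = seed

    def embed(self, accession: str, sequence: str) -> ResidueEmbeddingMatrix:
        key = zlib.crc32(accession.encode("utf-8"))
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(9, key))
        )
        return ResidueEmbeddingMatrix(
            accession, rng.standard_normal((len(sequence), self.dim))
        )


# -- bundle writer -----------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def write_bundle(spec: FixtureSpec, outdir, emit_matrices: bool = False) -> dict:
    """Emit the full input bundle into a directory; returns the file map.

    Files: fixture spec JSON, OBO ontology, FASTA sequences, reference
    annotation TSV, reference/query region-embedding TSVs, gold TSV, tracks
    TSV, nu TSV (and residue-matrix TSVs when requested).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ontology = make_ontology(spec)
    fixture = make_annotated_embeddings(spec, ontology, emit_matrices=emit_matrices)
    tracks, truths = make_track_collection(spec)
    nu_preds = make_nu_table(spec)

    paths = {
        "spec": outdir / "fixture_spec.json",
        "ontology": outdir / "ontology.obo",
        "fasta": outdir / "sequences.fasta",
        "annotations": outdir / "reference_annotations.tsv",
        "reference_embeddings": outdir / "reference_embeddings.tsv",
        "query_embeddings": outdir / "query_embeddings.tsv",
        "gold": outdir / "gold_annotations.tsv",
        "tracks": outdir / "tracks.tsv",
        "nu": outdir / "nu_table.tsv",
    }

    paths["spec"].write_text(spec.to_json() + "\n", encoding="utf-8")
    write_obo(ontology, paths["ontology"])

    rng = _rng(spec.seed, "sequences")
    with open(paths["fasta"], "w", encoding="utf-8", newline="\n") as fh:
        for emb in fixture.reference_embeddings + fixture.query_embeddings:
            length = emb.region.end
            seq = "".join(
                _AA[j] for j in rng.integers(0, len(_AA), size=length)
            )
            fh.write(f">{emb.region.accession}\n{seq}\n")

    fixture.annotations.to_csv(
        paths["annotations"], sep="\t", index=False, lineterminator="\n"
    )
    write_region_embeddings(fixture.reference_embeddings, paths["reference_embeddings"])
    write_region_embeddings(fixture.query_embeddings, paths["query_embeddings"])

    gold_rows = []
    for ns, gold in sorted(fixture.gold.items()):
        for key in sorted(gold.regions):
            for term in sorted(gold.regions[key]):
                gold_rows.append(
                    {
                        "accession": key[0],
                        "start": key[1],
                        "end": key[2],
                        "term": term,
                        "namespace": ns,
                    }
                )
    pd.DataFrame(
        gold_rows, columns=["accession", "start", "end", "term", "namespace"]
    ).to_csv(paths["gold"], sep="\t", index=False, lineterminator="\n")

    cns.write_tracks_tsv(tracks + truths, paths["tracks"])

    with open(paths["nu"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("accession\tstart\tend\tnu\n")
        for pred in nu_preds:
            fh.write(
                f"{pred.region.accession}\t{pred.region.start}\t"
                f"{pred.region.end}\t{float(pred.nu)!r}\n"
            )

    if emit_matrices:
        matpath = outdir / "residue_matrices.tsv"
        write_residue_matrices(fixture.residue_matrices, matpath)
        paths["residue_matrices"] = matpath

    return {name: str(path) for name, path in paths.items()}
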