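"""Weighted K-nearest-neighbour transfer of function terms between regions.

Reference regions (curated, e.g. DisProt-style) carry GO Molecular Function
and IDPO Disorder Function terms.  A query region inherits terms from its
nearest annotated neighbours in embedding space:

1. cosine distances from the query to every reference region;
2. neighbours beyond the distance cutoff (default 0.8) are discarded;
3. the K nearest survivors vote, each with raw weight ``1 - d/cutoff``;
4. weights are normalised to sum to 1, so a term's score is the weighted
   fraction of neighbours annotated with it (a convex combination in [0,1]);
5. scores are made hierarchy-consistent (parent >= child);
6. terms below the per-namespace score threshold are dropped, and the broad
   binding terms (GO:0005488, GO:0005515) additionally face a stricter
   threshold to damp label imbalance.

Biological Process and Cellular Component terms are never transferred unless
explicitly overridden: those namespaces are imported, not predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import RegionEmbedding, SequenceRegion, cosine_distance
from .ontology import NAMESPACES, Ontology, enforce_hierarchy, propagate_true_path

logger = logging.getLogger(__name__)

#: Namespaces the transfer runs on by default.
TRANSFER_NAMESPACES = ("molecular_function", "disorder_function")


@dataclass
class TransferConfig:
    """Tunables of the transfer; defaults follow the published optimum."""

    distance_cutoff: float = 0.8
    k: dict[str, int] = field(
        default_factory=lambda: {"molecular_function": 10, "disorder_function": 5}
    )
    score_threshold: dict[str, float] = field(
        default_factory=lambda: {
            "molecular_function": 0.44,
            "disorder_function": 0.59,
        }
    )
    strict_terms: dict[str, float] = field(
        default_factory=lambda: {"GO:0005488": 0.9, "GO:0005515": 0.9}
    )
    allow_all_namespaces: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.distance_cutoff <= 2.0):
            raise ValueError("distance_cutoff must be in (0, 2]")
        for ns, kk in self.k.items():
            if kk < 1:
                raise ValueError(f"k for {ns} must be >= 1")
        for ns, tau in self.score_threshold.items():
            if not (0.0 <= tau <= 1.0):
                raise ValueError(f"score threshold for {ns} must be in [0, 1]")

    def k_for(self, namespace: str) -> int:
        return self.k.get(namespace, 10)

    def tau_for(self, namespace: str) -> float:
        return self.score_threshold.get(namespace, 0.0)


@dataclass(frozen=True)
class ReferenceEntry:
    region: SequenceRegion
    embedding: RegionEmbedding
    terms: dict[str, frozenset[str]]  # namespace -> term ids


class ReferenceIndex:
    """Annotated reference regions with embeddings, in stable key order."""

    def __init__(
        self, entries: list[ReferenceEntry], ontology: Ontology, propagated: bool
    ) -> None:
        self.entries = sorted(entries, key=lambda e: e.region.key)
        self.ontology = ontology
        self.build_config = {"propagated": propagated}
        dims = {e.embedding.vector.size for e in self.entries}
        if len(dims) > 1:
            raise ValueError(f"mixed embedding dimensions in index: {sorted(dims)}")
        self._vectors = (
            np.vstack([e.embedding.vector for e in self.entries])
            if self.entries
            else np.empty((0, 0))
        )
        norms = np.linalg.norm(self._vectors, axis=1) if self.entries else np.empty(0)
        if np.any(norms == 0.0):
            bad = [
                self.entries[i].region.key for i in np.nonzero(norms == 0.0)[0][:5]
            ]
            raise ValueError(f"zero-norm reference embeddings: {bad}")
        self._norms = norms
        # per-namespace positions of entries annotated in that namespace
        self._ns_rows: dict[str, np.ndarray] = {}
        for ns in NAMESPACES:
            rows = [i for i, e in enumerate(self.entries) if e.terms.get(ns)]
            self._ns_rows[ns] = np.asarray(rows, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.entries)

    def namespace_size(self, namespace: str) -> int:
        return int(self._ns_rows.get(namespace, np.empty(0)).size)

    def distances(self, query: RegionEmbedding, namespace: str) -> tuple[np.ndarray, np.ndarray]:
        """Cosine distances from a query to the namespace's entries.

        Returns ``(rows, dists)`` where ``rows`` are positions into
        :attr:`entries` in stable index order.
        """
        rows = self._ns_rows[namespace]
        q = np.asarray(query.vector, dtype=np.float64)
        qn = np.linalg.norm(q)
        if qn == 0.0:
            raise ValueError(
                f"query {query.region.key} has a zero-norm embedding"
            )
        sub = self._vectors[rows]
        dists = 1.0 - (sub @ q) / (self._norms[rows] * qn)
        return rows, dists


def build_index(
    annotations: pd.DataFrame,
    embeddings: list[RegionEmbedding],
    ontology: Ontology,
    propagate: bool = True,
) -> ReferenceIndex:
    """Group a region annotation table into a :class:`ReferenceIndex`.

    ``annotations`` needs columns accession, start, end, term, namespace
    (evidence is carried along if present but unused).  Every annotated
    region must have an embedding; terms are optionally replaced by their
    true-path closure (on by default, matching CAFA-style gold sets).
    """
    emb_by_key = {e.region.key: e for e in embeddings}
    grouped: dict[tuple[str, int, int], dict[str, set[str]]] = {}
    for rec in annotations.itertuples(index=False):
        key = (str(rec.accession), int(rec.start), int(rec.end))
        term = ontology.resolve(str(rec.term))
        ns = ontology.namespace_of(term)
        declared = getattr(rec, "namespace", None)
        if declared and str(declared) != ns:
            raise ValueError(
                f"term {term} declared as {declared} but belongs to {ns}"
            )
        grouped.setdefault(key, {}).setdefault(ns, set()).add(term)

    missing = sorted({k[0] for k in grouped if k not in emb_by_key})
    if missing:
        raise ValueError(
            f"annotated regions without embeddings for accessions: {missing[:10]}"
        )

    entries = []
    for key, by_ns in grouped.items():
        terms: dict[str, frozenset[str]] = {}
        for ns, ts in by_ns.items():
            if propagate:
                ts = propagate_true_path(ts, ontology)
            terms[ns] = frozenset(ts)
        entries.append(
            ReferenceEntry(
                region=emb_by_key[key].region,
                embedding=emb_by_key[key],
                terms=terms,
            )
        )
    return ReferenceIndex(entries, ontology, propagated=propagate)


@dataclass
class TermScoreMap:
    """Scored term predictions for one query region, with provenance."""

    query: SequenceRegion
    namespace: str
    scores: dict[str, float]
    neighbors_used: list[tuple[tuple[str, int, int], float, float]]  # key, dist, weight


def transfer(
    query: RegionEmbedding,
    index: ReferenceIndex,
    config: TransferConfig,
    namespace: str,
) -> TermScoreMap:
    """Score terms for one query region by distance-weighted KNN voting."""
    if namespace not in TRANSFER_NAMESPACES and not config.allow_all_namespaces:
        raise ValueError(
            f"transfer is not executed for namespace {namespace!r}; "
            "pass allow_all_namespaces=True to override"
        )
    if index.namespace_size(namespace) == 0:
        raise ValueError(f"reference index has no entries for {namespace!r}")

    rows, dists = index.distances(query, namespace)
    cutoff = config.distance_cutoff
    keep = dists <= cutoff
    if not np.any(keep):
        return TermScoreMap(query.region, namespace, {}, [])
    rows, dists = rows[keep], dists[keep]

    k = config.k_for(namespace)
    if rows.size > k:
        # stable sort on distance: ties at the k-th distance break by index order
        order = np.argsort(dists, kind="stable")[:k]
        rows, dists = rows[order], dists[order]
    else:
        order = np.argsort(dists, kind="stable")
        rows, dists = rows[order], dists[order]

    raw = 1.0 - dists / cutoff
    total = raw.sum()
    if total == 0.0:
        logger.warning(
            "query %s: all surviving neighbours sit exactly at the cutoff; "
            "returning no predictions",
            query.region.key,
        )
        return TermScoreMap(query.region, namespace, {}, [])
    weights = raw / total

    scores: dict[str, float] = {}
    for row, w in zip(rows, weights):
        for term in index.entries[row].terms.get(namespace, ()):
            scores[term] = scores.get(term, 0.0) + float(w)
    scores = enforce_hierarchy(scores, index.ontology)

    tau = config.tau_for(namespace)
    out = {}
    for term, score in scores.items():
        if score < tau:
            continue
        strict = config.strict_terms.get(term)
        if strict is not None and score < strict:
            continue
        out[term] = min(score, 1.0)

    provenance = [
        (index.entries[r].region.key, float(d), float(w))
        for r, d, w in zip(rows, dists, weights)
    ]
    return TermScoreMap(query.region, namespace, out, provenance)


def transfer_all(
    queries: list[RegionEmbedding],
    index: ReferenceIndex,
    config: TransferConfig,
    namespaces: tuple[str, ...] = TRANSFER_NAMESPACES,
) -> dict[str, list[TermScoreMap]]:
    """Apply :func:`transfer` to every query, per namespace, in input order."""
    return {
        ns: [transfer(q, index, config, ns) for q in queries] for ns in namespaces
    }


def predictions_to_table(results: dict[str, list[TermScoreMap]]) -> pd.DataFrame:
    """Flatten transfer output into a TSV-ready table."""
    rows = []
    for ns, maps in results.items():
        for tsm in maps:
            for term in sorted(tsm.scores):
                rows.append(
                    {
                        "accession": tsm.query.accession,
                        "start": tsm.query.start,
                        "end": tsm.query.end,
                        "term": term,
                        "namespace": ns,
                        "score": round(tsm.scores[term], 6),
                        "neighbors_used": len(tsm.neighbors_used),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "start",
            "end",
            "term",
            "namespace",
            "score",
            "neighbors_used",
        ],
    )
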