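"""GO/IDPO ontology handling: loading, ancestor closure, true-path propagation.

Only ``is_a`` edges define the hierarchy.  The true-path rule states that
annotation with a term implies annotation with every ancestor of that term;
namespace root terms (e.g. ``molecular_function`` itself) carry no information
and are excluded from propagated sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Namespaces recognised throughout the toolkit.
NAMESPACES = (
    "molecular_function",
    "biological_process",
    "cellular_component",
    "disorder_function",
)


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown terms."""


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology term with its ``is_a`` parents."""

    id: str
    name: str
    namespace: str
    parents: frozenset[str] = field(default_factory=frozenset)


class Ontology:
    """A DAG of terms partitioned into namespaces.

    Parameters
    ----------
    terms
        Mapping from term id to :class:`OntologyTerm`.  Every parent id must
        resolve within the mapping, the parent graph must be acyclic, and a
        term must share its namespace with all of its ancestors.
    alt_ids
        Optional mapping from alternative (merged) ids to primary ids.
    """

    def __init__(
        self,
        terms: dict[str, OntologyTerm],
        alt_ids: dict[str, str] | None = None,
    ) -> None:
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._validate()
        self.roots: dict[str, set[str]] = {}
        for term in self.terms.values():
            if not term.parents:
                self.roots.setdefault(term.namespace, set()).add(term.id)

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                if parent not in self.terms:
                    raise OntologyError(
                        f"term {term.id!r} has dangling is_a target {parent!r}"
                    )
                graph.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            child, parent = cycle[0][0], cycle[0][1]
            raise OntologyError(
                f"cycle detected in is_a graph (edge {child!r} is_a {parent!r})"
            )
        for term in self.terms.values():
            for parent in term.parents:
                pns = self.terms[parent].namespace
                if pns != term.namespace:
                    raise OntologyError(
                        f"term {term.id!r} ({term.namespace}) has parent "
                        f"{parent!r} in a different namespace ({pns})"
                    )

    # -- queries -------------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its primary id; primary ids pass through."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise OntologyError(f"unknown term {term_id!r}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def __len__(self) -> int:
        return len(self.terms)

    def namespace_of(self, term_id: str) -> str:
        return self.terms[self.resolve(term_id)].namespace

    def is_root(self, term_id: str) -> bool:
        term = self.terms[self.resolve(term_id)]
        return not term.parents

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable via ``is_a`` edges, excluding the term itself."""
        term_id = self.resolve(term_id)
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.terms[term_id].parents)
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            hit = self._ancestor_cache.get(cur)
            if hit is not None:
                out.update(hit)
            else:
                stack.extend(self.terms[cur].parents)
        result = frozenset(out)
        self._ancestor_cache[term_id] = result
        return result


def ancestors(ontology: Ontology, term_id: str) -> frozenset[str]:
    """Functional alias for :meth:`Ontology.ancestors`."""
    return ontology.ancestors(term_id)


def propagate_true_path(
    annotations: set[str] | frozenset[str], ontology: Ontology
) -> set[str]:
    """Close an annotation set under the true-path rule.

    Returns the annotations plus every ancestor of each annotation, with
    namespace root terms removed (they are uninformative for evaluation).
    Idempotent.
    """
    out: set[str] = set()
    for term_id in annotations:
        term_id = ontology.resolve(term_id)
        out.add(term_id)
        out.update(ontology.ancestors(term_id))
    return {t for t in out if not ontology.is_root(t)}


def enforce_hierarchy(
    scores: dict[str, float], ontology: Ontology
) -> dict[str, float]:
    """Make a term-score map hierarchy-consistent.

    Each term's output score is the maximum input score over the term itself
    and all of its scored descendants, so a parent never scores below a
    child.  Only terms present in ``scores`` appear in the output.
    """
    out = {ontology.resolve(t): float(s) for t, s in scores.items()}
    for term_id, score in list(out.items()):
        for anc in ontology.ancestors(term_id):
            if anc in out and out[anc] < score:
                out[anc] = score
    return out


def load_obo(path) -> Ontology:
    """Load an OBO 1.2/1.4 file into an :class:`Ontology`.

    Only ``[Term]`` stanzas and ``is_a`` relations are consulted.  Obsolete
    terms are dropped with a logged warning; ``alt_id`` entries are mapped to
    their primary id.  Missing ``namespace`` lines default to the namespace
    of the term's root (resolved after loading) or ``molecular_function``.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    raw: dict[str, dict] = {}
    alt_ids: dict[str, str] = {}
    n_obsolete = 0
    for node, data in graph.nodes(data=True):
        if data.get("is_obsolete") == "true":
            n_obsolete += 1
            continue
        raw[node] = data
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    if n_obsolete:
        logger.warning("dropped %d obsolete term(s)", n_obsolete)

    parents: dict[str, set[str]] = {}
    for node in raw:
        ps = set()
        # obonet encodes "child is_a parent" as edge child -> parent, key "is_a"
        for _, parent, key in graph.out_edges(node, keys=True):
            if key != "is_a":
                continue
            if parent not in raw:
                if parent in graph:  # obsolete parent: relink not attempted
                    continue
                raise OntologyError(
                    f"term {node!r} has dangling is_a target {parent!r}"
                )
            ps.add(parent)
        parents[node] = ps

    namespaces = _infer_namespaces(raw, parents)
    terms = {
        node: OntologyTerm(
            id=node,
            name=data.get("name", node),
            namespace=namespaces[node],
            parents=frozenset(parents[node]),
        )
        for node, data in raw.items()
    }
    return Ontology(terms, alt_ids=alt_ids)


def _infer_namespaces(
    raw: dict[str, dict], parents: dict[str, set[str]]
) -> dict[str, str]:
    """Fill missing namespace declarations from each term's root."""
    out: dict[str, str] = {}

    def resolve(node: str, seen: frozenset[str]) -> str:
        if node in out:
            return out[node]
        declared = raw[node].get("namespace")
        if declared:
            out[node] = declared
            return declared
        for parent in parents[node]:
            if parent not in seen:
                ns = resolve(parent, seen | {node})
                out[node] = ns
                return ns
        out[node] = "molecular_function"
        return out[node]

    for node in raw:
        resolve(node, frozenset())
    return out


def write_obo(ontology: Ontology, path) -> None:
    """Serialise an :class:`Ontology` back to a minimal OBO 1.4 file."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.4\nontology: idranno-synthetic\n")
        for term_id in sorted(ontology.terms):
            term = ontology.terms[term_id]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term.id}\n")
            fh.write(f"name: {term.name}\n")
            fh.write(f"namespace: {term.namespace}\n")
            for parent in sorted(term.parents):
                fh.write(f"is_a: {parent} ! {ontology.terms[parent].name}\n")
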