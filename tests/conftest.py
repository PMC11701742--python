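import numpy as np
import pytest

from idranno.ontology import Ontology, OntologyTerm


@pytest.fixture
def chain_ontology() -> Ontology:
    """C is_a B is_a A, all molecular_function."""
    return Ontology(
        {
            "A": OntologyTerm("A", "a", "molecular_function", frozenset()),
            "B": OntologyTerm("B", "b", "molecular_function", frozenset({"A"})),
            "C": OntologyTerm("C", "c", "molecular_function", frozenset({"B"})),
        }
    )


def random_dag(rng: np.random.Generator, n_terms: int = 50,
               namespace: str = "molecular_function") -> Ontology:
    """A random rooted DAG: term i may take parents among terms < i."""
    terms = {"T000": OntologyTerm("T000", "root", namespace, frozenset())}
    ids = ["T000"]
    for i in range(1, n_terms):
        tid = f"T{i:03d}"
        n_parents = 1 + int(rng.integers(0, min(3, len(ids))))
        parents = rng.choice(len(ids), size=min(n_parents, len(ids)),
                             replace=False)
        terms[tid] = OntologyTerm(
            tid, tid.lower(), namespace,
            frozenset(ids[int(p)] for p in parents))
        ids.append(tid)
    return Ontology(terms)


def reachability_closure(ontology: Ontology) -> dict[str, set[str]]:
    """Ancestor sets by repeated squaring of the boolean adjacency matrix."""
    ids = sorted(ontology.terms)
    pos = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for term in ontology.terms.values():
        for parent in term.parents:
            adj[pos[term.id], pos[parent]] = True
    reach = adj.copy()
    power = adj.copy()
    for _ in range(int(np.ceil(np.log2(max(n, 2))))):
        power = power @ power
        reach = reach | power | (reach @ reach)
    return {t: {ids[j] for j in np.nonzero(reach[pos[t]])[0]} for t in ids}
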