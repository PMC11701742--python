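import numpy as np
import pandas as pd
import pytest

from idranno.embeddings import RegionEmbedding, SequenceRegion
from idranno.knn import (
    ReferenceIndex,
    TransferConfig,
    build_index,
    transfer,
    transfer_all,
)
from idranno.ontology import Ontology, OntologyTerm

from conftest import random_dag
from oracles import knn_transfer_oracle


def flat_ontology(terms, namespace="molecular_function"):
    """A root plus independent leaf terms (no hierarchy interactions)."""
    root = OntologyTerm("ROOT", "root", namespace, frozenset())
    out = {"ROOT": root}
    for t in terms:
        out[t] = OntologyTerm(t, t.lower(), namespace, frozenset({"ROOT"}))
    return Ontology(out)


def region_embedding(acc, vec, start=1, end=10):
    return RegionEmbedding(SequenceRegion(acc, start, end), np.asarray(vec, float))


def make_index(vectors, term_sets, ontology, propagate=False):
    embs = [region_embedding(f"R{i:03d}", v) for i, v in enumerate(vectors)]
    rows = []
    for emb, terms in zip(embs, term_sets):
        for t in terms:
            rows.append({"accession": emb.region.accession, "start": 1,
                         "end": 10, "term": t,
                         "namespace": ontology.namespace_of(t),
                         "evidence": "test"})
    ann = pd.DataFrame(rows)
    return build_index(ann, embs, ontology, propagate=propagate)


def vec_at_distance(base, d):
    """A 2-D vector at exact cosine distance d from base=(1,0)."""
    angle = np.arccos(1.0 - d)
    return np.array([np.cos(angle), np.sin(angle)])


class TestBuildIndex:
    def test_empty_annotations_empty_index(self):
        ont = flat_ontology(["T1"])
        idx = build_index(
            pd.DataFrame(columns=["accession", "start", "end", "term",
                                  "namespace", "evidence"]),
            [], ont)
        assert len(idx) == 0

    def test_same_region_annotations_union(self):
        ont = flat_ontology(["T1", "T2"])
        idx = make_index([[1.0, 0.0]], [["T1", "T2"]], ont)
        assert len(idx) == 1
        assert idx.entries[0].terms["molecular_function"] == {"T1", "T2"}

    def test_missing_embedding_is_error(self):
        ont = flat_ontology(["T1"])
        ann = pd.DataFrame([{"accession": "NOPE", "start": 1, "end": 10,
                             "term": "T1", "namespace": "molecular_function",
                             "evidence": "t"}])
        with pytest.raises(ValueError, match="NOPE"):
            build_index(ann, [], ont)

    def test_grouping_matches_hash_join(self):
        rng = np.random.default_rng(0)
        ont = flat_ontology([f"T{i}" for i in range(6)])
        embs, rows = [], []
        for i in range(20):
            acc = f"P{i % 7}"
            start, end = 1 + (i % 3) * 10, 10 + (i % 3) * 10
            embs.append(region_embedding(acc, rng.standard_normal(4),
                                         start, end))
            for t in rng.choice(6, size=2, replace=False):
                rows.append({"accession": acc, "start": start, "end": end,
                             "term": f"T{t}",
                             "namespace": "molecular_function",
                             "evidence": "t"})
        # deduplicate embeddings by key (same key regions share an embedding)
        by_key = {e.region.key: e for e in embs}
        idx = build_index(pd.DataFrame(rows), list(by_key.values()), ont)
        expected = {}
        for r in rows:
            expected.setdefault((r["accession"], r["start"], r["end"]),
                                set()).add(r["term"])
        got = {e.region.key: set(e.terms["molecular_function"])
               for e in idx.entries}
        assert got == expected

    def test_propagation_applied_at_build(self, chain_ontology):
        emb = region_embedding("P1", [1.0, 0.0])
        ann = pd.DataFrame([{"accession": "P1", "start": 1, "end": 10,
                             "term": "C", "namespace": "molecular_function",
                             "evidence": "t"}])
        idx = build_index(ann, [emb], chain_ontology, propagate=True)
        assert idx.entries[0].terms["molecular_function"] == {"C", "B"}
        idx = build_index(ann, [emb], chain_ontology, propagate=False)
        assert idx.entries[0].terms["molecular_function"] == {"C"}

    def test_stable_ordering(self):
        ont = flat_ontology(["T1"])
        idx = make_index([[1, 0], [0, 1], [1, 1]],
                         [["T1"], ["T1"], ["T1"]], ont)
        keys = [e.region.key for e in idx.entries]
        assert keys == sorted(keys)


class TestTransfer:
    def test_single_neighbor_at_zero_distance(self):
        ont = flat_ontology(["T1"])
        idx = make_index([[1.0, 0.0]], [["T1"]], ont)
        cfg = TransferConfig(score_threshold={"molecular_function": 0.0})
        out = transfer(region_embedding("Q", [2.0, 0.0]), idx, cfg,
                       "molecular_function")
        assert out.scores == pytest.approx({"T1": 1.0})

    def test_all_beyond_cutoff_gives_empty_map(self):
        ont = flat_ontology(["T1", "T2"])
        idx = make_index([vec_at_distance(None, 0.9), vec_at_distance(None, 1.2)],
                         [["T1"], ["T2"]], ont)
        out = transfer(region_embedding("Q", [1.0, 0.0]), idx,
                       TransferConfig(), "molecular_function")
        assert out.scores == {}
        assert out.neighbors_used == []

    def test_three_neighbor_weighted_vote(self):
        ont = flat_ontology(["A", "B"])
        vecs = [vec_at_distance(None, d) for d in (0.2, 0.4, 0.6)]
        idx = make_index(vecs, [["A"], ["A"], ["B"]], ont)
        cfg = TransferConfig(k={"molecular_function": 3},
                             score_threshold={"molecular_function": 0.0})
        out = transfer(region_embedding("Q", [1.0, 0.0]), idx, cfg,
                       "molecular_function")
        # raw weights 0.75, 0.5, 0.25 -> normalised 0.5, 1/3, 1/6
        assert out.scores["A"] == pytest.approx(0.5 + 1 / 3, abs=1e-12)
        assert out.scores["B"] == pytest.approx(1 / 6, abs=1e-12)

    def test_k1_copies_nearest_terms_with_score_one(self):
        ont = flat_ontology(["T1", "T2", "T3"])
        idx = make_index([vec_at_distance(None, 0.1),
                          vec_at_distance(None, 0.3)],
                         [["T1", "T2"], ["T3"]], ont)
        cfg = TransferConfig(k={"molecular_function": 1},
                             score_threshold={"molecular_function": 0.0})
        out = transfer(region_embedding("Q", [1.0, 0.0]), idx, cfg,
                       "molecular_function")
        assert out.scores == pytest.approx({"T1": 1.0, "T2": 1.0})

    def test_strict_binding_threshold_filters(self):
        ont = flat_ontology(["GO:0005515", "T2"])
        vecs = [vec_at_distance(None, 0.2), vec_at_distance(None, 0.4)]
        idx = make_index(vecs, [["GO:0005515"], ["T2"]], ont)
        cfg = TransferConfig(k={"molecular_function": 2},
                             score_threshold={"molecular_function": 0.0})
        out = transfer(region_embedding("Q", [1.0, 0.0]), idx, cfg,
                       "molecular_function")
        # protein binding scores 0.6 < 0.9 strict threshold -> dropped
        assert "GO:0005515" not in out.scores
        assert "T2" in out.scores

    def test_bp_cc_refused_without_override(self):
        ont = flat_ontology(["T1"], namespace="biological_process")
        idx = make_index([[1.0, 0.0]], [["T1"]], ont)
        q = region_embedding("Q", [1.0, 0.0])
        with pytest.raises(ValueError, match="not executed"):
            transfer(q, idx, TransferConfig(), "biological_process")
        cfg = TransferConfig(allow_all_namespaces=True)
        out = transfer(q, idx, cfg, "biological_process")
        assert out.scores == pytest.approx({"T1": 1.0})

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(4)
        ont = flat_ontology([f"T{i}" for i in range(5)])
        vecs = rng.standard_normal((30, 6))
        terms = [[f"T{int(rng.integers(0, 5))}"] for _ in range(30)]
        idx = make_index(list(vecs), terms, ont)
        q = region_embedding("Q", rng.standard_normal(6))
        n_prev = None
        for cutoff in (1.2, 0.8, 0.5, 0.2):
            cfg = TransferConfig(distance_cutoff=cutoff,
                                 k={"molecular_function": 100},
                                 score_threshold={"molecular_function": 0.0})
            out = transfer(q, idx, cfg, "molecular_function")
            n = len(out.neighbors_used)
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_scores_are_convex_combination(self):
        rng = np.random.default_rng(8)
        ont = flat_ontology([f"T{i}" for i in range(4)])
        vecs = rng.standard_normal((20, 5))
        terms = [[f"T{int(rng.integers(0, 4))}"] for _ in range(20)]
        idx = make_index(list(vecs), terms, ont)
        cfg = TransferConfig(score_threshold={"molecular_function": 0.0})
        out = transfer(region_embedding("Q", rng.standard_normal(5)),
                       idx, cfg, "molecular_function")
        for s in out.scores.values():
            assert 0.0 <= s <= 1.0
        if out.neighbors_used:
            weights = [w for _, _, w in out.neighbors_used]
            assert sum(weights) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        ont = random_dag(rng, n_terms=15)
        non_root = sorted(t for t in ont.terms if ont.terms[t].parents)
        n_ref = int(rng.integers(5, 50))
        dim = int(rng.integers(2, 8))
        vecs = rng.standard_normal((n_ref, dim))
        term_sets = []
        for _ in range(n_ref):
            n_t = int(rng.integers(1, 4))
            picks = rng.choice(len(non_root), size=n_t, replace=False)
            term_sets.append([non_root[int(p)] for p in picks])
        idx = make_index(list(vecs), term_sets, ont)
        cutoff = float(rng.uniform(0.3, 1.5))
        k = int(rng.integers(1, 12))
        tau = float(rng.uniform(0.0, 0.6))
        cfg = TransferConfig(distance_cutoff=cutoff,
                             k={"molecular_function": k},
                             score_threshold={"molecular_function": tau},
                             strict_terms={non_root[0]: 0.9})
        q = rng.standard_normal(dim)
        got = transfer(region_embedding("Q", q), idx, cfg,
                       "molecular_function").scores
        entries = [(e.region.key, e.embedding.vector,
                    set(e.terms["molecular_function"]))
                   for e in idx.entries]
        expected = knn_transfer_oracle(
            q, entries, cutoff, k, tau, {non_root[0]: 0.9},
            lambda t: set(ont.ancestors(t)))
        assert set(got) == set(expected)
        for term in got:
            assert got[term] == pytest.approx(expected[term], abs=1e-12)


class TestTransferAll:
    def test_empty_query_set(self):
        ont = flat_ontology(["T1"])
        idx = make_index([[1.0, 0.0]], [["T1"]], ont)
        out = transfer_all([], idx, TransferConfig(),
                           namespaces=("molecular_function",))
        assert out == {"molecular_function": []}

    def test_query_identical_to_reference_is_own_neighbor(self):
        ont = flat_ontology(["T1", "T2"])
        idx = make_index([[1.0, 0.2], [0.0, 1.0]], [["T1"], ["T2"]], ont)
        q = region_embedding("Q", [1.0, 0.2])
        cfg = TransferConfig(k={"molecular_function": 1},
                             score_threshold={"molecular_function": 0.0})
        out = transfer(q, idx, cfg, "molecular_function")
        assert out.neighbors_used[0][0] == ("R000", 1, 10)
        assert out.neighbors_used[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_batch_equals_individual_calls(self):
        rng = np.random.default_rng(77)
        ont = flat_ontology([f"T{i}" for i in range(4)])
        vecs = rng.standard_normal((15, 4))
        terms = [[f"T{int(rng.integers(0, 4))}"] for _ in range(15)]
        idx = make_index(list(vecs), terms, ont)
        queries = [region_embedding(f"Q{i}", rng.standard_normal(4))
                   for i in range(8)]
        cfg = TransferConfig(score_threshold={"molecular_function": 0.1})
        batch = transfer_all(queries, idx, cfg,
                             namespaces=("molecular_function",))
        singles = [transfer(q, idx, cfg, "molecular_function")
                   for q in queries]
        assert [m.scores for m in batch["molecular_function"]] == [
            m.scores for m in singles]
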