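"""Region-level f-max evaluation of term predictions, CAFA style.

For a score threshold t, precision is averaged over the regions that have at
least one prediction with score >= t, while recall is averaged over *all*
gold regions (a region with no surviving prediction contributes zero
recall).  f-max is the maximum over the threshold grid of the harmonic mean
of the two.  Namespaces are evaluated separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .knn import ReferenceIndex, TermScoreMap, TransferConfig, transfer
from .embeddings import RegionEmbedding
from .ontology import Ontology

RegionKey = tuple[str, int, int]


@dataclass
class GoldStandard:
    """True-path-propagated term sets per region, one namespace."""

    namespace: str
    regions: dict[RegionKey, frozenset[str]]

    def __post_init__(self) -> None:
        for key, terms in self.regions.items():
            if not terms:
                raise ValueError(f"gold region {key} has no terms")


@dataclass
class EvaluationResult:
    fmax: float
    optimal_threshold: float
    curve: list[tuple[float, float, float, float]]  # (t, precision, recall, f1)
    n_regions: int
    n_predicted: int
    extras: dict = field(default_factory=dict)


def default_grid(step: float = 0.01) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.round(np.linspace(0.0, 1.0, n + 1), 10)


def fmax(
    predictions: list[TermScoreMap],
    gold: GoldStandard,
    thresholds: np.ndarray | None = None,
    ontology: Ontology | None = None,
) -> EvaluationResult:
    """Sweep the threshold grid and report the best harmonic-mean F1.

    Prediction region keys must be a subset of the gold keys; gold regions
    with no prediction count fully against recall.  ``ontology`` is accepted
    for interface symmetry (term sets are assumed already propagated).
    """
    if not gold.regions:
        raise ValueError("empty gold standard")
    if thresholds is None:
        thresholds = default_grid()

    pred_by_key: dict[RegionKey, dict[str, float]] = {}
    offenders = []
    for tsm in predictions:
        key = tsm.query.key
        if key not in gold.regions:
            offenders.append(key)
            continue
        pred_by_key.setdefault(key, {}).update(tsm.scores)
    if offenders:
        raise ValueError(
            f"{len(offenders)} predicted region(s) absent from the gold "
            f"standard; first offenders: {offenders[:10]}"
        )

    gold_keys = sorted(gold.regions)
    curve = []
    best = (0.0, float(thresholds[0]), 0)
    for t in thresholds:
        t = float(t)
        precisions = []
        recalls = []
        n_predicted = 0
        for key in gold_keys:
            gold_terms = gold.regions[key]
            pred_terms = {
                term
                for term, s in pred_by_key.get(key, {}).items()
                if s >= t
            }
            if pred_terms:
                n_predicted += 1
                tp = len(pred_terms & gold_terms)
                precisions.append(tp / len(pred_terms))
                recalls.append(tp / len(gold_terms))
            else:
                recalls.append(0.0)
        p = float(np.mean(precisions)) if precisions else 0.0
        r = float(np.mean(recalls))
        f1 = 2.0 * p * r / (p + r) if (p + r) > 0.0 else 0.0
        curve.append((t, p, r, f1))
        if f1 > best[0]:
            best = (f1, t, n_predicted)
    return EvaluationResult(
        fmax=best[0],
        optimal_threshold=best[1],
        curve=curve,
        n_regions=len(gold_keys),
        n_predicted=best[2],
    )


def grid_search(
    index: ReferenceIndex,
    queries: list[RegionEmbedding],
    gold: GoldStandard,
    k_candidates: list[int],
    tau_grid: np.ndarray | None = None,
    config_template: TransferConfig | None = None,
) -> tuple[tuple[int, float], EvaluationResult, dict[int, EvaluationResult]]:
    """Optimise (K, tau) for one namespace on a held-out gold set.

    One transfer pass per K with the score threshold disabled; tau is then
    swept over the resulting scores by the f-max evaluator itself.  Ties are
    broken toward smaller K, then smaller tau (simpler models win).  Returns
    the best ``(k, tau)``, its :class:`EvaluationResult`, and the per-K
    results.
    """
    if not k_candidates:
        raise ValueError("no K candidates supplied")
    if tau_grid is None:
        tau_grid = default_grid()
    template = config_template or TransferConfig()
    ns = gold.namespace

    per_k: dict[int, EvaluationResult] = {}
    best_key = None
    best: tuple[int, float] | None = None
    best_result: EvaluationResult | None = None
    for k in sorted(k_candidates):
        cfg = TransferConfig(
            distance_cutoff=template.distance_cutoff,
            k={**template.k, ns: k},
            score_threshold={**template.score_threshold, ns: 0.0},
            strict_terms=dict(template.strict_terms),
            allow_all_namespaces=template.allow_all_namespaces,
        )
        preds = [transfer(q, index, cfg, ns) for q in queries]
        result = fmax(preds, gold, thresholds=tau_grid)
        per_k[k] = result
        cand_key = (-result.fmax, k, result.optimal_threshold)
        if best_key is None or cand_key < best_key:
            best_key = cand_key
            best = (k, result.optimal_threshold)
            best_result = result
    assert best is not None and best_result is not None
    return best, best_result, per_k


def map_regions(
    query_keys: list[RegionKey],
    gold_keys: list[RegionKey],
    jaccard_threshold: float = 0.5,
) -> dict[RegionKey, RegionKey]:
    """Map predicted regions onto gold regions by interval overlap.

    A toolkit utility for when predicted region boundaries do not exactly
    match curated ones: each query maps to the same-protein gold region with
    the highest interval Jaccard, kept only if Jaccard >= threshold.  Ties
    break toward the earlier (start, end) gold key.
    """
    by_acc: dict[str, list[RegionKey]] = {}
    for g in gold_keys:
        by_acc.setdefault(g[0], []).append(g)
    out: dict[RegionKey, RegionKey] = {}
    for q in query_keys:
        best_j, best_g = 0.0, None
        for g in sorted(by_acc.get(q[0], [])):
            inter = max(0, min(q[2], g[2]) - max(q[1], g[1]) + 1)
            union = (q[2] - q[1] + 1) + (g[2] - g[1] + 1) - inter
            j = inter / union if union else 0.0
            if j > best_j:
                best_j, best_g = j, g
        if best_g is not None and best_j >= jaccard_threshold:
            out[q] = best_g
    return out
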