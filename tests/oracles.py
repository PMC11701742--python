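"""Independent brute-force reimplementations used as test oracles.

Deliberately written with plain Python loops and the literal rule text, so
they share no code path with the package implementation.
"""

import math


def cosine_distance_slow(u, v):
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u))
    nv = math.sqrt(sum(b * b for b in v))
    return 1.0 - dot / (nu * nv)


def knn_transfer_oracle(query_vec, entries, cutoff, k, tau, strict, ancestors_of):
    """Literal weighted-KNN voting.

    entries: list of (entry_id, vector, term_set) in stable index order.
    ancestors_of: term -> set of ancestor terms (for max-propagation).
    Returns the post-threshold score dict.
    """
    # (1)-(2): distances, cutoff
    survivors = []
    for pos, (eid, vec, terms) in enumerate(entries):
        d = cosine_distance_slow(query_vec, vec)
        if d <= cutoff:
            survivors.append((d, pos, eid, terms))
    if not survivors:
        return {}
    # (3): k nearest, ties by stable index order
    survivors.sort(key=lambda x: (x[0], x[1]))
    nearest = survivors[:k]
    # (4)-(5): raw weights and normalisation
    raw = [1.0 - d / cutoff for d, _, _, _ in nearest]
    total = sum(raw)
    if total == 0.0:
        return {}
    weights = [w / total for w in raw]
    # (6): weighted indicator vote
    scores = {}
    for (d, pos, eid, terms), w in zip(nearest, weights):
        for term in terms:
            scores[term] = scores.get(term, 0.0) + w
    # (7): hierarchy enforcement (max over scored descendants)
    out = {}
    for term in scores:
        best = scores[term]
        for other in scores:
            if term in ancestors_of(other) and scores[other] > best:
                best = scores[other]
        out[term] = best
    # (8): thresholds
    final = {}
    for term, s in out.items():
        if s < tau:
            continue
        if term in strict and s < strict[term]:
            continue
        final[term] = min(s, 1.0)
    return final


def fmax_oracle(pred_by_key, gold_by_key, grid):
    """Literal CAFA-style region-level f-max sweep.

    Returns (fmax, optimal_threshold, curve) with curve entries
    (t, precision, recall, f1); the optimum is the smallest threshold
    attaining the maximum f1.
    """
    curve = []
    best_f, best_t = 0.0, grid[0]
    for t in grid:
        precisions = []
        recalls = []
        for key in sorted(gold_by_key):
            gold = gold_by_key[key]
            preds = {
                term
                for term, s in pred_by_key.get(key, {}).items()
                if s >= t
            }
            if preds:
                tp = len(preds & gold)
                precisions.append(tp / len(preds))
                recalls.append(tp / len(gold))
            else:
                recalls.append(0.0)
        p = sum(precisions) / len(precisions) if precisions else 0.0
        r = sum(recalls) / len(recalls)
        f1 = (2 * p * r / (p + r)) if (p + r) > 0 else 0.0
        curve.append((t, p, r, f1))
        if f1 > best_f:
            best_f, best_t = f1, t
    return best_f, best_t, curve


def consensus_residue_oracle(calls, mode, majority_thr, strict_thr,
                             denominator, n_tracks):
    """Literal per-residue consensus rule for one residue's column of calls.

    calls: iterable over the tracks' ternary values {1, 0, -1} at a residue.
    Returns the consensus call in {1, 0, -1}.
    """
    calls = list(calls)
    n_ann = sum(1 for c in calls if c == 1)
    n_cov = sum(1 for c in calls if c != -1)
    if n_cov == 0:
        return -1
    if mode == "merge":
        return 1 if n_ann >= 1 else 0
    thr = majority_thr if mode == "majority" else strict_thr
    denom = n_cov if denominator == "covered" else n_tracks
    return 1 if (denom > 0 and n_ann / denom >= thr) else 0
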