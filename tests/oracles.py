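"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — explicit set arithmetic, pair
enumeration and dense matrix products — and shares no code with the
package, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# similarity oracles


def jaccard_oracle(x: np.ndarray, y: np.ndarray) -> float:
    a = {i for i, v in enumerate(x) if v}
    b = {i for i, v in enumerate(y) if v}
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def mesh_oracle(trees_i: list[str], trees_j: list[str], decay: float = 0.5):
    """Wang-style DAG similarity by materializing both node sets."""

    def closure(trees):
        nodes = set()
        for t in trees:
            parts = t.split(".")
            for k in range(len(parts)):
                nodes.add(".".join(parts[: k + 1]))
        return nodes

    def contributions(trees):
        nodes = closure(trees)
        own = set(trees)
        C: dict[str, float] = {}

        def value(n: str) -> float:
            if n in C:
                return C[n]
            best = 1.0 if n in own else 0.0
            for child in nodes:
                if child != n and child.rsplit(".", 1)[0] == n and "." in child:
                    best = max(best, decay * value(child))
            C[n] = best
            return best

        for n in nodes:
            value(n)
        return C

    ci, cj = contributions(trees_i), contributions(trees_j)
    if not ci or not cj:
        return 0.0
    shared = set(ci) & set(cj)
    dv = sum(ci.values()) + sum(cj.values())
    return sum(ci[n] + cj[n] for n in shared) / dv


# ---------------------------------------------------------------------------
# normalization / graph oracles


def laplacian_oracle(S: np.ndarray) -> np.ndarray:
    out = np.zeros_like(S, dtype=float)
    d = S.sum(axis=1)
    for i in range(S.shape[0]):
        for j in range(S.shape[1]):
            if d[i] > 0 and d[j] > 0:
                out[i, j] = S[i, j] / np.sqrt(d[i] * d[j])
    return out


def block_graph_oracle(sr: np.ndarray, sd: np.ndarray, A: np.ndarray) -> np.ndarray:
    top = np.concatenate([laplacian_oracle(sr), A], axis=1)
    bottom = np.concatenate([A.T, laplacian_oracle(sd)], axis=1)
    return np.concatenate([top, bottom], axis=0)


def forward_oracle(a_h, H0, weights, attention, decoder, m, attends_input=True):
    """Dense from-scratch forward pass: normalize, propagate, attend, decode."""
    a_hat = laplacian_oracle(a_h)
    reps = [H0]
    H = H0
    for W in weights:
        H = np.maximum(a_hat @ H @ W, 0.0)
        reps.append(H)
    used = reps if attends_input else reps[1:]
    E = sum(a * h for a, h in zip(attention, used))
    logits = E[:m] @ decoder @ E[m:].T
    return 1.0 / (1.0 + np.exp(-logits))


# ---------------------------------------------------------------------------
# metric oracles


def auc_oracle(scores, labels) -> float:
    """Exhaustive pair counting; ties get half credit."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_oracle(scores, labels) -> float:
    """Step-wise (non-interpolated) precision-recall integration."""
    order = np.argsort(-np.asarray(scores), kind="mergesort")
    labels = np.asarray(labels)[order]
    scores = np.asarray(scores)[order]
    n_pos = labels.sum()
    ap, tp, fp = 0.0, 0, 0
    prev_recall = 0.0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:  # process tied block
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


def confusion_oracle(scores, labels, threshold):
    tp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 1)
    fp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 0)
    fn = sum(1 for s, y in zip(scores, labels) if s < threshold and y == 1)
    tn = sum(1 for s, y in zip(scores, labels) if s < threshold and y == 0)
    rec = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    acc = (tp + tn) / len(labels)
    return {"f1": f1, "acc": acc, "rec": rec, "spe": spe, "pre": pre}


def random_tree_numbers(rng: np.random.Generator, max_trees=3, max_depth=4, alphabet=6):
    """Random dot-delimited tree numbers over a small shared alphabet."""
    trees = []
    for _ in range(rng.integers(1, max_trees + 1)):
        depth = rng.integers(1, max_depth + 1)
        trees.append(".".join(f"N{rng.integers(alphabet)}" for _ in range(depth)))
    return trees
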