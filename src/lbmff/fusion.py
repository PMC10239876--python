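"""Similarity fusion, weight-grid search and the block feature graph.

Per-measure drug similarities are combined into one comprehensive drug
similarity S^r = α S^chem + β S^side + γ S^target + δ1 S^lit with
α+β+γ+δ1 = 1, and likewise S^d = θ S^mesh + δ2 S^lit for diseases.
Weights live on a lattice of step 0.01 by default and are chosen by grid
search against inner validation folds, so the outer test fold never
informs the fusion.

The fused similarities are symmetrically normalized,
~S = D^{-1/2} S D^{-1/2} with D = diag(Σ_j S_ij), and assembled with the
binary association matrix A into the (m+n)×(m+n) block adjacency

    A_H = [ ~S^r  A   ]
          [ A^T   ~S^d ]

which is what the graph convolutional encoder consumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_data import AssociationMatrix, ValidationError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FusionWeights",
    "FeatureGraph",
    "fuse_similarities",
    "enumerate_weight_grid",
    "search_fusion_weights",
    "laplacian_normalize",
    "build_feature_graph",
]

DEFAULT_STEP = 0.01
DEFAULT_GRID_CAP = 200_000
_SUM_TOL = 1e-9


@dataclass
class FusionWeights:
    """Convex-combination weights for the drug and disease measure sets."""

    drug_weights: np.ndarray
    disease_weights: np.ndarray
    step: float = DEFAULT_STEP
    drug_measures: tuple[str, ...] = ()
    disease_measures: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.drug_weights = np.asarray(self.drug_weights, dtype=float)
        self.disease_weights = np.asarray(self.disease_weights, dtype=float)
        for name, w in (("drug", self.drug_weights), ("disease", self.disease_weights)):
            if (w < -_SUM_TOL).any():
                raise ValidationError(f"{name} weights must be nonnegative")
            if abs(w.sum() - 1.0) > _SUM_TOL:
                raise ValidationError(f"{name} weights must sum to 1, got {w.sum()}")


def fuse_similarities(
    parts: list[tuple[SimilarityMatrix, float]], measure: str = "fused"
) -> SimilarityMatrix:
    """Elementwise convex combination of same-shaped similarity matrices."""
    if not parts:
        raise ValidationError("nothing to fuse")
    labels = parts[0][0].labels
    weights = np.array([w for _, w in parts], dtype=float)
    if (weights < -_SUM_TOL).any() or abs(weights.sum() - 1.0) > _SUM_TOL:
        raise ValidationError(f"fusion weights must be nonnegative and sum to 1")
    out = np.zeros_like(parts[0][0].values)
    for sim, w in parts:
        if sim.labels != labels:
            raise ValidationError("fused matrices must share labels and order")
        out += w * sim.values
    return SimilarityMatrix(out, labels, measure)


def enumerate_weight_grid(
    k: int, step: float = DEFAULT_STEP, cap: int = DEFAULT_GRID_CAP
) -> np.ndarray:
    """All nonnegative k-vectors on the step lattice summing to 1.

    Returned in lexicographic order, each vector exactly once; the count
    is the stars-and-bars number C(n+k-1, k-1) with n = 1/step, checked
    against ``cap`` before any memory is allocated.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-12 or n < 1:
        raise ValidationError(f"step {step} does not divide 1")
    count = math.comb(n + k - 1, k - 1)
    if count > cap:
        raise ValidationError(
            f"grid of {count} points exceeds cap {cap}; use a coarser step"
        )
    out = np.empty((count, k), dtype=float)
    comp = np.zeros(k, dtype=int)

    def rec(pos: int, remaining: int, row: list[int]) -> None:
        nonlocal _i
        if pos == k - 1:
            out[_i] = row + [remaining]
            _i += 1
            return
        for c in range(remaining + 1):
            rec(pos + 1, remaining - c, row + [c])

    _i = 0
    if k == 1:
        out[0] = [n]
    else:
        rec(0, n, [])
    return out / n


# ---------------------------------------------------------------------------
# weight search


def _objective_fn(name: str):
    from sklearn.metrics import average_precision_score, roc_auc_score

    table = {"aupr": average_precision_score, "auc": roc_auc_score}
    if name not in table:
        raise ValidationError(f"unknown objective {name!r}; choose from {sorted(table)}")
    return table[name]


def _inner_splits(A_train: np.ndarray, n_splits: int, frac: float, rng: np.random.Generator):
    """Hold out ``frac`` of the training positives, ``n_splits`` times."""
    pos = np.argwhere(A_train == 1)
    for _ in range(n_splits):
        perm = rng.permutation(len(pos))
        n_val = max(1, int(round(frac * len(pos))))
        val = pos[perm[:n_val]]
        A_inner = A_train.copy()
        A_inner[val[:, 0], val[:, 1]] = 0
        yield A_inner, val


def _propagation_scores(
    drug_sims: list[np.ndarray], disease_sims: list[np.ndarray], A_inner: np.ndarray
):
    """Per measure-pair propagated score blocks S_a @ A @ T_b."""
    return np.stack(
        [np.stack([S @ A_inner @ T for T in disease_sims]) for S in drug_sims]
    )  # (ka, kb, m, n)


def search_fusion_weights(
    drug_measures: dict[str, SimilarityMatrix],
    disease_measures: dict[str, SimilarityMatrix],
    A_train: np.ndarray | AssociationMatrix,
    objective: str = "aupr",
    inner_splits: int = 1,
    inner_frac: float = 0.2,
    step: float = DEFAULT_STEP,
    cap: int = DEFAULT_GRID_CAP,
    coarse_step: float = 0.05,
    seed: int = 0,
) -> FusionWeights:
    """Grid-search fusion weights against inner validation positives.

    Each lattice point is scored by ranking inner-validation positives
    among all cells unknown to the inner training matrix, using the
    training-free propagation scorer S^r @ A @ S^d (linear in the weights,
    so the whole grid reuses a small set of precomputed blocks).  The
    returned weights maximize the mean objective over the inner splits;
    ties break to the first point in lexicographic grid order.  Only the
    training matrix it is handed ever enters the search.
    """
    if isinstance(A_train, AssociationMatrix):
        A_train = A_train.values
    A_train = np.asarray(A_train, dtype=float)
    obj = _objective_fn(objective)
    ka, kb = len(drug_measures), len(disease_measures)
    d_names, z_names = tuple(drug_measures), tuple(disease_measures)
    if ka == 1 and kb == 1:
        return FusionWeights(np.ones(1), np.ones(1), step, d_names, z_names)

    rng = np.random.default_rng(seed)
    d_sims = [drug_measures[k].values for k in d_names]
    z_sims = [disease_measures[k].values for k in z_names]

    # materialize the inner splits once so every grid point (and every
    # refinement move) is scored against the same validation data
    splits = []
    for A_inner, _val in _inner_splits(A_train, inner_splits, inner_frac, rng):
        cand = A_inner == 0  # cells unknown to inner training
        labels = (A_train[cand] == 1).astype(int)
        P = _propagation_scores(d_sims, z_sims, A_inner)[:, :, cand]
        splits.append((labels, P))

    # accumulated objective per joint grid point over the inner splits
    def evaluate_grid(gd: np.ndarray, gz: np.ndarray) -> np.ndarray:
        totals = np.zeros(len(gd) * len(gz))
        for labels, P in splits:
            i = 0
            for w in gd:
                Pw = np.tensordot(w, P, axes=(0, 0))  # (kb, ncand)
                for v in gz:
                    totals[i] += obj(labels, v @ Pw)
                    i += 1
        return totals

    n_joint = math.comb(round(1 / step) + ka - 1, ka - 1) * math.comb(
        round(1 / step) + kb - 1, kb - 1
    )
    use_step = step if n_joint <= cap else coarse_step
    if use_step != step:
        logger.info(
            "joint grid of %d points exceeds cap %d; coarse search at step %g "
            "with greedy refinement at step %g", n_joint, cap, coarse_step, step,
        )
    gd = enumerate_weight_grid(ka, use_step, cap)
    gz = enumerate_weight_grid(kb, use_step, cap)
    totals = evaluate_grid(gd, gz)
    best = int(np.argmax(totals))  # argmax takes the first maximizer: lex order
    wd, wz = gd[best // len(gz)].copy(), gz[best % len(gz)].copy()

    if use_step != step:
        wd, wz = _greedy_refine(
            wd, wz, step, lambda a, b: evaluate_grid(a[None], b[None])[0]
        )
    return FusionWeights(wd, wz, step, d_names, z_names)


def _greedy_refine(wd, wz, step, score_fn):
    """Hill-climb on the fine lattice by moving mass ``step`` at a time."""
    best = score_fn(wd, wz)
    improved = True
    while improved:
        improved = False
        for w in (wd, wz):
            k = len(w)
            for i in range(k):
                for j in range(k):
                    if i == j or w[i] < step - _SUM_TOL:
                        continue
                    w[i] -= step
                    w[j] += step
                    s = score_fn(wd, wz)
                    if s > best + 1e-12:
                        best = s
                        improved = True
                    else:
                        w[i] += step
                        w[j] -= step
    return wd, wz


# ---------------------------------------------------------------------------
# normalization and graph assembly


def laplacian_normalize(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} S D^{-1/2}.

    D = diag(Σ_j S_ij).  Zero-degree rows take the pseudo-inverse
    convention d^{-1/2} = 0, leaving the row and column zero.
    """
    M = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if (M < 0).any():
        raise ValidationError("similarity matrix must be nonnegative")
    d = M.sum(axis=1)
    inv_sqrt = np.zeros_like(d)
    nz = d > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(d[nz])
    return M * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class FeatureGraph:
    """Block adjacency A_H with its degree vector; first m rows are drugs."""

    a_h: np.ndarray
    m: int
    n: int
    degree: np.ndarray = field(init=False)
    _a_hat: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.a_h.shape != (self.m + self.n, self.m + self.n):
            raise ValidationError("A_H must be (m+n) x (m+n)")
        self.degree = self.a_h.sum(axis=1)

    @property
    def a_hat(self) -> np.ndarray:
        """Degree-normalized adjacency D~^{-1/2} A_H D~^{-1/2} (cached)."""
        if self._a_hat is None:
            self._a_hat = laplacian_normalize(self.a_h)
        return self._a_hat

    @property
    def association_block(self) -> np.ndarray:
        return self.a_h[: self.m, self.m:]


def build_feature_graph(
    fused_drug: SimilarityMatrix,
    fused_disease: SimilarityMatrix,
    A: AssociationMatrix | np.ndarray,
) -> FeatureGraph:
    """Assemble A_H = [[~S^r, A], [A^T, ~S^d]].

    The similarity blocks are normalized here; the association off-blocks
    are the binary matrix exactly as given (typically the training-fold
    matrix with test associations zeroed).
    """
    Av = A.values if isinstance(A, AssociationMatrix) else np.asarray(A, dtype=float)
    m, n = Av.shape
    if fused_drug.values.shape != (m, m) or fused_disease.values.shape != (n, n):
        raise ValidationError(
            f"shape mismatch: drugs {fused_drug.values.shape}, "
            f"diseases {fused_disease.values.shape}, associations {Av.shape}"
        )
    sr = laplacian_normalize(fused_drug)
    sd = laplacian_normalize(fused_disease)
    a_h = np.block([[sr, Av.astype(float)], [Av.T.astype(float), sd]])
    return FeatureGraph(a_h, m, n)
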