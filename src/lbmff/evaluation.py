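"""Cross-validated evaluation, ablation and top-K ranking.

Known associations are split into five mutually exclusive folds; each
round masks one fold's positives out of the training matrix, trains from
the initial state, and scores the held-out positives against every pair
unknown to training.  AUC (rank statistic, ties half-credit) and AUPR
(step-wise precision-recall integration) are the primary metrics;
thresholded metrics (F1/Acc/Rec/Spe/Pre) use a threshold chosen on the
training fold — by default the F1-maximizing one — applied unchanged to
the test fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score

from .io_data import AssociationMatrix, Dataset, ValidationError
from .similarity import (
    SimilarityMatrix,
    build_disease_dag,
    compute_fingerprints,
    jaccard_similarity,
    mesh_similarity,
)
from .literature import EntityCorpus, cooccurrence_similarity
from .fusion import (
    FusionWeights,
    build_feature_graph,
    fuse_similarities,
    search_fusion_weights,
)
from .model import TrainConfig, init_embeddings, predict, train

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "FoldReport",
    "make_folds",
    "compute_metrics",
    "compute_measures",
    "cross_validate",
    "ablate",
    "rank_predictions",
]

METRIC_NAMES = ("aupr", "auc", "f1", "acc", "rec", "spe", "pre")


# ---------------------------------------------------------------------------
# folds


@dataclass
class FoldSplit:
    """k disjoint positive-pair index sets whose union is all positives."""

    folds: list[np.ndarray]  # each (s, 2) array of (drug, disease) indices
    seed: int

    def __post_init__(self) -> None:
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValidationError("fold sizes must differ by at most 1")

    @property
    def k(self) -> int:
        return len(self.folds)


def make_folds(A: AssociationMatrix | np.ndarray, k: int = 5, seed: int = 0) -> FoldSplit:
    """Randomly split the known positives into k near-equal folds."""
    Av = A.values if isinstance(A, AssociationMatrix) else np.asarray(A)
    pos = np.argwhere(Av == 1)
    if len(pos) < k:
        raise ValidationError(f"need >= {k} positives, have {len(pos)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pos))
    return FoldSplit([pos[chunk] for chunk in np.array_split(perm, k)], seed)


# ---------------------------------------------------------------------------
# metrics


def _confusion_metrics(scores, labels, threshold: float) -> dict[str, float]:
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    rec = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    acc = (tp + tn) / len(labels)
    return {"f1": f1, "acc": acc, "rec": rec, "spe": spe, "pre": pre}


def best_f1_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """The score threshold maximizing F1 (deterministic: first maximizer)."""
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    # the last P/R point (recall 0) has no threshold attached
    return float(thresholds[int(np.argmax(f1[:-1]))])


def compute_metrics(
    scores, labels, threshold: float | None = None, fold: int | None = None
) -> dict[str, float]:
    """AUC, AUPR and confusion metrics for one fold's score/label vectors.

    ``threshold=None`` picks the F1-maximizing threshold on these scores
    (used for self-contained calls; cross-validation passes the threshold
    it chose on the training fold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary")
    if labels.min() == labels.max():
        raise ValidationError(f"fold {fold}: labels contain a single class")
    if threshold is None:
        threshold = best_f1_threshold(scores, labels)
    out = {
        "aupr": float(average_precision_score(labels, scores)),
        "auc": float(roc_auc_score(labels, scores)),
    }
    out.update(_confusion_metrics(scores, labels, threshold))
    out["threshold"] = float(threshold)
    return out


# ---------------------------------------------------------------------------
# measure providers


def compute_measures(
    dataset: Dataset,
    radius: int = 2,
    nbits: int = 1024,
    use_idf: bool = True,
) -> tuple[dict[str, SimilarityMatrix], dict[str, SimilarityMatrix]]:
    """All available per-measure similarity matrices for one dataset.

    Drug measures (in the canonical order chemical, side_effect, target,
    literature) and disease measures (mesh, literature).  Chemical
    similarity comes from Morgan fingerprints when SMILES are present,
    else from precomputed substructure profiles; literature similarity
    from an attached precomputed matrix or, failing that, TF-IDF cosine
    over the per-entity corpus.
    """
    cat = dataset.catalog
    drug_measures: dict[str, SimilarityMatrix] = {}
    disease_measures: dict[str, SimilarityMatrix] = {}

    if dataset.smiles:
        fps = compute_fingerprints(
            {d: dataset.smiles.get(d, "") for d in cat.drug_ids}, radius, nbits
        )
        drug_measures["chemical"] = jaccard_similarity(fps.bits, cat.drug_ids, "chemical")
    elif dataset.chemical_profiles is not None:
        drug_measures["chemical"] = jaccard_similarity(
            dataset.chemical_profiles.values, cat.drug_ids, "chemical"
        )
    if dataset.side_effects is not None:
        drug_measures["side_effect"] = jaccard_similarity(
            dataset.side_effects.values, cat.drug_ids, "side_effect"
        )
    if dataset.targets is not None:
        drug_measures["target"] = jaccard_similarity(
            dataset.targets.values, cat.drug_ids, "target"
        )

    if dataset.mesh_trees:
        dags = build_disease_dag(dataset.mesh_trees)
        disease_measures["mesh"] = mesh_similarity(dags, cat.disease_ids)

    if dataset.literature_drug_sim is not None:
        drug_measures["literature"] = dataset.literature_drug_sim
    elif dataset.corpus and any(d in dataset.corpus for d in cat.drug_ids):
        corpus = EntityCorpus.from_mapping(dataset.corpus, cat.drug_ids)
        drug_measures["literature"] = cooccurrence_similarity(corpus, "literature", use_idf)
    if dataset.literature_disease_sim is not None:
        disease_measures["literature"] = dataset.literature_disease_sim
    elif dataset.corpus and any(d in dataset.corpus for d in cat.disease_ids):
        corpus = EntityCorpus.from_mapping(dataset.corpus, cat.disease_ids)
        disease_measures["literature"] = cooccurrence_similarity(corpus, "literature", use_idf)

    if not drug_measures or not disease_measures:
        raise ValidationError("dataset provides no drug or no disease measure")
    return drug_measures, disease_measures


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldReport:
    """Per-fold metric rows with mean and standard deviation."""

    rows: list[dict[str, float]]
    seed: int
    config: dict = field(default_factory=dict)
    weights: list[dict] = field(default_factory=list)
    fold_pairs: list = field(default_factory=list)  # test pairs per fold

    @property
    def mean(self) -> dict[str, float]:
        return {k: float(np.mean([r[k] for r in self.rows])) for k in METRIC_NAMES}

    @property
    def std(self) -> dict[str, float]:
        return {k: float(np.std([r[k] for r in self.rows])) for k in METRIC_NAMES}

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)[list(METRIC_NAMES)]
        df.loc["mean"] = df.mean()
        df.loc["std"] = df.iloc[:-1].std(ddof=0)
        return df

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "mean": self.mean,
            "std": self.std,
            "seed": self.seed,
            "config": self.config,
            "weights": self.weights,
        }


def _inner_threshold(A_train, fused_drug, fused_disease, cfg: TrainConfig) -> float:
    """F1-maximizing threshold from an inner validation split.

    A fifth of the training positives is masked, a model is fitted
    without them, and the threshold is chosen where those positives rank
    among all cells unknown to the inner training matrix.  Uses only
    training-fold information.
    """
    rng = np.random.default_rng(cfg.seed + 7)
    pos = np.argwhere(A_train == 1)
    n_val = max(1, len(pos) // 5)
    val = pos[rng.permutation(len(pos))[:n_val]]
    A_inner = A_train.copy()
    A_inner[val[:, 0], val[:, 1]] = 0
    graph = build_feature_graph(fused_drug, fused_disease, A_inner)
    inner_model = train(graph, A_inner, cfg)
    inner_scores = predict(inner_model, graph, A_inner)
    cand = A_inner == 0
    return best_f1_threshold(inner_scores[cand], A_train[cand])


def _assert_no_leakage(A_full, A_train, test_pairs, graph, H0, labels_train_frame):
    """Instrumented guard: test positives must be invisible to training."""
    ti, tj = test_pairs[:, 0], test_pairs[:, 1]
    assert (A_train[ti, tj] == 0).all(), "test positives present in training matrix"
    assert (H0[ti, A_train.shape[0] + tj] == 0).all(), "test positives leaked into H0"
    assert (graph.association_block[ti, tj] == 0).all(), "test positives leaked into A_H"
    assert (labels_train_frame[ti, tj] == 0).all(), (
        "test positives would enter the training loss as positives"
    )


def cross_validate(
    dataset: Dataset,
    weights: FusionWeights | str = "search",
    config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    measures: tuple[dict, dict] | None = None,
    folds: FoldSplit | None = None,
    threshold_policy: str | float = "inner_f1",
    negative_mode: str = "all",
    negative_ratio: float = 1.0,
    search_kwargs: dict | None = None,
) -> FoldReport:
    """k-fold cross-validation of the full pipeline.

    ``weights`` is either fixed :class:`FusionWeights` or ``"search"`` /
    ``"uniform"``; the search runs inside each training fold on inner
    validation splits, so the held-out fold never influences the fusion.
    ``negative_mode="all"`` evaluates against every pair unknown to
    training; ``"sampled"`` draws ``negative_ratio`` negatives per test
    positive.  Deterministic given ``seed``.

    Threshold policies for the confusion metrics: ``"inner_f1"``
    (default) holds out a fifth of the training positives, fits a model
    without them and takes the F1-maximizing threshold where those
    positives rank among unknown cells — the only view of the score
    scale that resembles the test fold; ``"train_f1"`` maximizes F1 on
    the training frame directly; a float is used as-is.  Either way the
    threshold is fixed before the test fold is scored.
    """
    config = config or TrainConfig()
    drug_m, disease_m = measures if measures is not None else compute_measures(dataset)
    A_full = dataset.associations.values.astype(int)
    split = folds if folds is not None else make_folds(A_full, k, seed)
    fold_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=split.k)

    rows, used_weights = [], []
    for f, test_pairs in enumerate(split.folds):
        A_train = A_full.copy()
        A_train[test_pairs[:, 0], test_pairs[:, 1]] = 0

        if isinstance(weights, FusionWeights):
            fw = weights
        elif weights == "uniform":
            fw = FusionWeights(
                np.full(len(drug_m), 1 / len(drug_m)),
                np.full(len(disease_m), 1 / len(disease_m)),
                drug_measures=tuple(drug_m),
                disease_measures=tuple(disease_m),
            )
        elif weights == "search":
            fw = search_fusion_weights(
                drug_m, disease_m, A_train, seed=int(fold_seeds[f]),
                **(search_kwargs or {}),
            )
        else:
            raise ValidationError(f"unknown weights spec {weights!r}")

        fused_drug = fuse_similarities(
            [(drug_m[name], w) for name, w in zip(drug_m, fw.drug_weights)],
            "fused_drug",
        )
        fused_disease = fuse_similarities(
            [(disease_m[name], w) for name, w in zip(disease_m, fw.disease_weights)],
            "fused_disease",
        )
        graph = build_feature_graph(fused_drug, fused_disease, A_train)
        H0 = init_embeddings(A_train)
        _assert_no_leakage(A_full, A_train, test_pairs, graph, H0, A_train)

        cfg = replace(config, seed=int(fold_seeds[f]))
        model = train(graph, A_train, cfg)
        scores = predict(model, graph, A_train)

        if threshold_policy == "inner_f1":
            thr = _inner_threshold(A_train, fused_drug, fused_disease, cfg)
        elif threshold_policy == "train_f1":
            # training frame: every cell except the held-out positives
            train_mask = np.ones_like(A_full, dtype=bool)
            train_mask[test_pairs[:, 0], test_pairs[:, 1]] = False
            thr = best_f1_threshold(scores[train_mask], A_train[train_mask])
        else:
            thr = float(threshold_policy)

        cand = A_train == 0  # everything unknown to training
        cand_scores, cand_labels = scores[cand], A_full[cand]
        if negative_mode == "sampled":
            rng = np.random.default_rng(fold_seeds[f] + 1)
            pos_idx = np.flatnonzero(cand_labels == 1)
            neg_idx = np.flatnonzero(cand_labels == 0)
            n_neg = min(len(neg_idx), int(round(negative_ratio * len(pos_idx))))
            keep = np.concatenate(
                [pos_idx, rng.choice(neg_idx, size=n_neg, replace=False)]
            )
            cand_scores, cand_labels = cand_scores[keep], cand_labels[keep]
        rows.append(compute_metrics(cand_scores, cand_labels, thr, fold=f))
        used_weights.append(
            {
                "drug": dict(zip(fw.drug_measures or tuple(drug_m), fw.drug_weights.tolist())),
                "disease": dict(zip(fw.disease_measures or tuple(disease_m), fw.disease_weights.tolist())),
            }
        )

    return FoldReport(
        rows, seed, config=asdict(config), weights=used_weights,
        fold_pairs=[p.tolist() for p in split.folds],
    )


# ---------------------------------------------------------------------------
# ablation


def ablate(
    dataset: Dataset,
    config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    measures: tuple[dict, dict] | None = None,
    weights: str = "uniform",
) -> dict[str, FoldReport]:
    """Single-measure rows vs. multi-feature fusion, on shared folds.

    One row per drug measure used alone (diseases use the MeSH measure,
    or the literature measure for the literature row), an ``MFF`` row
    fusing every non-literature measure, and a full row fusing all.  The
    identical :class:`FoldSplit` is reused across rows so comparisons are
    paired.
    """
    drug_m, disease_m = measures if measures is not None else compute_measures(dataset)
    folds = make_folds(dataset.associations, k, seed)
    reports: dict[str, FoldReport] = {}

    def dz_for(name: str) -> dict[str, SimilarityMatrix]:
        if name == "literature" and "literature" in disease_m:
            return {"literature": disease_m["literature"]}
        if "mesh" in disease_m:
            return {"mesh": disease_m["mesh"]}
        return disease_m

    for name, sim in drug_m.items():
        reports[name] = cross_validate(
            dataset, weights="uniform", config=config, seed=seed,
            measures=({name: sim}, dz_for(name)), folds=folds,
        )
    non_lit = {n: s for n, s in drug_m.items() if n != "literature"}
    non_lit_z = {n: s for n, s in disease_m.items() if n != "literature"}
    if len(non_lit) > 1 and non_lit_z:
        reports["MFF"] = cross_validate(
            dataset, weights=weights, config=config, seed=seed,
            measures=(non_lit, non_lit_z), folds=folds,
        )
    if len(drug_m) > len(non_lit) or len(disease_m) > len(non_lit_z):
        reports["LBMFF"] = cross_validate(
            dataset, weights=weights, config=config, seed=seed,
            measures=(drug_m, disease_m), folds=folds,
        )
    return reports


# ---------------------------------------------------------------------------
# ranking


def rank_predictions(
    scores: np.ndarray,
    dataset: Dataset,
    mode: str = "pairs",
    k: int = 10,
    entity_id: str | None = None,
    known: AssociationMatrix | np.ndarray | None = None,
) -> pd.DataFrame:
    """Top-K unknown pairs by predicted score.

    ``known`` positives (default: the dataset's association matrix) are
    excluded from the candidate set.  Modes: ``pairs`` ranks globally,
    ``per_drug`` ranks diseases for ``entity_id``, ``per_disease`` ranks
    drugs.  Ties break by (score desc, drug id, disease id).
    """
    cat = dataset.catalog
    Av = known.values if isinstance(known, AssociationMatrix) else known
    if Av is None:
        Av = dataset.associations.values
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (cat.m, cat.n):
        raise ValidationError("score matrix shape does not match the catalog")

    mask = np.asarray(Av) == 0
    if mode == "per_drug":
        if entity_id not in cat.drug_ids:
            raise ValidationError(f"unknown drug id {entity_id!r}")
        keep = np.zeros_like(mask)
        keep[cat.drug_index()[entity_id]] = True
        mask &= keep
    elif mode == "per_disease":
        if entity_id not in cat.disease_ids:
            raise ValidationError(f"unknown disease id {entity_id!r}")
        keep = np.zeros_like(mask)
        keep[:, cat.disease_index()[entity_id]] = True
        mask &= keep
    elif mode != "pairs":
        raise ValidationError(f"unknown mode {mode!r}")

    idx = np.argwhere(mask)
    if len(idx) < k:
        warnings.warn(f"only {len(idx)} candidate pairs available; truncating top-{k}")
    df = pd.DataFrame(
        {
            "drug_id": [cat.drug_ids[i] for i, _ in idx],
            "disease_id": [cat.disease_ids[j] for _, j in idx],
            "score": scores[mask],
        }
    )
    df = df.sort_values(
        ["score", "drug_id", "disease_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(k)
    return df.reset_index(drop=True)
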