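"""Database-derived similarity measures.

Four measures are computed here: chemical-structure similarity (Jaccard
index over Morgan fingerprints), side-effect and target profile Jaccard
similarity, and disease semantic similarity over the MeSH hierarchy
treated as a directed acyclic graph (a Wang-style measure in which each
ancestor's contribution decays by a factor of 0.5 per level).

Every function returns a :class:`SimilarityMatrix`: square, symmetric,
unit diagonal, entries in [0, 1].  For entities with an empty profile
the convention is self-similarity 1 and cross-similarity 0, which keeps
the unit-diagonal invariant and avoids 0/0.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_data import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "FingerprintSet",
    "DiseaseDAG",
    "compute_fingerprints",
    "jaccard_similarity",
    "build_disease_dag",
    "semantic_contribution",
    "mesh_similarity",
]

DEFAULT_DECAY = 0.5  # per-level semantic contribution decay factor

_TREE_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1] for one measure (or fused)."""

    values: np.ndarray
    labels: tuple[str, ...]
    measure: str = "fused"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"{self.measure}: similarity matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValidationError(f"{self.measure}: labels do not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError(f"{self.measure}: matrix not symmetric")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValidationError(f"{self.measure}: entries outside [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValidationError(f"{self.measure}: diagonal must be 1")
        # scrub numerical dust so downstream exact checks hold
        np.clip(v, 0.0, 1.0, out=v)
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 1.0)


@dataclass
class FingerprintSet:
    """Binary substructure-presence vectors, one row per drug."""

    bits: np.ndarray  # (n_drugs, nbits) uint8
    ids: tuple[str, ...]
    failed: tuple[str, ...] = ()  # drugs whose SMILES did not parse


def compute_fingerprints(
    smiles: dict[str, str], radius: int = 2, nbits: int = 1024
) -> FingerprintSet:
    """Morgan (circular substructure) fingerprints from SMILES strings.

    Unparseable SMILES yield an all-zero vector and a warning; if *no*
    molecule parses there is no chemical signal at all and we raise.
    """
    if radius < 0 or nbits < 8:
        raise ValidationError("radius must be >= 0 and nbits >= 8")
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    ids = tuple(smiles)
    bits = np.zeros((len(ids), nbits), dtype=np.uint8)
    failed: list[str] = []
    for i, d in enumerate(ids):
        mol = Chem.MolFromSmiles(smiles[d])
        if mol is None:
            failed.append(d)
            continue
        bits[i] = gen.GetFingerprintAsNumPy(mol)
    if failed:
        warnings.warn(f"{len(failed)} SMILES failed to parse: {failed[:5]}")
    if len(failed) == len(ids) and ids:
        raise ValidationError("no SMILES parsed; chemical similarity is undefined")
    return FingerprintSet(bits, ids, tuple(failed))


def jaccard_similarity(
    profiles: np.ndarray, ids: tuple[str, ...] | list[str], measure: str = "chemical"
) -> SimilarityMatrix:
    """Pairwise Jaccard index |X_i ∩ X_j| / |X_i ∪ X_j| over binary rows.

    The diagonal is defined as 1 even for all-zero rows; an empty union
    between two distinct entities gives similarity 0.
    """
    X = np.asarray(profiles)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValidationError("profiles must be a 2-D matrix with >= 1 row")
    if not np.isin(X, (0, 1)).all():
        raise ValidationError("profiles must be binary")
    X = X.astype(float)
    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, tuple(ids), measure)


# ---------------------------------------------------------------------------
# MeSH DAG semantic similarity


@dataclass
class DiseaseDAG:
    """Prefix-closure DAG of one disease's MeSH tree numbers.

    ``nodes`` maps each node (a dot-delimited tree-number prefix) to its
    semantic contribution C_d(n); ``own`` are the disease's complete tree
    numbers (C = 1 by definition).  ``dv`` is the semantic value DV(d),
    the sum of contributions over the node set.
    """

    disease_id: str
    own: frozenset[str]
    nodes: dict[str, float] = field(default_factory=dict)

    @property
    def dv(self) -> float:
        return float(sum(self.nodes.values()))


def _prefixes(tree: str) -> list[str]:
    parts = tree.split(".")
    return [".".join(parts[: k + 1]) for k in range(len(parts))]


def build_disease_dag(
    tree_numbers: dict[str, list[str]], decay: float = DEFAULT_DECAY
) -> dict[str, DiseaseDAG]:
    """Build one merged DAG per disease from its MeSH tree numbers.

    A node set is the union of proper-prefix closures over all of the
    disease's tree numbers (a disease with several tree numbers gets one
    merged DAG).  Contributions are filled in immediately via
    :func:`semantic_contribution`.
    """
    dags: dict[str, DiseaseDAG] = {}
    for disease, trees in tree_numbers.items():
        for t in trees:
            if not _TREE_RE.match(t):
                raise ValidationError(
                    f"malformed tree number {t!r} for disease {disease!r}"
                )
        node_set: set[str] = set()
        for t in trees:
            node_set.update(_prefixes(t))
        dag = DiseaseDAG(disease, frozenset(trees), {n: 0.0 for n in node_set})
        if node_set:
            semantic_contribution(dag, decay)
        dags[disease] = dag
    return dags


def semantic_contribution(dag: DiseaseDAG, decay: float = DEFAULT_DECAY) -> dict[str, float]:
    """Fill in C_d(n) for every node of one disease DAG.

    C_d(d) = 1 for the disease's own tree numbers; for an ancestor n,
    C_d(n) = max over its children n' inside the DAG of decay * C_d(n').
    Nodes are processed deepest-first so children are always ready.
    """
    if not (0 < decay <= 1):
        raise ValidationError("decay must be in (0, 1]")
    children: dict[str, list[str]] = {n: [] for n in dag.nodes}
    for n in dag.nodes:
        parts = n.split(".")
        if len(parts) > 1:
            parent = ".".join(parts[:-1])
            if parent not in dag.nodes:  # prefix closure guarantees presence
                raise RuntimeError(f"node {parent} missing from ancestor closure")
            children[parent].append(n)
    for n in sorted(dag.nodes, key=lambda s: -s.count(".")):
        c = 0.0
        if n in dag.own:
            c = 1.0
        if children[n]:
            c = max(c, max(decay * dag.nodes[ch] for ch in children[n]))
        if c == 0.0:
            raise RuntimeError(f"node {n} unreachable from {dag.disease_id}")
        dag.nodes[n] = c
    return dag.nodes


def mesh_similarity(
    dags: dict[str, DiseaseDAG], labels: tuple[str, ...] | list[str] | None = None
) -> SimilarityMatrix:
    """Pairwise disease semantic similarity from shared DAG ancestors.

    S_ij = sum over shared nodes of (C_i(n) + C_j(n)) / (DV(i) + DV(j)).
    Diseases sharing more (and deeper) ancestors score higher.  A disease
    with no tree numbers has similarity 0 to everything else and 1 to
    itself.
    """
    if labels is None:
        labels = tuple(dags)
    k = len(labels)
    S = np.eye(k)
    dvs = [dags[d].dv if d in dags else 0.0 for d in labels]
    for i in range(k):
        di = dags.get(labels[i])
        if di is None or not di.nodes:
            continue
        for j in range(i + 1, k):
            dj = dags.get(labels[j])
            if dj is None or not dj.nodes:
                continue
            shared = di.nodes.keys() & dj.nodes.keys()
            if not shared:
                continue
            num = sum(di.nodes[n] + dj.nodes[n] for n in shared)
            S[i, j] = S[j, i] = num / (dvs[i] + dvs[j])
    return SimilarityMatrix(S, tuple(labels), "mesh")
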