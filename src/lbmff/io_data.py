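"""Tabular input/output and the in-memory dataset.

All on-disk artifacts are TSV with a header row, UTF-8, keyed by entity
ids (never integer indices).  Association files are edge lists: two
columns ``(drug_id, partner_id)`` or three with a ``{0,1}`` value.
Internally every matrix is 0-based and row/column order is canonical:
lexicographic by id, fixed by the :class:`EntityCatalog`.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EntityCatalog",
    "AssociationMatrix",
    "Dataset",
    "ValidationError",
    "load_association_file",
    "load_dataset",
    "read_similarity",
    "write_similarity",
    "write_dataset",
]


class ValidationError(ValueError):
    """Raised when an input file or matrix violates a structural contract."""


@dataclass(frozen=True)
class EntityCatalog:
    """Canonical, ordered drug and disease identifiers.

    Row ``i`` of any drug-indexed matrix refers to ``drug_ids[i]``; column
    ``j`` of any disease-indexed matrix refers to ``disease_ids[j]``.
    """

    drug_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, ids in (("drug", self.drug_ids), ("disease", self.disease_ids)):
            if len(ids) == 0:
                raise ValidationError(f"catalog has no {name} ids")
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} ids in catalog")

    @property
    def m(self) -> int:
        return len(self.drug_ids)

    @property
    def n(self) -> int:
        return len(self.disease_ids)

    def drug_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.drug_ids)}

    def disease_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.disease_ids)}


@dataclass
class AssociationMatrix:
    """Binary entity-profile matrix with labelled rows and columns.

    ``role`` distinguishes drug-disease, drug-side-effect and drug-target
    matrices; only drug-disease pairs become graph edges downstream.
    """

    values: np.ndarray
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    role: str = "drug-disease"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"{self.role}: matrix shape {self.values.shape} does not match "
                f"({len(self.row_ids)}, {len(self.col_ids)}) labels"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError(f"{self.role}: entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def positives(self) -> np.ndarray:
        """(k, 2) array of row/column index pairs where the matrix is 1."""
        return np.argwhere(self.values == 1)


@dataclass
class Dataset:
    """Everything one run needs, resolved against a single catalog."""

    catalog: EntityCatalog
    associations: AssociationMatrix
    smiles: dict[str, str] = field(default_factory=dict)
    mesh_trees: dict[str, list[str]] = field(default_factory=dict)
    side_effects: AssociationMatrix | None = None
    targets: AssociationMatrix | None = None
    chemical_profiles: AssociationMatrix | None = None
    corpus: dict[str, str] = field(default_factory=dict)
    literature_drug_sim: "object | None" = None
    literature_disease_sim: "object | None" = None

    def __post_init__(self) -> None:
        if self.associations.row_ids != self.catalog.drug_ids:
            raise ValidationError("association rows do not match catalog drugs")
        if self.associations.col_ids != self.catalog.disease_ids:
            raise ValidationError("association columns do not match catalog diseases")

    def flagged_entities(self) -> dict[str, list[str]]:
        """Ids lacking a given feature; permitted but worth surfacing."""
        return {
            "drugs_without_smiles": [
                d for d in self.catalog.drug_ids
                if d not in self.smiles and self.chemical_profiles is None
            ],
            "diseases_without_mesh": [
                d for d in self.catalog.disease_ids if not self.mesh_trees.get(d)
            ],
        }


# ---------------------------------------------------------------------------
# edge-list readers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_association_file(
    path: str | Path,
    role: str = "drug-disease",
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
    strict: bool = True,
) -> AssociationMatrix:
    """Read an edge-list TSV into a dense binary matrix.

    Two columns mean every listed pair has value 1; a third column carries
    an explicit ``{0,1}`` value.  Duplicate pairs are deduplicated;
    duplicates with *conflicting* values raise.  When ``row_ids`` /
    ``col_ids`` are given they fix the matrix frame; ids in the file but
    not in the frame raise (``strict``) or are dropped with a warning.
    """
    df = _read_tsv(path)
    if df.shape[1] not in (2, 3):
        raise ValidationError(f"{path}: expected 2 or 3 columns, got {df.shape[1]}")
    rows = df.iloc[:, 0].astype(str)
    cols = df.iloc[:, 1].astype(str)
    if df.shape[1] == 3:
        vals = pd.to_numeric(df.iloc[:, 2], errors="coerce")
        if vals.isna().any() or not vals.isin((0, 1)).all():
            raise ValidationError(f"{path}: third column must be 0/1")
        vals = vals.astype(int)
    else:
        vals = pd.Series(np.ones(len(df), dtype=int))

    pairs: dict[tuple[str, str], int] = {}
    n_dup = 0
    for r, c, v in zip(rows, cols, vals):
        key = (r, c)
        if key in pairs:
            n_dup += 1
            if pairs[key] != v:
                raise ValidationError(f"{path}: conflicting values for pair {key}")
        else:
            pairs[key] = int(v)
    if n_dup:
        logger.info("%s: deduplicated %d repeated pairs", path, n_dup)
    if len(df) == 0:
        warnings.warn(f"{path}: empty association file; matrix is all zero")

    if row_ids is None:
        row_ids = sorted({r for r, _ in pairs})
    if col_ids is None:
        col_ids = sorted({c for _, c in pairs})
    ri = {d: i for i, d in enumerate(row_ids)}
    ci = {d: i for i, d in enumerate(col_ids)}
    values = np.zeros((len(row_ids), len(col_ids)), dtype=np.int8)
    for (r, c), v in pairs.items():
        if r not in ri or c not in ci:
            if strict:
                raise ValidationError(f"{path}: id {(r, c)} not in catalog frame")
            warnings.warn(f"{path}: dropping pair {(r, c)} with unknown id")
            continue
        values[ri[r], ci[c]] = v
    return AssociationMatrix(values, tuple(row_ids), tuple(col_ids), role)


def _load_two_col_map(path: str | Path, multi: bool = False):
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected 2 columns")
    if multi:
        out: dict[str, list[str]] = {}
        for k, v in zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)):
            out.setdefault(k, []).append(v)
        return out
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def load_dataset(paths: Mapping[str, str | Path], strict: bool = False) -> Dataset:
    """Assemble a :class:`Dataset` from a mapping of file locations.

    Recognised keys: ``associations`` (required), ``smiles``,
    ``mesh_trees``, ``side_effects``, ``targets``, ``chemical_profiles``,
    ``corpus``.  The catalog is the lexicographically sorted union of
    drug/disease ids across the primary files; entities appearing only in
    auxiliary profile files (side effects, targets) stay profile columns.
    """
    if "associations" not in paths:
        raise ValidationError("paths must include 'associations'")
    assoc_raw = load_association_file(paths["associations"], "drug-disease")
    drug_ids = set(assoc_raw.row_ids)
    disease_ids = set(assoc_raw.col_ids)

    smiles = _load_two_col_map(paths["smiles"]) if "smiles" in paths else {}
    mesh = _load_two_col_map(paths["mesh_trees"], multi=True) if "mesh_trees" in paths else {}
    drug_ids |= set(smiles)
    disease_ids |= set(mesh)

    aux: dict[str, AssociationMatrix | None] = {}
    for key, role in (
        ("side_effects", "drug-side-effect"),
        ("targets", "drug-target"),
        ("chemical_profiles", "drug-substructure"),
    ):
        if key in paths:
            a = load_association_file(paths[key], role)
            drug_ids |= set(a.row_ids)
            aux[key] = a
        else:
            aux[key] = None

    catalog = EntityCatalog(tuple(sorted(drug_ids)), tuple(sorted(disease_ids)))
    associations = load_association_file(
        paths["associations"], "drug-disease",
        row_ids=catalog.drug_ids, col_ids=catalog.disease_ids, strict=strict,
    )
    # re-frame auxiliary matrices onto the full drug catalog (zero rows for
    # drugs with no records; the profile-column ids keep their own order)
    for key in ("side_effects", "targets", "chemical_profiles"):
        a = aux[key]
        if a is not None:
            aux[key] = load_association_file(
                paths[key], a.role, row_ids=catalog.drug_ids, col_ids=a.col_ids,
                strict=strict,
            )

    corpus = _load_two_col_map(paths["corpus"]) if "corpus" in paths else {}

    ds = Dataset(
        catalog=catalog,
        associations=associations,
        smiles=smiles,
        mesh_trees={k: list(v) for k, v in mesh.items()},
        side_effects=aux["side_effects"],
        targets=aux["targets"],
        chemical_profiles=aux["chemical_profiles"],
        corpus=corpus,
    )
    flagged = ds.flagged_entities()
    for what, ids in flagged.items():
        if ids:
            logger.warning("%s: %d entities (%s...)", what, len(ids), ids[:3])
    return ds


# ---------------------------------------------------------------------------
# similarity matrix I/O


def write_similarity(matrix, path: str | Path) -> None:
    """Write a square labelled similarity matrix as TSV (ids on both axes)."""
    from .similarity import SimilarityMatrix  # local import, avoids cycle

    if not isinstance(matrix, SimilarityMatrix):
        raise ValidationError("write_similarity expects a SimilarityMatrix")
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def read_similarity(path: str | Path, labels: Sequence[str], measure: str = "fused"):
    """Read a similarity TSV and re-index it to the canonical label order.

    The file's id set must equal ``labels`` as a set; row/column order in
    the file is permitted to differ and is repaired here.
    """
    from .similarity import SimilarityMatrix

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if set(df.index) != set(labels) or set(df.columns) != set(labels):
        raise ValidationError(f"{path}: header ids do not match the catalog")
    df = df.loc[list(labels), list(labels)]
    return SimilarityMatrix(df.to_numpy(dtype=float), tuple(labels), measure)


# ---------------------------------------------------------------------------
# dataset writer (used by the synthetic generator and the CLI)


def _write_edges(path: Path, a: AssociationMatrix, header: tuple[str, str]) -> None:
    idx = np.argwhere(a.values == 1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for i, j in idx:
            fh.write(f"{a.row_ids[i]}\t{a.col_ids[j]}\n")


def write_dataset(ds: Dataset, out_dir: str | Path, manifest: dict | None = None) -> dict[str, Path]:
    """Emit a dataset as the standard TSV file set; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["associations"] = out / "associations.tsv"
    _write_edges(paths["associations"], ds.associations, ("drug_id", "disease_id"))
    if ds.smiles:
        paths["smiles"] = out / "smiles.tsv"
        pd.DataFrame(
            {"drug_id": list(ds.smiles), "smiles": list(ds.smiles.values())}
        ).to_csv(paths["smiles"], sep="\t", index=False)
    if ds.mesh_trees:
        paths["mesh_trees"] = out / "mesh_trees.tsv"
        rows = [(d, t) for d, trees in ds.mesh_trees.items() for t in trees]
        pd.DataFrame(rows, columns=["disease_id", "tree_number"]).to_csv(
            paths["mesh_trees"], sep="\t", index=False
        )
    for key, attr, header in (
        ("side_effects", ds.side_effects, ("drug_id", "side_effect_id")),
        ("targets", ds.targets, ("drug_id", "target_id")),
        ("chemical_profiles", ds.chemical_profiles, ("drug_id", "substructure_id")),
    ):
        if attr is not None:
            paths[key] = out / f"{key}.tsv"
            _write_edges(paths[key], attr, header)
    if ds.corpus:
        paths["corpus"] = out / "corpus.tsv"
        pd.DataFrame(
            {"entity_id": list(ds.corpus), "text": list(ds.corpus.values())}
        ).to_csv(paths["corpus"], sep="\t", index=False)
    if manifest is not None:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
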