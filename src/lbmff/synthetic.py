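"""Self-contained synthetic datasets with planted block structure.

The generator makes the method's core premise literal: drugs that share
profiles treat diseases that share ancestry.  Drugs and diseases are
assigned to ``b`` latent blocks; a drug-disease association fires with
probability ``p_in`` when their blocks match and ``p_out`` otherwise.
Every similarity source is tied to the same blocks at a tunable
informativeness ``rho``:

* profile measures (chemical substructures, side effects, targets) give
  each entity its block's random prototype bit-vector with per-bit flip
  probability (1 - rho)/2, so profile Jaccard similarity tracks block
  co-membership with strength rho;
* disease tree numbers are paths through a block-rooted hierarchy, so
  the DAG semantic similarity is high within blocks;
* corpus texts draw tokens from a block vocabulary with probability rho
  and from a shared noise vocabulary otherwise.

At ``rho=0`` a measure carries no block signal at all; at ``rho=1`` it
is noiseless.  Everything is emitted in the standard on-disk formats, so
generated datasets exercise the exact I/O paths real extracts would.
"""

from __future__ import annotations


from dataclasses import dataclass, asdict, replace as dc_replace

import numpy as np

from .io_data import AssociationMatrix, Dataset, EntityCatalog, ValidationError

__all__ = ["SyntheticSpec", "generate", "degrade_measure", "shuffle_associations"]

PROFILE_MEASURES = ("chemical", "side_effect", "target")
ALL_MEASURES = PROFILE_MEASURES + ("mesh", "corpus")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters; all of them are recorded in the manifest."""

    m: int = 20                  # drugs
    n: int = 30                  # diseases
    b: int = 2                   # latent blocks
    p_in: float = 0.9            # association probability, matched blocks
    p_out: float = 0.02          # association probability, otherwise
    rho: dict[str, float] | float = 0.8   # per-measure informativeness
    n_chemical_bits: int = 64
    n_side_effects: int = 40
    n_targets: int = 30
    dag_depth: int = 3
    vocab_size: int = 60         # block-specific tokens per block
    noise_vocab_size: int = 120
    tokens_per_entity: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValidationError("need 0 <= p_out < p_in <= 1")
        if not (1 <= self.b <= min(self.m, self.n)):
            raise ValidationError("need 1 <= b <= min(m, n)")
        for k, r in self.rho_map().items():
            if not (0 <= r <= 1):
                raise ValidationError(f"rho[{k}] must be in [0, 1]")

    def rho_map(self) -> dict[str, float]:
        if isinstance(self.rho, dict):
            unknown = set(self.rho) - set(ALL_MEASURES)
            if unknown:
                raise ValidationError(f"unknown measures in rho: {sorted(unknown)}")
            return {k: self.rho.get(k, 0.8) for k in ALL_MEASURES}
        return {k: float(self.rho) for k in ALL_MEASURES}


def _block_assignment(count: int, b: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced random assignment: sizes differ by at most one."""
    blocks = np.arange(count) % b
    return blocks[rng.permutation(count)]


def _profile_matrix(
    blocks: np.ndarray, nbits: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    prototypes = rng.integers(0, 2, size=(blocks.max() + 1, nbits))
    profiles = prototypes[blocks]
    flips = rng.random(profiles.shape) < (1.0 - rho) / 2.0
    return np.where(flips, 1 - profiles, profiles).astype(np.int8)


def generate(spec: SyntheticSpec) -> tuple[Dataset, dict[str, np.ndarray]]:
    """Draw one dataset; returns it with the ground-truth block labels."""
    rng = np.random.default_rng(spec.seed)
    rho = spec.rho_map()

    drug_ids = tuple(f"DR{i:03d}" for i in range(spec.m))
    disease_ids = tuple(f"DZ{j:03d}" for j in range(spec.n))
    catalog = EntityCatalog(drug_ids, disease_ids)

    drug_blocks = _block_assignment(spec.m, spec.b, rng)
    disease_blocks = _block_assignment(spec.n, spec.b, rng)

    matched = drug_blocks[:, None] == disease_blocks[None, :]
    p = np.where(matched, spec.p_in, spec.p_out)
    A = (rng.random((spec.m, spec.n)) < p).astype(np.int8)
    if A.sum() == 0:
        raise ValidationError("spec produced an all-zero association matrix")

    def profile(measure: str, nbits: int, sub_id: str) -> AssociationMatrix:
        prof = _profile_matrix(drug_blocks, nbits, rho[measure], rng)
        cols = tuple(f"{sub_id}{k:03d}" for k in range(nbits))
        return AssociationMatrix(prof, drug_ids, cols, f"drug-{measure}")

    chemical = profile("chemical", spec.n_chemical_bits, "FP")
    side_effects = profile("side_effect", spec.n_side_effects, "SE")
    targets = profile("target", spec.n_targets, "TG")

    # block-rooted MeSH-like trees: root B{k}, a shared subgroup level,
    # then the disease's own leaf.  With prob 1 - rho the whole path is
    # drawn from a uniformly random block instead of the disease's own.
    mesh_trees: dict[str, list[str]] = {}
    for j, d in enumerate(disease_ids):
        blk = disease_blocks[j] if rng.random() < rho["mesh"] else rng.integers(spec.b)
        parts = [f"B{blk}"]
        for depth in range(1, spec.dag_depth - 1):
            parts.append(f"S{blk}x{rng.integers(2)}x{depth}")
        parts.append(f"L{j:03d}")
        mesh_trees[d] = [".".join(parts[: spec.dag_depth])]

    block_vocab = [
        [f"tok_b{k}_{t}" for t in range(spec.vocab_size)] for k in range(spec.b)
    ]
    noise_vocab = [f"noise_{t}" for t in range(spec.noise_vocab_size)]
    corpus: dict[str, str] = {}
    for ent, blk in [
        *zip(drug_ids, drug_blocks), *zip(disease_ids, disease_blocks)
    ]:
        r = rho["corpus"]
        tokens = [
            block_vocab[blk][rng.integers(spec.vocab_size)]
            if rng.random() < r
            else noise_vocab[rng.integers(spec.noise_vocab_size)]
            for _ in range(spec.tokens_per_entity)
        ]
        corpus[ent] = " ".join(tokens)

    ds = Dataset(
        catalog=catalog,
        associations=AssociationMatrix(A, drug_ids, disease_ids, "drug-disease"),
        mesh_trees=mesh_trees,
        side_effects=side_effects,
        targets=targets,
        chemical_profiles=chemical,
        corpus=corpus,
    )
    truth = {
        "drug_blocks": drug_blocks,
        "disease_blocks": disease_blocks,
        "spec": asdict(spec),
    }
    return ds, truth


def degrade_measure(
    dataset: Dataset, measure: str, mode: str = "shuffle", seed: int = 0
) -> Dataset:
    """Destroy one measure's block signal while keeping its marginals.

    ``shuffle`` permutes whole entity profiles between entities (the
    off-diagonal similarity distribution is unchanged as a multiset);
    ``zero`` empties the profiles, collapsing to the empty-profile
    convention.  Returns a new dataset; the input is untouched.
    """
    rng = np.random.default_rng(seed)
    ds = dc_replace(dataset)

    def permuted(a: AssociationMatrix) -> AssociationMatrix:
        perm = rng.permutation(a.values.shape[0])
        vals = np.zeros_like(a.values) if mode == "zero" else a.values[perm]
        return AssociationMatrix(vals, a.row_ids, a.col_ids, a.role)

    if mode not in ("shuffle", "zero"):
        raise ValidationError(f"unknown degradation mode {mode!r}")
    if measure == "chemical" and dataset.chemical_profiles is not None:
        ds.chemical_profiles = permuted(dataset.chemical_profiles)
    elif measure == "side_effect" and dataset.side_effects is not None:
        ds.side_effects = permuted(dataset.side_effects)
    elif measure == "target" and dataset.targets is not None:
        ds.targets = permuted(dataset.targets)
    elif measure == "mesh" and dataset.mesh_trees:
        keys = list(dataset.mesh_trees)
        if mode == "zero":
            ds.mesh_trees = {k: [] for k in keys}
        else:
            perm = rng.permutation(len(keys))
            ds.mesh_trees = {keys[i]: dataset.mesh_trees[keys[int(p)]] for i, p in enumerate(perm)}
    elif measure == "corpus" and dataset.corpus:
        keys = list(dataset.corpus)
        if mode == "zero":
            ds.corpus = {k: "" for k in keys}
        else:
            perm = rng.permutation(len(keys))
            ds.corpus = {keys[i]: dataset.corpus[keys[int(p)]] for i, p in enumerate(perm)}
    else:
        raise ValidationError(f"measure {measure!r} not present in dataset")
    return ds


def shuffle_associations(dataset: Dataset, seed: int = 0) -> Dataset:
    """Null control: permute all association cells, destroying structure."""
    rng = np.random.default_rng(seed)
    flat = dataset.associations.values.flatten()
    shuffled = flat[rng.permutation(flat.size)].reshape(dataset.associations.shape)
    ds = dc_replace(dataset)
    ds.associations = AssociationMatrix(
        shuffled,
        dataset.associations.row_ids,
        dataset.associations.col_ids,
        dataset.associations.role,
    )
    return ds
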