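"""Atom-order shuffling and the one-molecule-to-many-images expansion.

The image encoder is *not* permutation invariant: reordering a molecule's
atoms permutes the rows and columns of every descriptor matrix and so
produces a different (but equally valid) image.  Rather than fighting
this, the method exploits it — drawing a fresh atom ordering per emitted
image turns each molecule into ``k`` distinct training points while every
copy keeps the molecule's label.

Four shuffle strategies of increasing entropy (worked on the ordering
``C O1 O2 H1 H2``):

none
    identity — the file order is kept (``C O1 O2 H1 H2``); admits exactly
    one ordering, so ``k > 1`` only duplicates images.
groups
    independent uniform permutation *within each element class*; the
    element occupying every position never changes
    (``C O2 O1 H1 H2``).
partial
    atoms split into heavy (C/O/N/F) and hydrogen groups; uniform
    permutation within each group's position set, never across
    (``O1 O2 C H2 H1``).
full
    uniform permutation of all positions (``O2 C H1 H2 O1``).

Coordinates always travel with their atoms, and labels are never touched.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem_tables import ElementTable, PairParamTable
from .image_encoder import EncodingConfig, encode
from .xyz_io import DatasetManifest, Molecule, write_image, write_manifest

logger = logging.getLogger(__name__)

SHUFFLE_KINDS = ("none", "groups", "partial", "full")
DEFAULT_HEAVY_SET = frozenset({"C", "O", "N", "F"})

#: Above this many distinct orderings, uniqueness is enforced by rejection
#: sampling instead of exhaustive enumeration (collisions are then vanishingly
#: rare anyway).
_ENUMERATION_LIMIT = 20000


@dataclass(frozen=True)
class ShuffleSpec:
    kind: str = "groups"
    heavy_set: frozenset = DEFAULT_HEAVY_SET

    def __post_init__(self):
        if self.kind not in SHUFFLE_KINDS:
            raise ValueError(f"kind must be one of {SHUFFLE_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "heavy_set", frozenset(self.heavy_set))


@dataclass(frozen=True)
class AugmentationPlan:
    """Accounting of the dataset expansion: n molecules x k images each."""

    n_molecules: int
    images_per_molecule: int

    def __post_init__(self):
        if self.n_molecules < 1 or self.images_per_molecule < 1:
            raise ValueError("n_molecules and images_per_molecule must be >= 1")

    @property
    def total_points(self) -> int:
        return self.n_molecules * self.images_per_molecule


def _position_classes(symbols: Sequence[str], spec: ShuffleSpec) -> list[list[int]]:
    """Index sets within which positions may be permuted."""
    n = len(symbols)
    if spec.kind == "none":
        return [[i] for i in range(n)]
    if spec.kind == "full":
        return [list(range(n))]
    if spec.kind == "partial":
        heavy = [i for i, s in enumerate(symbols) if s in spec.heavy_set]
        light = [i for i in range(n) if i not in set(heavy)]
        return [c for c in (heavy, light) if c]
    # groups: one class per element symbol
    classes: dict[str, list[int]] = {}
    for i, s in enumerate(symbols):
        classes.setdefault(s, []).append(i)
    return list(classes.values())


def permutation_for(symbols: Sequence[str], spec: ShuffleSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one atom-order permutation: new position k holds old atom perm[k]."""
    perm = np.arange(len(symbols))
    for cls in _position_classes(symbols, spec):
        cls = np.asarray(cls)
        perm[cls] = perm[cls][rng.permutation(len(cls))]
    return perm


def permute_atoms(mol: Molecule, spec: ShuffleSpec, rng: np.random.Generator) -> Molecule:
    """Reordered copy of ``mol`` per the shuffle strategy; label preserved."""
    if spec.kind == "none":
        return mol
    return mol.permuted(permutation_for(mol.symbols, spec, rng))


def count_distinct_orderings(symbols: Sequence[str], spec: ShuffleSpec) -> int:
    """Number of distinct index permutations the strategy can produce."""
    return math.prod(
        math.factorial(len(c)) for c in _position_classes(symbols, spec)
    )


def _enumerate_permutations(symbols: Sequence[str], spec: ShuffleSpec) -> list[tuple[int, ...]]:
    classes = _position_classes(symbols, spec)
    out = []
    for assignment in itertools.product(
        *(itertools.permutations(c) for c in classes)
    ):
        perm = np.arange(len(symbols))
        for cls, assigned in zip(classes, assignment):
            perm[np.asarray(cls)] = assigned
        out.append(tuple(perm.tolist()))
    return out


def sample_permutations(
    symbols: Sequence[str],
    spec: ShuffleSpec,
    k: int,
    rng: np.random.Generator,
) -> list[tuple[int, ...]]:
    """Draw ``k`` permutations, unique while the strategy admits that many.

    If the molecule admits fewer than ``k`` distinct orderings (small or
    highly symmetric molecules), all distinct orderings are used and the
    remainder are duplicate draws, with a warning.
    """
    distinct = count_distinct_orderings(symbols, spec)
    if distinct >= k and distinct <= _ENUMERATION_LIMIT:
        pool = _enumerate_permutations(symbols, spec)
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in idx]
    if distinct >= k:
        # Astronomically many orderings: rejection-sample, dedupe.
        seen: dict[tuple[int, ...], None] = {}
        while len(seen) < k:
            seen.setdefault(tuple(permutation_for(symbols, spec, rng).tolist()), None)
        return list(seen)
    warnings.warn(
        f"molecule admits only {distinct} distinct orderings under "
        f"{spec.kind!r} shuffle; k={k} will include duplicates",
        stacklevel=2,
    )
    pool = _enumerate_permutations(symbols, spec)
    out = [pool[i] for i in rng.permutation(len(pool))]
    while len(out) < k:
        out.append(pool[int(rng.integers(len(pool)))])
    return out[:k]


def plan_augmentation(
    n_molecules: int, k: int, shuffle_kind: str | None = None
) -> AugmentationPlan:
    """Dataset-size arithmetic: n molecules x k images = n*k data points."""
    if shuffle_kind == "none" and k > 1:
        warnings.warn(
            "k > 1 with shuffle kind 'none' duplicates identical images "
            "(useful only as a control experiment)",
            stacklevel=2,
        )
    return AugmentationPlan(n_molecules=n_molecules, images_per_molecule=k)


def subset_database(
    mols: Sequence[Molecule], denominator: int, rng: np.random.Generator
) -> list[Molecule]:
    """Uniform random 1/N subset (floor(|mols| / N) molecules), seeded."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    size = len(mols) // denominator
    if size == 0:
        raise ValueError(
            f"denominator {denominator} leaves an empty subset of {len(mols)} molecules"
        )
    if denominator == 1:
        return list(mols)
    idx = np.sort(rng.choice(len(mols), size=size, replace=False))
    return [mols[i] for i in idx]


def generate_dataset(
    mols: Sequence[Molecule],
    cfg: EncodingConfig,
    spec: ShuffleSpec,
    k: int,
    rng: np.random.Generator,
    out_dir: str | Path,
    elements: ElementTable,
    params: PairParamTable,
) -> DatasetManifest:
    """Emit ``k`` PNG images per molecule plus a manifest CSV.

    Each image comes from an independent permutation draw (unique per
    molecule while the strategy allows); manifest rows record the source
    molecule, permutation index, label and config fingerprint.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    fingerprint = cfg.fingerprint()
    rows = []
    for mol in mols:
        perms = sample_permutations(mol.symbols, spec, k, rng)
        for p_idx, perm in enumerate(perms):
            shuffled = mol.permuted(perm) if spec.kind != "none" else mol
            img = encode(shuffled, elements, params, cfg, rng, permutation_index=p_idx)
            path = img_dir / f"{mol.id}_p{p_idx}.png"
            write_image(img.pixels, path)
            rows.append(
                {
                    "image_path": str(path),
                    "molecule_id": mol.id,
                    "permutation_index": p_idx,
                    "label": mol.label,
                    "encoding_fingerprint": fingerprint,
                }
            )
    return write_manifest(rows, out_dir / "manifest.csv")
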