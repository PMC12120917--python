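"""Synthetic QM9-like molecules for tests, examples and desk-scale runs.

QM9 itself is a 133,885-molecule quantum-chemistry database (CHONF
composition, up to 9 heavy atoms) that has to be downloaded; nothing in
this package requires it.  This generator emulates its *shape*: molecules
with 1-9 heavy atoms drawn from {C, N, O, F}, hydrogen-completed, with
plausible bond-length geometry and a scalar label in the HOMO-LUMO-gap
range (eV).

Geometry is plausible, not physical: heavy atoms form a random tree
respecting simple valences (C4 N3 O2 F1), bonds get tabulated covalent
lengths with small Gaussian perturbation, directions are random, and any
geometry with two atoms closer than 0.5 Å is rejected and redrawn.  The
encoder consumes only symbols and coordinates, so this suffices for every
downstream test.

The label is an *affine function of a descriptor summary* plus Gaussian
noise — by default ``label = intercept + slope * sum(distance matrix)``.
That summary is invariant under every atom-order shuffle (so augmented
copies keep consistent labels) and, under black-margin fixed-range
encoding, is proportional to the mean red-channel intensity, giving
learning-sanity tests a signal a CNN can recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .descriptors import distance_matrix
from .xyz_io import Molecule, format_xyz, write_labels_csv

VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "H": 1}

#: Approximate single-bond lengths, Å.
BOND_LENGTHS: dict[frozenset, float] = {
    frozenset(p): d
    for p, d in {
        ("C", "C"): 1.54, ("C", "N"): 1.47, ("C", "O"): 1.43, ("C", "F"): 1.35,
        ("N", "N"): 1.45, ("N", "O"): 1.40, ("N", "F"): 1.37,
        ("O", "O"): 1.48, ("O", "F"): 1.42, ("F", "F"): 1.41,
        ("C", "H"): 1.09, ("N", "H"): 1.01, ("O", "H"): 0.96, ("F", "H"): 0.92,
    }.items()
}

MIN_PAIR_DISTANCE = 0.5  # Å; hard floor on any interatomic separation


@dataclass(frozen=True)
class SynthesisConfig:
    """Stated world of the synthetic corpus.

    Defaults give a QM9-flavoured mix: mostly carbon skeletons of 2-9
    heavy atoms with occasional N/O/F, labels around 2-9 eV with 0.05 eV
    observation noise.
    """

    n_molecules: int = 300
    heavy_atom_range: tuple[int, int] = (2, 9)
    element_weights: Mapping[str, float] = field(
        default_factory=lambda: {"C": 0.70, "N": 0.10, "O": 0.15, "F": 0.05}
    )
    bond_length_jitter: float = 0.03  # Å, sd of bond-length perturbation
    label_summary: str = "distance_sum"
    label_intercept: float = 2.0  # eV
    label_slope: float = 0.005  # eV per Å of summed distance entries
    noise_sigma: float = 0.05  # eV

    def __post_init__(self):
        lo, hi = self.heavy_atom_range
        if not (1 <= lo <= hi <= 9):
            raise ValueError("heavy_atom_range must satisfy 1 <= lo <= hi <= 9")
        weights = dict(self.element_weights)
        if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) == 0:
            raise ValueError("element_weights must be non-negative and not all zero")
        unknown = set(weights) - {"C", "N", "O", "F"}
        if unknown:
            raise ValueError(f"heavy elements must be within CNOF, got {sorted(unknown)}")
        if self.label_summary != "distance_sum":
            raise ValueError(f"unknown label_summary {self.label_summary!r}")
        object.__setattr__(self, "element_weights", weights)


def descriptor_summary(mol: Molecule, kind: str = "distance_sum") -> float:
    """The scalar the synthetic label is affine in (shuffle-invariant)."""
    if kind != "distance_sum":
        raise ValueError(f"unknown summary {kind!r}")
    return float(distance_matrix(mol).values.sum())


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _bond_length(a: str, b: str, rng: np.random.Generator, jitter: float) -> float:
    return BOND_LENGTHS[frozenset((a, b))] + rng.normal(0.0, jitter)


def _try_place(
    coords: list[np.ndarray],
    anchor: np.ndarray,
    length: float,
    rng: np.random.Generator,
    tries: int = 60,
) -> np.ndarray | None:
    """A point at ``length`` from ``anchor`` at least MIN_PAIR_DISTANCE from all."""
    for _ in range(tries):
        pos = anchor + length * _random_unit(rng)
        if all(np.linalg.norm(pos - c) > MIN_PAIR_DISTANCE for c in coords):
            return pos
    return None


def generate_molecule(
    cfg: SynthesisConfig, rng: np.random.Generator, mol_id: str = "synth"
) -> Molecule:
    """One synthetic molecule: tree skeleton, hydrogen fill, affine label."""
    elements = list(cfg.element_weights)
    probs = np.array([cfg.element_weights[e] for e in elements], dtype=float)
    probs /= probs.sum()
    lo, hi = cfg.heavy_atom_range

    for _attempt in range(200):
        n_heavy = int(rng.integers(lo, hi + 1))
        symbols = [str(rng.choice(elements, p=probs))]
        coords = [np.zeros(3)]
        degrees = [0]
        ok = True
        for _ in range(n_heavy - 1):
            open_idx = [i for i in range(len(symbols)) if degrees[i] < VALENCE[symbols[i]]]
            if not open_idx:
                ok = False
                break
            parent = int(rng.choice(open_idx))
            sym = str(rng.choice(elements, p=probs))
            pos = _try_place(
                coords, coords[parent],
                _bond_length(symbols[parent], sym, rng, cfg.bond_length_jitter), rng,
            )
            if pos is None:
                ok = False
                break
            symbols.append(sym)
            coords.append(pos)
            degrees.append(1)
            degrees[parent] += 1
        if not ok:
            continue
        # Hydrogen completion of every open valence.
        n_heavy_final = len(symbols)
        for i in range(n_heavy_final):
            for _h in range(VALENCE[symbols[i]] - degrees[i]):
                pos = _try_place(
                    coords, coords[i],
                    _bond_length(symbols[i], "H", rng, cfg.bond_length_jitter), rng,
                )
                if pos is None:
                    ok = False
                    break
                symbols.append("H")
                coords.append(pos)
            if not ok:
                break
        if not ok:
            continue
        mol = Molecule(id=mol_id, symbols=tuple(symbols), coords=np.array(coords))
        label = (
            cfg.label_intercept
            + cfg.label_slope * descriptor_summary(mol, cfg.label_summary)
            + rng.normal(0.0, cfg.noise_sigma)
        )
        return mol.with_label(float(label))
    raise RuntimeError("failed to generate a valid molecule in 200 attempts")


def generate_molecules(cfg: SynthesisConfig, rng: np.random.Generator) -> list[Molecule]:
    return [
        generate_molecule(cfg, rng, mol_id=f"synth{i:05d}")
        for i in range(cfg.n_molecules)
    ]


def generate_corpus(
    cfg: SynthesisConfig, rng: np.random.Generator, out_dir: str | Path
) -> list[Molecule]:
    """Write plain-xyz fixtures plus a ``labels.csv`` keyed by molecule id."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mols = generate_molecules(cfg, rng)
    labels = {}
    for mol in mols:
        (out_dir / f"{mol.id}.xyz").write_text(
            format_xyz(mol, comment=f"synthetic molecule {mol.id}")
        )
        labels[mol.id] = mol.label
    write_labels_csv(labels, out_dir / "labels.csv")
    return mols
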