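"""Symmetric per-molecule descriptor matrices.

Each descriptor maps an N-atom molecule to a symmetric ``N x N`` real
matrix; the image encoder later normalizes these to [0, 255] and stacks
them into colour channels.

Off-diagonal (pair) descriptors
    * Euclidean interatomic distance ``R_ij`` (Å), zero diagonal.
    * Coulomb matrix ``Z_i Z_j / R_ij``; the *full* variant carries
      ``0.5 Z_i^2.4`` on the diagonal, the *reduced* variant a zero
      diagonal.
    * Uncorrected ReaxFF bond order
      ``BO'_ij = BO_sigma + BO_pi + BO_pipi`` with each term
      ``exp[pbo_odd * (r_ij / r0)^pbo_even]``; a term whose reference
      radius is the -1 sentinel (any r0 <= 0) contributes exactly 0, and a
      pair absent from the parameter table yields BO' = 0 with a warning.
      No cutoff, taper or overcoordination correction is applied — only
      the raw pairwise primitive.

Diagonal (atom) descriptors
    First ionization energy (eV) and atomic number Z, zero off-diagonal.

All matrices are exactly symmetric and permutation-equivariant: reordering
the atoms permutes rows and columns identically, bit for bit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .chem_tables import ElementTable, PairParamTable, load_element_table
from .xyz_io import Molecule

logger = logging.getLogger(__name__)

PROPERTY_TAGS = (
    "distance",
    "coulomb_full",
    "coulomb_reduced",
    "bond_order",
    "ionization_diag",
    "atomic_number_diag",
)

#: Exponent of the Coulomb-matrix diagonal term 0.5 * Z**2.4.
COULOMB_DIAG_EXPONENT = 2.4


class DegenerateGeometryError(ValueError):
    """Two distinct atoms coincide (R_ij = 0 for i != j)."""


@dataclass(frozen=True)
class DescriptorMatrix:
    values: np.ndarray
    property_tag: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.property_tag not in PROPERTY_TAGS:
            raise ValueError(f"unknown property_tag {self.property_tag!r}")
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"descriptor matrix must be square, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("descriptor matrix must be finite")
        if not np.array_equal(v, v.T):
            raise ValueError("descriptor matrix must be exactly symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _pairwise_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    # (x_i - x_j)**2 == (x_j - x_i)**2 bit-exactly, so this is symmetric.
    # Components are added left-to-right so the result matches a scalar
    # evaluation of dx^2 + dy^2 + dz^2 to the last bit.
    sq = diff * diff
    return np.sqrt(sq[..., 0] + sq[..., 1] + sq[..., 2])


def distance_matrix(mol: Molecule) -> DescriptorMatrix:
    """Euclidean pairwise distances in Å; the diagonal is exactly 0."""
    return DescriptorMatrix(_pairwise_distances(mol.coords), "distance")


def coulomb_matrix(
    mol: Molecule,
    mode: str = "full",
    elements: ElementTable | None = None,
) -> DescriptorMatrix:
    """Coulomb matrix: ``Z_i Z_j / R_ij`` off-diagonal.

    ``mode="full"`` puts ``0.5 * Z_i**2.4`` on the diagonal; ``"reduced"``
    zeroes it (the diagonal terms are numerically much larger than the
    off-diagonal ones and can dominate the later [0, 255] scaling).
    """
    if mode not in ("full", "reduced"):
        raise ValueError(f"mode must be 'full' or 'reduced', got {mode!r}")
    elements = elements or load_element_table()
    z = np.array([elements.lookup(s).Z for s in mol.symbols], dtype=float)
    r = _pairwise_distances(mol.coords)
    n = mol.n_atoms
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] == 0.0):
        i, j = np.argwhere((r == 0.0) & off)[0]
        raise DegenerateGeometryError(
            f"atoms {i} and {j} coincide; Coulomb matrix undefined"
        )
    m = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        m[off] = (z[:, None] * z[None, :])[off] / r[off]
    if mode == "full":
        np.fill_diagonal(m, 0.5 * z**COULOMB_DIAG_EXPONENT)
    tag = "coulomb_full" if mode == "full" else "coulomb_reduced"
    return DescriptorMatrix(m, tag)


def _bond_order_term(r: np.ndarray, r0: float, pbo_odd: float, pbo_even: float) -> np.ndarray:
    """One sigma/pi/pipi term; r0 <= 0 (the -1 sentinel) disables it."""
    if r0 <= 0.0:
        return np.zeros_like(r)
    return np.exp(pbo_odd * (r / r0) ** pbo_even)


def bond_order_pair(r: float, params) -> float:
    """Scalar uncorrected bond order BO' for one pair at separation ``r``."""
    return float(
        _bond_order_term(np.asarray(r), params.r0_sigma, params.pbo1, params.pbo2)
        + _bond_order_term(np.asarray(r), params.r0_pi, params.pbo3, params.pbo4)
        + _bond_order_term(np.asarray(r), params.r0_pipi, params.pbo5, params.pbo6)
    )


def bond_order_matrix(mol: Molecule, params: PairParamTable) -> DescriptorMatrix:
    """Uncorrected ReaxFF bond order BO' for every atom pair; zero diagonal.

    Pairs missing from ``params`` contribute 0 and emit a warning once per
    call per element pair.
    """
    n = mol.n_atoms
    r = _pairwise_distances(mol.coords)
    m = np.zeros((n, n))
    warned: set[frozenset] = set()
    for i in range(n):
        for j in range(i + 1, n):
            p = params.lookup(mol.symbols[i], mol.symbols[j])
            if p is None:
                key = frozenset((mol.symbols[i], mol.symbols[j]))
                if key not in warned:
                    warned.add(key)
                    msg = (
                        f"no bond-order parameters for pair "
                        f"{mol.symbols[i]}-{mol.symbols[j]}; using BO'=0"
                    )
                    logger.warning(msg)
                    warnings.warn(msg, stacklevel=2)
                continue
            m[i, j] = m[j, i] = bond_order_pair(r[i, j], p)
    return DescriptorMatrix(m, "bond_order")


def ionization_diag(mol: Molecule, elements: ElementTable | None = None) -> DescriptorMatrix:
    """Diagonal matrix of first ionization energies (eV); zero off-diagonal."""
    elements = elements or load_element_table()
    vals = [elements.lookup(s).ionization_energy for s in mol.symbols]
    return DescriptorMatrix(np.diag(vals), "ionization_diag")


def atomic_number_diag(mol: Molecule, elements: ElementTable | None = None) -> DescriptorMatrix:
    """Diagonal matrix of atomic numbers Z; zero off-diagonal."""
    elements = elements or load_element_table()
    vals = [float(elements.lookup(s).Z) for s in mol.symbols]
    return DescriptorMatrix(np.diag(vals), "atomic_number_diag")
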