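"""Reading and writing molecular structures, images and dataset manifests.

The unit of work everywhere in this package is a :class:`Molecule`: an
*ordered* list of atoms (element symbols plus Cartesian coordinates in Å)
with an optional scalar label (for QM9-style data the HOMO-LUMO gap, in eV).
Atom order matters: the image encoder writes atom ``i`` into row/column
``i`` of every descriptor matrix, so two orderings of the same structure
produce different images.  Parsing therefore preserves file order exactly.

Two xyz dialects are supported:

``plain``
    count line, free-form comment line, then ``symbol x y z`` rows.
``qm9``
    the extended-xyz flavour used by the QM9 distribution, whose comment
    line is a whitespace-separated list of scalar properties.  Which field
    holds the HOMO-LUMO gap, and its unit, vary between redistributions,
    so both are configurable (``gap_field``, ``gap_unit``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

#: Elements the descriptor tables cover (QM9 composition space).
SUPPORTED_ELEMENTS = ("H", "C", "N", "O", "F")

#: CODATA value used to convert hartree-valued labels to eV.
HARTREE_TO_EV = 27.211386245988

MANIFEST_COLUMNS = (
    "image_path",
    "molecule_id",
    "permutation_index",
    "label",
    "encoding_fingerprint",
)


class XyzParseError(ValueError):
    """Malformed xyz content (count mismatch, bad numeric field, ...)."""


class UnsupportedElementError(ValueError):
    """An element symbol outside the supported set was encountered."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(
            f"unsupported element symbol {symbol!r}; supported: "
            f"{', '.join(SUPPORTED_ELEMENTS)}"
        )


@dataclass(frozen=True)
class Molecule:
    """Ordered atoms with optional scalar label.

    Attributes
    ----------
    id:
        Free-form identifier (file stem, corpus index, ...).
    symbols:
        Element symbols in order, length ``N >= 1``.
    coords:
        ``(N, 3)`` Cartesian coordinates in Å.
    label:
        Optional scalar target (HOMO-LUMO gap, eV).
    """

    id: str
    symbols: tuple[str, ...]
    coords: np.ndarray
    label: float | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        if len(self.symbols) < 1:
            raise ValueError("molecule must contain at least one atom")
        if coords.shape != (len(self.symbols), 3):
            raise ValueError(
                f"coords shape {coords.shape} inconsistent with "
                f"{len(self.symbols)} symbols"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        for sym in self.symbols:
            if sym not in SUPPORTED_ELEMENTS:
                raise UnsupportedElementError(sym)
        if self.label is not None and not np.isfinite(self.label):
            raise ValueError("label must be finite when present")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def with_label(self, label: float | None) -> "Molecule":
        return replace(self, label=label)

    def permuted(self, perm: Sequence[int], suffix: str = "") -> "Molecule":
        """Reorder atoms so new position ``k`` holds old atom ``perm[k]``."""
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(self.n_atoms)):
            raise ValueError("perm must be a permutation of atom indices")
        return Molecule(
            id=self.id + suffix,
            symbols=tuple(self.symbols[i] for i in perm),
            coords=self.coords[perm],
            label=self.label,
        )


def parse_xyz(
    text: str,
    dialect: str = "plain",
    *,
    mol_id: str = "mol",
    gap_field: int = 9,
    gap_unit: str = "hartree",
) -> Molecule:
    """Parse xyz ``text`` into a :class:`Molecule`.

    Parameters
    ----------
    dialect:
        ``"plain"`` ignores the comment line; ``"qm9"`` reads the scalar
        at 0-based whitespace-token index ``gap_field`` of the comment line
        as the label.  QM9 atom rows may carry extra per-atom columns
        (Mulliken charges); columns beyond ``symbol x y z`` are ignored.
    gap_field, gap_unit:
        Redistributions of QM9 differ in their comment-line layout, so both
        are configuration, not convention.  The defaults match the original
        distribution: ``tag index A B C mu alpha homo lumo gap ...`` puts
        the HOMO-LUMO gap at token 9, in hartree.
    gap_unit:
        ``"ev"`` or ``"hartree"`` (converted to eV via 27.211386...).
    """
    if dialect not in ("plain", "qm9"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = text.splitlines()
    if not lines:
        raise XyzParseError("empty xyz content")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise XyzParseError(f"first line is not an atom count: {lines[0]!r}") from exc
    if len(lines) < n + 2:
        raise XyzParseError(f"file declares {n} atoms but has {max(len(lines) - 2, 0)} atom lines")

    label = None
    if dialect == "qm9":
        fields = lines[1].split()
        if gap_field >= len(fields):
            raise XyzParseError(
                f"comment line has {len(fields)} fields; gap_field={gap_field} out of range"
            )
        try:
            # QM9 uses Fortran-style exponents ('1.23*^-4') in some mirrors.
            label = float(fields[gap_field].replace("*^", "e"))
        except ValueError as exc:
            raise XyzParseError(f"gap field {fields[gap_field]!r} is not numeric") from exc
        if gap_unit == "hartree":
            label *= HARTREE_TO_EV
        elif gap_unit != "ev":
            raise ValueError(f"unknown gap_unit {gap_unit!r}")

    symbols: list[str] = []
    coords: list[list[float]] = []
    for lineno, line in enumerate(lines[2 : 2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise XyzParseError(f"line {lineno}: expected 'symbol x y z', got {line!r}")
        sym = parts[0]
        if sym not in SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(sym)
        try:
            xyz = [float(p.replace("*^", "e")) for p in parts[1:4]]
        except ValueError as exc:
            raise XyzParseError(f"line {lineno}: non-numeric coordinate in {line!r}") from exc
        symbols.append(sym)
        coords.append(xyz)
    # Trailing non-blank lines after the declared atoms indicate a count
    # mismatch (unless they are QM9 frequency/SMILES footer lines, which a
    # plain-dialect caller will not have).
    if dialect == "plain":
        for extra in lines[2 + n :]:
            if extra.strip():
                raise XyzParseError(f"file declares {n} atoms but more atom lines follow: {extra!r}")
    return Molecule(id=mol_id, symbols=tuple(symbols), coords=np.array(coords), label=label)


def format_xyz(mol: Molecule, comment: str = "", precision: int = 8) -> str:
    """Serialize ``mol`` to plain xyz (inverse of :func:`parse_xyz`)."""
    out = [str(mol.n_atoms), comment]
    for sym, (x, y, z) in zip(mol.symbols, mol.coords):
        out.append(f"{sym} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}")
    return "\n".join(out) + "\n"


def read_xyz_file(path: str | Path, dialect: str = "plain", **kw) -> Molecule:
    path = Path(path)
    return parse_xyz(path.read_text(), dialect, mol_id=kw.pop("mol_id", path.stem), **kw)


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write an ``(S, S, 3)`` array of values in [0, 255] as 8-bit RGB PNG.

    Float inputs are rounded half-up; read-back equals the quantized input
    exactly (PNG is lossless).
    """
    arr = np.asarray(pixels)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected (S, S, 3) array, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(
            f"pixel values must lie in [0, 255]; got range [{arr.min()}, {arr.max()}]"
        )
    if arr.dtype != np.uint8:
        arr = np.floor(arr + 0.5).astype(np.uint8)  # round half up
    Image.fromarray(arr, mode="RGB").save(str(path), format="PNG")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG written by :func:`write_image` back to uint8 ``(S, S, 3)``."""
    with Image.open(str(path)) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


@dataclass
class DatasetManifest:
    """Tabular index of generated images: one row per emitted image."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    )

    def __post_init__(self):
        missing = set(MANIFEST_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        self.rows = self.rows[list(MANIFEST_COLUMNS)].reset_index(drop=True)
        if self.rows["image_path"].duplicated().any():
            dup = self.rows["image_path"][self.rows["image_path"].duplicated()].iloc[0]
            raise ValueError(f"duplicate image_path in manifest: {dup!r}")

    def __len__(self) -> int:
        return len(self.rows)


def write_manifest(rows: Iterable[dict] | pd.DataFrame, path: str | Path) -> DatasetManifest:
    """Validate ``rows`` and write them as a headered CSV; returns the manifest."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows), columns=list(MANIFEST_COLUMNS))
    manifest = DatasetManifest(df)
    manifest.rows.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
    return manifest


def read_manifest(path: str | Path) -> DatasetManifest:
    df = pd.read_csv(path, dtype={"image_path": str, "molecule_id": str, "encoding_fingerprint": str})
    if df.empty:
        df = pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    return DatasetManifest(df)


def write_labels_csv(labels: dict[str, float], path: str | Path) -> None:
    """Write a molecule-id -> label table (first-class alternative to qm9 comment lines)."""
    pd.DataFrame(
        {"molecule_id": list(labels.keys()), "label": list(labels.values())}
    ).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, dtype={"molecule_id": str})
    return dict(zip(df["molecule_id"], df["label"].astype(float)))
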