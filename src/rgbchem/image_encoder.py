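"""Turn descriptor matrices into fixed-size three-channel images.

Pipeline (in this order): compute the descriptor matrices for the
molecule's current atom order, normalize each property onto [0, 255],
compose them into the red/green/blue planes of one of the six generation
types A-F, then unify the image size to ``S x S`` with a margin policy
(bilinear resize, black fill, or channel-average fill; block placed at a
fixed top-left or a random offset).  Normalization happens *before*
margin filling, so the average fill equals the mean of the normalized
molecular block.

Generation types (off-diagonal properties in the cells ``i != j``,
diagonal properties in ``i == j``):

====  =========================  ====================  =======================
type  red                        green                 blue
====  =========================  ====================  =======================
A     distance + ionization      reduced Coulomb       bond order
B     distance + ionization      full Coulomb          bond order
C     distance                   reduced Coulomb       bond order
D     distance                   reduced Coulomb       bond order + atomic no.
E     ionization                 full Coulomb          atomic number
F     distance + ionization      full Coulomb          atomic number
====  =========================  ====================  =======================

Any two types adjacent in this family differ in exactly one colour plane,
which the tests assert as the "channel-identity lattice".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .chem_tables import ElementTable, PairParamTable
from .descriptors import (
    atomic_number_diag,
    bond_order_matrix,
    coulomb_matrix,
    distance_matrix,
    ionization_diag,
)
from .xyz_io import Molecule

GEN_TYPES = ("A", "B", "C", "D", "E", "F")

# Channel layout per generation type: each channel is a list of
# (property_tag, placement) with placement "both" (single property filling
# the whole plane), "offdiag" or "diag" (combined channels).
CHANNEL_LAYOUTS: dict[str, tuple[tuple[tuple[str, str], ...], ...]] = {
    "A": (
        (("distance", "offdiag"), ("ionization_diag", "diag")),
        (("coulomb_reduced", "both"),),
        (("bond_order", "both"),),
    ),
    "B": (
        (("distance", "offdiag"), ("ionization_diag", "diag")),
        (("coulomb_full", "both"),),
        (("bond_order", "both"),),
    ),
    "C": (
        (("distance", "both"),),
        (("coulomb_reduced", "both"),),
        (("bond_order", "both"),),
    ),
    "D": (
        (("distance", "both"),),
        (("coulomb_reduced", "both"),),
        (("bond_order", "offdiag"), ("atomic_number_diag", "diag")),
    ),
    "E": (
        (("ionization_diag", "both"),),
        (("coulomb_full", "both"),),
        (("atomic_number_diag", "both"),),
    ),
    "F": (
        (("distance", "offdiag"), ("ionization_diag", "diag")),
        (("coulomb_full", "both"),),
        (("atomic_number_diag", "both"),),
    ),
}


class ConfigError(ValueError):
    pass


class CanvasSizeError(ValueError):
    """Molecule too large for the canvas in a non-resize margin mode."""


@dataclass(frozen=True)
class EncodingConfig:
    """Every knob of the molecule-to-image encoding.

    Attributes
    ----------
    gen_type:
        Channel layout, one of A-F (see module docstring).
    canvas_size:
        Output side length S in pixels (the study sweeps 32-48).
    margin_mode:
        "resize" (bilinear), "black" (zero fill) or "average" (fill with
        the per-channel mean of the molecular block).
    offset_mode:
        "fixed" (top-left) or "random"; must be "fixed" under resize,
        where positioning is not applicable.
    normalization:
        "per_image" maps each property's observed min/max to 0/255
        (constant matrices map to 0); "fixed" uses ``fixed_ranges`` per
        property tag with clipping.
    fixed_ranges:
        property tag -> (lo, hi), required for every property in the
        layout when normalization="fixed".
    combined_joint_norm:
        If True, a combined channel (e.g. distance + ionization) is
        normalized jointly over both properties instead of independently.
    quantize:
        Round half-up to uint8 at emission (default; matches PNG output).
    """

    gen_type: str = "A"
    canvas_size: int = 32
    margin_mode: str = "black"
    offset_mode: str = "fixed"
    normalization: str = "per_image"
    fixed_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    combined_joint_norm: bool = False
    quantize: bool = True

    def __post_init__(self):
        if self.gen_type not in GEN_TYPES:
            raise ConfigError(f"gen_type must be one of {GEN_TYPES}, got {self.gen_type!r}")
        if self.canvas_size < 1:
            raise ConfigError("canvas_size must be >= 1")
        if self.margin_mode not in ("resize", "black", "average"):
            raise ConfigError(f"unknown margin_mode {self.margin_mode!r}")
        if self.offset_mode not in ("fixed", "random"):
            raise ConfigError(f"unknown offset_mode {self.offset_mode!r}")
        if self.margin_mode == "resize" and self.offset_mode != "fixed":
            raise ConfigError("offset_mode must be 'fixed' when margin_mode='resize'")
        if self.normalization not in ("per_image", "fixed"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        object.__setattr__(self, "fixed_ranges", dict(self.fixed_ranges))

    def fingerprint(self) -> str:
        """Short stable hash of the full configuration."""
        payload = json.dumps(
            {
                "gen_type": self.gen_type,
                "canvas_size": self.canvas_size,
                "margin_mode": self.margin_mode,
                "offset_mode": self.offset_mode,
                "normalization": self.normalization,
                "fixed_ranges": sorted(
                    (k, list(v)) for k, v in self.fixed_ranges.items()
                ),
                "combined_joint_norm": self.combined_joint_norm,
                "quantize": self.quantize,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class ImageTensor:
    """An ``(S, S, 3)`` image in [0, 255] plus provenance."""

    pixels: np.ndarray
    molecule_id: str
    permutation_index: int = 0
    fingerprint: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[0] != px.shape[1] or px.shape[2] != 3:
            raise ValueError(f"pixels must be (S, S, 3), got {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixels must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)


def normalize_matrix(
    values: np.ndarray,
    scheme: str = "per_image",
    fixed_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Affine-map a finite matrix onto [0, 255].

    per_image: observed min -> 0, max -> 255; a constant matrix maps to 0.
    fixed: ``255 * (v - lo) / (hi - lo)`` clipped to [0, 255].
    """
    v = np.asarray(values, dtype=float)
    if scheme == "per_image":
        lo, hi = float(v.min()), float(v.max())
        if hi == lo:
            return np.zeros_like(v)
    elif scheme == "fixed":
        if fixed_range is None:
            raise ConfigError("fixed normalization requires a (lo, hi) range")
        lo, hi = fixed_range
        if hi <= lo:
            raise ConfigError(f"fixed range must have hi > lo, got ({lo}, {hi})")
    else:
        raise ConfigError(f"unknown normalization scheme {scheme!r}")
    # Divide before scaling so the observed max maps to exactly 255.
    return np.clip((v - lo) / (hi - lo) * 255.0, 0.0, 255.0)


def _descriptor_values(
    tag: str,
    mol: Molecule,
    elements: ElementTable,
    params: PairParamTable,
) -> np.ndarray:
    if tag == "distance":
        return distance_matrix(mol).values
    if tag == "coulomb_full":
        return coulomb_matrix(mol, "full", elements).values
    if tag == "coulomb_reduced":
        return coulomb_matrix(mol, "reduced", elements).values
    if tag == "bond_order":
        return bond_order_matrix(mol, params).values
    if tag == "ionization_diag":
        return ionization_diag(mol, elements).values
    if tag == "atomic_number_diag":
        return atomic_number_diag(mol, elements).values
    raise ValueError(f"unknown property tag {tag!r}")


def compose_channels(
    mol: Molecule,
    elements: ElementTable,
    params: PairParamTable,
    cfg: EncodingConfig,
) -> np.ndarray:
    """Raw ``(N, N, 3)`` image: each plane filled per the gen-type layout.

    In a combined channel the off-diagonal and diagonal properties are by
    default normalized independently before being written into their
    disjoint cells (``combined_joint_norm`` switches to joint scaling).
    """
    n = mol.n_atoms
    layout = CHANNEL_LAYOUTS[cfg.gen_type]
    raw = np.zeros((n, n, 3))
    diag = np.eye(n, dtype=bool)
    for c, channel in enumerate(layout):
        if cfg.combined_joint_norm and len(channel) > 1:
            combined = np.zeros((n, n))
            for tag, placement in channel:
                vals = _descriptor_values(tag, mol, elements, params)
                mask = diag if placement == "diag" else ~diag
                combined[mask] = vals[mask]
            raw[:, :, c] = _normalize_for(combined, channel[0][0], cfg)
        else:
            for tag, placement in channel:
                norm = _normalize_for(
                    _descriptor_values(tag, mol, elements, params), tag, cfg
                )
                if placement == "both":
                    raw[:, :, c] = norm
                elif placement == "diag":
                    raw[:, :, c][diag] = norm[diag]
                else:
                    raw[:, :, c][~diag] = norm[~diag]
    return raw


def _normalize_for(values: np.ndarray, tag: str, cfg: EncodingConfig) -> np.ndarray:
    if cfg.normalization == "fixed":
        if tag not in cfg.fixed_ranges:
            raise ConfigError(f"fixed normalization needs a range for property {tag!r}")
        return normalize_matrix(values, "fixed", tuple(cfg.fixed_ranges[tag]))
    return normalize_matrix(values, "per_image")


def bilinear_resize(plane: np.ndarray, size: int) -> np.ndarray:
    """Half-pixel-centred bilinear resampling of one 2-D plane to size x size.

    Destination pixel centre k maps to source coordinate
    ``(k + 0.5) * N / S - 0.5``, clamped to the source grid.  With N == S
    this is the identity map.
    """
    n = plane.shape[0]
    if n == size:
        return plane.copy()
    pos = (np.arange(size) + 0.5) * n / size - 0.5
    pos = np.clip(pos, 0, n - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n - 1)
    frac = pos - i0
    # Separable: rows then columns.
    rows = plane[i0, :] * (1 - frac)[:, None] + plane[i1, :] * frac[:, None]
    return rows[:, i0] * (1 - frac)[None, :] + rows[:, i1] * frac[None, :]


def place_on_canvas(
    raw: np.ndarray,
    cfg: EncodingConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Unify an ``(N, N, 3)`` block to ``(S, S, 3)`` per the margin policy.

    black: remainder exactly 0.  average: remainder equals the per-channel
    mean of the raw block.  resize: per-channel bilinear interpolation.
    Offset: fixed = top-left (0, 0); random = uniform over all
    ``(S - N + 1)**2`` placements drawn from ``rng``.  With N == S every
    mode degenerates to the identity.
    """
    n, s = raw.shape[0], cfg.canvas_size
    if cfg.margin_mode == "resize":
        return np.stack([bilinear_resize(raw[:, :, c], s) for c in range(3)], axis=-1)
    if n > s:
        raise CanvasSizeError(
            f"molecule block ({n}x{n}) exceeds canvas ({s}x{s}) in "
            f"margin_mode={cfg.margin_mode!r}; use resize or a larger canvas"
        )
    if cfg.margin_mode == "black":
        canvas = np.zeros((s, s, 3))
    else:  # average
        canvas = np.tile(raw.mean(axis=(0, 1)), (s, s, 1))
    if cfg.offset_mode == "random" and n < s:
        if rng is None:
            raise ConfigError("random offset requires an rng")
        r, c = rng.integers(0, s - n + 1, size=2)
    else:
        r, c = 0, 0
    canvas[r : r + n, c : c + n, :] = raw
    return canvas


def quantize(pixels: np.ndarray) -> np.ndarray:
    """Round half-up to uint8."""
    return np.floor(np.asarray(pixels) + 0.5).astype(np.uint8)


def encode(
    mol: Molecule,
    elements: ElementTable,
    params: PairParamTable,
    cfg: EncodingConfig,
    rng: np.random.Generator | None = None,
    permutation_index: int = 0,
) -> ImageTensor:
    """Full encoder: compose -> place on canvas -> optional quantization.

    Deterministic given the molecule's atom order, the config and the rng
    state.
    """
    raw = compose_channels(mol, elements, params, cfg)
    pixels = place_on_canvas(raw, cfg, rng)
    if cfg.quantize:
        pixels = quantize(pixels)
    return ImageTensor(
        pixels=pixels,
        molecule_id=mol.id,
        permutation_index=permutation_index,
        fingerprint=cfg.fingerprint(),
    )
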