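"""Element constants and bond-order pair parameters.

Two small lookup tables feed the image channels:

* per-element constants (atomic number ``Z``, first ionization energy in
  eV) — used for the diagonal channels;
* per-element-pair bond-order parameters (reference radii ``r0_sigma``,
  ``r0_pi``, ``r0_pipi`` in Å and exponents ``pbo1..pbo6``) — used for the
  off-diagonal ReaxFF-style bond-order channel.

Both ship as versioned plain-text data files, not code.  Fluorine rarely
bonds to anything but carbon in QM9-composition molecules, so by default
the O-F, F-N and F-H pairs (and, via ``suppress_ff``, F-F) have all their
reference radii forced to the ``-1`` sentinel, which zeroes every
bond-order term for those pairs regardless of what the parameter file
says.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

from .xyz_io import UnsupportedElementError

#: Pairs whose bond order is suppressed (all r0 -> -1) by default.
FLUORINE_OVERRIDE_PAIRS = (("O", "F"), ("F", "N"), ("F", "H"))

_PBO_KEYS = ("pbo1", "pbo2", "pbo3", "pbo4", "pbo5", "pbo6")
_R0_KEYS = ("r0_sigma", "r0_pi", "r0_pipi")


class PairParamParseError(ValueError):
    """Malformed pair-parameter file; message carries the line number."""


@dataclass(frozen=True)
class ElementData:
    symbol: str
    Z: int
    ionization_energy: float  # eV

    def __post_init__(self):
        if self.Z < 1 or int(self.Z) != self.Z:
            raise ValueError(f"Z must be a positive integer, got {self.Z}")
        if self.ionization_energy <= 0:
            raise ValueError("ionization_energy must be > 0")


@dataclass(frozen=True)
class PairParams:
    """Bond-order parameters for one unordered element pair.

    An ``r0`` of exactly ``-1`` (or any value <= 0) marks the corresponding
    sigma/pi/pipi term as absent: it contributes 0 to the bond order.
    """

    elements: frozenset
    r0_sigma: float
    r0_pi: float
    r0_pipi: float
    pbo1: float
    pbo2: float
    pbo3: float
    pbo4: float
    pbo5: float
    pbo6: float

    def suppressed(self) -> "PairParams":
        """Copy with every reference radius set to the -1 sentinel."""
        return replace(self, r0_sigma=-1.0, r0_pi=-1.0, r0_pipi=-1.0)


def _pair_key(a: str, b: str) -> frozenset:
    return frozenset((a, b))


class ElementTable:
    def __init__(self, entries: dict[str, ElementData]):
        self._entries = dict(entries)

    def lookup(self, symbol: str) -> ElementData:
        try:
            return self._entries[symbol]
        except KeyError:
            raise UnsupportedElementError(symbol) from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._entries

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self._entries)


class PairParamTable:
    """Symmetric lookup of :class:`PairParams` by unordered element pair."""

    def __init__(self, entries: dict[frozenset, PairParams]):
        self._entries = dict(entries)

    def lookup(self, a: str, b: str) -> PairParams | None:
        """Return params for the unordered pair, or None if absent."""
        return self._entries.get(_pair_key(a, b))

    def __len__(self) -> int:
        return len(self._entries)

    def with_fluorine_override(self, suppress_ff: bool = True) -> "PairParamTable":
        """Force the -1 radius sentinel onto the rare fluorine pairs.

        Idempotent: applying twice equals applying once.
        """
        pairs = list(FLUORINE_OVERRIDE_PAIRS) + ([("F", "F")] if suppress_ff else [])
        entries = dict(self._entries)
        for a, b in pairs:
            key = _pair_key(a, b)
            if key in entries:
                entries[key] = entries[key].suppressed()
        return PairParamTable(entries)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("rgbchem").joinpath("data", name)))


def load_element_table(path: str | Path | None = None) -> ElementTable:
    """Load the element-constant CSV (default: the shipped table)."""
    path = _data_path("elements.csv") if path is None else Path(path)
    entries: dict[str, ElementData] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("symbol"):
            continue
        sym, z, ie = line.split(",")
        entries[sym] = ElementData(symbol=sym, Z=int(z), ionization_energy=float(ie))
    return ElementTable(entries)


_DEFAULT_ELEMENTS: ElementTable | None = None


def lookup_element(symbol: str) -> ElementData:
    """Constants for ``symbol`` from the shipped default table."""
    global _DEFAULT_ELEMENTS
    if _DEFAULT_ELEMENTS is None:
        _DEFAULT_ELEMENTS = load_element_table()
    return _DEFAULT_ELEMENTS.lookup(symbol)


def load_pair_params(
    path: str | Path | None = None,
    *,
    fluorine_override: bool = True,
    suppress_ff: bool = True,
) -> PairParamTable:
    """Parse a pair-parameter file into a symmetric :class:`PairParamTable`.

    The file format is documented in the shipped
    ``data/pair_params_synthetic.txt``: blocks introduced by ``pair: A B``
    followed by ``key=value`` lines for the three radii and six exponents.

    With ``fluorine_override`` (default), O-F / F-N / F-H entries come back
    fully sentineled no matter what the file holds; ``suppress_ff`` extends
    that to F-F.
    """
    path = _data_path("pair_params_synthetic.txt") if path is None else Path(path)
    entries: dict[frozenset, PairParams] = {}
    current: dict | None = None

    def _close(block: dict | None):
        if block is None:
            return
        missing = [k for k in _R0_KEYS + _PBO_KEYS if k not in block["values"]]
        if missing:
            raise PairParamParseError(
                f"pair {block['pair']} missing keys {missing} (block starting line {block['line']})"
            )
        a, b = block["pair"]
        entries[_pair_key(a, b)] = PairParams(elements=_pair_key(a, b), **block["values"])

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("pair:"):
            _close(current)
            elems = line[len("pair:") :].split()
            if len(elems) != 2:
                raise PairParamParseError(f"line {lineno}: expected 'pair: A B', got {raw!r}")
            current = {"pair": tuple(elems), "values": {}, "line": lineno}
        elif "=" in line:
            if current is None:
                raise PairParamParseError(f"line {lineno}: key=value outside a pair block")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in _R0_KEYS + _PBO_KEYS:
                raise PairParamParseError(f"line {lineno}: unknown key {key!r}")
            try:
                current["values"][key] = float(val)
            except ValueError:
                raise PairParamParseError(
                    f"line {lineno}: malformed numeric field {val!r} for key {key!r}"
                ) from None
        else:
            raise PairParamParseError(f"line {lineno}: unparseable line {raw!r}")
    _close(current)

    table = PairParamTable(entries)
    if fluorine_override:
        table = table.with_fluorine_override(suppress_ff=suppress_ff)
    return table
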