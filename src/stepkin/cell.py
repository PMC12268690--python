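"""Minimal crystallographic cell arithmetic and a cell-block CIF reader.

Covers exactly what the step-kinetics analysis needs: unit-cell volume,
calculated density, formula weight, and the AFM-observable step-height
classes on (200), which are the a-axis repeat and its half (the two halves
of the cell are related by a glide plane and grow at the same velocity).
Loops, symmetry operators and reflection data are deliberately ignored.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass

import gemmi

from .constants import ATOMIC_WEIGHTS, N_AVOGADRO
from .errors import DomainError, ParseError

__all__ = [
    "CellParams",
    "read_cif_cell",
    "molecular_weight",
    "cell_volume",
    "calc_density",
    "step_heights",
    "AFM_A_AXIS_NM",
]

#: Room-temperature a-axis repeat observed by AFM on the (200) face, nm.
#: (The 100 K single-crystal cell has a = 2.42655 nm; step heights are
#: room-temperature observables, so this is the default.)
AFM_A_AXIS_NM = 2.413

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class CellParams:
    """Unit-cell lengths (Å), angles (deg), Z and chemical formula."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    space_group: str = ""
    Z: int | None = None
    formula: str | None = None
    formula_weight: float | None = None  # g/mol; computed from formula if absent

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise DomainError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0 < ang < 180:
                raise DomainError(f"cell angle {name} must be in (0, 180), got {ang}")

    @property
    def fw(self) -> float:
        """Formula weight in g/mol, computed from the formula if not given."""
        if self.formula_weight is not None:
            return self.formula_weight
        if self.formula is None:
            raise DomainError("neither formula_weight nor formula is set")
        return molecular_weight(self.formula)


def _strip_su(value: str, tag: str) -> float:
    """Parse a CIF numeric value, stripping a standard-uncertainty suffix.

    '24.2655(8)' -> 24.2655.  A malformed suffix raises a parse error
    naming the tag.
    """
    m = re.fullmatch(r"\s*(-?\d+(?:\.\d+)?)(?:\((\d+)\))?\s*", value)
    if m is None:
        raise ParseError(f"malformed numeric value {value!r} for tag {tag}")
    return float(m.group(1))


def read_cif_cell(path: str) -> CellParams:
    """Read the cell/formula subset of a CIF file into :class:`CellParams`.

    Requires the six ``_cell_length_*`` / ``_cell_angle_*`` tags in a single
    data block; ``_cell_formula_units_Z``, the chemical formula and the
    space group are optional.
    """
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse CIF file {path}: {exc}") from exc
    if len(doc) == 0:
        raise ParseError(f"no data block found in {path}")
    block = doc.sole_block() if len(doc) == 1 else doc[0]

    def need(tag: str) -> float:
        raw = block.find_value(tag)
        if raw is None:
            raise ParseError(f"missing mandatory tag {tag} in {path}")
        return _strip_su(raw, tag)

    def optional(tag: str) -> str | None:
        raw = block.find_value(tag)
        if raw is None:
            return None
        return gemmi.cif.as_string(raw)

    z_raw = block.find_value("_cell_formula_units_Z")
    formula = optional("_chemical_formula_sum") or optional("_chemical_formula_moiety")
    fw_raw = block.find_value("_chemical_formula_weight")
    return CellParams(
        a=need("_cell_length_a"),
        b=need("_cell_length_b"),
        c=need("_cell_length_c"),
        alpha=need("_cell_angle_alpha"),
        beta=need("_cell_angle_beta"),
        gamma=need("_cell_angle_gamma"),
        space_group=optional("_space_group_name_H-M_alt")
        or optional("_symmetry_space_group_name_H-M")
        or "",
        Z=int(_strip_su(z_raw, "_cell_formula_units_Z")) if z_raw is not None else None,
        formula=formula,
        formula_weight=_strip_su(fw_raw, "_chemical_formula_weight") if fw_raw else None,
    )


def molecular_weight(formula: str) -> float:
    """Formula weight (g/mol) of a Hill-style formula like 'C7H8N4O2'.

    Whitespace between element groups ('C7 H8 N4 O2') is accepted.
    """
    compact = formula.replace(" ", "")
    if not compact:
        raise ParseError("empty chemical formula")
    total = 0.0
    pos = 0
    for m in _FORMULA_TOKEN.finditer(compact):
        if m.start() != pos:
            raise ParseError(f"unparseable formula fragment {compact[pos:]!r}")
        if not m.group(0):
            break
        element, count = m.group(1), int(m.group(2) or 1)
        if element not in ATOMIC_WEIGHTS:
            raise ParseError(f"unknown element symbol {element!r} in formula {formula!r}")
        total += ATOMIC_WEIGHTS[element] * count
        pos = m.end()
    if pos != len(compact):
        raise ParseError(f"unparseable formula fragment {compact[pos:]!r}")
    return total


def cell_volume(cell: CellParams) -> float:
    """Unit-cell volume in ų (general triclinic formula).

    V = abc·sqrt(1 − cos²α − cos²β − cos²γ + 2·cosα·cosβ·cosγ); reduces to
    a·b·c for orthorhombic cells.
    """
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0:
        raise DomainError(f"degenerate cell metric (discriminant {arg})")
    return cell.a * cell.b * cell.c * math.sqrt(arg)


def calc_density(cell: CellParams) -> float:
    """Calculated crystal density Dc = Z·Fw/(N_A·V), in g/cm³."""
    if cell.Z is None:
        raise DomainError("cell has no Z; cannot compute density")
    v_cm3 = cell_volume(cell) * 1e-24
    return cell.Z * cell.fw / (N_AVOGADRO * v_cm3)


def step_heights(a_nm: float = AFM_A_AXIS_NM) -> dict[str, float]:
    """Admissible AFM step-height classes on (200): full and half a-axis.

    Steps of the full unit-cell repeat coexist with sub-steps of half the
    repeat (the two half-cells are glide-related); with the AFM a-axis of
    2.413 nm the classes are 2.413 and ~1.2 nm.
    """
    if a_nm <= 0:
        raise DomainError(f"a_nm must be > 0, got {a_nm}")
    return {"full": a_nm, "half": a_nm / 2.0}
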