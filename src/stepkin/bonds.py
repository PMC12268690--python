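"""Bond-chain accounting on the (200) plane.

The (200) layer of Form II theophylline is modeled as a rectangular lattice
with two strong periodic bond chains — π−π stacking along [010] and an
N–H···N hydrogen-bond chain along the [011] diagonal — plus a pooled
in-plane van der Waals contact along [001] and out-of-plane van der Waals
contacts to the adjacent (200) layers.

Two quantities are derived from a bond scheme:

* the cost of creating four kinks by the extraction–reattachment pathway
  (move an edge-embedded molecule to an intact segment of the same step),
  enumerated bond-by-bond on an explicit half-plane geometry, and
* the lattice (crystallization) enthalpy, −½ Σ energy × multiplicity per
  molecule, which constrains any proposed scheme against the measured ΔH°.

No numeric bond energies ship as defaults: the study quantifies neither
E(π−π) nor E(H-bond) individually, so schemes are user inputs or outputs of
:func:`calibrate_scheme`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from .errors import CalibrationError, ConfigError, DomainError

__all__ = [
    "BondType",
    "BondScheme",
    "StepGeometry",
    "KinkCost",
    "kink_creation_cost",
    "lattice_enthalpy",
    "calibrate_scheme",
]

BOND_NAMES = ("pi_stack", "h_bond", "vdw_in_plane", "vdw_out_of_plane")


@dataclass(frozen=True)
class BondType:
    """One bond type: binding energy magnitude and per-molecule multiplicity."""

    name: str
    energy: float  # J/mol, >= 0 (binding magnitude)
    multiplicity: int  # bonds per molecule (each bond counted at both ends)
    direction: str = ""  # crystallographic label, e.g. "[010]"

    def __post_init__(self) -> None:
        if self.name not in BOND_NAMES:
            raise ConfigError(f"unknown bond type {self.name!r}; expected one of {BOND_NAMES}")
        if self.energy < 0:
            raise DomainError(f"bond energy must be >= 0, got {self.energy}")
        if self.multiplicity < 0:
            raise DomainError("bond multiplicity must be >= 0")


@dataclass(frozen=True)
class BondScheme:
    """A complete bond assignment for the (200) lattice."""

    bonds: tuple[BondType, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.bonds]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate bond type in scheme")

    def energy(self, name: str) -> float:
        for b in self.bonds:
            if b.name == name:
                return b.energy
        return 0.0

    def get(self, name: str) -> BondType | None:
        for b in self.bonds:
            if b.name == name:
                return b
        return None

    @classmethod
    def from_energies(
        cls,
        pi_stack: float,
        h_bond: float,
        vdw_in_plane: float,
        vdw_out_of_plane: float = 0.0,
        out_of_plane_multiplicity: int = 4,
    ) -> "BondScheme":
        return cls(
            bonds=(
                BondType("pi_stack", pi_stack, 2, "[010]"),
                BondType("h_bond", h_bond, 2, "[011]"),
                BondType("vdw_in_plane", vdw_in_plane, 2, "[001]"),
                BondType("vdw_out_of_plane", vdw_out_of_plane, out_of_plane_multiplicity, "[100]"),
            )
        )

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": b.name,
                    "energy_J_per_mol": b.energy,
                    "multiplicity": b.multiplicity,
                    "direction": b.direction,
                }
                for b in self.bonds
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BondScheme":
        data = json.loads(text)
        return cls(
            bonds=tuple(
                BondType(
                    d["name"], d["energy_J_per_mol"], d["multiplicity"], d.get("direction", "")
                )
                for d in data
            )
        )


@dataclass(frozen=True)
class StepGeometry:
    """A step on (200): its advance direction and in-plane edge direction."""

    advance_direction: str  # "[010]" or "[001]"
    edge_direction: str = ""

    def __post_init__(self) -> None:
        if self.advance_direction not in ("[010]", "[001]"):
            raise ConfigError(
                f"advance_direction must be '[010]' or '[001]', got {self.advance_direction!r}"
            )
        expected_edge = "[001]" if self.advance_direction == "[010]" else "[010]"
        if self.edge_direction and self.edge_direction != expected_edge:
            raise ConfigError(
                f"edge_direction {self.edge_direction!r} is not perpendicular to "
                f"advance {self.advance_direction!r} in the (200) plane"
            )
        object.__setattr__(self, "edge_direction", expected_edge)


# (200)-plane neighbor offsets (axis0 along [001], axis1 along [010]) and
# the bond type carried by each offset.  The H-bond chain runs along the
# [011] diagonal; in-plane vdW pools the remaining [001] contact.
_NEIGHBOR_BONDS: tuple[tuple[tuple[int, int], str], ...] = (
    ((0, 1), "pi_stack"),
    ((0, -1), "pi_stack"),
    ((1, 0), "vdw_in_plane"),
    ((-1, 0), "vdw_in_plane"),
    ((1, 1), "h_bond"),
    ((-1, -1), "h_bond"),
)


@dataclass(frozen=True)
class KinkCost:
    """Result of the four-kink extraction–reattachment enumeration."""

    total_for_4_kinks: float  # J/mol
    per_kink: float  # J/mol
    ledger: tuple[tuple[str, str], ...] = field(default_factory=tuple)  # (bond, action)


def _occupied(p: tuple[int, int], advance_axis: int) -> bool:
    """Half-plane occupancy: filled up to and including the edge row."""
    return p[advance_axis] <= 0


def kink_creation_cost(step: StepGeometry, scheme: BondScheme) -> KinkCost:
    """Net energy of creating four kinks on a straight step edge.

    Follows the extraction–reattachment pathway: a molecule embedded in the
    step edge is removed (breaking its bonds to occupied neighbors; bonds to
    the underlying (200) plane cancel between the two configurations) and
    re-deposited against an intact, distant segment of the same edge
    (restoring the bonds it forms there).  The operation creates exactly
    four kinks — two at the vacancy, two at the adatom — so the per-kink
    energy is the net cost divided by four.

    For a [001]-advancing step (edge along the π-stack chain) the net is two
    π−π bonds plus any imbalance of in-plane vdW; for a [010]-advancing step
    (edge along [001]) the π−π and H-bonds each break once and restore once,
    leaving only in-plane vdW contacts.
    """
    advance_axis = 0 if step.advance_direction == "[001]" else 1
    edge_axis = 1 - advance_axis
    origin = (0, 0)

    ledger: list[tuple[str, str]] = []
    total = 0.0
    # Extraction from the edge: break bonds to every occupied neighbor.
    for offset, bond in _NEIGHBOR_BONDS:
        nb = (origin[0] + offset[0], origin[1] + offset[1])
        if _occupied(nb, advance_axis):
            total += scheme.energy(bond)
            ledger.append((bond, "broken"))
    # Reattachment in front of an intact, distant edge segment.
    far = [0, 0]
    far[advance_axis] = 1
    far[edge_axis] = 10  # far from the vacancy left behind
    site = (far[0], far[1])
    for offset, bond in _NEIGHBOR_BONDS:
        nb = (site[0] + offset[0], site[1] + offset[1])
        if _occupied(nb, advance_axis):
            total -= scheme.energy(bond)
            ledger.append((bond, "restored"))
    return KinkCost(total_for_4_kinks=total, per_kink=total / 4.0, ledger=tuple(ledger))


def lattice_enthalpy(scheme: BondScheme) -> float:
    """Crystallization enthalpy implied by the scheme, J/mol.

    The half sum of all bonds per molecule, with the crystallization sign:
    −½ Σ energy × multiplicity.
    """
    return -0.5 * sum(b.energy * b.multiplicity for b in scheme.bonds)


def enthalpy_residual(scheme: BondScheme, target: float) -> float:
    """Signed residual of the scheme's lattice enthalpy against a target."""
    return lattice_enthalpy(scheme) - target


def calibrate_scheme(
    enthalpy_target: float,
    omega_010_target: float,
    pi_stack_energy: float,
    h_bond_energy: float,
    out_of_plane_multiplicity: int = 4,
) -> BondScheme:
    """Solve for the vdW energies satisfying two constraints.

    (i) the per-kink cost of a [010]-advancing step equals ``omega_010_target``
    (the reported low kink energy of the rough steps), and (ii) the lattice
    enthalpy equals ``enthalpy_target`` (negative, solution → crystal).  The
    [010] kink cost involves only in-plane vdW (two bonds per four kinks),
    which fixes E(vdW in-plane) = 2·ω; the enthalpy remainder is then spread
    uniformly over the out-of-plane vdW slots.
    """
    if omega_010_target < 0:
        raise CalibrationError("omega_010_target must be >= 0")
    if out_of_plane_multiplicity <= 0:
        raise CalibrationError("out_of_plane_multiplicity must be > 0")
    e_vdw_in = 2.0 * omega_010_target
    bond_sum_target = -2.0 * enthalpy_target  # Σ energy × multiplicity
    remainder = bond_sum_target - 2.0 * pi_stack_energy - 2.0 * h_bond_energy - 2.0 * e_vdw_in
    if remainder < 0:
        raise CalibrationError(
            "infeasible calibration: strong bonds plus in-plane vdW already exceed "
            f"the enthalpy target (excess {-remainder:.1f} J/mol on the bond sum)"
        )
    e_vdw_out = remainder / out_of_plane_multiplicity
    scheme = BondScheme.from_energies(
        pi_stack=pi_stack_energy,
        h_bond=h_bond_energy,
        vdw_in_plane=e_vdw_in,
        vdw_out_of_plane=e_vdw_out,
        out_of_plane_multiplicity=out_of_plane_multiplicity,
    )
    return scheme


def ledger_table(cost: KinkCost) -> str:
    """Human-readable broken/restored bond table."""
    lines = [f"{'bond':20s} {'action':10s}"]
    for bond, action in cost.ledger:
        lines.append(f"{bond:20s} {action:10s}")
    lines.append(f"net for 4 kinks: {cost.total_for_4_kinks:.6g} J/mol")
    lines.append(f"per kink:        {cost.per_kink:.6g} J/mol")
    return "\n".join(lines)
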