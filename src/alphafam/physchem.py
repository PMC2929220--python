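"""Predicted molecular mass of a protein sequence.

Average (isotope-abundance-weighted) residue masses are used, since the
prediction is compared to SDS-PAGE-scale kilodalton estimates.  The mass
of a chain is the sum of its residue masses plus one water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import ProteinSequence

WATER_MASS = 18.0153  # Da

# Average residue (monomer minus water) masses, Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}


@dataclass(frozen=True)
class MassTable:
    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASS)
    )
    water: float = WATER_MASS

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.residue_masses.values()) or self.water <= 0:
            raise ValueError("masses must be positive")

    @property
    def mean_residue_mass(self) -> float:
        return sum(self.residue_masses.values()) / len(self.residue_masses)


def molecular_weight(
    p: ProteinSequence,
    table: MassTable | None = None,
    allow_ambiguous: bool = False,
) -> float:
    """Average molecular mass of a protein in daltons.

    Ambiguous residues (X) raise unless ``allow_ambiguous`` substitutes the
    mean of the 20 canonical residue masses.
    """
    table = table or MassTable()
    total = table.water
    for c in p.residues:
        if c in table.residue_masses:
            total += table.residue_masses[c]
        elif allow_ambiguous:
            total += table.mean_residue_mass
        else:
            raise ValueError(
                f"{p.id}: ambiguous residue {c!r} (pass allow_ambiguous "
                "to use the mean residue mass)"
            )
    return total


def molecular_weight_kda(
    p: ProteinSequence,
    table: MassTable | None = None,
    allow_ambiguous: bool = False,
) -> int:
    """Mass rounded to the nearest kilodalton."""
    return round(molecular_weight(p, table, allow_ambiguous) / 1000.0)
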