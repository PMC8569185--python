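"""Peptide monoisotopic mass utilities.

Masses assume a free N-terminal amine and free C-terminal acid (the form in
which the blenniorphins were synthesized): the peptide monoisotopic mass is
the sum of residue masses plus one water, and [M+H]+ adds one proton. No
modifications, average masses or fragment masses are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

from blennymine.exceptions import InputError

# Standard monoisotopic residue masses (Da), 5 decimal places.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON_MONO = 1.007276


@dataclass(frozen=True)
class Peptide:
    """A linear peptide with free amine/acid termini."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"peptide {self.id!r}: empty sequence")
        for pos, residue in enumerate(self.sequence, start=1):
            if residue not in RESIDUE_MASSES:
                raise InputError(
                    f"peptide {self.id!r}: non-canonical residue {residue!r} at position {pos}"
                )


def monoisotopic_mass(peptide: Peptide | str) -> float:
    """Monoisotopic neutral mass in Da (residue masses + one water)."""
    if isinstance(peptide, str):
        peptide = Peptide(id="peptide", sequence=peptide)
    return sum(RESIDUE_MASSES[r] for r in peptide.sequence) + WATER_MONO


def mh_plus(peptide: Peptide | str) -> float:
    """Monoisotopic [M+H]+ in Da (neutral mass + one proton)."""
    return monoisotopic_mass(peptide) + PROTON_MONO
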