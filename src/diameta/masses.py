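"""Monoisotopic mass constants for peptide chemistry.

Residue masses are monoisotopic residue (i.e. dehydrated) masses. Cysteine
is listed unmodified; carbamidomethylation is applied as a fixed
modification by the digest/search layer.
"""

from __future__ import annotations

PROTON = 1.007276
WATER = 18.010565
ISOTOPE_SPACING = 1.00335  # average C13-C12 spacing used for charge inference

CARBAMIDOMETHYL = 57.02146  # fixed on C
OXIDATION = 15.99491  # variable on M

#: Monoisotopic residue masses of the 20 standard amino acids, in Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

#: Residue alphabet accepted in protein records (X marks unknown residues;
#: peptides containing X are excluded from digestion output).
PROTEIN_ALPHABET = frozenset(RESIDUE_MASSES) | {"X"}


def mz_from_neutral_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return neutral_mass / charge + PROTON


def neutral_mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from observed m/z and charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return charge * (mz - PROTON)


def ppm_delta(mz: float, ppm: float) -> float:
    """Absolute m/z tolerance corresponding to ``ppm`` at ``mz``."""
    return mz * ppm * 1e-6
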