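"""Monoisotopic mass constants.

Residue masses are the standard monoisotopic masses of the 20 amino-acid
residues (i.e. the free amino acid minus one water). A peptide's neutral
monoisotopic mass is the sum of its residue masses plus one water, plus any
modification deltas. m/z at charge z is (M + z * proton) / z with the proton
(charged hydrogen) mass, not the hydrogen atom mass.
"""

from __future__ import annotations

import re

from .errors import InputError

WATER: float = 18.010565
PROTON: float = 1.007276

#: Monoisotopic element masses used for composition arithmetic.
ELEMENT_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Monoisotopic residue masses, Da.
RESIDUE_MASS: dict[str, float] = {
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

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def composition_mass(formula: str) -> float:
    """Monoisotopic mass of an element composition such as ``"C2H3NO"``.

    >>> round(composition_mass("C2H3NO"), 3)   # carbamidomethyl delta
    57.021
    """
    if not formula:
        raise InputError("empty composition formula")
    mass = 0.0
    consumed = 0
    for element, count in _FORMULA_TOKEN.findall(formula):
        if not element:
            continue
        if element not in ELEMENT_MASS:
            raise InputError(f"unknown element {element!r} in {formula!r}")
        n = int(count) if count else 1
        mass += ELEMENT_MASS[element] * n
        consumed += len(element) + len(count)
    if consumed != len(formula):
        raise InputError(f"could not parse composition formula {formula!r}")
    return mass


# Modification deltas derived from their element compositions; these round to
# the conventional search-engine values 57.021 / 15.995 / 42.011 Da.
CARBAMIDOMETHYL_DELTA: float = composition_mass("C2H3NO")
OXIDATION_DELTA: float = composition_mass("O")
ACETYL_DELTA: float = composition_mass("C2H2O")
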