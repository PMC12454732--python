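"""Monoisotopic mass constants.

Single source of truth for atomic masses used everywhere in the package.
Values are the masses of the most abundant isotope of each element (Da),
CODATA/IUPAC values; the electron mass matters for ion m/z at the sub-ppm
level and is therefore carried explicitly.
"""

from __future__ import annotations

# most-abundant-isotope masses, Da
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.96370649,
    "F": 18.9984031627,
    "Cl": 34.96885268,
    "Br": 78.9183376,
    "I": 126.9044719,
}

ELECTRON_MASS: float = 0.00054858

#: proton mass (H minus one electron), convenient for [M+H]+ arithmetic
PROTON_MASS: float = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

#: halogens are counted like hydrogen in ring-plus-double-bond arithmetic
HALOGENS: frozenset[str] = frozenset({"F", "Cl", "Br", "I"})

KNOWN_ELEMENTS: frozenset[str] = frozenset(MONOISOTOPIC_MASS)
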