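"""Pinned isotope masses and natural abundances for C, H, N, O, P, S.

Atomic masses are from the AME2020 atomic mass evaluation; isotopic
abundances are the IUPAC-CIAAW 2021 representative values. The table is
pinned in-repo (rather than taken from a chemistry library at run time) so
that exact masses, ion m/z values and predicted isotope patterns are
bit-stable across library versions.

All masses are in Da (unified atomic mass units).
"""

from __future__ import annotations

#: Elements handled by the whole package, in Hill order (C, H, then alphabetical).
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "P", "S")

#: Electron rest mass, Da (CODATA 2018).
ELECTRON_MASS: float = 0.000548579909065

#: Per element: list of (isotope mass in Da, natural abundance fraction),
#: ordered by increasing mass. The first entry is the lightest (monoisotopic)
#: isotope. Abundances sum to 1 within rounding of the source tables.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.003354835, 0.0107)],
    "H": [(1.007825031898, 0.999885), (2.014101777844, 0.000115)],
    "N": [(14.003074004251, 0.99636), (15.000108898266, 0.00364)],
    "O": [
        (15.994914619257, 0.99757),
        (16.999131755953, 0.00038),
        (17.999159612136, 0.00205),
    ],
    "P": [(30.973761998842, 1.0)],
    "S": [
        (31.972071174414, 0.9499),
        (32.971458909774, 0.0075),
        (33.967867011, 0.0425),
        (35.96708069, 0.0001),
    ],
}

#: Monoisotopic (lightest-isotope) mass per element, Da.
MONOISOTOPIC_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: Exact masses of adduct atoms that are not part of the CHNOPS alphabet.
SODIUM_MASS: float = 22.989769282019
POTASSIUM_MASS: float = 38.963706486449

#: Singly charged positive adducts: name -> mass added to the neutral
#: molecule before subtracting one electron mass.
ADDUCT_MASS: dict[str, float] = {
    "[M+H]+": MONOISOTOPIC_MASS["H"],
    "[M+Na]+": SODIUM_MASS,
    "[M+K]+": POTASSIUM_MASS,
}

DEFAULT_ADDUCTS: tuple[str, ...] = ("[M+H]+", "[M+Na]+", "[M+K]+")
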