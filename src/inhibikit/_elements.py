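"""Isotope and atomic-mass tables shared across modules.

Monoisotopic masses are those of the most abundant natural isotope and are
the values used for exact-mass ion annotation; average atomic weights are
used only for mass-weighted geometry (centre of mass, radius of gyration).
"""

# Most-abundant-isotope masses, Da (CODATA/IUPAC values truncated at the
# precision a QTOF workflow needs).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "Cl": 34.96885268,
}

HYDROGEN_ATOM_MASS = MONOISOTOPIC_MASS["H"]

# Standard average atomic weights, Da, for geometric mass-weighting only.
ATOMIC_WEIGHT: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "F": 18.998,
    "Br": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "CO": 58.933,
    "NI": 58.693,
    "CU": 63.546,
    "ZN": 65.38,
}

# Elements treated as metal centres when flagging receptor atoms (the
# tyrosinase active site is defined by its binuclear copper pair).
METAL_ELEMENTS = frozenset(
    {"CU", "ZN", "FE", "MN", "MG", "CA", "NA", "K", "CO", "NI"}
)


def atomic_weight(element: str) -> float:
    """Average atomic weight of *element* (case-insensitive symbol)."""
    try:
        return ATOMIC_WEIGHT[element.strip().upper()]
    except KeyError:
        raise KeyError(f"no atomic weight tabulated for element {element!r}") from None
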