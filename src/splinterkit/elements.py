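"""Element data: covalent radii for bond perception.

Covalent radii (Å) follow the Cordero 2008 consensus set for the elements
that occur in small-molecule fragment libraries.  Bond perception draws an
edge when the interatomic distance is below the sum of covalent radii plus
a 0.4 Å tolerance; only graph equality is ever consumed downstream, so the
exact radius source matters less than determinism.
"""

COVALENT_RADII = {
    "H": 0.31,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Na": 1.66,
    "Mg": 1.41,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "K": 2.03,
    "Ca": 1.76,
    "Br": 1.20,
    "I": 1.39,
}

BOND_TOLERANCE = 0.4  # Å added to the covalent-radius sum


def covalent_radius(element: str) -> float:
    try:
        return COVALENT_RADII[element]
    except KeyError:
        raise KeyError(f"no covalent radius for element {element!r}") from None
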