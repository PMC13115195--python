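"""Van der Waals radii (Å), Bondi-style compilation.

Used by the steric clash filter: two atoms overlap when their distance
falls below ``scale * (r_i + r_j)``.  Coverage includes every element the
engine's built-in chemistry can produce plus common halogens.
"""

from __future__ import annotations

# Bondi (1964) values, with the commonly used H = 1.10 Å revision.
BONDI_RADII: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
}

RADII_SETS: dict[str, dict[str, float]] = {"bondi": BONDI_RADII}


def vdw_radius(element: str, radii_set: str = "bondi") -> float:
    """Return the van der Waals radius of ``element`` in Å.

    Raises
    ------
    KeyError
        If the element has no tabulated radius (the clash filter treats
        this as a hard error naming the element).
    """
    table = RADII_SETS[radii_set]
    key = element.strip().upper()
    if key not in table:
        raise KeyError(
            f"no van der Waals radius tabulated for element {element!r} "
            f"in radii set {radii_set!r}"
        )
    return table[key]
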