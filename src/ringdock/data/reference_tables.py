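"""Reference PM7 binding thermochemistry for three-membered rings in the
BChE active site (small 35-residue cluster model, T = 298.15 K,
p = 101 325 Pa).

Each row is ``(dbH, TdbS, dbG)`` in kJ mol⁻¹: standard binding enthalpy,
entropy contribution at room temperature (T·ΔbS°), and Gibbs free energy
of binding.  Values are printed at two decimals, so ΔbG° = ΔbH° − T·ΔbS°
holds to 0.01 kJ mol⁻¹ on every row.

``BCHE_RING_BINDING_SINGLE`` covers one docked molecule, keyed by
``(ring, cluster)`` with cluster 1 the lowest-energy binding position
(near Ser198/Glu197) and cluster 2 the acyl-pocket position.
``BCHE_RING_BINDING_DUAL`` covers two molecules docked simultaneously.
"""

from __future__ import annotations

# (ring, cluster) -> (dbH, TdbS, dbG) [kJ/mol], one docked molecule
BCHE_RING_BINDING_SINGLE: dict[tuple[str, int], tuple[float, float, float]] = {
    ("cyclopropane", 1): (-65.56, -40.31, -25.25),
    ("cyclopropane", 2): (-59.25, -37.04, -22.21),
    ("aziridine", 1): (-149.45, -50.94, -98.50),
    ("aziridine", 2): (-138.35, -49.28, -89.07),
    ("oxirane", 1): (-99.11, -48.42, -50.69),
    ("oxirane", 2): (-84.60, -45.61, -38.99),
    ("phosphirane", 1): (-194.03, -50.13, -143.90),
    ("phosphirane", 2): (-110.03, -45.98, -64.05),
    ("thiirane", 1): (-90.81, -43.65, -47.16),
    ("thiirane", 2): (-60.21, -41.49, -18.72),
}

# ring -> (dbH, TdbS, dbG) [kJ/mol], two molecules docked simultaneously
BCHE_RING_BINDING_DUAL: dict[str, tuple[float, float, float]] = {
    "cyclopropane": (-124.68, -80.15, -44.54),
    "aziridine": (-244.39, -98.32, -146.07),
    "oxirane": (-183.34, -95.75, -87.59),
    "phosphirane": (-233.51, -92.86, -140.66),
    "thiirane": (-186.45, -85.24, -101.21),
}

RING_NAMES: tuple[str, ...] = (
    "cyclopropane",
    "aziridine",
    "oxirane",
    "phosphirane",
    "thiirane",
)
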