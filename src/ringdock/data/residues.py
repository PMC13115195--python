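"""Active-site residue selections for human butyrylcholinesterase (BChE).

Two published truncated cluster models of the BChE active-site gorge:

* ``BCHE_ACTIVE_SITE_127`` — the large 127-residue model used for
  high-throughput single-point scoring of docked poses;
* ``BCHE_ACTIVE_SITE_35`` — the small 35-residue model (a subset of the
  large one) used for the more expensive geometry optimisations and
  harmonic-frequency thermochemistry.

Each entry is a ``(residue_name, residue_number)`` pair with three-letter
residue codes and the numbering of the mature human BChE sequence; the
catalytic triad Ser198–His438–Glu325, the oxyanion hole (Gly116/Gly117/
Ala199) and the acyl pocket (Trp231, Leu286, Val288) are all included.
"""

from __future__ import annotations

BCHE_ACTIVE_SITE_127: tuple[tuple[str, int], ...] = (
    ("CYS", 65), ("CYS", 66), ("GLN", 67), ("ASN", 68), ("ILE", 69), ("ASP", 70),
    ("GLN", 71), ("SER", 72), ("PHE", 73), ("PRO", 74), ("GLY", 75), ("PHE", 76),
    ("HIS", 77), ("GLY", 78), ("SER", 79), ("GLU", 80), ("MET", 81), ("TRP", 82),
    ("ASN", 83), ("PRO", 84), ("ASN", 85), ("THR", 86), ("ASP", 87), ("LEU", 88),
    ("TRP", 112), ("ILE", 113), ("TYR", 114), ("GLY", 115), ("GLY", 116), ("GLY", 117),
    ("PHE", 118), ("GLN", 119), ("THR", 120), ("GLY", 121), ("THR", 122), ("SER", 123),
    ("SER", 124), ("LEU", 125), ("HIS", 126), ("VAL", 127), ("TYR", 128), ("ASP", 129),
    ("GLY", 130), ("ASN", 145), ("TYR", 146), ("ARG", 147), ("VAL", 148), ("GLY", 149),
    ("GLY", 196), ("GLU", 197), ("SER", 198), ("ALA", 199), ("GLY", 200), ("ALA", 201),
    ("ALA", 202), ("SER", 203), ("GLN", 223), ("SER", 224), ("GLY", 225), ("SER", 226),
    ("PHE", 227), ("ASN", 228), ("ALA", 229), ("PRO", 230), ("TRP", 231), ("ALA", 232),
    ("VAL", 233), ("THR", 234), ("ARG", 242), ("TYR", 282), ("GLY", 283), ("THR", 284),
    ("PRO", 285), ("LEU", 286), ("SER", 287), ("VAL", 288), ("ASN", 289), ("PHE", 290),
    ("GLY", 291), ("PRO", 292), ("ASN", 322), ("LYS", 323), ("ASP", 324), ("GLU", 325),
    ("GLY", 326), ("THR", 327), ("ALA", 328), ("PHE", 329), ("LEU", 330), ("VAL", 331),
    ("TYR", 332), ("GLY", 333), ("ALA", 334), ("GLY", 353), ("LEU", 354), ("LYS", 355),
    ("ILE", 356), ("PHE", 357), ("PHE", 358), ("PRO", 359), ("GLY", 360), ("VAL", 393),
    ("GLY", 394), ("TYR", 396), ("ASN", 397), ("PHE", 398), ("PRO", 401), ("LEU", 428),
    ("PRO", 429), ("TRP", 430), ("PRO", 431), ("GLU", 432), ("TRP", 433), ("MET", 434),
    ("GLY", 435), ("VAL", 436), ("MET", 437), ("HIS", 438), ("GLY", 439), ("TYR", 440),
    ("GLU", 441), ("ILE", 442), ("GLU", 443), ("PHE", 444), ("VAL", 445), ("PHE", 446),
    ("GLY", 447),
)

BCHE_ACTIVE_SITE_35: tuple[tuple[str, int], ...] = (
    ("ASP", 70), ("TRP", 82), ("ASN", 83), ("TYR", 114), ("GLY", 115), ("GLY", 116),
    ("GLY", 117), ("GLN", 119), ("THR", 120), ("GLY", 121), ("THR", 122), ("LEU", 125),
    ("TYR", 128), ("GLU", 197), ("SER", 198), ("ALA", 199), ("SER", 224), ("TRP", 231),
    ("PRO", 285), ("LEU", 286), ("SER", 287), ("VAL", 288), ("ASN", 289), ("ASP", 324),
    ("GLU", 325), ("GLY", 326), ("ALA", 328), ("PHE", 329), ("TYR", 332), ("PHE", 398),
    ("MET", 437), ("HIS", 438), ("GLY", 439), ("TYR", 440), ("ILE", 442),
)
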