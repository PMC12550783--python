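"""Reference constants: alphabets, masses, and the canonical residue selections
used throughout the MEK-ERK docking-interface analysis.

Residue numbering follows the human MEK1 / ERK2 convention: the five key
D-site residues sit at MEK positions 3, 5, 9, 11 and 16; the ERK
D-recruitment site (DRS) residues that receive them are 15, 81, 114, 119,
159, 162, 318 and 321; MEK's active site spans residues 216-222.
"""

from __future__ import annotations

import math

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
AMBIGUOUS: str = "X"
ALLOWED_CHARS = frozenset(AMINO_ACIDS) | {GAP, AMBIGUOUS}

#: log2(20): entropy of a uniform residue distribution, the upper bound in bits.
MAX_ENTROPY_BITS: float = math.log2(20.0)

#: N-terminal 32 residues of human MEK1 (the intrinsically disordered docking
#: region; UniProt A4QPA9 / Q02750 share this N terminus).
HUMAN_MEK1_NTERM: str = "MPKKKPTPIQLNPAPDGSAVNGTSSAETNLEA"

#: Key docking-site residues of MEK (human numbering).
DSITE_RESIDUES: tuple[int, ...] = (3, 5, 9, 11, 16)

#: ERK D-recruitment-site residues contacted by the D-site.
DRS_RESIDUES: tuple[int, ...] = (15, 81, 114, 119, 159, 162, 318, 321)

#: MEK active-site (A-site) residues probed for allosteric coupling.
ACTIVE_SITE_RESIDUES: tuple[int, ...] = tuple(range(216, 223))

#: Protein backbone atom names (O included by standard convention).
BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O"})

#: Default hydrophobic (Φ) class for the docking-motif grammar.
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset("LIVM")

#: Monoisotopic-free average atomic masses (Da) for the elements that occur in
#: protein heavy atoms plus hydrogen/deuterium.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

# Analysis thresholds (defaults; overridable per call).
DISTANCE_THRESHOLD: float = 0.2          # similarity-network edge cutoff (p-distance)
CONTACT_CUTOFF_ANGSTROM: float = 4.0     # non-hydrogen interchain contact rule
DISSOCIATION_THRESHOLD_ANGSTROM: float = 15.0  # COM-distance dissociation threshold
PLDDT_DISORDER_MAX: float = 50.0         # pLDDT below this => disordered
PLDDT_ORDER_MIN: float = 70.0            # pLDDT above this => well-ordered
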