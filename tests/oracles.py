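"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the motif oracle expands
the docking-motif grammar into concrete regular expressions, and the contact
oracle is a pure-Python all-pairs distance loop.
"""

from __future__ import annotations

import math
import re

PHI = "LIVM"


def regex_motif_matches(sequence: str) -> set[tuple[int, ...]]:
    """Key-position tuples for every match of
    K/R-X-K/R-X(2,3)-PHI-X-PHI-X(4,5)-D/E, via explicit repeat expansion."""
    seq = sequence.upper()
    found: set[tuple[int, ...]] = set()
    for m in (2, 3):
        for n in (4, 5):
            pat = re.compile(f"[KR].[KR].{{{m}}}[{PHI}].[{PHI}].{{{n}}}[DE]")
            for start in range(len(seq)):
                if pat.match(seq, start):
                    found.add(
                        (
                            start + 1,
                            start + 3,
                            start + 4 + m,
                            start + 6 + m,
                            start + 7 + m + n,
                        )
                    )
    return found


def brute_force_contact_map(model, chain_a, chain_b, cutoff):
    """All-pairs O(N^2) minimum non-hydrogen distance contact map as nested
    lists, rows/cols in chain residue order."""
    ca = next(c for c in model.chains if c.chain_id == chain_a)
    cb = next(c for c in model.chains if c.chain_id == chain_b)
    out = []
    for ra in ca.residues:
        row = []
        for rb in cb.residues:
            contact = 0
            for atom_a in ra.atoms:
                if atom_a.element in ("H", "D"):
                    continue
                for atom_b in rb.atoms:
                    if atom_b.element in ("H", "D"):
                        continue
                    d = math.dist(atom_a.xyz, atom_b.xyz)
                    if d <= cutoff:
                        contact = 1
            row.append(contact)
        out.append(row)
    return out


def entropy_by_counting(column: str) -> float:
    """Shannon entropy (bits) of the non-gap residues of one column, via a
    plain dictionary count."""
    counts: dict[str, int] = {}
    for c in column:
        if c not in "-X":
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    return -sum((k / total) * math.log2(k / total) for k in counts.values())
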