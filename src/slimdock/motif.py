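"""Docking-motif (SLiM) grammar and scanner.

The consensus D-site pattern is

    K/R - X - K/R - X(2,3) - PHI - X - PHI - X(4,5) - D/E

with five constrained "key" positions: two basic residues, two hydrophobics
(PHI, default {L,I,V,M}) and an acidic anchor.  On the human MEK1 N terminus
the keys land at positions 3, 5, 9, 11 and 16.  The scanner enumerates every
start offset and every wildcard-repeat expansion, deduplicating matches by
their key-position tuple; no best-match ranking is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError
from .reference import AMINO_ACIDS, HYDROPHOBIC_RESIDUES

__all__ = ["MotifElement", "MotifPattern", "MotifMatch", "consensus_pattern", "scan_motif"]


@dataclass(frozen=True)
class MotifElement:
    """One grammar element: a residue class (None = wildcard) with a repeat range."""

    residues: frozenset[str] | None
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.min_repeat < 0 or self.min_repeat > self.max_repeat:
            raise ConfigError(
                f"invalid repeat range {self.min_repeat}..{self.max_repeat}"
            )

    @property
    def is_wildcard(self) -> bool:
        return self.residues is None


@dataclass(frozen=True)
class MotifPattern:
    elements: tuple[MotifElement, ...]

    def __post_init__(self) -> None:
        if not any(not e.is_wildcard for e in self.elements):
            raise ConfigError("pattern needs at least one constrained element")

    @property
    def n_key_positions(self) -> int:
        """Number of constrained (non-wildcard) elements."""
        return sum(1 for e in self.elements if not e.is_wildcard)

    @property
    def min_span(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_span(self) -> int:
        return sum(e.max_repeat for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """A single motif hit in 1-based sequence coordinates."""

    start: int
    end: int
    key_positions: tuple[int, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def consensus_pattern(
    hydrophobic: frozenset[str] | str = HYDROPHOBIC_RESIDUES,
) -> MotifPattern:
    """The default D-site consensus K/R-X-K/R-X(2,3)-PHI-X-PHI-X(4,5)-D/E.

    The hydrophobic class is configurable; pass ``"LI"`` for the strict
    Leu/Ile reading.
    """
    phi = frozenset(hydrophobic)
    basic = frozenset("KR")
    acidic = frozenset("DE")
    wild = None
    return MotifPattern(
        elements=(
            MotifElement(basic),
            MotifElement(wild),
            MotifElement(basic),
            MotifElement(wild, 2, 3),
            MotifElement(phi),
            MotifElement(wild),
            MotifElement(phi),
            MotifElement(wild, 4, 5),
            MotifElement(acidic),
        )
    )


def scan_motif(sequence: str, pattern: MotifPattern) -> list[MotifMatch]:
    """All motif matches in an ungapped sequence.

    Every start offset and wildcard expansion is tried; matches sharing a
    key-position tuple are collapsed to the shortest span; results are ordered
    by start, then span.
    """
    seq = sequence.upper()
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ConfigError(f"sequence contains non-residue characters {sorted(bad)}")
    n = len(seq)
    elements = pattern.elements
    found: dict[tuple[int, ...], MotifMatch] = {}

    def extend(start: int, pos: int, idx: int, keys: list[int]) -> None:
        if idx == len(elements):
            key = tuple(keys)
            match = MotifMatch(start=start + 1, end=pos, key_positions=key)
            prev = found.get(key)
            if prev is None or (match.start, match.end) < (prev.start, prev.end):
                found[key] = match
            return
        el = elements[idx]
        for rep in range(el.min_repeat, el.max_repeat + 1):
            if pos + rep > n:
                break
            if el.residues is not None and any(
                seq[pos + k] not in el.residues for k in range(rep)
            ):
                break  # longer repeats include the failing residue
            if el.residues is not None and rep > 0:
                extend(start, pos + rep, idx + 1, keys + [pos + 1])
            else:
                extend(start, pos + rep, idx + 1, keys)

    for start in range(n):
        extend(start, start, 0, [])
    return sorted(found.values(), key=lambda m: (m.start, m.end, m.key_positions))
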