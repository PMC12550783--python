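"""Per-column conservation analysis of gapped protein alignments.

The conservation statistic is the per-column Shannon entropy

    H_j = -sum_a p_a(j) log2 p_a(j)    [bits]

computed over the amino-acid distribution of alignment column j.  Low entropy
means strong conservation; the maximum, log2(20) ~ 4.32 bits, corresponds to a
uniform distribution over the 20 residues.  Gap handling is explicit: under the
default ``exclude`` policy probabilities are renormalised over non-gap residues
and the gap fraction is reported separately, which is appropriate for gap-rich
disordered regions such as the MEK D-site.  The 'X' ambiguity code is treated
as gap-equivalent (no defensible residue distribution can be assigned to it).

Region extraction is reference-anchored and gap-aware: a domain annotation such
as "residues 1-32" refers to ungapped positions on a named reference sequence,
and the corresponding alignment columns are recovered by walking the gapped
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentShapeError, ConfigError, FormatError
from .reference import (
    ALLOWED_CHARS,
    AMBIGUOUS,
    AMINO_ACIDS,
    GAP,
    MAX_ENTROPY_BITS,
)

__all__ = [
    "AlignedSequenceSet",
    "EntropyProfile",
    "PositionFrequencyMatrix",
    "DomainAnnotation",
    "RegionExtraction",
    "read_fasta_alignment",
    "write_fasta",
    "shannon_entropy_profile",
    "extract_region",
    "frequency_matrix",
]


@dataclass(frozen=True)
class AlignedSequenceSet:
    """A gapped multiple sequence alignment over the amino-acid alphabet.

    Records preserve input order; ids are unique; all sequences share one
    length.  An empty record set is permitted (it arises when region
    extraction drops every sequence) and has length 0.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentShapeError("duplicate sequence ids in alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        if self.records and 0 in lengths:
            raise AlignmentShapeError("alignment length must be >= 1")
        for sid, seq in self.records:
            bad = set(seq) - ALLOWED_CHARS
            if bad:
                raise FormatError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        """Number of alignment columns (0 for an empty set)."""
        return len(self.records[0][1]) if self.records else 0

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(seq for _, seq in self.records)

    def get(self, sid: str) -> str:
        for rid, seq in self.records:
            if rid == sid:
                return seq
        raise ConfigError(f"sequence id {sid!r} not in alignment")

    def to_matrix(self) -> np.ndarray:
        """Character matrix of shape (n_sequences, length), dtype '<U1'."""
        return np.array([list(seq) for seq in self.sequences], dtype="<U1").reshape(
            self.n_sequences, self.length
        )


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column Shannon entropy (bits), gap fraction, and effective counts."""

    entropy: np.ndarray
    gap_fraction: np.ndarray
    n_effective: np.ndarray
    gap_policy: str = "exclude"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, len(self.entropy) + 1),
                "entropy_bits": self.entropy,
                "gap_fraction": self.gap_fraction,
                "n_effective": self.n_effective,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Column-wise residue probabilities and information content.

    ``probs`` has one row per alignment column and one column per residue in
    ``alphabet`` order; rows sum to 1 over non-gap mass (all-zero for all-gap
    columns).  ``info_content`` is the logo height R_j = log2(20) - H_j in
    bits, optionally with the small-sample correction subtracted.
    """

    probs: np.ndarray
    info_content: np.ndarray
    gap_fraction: np.ndarray
    alphabet: str = AMINO_ACIDS

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(self.alphabet))
        df.insert(0, "column", np.arange(1, len(df) + 1))
        df["info_bits"] = self.info_content
        df["gap_fraction"] = self.gap_fraction
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class DomainAnnotation:
    """A named region in 1-based inclusive ungapped reference coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ConfigError(
                f"annotation {self.name!r}: require 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )


@dataclass(frozen=True)
class RegionExtraction:
    """Result of gap-aware region extraction: the column slice plus bookkeeping
    about sequences dropped for being entirely gapped within the region."""

    alignment: AlignedSequenceSet
    excluded_ids: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()
    columns: tuple[int, int] | None = None  # 1-based inclusive column span

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)


def read_fasta_alignment(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA file.

    Sequences are uppercased and '.' gaps normalised to '-'.  Ragged record
    lengths raise :class:`AlignmentShapeError`; an empty file raises
    :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records = [
        (rec.id, str(rec.seq).upper().replace(".", GAP))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return AlignedSequenceSet(tuple(records))


def write_fasta(msa: AlignedSequenceSet, path: str | Path, width: int = 60) -> None:
    """Write an alignment (or ungapped set) as plain FASTA."""
    with open(path, "w") as fh:
        for sid, seq in msa.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _column_counts(msa: AlignedSequenceSet) -> tuple[np.ndarray, np.ndarray]:
    """Residue counts (20, L) and gap-like counts (L,) per column."""
    mat = msa.to_matrix()
    counts = np.stack([(mat == aa).sum(axis=0) for aa in AMINO_ACIDS])
    gaplike = ((mat == GAP) | (mat == AMBIGUOUS)).sum(axis=0)
    return counts.astype(float), gaplike.astype(float)


def shannon_entropy_profile(
    msa: AlignedSequenceSet, gap_policy: str = "exclude"
) -> EntropyProfile:
    """Per-column Shannon entropy H_j in bits.

    Under ``exclude`` (default) the distribution is over non-gap residues and
    all-gap columns yield NaN; under ``as_symbol`` the gap counts as a 21st
    symbol.  'X' is gap-equivalent under both policies.
    """
    if msa.n_sequences == 0:
        raise ConfigError("cannot profile an empty alignment")
    if gap_policy not in ("exclude", "as_symbol"):
        raise ConfigError(f"unknown gap_policy {gap_policy!r}")
    counts, gaplike = _column_counts(msa)
    n = float(msa.n_sequences)
    n_eff = n - gaplike
    gap_fraction = gaplike / n

    if gap_policy == "as_symbol":
        full = np.vstack([counts, gaplike])
        probs = full / n
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(n_eff > 0, counts / np.where(n_eff > 0, n_eff, 1.0), 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        logp = np.where(probs > 0, np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
    entropy = -(probs * logp).sum(axis=0)
    if gap_policy == "exclude":
        entropy = np.where(n_eff > 0, entropy, np.nan)
    return EntropyProfile(
        entropy=entropy,
        gap_fraction=gap_fraction,
        n_effective=n_eff.astype(int),
        gap_policy=gap_policy,
    )


def frequency_matrix(
    msa: AlignedSequenceSet, small_sample_correction: bool = False
) -> PositionFrequencyMatrix:
    """Per-column residue probabilities (non-gap mass) and logo information
    content R_j = log2(20) - H_j.

    All-gap columns get a zero probability row and NaN information content.
    ``small_sample_correction`` subtracts the standard bias term
    e_n = 19 / (2 ln2 n_eff) from R_j (clipped at 0).
    """
    if msa.n_sequences == 0:
        raise ConfigError("cannot profile an empty alignment")
    counts, gaplike = _column_counts(msa)
    n = float(msa.n_sequences)
    n_eff = n - gaplike
    denom = np.where(n_eff > 0, n_eff, 1.0)
    probs = (counts / denom).T  # (L, 20)
    probs[n_eff == 0, :] = 0.0

    with np.errstate(invalid="ignore", divide="ignore"):
        logp = np.where(probs > 0, np.log2(np.where(probs > 0, probs, 1.0)), 0.0)
    entropy = -(probs * logp).sum(axis=1)
    info = MAX_ENTROPY_BITS - entropy
    if small_sample_correction:
        correction = np.where(n_eff > 0, 19.0 / (2.0 * np.log(2.0) * denom), 0.0)
        info = np.maximum(info - correction, 0.0)
    info = np.where(n_eff > 0, info, np.nan)
    return PositionFrequencyMatrix(
        probs=probs, info_content=info, gap_fraction=gaplike / n
    )


def extract_region(
    msa: AlignedSequenceSet,
    annotation: DomainAnnotation,
    reference_id: str,
) -> RegionExtraction:
    """Extract the alignment columns spanning an annotated reference region.

    The annotation is in ungapped 1-based coordinates on ``reference_id``;
    the returned slice runs from the column of the first annotated residue to
    the column of the last (internal gap columns included).  Sequences that
    are entirely gaps within the region are dropped and reported.  A reference
    that lacks the region entirely yields an empty result with a warning.
    """
    ref = msa.get(reference_id)
    residue_columns = [j for j, c in enumerate(ref) if c != GAP]
    warn: list[str] = []
    if annotation.start > len(residue_columns):
        warn.append(
            f"reference {reference_id!r} has only {len(residue_columns)} residues; "
            f"region {annotation.name!r} ({annotation.start}..{annotation.end}) absent"
        )
        return RegionExtraction(AlignedSequenceSet(()), warnings=tuple(warn))
    end = annotation.end
    if end > len(residue_columns):
        warn.append(
            f"region {annotation.name!r} truncated to reference length "
            f"{len(residue_columns)}"
        )
        end = len(residue_columns)
    c0 = residue_columns[annotation.start - 1]
    c1 = residue_columns[end - 1]

    kept: list[tuple[str, str]] = []
    excluded: list[str] = []
    for sid, seq in msa.records:
        sub = seq[c0 : c1 + 1]
        if set(sub) <= {GAP}:
            excluded.append(sid)
        else:
            kept.append((sid, sub))
    return RegionExtraction(
        alignment=AlignedSequenceSet(tuple(kept)),
        excluded_ids=tuple(excluded),
        warnings=tuple(warn),
        columns=(c0 + 1, c1 + 1),
    )
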