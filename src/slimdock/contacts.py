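"""Interchain residue contact maps and pLDDT-based disorder classification.

A residue pair (one residue per chain) is in contact when any pair of
non-hydrogen atoms lies within the cutoff (default 4.0 Å, inclusive).  Contact
maps may be restricted to declared residue subsets, e.g. the five D-site key
residues against the eight DRS residues.  Per-residue model confidence is read
from the B-factor column (AlphaFold convention: pLDDT in [0, 100]) and binned
into disordered (< 50), intermediate, and well-ordered (> 70).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError, FormatError
from .reference import (
    ATOMIC_MASSES,
    CONTACT_CUTOFF_ANGSTROM,
    PLDDT_DISORDER_MAX,
    PLDDT_ORDER_MIN,
)

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "ContactMap",
    "ConfidenceProfile",
    "MapComparison",
    "read_structure",
    "write_pdb",
    "write_mmcif",
    "interchain_contact_map",
    "confidence_profile",
    "compare_maps",
]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    bfactor: float = 0.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element, 12.011)


@dataclass(frozen=True)
class Residue:
    number: int
    name: str
    atoms: tuple[Atom, ...]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms if not a.is_hydrogen], dtype=float)


@dataclass(frozen=True)
class Chain:
    chain_id: str
    residues: tuple[Residue, ...]

    def residue(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise ConfigError(f"residue {number} not in chain {self.chain_id!r}")


@dataclass(frozen=True)
class StructureModel:
    """A parsed complex: chains of residues of atoms, with per-atom B-factor
    carrying model confidence for AlphaFold-convention files."""

    chains: tuple[Chain, ...]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ConfigError(
            f"chain {chain_id!r} not in model (have {[c.chain_id for c in self.chains]})"
        )


@dataclass(frozen=True)
class ContactMap:
    """Residue-pair contact matrix between two chains.

    ``values`` is binary {0, 1} for a single structure or an occupancy
    fraction in [0, 1] over trajectory frames.  ``min_distances`` retains the
    per-pair minimum heavy-atom distance for binary maps.
    """

    row_residues: tuple[tuple[str, int], ...]
    col_residues: tuple[tuple[str, int], ...]
    values: np.ndarray
    cutoff: float
    kind: str = "binary"
    min_distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_residues), len(self.col_residues)):
            raise DataError("contact-map shape does not match residue axes")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise DataError("contact values must lie in [0, 1]")

    def transpose(self) -> "ContactMap":
        return ContactMap(
            row_residues=self.col_residues,
            col_residues=self.row_residues,
            values=self.values.T.copy(),
            cutoff=self.cutoff,
            kind=self.kind,
            min_distances=None if self.min_distances is None else self.min_distances.T.copy(),
        )

    def support(self, threshold: float = 0.5) -> set[tuple[tuple[str, int], tuple[str, int]]]:
        """Residue pairs in contact (binary: value == 1; occupancy: >= threshold)."""
        pairs = set()
        for i, rr in enumerate(self.row_residues):
            for j, cc in enumerate(self.col_residues):
                v = self.values[i, j]
                if (self.kind == "binary" and v >= 0.5) or (
                    self.kind != "binary" and v >= threshold
                ):
                    pairs.add((rr, cc))
        return pairs

    def to_dataframe(self) -> pd.DataFrame:
        rows = [f"{c}:{n}" for c, n in self.row_residues]
        cols = [f"{c}:{n}" for c, n in self.col_residues]
        return pd.DataFrame(self.values, index=rows, columns=cols)

    def to_long_dataframe(self) -> pd.DataFrame:
        recs = [
            (ra[0], ra[1], rb[0], rb[1], self.values[i, j])
            for i, ra in enumerate(self.row_residues)
            for j, rb in enumerate(self.col_residues)
        ]
        return pd.DataFrame(recs, columns=["chain_a", "res_a", "chain_b", "res_b", "value"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class ConfidenceProfile:
    """Per-residue pLDDT values with disorder classes at the 50/70 thresholds."""

    chain_id: str
    residue_numbers: tuple[int, ...]
    plddt: np.ndarray
    classes: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": self.chain_id,
                "residue": self.residue_numbers,
                "plddt": self.plddt,
                "class": self.classes,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class MapComparison:
    """Set algebra between a binary (predicted) and an occupancy (trajectory)
    contact map thresholded at ``occupancy_threshold``."""

    shared: tuple
    prediction_only: tuple
    trajectory_only: tuple
    jaccard: float
    occupancy_threshold: float


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ATOMIC_MASSES:
        return stripped[:2].upper()
    return stripped[0].upper()


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF structure (first model only).

    Hydrogens are retained but flagged via their element; water/hetero records
    are skipped; insertion codes are rejected; for disordered atoms the
    highest-occupancy conformer is kept.  A file with no polymer residues is
    an error.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or ("mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")
    if fmt not in ("pdb", "mmcif"):
        raise ConfigError(f"unknown structure format {fmt!r}")
    parser = MMCIFParser(QUIET=True) if fmt == "mmcif" else PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("model", str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    models = list(structure.get_models())
    if not models:
        raise FormatError(f"no models in {path}")
    chains = []
    for ch in models[0]:
        residues = []
        for res in ch:
            hetflag, number, icode = res.id
            if hetflag.strip():
                continue  # water and other HETATM records are not polymer
            if icode.strip():
                raise DataError(
                    f"insertion code {icode!r} at {ch.id}:{number} not supported "
                    "(AlphaFold-convention models have none)"
                )
            atoms = []
            for atom in res:
                if atom.is_disordered():
                    atom = max(
                        atom.disordered_get_list(),
                        key=lambda a: a.get_occupancy() or 0.0,
                    )
                element = (atom.element or "").strip().upper()
                if element not in ATOMIC_MASSES:
                    inferred = _infer_element(atom.get_name())
                    warnings.warn(
                        f"unknown element for atom {atom.get_name()!r}; "
                        f"inferred {inferred!r}"
                    )
                    element = inferred
                coord = np.asarray(atom.coord, dtype=float)
                if not np.all(np.isfinite(coord)):
                    raise DataError(f"non-finite coordinates at {ch.id}:{number}")
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=element,
                        xyz=tuple(float(x) for x in coord),
                        bfactor=float(atom.get_bfactor() or 0.0),
                    )
                )
            if atoms:
                residues.append(Residue(int(number), res.get_resname(), tuple(atoms)))
        if residues:
            chains.append(Chain(str(ch.id), tuple(residues)))
    if not chains:
        raise DataError(f"no polymer residues in {path}")
    return StructureModel(tuple(chains))


def _to_biopdb_structure(model: StructureModel):
    from Bio.PDB.StructureBuilder import StructureBuilder

    sb = StructureBuilder()
    sb.init_structure("model")
    sb.init_model(0)
    serial = 1
    for chain in model.chains:
        sb.init_chain(chain.chain_id)
        sb.init_seg("    ")
        for res in chain.residues:
            sb.init_residue(res.name, " ", res.number, " ")
            for atom in res.atoms:
                fullname = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                sb.init_atom(
                    atom.name,
                    np.array(atom.xyz, dtype=float),
                    atom.bfactor,
                    1.0,
                    " ",
                    fullname,
                    serial_number=serial,
                    element=atom.element,
                )
                serial += 1
    return sb.get_structure()


def write_pdb(model: StructureModel, path: str | Path) -> None:
    from Bio.PDB import PDBIO

    io = PDBIO()
    io.set_structure(_to_biopdb_structure(model))
    io.save(str(path))


def write_mmcif(model: StructureModel, path: str | Path) -> None:
    from Bio.PDB.mmcifio import MMCIFIO

    io = MMCIFIO()
    io.set_structure(_to_biopdb_structure(model))
    io.save(str(path))


def _gather_heavy(
    chain: Chain, subset: tuple[int, ...] | None
) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    """Residue axis (subset order preserved), heavy-atom coords and their
    residue indices."""
    if subset is not None:
        missing = [n for n in subset if n not in {r.number for r in chain.residues}]
        if missing:
            raise ConfigError(
                f"residues {missing} not in chain {chain.chain_id!r}"
            )
        residues = [chain.residue(n) for n in subset]
    else:
        residues = list(chain.residues)
    if not residues:
        raise ConfigError(f"empty residue selection on chain {chain.chain_id!r}")
    axis = [(chain.chain_id, r.number) for r in residues]
    coords, ridx = [], []
    for i, r in enumerate(residues):
        hv = r.heavy_coords()
        if hv.size:
            coords.append(hv)
            ridx.append(np.full(len(hv), i))
    if coords:
        return axis, np.vstack(coords), np.concatenate(ridx)
    return axis, np.empty((0, 3)), np.empty(0, dtype=int)


def min_heavy_distances(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    subset_a: tuple[int, ...] | None = None,
    subset_b: tuple[int, ...] | None = None,
) -> tuple[tuple[tuple[str, int], ...], tuple[tuple[str, int], ...], np.ndarray]:
    """Minimum non-hydrogen atom-pair distance for every interchain residue
    pair (inf where a residue has no heavy atoms)."""
    axis_a, xa, ra = _gather_heavy(model.chain(chain_a), subset_a)
    axis_b, xb, rb = _gather_heavy(model.chain(chain_b), subset_b)
    mind = np.full((len(axis_a), len(axis_b)), np.inf)
    if len(xa) and len(xb):
        d = cdist(xa, xb)
        np.minimum.at(mind, (ra[:, None], rb[None, :]), d)
    return tuple(axis_a), tuple(axis_b), mind


def interchain_contact_map(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    cutoff: float = CONTACT_CUTOFF_ANGSTROM,
    subset_a: tuple[int, ...] | None = None,
    subset_b: tuple[int, ...] | None = None,
) -> ContactMap:
    """Binary interchain contact map: entry (i, j) = 1 iff some non-hydrogen
    atom pair between the residues lies within ``cutoff`` (inclusive)."""
    axis_a, axis_b, mind = min_heavy_distances(model, chain_a, chain_b, subset_a, subset_b)
    values = (mind <= cutoff).astype(float)
    return ContactMap(
        row_residues=axis_a,
        col_residues=axis_b,
        values=values,
        cutoff=cutoff,
        kind="binary",
        min_distances=mind,
    )


def confidence_profile(model: StructureModel, chain: str) -> ConfidenceProfile:
    """Per-residue pLDDT from the B-factor column (Cα representative, mean over
    atoms as fallback) classified at the 50/70 disorder thresholds."""
    ch = model.chain(chain)
    numbers, values, classes = [], [], []
    for res in ch.residues:
        ca = [a for a in res.atoms if a.name == "CA"]
        if ca:
            v = ca[0].bfactor
        else:
            v = float(np.mean([a.bfactor for a in res.atoms]))
        numbers.append(res.number)
        values.append(v)
        if v < PLDDT_DISORDER_MAX:
            classes.append("disordered")
        elif v > PLDDT_ORDER_MIN:
            classes.append("ordered")
        else:
            classes.append("intermediate")
    arr = np.array(values, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 100):
        warnings.warn(
            f"B-factors on chain {chain!r} outside [0, 100]: not an "
            "AlphaFold-convention confidence column"
        )
    return ConfidenceProfile(
        chain_id=chain,
        residue_numbers=tuple(numbers),
        plddt=arr,
        classes=tuple(classes),
    )


def compare_maps(
    binary: ContactMap, occupancy: ContactMap, occupancy_threshold: float = 0.5
) -> MapComparison:
    """Overlap between a predicted binary map and a trajectory occupancy map
    thresholded at ``occupancy_threshold`` (Jaccard = 1 when both are empty)."""
    if (
        binary.row_residues != occupancy.row_residues
        or binary.col_residues != occupancy.col_residues
    ):
        raise DataError("contact maps have mismatched residue axes")
    sb = binary.support()
    so = occupancy.support(occupancy_threshold)
    union = sb | so
    jaccard = 1.0 if not union else len(sb & so) / len(union)
    return MapComparison(
        shared=tuple(sorted(sb & so)),
        prediction_only=tuple(sorted(sb - so)),
        trajectory_only=tuple(sorted(so - sb)),
        jaccard=jaccard,
        occupancy_threshold=occupancy_threshold,
    )
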