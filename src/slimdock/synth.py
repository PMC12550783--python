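"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the three data layers:

* ``generate_group_msa`` — docking-site alignments composed of several
  internally conserved, mutually divergent groups.  Each group's consensus is
  a synthetic motif-bearing sequence (the default set of four is loosely
  inspired by the vertebrate / fish / nematode / insect clades but is not any
  real clade consensus); sequences are sampled by i.i.d. substitution, and
  planted group labels are returned for recovery tests.

* ``generate_trajectory`` — two pseudo-residue clusters whose COM separation
  follows a truncated discrete Ornstein-Uhlenbeck process around a bound mean
  (emulating the 5-10 Å fluctuation band of a stably docked motif) until, in
  escape mode, a planted switch time after which the separation drifts
  outward at constant speed.  The planted first-crossing time of the 15 Å
  threshold is returned as ground truth.  No physical realism is claimed; the
  process is the simplest one with a tunable stationary band and an exactly
  known dissociation time.

* ``generate_interface_structure`` — a two-chain pseudo-complex with planted
  interchain contacts (closest heavy-atom distance kept below cutoff minus a
  safety margin) and decoy pairs kept above cutoff plus the margin, with a
  pLDDT profile written into the B-factor column.

All generators are deterministic given their seed, and every generated object
round-trips through the package's public readers (FASTA, PDB, plain-text
frames), never through privileged code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import AlignedSequenceSet
from .contacts import Atom, Chain, ContactMap, Residue, StructureModel, interchain_contact_map
from .errors import ConfigError, DataError
from .kinetics import TrajectoryBundle, dissociation_time
from .reference import (
    AMINO_ACIDS,
    ATOMIC_MASSES,
    CONTACT_CUTOFF_ANGSTROM,
    DISSOCIATION_THRESHOLD_ANGSTROM,
    DRS_RESIDUES,
    DSITE_RESIDUES,
    GAP,
)

__all__ = [
    "GroupMsaSpec",
    "TrajectorySpec",
    "InterfaceSpec",
    "SyntheticMsa",
    "SyntheticTrajectory",
    "SyntheticInterface",
    "DEFAULT_GROUP_CONSENSUS",
    "generate_group_msa",
    "generate_trajectory",
    "generate_interface_structure",
]

#: Four synthetic 20-mer group consensi, each carrying one instance of the
#: K/R-X-K/R-X(2,3)-PHI-X-PHI-X(4,5)-D/E docking motif at keys {3,5,9,11,16}
#: and mutually divergent elsewhere.
DEFAULT_GROUP_CONSENSUS: tuple[str, ...] = (
    "MPKKKPTPIQLNPAPDSQHV",  # vertebrate-like
    "ASRTRGSAVEIDANSETGKA",  # fish-like
    "GNKEKNNGLSMTGGTDPWYF",  # nematode-like
    "TWRNRWWTIPLGWSQEFMNT",  # insect-like
)

_BACKBONE_TEMPLATE: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("N", "N", (-0.70, 0.35, 0.00)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (0.70, 0.35, 0.00)),
    ("O", "O", (0.95, -0.60, 0.45)),
)


@dataclass(frozen=True)
class GroupMsaSpec:
    """Study conditions for the grouped docking-site alignment: 4 groups x 50
    sequences at 5% per-position substitution noise, no indels by default."""

    seed: int
    consensus: tuple[str, ...] = DEFAULT_GROUP_CONSENSUS
    n_per_group: int = 50
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    max_indel: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 1) or not (0 <= self.indel_rate < 1):
            raise ConfigError("rates must lie in [0, 1)")
        if len(set(self.consensus)) != len(self.consensus):
            raise ConfigError("group consensus sequences must be mutually distinct")
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        for c in self.consensus:
            bad = set(c) - set(AMINO_ACIDS)
            if bad:
                raise ConfigError(f"consensus contains non-residues {sorted(bad)}")


@dataclass(frozen=True)
class SyntheticMsa:
    alignment: AlignedSequenceSet
    labels: dict[str, int]  # id -> planted group index


@dataclass(frozen=True)
class TrajectorySpec:
    """Study conditions for one synthetic trajectory: 1000 frames at 1 ns
    emulating a 1 μs run, bound band 7.5 ± 0.8 Å (within the observed 5-10 Å
    range), escape planted at 300 ns drifting out at 0.5 Å/ns."""

    seed: int
    mode: str = "bound"
    n_frames: int = 1000
    dt_ns: float = 1.0
    bound_mean: float = 7.5
    bound_sd: float = 0.8
    escape_time_ns: float = 300.0
    escape_speed: float = 0.5
    relaxation_ns: float = 5.0
    jitter: float = 0.02
    ligand_chain: str = "MEK"
    receptor_chain: str = "ERK"
    ligand_residues: tuple[int, ...] = DSITE_RESIDUES
    receptor_residues: tuple[int, ...] = DRS_RESIDUES

    def __post_init__(self) -> None:
        if self.mode not in ("bound", "escape"):
            raise ConfigError(f"unknown trajectory mode {self.mode!r}")
        if self.bound_mean - 3 * self.bound_sd <= 0:
            raise ConfigError("require bound_mean - 3*bound_sd > 0")
        if self.n_frames < 2 or self.dt_ns <= 0:
            raise ConfigError("need >= 2 frames with positive dt")
        if self.mode == "escape":
            if not (0 <= self.escape_time_ns < (self.n_frames - 1) * self.dt_ns):
                raise ConfigError("escape_time_ns must fall within the run")
            if self.escape_speed <= 0:
                raise ConfigError("escape_speed must be positive")


@dataclass(frozen=True)
class SyntheticTrajectory:
    bundle: TrajectoryBundle
    t_d_true: float | None
    planted_distance: np.ndarray


@dataclass(frozen=True)
class InterfaceSpec:
    """Planted-contact pseudo-complex.  Default: each of the five docking-site
    residues (chain A) contacts one of the eight DRS residues (chain B), with
    B-factors encoding an ordered interface."""

    seed: int
    dsite_residues: tuple[int, ...] = DSITE_RESIDUES
    drs_residues: tuple[int, ...] = DRS_RESIDUES
    planted_pairs: tuple[tuple[int, int], ...] = (
        (3, 81),
        (5, 162),
        (9, 119),
        (11, 159),
        (16, 114),
    )
    cutoff: float = CONTACT_CUTOFF_ANGSTROM
    jitter: float = 0.4
    contact_distance: float = 3.0
    plddt: dict = field(default_factory=lambda: {"A": 75.0, "B": 90.0})
    chain_a: str = "A"
    chain_b: str = "B"

    def __post_init__(self) -> None:
        for a, b in self.planted_pairs:
            if a not in self.dsite_residues or b not in self.drs_residues:
                raise ConfigError(f"planted pair ({a}, {b}) outside declared axes")
        if self.jitter < 0 or self.contact_distance + self.jitter >= self.cutoff:
            raise ConfigError(
                "need contact_distance + jitter < cutoff for realizable geometry"
            )


@dataclass(frozen=True)
class SyntheticInterface:
    model: StructureModel
    planted_map: ContactMap


def generate_group_msa(spec: GroupMsaSpec) -> SyntheticMsa:
    """Sample grouped sequences by i.i.d. substitution (uniform over the other
    19 residues).  With ``indel_rate > 0`` a random insert of 1..max_indel
    residues is planted at the mid-sequence linker position and all sequences
    are gap-padded there, left-justified (a deterministic placement rule);
    consensus length differences are padded at the right end."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    records: list[tuple[str, str, str]] = []  # (id, core, insert)
    labels: dict[str, int] = {}
    for gi, cons in enumerate(spec.consensus):
        base = np.array(list(cons))
        for si in range(spec.n_per_group):
            seq = base.copy()
            mutate = rng.random(len(seq)) < spec.substitution_rate
            for j in np.flatnonzero(mutate):
                choices = aa[aa != seq[j]]
                seq[j] = choices[rng.integers(len(choices))]
            insert = ""
            if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
                k = int(rng.integers(1, spec.max_indel + 1))
                insert = "".join(aa[rng.integers(len(aa), size=k)])
            sid = f"g{gi}_s{si}"
            records.append((sid, "".join(seq), insert))
            labels[sid] = gi

    max_insert = max(len(ins) for _, _, ins in records)
    max_core = max(len(core) for _, core, _ in records)
    aligned: list[tuple[str, str]] = []
    for sid, core, ins in records:
        linker = len(core) // 2
        padded_insert = ins + GAP * (max_insert - len(ins))
        seq = core[:linker] + padded_insert + core[linker:]
        seq += GAP * (max_core - len(core))
        aligned.append((sid, seq))
    return SyntheticMsa(alignment=AlignedSequenceSet(tuple(aligned)), labels=labels)


def _residue_layout(n: int, spread: float) -> np.ndarray:
    """Deterministic compact residue-center layout with zero mean."""
    centers = np.zeros((n, 3))
    for i in range(n):
        row, col = divmod(i, 4)
        centers[i] = (col * spread, row * spread, 0.0)
    return centers - centers.mean(axis=0)


def _cluster_atoms(
    chain: str, residues: tuple[int, ...], spread: float
) -> tuple[list[tuple[str, int, str, str, float]], np.ndarray]:
    """Atom table rows and mass-centered offsets for one pseudo-residue cluster."""
    centers = _residue_layout(len(residues), spread)
    rows, offsets, masses = [], [], []
    for center, resnum in zip(centers, residues):
        for name, element, delta in _BACKBONE_TEMPLATE:
            rows.append((chain, resnum, name, element, ATOMIC_MASSES[element]))
            offsets.append(center + np.array(delta))
            masses.append(ATOMIC_MASSES[element])
    offsets = np.array(offsets)
    masses = np.array(masses)
    com = (offsets * masses[:, None]).sum(axis=0) / masses.sum()
    return rows, offsets - com  # mass-weighted COM exactly at the origin


def generate_trajectory(spec: TrajectorySpec) -> SyntheticTrajectory:
    """Synthesise a docking trajectory with an exactly known dissociation time.

    The receptor cluster is held fixed with its mass-weighted COM at the
    origin; the ligand cluster's COM sits at (d(t), 0, 0) where d(t) is a
    truncated discrete OU process (stationary mean ``bound_mean``, sd
    ``bound_sd``, relaxation time ``relaxation_ns``, clipped at ±4 sd) until
    the planted escape time, after which it drifts outward at
    ``escape_speed``.  Ligand atoms get per-frame Gaussian jitter; the ground
    truth t_D is the first planted-series crossing of the 15 Å threshold.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.n_frames, dtype=float) * spec.dt_ns

    phi = np.exp(-spec.dt_ns / spec.relaxation_ns)
    innov_sd = spec.bound_sd * np.sqrt(1.0 - phi**2)
    lo, hi = spec.bound_mean - 4 * spec.bound_sd, spec.bound_mean + 4 * spec.bound_sd
    d = np.empty(spec.n_frames)
    d[0] = spec.bound_mean
    noise = rng.normal(0.0, innov_sd, size=spec.n_frames)
    escaped_at: float | None = None
    for t in range(1, spec.n_frames):
        if spec.mode == "escape" and times[t] >= spec.escape_time_ns:
            if escaped_at is None:
                escaped_at = times[t - 1]
                d_escape = d[t - 1]
            d[t] = d_escape + spec.escape_speed * (times[t] - escaped_at)
        else:
            d[t] = np.clip(spec.bound_mean + phi * (d[t - 1] - spec.bound_mean) + noise[t], lo, hi)

    t_d_true = dissociation_time(d, times, DISSOCIATION_THRESHOLD_ANGSTROM)
    if spec.mode == "escape" and t_d_true is None:
        raise DataError(
            "escape trajectory never crossed the dissociation threshold; "
            "increase escape_speed or run length"
        )

    rec_rows, rec_offsets = _cluster_atoms(
        spec.receptor_chain, spec.receptor_residues, spread=3.0
    )
    lig_rows, lig_offsets = _cluster_atoms(
        spec.ligand_chain, spec.ligand_residues, spread=2.5
    )
    atom_table = pd.DataFrame(
        rec_rows + lig_rows, columns=["chain", "resnum", "name", "element", "mass"]
    )
    n_rec, n_lig = len(rec_rows), len(lig_rows)
    frames = np.empty((spec.n_frames, n_rec + n_lig, 3))
    frames[:, :n_rec] = rec_offsets[None, :, :]
    lig_com = np.zeros((spec.n_frames, 3))
    lig_com[:, 0] = d
    jitter = rng.normal(0.0, spec.jitter, size=(spec.n_frames, n_lig, 3))
    frames[:, n_rec:] = lig_com[:, None, :] + lig_offsets[None, :, :] + jitter

    bundle = TrajectoryBundle(frames=frames, times=times, atom_table=atom_table)
    return SyntheticTrajectory(bundle=bundle, t_d_true=t_d_true, planted_distance=d)


def generate_interface_structure(spec: InterfaceSpec) -> SyntheticInterface:
    """Build the planted-contact pseudo-complex and verify it reproduces its
    own contact map at the declared cutoff (else raise a construction error).

    Receptor (chain B) residues are spaced 18 Å apart along a line; each
    docking residue (chain A) with planted partners is placed at the partner
    centroid offset so its closest heavy atoms sit near ``contact_distance``;
    residues without partners are parked far from the interface.  A small
    seeded perturbation (<= jitter/4 per coordinate) keeps the geometry
    non-idealised without violating the realizability margins.
    """
    rng = np.random.default_rng(spec.seed)

    def perturb() -> np.ndarray:
        return rng.uniform(-spec.jitter / 4.0, spec.jitter / 4.0, size=3)

    def make_residue(resnum: int, center: np.ndarray, plddt: float) -> Residue:
        atoms = []
        for name, element, delta in _BACKBONE_TEMPLATE:
            xyz = center + np.array(delta) * 0.6 + perturb()
            atoms.append(
                Atom(name=name, element=element, xyz=tuple(xyz), bfactor=plddt)
            )
        return Residue(number=resnum, name="GLY", atoms=tuple(atoms))

    def plddt_for(chain: str, i: int) -> float:
        value = spec.plddt.get(chain, 70.0)
        if np.isscalar(value):
            return float(value)
        return float(value[i])

    b_centers = {
        rn: np.array([18.0 * i, 0.0, 0.0]) for i, rn in enumerate(spec.drs_residues)
    }
    chain_b = Chain(
        spec.chain_b,
        tuple(
            make_residue(rn, b_centers[rn], plddt_for(spec.chain_b, i))
            for i, rn in enumerate(spec.drs_residues)
        ),
    )

    partners: dict[int, list[int]] = {a: [] for a in spec.dsite_residues}
    for a, b in spec.planted_pairs:
        partners[a].append(b)
    a_residues = []
    far = 120.0
    for i, rn in enumerate(spec.dsite_residues):
        if partners[rn]:
            centroid = np.mean([b_centers[b] for b in partners[rn]], axis=0)
            center = centroid + np.array([0.0, spec.contact_distance, 0.0])
        else:
            center = np.array([18.0 * i, far, 0.0])
        a_residues.append(make_residue(rn, center, plddt_for(spec.chain_a, i)))
    chain_a = Chain(spec.chain_a, tuple(a_residues))
    model = StructureModel((chain_a, chain_b))

    planted_values = np.zeros((len(spec.dsite_residues), len(spec.drs_residues)))
    for a, b in spec.planted_pairs:
        planted_values[spec.dsite_residues.index(a), spec.drs_residues.index(b)] = 1.0
    planted = ContactMap(
        row_residues=tuple((spec.chain_a, n) for n in spec.dsite_residues),
        col_residues=tuple((spec.chain_b, n) for n in spec.drs_residues),
        values=planted_values,
        cutoff=spec.cutoff,
        kind="binary",
    )

    realized = interchain_contact_map(
        model,
        spec.chain_a,
        spec.chain_b,
        cutoff=spec.cutoff,
        subset_a=spec.dsite_residues,
        subset_b=spec.drs_residues,
    )
    if not np.array_equal(realized.values, planted.values):
        raise DataError("unrealizable planted-contact geometry for this spec")
    # Enforce the margin contract: planted pairs below cutoff - jitter, decoys above.
    assert realized.min_distances is not None
    on = planted_values.astype(bool)
    if np.any(realized.min_distances[on] > spec.cutoff - spec.jitter) or np.any(
        realized.min_distances[~on] < spec.cutoff + spec.jitter
    ):
        raise DataError("planted-contact margins violated; reduce jitter or spacing")
    return SyntheticInterface(model=model, planted_map=planted)
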