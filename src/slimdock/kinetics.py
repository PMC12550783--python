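"""Trajectory statistics for docking-motif dissociation and allostery.

The order parameter for binding is the distance between the centers of mass
(COM) of two residue selections — canonically the backbone atoms of the five
MEK D-site key residues and of the eight ERK DRS residues.  For trajectory i
the dissociation time t_D^(i) is the earliest frame at which this distance
strictly exceeds a threshold (default 15 Å); the binary indicator

    eta_i(t) = 0 for t < t_D^(i),  1 for t >= t_D^(i)

averaged over N trajectories gives the cumulative fraction dissociated
F(t) = (1/N) sum_i eta_i(t), a right-continuous non-decreasing step function
with values in {0, 1/N, ..., 1} (plateaus below 1 when some runs never
dissociate).

Subdomain flexibility is tracked as the RMSD of a selection against frame 0,

    RMSD(t) = sqrt( (1/M) sum_m || r_m(t) - r_m(0) ||^2 ),

optionally after rigid-body (Kabsch) superposition of each frame onto frame 0
using a declared anchor selection; without superposition the statistic
includes global tumbling and diffusion, so the default pipeline superposes on
a stable core and the literal no-fit mode remains available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .contacts import ContactMap
from .errors import ConfigError, DataError, FormatError
from .reference import (
    ATOMIC_MASSES,
    BACKBONE_ATOMS,
    CONTACT_CUTOFF_ANGSTROM,
    DISSOCIATION_THRESHOLD_ANGSTROM,
)

__all__ = [
    "TrajectoryBundle",
    "ResidueSelection",
    "DissociationResult",
    "RMSDSeries",
    "read_trajectory",
    "write_frames_text",
    "center_of_mass",
    "com_distance_series",
    "dissociation_time",
    "indicator",
    "cumulative_fraction",
    "analyze_dissociation",
    "contact_occupancy",
    "subdomain_rmsd",
]


@dataclass(frozen=True)
class TrajectoryBundle:
    """Frame-ordered coordinates (T, A, 3) in Å with per-frame times in ns and
    an atom table (chain, resnum, name, element, mass)."""

    frames: np.ndarray
    times: np.ndarray
    atom_table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise DataError(f"frames must be (T, A, 3), got {self.frames.shape}")
        if self.frames.shape[0] != len(self.times):
            raise DataError("frame count and time count disagree")
        if self.frames.shape[1] != len(self.atom_table):
            raise DataError("atom count mismatch between frames and atom table")
        if not np.all(np.isfinite(self.frames)):
            raise DataError("non-finite coordinates in trajectory")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise DataError("times must be strictly increasing")
        if (self.atom_table["mass"] <= 0).any():
            raise DataError("atom masses must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class ResidueSelection:
    """A chain + residue-number selection with an atom filter.

    ``atom_filter`` is one of ``backbone`` ({N, CA, C, O}), ``heavy``
    (non-hydrogen), or ``all``.
    """

    chain: str
    residues: tuple[int, ...]
    atom_filter: str = "backbone"

    def __post_init__(self) -> None:
        if self.atom_filter not in ("backbone", "heavy", "all"):
            raise ConfigError(f"unknown atom filter {self.atom_filter!r}")
        if not self.residues:
            raise ConfigError("empty residue list in selection")

    @classmethod
    def from_string(cls, spec: str) -> "ResidueSelection":
        """Parse ``CHAIN:3,5,9,11,16:backbone`` (ranges like 216-222 allowed)."""
        parts = spec.split(":")
        if len(parts) not in (2, 3):
            raise ConfigError(f"cannot parse selection {spec!r}")
        chain, resspec = parts[0], parts[1]
        atom_filter = parts[2] if len(parts) == 3 else "backbone"
        residues: list[int] = []
        for tok in resspec.split(","):
            tok = tok.strip()
            if "-" in tok:
                lo, hi = tok.split("-")
                residues.extend(range(int(lo), int(hi) + 1))
            elif tok:
                residues.append(int(tok))
        return cls(chain=chain, residues=tuple(residues), atom_filter=atom_filter)

    def resolve(self, bundle: TrajectoryBundle) -> np.ndarray:
        """Atom indices in the bundle matching this selection (>= 1 required)."""
        t = bundle.atom_table
        mask = (t["chain"] == self.chain) & t["resnum"].isin(self.residues)
        if self.atom_filter == "backbone":
            mask &= t["name"].isin(BACKBONE_ATOMS)
        elif self.atom_filter == "heavy":
            mask &= ~t["element"].isin(("H", "D"))
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise ConfigError(f"selection {self} resolves to no atoms")
        return idx


@dataclass(frozen=True)
class DissociationResult:
    """Per-trajectory dissociation times, indicator matrix, and pooled F(t)."""

    t_ds: tuple[float | None, ...]
    grid: np.ndarray
    etas: np.ndarray  # (N, len(grid)) binary
    fraction: np.ndarray  # F(t) on grid
    threshold: float

    @property
    def n(self) -> int:
        return len(self.t_ds)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.grid, "fraction_dissociated": self.fraction})

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class RMSDSeries:
    """Per-frame RMSD (Å) of a subdomain vs frame 0, with the superposition
    policy that produced it."""

    rmsd: np.ndarray
    times: np.ndarray
    superposition: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "rmsd_angstrom": self.rmsd})

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trajectory(
    frames_path: str | Path,
    topology_path: str | Path | None = None,
    format: str = "auto",
) -> TrajectoryBundle:
    """Load a trajectory.

    ``format="xyzt"`` (or a ``.xyzt``/``.txt`` suffix under ``auto``) reads the
    plain-text frames format: a header line ``natoms ntimes dt_ns`` followed by
    ``ntimes`` blocks of ``natoms`` lines ``chain resnum atomname element mass
    x y z``.  Any other format is dispatched to mdtraj with ``topology_path``
    as topology (mdtraj's native ps times are converted to ns, nm to Å).
    """
    frames_path = Path(frames_path)
    if not frames_path.exists():
        raise FormatError(f"no such file: {frames_path}")
    if format == "auto":
        format = "xyzt" if frames_path.suffix.lower() in (".xyzt", ".txt") else "mdtraj"
    if format == "xyzt":
        return _read_frames_text(frames_path)
    return _read_mdtraj(frames_path, topology_path)


def _read_frames_text(path: Path) -> TrajectoryBundle:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"empty trajectory file {path}")
    try:
        natoms_s, ntimes_s, dt_s = lines[0].split()
        natoms, ntimes, dt_ns = int(natoms_s), int(ntimes_s), float(dt_s)
    except ValueError as exc:
        raise FormatError(f"bad header in {path}: {lines[0]!r}") from exc
    body = lines[1:]
    if len(body) != natoms * ntimes:
        raise DataError(
            f"{path}: expected {natoms * ntimes} atom lines, found {len(body)}"
        )
    table_rows: list[tuple[str, int, str, str, float]] = []
    coords = np.empty((ntimes, natoms, 3))
    for t in range(ntimes):
        for a in range(natoms):
            parts = body[t * natoms + a].split()
            if len(parts) != 8:
                raise FormatError(f"{path}: bad atom line {parts}")
            chain, resnum, name, element, mass = (
                parts[0],
                int(parts[1]),
                parts[2],
                parts[3].upper(),
                float(parts[4]),
            )
            xyz = [float(x) for x in parts[5:8]]
            if not all(np.isfinite(xyz)):
                raise DataError(f"{path}: non-finite coordinate in frame {t}")
            coords[t, a] = xyz
            if t == 0:
                table_rows.append((chain, resnum, name, element, mass))
            elif (chain, resnum, name) != table_rows[a][:3]:
                raise DataError(
                    f"{path}: atom identity changed between frames at index {a}"
                )
    atom_table = pd.DataFrame(
        table_rows, columns=["chain", "resnum", "name", "element", "mass"]
    )
    times = np.arange(ntimes, dtype=float) * dt_ns
    return TrajectoryBundle(frames=coords, times=times, atom_table=atom_table)


def _read_mdtraj(frames_path: Path, topology_path: str | Path | None) -> TrajectoryBundle:
    import mdtraj as md

    if topology_path is None:
        traj = md.load(str(frames_path))
    else:
        traj = md.load(str(frames_path), top=str(topology_path))
    top = traj.topology
    rows = []
    for atom in top.atoms:
        element = (atom.element.symbol if atom.element is not None else "C").upper()
        mass = float(atom.element.mass) if atom.element is not None else 12.011
        chain_id = atom.residue.chain.chain_id or chr(ord("A") + atom.residue.chain.index)
        rows.append((str(chain_id), int(atom.residue.resSeq), atom.name, element, mass))
    atom_table = pd.DataFrame(rows, columns=["chain", "resnum", "name", "element", "mass"])
    frames = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Å
    times = np.asarray(traj.time, dtype=float) / 1000.0  # ps -> ns
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(frames), dtype=float)  # container had no time metadata
    return TrajectoryBundle(frames=frames, times=times, atom_table=atom_table)


def write_frames_text(bundle: TrajectoryBundle, path: str | Path) -> None:
    """Write the plain-text frames format (requires uniform frame spacing)."""
    if bundle.n_frames > 1:
        dts = np.diff(bundle.times)
        if not np.allclose(dts, dts[0]):
            raise DataError("plain-text format requires uniform frame spacing")
        dt = float(dts[0])
    else:
        dt = 1.0
    t = bundle.atom_table
    with open(path, "w") as fh:
        fh.write(f"{bundle.n_atoms} {bundle.n_frames} {dt:.10g}\n")
        for f in range(bundle.n_frames):
            for a in range(bundle.n_atoms):
                row = t.iloc[a]
                x, y, z = bundle.frames[f, a]
                fh.write(
                    f"{row['chain']} {row['resnum']} {row['name']} {row['element']} "
                    f"{row['mass']:.4f} {x:.6f} {y:.6f} {z:.6f}\n"
                )


def _weights(bundle: TrajectoryBundle, idx: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "mass":
        return bundle.atom_table["mass"].to_numpy()[idx]
    if weighting == "geometric":
        return np.ones(len(idx))
    raise ConfigError(f"unknown weighting {weighting!r}")


def center_of_mass(
    bundle: TrajectoryBundle,
    selection: ResidueSelection,
    frame_index: int,
    weighting: str = "mass",
) -> np.ndarray:
    """Weighted centroid of the selection in one frame (Å)."""
    idx = selection.resolve(bundle)
    w = _weights(bundle, idx, weighting)
    x = bundle.frames[frame_index, idx]
    return (x * w[:, None]).sum(axis=0) / w.sum()


def com_distance_series(
    bundle: TrajectoryBundle,
    sel_a: ResidueSelection,
    sel_b: ResidueSelection,
    weighting: str = "mass",
) -> np.ndarray:
    """Per-frame Euclidean distance between the two selection COMs (Å)."""
    ia, ib = sel_a.resolve(bundle), sel_b.resolve(bundle)
    wa, wb = _weights(bundle, ia, weighting), _weights(bundle, ib, weighting)
    coma = (bundle.frames[:, ia] * wa[None, :, None]).sum(axis=1) / wa.sum()
    comb = (bundle.frames[:, ib] * wb[None, :, None]).sum(axis=1) / wb.sum()
    return np.linalg.norm(coma - comb, axis=1)


def dissociation_time(
    series: np.ndarray,
    times: np.ndarray,
    threshold: float = DISSOCIATION_THRESHOLD_ANGSTROM,
) -> float | None:
    """Time of the first frame whose distance strictly exceeds the threshold;
    None if never exceeded.  A single-frame crossing suffices (no dwell-time
    filter, no re-entry logic)."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.shape != times.shape:
        raise DataError("series and times must have the same length")
    hits = np.flatnonzero(series > threshold)
    return None if hits.size == 0 else float(times[hits[0]])


def indicator(t_d: float | None, grid: np.ndarray) -> np.ndarray:
    """eta(t): 0 before t_D, 1 from t_D on (right-continuous)."""
    grid = np.asarray(grid, dtype=float)
    if t_d is None:
        return np.zeros(len(grid))
    return (grid >= t_d).astype(float)


def cumulative_fraction(
    t_ds: list[float | None] | tuple[float | None, ...], grid: np.ndarray
) -> np.ndarray:
    """F(t) = (1/N) sum_i 1[t >= t_D^(i)] on the given grid."""
    if len(t_ds) == 0:
        raise ConfigError("cumulative fraction requires at least one trajectory")
    etas = np.stack([indicator(td, grid) for td in t_ds])
    return etas.mean(axis=0)


def analyze_dissociation(
    bundles: list[TrajectoryBundle],
    sel_a: ResidueSelection,
    sel_b: ResidueSelection,
    threshold: float = DISSOCIATION_THRESHOLD_ANGSTROM,
    grid: np.ndarray | None = None,
    weighting: str = "mass",
) -> DissociationResult:
    """Full dissociation analysis for a set of trajectories: per-run t_D,
    indicator matrix, and pooled F(t) on a shared grid (default: the union of
    all frame times)."""
    if not bundles:
        raise ConfigError("need at least one trajectory")
    t_ds: list[float | None] = []
    for b in bundles:
        series = com_distance_series(b, sel_a, sel_b, weighting=weighting)
        t_ds.append(dissociation_time(series, b.times, threshold))
    if grid is None:
        grid = np.unique(np.concatenate([b.times for b in bundles]))
    etas = np.stack([indicator(td, grid) for td in t_ds])
    return DissociationResult(
        t_ds=tuple(t_ds),
        grid=np.asarray(grid, dtype=float),
        etas=etas,
        fraction=etas.mean(axis=0),
        threshold=threshold,
    )


def contact_occupancy(
    bundle: TrajectoryBundle,
    sel_a: ResidueSelection,
    sel_b: ResidueSelection,
    cutoff: float = CONTACT_CUTOFF_ANGSTROM,
) -> ContactMap:
    """Occupancy contact map: fraction of frames in which each interchain
    residue pair has some non-hydrogen atom pair within the cutoff.  Heavy
    atoms are always used, regardless of the selections' atom filters."""
    t = bundle.atom_table
    heavy = ~t["element"].isin(("H", "D"))

    def residue_atoms(sel: ResidueSelection) -> list[tuple[int, np.ndarray]]:
        out = []
        for rn in sel.residues:
            mask = (t["chain"] == sel.chain) & (t["resnum"] == rn) & heavy
            idx = np.flatnonzero(mask.to_numpy())
            out.append((rn, idx))
        if all(len(idx) == 0 for _, idx in out):
            raise ConfigError(f"selection {sel} resolves to no heavy atoms")
        return out

    ra = residue_atoms(sel_a)
    rb = residue_atoms(sel_b)
    ia = np.concatenate([idx for _, idx in ra]) if ra else np.empty(0, int)
    ib = np.concatenate([idx for _, idx in rb]) if rb else np.empty(0, int)
    lab_a = np.concatenate([np.full(len(idx), i) for i, (_, idx) in enumerate(ra)])
    lab_b = np.concatenate([np.full(len(idx), i) for i, (_, idx) in enumerate(rb)])

    counts = np.zeros((len(ra), len(rb)))
    for f in range(bundle.n_frames):
        d = cdist(bundle.frames[f, ia], bundle.frames[f, ib])
        mind = np.full((len(ra), len(rb)), np.inf)
        np.minimum.at(mind, (lab_a[:, None], lab_b[None, :]), d)
        counts += mind <= cutoff
    return ContactMap(
        row_residues=tuple((sel_a.chain, rn) for rn, _ in ra),
        col_residues=tuple((sel_b.chain, rn) for rn, _ in rb),
        values=counts / bundle.n_frames,
        cutoff=cutoff,
        kind="occupancy",
    )


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Optimal rotation mapping centered ``mov`` onto centered ``ref``."""
    cref = ref.mean(axis=0)
    cmov = mov.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - cref, mov - cmov)
    return rot, cref, cmov


def subdomain_rmsd(
    bundle: TrajectoryBundle,
    selection: ResidueSelection,
    superpose_on: ResidueSelection | None = None,
) -> RMSDSeries:
    """RMSD of a subdomain against frame 0.

    With ``superpose_on`` each frame is first rigid-body fitted (Kabsch) onto
    frame 0 using the anchor selection, which must resolve to >= 3
    non-degenerate (non-collinear) atoms; without it the literal no-fit
    definition is used.
    """
    idx = selection.resolve(bundle)
    ref = bundle.frames[0, idx]
    anchor_idx = None
    if superpose_on is not None:
        anchor_idx = superpose_on.resolve(bundle)
        if len(anchor_idx) < 3:
            raise ConfigError("superposition anchor needs at least 3 atoms")
        a0 = bundle.frames[0, anchor_idx]
        if np.linalg.matrix_rank(a0 - a0.mean(axis=0), tol=1e-8) < 2:
            raise DataError("superposition anchor is degenerate (collinear)")
    out = np.empty(bundle.n_frames)
    for f in range(bundle.n_frames):
        x = bundle.frames[f, idx]
        if anchor_idx is not None:
            rot, cref, cmov = _kabsch(
                bundle.frames[0, anchor_idx], bundle.frames[f, anchor_idx]
            )
            x = rot.apply(x - cmov) + cref
        out[f] = np.sqrt(((x - ref) ** 2).sum(axis=1).mean())
    policy = "none" if superpose_on is None else (
        f"kabsch:{superpose_on.chain}:{len(anchor_idx)}atoms"
    )
    return RMSDSeries(rmsd=out, times=bundle.times.copy(), superposition=policy)
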