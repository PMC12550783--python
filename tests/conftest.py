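from __future__ import annotations

import numpy as np
import pytest

from slimdock.conservation import AlignedSequenceSet
from slimdock.contacts import Atom, Chain, Residue, StructureModel


def make_msa(*sequences: str, ids: list[str] | None = None) -> AlignedSequenceSet:
    ids = ids or [f"s{i}" for i in range(len(sequences))]
    return AlignedSequenceSet(tuple(zip(ids, sequences)))


@pytest.fixture
def msa_factory():
    return make_msa


def random_two_chain_model(
    rng: np.random.Generator,
    n_residues: int = 8,
    atoms_per_residue: int = 4,
    box: float = 12.0,
    hydrogen_fraction: float = 0.25,
) -> StructureModel:
    """A random two-chain pseudo-structure for oracle cross-checks."""
    chains = []
    for cid in ("A", "B"):
        offset = np.zeros(3) if cid == "A" else rng.uniform(2.0, 6.0, 3)
        residues = []
        for rn in range(1, n_residues + 1):
            atoms = []
            for ai in range(atoms_per_residue):
                is_h = rng.random() < hydrogen_fraction
                xyz = rng.uniform(0, box, 3) + offset
                atoms.append(
                    Atom(
                        name=("H" if is_h else "C") + str(ai),
                        element="H" if is_h else "C",
                        xyz=tuple(float(x) for x in xyz),
                        bfactor=70.0,
                    )
                )
            residues.append(Residue(rn, "GLY", tuple(atoms)))
        chains.append(Chain(cid, tuple(residues)))
    return StructureModel(tuple(chains))


@pytest.fixture
def structure_factory():
    return random_two_chain_model
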