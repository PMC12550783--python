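"""Divergence analysis of aligned docking-site sequences.

Pairwise distance is the p-distance over pairwise-complete columns: the
proportion of mismatches among columns where both sequences carry a residue
(gaps and 'X' excluded).  A similarity network connects sequences whose
distance falls strictly below a threshold (default 0.2, i.e. >= 80% identity).
Sequence groups are recovered with K-means on the distance-profile embedding
(each sequence represented by its row of the distance matrix) with k-means++
initialisation and multiple restarts; the number of groups is either fixed or
selected by mean silhouette over a scanned range.  A spectral embedding of the
network adjacency is available as an alternative behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .conservation import AlignedSequenceSet
from .errors import AlignmentShapeError, ConfigError, DataError
from .reference import AMBIGUOUS, DISTANCE_THRESHOLD, GAP

__all__ = [
    "DistanceMatrix",
    "SimilarityNetwork",
    "ClusterAssignment",
    "pairwise_distance",
    "distance_matrix",
    "build_network",
    "cluster_network",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise p-distances in [0, 1]; NaN marks pairs with no
    pairwise-complete column."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise AlignmentShapeError(
                f"distance matrix shape {self.d.shape} != ({n}, {n})"
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6g")


@dataclass(frozen=True)
class SimilarityNetwork:
    """Undirected graph over sequence ids; an edge joins two sequences iff
    their distance is strictly below ``threshold``."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    threshold: float = DISTANCE_THRESHOLD

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def write_edges_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.edges, columns=["id_a", "id_b"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class ClusterAssignment:
    """K-means group labels (contiguous from 0, ordered by first appearance),
    the silhouette of every k examined, and a degeneracy flag raised when no
    examined k achieves appreciable silhouette (no real group structure)."""

    labels: dict[str, int]
    k: int
    quality: dict[int, float]
    seed: int
    degenerate: bool = False

    def label_array(self, ids: tuple[str, ...]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"id": list(self.labels), "cluster": list(self.labels.values())}
        ).to_csv(path, sep="\t", index=False)


def _residue_mask(mat: np.ndarray) -> np.ndarray:
    return (mat != GAP) & (mat != AMBIGUOUS)


def pairwise_distance(a: str, b: str) -> float:
    """p-distance between two aligned (gapped) sequences.

    Proportion of mismatches over columns where both carry a residue; NaN if
    no such column exists.
    """
    if len(a) != len(b):
        raise AlignmentShapeError(
            f"sequences must be aligned: lengths {len(a)} != {len(b)}"
        )
    av = np.array(list(a.upper()), dtype="<U1")
    bv = np.array(list(b.upper()), dtype="<U1")
    both = _residue_mask(av) & _residue_mask(bv)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float((av[both] != bv[both]).mean())


def distance_matrix(msa: AlignedSequenceSet) -> DistanceMatrix:
    """All-pairs p-distance matrix (vectorised; zero diagonal)."""
    if msa.n_sequences < 2:
        raise ConfigError("need at least 2 sequences for a distance matrix")
    mat = msa.to_matrix()
    valid = _residue_mask(mat)
    both = valid[:, None, :] & valid[None, :, :]
    mism = (mat[:, None, :] != mat[None, :, :]) & both
    denom = both.sum(axis=2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, mism.sum(axis=2) / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=msa.ids, d=d)


def build_network(
    msa: AlignedSequenceSet, threshold: float = DISTANCE_THRESHOLD
) -> tuple[SimilarityNetwork, DistanceMatrix]:
    """Similarity network: edge (i, j) iff d[i, j] < threshold (strict).

    NaN distances never produce an edge.
    """
    dmat = distance_matrix(msa)
    ids = dmat.ids
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dij = dmat.d[i, j]
            if np.isfinite(dij) and dij < threshold:
                edges.append((ids[i], ids[j]))
    return SimilarityNetwork(nodes=ids, edges=tuple(edges), threshold=threshold), dmat


def _spectral_embedding(network: SimilarityNetwork, n_components: int) -> np.ndarray:
    """Leading eigenvectors of the symmetrically normalised adjacency."""
    idx = {sid: i for i, sid in enumerate(network.nodes)}
    n = len(network.nodes)
    a = np.zeros((n, n))
    for u, v in network.edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    a += np.eye(n)  # self-loops keep isolated nodes well-defined
    deg = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(deg)
    sym = dinv[:, None] * a * dinv[None, :]
    w, v = np.linalg.eigh(sym)
    order = np.argsort(w)[::-1]
    return v[:, order[:n_components]]


def _relabel_by_first_appearance(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def cluster_network(
    network: SimilarityNetwork,
    dmat: DistanceMatrix,
    k: int | str = "auto",
    seed: int = 0,
    k_range: tuple[int, int] = (2, 8),
    embedding: str = "distance",
    n_init: int = 10,
) -> ClusterAssignment:
    """Cluster the network's sequences with K-means.

    ``embedding="distance"`` uses each sequence's distance-matrix row as its
    feature vector; ``"spectral"`` uses eigenvectors of the normalised
    adjacency.  With ``k="auto"`` the k in ``k_range`` maximising the mean
    silhouette is chosen (smaller k on ties); silhouettes for every examined
    k are reported.  Deterministic given ``seed``.
    """
    ids = dmat.ids
    n = len(ids)
    if tuple(network.nodes) != tuple(ids):
        raise DataError("network nodes and distance-matrix ids disagree")
    if embedding == "distance":
        x_full = dmat.d.copy()
        if np.isnan(x_full).any():
            x_full = np.nan_to_num(x_full, nan=1.0)  # incomparable pairs maximally distant

        def embed(kk: int) -> np.ndarray:
            return x_full

    elif embedding == "spectral":

        def embed(kk: int) -> np.ndarray:
            # top-k eigenvectors of the normalised adjacency, row-normalised
            v = _spectral_embedding(network, min(kk, n - 1) if n > 1 else 1)
            norms = np.linalg.norm(v, axis=1, keepdims=True)
            return v / np.where(norms > 0, norms, 1.0)

    else:
        raise ConfigError(f"unknown embedding {embedding!r}")

    if k == "auto":
        ks = [kk for kk in range(k_range[0], k_range[1] + 1) if kk < n]
        if not ks:
            raise ConfigError(f"too few sequences ({n}) for k in {k_range}")
    else:
        k = int(k)
        if k < 2:
            raise ConfigError("k must be >= 2")
        if k > n:
            raise ConfigError(f"k={k} exceeds number of sequences ({n})")
        ks = [k]

    quality: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for kk in ks:
        x = embed(kk)
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
        labels = km.fit_predict(x)
        if len(np.unique(labels)) > 1 and kk < n:
            quality[kk] = float(silhouette_score(x, labels))
        else:
            quality[kk] = float("nan")
        fits[kk] = labels

    finite = {kk: q for kk, q in quality.items() if np.isfinite(q)}
    if k == "auto" or isinstance(k, str):
        best_k = max(sorted(finite), key=lambda kk: finite[kk]) if finite else ks[0]
    else:
        best_k = ks[0]
    labels = _relabel_by_first_appearance(fits[best_k])
    best_sil = quality.get(best_k, float("nan"))
    degenerate = not np.isfinite(best_sil) or best_sil < 0.1
    return ClusterAssignment(
        labels={sid: int(lab) for sid, lab in zip(ids, labels)},
        k=int(best_k),
        quality=quality,
        seed=seed,
        degenerate=degenerate,
    )
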