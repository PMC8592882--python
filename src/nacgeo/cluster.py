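"""Sieved average-linkage conformational clustering on best-fit RMSD.

The procedure mirrors the cpptraj workflow used for long MD trajectories:

1. take every s-th frame (the *sieve*; systematic, deterministic),
2. build the pairwise best-fit RMSD matrix over a selection (default:
   non-hydrogen protein atoms),
3. agglomerate by average linkage — at each step merge the two clusters
   with the smallest mean inter-cluster pairwise distance — down to k
   clusters,
4. assign every non-sieved frame to the cluster whose representative it is
   closest to by best-fit RMSD,
5. report populations over ALL frames, a representative per cluster (the
   member minimising mean RMSD to its sieved co-members), and an averaged
   structure (arithmetic mean of member coordinates after superposing each
   member onto the representative — cpptraj-faithful, which can produce
   non-physical bond lengths, so the representative frame is always kept
   alongside).

Cluster ids are relabelled 0, 1, 2, ... by descending population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .geometry import kabsch, pairwise_rmsd, rmsd_to_reference
from .structio import AtomSelection, Structure, Trajectory, select

__all__ = ["ClusterParams", "ClusterModel", "average_linkage", "cluster_trajectory", "report_populations"]

DEFAULT_SELECTION = "protein and not hydrogen"


@dataclass(frozen=True)
class ClusterParams:
    """Clustering controls: cluster count k, sieve stride s, RMSD selection."""

    n_clusters: int = 10
    sieve: int = 10
    selection: str = DEFAULT_SELECTION

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.sieve < 1:
            raise ValueError("sieve must be >= 1")


@dataclass(frozen=True)
class ClusterModel:
    """Result of clustering: assignments, populations (percent of all
    frames), per-cluster representative frame and averaged structure."""

    assignment: np.ndarray            # (F,) cluster id per frame
    populations: np.ndarray           # (k,) percent of F, descending
    representative: np.ndarray        # (k,) global frame index
    average_structure: list[Structure]
    sieved_frames: np.ndarray         # global indices of the sieved set

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def average_linkage(dist: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage agglomeration of a condensed-able distance matrix
    down to ``k`` clusters; returns per-item integer labels.

    Labels are ordered by first occurrence so the result is deterministic
    for a given matrix.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} items")
    if k == n:
        return np.arange(n)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = cut_tree(Z, n_clusters=k).ravel()
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel by first occurrence (stable, permutation of ids only)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        out[i] = mapping.setdefault(int(lab), len(mapping))
    return out


def cluster_trajectory(traj: Trajectory, params: ClusterParams = ClusterParams()) -> ClusterModel:
    """Full sieved clustering of a trajectory (see module docstring)."""
    F = traj.n_frames
    if F < params.sieve:
        raise ValueError(f"sieve {params.sieve} exceeds trajectory length {F}")
    sieved = np.arange(0, F, params.sieve)
    if params.n_clusters > sieved.size:
        raise ValueError(
            f"k={params.n_clusters} exceeds the {sieved.size} sieved frames"
        )
    sel_idx = select(traj.topology, AtomSelection(params.selection))
    if sel_idx.size == 0:
        raise ValueError(f"selection {params.selection!r} matched no atoms")
    metric_coords = traj.coords[:, sel_idx, :]

    if sieved.size == 1:
        sieved_labels = np.zeros(1, dtype=int)
    else:
        D = pairwise_rmsd(metric_coords[sieved])
        sieved_labels = average_linkage(D, params.n_clusters)
    k = int(sieved_labels.max()) + 1

    # representative: sieved member minimising mean RMSD to sieved co-members
    representative = np.empty(k, dtype=int)
    for c in range(k):
        members = np.flatnonzero(sieved_labels == c)
        if members.size == 1:
            representative[c] = sieved[members[0]]
        else:
            sub = D[np.ix_(members, members)]
            representative[c] = sieved[members[np.argmin(sub.mean(axis=1))]]

    # restore non-sieved frames: nearest representative by best-fit RMSD
    assignment = np.full(F, -1, dtype=int)
    assignment[sieved] = sieved_labels
    rest = np.flatnonzero(assignment < 0)
    if rest.size:
        dists = np.stack(
            [rmsd_to_reference(metric_coords[rest], metric_coords[r]) for r in representative],
            axis=1,
        )
        assignment[rest] = np.argmin(dists, axis=1)

    populations = 100.0 * np.bincount(assignment, minlength=k) / F

    # relabel by descending population (ties: lower original id first)
    order = np.argsort(-populations, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    assignment = remap[assignment]
    populations = populations[order]
    representative = representative[order]

    averages = []
    for c in range(k):
        members = np.flatnonzero(assignment == c)
        rep_metric = metric_coords[representative[c]]
        acc = np.zeros((traj.n_atoms, 3))
        for m in members:
            tf, _ = kabsch(metric_coords[m], rep_metric)
            acc += tf.apply(traj.coords[m])
        averages.append(traj.topology.with_coords(acc / members.size))

    return ClusterModel(
        assignment=assignment,
        populations=populations,
        representative=representative,
        average_structure=averages,
        sieved_frames=sieved,
    )


def report_populations(model: ClusterModel, top: int = 3) -> pd.DataFrame:
    """Top-n cluster populations, percentages to one decimal (descending)."""
    n = min(top, model.n_clusters)
    return pd.DataFrame(
        {
            "cluster": np.arange(n),
            "population_pct": np.round(model.populations[:n], 1),
            "representative_frame": model.representative[:n],
        }
    )
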