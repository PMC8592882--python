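"""Independent oracles used by the tests.

Each oracle is implemented from first principles, separately from the code
path it checks: the Horn quaternion method for superposition, a naive cubic
re-scan for average-linkage agglomeration, and closed-form sphere/cap areas
for SASA.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Best-fit RMSD via Horn's quaternion eigenvalue method."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    E0 = (P0 ** 2).sum() + (Q0 ** 2).sum()
    msd = max(E0 - 2.0 * lam_max, 0.0) / len(P)
    return float(np.sqrt(msd))


def naive_average_linkage(D: np.ndarray, k: int) -> np.ndarray:
    """O(n^3) agglomeration re-scanning every cluster pair at each merge.

    Merges the pair with the smallest mean cross-pair distance; ties broken
    by the lexicographically smallest (cluster, cluster) index pair.
    """
    n = len(D)
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                mean_d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or mean_d < best[0]:
                    best = (mean_d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for ci, members in enumerate(clusters):
        for i in members:
            labels[i] = ci
    return labels


def canonical_partition(labels) -> tuple[int, ...]:
    """Relabel a partition by first occurrence so partitions compare
    independently of arbitrary cluster ids."""
    mapping: dict[int, int] = {}
    return tuple(mapping.setdefault(int(x), len(mapping)) for x in labels)


def sphere_area(r_vdw: float, probe: float) -> float:
    """Area of an isolated solvent-expanded sphere."""
    return 4.0 * np.pi * (r_vdw + probe) ** 2


def two_sphere_accessible(r1: float, r2: float, d: float, probe: float) -> tuple[float, float]:
    """Closed-form accessible areas of two intersecting expanded spheres.

    Each sphere loses the cap beyond the radical plane of the two expanded
    spheres (cap area 2*pi*R*h with h = R - x, x the plane offset).
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return sphere_area(r1, probe), sphere_area(r2, probe)
    x1 = (d * d - R2 * R2 + R1 * R1) / (2.0 * d)
    x2 = d - x1
    cap1 = 2.0 * np.pi * R1 * (R1 - x1)
    cap2 = 2.0 * np.pi * R2 * (R2 - x2)
    return 4.0 * np.pi * R1 * R1 - cap1, 4.0 * np.pi * R2 * R2 - cap2


def nac_grid_oracle(d_grid: np.ndarray, theta_grid: np.ndarray) -> np.ndarray:
    """Exhaustive NAC decision over a (d, theta) grid, straight from the
    definition: distance within 3.2 A and angle within 15 deg of 180."""
    D, T = np.meshgrid(d_grid, theta_grid, indexing="ij")
    return (D <= 3.2) & (np.abs(180.0 - T) <= 15.0)
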