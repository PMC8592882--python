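"""Near-attack-conformation (NAC) reaction-coordinate statistics.

In the S\\ :sub:`N`\\ 2 methyl transfer catalysed by PRMT1, the substrate
arginine nitrogen (Nη1 or Nη2) attacks the AdoMet methyl carbon in line with
the sulfur leaving group.  A frame samples a *near attack conformation* when
the attack distance d(N···CH3) is within 3.2 Å and the attack angle
θ(N···CH3···S), measured at the methyl carbon, is within 15° of the ideal
180° transfer geometry.  Both bounds are inclusive, so boundary frames count
as NACs.

The scalar reaction coordinate combines both requirements::

    r = d + 0.5 * cos(theta)

A perfectly in-line approach (θ = 180°) scales d down by 0.5 Å; productive
angles in (90°, 180°) reduce r, while unproductive approach angles below 90°
penalise it.  Trajectory distributions of r, their peak positions and
heights, and the fraction of NAC frames are the per-variant summaries
compared across enzyme constructs.

Peak heights are probability densities and therefore depend on the
histogram bin width; every summary carries its bin width so heights are
interpretable (the default is 0.1 Å).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .structio import Trajectory

__all__ = [
    "NAC_MAX_DISTANCE",
    "NAC_MAX_ANGLE_DEVIATION",
    "NacTriplet",
    "NacSeries",
    "NacSummary",
    "nac_series",
    "is_nac",
    "nac_fraction",
    "nac_distribution",
]

#: NAC attack-distance bound d(N···CH3), Å (inclusive).
NAC_MAX_DISTANCE = 3.2
#: NAC attack-angle bound: |180° - θ| must not exceed this (inclusive).
NAC_MAX_ANGLE_DEVIATION = 15.0


@dataclass(frozen=True)
class NacTriplet:
    """Atom indices of one attack geometry: nucleophile N, methyl C, sulfur.

    ``label`` distinguishes the two guanidino nitrogens (NH1/NH2 attack).
    """

    n_attack: int
    c_methyl: int
    sulfur: int
    label: str = "NH1"

    def __post_init__(self):
        if len({self.n_attack, self.c_methyl, self.sulfur}) != 3:
            raise ValueError("NAC triplet requires three distinct atom indices")


@dataclass(frozen=True)
class NacSeries:
    """Per-frame attack geometry: d (Å), θ (deg), and r = d + 0.5·cosθ (Å)."""

    d: np.ndarray
    theta: np.ndarray
    r: np.ndarray
    label: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.d)

    @classmethod
    def from_d_theta(cls, d, theta, label: str = "") -> "NacSeries":
        d = np.asarray(d, dtype=float)
        theta = np.asarray(theta, dtype=float)
        if d.shape != theta.shape:
            raise ValueError("d and theta must have equal length")
        r = d + 0.5 * np.cos(np.radians(theta))
        return cls(d=d, theta=theta, r=r, label=label)


@dataclass(frozen=True)
class NacSummary:
    """Distribution summary of the attack coordinate over a trajectory."""

    nac_fraction: float
    bin_edges: np.ndarray
    density: np.ndarray
    peak_location: float
    peak_height: float
    bin_width: float
    label: str = ""


def nac_series(traj: Trajectory, triplet: NacTriplet) -> NacSeries:
    """Attack distance, angle and reaction coordinate for every frame."""
    n_atoms = traj.n_atoms
    for idx in (triplet.n_attack, triplet.c_methyl, triplet.sulfur):
        if not (0 <= idx < n_atoms):
            raise IndexError(f"atom index {idx} out of range for {n_atoms}-atom topology")
    N = traj.coords[:, triplet.n_attack, :]
    C = traj.coords[:, triplet.c_methyl, :]
    S = traj.coords[:, triplet.sulfur, :]
    d = np.linalg.norm(N - C, axis=1)
    u1 = N - C
    u2 = S - C
    n1 = np.linalg.norm(u1, axis=1)
    n2 = np.linalg.norm(u2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("coincident atoms make the attack angle undefined")
    cost = np.clip((u1 * u2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
    theta = np.degrees(np.arccos(cost))
    return NacSeries(d=d, theta=theta, r=d + 0.5 * cost, label=triplet.label)


def is_nac(d, theta) -> Union[bool, np.ndarray]:
    """NAC decision for scalar or array (d, θ); bounds inclusive."""
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    out = (d <= NAC_MAX_DISTANCE) & ((180.0 - theta) <= NAC_MAX_ANGLE_DEVIATION)
    return bool(out) if out.ndim == 0 else out


def nac_fraction(series: NacSeries) -> float:
    """Fraction of frames sampling a NAC."""
    if series.n_frames < 1:
        raise ValueError("empty series")
    return float(np.count_nonzero(is_nac(series.d, series.theta))) / series.n_frames


def nac_distribution(series: NacSeries, bin_width: float = 0.1, r_max: float = 10.0) -> NacSummary:
    """Probability-density histogram of r with its peak and the NAC fraction.

    Bins of ``bin_width`` cover [min(r) floored to the bin grid, ``r_max``];
    frames with r beyond ``r_max`` are excluded from the density (which is
    normalised over the binned frames).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    r = series.r
    if r.size < 1:
        raise ValueError("empty series")
    if r.min() > r_max:
        raise ValueError(
            f"all reaction-coordinate values exceed r_max={r_max} Å; increase r_max"
        )
    start = np.floor(r.min() / bin_width) * bin_width
    n_bins = int(np.ceil((r_max - start) / bin_width - 1e-12))
    edges = start + bin_width * np.arange(n_bins + 1)
    density, edges = np.histogram(r, bins=edges, density=True)
    peak_bin = int(np.argmax(density))
    return NacSummary(
        nac_fraction=nac_fraction(series),
        bin_edges=edges,
        density=density,
        peak_location=float(0.5 * (edges[peak_bin] + edges[peak_bin + 1])),
        peak_height=float(density[peak_bin]),
        bin_width=float(bin_width),
        label=series.label,
    )
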