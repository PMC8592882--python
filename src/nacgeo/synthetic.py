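"""Synthetic trajectories with planted ground truth.

Every analysis stage in this package is validated against data whose answer
is known by construction rather than against (unavailable) microsecond MD
ensembles.  Four generators emulate the statistical structure the analyses
assume:

* :func:`gen_nac` — a 3-atom S/CH3/N attack geometry whose frames are a
  mixture of guaranteed NAC-forming conformers (d ~ U(2.8, 3.2) Å,
  θ ~ U(168°, 180°)) and non-forming ones (d ~ N(6, 1) truncated ≥ 3.5 Å,
  θ ~ U(60°, 180°)) at a planted fraction;
* :func:`gen_hbond` — a donor/H/acceptor triad toggling between a bound
  geometry (D–A 2.8 Å, D–H–A 175°) and an unbound one (D–A 5.0 Å) at a
  planted occupancy;
* :func:`gen_conformers` — a mixture of k rigid reference chains at planted
  populations, plus isotropic Gaussian noise and a random rigid motion per
  frame;
* :func:`gen_toy_structures` — one/two-sphere and two-chain structures
  whose SASA and buried area follow from closed-form sphere-cap geometry.

Planted quantities are realised as exact counts (``round(f * n)`` frames),
not i.i.d. draws, so recovery tests are exact; pass ``iid=True`` for
binomial sampling when a statistical tolerance is the point.  All
randomness flows from one :func:`numpy.random.default_rng` generator seeded
per call: identical seed and parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import kabsch
from .structio import Structure, Trajectory

__all__ = [
    "SynthSpec",
    "generate",
    "gen_nac",
    "gen_hbond",
    "gen_conformers",
    "gen_toy_structures",
    "toy_dimer_analytic_buried",
    "sphere_cap_buried",
]

_SC_BOND = 1.81  # S-CH3 bond length, Å (AdoMet sulfonium)
_DH_BOND = 1.01  # N-H bond length, Å


@dataclass(frozen=True)
class SynthSpec:
    """Declarative description of one synthetic dataset."""

    kind: str  # nac | hbond | conformers | toy_dimer | spheres
    n_frames: int
    seed: int
    params: dict[str, Any] = field(default_factory=dict)


def generate(spec: SynthSpec):
    """Dispatch a :class:`SynthSpec` to its generator."""
    if spec.kind == "nac":
        return gen_nac(spec.n_frames, seed=spec.seed, **spec.params)
    if spec.kind == "hbond":
        return gen_hbond(spec.n_frames, seed=spec.seed, **spec.params)
    if spec.kind == "conformers":
        return gen_conformers(spec.n_frames, seed=spec.seed, **spec.params)
    if spec.kind in ("spheres", "toy_dimer"):
        return gen_toy_structures(spec.kind, **spec.params)
    raise ValueError(f"unknown synthetic kind {spec.kind!r}")


def _planted_mask(n: int, fraction: float, rng: np.random.Generator, iid: bool) -> np.ndarray:
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("planted fraction must be in [0, 1]")
    if iid:
        return rng.random(n) < fraction
    n_true = round(fraction * n)
    if fraction > 0 and n_true < 1:
        import warnings

        warnings.warn(f"fraction {fraction} yields zero planted frames at n={n}")
    mask = np.zeros(n, dtype=bool)
    mask[:n_true] = True
    rng.shuffle(mask)
    return mask


def _random_rigid(rng: np.random.Generator, tscale: float = 20.0):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-tscale, tscale, size=3)
    return R, t


def gen_nac(n_frames: int, fraction: float = 0.3, seed: int = 0,
            iid: bool = False) -> tuple[Trajectory, np.ndarray]:
    """Mixture of NAC-forming and non-forming attack geometries.

    Returns the trajectory (atoms SD, CE, NH1: sulfur, methyl carbon,
    nucleophile nitrogen) and the per-frame ground-truth labels.
    """
    rng = np.random.default_rng(seed)
    labels = _planted_mask(n_frames, fraction, rng, iid)
    d = np.where(
        labels,
        rng.uniform(2.8, 3.2, n_frames),
        np.clip(rng.normal(6.0, 1.0, n_frames), 3.5, None),
    )
    theta = np.where(
        labels,
        rng.uniform(168.0, 180.0, n_frames),
        rng.uniform(60.0, 180.0, n_frames),
    )
    coords = np.empty((n_frames, 3, 3))
    az = rng.uniform(0.0, 2.0 * np.pi, n_frames)
    for f in range(n_frames):
        # S on +x from the methyl carbon at the origin; N at angle theta from S
        C = np.zeros(3)
        S = np.array([_SC_BOND, 0.0, 0.0])
        th = np.radians(theta[f])
        N = d[f] * np.array([np.cos(th), np.sin(th) * np.cos(az[f]), np.sin(th) * np.sin(az[f])])
        R, t = _random_rigid(rng)
        coords[f] = np.stack([S, C, N]) @ R.T + t
    top = Structure.from_arrays(
        coords[0],
        name=["SD", "CE", "NH1"],
        element=["S", "C", "N"],
        resname=["SAM", "SAM", "ARG"],
        resid=[1, 1, 2],
        chain=["A", "A", "A"],
        hetero=[True, True, False],
    )
    return Trajectory(top, coords), labels


def gen_hbond(n_frames: int, occupancy: float = 0.247, seed: int = 0,
              iid: bool = False) -> tuple[Trajectory, np.ndarray]:
    """Donor/H/acceptor triad toggling between bound and unbound geometry.

    Bound frames: D–A = 2.8 Å with a 175° D–H···A angle; unbound frames:
    D–A = 5.0 Å (same internal angle, scaled away).  Atoms are NH1, HH11
    (arginine donor) and OE1 (glutamate acceptor).
    """
    rng = np.random.default_rng(seed)
    labels = _planted_mask(n_frames, occupancy, rng, iid)

    def _triad(d_da: float) -> np.ndarray:
        D = np.zeros(3)
        H = np.array([_DH_BOND, 0.0, 0.0])
        # place A so that the angle at H between H->D and H->A is 175 deg
        ang = np.radians(180.0 - 175.0)
        direction = np.array([np.cos(ang), np.sin(ang), 0.0])
        # solve |D - (H + t*dir)| = d_da for t > 0
        b = 2.0 * direction @ (H - D)
        c = ((H - D) ** 2).sum() - d_da**2
        t = (-b + np.sqrt(b * b - 4.0 * c)) / 2.0
        return np.stack([D, H, H + t * direction])

    bound = _triad(2.8)
    unbound = _triad(5.0)
    coords = np.empty((n_frames, 3, 3))
    for f in range(n_frames):
        base = bound if labels[f] else unbound
        R, t = _random_rigid(rng)
        coords[f] = base @ R.T + t
    top = Structure.from_arrays(
        coords[0],
        name=["NH1", "HH11", "OE1"],
        element=["N", "H", "O"],
        resname=["ARG", "ARG", "GLU"],
        resid=[1, 1, 2],
        chain=["A", "A", "A"],
    )
    return Trajectory(top, coords), labels


def gen_conformers(n_frames: int, k: int = 3,
                   populations: tuple[float, ...] = (0.6, 0.25, 0.15),
                   noise_sigma: float = 0.3, rmsd_scale: float = 8.0,
                   n_atoms: int = 20, seed: int = 0,
                   iid: bool = False) -> tuple[Trajectory, np.ndarray]:
    """Mixture of k rigid reference conformations at planted populations.

    References are random fixed-bond-length chains rescaled so the minimum
    pairwise best-fit RMSD equals ``rmsd_scale``; each frame is a reference
    plus isotropic Gaussian noise (``noise_sigma``) under a random rigid
    motion.  Returns the trajectory and the true per-frame assignment.
    """
    populations = tuple(populations)
    if len(populations) != k:
        raise ValueError("need one population per conformer")
    if not np.isclose(sum(populations), 1.0, atol=1e-9):
        raise ValueError("populations must sum to 1")
    rng = np.random.default_rng(seed)

    refs = _reference_chains(k, n_atoms, rmsd_scale, rng)
    min_rmsd = min(
        kabsch(refs[i], refs[j])[1] for i in range(k) for j in range(i + 1, k)
    ) if k > 1 else np.inf
    if noise_sigma > 0 and min_rmsd < 10.0 * noise_sigma:
        raise ValueError(
            f"reference conformers are too close (min RMSD {min_rmsd:.2f} Å) "
            f"for noise sigma {noise_sigma} Å"
        )

    if iid:
        truth = rng.choice(k, size=n_frames, p=populations)
    else:
        counts = [round(p * n_frames) for p in populations]
        counts[int(np.argmax(populations))] += n_frames - sum(counts)
        truth = np.repeat(np.arange(k), counts)
        rng.shuffle(truth)

    coords = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        base = refs[truth[f]] + rng.normal(0.0, noise_sigma, size=(n_atoms, 3))
        R, t = _random_rigid(rng, tscale=50.0)
        coords[f] = base @ R.T + t
    top = Structure.from_arrays(
        coords[0],
        name=["CA"] * n_atoms,
        element=["C"] * n_atoms,
        resname=["ALA"] * n_atoms,
        resid=np.arange(1, n_atoms + 1),
        chain=["A"] * n_atoms,
    )
    return Trajectory(top, coords), truth


def _reference_chains(k: int, n_atoms: int, rmsd_scale: float,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """k centred random chains rescaled to the requested minimum pairwise
    best-fit RMSD."""
    refs = []
    for _ in range(k):
        steps = rng.normal(size=(n_atoms - 1, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        chain = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        refs.append(chain - chain.mean(axis=0))
    if k > 1:
        min_rmsd = min(
            kabsch(refs[i], refs[j])[1] for i in range(k) for j in range(i + 1, k)
        )
        scale = rmsd_scale / min_rmsd
        refs = [r * scale for r in refs]
    return refs


def gen_toy_structures(kind: str = "spheres", radii: tuple[float, ...] = (1.6,),
                       separation: float = 2.0, elements: tuple[str, ...] | None = None,
                       chain_atoms: int = 4, chain_spacing: float = 20.0
                       ) -> Structure:
    """Toy structures with analytically known SASA / buried area.

    ``spheres``: 1-2 pseudo-atoms on the x-axis at the given separation.
    ``toy_dimer``: two chains of widely spaced atoms (no intra-chain
    occlusion) with exactly one cross-chain contact pair at ``separation``,
    so the buried area equals the closed-form two-sphere cap value.
    """
    if kind == "spheres":
        n = len(radii)
        if n not in (1, 2):
            raise ValueError("spheres supports 1 or 2 atoms")
        coords = np.zeros((n, 3))
        if n == 2:
            coords[1, 0] = separation
        elems = elements if elements is not None else ["C"] * n
        return Structure.from_arrays(
            coords,
            name=[f"X{i+1}" for i in range(n)],
            element=elems,
            resname=["SPH"] * n,
            resid=np.arange(1, n + 1),
            chain=["A"] * n,
            hetero=[True] * n,
        )
    if kind == "toy_dimer":
        m = chain_atoms
        a = np.column_stack([np.zeros(m), chain_spacing * np.arange(m), np.zeros(m)])
        b = a.copy()
        b[:, 0] = separation  # every a[i]-b[i] pair is `separation` apart...
        b[1:, 1] += chain_spacing / 2.0  # ...except only pair 0 stays in contact
        coords = np.vstack([a, b])
        return Structure.from_arrays(
            coords,
            name=["CA"] * (2 * m),
            element=["C"] * (2 * m),
            resname=["GLY"] * (2 * m),
            resid=list(range(1, m + 1)) * 2,
            chain=["A"] * m + ["B"] * m,
        )
    raise ValueError(f"unknown toy kind {kind!r}")


def sphere_cap_buried(r1: float, r2: float, d: float, probe: float = 1.4) -> float:
    """Closed-form buried area (Ų) of two solvent-expanded spheres.

    For expanded radii R1 = r1 + probe, R2 = r2 + probe at centre distance
    d < R1 + R2, each sphere loses the spherical cap cut off by the radical
    plane; the returned value is the total SASA lost, i.e. the sum of both
    cap areas 2*pi*R*h.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 0.0
    if d <= abs(R1 - R2):
        # one sphere engulfed: the smaller sphere's whole surface is buried
        Rs = min(R1, R2)
        return 4.0 * np.pi * Rs**2
    x = (d * d - R2 * R2 + R1 * R1) / (2.0 * d)  # radical-plane offset from centre 1
    h1 = R1 - x
    h2 = R2 - (d - x)
    return 2.0 * np.pi * (R1 * h1 + R2 * h2)


def toy_dimer_analytic_buried(separation: float, r: float = 1.70, probe: float = 1.4) -> float:
    """Analytic buried area of the :func:`gen_toy_structures` toy dimer
    (a single carbon-carbon contact pair)."""
    return sphere_cap_buried(r, r, separation, probe)
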