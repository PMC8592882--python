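"""Hydrogen-bond detection and trajectory occupancy.

A hydrogen bond is scored on heavy-atom distance and hydrogen angle, the
cpptraj convention: donor-heavy to acceptor-heavy distance <= 3.0 Å and
donor–H···acceptor angle (vertex at the hydrogen) >= 135° by default.
Atoms may be grouped into chemically equivalent sets — e.g. both glutamate
carboxylate oxygens "OE(1+2)", or both Nη2 guanidino protons "HH(21+22)" —
and a frame satisfies the bond if ANY donor/hydrogen/acceptor combination
over the groups does (union semantics: one occupancy per grouped row, never
a sum over members).

Occupancy is the percentage of trajectory frames in which the bond is
present.  Structures without explicit hydrogens (crystal structures) are
rejected rather than guessing proton positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import Structure, Trajectory

__all__ = ["HBondSpec", "HBondCriteria", "HBondOccupancy", "hbond_present", "occupancy"]


@dataclass(frozen=True)
class HBondCriteria:
    """Distance/angle cutoffs; defaults 3.0 Å and 135°."""

    max_heavy_distance: float = 3.0
    min_angle: float = 135.0

    def __post_init__(self):
        if self.max_heavy_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0.0 < self.min_angle <= 180.0):
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class HBondSpec:
    """One (possibly grouped) donor/hydrogen/acceptor bond specification.

    ``hydrogen_donor`` maps each hydrogen (by position in ``hydrogens``) to
    the index of its covalently bound donor within ``donor_heavy``.  When
    omitted and the two groups have equal length the pairing is positional.
    """

    acceptors: tuple[int, ...]
    donor_heavy: tuple[int, ...]
    hydrogens: tuple[int, ...]
    hydrogen_donor: tuple[int, ...] = field(default=())
    label: str = ""

    def __post_init__(self):
        acc = tuple(int(i) for i in self.acceptors)
        don = tuple(int(i) for i in self.donor_heavy)
        hyd = tuple(int(i) for i in self.hydrogens)
        if not acc or not don or not hyd:
            raise ValueError("acceptor, donor and hydrogen groups must be non-empty")
        hmap = tuple(int(i) for i in self.hydrogen_donor)
        if not hmap:
            if len(hyd) != len(don):
                raise ValueError(
                    "hydrogen with no mapped donor: provide hydrogen_donor when "
                    "group sizes differ"
                )
            hmap = tuple(range(len(don)))
        if len(hmap) != len(hyd):
            raise ValueError("hydrogen_donor must map every hydrogen")
        if any(not (0 <= m < len(don)) for m in hmap):
            raise ValueError("hydrogen_donor entries must index donor_heavy")
        object.__setattr__(self, "acceptors", acc)
        object.__setattr__(self, "donor_heavy", don)
        object.__setattr__(self, "hydrogens", hyd)
        object.__setattr__(self, "hydrogen_donor", hmap)


@dataclass(frozen=True)
class HBondOccupancy:
    label: str
    percent: float
    n_frames: int


def _present_mask(coords: np.ndarray, spec: HBondSpec, crit: HBondCriteria) -> np.ndarray:
    """Boolean per-frame presence over an (F, N, 3) coordinate array."""
    D = coords[:, [spec.donor_heavy[m] for m in spec.hydrogen_donor], :]  # (F, nH, 3)
    H = coords[:, list(spec.hydrogens), :]                                # (F, nH, 3)
    A = coords[:, list(spec.acceptors), :]                                # (F, nA, 3)
    # distance: donor heavy atom to acceptor heavy atom
    dda = np.linalg.norm(D[:, :, None, :] - A[:, None, :, :], axis=-1)    # (F, nH, nA)
    # angle at the hydrogen between H->D and H->A
    u1 = D - H                                                            # (F, nH, 3)
    u2 = A[:, None, :, :] - H[:, :, None, :]                              # (F, nH, nA, 3)
    n1 = np.linalg.norm(u1, axis=-1)
    n2 = np.linalg.norm(u2, axis=-1)
    denom = n1[:, :, None] * n2
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("fhi,fhai->fha", u1, u2) / denom
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = (dda <= crit.max_heavy_distance) & (ang >= crit.min_angle)
    return ok.any(axis=(1, 2))


def hbond_present(frame_coords: np.ndarray, spec: HBondSpec,
                  crit: HBondCriteria = HBondCriteria()) -> bool:
    """True iff any donor/hydrogen/acceptor combination satisfies the cutoffs
    in a single (N, 3) frame."""
    coords = np.asarray(frame_coords, dtype=float)
    if coords.ndim != 2:
        raise ValueError("frame_coords must be (N, 3)")
    return bool(_present_mask(coords[None], spec, crit)[0])


def occupancy(traj: Trajectory, specs: list[HBondSpec],
              crit: HBondCriteria = HBondCriteria()) -> list[HBondOccupancy]:
    """Percent-of-frames occupancy for each bond specification."""
    if traj.n_frames < 1:
        raise ValueError("empty trajectory")
    _require_hydrogens(traj.topology, specs)
    out = []
    for spec in specs:
        present = _present_mask(traj.coords, spec, crit)
        pct = 100.0 * np.count_nonzero(present) / traj.n_frames
        out.append(HBondOccupancy(label=spec.label, percent=float(pct), n_frames=traj.n_frames))
    return out


def occupancy_table(results: list[HBondOccupancy]) -> pd.DataFrame:
    """Occupancy rows as a table (label, percent, n_frames)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "percent": [r.percent for r in results],
            "n_frames": [r.n_frames for r in results],
        }
    )


def _require_hydrogens(top: Structure, specs: list[HBondSpec]) -> None:
    for spec in specs:
        for h in spec.hydrogens:
            if not (0 <= h < top.n_atoms):
                raise IndexError(f"hydrogen index {h} out of range")
            if top.element[h] != "H":
                raise ValueError(
                    f"atom {h} ({top.name[h]!r}) in spec {spec.label!r} is not a "
                    "hydrogen; structures without explicit hydrogens cannot be "
                    "scored — add protons before the analysis"
                )
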