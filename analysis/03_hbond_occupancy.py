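#!/usr/bin/env python
"""Hydrogen-bond occupancy on the planted triad trajectory.

Recovers the planted 24.7% occupancy at the 3.0 A / 135 deg cutoffs and
demonstrates the grouped-acceptor union semantics (overlapping bound
windows give the union of frames, not the sum of percentages).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nacgeo.hbond import HBondCriteria, HBondSpec, occupancy
from nacgeo.structio import Structure, Trajectory, read_pdb, write_pdb
from nacgeo.synthetic import gen_hbond

ROOT = Path(__file__).resolve().parent.parent
TRAJ = ROOT / "scratch" / "hbond_triad.pdb"
RESULTS = ROOT / "results"


def union_case() -> float:
    """Acceptor 1 bound in frames 0-29, acceptor 2 in 20-49 of 100."""
    base, _ = gen_hbond(1, occupancy=1.0, seed=0)
    bound = base.coords[0]
    far = bound.copy()
    far[2] = bound[1] + 10.0  # move the acceptor out of range
    frames = []
    for f in range(100):
        a1 = bound[2] if f < 30 else far[2]
        a2 = bound[2] if 20 <= f < 50 else far[2]
        frames.append(np.stack([bound[0], bound[1], a1, a2]))
    top = Structure.from_arrays(
        frames[0], name=["NH1", "HH11", "OE1", "OE2"], element=["N", "H", "O", "O"],
        resname=["ARG", "ARG", "GLU", "GLU"], resid=[1, 1, 2, 2], chain=["A"] * 4,
    )
    spec = HBondSpec(acceptors=(2, 3), donor_heavy=(0,), hydrogens=(1,), label="OE(1+2)")
    return occupancy(Trajectory(top, np.stack(frames)), [spec])[0].percent


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    if not TRAJ.exists():
        TRAJ.parent.mkdir(exist_ok=True)
        traj, _ = gen_hbond(1000, occupancy=0.247, seed=7)
        write_pdb(traj, TRAJ, force_model_records=True)
    traj = read_pdb(TRAJ)
    spec = HBondSpec(acceptors=(2,), donor_heavy=(0,), hydrogens=(1,),
                     label="GLU@OE1 <- ARG@HH11")
    row = occupancy(traj, [spec], HBondCriteria(3.0, 135.0))[0]
    union_pct = union_case()

    pd.DataFrame([
        {"label": row.label, "percent": row.percent, "n_frames": row.n_frames,
         "note": "planted 24.7%"},
        {"label": "GLU@OE(1+2) union case", "percent": union_pct, "n_frames": 100,
         "note": "windows 0-29 and 20-49: union 50%, not 80%"},
    ]).to_csv(RESULTS / "hbond_occupancy.csv", index=False)

    print(f"{row.label}: {row.percent:.1f}% of {row.n_frames} frames (planted 24.7%)")
    print(f"grouped-acceptor union case: {union_pct:.1f}% (additive counting would say 80%)")
    print("wrote results/hbond_occupancy.csv")


if __name__ == "__main__":
    main()
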