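"""Plain-text trajectory and observable-table I/O.

Trajectories are written as extended XYZ: one block per frame, a comment
line carrying the box, step number and seed, and per-bead rows with the
species label, wrapped coordinates, and unwrapped coordinates.  The bond
list is written once to a sidecar file.  Observable tables are delimited
text with a ``#`` metadata header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import Trajectory

__all__ = ["write_xyz", "read_xyz", "write_bonds", "read_bonds", "write_table"]


def write_xyz(trajectory: Trajectory, path) -> None:
    """Write all frames as extended XYZ (species, wrapped xyz, unwrapped xyz)."""
    path = Path(path)
    L = trajectory.box_length
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            step = trajectory.steps[f]
            fh.write(f"{trajectory.n_beads}\n")
            fh.write(
                f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
                f"Properties=species:S:1:pos:R:3:unwrapped:R:3 "
                f"step={step} dt={trajectory.dt} seed={trajectory.seed}\n"
            )
            w = trajectory.wrapped[f]
            u = trajectory.unwrapped[f]
            for i in range(trajectory.n_beads):
                fh.write(
                    f"{trajectory.species[i]} "
                    f"{w[i, 0]:.8f} {w[i, 1]:.8f} {w[i, 2]:.8f} "
                    f"{u[i, 0]:.8f} {u[i, 1]:.8f} {u[i, 2]:.8f}\n"
                )


def read_xyz(path, bonds: np.ndarray | None = None) -> Trajectory:
    """Read a trajectory written by :func:`write_xyz`."""
    steps, wrapped, unwrapped = [], [], []
    species = None
    L = dt = None
    seed = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        comment = lines[i + 1]
        meta = dict(
            kv.split("=", 1) for kv in comment.replace('"', " ").split() if "=" in kv
        )
        if L is None:
            lat = comment.split('"')[1].split()
            L = float(lat[0])
            dt = float(meta.get("dt", 0.05))
            seed = int(meta.get("seed", 0))
        steps.append(int(meta["step"]))
        block = lines[i + 2 : i + 2 + n]
        sp = [ln.split()[0] for ln in block]
        vals = np.array([ln.split()[1:7] for ln in block], dtype=float)
        if species is None:
            species = np.array(sp)
        wrapped.append(vals[:, :3])
        unwrapped.append(vals[:, 3:6])
        i += 2 + n
    return Trajectory(
        steps=np.array(steps, dtype=np.int64),
        wrapped=np.array(wrapped),
        unwrapped=np.array(unwrapped),
        species=species,
        bonds=bonds if bonds is not None else np.empty((0, 2), dtype=np.int64),
        box_length=L,
        seed=seed,
        dt=dt,
    )


def write_bonds(bonds: np.ndarray, path) -> None:
    np.savetxt(path, bonds, fmt="%d", header="i j (0-based bead indices)")


def read_bonds(path) -> np.ndarray:
    arr = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return arr.reshape(-1, 2)


def write_table(path, columns: dict[str, np.ndarray], metadata: dict | None = None) -> None:
    """Delimited observable table with a '#' metadata header."""
    path = Path(path)
    meta_lines = [f"# {k} = {v}" for k, v in (metadata or {}).items()]
    header = "\t".join(columns)
    data = np.column_stack([np.asarray(v, dtype=float) for v in columns.values()])
    with open(path, "w") as fh:
        for ln in meta_lines:
            fh.write(ln + "\n")
        fh.write("# " + header + "\n")
        np.savetxt(fh, data, fmt="%.8g", delimiter="\t")
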