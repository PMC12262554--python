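"""File formats: PDB topologies, XYZ-block trajectories, CSV tables.

PDB reading/writing is delegated to biotite; the whitespace-delimited
XYZ-block trajectory format is native to this package:

    # lovhydra xyz trajectory
    frame 0 time_ps 0.0
    x y z        (one line per atom, topology order)
    ...
    frame 1 time_ps 1.0
    ...

CSV tables are UTF-8 with a header row; readers raise errors naming the
file and the missing column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .frames import Frame, Trajectory

__all__ = [
    "read_structure", "write_structure",
    "read_xyz_trajectory", "write_xyz_trajectory",
    "read_table", "write_table",
]


def read_structure(path: str | Path) -> Frame:
    """Read a PDB file (ATOM/HETATM records) into a :class:`Frame`.

    Residue numbers are taken verbatim; no renumbering.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
    except Exception as exc:
        raise ValueError(f"{path}: failed to parse PDB: {exc}") from exc
    element = np.array([e.capitalize() if len(e) > 1 else e
                        for e in atoms.element], dtype=object)
    return Frame(
        coords=atoms.coord,
        resid=atoms.res_id,
        resname=np.array(atoms.res_name, dtype=object),
        element=element,
        atom_name=np.array(atoms.atom_name, dtype=object),
    )


def write_structure(frame: Frame, path: str | Path) -> None:
    """Write a :class:`Frame` as a PDB topology."""
    n = frame.n_atoms
    atoms = bst.AtomArray(n)
    atoms.coord = np.asarray(frame.coords, dtype=np.float32)
    atoms.res_id = frame.resid
    atoms.res_name = frame.resname.astype("U5")
    atoms.atom_name = frame.atom_name.astype("U6")
    atoms.element = np.array([str(e).upper() for e in frame.element],
                             dtype="U2")
    atoms.hetero = frame.is_water
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# lovhydra xyz trajectory\n")
        fh.write(f"# n_atoms {traj.topology.n_atoms}\n")
        for i in range(traj.n_frames):
            fh.write(f"frame {i} time_ps {float(traj.times_ps[i])!r}\n")
            np.savetxt(fh, traj.coords[i], fmt="%.6f")


def read_xyz_trajectory(path: str | Path, topology: Frame) -> Trajectory:
    """Read a native XYZ-block trajectory against a PDB-derived topology."""
    path = Path(path)
    n_atoms = topology.n_atoms
    frames, times = [], []
    block: list[list[float]] = []

    def flush(lineno: int) -> None:
        if not times:
            return
        if len(block) != n_atoms:
            raise ValueError(
                f"{path}:{lineno}: frame {len(frames)} has {len(block)} "
                f"coordinate lines, topology has {n_atoms} atoms")
        frames.append(np.array(block, dtype=float))
        block.clear()

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("frame"):
                flush(lineno)
                parts = line.split()
                try:
                    times.append(float(parts[3]))
                except (IndexError, ValueError) as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed frame header "
                        f"{line!r}") from exc
            else:
                vals = line.split()
                if len(vals) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 coordinates, "
                        f"got {len(vals)} in field {vals!r}")
                block.append([float(v) for v in vals])
        flush(lineno + 1)
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(topology, np.stack(frames), np.array(times))


def read_table(path: str | Path,
               required_columns: Sequence[str]) -> pd.DataFrame:
    """CSV with a validated header; errors name the file and the column."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: failed to read CSV: {exc}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
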