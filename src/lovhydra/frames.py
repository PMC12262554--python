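"""Core coordinate containers shared by all molecular-dynamics-facing stages.

A :class:`Frame` is a single snapshot of atom coordinates with residue
identity and water/protein flags; a :class:`Trajectory` is a stack of frames
over a shared topology.  Units are angstrom for coordinates and picoseconds
for frame times throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

#: residue names recognised as water in topologies we read or write
WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP3P", "SPC"})


@dataclass
class Frame:
    """One coordinate snapshot.

    Parameters
    ----------
    coords
        ``(n_atoms, 3)`` float array, angstrom.
    resid
        ``(n_atoms,)`` integer residue numbers (taken verbatim from the
        topology; no renumbering).
    resname
        ``(n_atoms,)`` residue names.
    element
        ``(n_atoms,)`` element symbols (``"O"``, ``"H"``, ``"C"``, ...).
    atom_name
        ``(n_atoms,)`` atom names (``"OW"``, ``"CA"``, ...).
    time_ps
        Frame time in picoseconds.
    """

    coords: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    element: np.ndarray
    atom_name: np.ndarray
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        n = self.coords.shape[0]
        for name in ("resid", "resname", "element", "atom_name"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def is_water(self) -> np.ndarray:
        return np.array([rn in WATER_RESNAMES for rn in self.resname], dtype=bool)

    @property
    def is_water_oxygen(self) -> np.ndarray:
        return self.is_water & (self.element == "O")

    @property
    def is_water_hydrogen(self) -> np.ndarray:
        return self.is_water & (self.element == "H")

    @property
    def is_protein_heavy(self) -> np.ndarray:
        return ~self.is_water & (self.element != "H")

    def water_oxygen_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_water_oxygen)

    def hydrogens_of_water(self, o_index: int) -> np.ndarray:
        """Indices of the two hydrogens belonging to the water of ``o_index``."""
        mask = self.is_water_hydrogen & (self.resid == self.resid[o_index])
        h = np.flatnonzero(mask)
        if h.size != 2:
            raise ValueError(
                f"water residue {self.resid[o_index]} has {h.size} hydrogens, expected 2"
            )
        return h

    def validate_waters(self) -> None:
        """Raise if any water oxygen does not carry exactly two hydrogens."""
        for o in self.water_oxygen_indices():
            self.hydrogens_of_water(int(o))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Frame":
        """Rigid-body transformed copy (rotation applied first)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return Frame(xyz, self.resid, self.resname, self.element,
                     self.atom_name, self.time_ps)


@dataclass
class Trajectory:
    """Frames over a shared topology with uniformly or explicitly spaced times."""

    topology: Frame
    coords: np.ndarray = field(repr=False)  # (n_frames, n_atoms, 3)
    times_ps: np.ndarray = field(default=None, repr=False)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.times_ps is None:
            self.times_ps = np.arange(self.coords.shape[0], dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.times_ps.shape != (self.coords.shape[0],):
            raise ValueError("times_ps must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dt_ps(self) -> float:
        """Frame spacing; raises if frames are not uniformly spaced."""
        if self.n_frames < 2:
            raise ValueError("dt undefined for a single-frame trajectory")
        diffs = np.diff(self.times_ps)
        if not np.allclose(diffs, diffs[0]):
            raise ValueError("frames are not uniformly spaced")
        return float(diffs[0])

    def frame(self, i: int) -> Frame:
        t = self.topology
        return Frame(self.coords[i], t.resid, t.resname, t.element,
                     t.atom_name, float(self.times_ps[i]))

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames


def as_frames(traj: "Trajectory | Iterable[Frame]") -> Iterable[Frame]:
    """Adapter contract: any iterable of :class:`Frame` acts as a trajectory.

    Readers for compressed trajectory formats only need to yield frames to
    plug into the analysis stages.
    """
    return iter(traj)
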