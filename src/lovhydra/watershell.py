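"""Hydration-water structure classification and shell residence analysis.

The water-structure order parameter used throughout is the three-body angle
(3BA): the angle at a central water oxygen subtended by two of its
hydrogen-bonded neighbour oxygens.  Angle windows separate three structural
archetypes of hydration water:

* **wrap** water — low-density, tetrahedrally coordinated (3BA 100–120°),
  hydrating small hydrophobic patches;
* **icosahedral** water — higher-density bulk-like water (3BA 50–70°);
* **bound** water — near-planar hydrogen-bond geometry (3BA 150–170°) with
  the longest surface residence times.

Waters are assigned to per-residue hydration shells by a heavy-atom distance
cutoff, and residence times are computed in first-passage mode (a water's
first continuous stay in a shell; re-entries excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .frames import Frame, Trajectory

__all__ = [
    "HBondCriterion",
    "ClassWindows",
    "find_hbond_neighbors",
    "three_body_angles",
    "classify_angles",
    "shell_assign",
    "hydration_profile",
    "residence_times",
    "wrap_change_flags",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition between two waters.

    A pair of water oxygens (i, j) is hydrogen bonded iff their O–O distance
    is at most ``max_oo`` and at least one of the two waters donates a
    hydrogen lying within ``max_angle_dev`` degrees of its O→O axis.
    Defaults are the standard geometric criterion for rigid 3-site waters.
    """

    max_oo: float = 3.5          # angstrom
    max_angle_dev: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.max_oo <= 0:
            raise ValueError("max_oo must be positive")
        if not 0.0 <= self.max_angle_dev <= 90.0:
            raise ValueError("max_angle_dev must be in [0, 90] degrees")


@dataclass(frozen=True)
class ClassWindows:
    """Angle windows (degrees) assigning each 3BA to one water class."""

    wrap: Tuple[float, float] = (100.0, 120.0)
    icosahedral: Tuple[float, float] = (50.0, 70.0)
    bound: Tuple[float, float] = (150.0, 170.0)

    def __post_init__(self) -> None:
        spans = sorted([self.icosahedral, self.wrap, self.bound])
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if hi1 > lo2:
                raise ValueError("class windows must be disjoint")

    def items(self):
        return (("wrap", self.wrap), ("icosahedral", self.icosahedral),
                ("bound", self.bound))


def find_hbond_neighbors(frame: Frame,
                         crit: HBondCriterion = HBondCriterion()
                         ) -> Dict[int, List[int]]:
    """Hydrogen-bonded neighbour oxygens for every water oxygen.

    Returns a mapping ``atom index of water O -> sorted list of neighbour
    water-O atom indices``.  The relation is symmetric and irreflexive.
    """
    o_idx = frame.water_oxygen_indices()
    neighbors: Dict[int, List[int]] = {int(i): [] for i in o_idx}
    if o_idx.size < 2:
        return neighbors
    o_xyz = frame.coords[o_idx]
    # hydrogens per water, in o_idx order
    h_xyz = np.empty((o_idx.size, 2, 3))
    for k, o in enumerate(o_idx):
        h = frame.hydrogens_of_water(int(o))
        h_xyz[k] = frame.coords[h]

    tree = cKDTree(o_xyz)
    pairs = tree.query_pairs(crit.max_oo, output_type="ndarray")
    cos_tol = np.cos(np.radians(crit.max_angle_dev))
    for a, b in pairs:
        oo = o_xyz[b] - o_xyz[a]
        d = np.linalg.norm(oo)
        if d == 0.0:
            continue
        bonded = False
        for donor, axis in ((a, oo / d), (b, -oo / d)):
            oh = h_xyz[donor] - o_xyz[donor]
            oh_norm = np.linalg.norm(oh, axis=1)
            cosang = (oh @ axis) / oh_norm
            if np.any(cosang >= cos_tol):
                bonded = True
                break
        if bonded:
            neighbors[int(o_idx[a])].append(int(o_idx[b]))
            neighbors[int(o_idx[b])].append(int(o_idx[a]))
    for k in neighbors:
        neighbors[k].sort()
    return neighbors


def three_body_angles(frame: Frame,
                      neighbors: Dict[int, List[int]],
                      max_neighbors: int = 4
                      ) -> List[Tuple[int, float]]:
    """Three-body angles at each central water oxygen, in degrees.

    For every central oxygen, the angle at the central O is computed for each
    unordered pair among its hydrogen-bonded neighbour oxygens, capped at the
    ``max_neighbors`` nearest neighbours (distance ties broken by atom
    index).  Waters with fewer than two neighbours contribute no angles.

    Returns a list of ``(central O atom index, angle in [0, 180])``.
    """
    out: List[Tuple[int, float]] = []
    for center, nbrs in neighbors.items():
        if len(nbrs) < 2:
            continue
        c = frame.coords[center]
        if len(nbrs) > max_neighbors:
            d = np.linalg.norm(frame.coords[nbrs] - c, axis=1)
            order = np.lexsort((nbrs, d))[:max_neighbors]
            nbrs = [nbrs[i] for i in sorted(order)]
        vecs = frame.coords[nbrs] - c
        vecs /= np.linalg.norm(vecs, axis=1)[:, None]
        m = len(nbrs)
        for i in range(m):
            for j in range(i + 1, m):
                cosang = float(np.clip(vecs[i] @ vecs[j], -1.0, 1.0))
                out.append((center, float(np.degrees(np.arccos(cosang)))))
    return out


def classify_angles(angles: Sequence[float] | Sequence[Tuple[int, float]],
                    windows: ClassWindows = ClassWindows()
                    ) -> pd.Series:
    """Counts and fractions of 3BA values per water class.

    Accepts either bare angles or ``(center, angle)`` tuples.  Each angle is
    assigned to exactly one window or to ``unclassified``; returned Series
    has counts ``n_<class>`` and fractions ``frac_<class>`` over all angles.
    """
    vals = np.array([a[1] if isinstance(a, tuple) else a for a in angles],
                    dtype=float)
    counts = {name: 0 for name, _ in windows.items()}
    counts["unclassified"] = 0
    for a in vals:
        for name, (lo, hi) in windows.items():
            if lo <= a <= hi:
                counts[name] += 1
                break
        else:
            counts["unclassified"] += 1
    total = max(len(vals), 1)
    data = {}
    for name, n in counts.items():
        data[f"n_{name}"] = n
        data[f"frac_{name}"] = n / total if len(vals) else 0.0
    data["n_total"] = len(vals)
    return pd.Series(data)


def shell_assign(frame: Frame, cutoff: float = 4.5
                 ) -> Dict[int, set]:
    """Map residue number -> set of water-O atom indices in its shell.

    A water oxygen belongs to residue ``r``'s hydration shell iff it lies
    within ``cutoff`` angstrom of any heavy atom of ``r``; a water may belong
    to several shells.
    """
    heavy = np.flatnonzero(frame.is_protein_heavy)
    o_idx = frame.water_oxygen_indices()
    resids = np.unique(frame.resid[heavy]) if heavy.size else np.array([], int)
    shells: Dict[int, set] = {int(r): set() for r in resids}
    if heavy.size == 0 or o_idx.size == 0:
        return shells
    tree = cKDTree(frame.coords[o_idx])
    for r in resids:
        atoms = heavy[frame.resid[heavy] == r]
        hits = tree.query_ball_point(frame.coords[atoms], cutoff)
        members = set()
        for lst in hits:
            members.update(int(o_idx[i]) for i in lst)
        shells[int(r)] = members
    return shells


def hydration_profile(traj: Trajectory | Iterable[Frame],
                      windows: ClassWindows = ClassWindows(),
                      cutoff: float = 4.5,
                      crit: HBondCriterion = HBondCriterion(),
                      time_window: Tuple[float, float] | None = None,
                      label: str = "",
                      max_neighbors: int = 4) -> pd.DataFrame:
    """Per-residue water-class fractions averaged over frames in a window.

    A 3BA is counted toward residue ``r`` iff its *central* water lies in
    ``r``'s shell in that frame.  Residues whose shells hold no angles in the
    window get zero fractions and ``empty_shell=True``.

    Returns a DataFrame indexed by residue number with columns
    ``shell_count`` (mean waters per frame), ``frac_wrap``,
    ``frac_icosahedral``, ``frac_bound``, ``frac_unclassified``,
    ``n_angles``, ``empty_shell`` and ``window`` (the label).
    """
    per_res_counts: Dict[int, Dict[str, float]] = {}
    n_frames = 0
    for fr in traj:
        if time_window is not None and not (
                time_window[0] <= fr.time_ps <= time_window[1]):
            continue
        n_frames += 1
        nbrs = find_hbond_neighbors(fr, crit)
        angles = three_body_angles(fr, nbrs, max_neighbors=max_neighbors)
        shells = shell_assign(fr, cutoff)
        # invert: water O -> residues whose shell holds it
        water_res: Dict[int, List[int]] = {}
        for r, members in shells.items():
            rec = per_res_counts.setdefault(r, {
                "shell_count": 0.0, "wrap": 0, "icosahedral": 0,
                "bound": 0, "unclassified": 0, "n_angles": 0})
            rec["shell_count"] += len(members)
            for o in members:
                water_res.setdefault(o, []).append(r)
        for center, ang in angles:
            for r in water_res.get(center, ()):
                rec = per_res_counts[r]
                rec["n_angles"] += 1
                for name, (lo, hi) in windows.items():
                    if lo <= ang <= hi:
                        rec[name] += 1
                        break
                else:
                    rec["unclassified"] += 1
    if n_frames == 0:
        raise ValueError("no frames fall in the requested time window")

    rows = []
    for r in sorted(per_res_counts):
        rec = per_res_counts[r]
        tot = rec["n_angles"]
        row = {
            "residue": r,
            "shell_count": rec["shell_count"] / n_frames,
            "n_angles": tot,
            "empty_shell": tot == 0,
            "window": label,
        }
        for name in ("wrap", "icosahedral", "bound", "unclassified"):
            row[f"frac_{name}"] = rec[name] / tot if tot else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("residue")


def residence_times(traj: Trajectory, cutoff: float = 4.5) -> pd.DataFrame:
    """First-passage residence times of shell waters, per residue.

    For each (water, residue) pair, only the water's *first* continuous
    occupancy interval counts — from first entry to first exit, with later
    re-entries excluded; intervals still open at the trajectory end are
    discarded.  Durations are ``n_occupied_frames * dt``.

    Returns a DataFrame indexed by residue with columns
    ``mean_residence_ps`` and ``n_visits``.
    """
    if traj.n_frames < 2:
        raise ValueError("residence times need at least two frames")
    dt = traj.dt_ps

    # occupancy[(water, residue)] -> list of frame indices, built frame by frame
    first_entry: Dict[Tuple[int, int], int] = {}
    first_exit: Dict[Tuple[int, int], int] = {}
    prev_in: set = set()
    residues: set = set()
    for fi, fr in enumerate(traj):
        shells = shell_assign(fr, cutoff)
        residues.update(shells)
        now_in = {(o, r) for r, members in shells.items() for o in members}
        for key in now_in - prev_in:
            if key not in first_entry and key not in first_exit:
                first_entry[key] = fi
        for key in prev_in - now_in:
            if key in first_entry and key not in first_exit:
                first_exit[key] = fi
        prev_in = now_in

    per_res: Dict[int, List[float]] = {int(r): [] for r in residues}
    for (o, r), start in first_entry.items():
        if (o, r) in first_exit:  # completed visits only
            per_res[r].append((first_exit[(o, r)] - start) * dt)
    rows = [{"residue": r,
             "mean_residence_ps": float(np.mean(v)) if v else np.nan,
             "n_visits": len(v)}
            for r, v in sorted(per_res.items())]
    return pd.DataFrame(rows).set_index("residue")


def wrap_change_flags(profile_ref: pd.DataFrame,
                      profile_t: pd.DataFrame) -> pd.DataFrame:
    """Residues whose wrap-water fraction dropped by more than half the mean.

    A residue is flagged iff ``wrap_ref(i) - wrap_t(i)`` exceeds 0.5 times
    the mean wrap fraction of the reference profile over all residues —
    the per-residue criterion used to mark sites of concerted wrap-water
    loss between a reference window and a later time point.
    """
    common = profile_ref.index.intersection(profile_t.index)
    ref = profile_ref.loc[common, "frac_wrap"]
    cur = profile_t.loc[common, "frac_wrap"]
    threshold = 0.5 * float(profile_ref["frac_wrap"].mean())
    delta = ref - cur
    return pd.DataFrame({
        "wrap_ref": ref,
        "wrap_t": cur,
        "delta": delta,
        "threshold": threshold,
        "flagged": delta > threshold,
    })
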