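"""Trajectory segmentation and conformer selection.

Solvent-accessible surface area (Shrake–Rupley), penalised change-point
detection on SASA series, GROMOS-style greedy RMSD clustering (Daura
neighbour-count algorithm) for representative-conformer selection, and
residue-wise displacement relative to a reference structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .frames import Frame

__all__ = [
    "BONDI_RADII",
    "sphere_points",
    "sasa",
    "changepoints",
    "pairwise_rmsd",
    "daura_cluster",
    "residue_displacement",
    "ClusterResult",
]

#: Bondi van der Waals radii (angstrom)
BONDI_RADII: Dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}
DEFAULT_VDW = 1.70


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points by the golden-spiral construction."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(frame: Frame, probe: float = 1.4, n_points: int = 960,
         per_residue: bool = False,
         default_radius: float = DEFAULT_VDW) -> float | pd.Series:
    """Shrake–Rupley solvent-accessible surface area of the heavy atoms.

    For each heavy atom, ``n_points`` quasi-uniform points are placed on a
    sphere of radius r_vdw + probe; the accessible fraction (points not
    inside any other inflated atom) times the sphere area gives the atomic
    SASA.  Unknown elements fall back to ``default_radius`` with a warning.

    Returns the total area in Å², or a per-residue Series if requested.
    """
    heavy = np.flatnonzero(frame.element != "H")
    xyz = frame.coords[heavy]
    radii = np.empty(heavy.size)
    for k, i in enumerate(heavy):
        el = str(frame.element[i]).upper()
        if el not in BONDI_RADII:
            warnings.warn(f"no vdW radius for element {el!r}; "
                          f"using {default_radius} Å", stacklevel=2)
        radii[k] = BONDI_RADII.get(el, default_radius)
    inflated = radii + probe
    pts = sphere_points(n_points)

    areas = np.zeros(heavy.size)
    for k in range(heavy.size):
        surf = xyz[k] + inflated[k] * pts
        accessible = np.ones(n_points, dtype=bool)
        d0 = np.linalg.norm(xyz - xyz[k], axis=1)
        close = np.flatnonzero((d0 < inflated + inflated[k]) &
                               (np.arange(heavy.size) != k))
        for j in close:
            accessible &= (np.linalg.norm(surf - xyz[j], axis=1)
                           >= inflated[j])
            if not accessible.any():
                break
        areas[k] = accessible.mean() * 4.0 * np.pi * inflated[k] ** 2
    if per_residue:
        return pd.Series(areas).groupby(frame.resid[heavy]).sum()
    return float(areas.sum())


def _segment_cost(prefix: np.ndarray, prefix2: np.ndarray,
                  i: int, j: int) -> float:
    """Within-segment squared error of series[i:j] from prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def changepoints(series: np.ndarray, penalty: float | None = None,
                 min_size: int = 2) -> List[int]:
    """Binary-segmentation change-point detection with L2 cost.

    Splits are accepted greedily wherever the best single split of a
    segment reduces the within-segment squared error by more than
    ``penalty``; ties break to the lowest index, so the result is
    deterministic.  The default penalty is 2·σ̂²·log(n) with σ̂² estimated
    from first differences (var(diff)/2), which admits no splits on a
    constant series for any n.

    Returns sorted breakpoint indices: a breakpoint b means segments
    ``[..., b)`` and ``[b, ...)``.
    """
    y = np.asarray(series, dtype=float)
    n = y.size
    if n < 2 * min_size:
        return []
    if penalty is None:
        sigma2 = float(np.var(np.diff(y))) / 2.0
        penalty = 2.0 * max(sigma2, 1e-300) * np.log(n)
    prefix = np.concatenate([[0.0], np.cumsum(y)])
    prefix2 = np.concatenate([[0.0], np.cumsum(y * y)])
    # floor against float rounding in the prefix sums (exact-constant input)
    penalty = max(penalty, 1e3 * np.finfo(float).eps * (prefix2[-1] + 1.0))

    def best_split(i: int, j: int) -> Tuple[float, int]:
        whole = _segment_cost(prefix, prefix2, i, j)
        best_gain, best_b = -np.inf, -1
        for b in range(i + min_size, j - min_size + 1):
            gain = whole - _segment_cost(prefix, prefix2, i, b) \
                - _segment_cost(prefix, prefix2, b, j)
            if gain > best_gain + 1e-12:
                best_gain, best_b = gain, b
        return best_gain, best_b

    breaks: List[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop(0)
        if j - i < 2 * min_size:
            continue
        gain, b = best_split(i, j)
        if b >= 0 and gain > penalty:
            breaks.append(b)
            stack.append((i, b))
            stack.append((b, j))
    return sorted(breaks)


def pairwise_rmsd(frame_a: Frame, frame_b: Frame, fit: bool = True) -> float:
    """Heavy-atom RMSD in nm, after centroid removal and optional Kabsch fit."""
    ha = np.flatnonzero(frame_a.element != "H")
    hb = np.flatnonzero(frame_b.element != "H")
    if ha.size != hb.size:
        raise ValueError("frames have different heavy-atom counts")
    A = frame_a.coords[ha] - frame_a.coords[ha].mean(axis=0)
    B = frame_b.coords[hb] - frame_b.coords[hb].mean(axis=0)
    if fit:
        # Kabsch: optimal proper rotation by SVD of the covariance
        H = B.T @ A
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1.0, 1.0, d]) @ Vt
        B = B @ R
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1)))) / 10.0


@dataclass
class ClusterResult:
    """Daura clustering output: centers index into the input frame list."""

    centers: List[int]
    members: List[List[int]]
    cutoff_nm: float

    def labels(self) -> np.ndarray:
        n = sum(len(m) for m in self.members)
        lab = np.empty(n, dtype=int)
        for ci, mem in enumerate(self.members):
            lab[mem] = ci
        return lab


def daura_cluster(frames: Sequence[Frame], cutoff_nm: float = 0.2,
                  fit: bool = True,
                  rmsd_matrix: np.ndarray | None = None) -> ClusterResult:
    """Greedy neighbour-count RMSD clustering (Daura / GROMOS algorithm).

    Iteratively: count each remaining frame's neighbours within the RMSD
    cutoff, take the frame with the most neighbours as a cluster center
    (ties to the lowest frame index), remove it and its neighbours, repeat.
    The result is a partition whose centers are members of their clusters.
    """
    n = len(frames)
    if rmsd_matrix is None:
        rmsd_matrix = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                rmsd_matrix[i, j] = rmsd_matrix[j, i] = \
                    pairwise_rmsd(frames[i], frames[j], fit=fit)
    adj = rmsd_matrix <= cutoff_nm
    np.fill_diagonal(adj, False)

    remaining = np.ones(n, dtype=bool)
    centers: List[int] = []
    members: List[List[int]] = []
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        group = np.flatnonzero(adj[center] & remaining).tolist()
        group = sorted(set(group) | {center})
        centers.append(center)
        members.append(group)
        remaining[group] = False
    return ClusterResult(centers, members, cutoff_nm)


def residue_displacement(frame: Frame, reference: Frame,
                         fit_rotation: bool = False) -> pd.Series:
    """Per-residue centroid displacement (Å) after center-of-gravity overlay.

    Both structures are translated so their heavy-atom centers of gravity
    coincide (no rotation by default; an optional Kabsch rotational fit is
    available).  The displacement of residue r is the Euclidean distance
    between its heavy-atom centroids in the two structures.
    """
    ha = np.flatnonzero(frame.is_protein_heavy)
    hr = np.flatnonzero(reference.is_protein_heavy)
    if ha.size != hr.size or not np.array_equal(frame.resid[ha],
                                                reference.resid[hr]):
        raise ValueError("frame and reference topologies do not match")
    A = frame.coords[ha] - frame.coords[ha].mean(axis=0)
    B = reference.coords[hr] - reference.coords[hr].mean(axis=0)
    if fit_rotation:
        H = A.T @ B
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1.0, 1.0, d]) @ Vt
        A = A @ R
    resid = frame.resid[ha]
    out = {}
    for r in np.unique(resid):
        sel = resid == r
        out[int(r)] = float(np.linalg.norm(A[sel].mean(axis=0)
                                           - B[sel].mean(axis=0)))
    return pd.Series(out, name="displacement_A")
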