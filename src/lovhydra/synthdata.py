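"""Synthetic inputs for every analysis stage.

Each generator is a pure function of its spec (including the seed) and
retains its ground-truth parameters, so every analysis stage can be tested
by parameter recovery without any external data:

* water configurations whose hydrogen-bonded three-body angles sit exactly
  at a chosen geometry class (tetrahedral / icosahedral / planar / mixed);
* toy trajectories in which waters enter and leave per-residue shells as a
  two-state telegraph process with exponential dwell times;
* quadratic pressure–shift tables with a sparse subset of nonlinear
  residues;
* multi-component ¹⁷O inversion-recovery curves;
* two-Gaussian distance distributions rendered to dipolar traces;
* single-exponential recovery series.

Synthetic waters use the rigid 3-site geometry (O–H 0.9572 Å, H–O–H
104.52°) with hydrogens oriented so the geometric hydrogen-bond criterion
fires by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import deerpop, oxy17
from .curves import RecoveryCurve
from .frames import Frame, Trajectory

__all__ = [
    "GeometrySpec", "ShellDynamicsSpec", "ShiftTableSpec", "RelaxSpec",
    "DeerSpec", "ShiftTable",
    "gen_water_geometry", "gen_toy_trajectory", "gen_shift_table",
    "gen_inversion_recovery", "gen_deer_trace", "gen_decay_series",
    "TETRAHEDRAL_ANGLE", "ICOSAHEDRAL_ANGLE",
]

OH_BOND = 0.9572      # angstrom, rigid 3-site water
HOH_ANGLE = 104.52    # degrees
OO_HBOND = 2.8        # angstrom, generated O–O hydrogen-bond length
UNIT_PITCH = 16.0     # angstrom between generated water clusters

TETRAHEDRAL_ANGLE = float(np.degrees(np.arccos(-1.0 / 3.0)))   # 109.471...
ICOSAHEDRAL_ANGLE = float(np.degrees(np.arccos(1.0 / np.sqrt(5.0))))  # 63.43

_CLASS_UNIT_SIZE = {"tetrahedral": 5, "icosahedral": 13, "planar": 3}
_CLASS_ANGLES_PER_UNIT = {"tetrahedral": 6, "icosahedral": 3, "planar": 1}

_TETRA_DIRS = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / np.sqrt(3.0)

_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [[0, 1, _PHI], [0, -1, _PHI], [0, 1, -_PHI], [0, -1, -_PHI],
     [1, _PHI, 0], [-1, _PHI, 0], [1, -_PHI, 0], [-1, -_PHI, 0],
     [_PHI, 0, 1], [-_PHI, 0, 1], [_PHI, 0, -1], [-_PHI, 0, -1]],
    dtype=float)
_ICO_VERTS /= np.linalg.norm(_ICO_VERTS, axis=1)[:, None]
#: indices of one triangular face (mutually adjacent vertices)
_ICO_FACE = (0, 1, 8)


@dataclass(frozen=True)
class GeometrySpec:
    """Prescribed 3BA geometry class for a synthetic water configuration."""

    class_label: str
    n_waters: int
    jitter_deg: float = 0.0
    box_edge: float = 60.0
    seed: int = 0
    planar_angle: float = 160.0        # degrees, inside [150, 170]
    mix_fractions: Dict[str, float] = field(
        default_factory=lambda: {"tetrahedral": 0.5, "icosahedral": 0.5})

    def __post_init__(self) -> None:
        known = set(_CLASS_UNIT_SIZE) | {"mixed"}
        if self.class_label not in known:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.n_waters < 1:
            raise ValueError("n_waters must be >= 1")
        if self.jitter_deg < 0:
            raise ValueError("jitter_deg must be >= 0")
        if self.class_label in _CLASS_UNIT_SIZE and \
                self.n_waters < _CLASS_UNIT_SIZE[self.class_label]:
            raise ValueError(
                f"{self.class_label} geometry needs at least "
                f"{_CLASS_UNIT_SIZE[self.class_label]} waters")
        if not 150.0 <= self.planar_angle <= 170.0:
            raise ValueError("planar_angle must lie in [150, 170] degrees")


def _perp(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to v."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(v @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, a)
    return p / np.linalg.norm(p)


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    return (v * np.cos(angle_rad) + np.cross(axis, v) * np.sin(angle_rad)
            + axis * (axis @ v) * (1.0 - np.cos(angle_rad)))


def _jittered(u: np.ndarray, jitter_deg: float,
              rng: np.random.Generator) -> np.ndarray:
    if jitter_deg == 0:
        return u
    angle = abs(rng.normal(0.0, np.radians(jitter_deg)))
    axis = _perp(u)
    axis = _rotate(axis, u, rng.uniform(0.0, 2.0 * np.pi))
    return _rotate(u, axis, angle)


def _water_atoms(o: np.ndarray, h1_dir: np.ndarray,
                 h2_hint: np.ndarray) -> np.ndarray:
    """O plus two rigid hydrogens; H1 along h1_dir, H2 in the (h1, hint)
    plane at the rigid H-O-H angle."""
    d1 = h1_dir / np.linalg.norm(h1_dir)
    hint = h2_hint - (h2_hint @ d1) * d1
    nh = np.linalg.norm(hint)
    hint = _perp(d1) if nh < 1e-9 else hint / nh
    ang = np.radians(HOH_ANGLE)
    d2 = np.cos(ang) * d1 + np.sin(ang) * hint
    return np.stack([o, o + OH_BOND * d1, o + OH_BOND * d2])


def _unit_waters(label: str, center: np.ndarray, planar_angle: float,
                 jitter_deg: float, rng: np.random.Generator
                 ) -> List[np.ndarray]:
    """Water (O,H1,H2) triples of one cluster of the requested class.

    The first water is the central one; its hydrogen-bonded neighbours are
    placed so every 3BA at the central oxygen equals the class angle before
    jitter, and no spurious hydrogen bonds arise elsewhere in the cluster.
    """
    waters: List[np.ndarray] = []
    if label == "tetrahedral":
        dirs = [_jittered(d, jitter_deg, rng) for d in _TETRA_DIRS]
        waters.append(_water_atoms(center, dirs[0], dirs[1]))
        for d in dirs:
            o = center + OO_HBOND * d
            waters.append(_water_atoms(o, -d, _perp(d)))  # donates to center
    elif label == "icosahedral":
        verts = [_jittered(v, jitter_deg, rng) for v in _ICO_VERTS]
        # central hydrogens: H1 along the face-centroid axis (>=37 deg from
        # every vertex); H2's azimuth on the rigid H-O-H cone is chosen to
        # maximise clearance from all vertex directions (~35 deg optimum),
        # so the central water never donates a bond beyond the face
        f = sum(verts[i] for i in _ICO_FACE)
        f /= np.linalg.norm(f)
        vmat = np.stack(verts)
        e1 = _perp(f)
        e2 = np.cross(f, e1)
        ang = np.radians(HOH_ANGLE)
        best_hint, best_clear = e1, -1.0
        for az in np.linspace(0.0, 2.0 * np.pi, 144, endpoint=False):
            hint = np.cos(az) * e1 + np.sin(az) * e2
            d2 = np.cos(ang) * f + np.sin(ang) * hint
            clear = float(np.arccos(np.clip(vmat @ d2, -1, 1)).min())
            if clear > best_clear:
                best_clear, best_hint = clear, hint
        waters.append(_water_atoms(center, f, best_hint))
        for k, v in enumerate(verts):
            o = center + OO_HBOND * v
            if k in _ICO_FACE:       # face waters donate toward the center
                waters.append(_water_atoms(o, -v, _perp(v)))
            else:                    # others point both hydrogens outward
                p = _perp(v)
                half = np.radians(HOH_ANGLE / 2.0)
                d1 = _rotate(v, p, half)
                d2 = _rotate(v, p, -half)
                waters.append(_water_atoms(o, d1, d2))
    elif label == "planar":
        d0 = _jittered(np.array([1.0, 0.0, 0.0]), jitter_deg, rng)
        d1 = _rotate(d0, np.array([0.0, 0.0, 1.0]),
                     np.radians(planar_angle))
        d1 = _jittered(d1, jitter_deg, rng)
        waters.append(_water_atoms(center, d0, d1))
        for d in (d0, d1):
            o = center + OO_HBOND * d
            waters.append(_water_atoms(o, -d, _perp(d)))
    else:  # pragma: no cover - guarded by the spec
        raise ValueError(label)
    return waters


def gen_water_geometry(spec: GeometrySpec) -> Frame:
    """Water configuration with prescribed 3BA geometry.

    Builds isolated clusters ("units") on a coarse grid: each unit has one
    central water whose hydrogen-bonded neighbour oxygens realise the class
    angle exactly (109.47° tetrahedral, 63.43° icosahedral adjacent-vertex,
    configurable 150–170° planar) before angular jitter.  ``mixed`` draws
    the class of each unit from ``spec.mix_fractions``.

    The returned :class:`Frame` carries a ``truth`` attribute with the
    per-unit class labels and the expected angle-level class fractions.
    """
    rng = np.random.default_rng(spec.seed)
    budget = spec.n_waters
    unit_classes: List[str] = []
    if spec.class_label == "mixed":
        labels = sorted(spec.mix_fractions)
        probs = np.array([spec.mix_fractions[l] for l in labels], dtype=float)
        if np.any(probs < 0) or probs.sum() <= 0:
            raise ValueError("mix_fractions must be non-negative, not all 0")
        probs = probs / probs.sum()
        while budget >= min(_CLASS_UNIT_SIZE[l] for l in labels):
            lab = rng.choice(labels, p=probs)
            if _CLASS_UNIT_SIZE[lab] > budget:
                continue
            unit_classes.append(str(lab))
            budget -= _CLASS_UNIT_SIZE[lab]
    else:
        size = _CLASS_UNIT_SIZE[spec.class_label]
        unit_classes = [spec.class_label] * (budget // size)
    if not unit_classes:
        raise ValueError("n_waters too small for any unit of the "
                         "requested class")

    m = int(np.ceil(len(unit_classes) ** (1.0 / 3.0)))
    grid = [UNIT_PITCH * np.array([i, j, k], dtype=float)
            for i in range(m) for j in range(m) for k in range(m)]
    coords, resid = [], []
    origins: List[np.ndarray] = []
    next_resid = 1
    for lab, origin in zip(unit_classes, grid):
        origins.append(origin)
        for triple in _unit_waters(lab, origin, spec.planar_angle,
                                   spec.jitter_deg, rng):
            coords.append(triple)
            resid.extend([next_resid] * 3)
            next_resid += 1
    coords = np.concatenate(coords, axis=0)
    n_waters = next_resid - 1
    frame = Frame(
        coords=coords,
        resid=np.array(resid),
        resname=np.array(["HOH"] * coords.shape[0], dtype=object),
        element=np.array(["O", "H", "H"] * n_waters, dtype=object),
        atom_name=np.array(["OW", "HW1", "HW2"] * n_waters, dtype=object),
    )
    angle_counts: Dict[str, int] = {}
    for lab in unit_classes:
        key = "wrap" if lab == "tetrahedral" else (
            "bound" if lab == "planar" else lab)
        angle_counts[key] = angle_counts.get(key, 0) \
            + _CLASS_ANGLES_PER_UNIT[lab]
    total = sum(angle_counts.values())
    frame.truth = {
        "unit_classes": unit_classes,
        "unit_origins": origins,
        "n_angles": total,
        "angle_fractions": {k: v / total for k, v in angle_counts.items()},
    }
    return frame


@dataclass(frozen=True)
class ShellDynamicsSpec:
    """Telegraph-process shell occupancy dynamics around fixed beads."""

    n_residues: int = 20
    n_frames: int = 2000
    dt: float = 1.0            # ps per frame
    mean_dwell: float = 50.0   # ps in-shell dwell per residue
    occupancy: float = 1.0     # expected waters per shell
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_residues < 1 or self.n_frames < 1:
            raise ValueError("n_residues and n_frames must be >= 1")
        if self.occupancy < 0:
            raise ValueError("occupancy must be >= 0")


def gen_toy_trajectory(spec: ShellDynamicsSpec) -> Trajectory:
    """Pseudo-residue beads with telegraph-process shell waters.

    Beads sit 30 Å apart (shells never overlap).  Each residue owns a small
    pool of waters; every water alternates between an in-shell position
    (3 Å from the bead) and a far position, with exponential in-shell dwell
    of mean ``mean_dwell`` ps and an out-of-shell dwell chosen so the
    stationary shell occupancy equals ``spec.occupancy``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pool = 0 if spec.occupancy == 0 else max(1, int(np.ceil(
        2.0 * spec.occupancy)))
    occ_frac = spec.occupancy / n_pool if n_pool else 0.0
    mean_out = (spec.mean_dwell * (1.0 - occ_frac) / occ_frac
                if occ_frac > 0 else np.inf)

    bead_xyz = np.array([[30.0 * i, 0.0, 0.0]
                         for i in range(spec.n_residues)])
    n_waters = spec.n_residues * n_pool
    # topology: beads first, then (O,H,H) per water
    coords0 = [bead_xyz]
    resid = list(range(403, 403 + spec.n_residues))
    resname = ["ALA"] * spec.n_residues
    element = ["C"] * spec.n_residues
    atom_name = ["CA"] * spec.n_residues
    for w in range(n_waters):
        coords0.append(np.zeros((3, 3)))
        resid.extend([10000 + w] * 3)
        resname.extend(["HOH"] * 3)
        element.extend(["O", "H", "H"])
        atom_name.extend(["OW", "HW1", "HW2"])
    topo = Frame(np.concatenate(coords0, axis=0), np.array(resid),
                 np.array(resname, dtype=object),
                 np.array(element, dtype=object),
                 np.array(atom_name, dtype=object))

    times = np.arange(spec.n_frames) * spec.dt
    coords = np.empty((spec.n_frames, topo.n_atoms, 3))
    coords[:, :spec.n_residues] = bead_xyz[None, :, :]
    h_off = np.array([[OH_BOND, 0.0, 0.0],
                      [OH_BOND * np.cos(np.radians(HOH_ANGLE)),
                       OH_BOND * np.sin(np.radians(HOH_ANGLE)), 0.0]])
    t_end = spec.n_frames * spec.dt
    for w in range(n_waters):
        res_i = w // n_pool
        slot = w % n_pool
        in_pos = bead_xyz[res_i] + np.array([0.0, 3.0, 0.4 * slot])
        out_pos = bead_xyz[res_i] + np.array([0.0, 0.0, 60.0 + 3.0 * slot])
        occupied = np.zeros(spec.n_frames, dtype=bool)
        state = bool(rng.random() < occ_frac)
        t = 0.0
        while t < t_end:
            dur = rng.exponential(spec.mean_dwell if state else mean_out)
            if state:
                i0 = int(np.ceil(t / spec.dt - 1e-12))
                i1 = min(int(np.ceil((t + dur) / spec.dt - 1e-12)),
                         spec.n_frames)
                if i1 > i0:
                    occupied[i0:i1] = True
            t += dur
            state = not state
        a0 = spec.n_residues + 3 * w
        o_xyz = np.where(occupied[:, None], in_pos[None, :],
                         out_pos[None, :])
        coords[:, a0] = o_xyz
        coords[:, a0 + 1] = o_xyz + h_off[0]
        coords[:, a0 + 2] = o_xyz + h_off[1]
    return Trajectory(topo, coords, times,
                      meta={"truth": {"mean_dwell": spec.mean_dwell,
                                      "occupancy": spec.occupancy,
                                      "n_pool": n_pool}})


@dataclass(frozen=True)
class ShiftTableSpec:
    """Quadratic pressure-shift tables with sparse nonlinear residues."""

    n_residues: int = 100
    pressures: Tuple[float, ...] = (20., 500., 1000., 1500., 2000., 2500.)
    frac_nonlinear: float = 0.1
    coeff_scales: Tuple[float, float, float] = (1.0, 2e-4, 1e-7)
    noise_ppm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        if p.size < 3 or np.any(np.diff(p) <= 0):
            raise ValueError("pressures must be strictly increasing, >=3")
        if not 0.0 <= self.frac_nonlinear <= 1.0:
            raise ValueError("frac_nonlinear must be in [0, 1]")


@dataclass
class ShiftTable:
    """Generated shift records plus retained ground-truth coefficients."""

    data: pd.DataFrame   # residue, nucleus, pressure_bar, shift_ppm
    truth: pd.DataFrame  # residue, nucleus, a, b, c, nonlinear


#: reference chemical shifts per nucleus (ppm) around which offsets scatter
_NUCLEUS_CENTER = {"H": 8.0, "N": 118.0, "CO": 176.0}


def gen_shift_table(spec: ShiftTableSpec) -> ShiftTable:
    """δ(p) = a + b·p + c·p² per residue and nucleus, plus Gaussian noise.

    A fraction ``frac_nonlinear`` of residues (the same residues across all
    three nuclei, as for a local conformational transition) receive a
    nonzero curvature c of magnitude near ``coeff_scales[2]``; the rest are
    exactly linear (c = 0).
    """
    rng = np.random.default_rng(spec.seed)
    a_sc, b_sc, c_sc = spec.coeff_scales
    n_nl = int(round(spec.frac_nonlinear * spec.n_residues))
    nl_set = set(rng.choice(spec.n_residues, size=n_nl, replace=False)
                 .tolist())
    p = np.asarray(spec.pressures, dtype=float)
    recs, truths = [], []
    for res in range(spec.n_residues):
        for nuc in ("H", "N", "CO"):
            a = _NUCLEUS_CENTER[nuc] + rng.normal(0.0, a_sc)
            b = rng.normal(0.0, b_sc)
            if res in nl_set:
                c = rng.choice([-1.0, 1.0]) * c_sc * rng.uniform(0.8, 1.2)
            else:
                c = 0.0
            shift = a + b * p + c * p * p
            if spec.noise_ppm > 0:
                shift = shift + rng.normal(0.0, spec.noise_ppm, size=p.size)
            truths.append({"residue": res, "nucleus": nuc, "a": a, "b": b,
                           "c": c, "nonlinear": res in nl_set})
            for pi, si in zip(p, shift):
                recs.append({"residue": res, "nucleus": nuc,
                             "pressure_bar": pi, "shift_ppm": si})
    return ShiftTable(pd.DataFrame(recs), pd.DataFrame(truths))


@dataclass(frozen=True)
class RelaxSpec:
    """Multi-component inversion-recovery series settings."""

    components: Tuple[Tuple[float, float, str], ...] = (
        (2.21, 1.0, "wrap"), (7.95, 1.0, "bulk"), (1.69, 1.0, "bound"))
    delays: Tuple[float, ...] = tuple(np.geomspace(0.2, 50.0, 25))
    flip_deg: float = 90.0
    tr_ms: float = 1e6
    inv_eff: float = 1.0
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for T1, amp, _ in self.components:
            if T1 <= 0:
                raise ValueError("every T1 must be positive")
            if amp < 0:
                raise ValueError("amplitudes must be >= 0")
        if np.any(np.asarray(self.delays) < 0):
            raise ValueError("delays must be non-negative")


def gen_inversion_recovery(spec: RelaxSpec) -> RecoveryCurve:
    """Sum of steady-state suppression-sequence amplitudes over components.

    At each delay τ the signal is Σ_i A_i·sinθ·Mz⁻(τ; T1_i, f, TR), i.e.
    the recovery curve traced by sweeping the inversion delay of the
    bulk-suppression sequence.  Relative Gaussian noise is added on the
    full signal scale.  Ground truth is kept in ``curve.meta['truth']``.
    """
    rng = np.random.default_rng(spec.seed)
    delays = np.asarray(spec.delays, dtype=float)
    clean = np.zeros_like(delays)
    for T1, amp, _ in spec.components:
        for i, tau in enumerate(delays):
            st = oxy17.SuppressionSettings(
                tau_zc=float(tau), tau_d=0.0, flip_deg=spec.flip_deg,
                tr=spec.tr_ms, inv_eff=spec.inv_eff)
            clean[i] += amp * oxy17.steady_state_amplitude(T1, st)
    y = clean
    if spec.noise_frac > 0:
        sd = spec.noise_frac * np.max(np.abs(clean))
        y = clean + rng.normal(0.0, sd, size=clean.shape)
    return RecoveryCurve(delays, y, "ms", meta={"truth": {
        "components": list(spec.components), "flip_deg": spec.flip_deg,
        "tr_ms": spec.tr_ms, "inv_eff": spec.inv_eff,
        "noise_frac": spec.noise_frac}})


@dataclass(frozen=True)
class DeerSpec:
    """Two-Gaussian distance distribution rendered to a dipolar trace."""

    gauss_params: Tuple[Tuple[float, float, float], ...] = (
        (2.2, 0.15, 0.79), (4.0, 0.30, 0.21))
    t_max_us: float = 3.0
    n_t: int = 200
    mod_depth: float = 0.3
    bg_rate: float = 0.05    # per µs
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.array([g[2] for g in self.gauss_params])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be >= 0 and sum to 1")
        for mean, width, _ in self.gauss_params:
            if mean <= 0 or width <= 0:
                raise ValueError("means and widths must be positive")
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must be in [0, 1]")


def gen_deer_trace(spec: DeerSpec) -> deerpop.DipolarTrace:
    """Render the spec's P(r) through the dipolar kernel (truth retained)."""
    rng = np.random.default_rng(spec.seed)
    dist = deerpop.DistanceDistribution(list(spec.gauss_params))
    t = np.linspace(0.0, spec.t_max_us, spec.n_t)
    return deerpop.simulate_trace(dist, spec.mod_depth, spec.bg_rate, t,
                                  noise_sd=spec.noise_sd, rng=rng)


def gen_decay_series(tau: float, a0: float, a_inf: float,
                     times: Sequence[float], noise_sd: float = 0.0,
                     seed: int = 0, time_unit: str = "s") -> RecoveryCurve:
    """a_inf + (a0 − a_inf)·e^(−t/τ) plus Gaussian noise."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    y = a_inf + (a0 - a_inf) * np.exp(-t / tau)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return RecoveryCurve(t, y, time_unit,
                         meta={"truth": {"tau": tau, "a0": a0,
                                         "a_inf": a_inf,
                                         "noise_sd": noise_sd}})
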