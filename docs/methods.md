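# Methods

This note records the models implemented in `lovhydra`, the defaults and
why, what the synthetic-data generators do and do not emulate, and the
numerical choices a user should know before trusting the output.

## Water-structure classification (watershell)

**Order parameter.** The three-body angle (3BA) is the angle at a central
water oxygen subtended by two of its hydrogen-bonded neighbour oxygens.
Angles are enumerated over all unordered pairs among a central oxygen's
neighbours, capped at the 4 nearest neighbours (distance ties broken by
atom index) — the cap bounds cost and matches tetrahedral coordination.
Class windows: wrap/tetrahedral [100°, 120°], icosahedral [50°, 70°],
bound/planar [150°, 170°]; anything else is `unclassified`. Windows must
be disjoint, so every angle has exactly one class.

**Hydrogen-bond criterion.** O–O ≤ 3.5 Å AND at least one of the two
waters donates a hydrogen within 30° of its O→O axis. Both parameters are
configurable (`HBondCriterion`); the defaults are the standard geometric
criterion for rigid three-site water models. The relation is symmetric and
irreflexive by construction.

**Shells and fractions.** A water belongs to residue r's hydration shell
iff its oxygen lies within 4.5 Å (configurable) of any heavy atom of r; a
water may belong to several shells. Class fractions are *angle-level*
statistics (each 3BA is one vote), counted toward every residue whose
shell holds the central water. This treats the wrap fraction as a
population statement over local hydrogen-bond geometries; a molecule-level
majority classifier could be layered on top but is not the default.

**Residence times** are first-passage: for each (water, residue) pair only
the water's first continuous occupancy interval counts, from first entry
to first exit; re-entries are excluded and intervals still open at the
trajectory end are discarded. Durations are whole occupied frames × dt,
so the resolution is one frame. A visit already in progress at frame 0 is
kept — for the memoryless dwell model the residual lifetime has the same
mean, and for real data the bias is one-sided and documented here.

**Wrap-change flags.** Residue i is flagged when
wrap_ref(i) − wrap_t(i) > 0.5 × mean_i wrap_ref — i.e. the wrap loss
exceeds half the mean reference wrap fraction across residues.

## Trajectory segmentation (mdsegment)

**SASA** is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å, Bondi vdW radii, fallback radius 1.70 Å
with a warning for unknown elements). Doubling the point count changes a
single-sphere area by < 0.5%.

**Change points** use greedy binary segmentation with L2 (within-segment
squared error) cost and a per-breakpoint penalty. Default penalty is
2·σ̂²·log(n) with σ̂² = var(first differences)/2, which admits no splits on
a constant series; a numerical floor (∝ machine epsilon × accumulated
squares) guards against float rounding on exactly constant input. Split
ties resolve to the lowest index, so results are deterministic. An
exhaustive single-split least-squares oracle backs the tests.

**Clustering** is the Daura (GROMOS) greedy neighbour-count algorithm on
the pairwise heavy-atom RMSD matrix (centroid removal plus Kabsch
superposition by default; RMSD reported in nm). Cutoff default 0.2 nm.
Ties in neighbour count resolve to the lowest frame index, making the
partition invariant to input order up to relabelling.

**Residue displacement** overlays the two structures by translating their
heavy-atom centers of gravity together — translation only, because the
quantity of interest is displacement *relative to the center of gravity*
of the reference; a Kabsch rotational fit is available as an option for
users who want internal-motion-only displacements.

## High-pressure shift analysis (hpnmr)

Each (residue, nucleus) series is fitted by ordinary least squares to
δ(p) = a + b·p + c·p² (p in bar, δ in ppm); b tracks partial-molar-volume
change, c compressibility change. At least three distinct pressures are
required; with exactly three the fit is exact and standard errors are
undefined (flagged). Coefficient covariance comes from the residuals.

Per-nucleus flags mark |c| > mean + z·SD with z = 1.645 (top ~10% of a
normal population); sample SD, computed within one nucleus so ppm scales
never mix. The composite score z-scores |c| per nucleus over residues and
sums zH(i) + zN(i) + zCO(i−1) — the carbonyl belongs to the peptide plane
of the preceding residue, which is how the HNCO experiment correlates the
three nuclei. A robust median/MAD normalisation is available by option.
Residues missing a nucleus (prolines, unassigned, chain start for the
i−1 carbonyl) contribute 0 for that term and clear a completeness flag;
threshold flags are reported both per nucleus and on the composite, since
either convention is defensible.

Unit behaviour is exact: rescaling bar→kbar multiplies b by 10³ and c by
10⁶ and leaves the composite invariant; adding any affine-in-p
perturbation changes a and b but not c.

## ¹⁷O relaxometry (oxy17)

The bulk-suppression sequence is modelled as the periodic cycle
(inversion with efficiency f, delay τ_zc, read pulse θ, delay τ_D,
recovery to TR). The zero crossing of a component is τ = T1·ln(2f), and
the steady-state read amplitude sinθ·Mz⁻(τ_zc) follows from the one-cycle
recursion in closed form; it reduces to the single-shot formula
sinθ·(1 − 2f·e^(−τ_zc/T1)) as TR/T1 → ∞ and is cross-checked against an
iterated-sequence oracle. τ_D does not enter the amplitude model (it
matters for spectra, which are out of scope). The spectral dimension is
abstracted away entirely: populations enter as amplitudes with attached
chemical-shift-range labels (bound −8..−0.5 ppm, bulk −0.4..0.4 ppm, wrap
0.5..8 ppm relative to bulk water); no lineshape model. Inversion
efficiency defaults to 1.0 and is configurable; the operating τ_zc is a
free setting.

**T1 decomposition** fits Σᵢ Aᵢ(1 − 2f·e^(−τ/T1ᵢ)) by separable nonlinear
least squares (amplitudes solved linearly at each T1 trial), with
multi-start initialisation over all k! orderings of k log-spaced T1 seeds.
Components are labelled by sorting T1 (bound < wrap < bulk for k = 3).
Standard errors come from the full jacobian; the fit is declared
*unidentifiable* when the ±2σ intervals of adjacent sorted T1s overlap or
the errors are not finite.

A caution established while validating this module: resolving T1
components whose ratio is ≲ 1.5 from a single unresolved recovery curve
is ill-conditioned. With the hydration trio 1.69/2.21/7.95 ms at equal
amplitudes, even 1% relative noise makes the two short components
unrecoverable (errors of tens of percent regardless of starting point),
and well-separated trios (ratio 5) still show ~10–20% worst-case T1 error
at that noise. Noise-free curves round-trip to < 0.1%. In the experiment
this package models, close T1s are resolved *spectrally* — per
chemical-shift region — not from one curve; users should do the same and
treat the `identifiable` flag seriously.

**Population kinetics** fit each labelled amplitude series with the shared
single-exponential module and report both τ and the half-time τ·ln 2,
since recovery times are quoted in both conventions. A series with no
resolvable amplitude change is flagged `no_recovery` rather than fitted.

## DEER analysis (deerpop)

Forward model: V(t) = [1 − λ + λ·(K·P)(t)]·e^(−k·t), normalised to
V(0) = 1, with a 3-D homogeneous (pure exponential) background and the
orientation-averaged kernel K(t,r) = ∫₀¹ cos[(1−3u²)·ω_dd(r)·t] du
evaluated by 201-point Gauss–Legendre quadrature (max deviation < 10⁻⁶
against a 10⁴-point trapezoid oracle). The dipolar constant
ν_dd·r³ = (μ₀/4π)·g²μ_B²/h ≈ 52.04 MHz·nm³ is computed from physical
constants at import.

P(r) is the parametric two-Gaussian model on r ∈ [1.5, 8] nm — no
Tikhonov or model-free inversion, since the published analysis this
mirrors is explicitly parametric. Fitting is separable: the three linear
amplitudes (unmodulated offset and the two modulated components) are
solved by non-negative least squares inside a bounded optimisation over
(two means, two widths, background rate), with multi-start over
compact/extended mean pairs. λ and the simplex-constrained weights are
read off the linear amplitudes. A fitted mean at the grid boundary is
flagged. The extended state is reported two ways — the second Gaussian's
mixture weight, and the P(r) mass in the 3–5 nm window (exact Gaussian
CDFs, normalised to the grid range) — because published percentages do
not always say which convention they use; for well-separated narrow
components the two agree to < 10⁻³.

## Photocycle kinetics (kinetics)

Single-exponential only: A(t) = a_∞ + (a₀ − a_∞)e^(−t/τ), initial τ from
a log-linearised tail, τ bounded positive. The model is equivariant under
amplitude affine maps and exactly covariant under time rescaling. Data
without a clear monotone trend (|corr(t, A)| < 0.3) are fitted anyway but
flagged. Time-constant ratios carry first-order propagated errors
(validated against a Monte-Carlo oracle) and are additionally rounded to
one decimal for headline reporting. Stretched and bi-exponential models
are deliberately out of scope.

## Synthetic data (synthdata)

Every generator is a pure function of its spec including the seed (one
`numpy` Generator passed down; no global state), and retains its ground
truth, so each analysis stage is tested by parameter recovery.

* **Water geometry**: isolated clusters on a 16 Å grid, one central water
  per cluster whose hydrogen-bonded neighbours realise the class angle
  exactly before jitter — 4 tetrahedral neighbours (6 angles of 109.47°),
  a 13-water icosahedral shell in which only one triangular face donates
  to the center (3 angles of 63.43°; the central water's own hydrogens
  are oriented by a small search to stay ≥ ~35° from every vertex so no
  spurious bond forms), or 2 planar neighbours (one configurable angle in
  [150°, 170°]). Waters are rigid 3-site (O–H 0.9572 Å, H–O–H 104.52°)
  with donor hydrogens exactly on the O→O axis, so the default
  hydrogen-bond criterion fires by construction. Angular jitter is applied
  as a random-axis rotation with half-normal magnitude; it is intended
  small (a few degrees) — beyond ~7° the icosahedral construction can
  start leaking spurious bonds.
* **Shell dynamics**: fixed beads 30 Å apart; each water alternates
  between an in-shell and a far position as a continuous-time telegraph
  process with exponential dwells (in-shell mean as specified; out-of-
  shell mean set so the stationary occupancy matches the spec), sampled
  at the frame times. Exponential dwells are the memoryless baseline
  whose first-passage mean is known analytically; the sampled-grid
  measurement carries an O(dt) discretisation bias, which is why recovery
  is asserted at 10%.
* **Shift tables**: the same sparse residue subset is nonlinear across
  all three nuclei (as for a local conformational transition), curvature
  magnitude ~c_scale with ±20% spread and random sign; linear residues
  have exactly c = 0. Defaults: 6 pressures from 20 to 2500 bar, scales
  (1 ppm, 2×10⁻⁴ ppm/bar, 10⁻⁷ ppm/bar²).
* **Inversion recovery**: sums the closed-form suppression-sequence
  amplitude per component over the delay grid; default components are the
  three resolved hydration T1s at equal amplitude. Noise is Gaussian with
  SD = noise_frac × max|signal|.
* **DEER**: renders P(r) through the same kernel used for fitting, with
  modulation depth, exponential background, and V(0) = 1 before noise.
* **Decay series**: a_∞ + (a₀ − a_∞)e^(−t/τ) plus noise.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: no force fields or water dynamics (geometry
frames are static and clusters are isolated, so there is no exchange,
no density effects, no protein surface chemistry); telegraph waters have
no spatial diffusion and shells never overlap; shift noise is i.i.d.
Gaussian with no peak-picking error or exchange broadening; recovery
curves have no lineshape, no MAS sidebands, no quadrupolar relaxation
theory; DEER traces have no orientation selection, multi-spin effects or
pulse artifacts. Round-trip success demonstrates the estimators are
correct and calibrated under their own model assumptions, not that those
assumptions hold for any particular spectrometer or trajectory.

## Pipeline and I/O

Units are fixed per domain and embedded in column headers: Å and ps for
the MD arm, ms for relaxometry, s for photocycle, min for population
kinetics, µs for DEER; pressures in bar; residue numbers verbatim from
the topology (the AsLOV2 403–546 convention in the demo stages). The
configuration is a flat `key = value` file with a closed key set — any
unknown key is rejected before computation — and CLI flags override file
values. Reports are JSON with sorted keys and no timestamps, so a rerun
with the same config and seed reproduces the stage bodies byte for byte.
PDB topologies go through biotite; the per-frame XYZ-block trajectory
format is native to this package, and any iterator of frames satisfies
the trajectory contract, which is the adapter point for compressed
formats. The demo pipeline runs every stage on synthetic inputs sized to
finish in seconds (400-water geometry frames, 20 × 1200-frame telegraph
trajectories, 80-residue shift tables, 200-point DEER traces).

## Known limitations

* Angle-level class fractions weight a water by its number of
  hydrogen-bonded neighbour pairs; molecule-level statistics would weight
  each water once. Both conventions exist in the literature and they can
  differ when coordination numbers differ across classes.
* The hydrogen-bond and shell-cutoff defaults are declared conventions,
  not fitted to any dataset; conclusions sensitive to them should be
  re-run across a cutoff range.
* Multi-component T1 decomposition is ill-conditioned for close T1s (see
  above); the identifiability flag is a necessary, not sufficient, check.
* The DEER background is purely exponential (3-D homogeneous); excluded-
  volume or fractal backgrounds are not modelled.
* Binary segmentation is greedy; for series with many close change points
  an exact dynamic-programming search would be preferable.
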