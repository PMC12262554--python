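# lovhydra

Analysis pipeline for studying **hydraulic activation of LOV-domain
photoreceptors** — the hypothesis that blue-light (or pressure) activation of
AsLOV2, the second light–oxygen–voltage domain of *Avena sativa* phototropin
1, is accompanied by concerted eviction of low-entropy, tetrahedrally
structured "wrap" hydration water. The package re-implements, as a tested
reusable library, the analysis stages such a study needs:

* **watershell** — classify hydration-water structure by the three-body
  angle (3BA): the angle at a central water oxygen subtended by two
  hydrogen-bonded neighbour oxygens. Wrap water is tetrahedral
  (3BA ∈ [100°, 120°], ideal 109.5°), icosahedral bulk-like water sits in
  [50°, 70°] (adjacent-vertex angle arccos(1/√5) = 63.4°), and bound water
  is near-planar ([150°, 170°]). Waters are assigned to per-residue shells
  by a heavy-atom cutoff, and residence times are computed in first-passage
  mode (first continuous visit only, re-entries excluded).
* **mdsegment** — Shrake–Rupley solvent-accessible surface area, penalised
  binary-segmentation change-point detection on SASA series, Daura/GROMOS
  greedy RMSD clustering, and residue-wise displacement after
  center-of-gravity overlay.
* **hpnmr** — per-residue quadratic pressure–shift fits
  δᵢ(p) = aᵢ + bᵢp + cᵢp² across amide ¹H/¹⁵N and carbonyl ¹³C′, per-nucleus
  |c| thresholding at mean + 1.645 SD, and a composite per-peptide-group
  nonlinearity score zH(i) + zN(i) + zCO(i−1).
* **oxy17** — the bulk-suppressed ¹⁷O inversion-recovery experiment:
  zero crossing τ_zc = T1·ln(2f), closed-form steady-state amplitudes under
  the periodic suppression sequence, multi-component T1 decomposition, and
  water-population recovery kinetics.
* **deerpop** — two-Gaussian distance-distribution fitting of 4-pulse DEER
  dipolar traces through the orientation-averaged kernel
  K(t,r) = ∫₀¹ cos[(1−3u²)·ω_dd(r)·t] du with ν_dd·r³ ≈ 52.04 MHz·nm³, and
  extended-state fractions (P(r) mass in 3–5 nm).
* **kinetics** — shared single-exponential recovery fitting
  (A(t) = a_∞ + (a₀−a_∞)e^(−t/τ)) for photocycle and population series,
  with time-constant ratios and propagated errors.
* **synthdata** — generators for every input the stages need, each a pure
  function of its spec and seed with retained ground truth, so the whole
  pipeline is testable by parameter recovery without any external data.

## Worked example

```bash
python examples/06_deer_populations.py
```

```
dipolar frequency at 2.2 nm : 4.89 MHz
compact : mean 2.19 nm  width 0.15 nm  weight 0.788
extended: mean 3.99 nm  width 0.33 nm  weight 0.212
extended weight     : 21.2% (truth 21%)
mass in 3-5 nm      : 21.2%
modulation depth    : 0.302   background 0.049 /us
```

A dipolar trace was simulated from a distance distribution with a compact
conformer at 2.2 nm (spin labels on the A′α and Jα helices in the dark
state) and a 21%-weighted extended conformer at 4.0 nm, with 0.5% added
noise. The separable two-Gaussian fit recovers the component means, the
extended-state population (both as mixture weight and as P(r) mass in the
3–5 nm window), the modulation depth and the background rate. The other
scripts in `examples/` exercise water-structure classification, residence
times, trajectory segmentation, pressure-shift scoring, ¹⁷O population
analysis and photocycle kinetics the same way, each printing recovered
values next to generator truth.

The end-to-end pipeline with a combined report:

```bash
lovhydra run --seed 1 --out-dir out/
# or stage by stage: lovhydra deer --seed 1 --out-dir out/
```

## Scope

The package analyses trajectories, shift tables, recovery curves and
dipolar traces; it does not run molecular dynamics, process raw NMR/EPR
spectra, or model photochemistry. See `docs/methods.md` for the models,
defaults, numerical choices and known limitations.
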