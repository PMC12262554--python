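"""Quadratic pressure-shift fitting, thresholds and composite scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lovhydra import hpnmr, synthdata as sd


def _table(records):
    return pd.DataFrame(records,
                        columns=["residue", "nucleus", "pressure_bar",
                                 "shift_ppm"])


def _series_from_coeffs(coeffs, pressures):
    recs = []
    for (res, nuc), (a, b, c) in coeffs.items():
        for p in pressures:
            recs.append((res, nuc, p, a + b * p + c * p * p))
    return _table(recs)


PRESSURES = [20.0, 500.0, 1000.0, 1500.0, 2000.0, 2500.0]


class TestQuadraticFit:
    def test_noise_free_quadratic_is_exact(self):
        coeffs = {(1, "H"): (8.1, 2e-4, 3e-7), (1, "N"): (118.0, -1e-4, 0.0)}
        fits = hpnmr.fit_pressure_quadratic(
            _series_from_coeffs(coeffs, PRESSURES))
        row = fits.set_index(["residue", "nucleus"])
        assert row.loc[(1, "H"), "c"] == pytest.approx(3e-7, rel=1e-9)
        assert abs(row.loc[(1, "N"), "c"]) < 1e-12

    def test_linear_truth_gives_zero_curvature(self):
        coeffs = {(i, "CO"): (176.0 + i, 5e-4, 0.0) for i in range(5)}
        fits = hpnmr.fit_pressure_quadratic(
            _series_from_coeffs(coeffs, PRESSURES))
        assert np.all(np.abs(fits["c"]) < 1e-12)

    def test_matches_normal_equations_oracle(self):
        table = sd.gen_shift_table(sd.ShiftTableSpec(
            n_residues=15, noise_ppm=0.005, seed=3))
        fits = hpnmr.fit_pressure_quadratic(table.data).set_index(
            ["residue", "nucleus"])
        for (res, nuc), grp in table.data.groupby(["residue", "nucleus"]):
            p = grp["pressure_bar"].to_numpy()
            d = grp["shift_ppm"].to_numpy()
            X = np.column_stack([np.ones_like(p), p, p * p])
            beta = np.linalg.solve(X.T @ X, X.T @ d)
            got = fits.loc[(res, nuc), ["a", "b", "c"]].to_numpy(float)
            assert np.allclose(got, beta, rtol=0, atol=1e-10)

    def test_three_points_exact_but_errors_undefined(self):
        coeffs = {(1, "H"): (8.0, 1e-4, 2e-7)}
        fits = hpnmr.fit_pressure_quadratic(
            _series_from_coeffs(coeffs, [100.0, 1000.0, 2000.0]))
        assert bool(fits.loc[0, "errors_undefined"])
        assert np.isnan(fits.loc[0, "c_stderr"])
        assert fits.loc[0, "c"] == pytest.approx(2e-7, rel=1e-9)

    def test_duplicate_pressures_rejected(self):
        recs = [(1, "H", 100.0, 8.0), (1, "H", 100.0, 8.1),
                (1, "H", 100.0, 8.2), (1, "H", 200.0, 8.3)]
        with pytest.raises(ValueError, match="rank deficient"):
            hpnmr.fit_pressure_quadratic(_table(recs))

    def test_missing_column_named_in_error(self):
        with pytest.raises(ValueError, match="pressure_bar"):
            hpnmr.fit_pressure_quadratic(
                pd.DataFrame({"residue": [], "nucleus": [],
                              "shift_ppm": []}))


class TestNucleusThreshold:
    def test_equal_magnitudes_never_flagged(self):
        fits = pd.DataFrame({"residue": range(10), "nucleus": ["H"] * 10,
                             "c": [2e-7] * 10})
        assert not hpnmr.nucleus_threshold(fits)["flagged"].any()

    def test_single_outlier_among_zeros_is_the_only_flag(self):
        fits = pd.DataFrame({"residue": range(51), "nucleus": ["N"] * 51,
                             "c": [0.0] * 50 + [5e-6]})
        out = hpnmr.nucleus_threshold(fits)
        assert out["flagged"].sum() == 1
        assert out.loc[out["flagged"], "residue"].item() == 50

    def test_half_normal_tail_fraction_matches_closed_form(self):
        # |c| ~ half-normal; flagged fraction ~ P(|X| > mu_hn + z sd_hn)
        rng = np.random.default_rng(12)
        n = 100_000
        fits = pd.DataFrame({"residue": range(n), "nucleus": ["H"] * n,
                             "c": rng.normal(0.0, 1.0, n)})
        frac = hpnmr.nucleus_threshold(fits)["flagged"].mean()
        mu_hn = np.sqrt(2.0 / np.pi)
        sd_hn = np.sqrt(1.0 - 2.0 / np.pi)
        expect = 2.0 * stats.norm.sf(mu_hn + 1.645 * sd_hn)
        assert frac == pytest.approx(expect, abs=1.5e-3)


class TestCompositeScore:
    def test_all_zero_curvatures_give_zero_scores(self):
        fits = pd.DataFrame(
            [{"residue": r, "nucleus": n, "c": 0.0}
             for r in range(4) for n in ("H", "N", "CO")])
        scores = hpnmr.composite_score(fits)
        assert np.allclose(scores["composite"], 0.0)

    def test_three_residue_hand_table(self):
        # |c| per nucleus over residues 1..3; the CO term comes from i-1
        cvals = {("H"): [1.0, 2.0, 6.0], ("N"): [3.0, 3.0, 9.0],
                 ("CO"): [2.0, 4.0, 12.0]}
        fits = pd.DataFrame(
            [{"residue": r + 1, "nucleus": n, "c": cvals[n][r]}
             for r in range(3) for n in ("H", "N", "CO")])
        scores = hpnmr.composite_score(fits)

        def z(vals, x):
            vals = np.asarray(vals, float)
            return (x - vals.mean()) / vals.std(ddof=1)

        # residue 2: zH(2) + zN(2) + zCO(1)
        expect = (z(cvals["H"], 2.0) + z(cvals["N"], 3.0)
                  + z(cvals["CO"], 2.0))
        assert scores.loc[2, "composite"] == pytest.approx(expect)
        assert bool(scores.loc[2, "complete"])
        # residue 1 lacks the i-1 carbonyl: contributes 0, flagged
        expect1 = z(cvals["H"], 1.0) + z(cvals["N"], 3.0)
        assert scores.loc[1, "composite"] == pytest.approx(expect1)
        assert not bool(scores.loc[1, "complete"])

    def test_row_order_permutation_invariant(self, rng):
        fits = pd.DataFrame(
            [{"residue": r, "nucleus": n, "c": rng.normal()}
             for r in range(8) for n in ("H", "N", "CO")])
        s0 = hpnmr.composite_score(fits)
        s1 = hpnmr.composite_score(
            fits.sample(frac=1.0, random_state=5).reset_index(drop=True))
        pd.testing.assert_frame_equal(s0, s1)


class TestTopResidues:
    def test_uniform_scores_empty(self):
        scores = pd.DataFrame({"composite": [1.0] * 10, "complete": True},
                              index=range(10))
        assert len(hpnmr.top_residues(scores)) == 0

    def test_infinite_z_empty(self, rng):
        scores = pd.DataFrame({"composite": rng.normal(size=30)},
                              index=range(30))
        assert len(hpnmr.top_residues(scores, z=np.inf)) == 0

    def test_planted_nonlinear_residues_recovered_exactly(self):
        table = sd.gen_shift_table(sd.ShiftTableSpec(
            n_residues=50, frac_nonlinear=0.1, noise_ppm=0.0, seed=6))
        fits = hpnmr.fit_pressure_quadratic(table.data)
        top = hpnmr.top_residues(hpnmr.composite_score(fits))
        planted = set(table.truth.loc[table.truth["nonlinear"],
                                      "residue"])
        assert set(top.index) == planted


class TestInvariances:
    def test_affine_in_pressure_perturbation_leaves_c_unchanged(self):
        table = sd.gen_shift_table(sd.ShiftTableSpec(
            n_residues=6, frac_nonlinear=0.5, noise_ppm=0.003, seed=9))
        fits0 = hpnmr.fit_pressure_quadratic(table.data)
        perturbed = table.data.copy()
        perturbed["shift_ppm"] += 0.7 + 3.1e-4 * perturbed["pressure_bar"]
        fits1 = hpnmr.fit_pressure_quadratic(perturbed)
        assert np.all(np.abs(fits1["c"] - fits0["c"]) < 1e-12)

    def test_pressure_unit_rescaling(self):
        # bar -> kbar rescales b by 1e3 and c by 1e6; composite invariant
        table = sd.gen_shift_table(sd.ShiftTableSpec(
            n_residues=10, frac_nonlinear=0.3, noise_ppm=0.001, seed=7))
        fits_bar = hpnmr.fit_pressure_quadratic(table.data)
        kbar = table.data.copy()
        kbar["pressure_bar"] /= 1e3
        fits_kbar = hpnmr.fit_pressure_quadratic(kbar)
        assert np.allclose(fits_kbar["b"], fits_bar["b"] * 1e3, rtol=1e-9)
        assert np.allclose(fits_kbar["c"], fits_bar["c"] * 1e6, rtol=1e-9)
        s_bar = hpnmr.composite_score(fits_bar)["composite"]
        s_kbar = hpnmr.composite_score(fits_kbar)["composite"]
        assert np.allclose(s_bar, s_kbar, atol=1e-9)


class TestPlantedSignalRecovery:
    def test_sensitivity_and_false_flag_rate_over_seeds(self):
        """Composite scoring finds >=90% of planted nonlinear residues and
        flags <=5% of linear residues, at curvature SNR >= 5."""
        noise = 0.002
        spec0 = sd.ShiftTableSpec(n_residues=100, frac_nonlinear=0.1,
                                  noise_ppm=noise, seed=0)
        # curvature signal-to-noise from the OLS design
        p = np.asarray(spec0.pressures)
        X = np.column_stack([np.ones_like(p), p, p * p])
        se_c = noise * np.sqrt(np.linalg.inv(X.T @ X)[2, 2])
        assert spec0.coeff_scales[2] * 0.8 / se_c >= 5.0

        sens, false_rate = [], []
        for seed in range(100):
            table = sd.gen_shift_table(sd.ShiftTableSpec(
                n_residues=100, frac_nonlinear=0.1, noise_ppm=noise,
                seed=seed))
            fits = hpnmr.fit_pressure_quadratic(table.data)
            top = hpnmr.top_residues(hpnmr.composite_score(fits))
            planted = set(table.truth.loc[table.truth["nonlinear"],
                                          "residue"])
            found = set(top.index)
            sens.append(len(found & planted) / len(planted))
            false_rate.append(len(found - planted)
                              / (100 - len(planted)))
        assert np.mean(sens) >= 0.9
        assert np.mean(false_rate) <= 0.05
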