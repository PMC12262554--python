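"""High-pressure NMR chemical-shift nonlinearity analysis.

Pressure-dependent backbone chemical shifts δ_i(p) of each residue and
nucleus (amide ¹H and ¹⁵N, carbonyl ¹³C′) are fitted to the empirical
quadratic

    δ_i(p) = a_i + b_i·p + c_i·p²   (p in bar, δ in ppm),

where b_i tracks partial-molar-volume changes and the curvature c_i tracks
compressibility changes — residues with significant |c_i| report population
shifts toward pressure-favoured conformations absent at ambient pressure.
Per-nucleus thresholding flags |c| beyond mean + z·SD (z = 1.645, the top
~10% of a normal population), and a composite per-peptide-group score sums
z-score-normalised |c| across nuclei, aligning the carbonyl of residue i−1
with amide i (the three nuclei of one peptide plane, as correlated by the
HNCO experiment).
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "fit_pressure_quadratic",
    "nucleus_threshold",
    "composite_score",
    "top_residues",
    "NUCLEI",
]

NUCLEI = ("H", "N", "CO")


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    required = {"residue", "nucleus", "pressure_bar", "shift_ppm"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"shift table missing columns: {sorted(missing)}")
    if (series["pressure_bar"] <= 0).any():
        raise ValueError("pressures must be positive")
    return series


def fit_pressure_quadratic(series: pd.DataFrame) -> pd.DataFrame:
    """Ordinary least squares of δ on (1, p, p²) per (residue, nucleus).

    Requires at least three distinct pressures per fitted group; with
    exactly three points the fit is exact and standard errors are undefined
    (returned NaN with ``errors_undefined=True``).  Duplicate-pressure-only
    groups are rank deficient and raise.

    Returns a DataFrame with columns residue, nucleus, a, b, c, their
    standard errors, residual_sd, n_points, errors_undefined.
    """
    series = _validate_series(series)
    rows = []
    for (res, nuc), grp in series.groupby(["residue", "nucleus"], sort=True):
        p = grp["pressure_bar"].to_numpy(dtype=float)
        d = grp["shift_ppm"].to_numpy(dtype=float)
        if np.unique(p).size < 3:
            raise ValueError(
                f"residue {res} nucleus {nuc}: need >=3 distinct pressures "
                f"(got {np.unique(p).size}) — design is rank deficient")
        X = np.column_stack([np.ones_like(p), p, p * p])
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        resid = d - X @ coef
        dof = p.size - 3
        if dof > 0:
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            se = np.sqrt(np.diag(cov))
            resid_sd = np.sqrt(s2)
            undef = False
        else:
            se = np.full(3, np.nan)
            resid_sd = np.nan
            undef = True
        rows.append({
            "residue": res, "nucleus": nuc,
            "a": coef[0], "b": coef[1], "c": coef[2],
            "a_stderr": se[0], "b_stderr": se[1], "c_stderr": se[2],
            "residual_sd": resid_sd, "n_points": int(p.size),
            "errors_undefined": undef,
        })
    return pd.DataFrame(rows)


def nucleus_threshold(fits: pd.DataFrame, z: float = 1.645) -> pd.DataFrame:
    """Flag per-(residue, nucleus) curvatures beyond mean + z·SD of |c|.

    The mean and (sample) standard deviation are taken over residues within
    each nucleus separately, so ppm scales of different nuclei never mix.
    """
    out = fits[["residue", "nucleus", "c"]].copy()
    out["abs_c"] = out["c"].abs()
    flags = np.zeros(len(out), dtype=bool)
    cutoffs = np.full(len(out), np.nan)
    for nuc, idx in out.groupby("nucleus").groups.items():
        vals = out.loc[idx, "abs_c"]
        sd = vals.std(ddof=1)
        cut = vals.mean() + z * (sd if np.isfinite(sd) else 0.0)
        cutoffs[out.index.get_indexer(idx)] = cut
        flags[out.index.get_indexer(idx)] = vals > cut
    out["cutoff"] = cutoffs
    out["flagged"] = flags
    return out


def _normalize(vals: pd.Series, method: Literal["zscore", "robust"]) -> pd.Series:
    if method == "zscore":
        sd = vals.std(ddof=1)
        return (vals - vals.mean()) / sd if sd > 0 else vals * 0.0
    if method == "robust":
        med = vals.median()
        mad = (vals - med).abs().median() * 1.4826
        return (vals - med) / mad if mad > 0 else vals * 0.0
    raise ValueError(f"unknown normalization {method!r}")


def composite_score(fits: pd.DataFrame,
                    method: Literal["zscore", "robust"] = "zscore"
                    ) -> pd.DataFrame:
    """Combined per-peptide-group nonlinearity score.

    |c| is normalised per nucleus over residues (z-score by default, robust
    median/MAD optional); the composite of residue i sums the normalised
    amide ¹H and ¹⁵N values of i and the carbonyl ¹³C′ value of residue
    i−1.  A missing nucleus contributes 0 and clears ``complete``.
    """
    if fits.empty:
        raise ValueError("no fits provided")
    pivot = fits.pivot_table(index="residue", columns="nucleus", values="c",
                             aggfunc="first").abs()
    for nuc in pivot.columns:
        if pivot[nuc].notna().sum() < 2:
            raise ValueError(
                f"nucleus {nuc}: need >=2 residues to define normalization")
    norm = pivot.apply(lambda col: _normalize(col.dropna(), method)
                       .reindex(col.index))
    residues = norm.index
    rows = []
    for res in residues:
        parts = {}
        parts["H"] = norm.at[res, "H"] if "H" in norm.columns else np.nan
        parts["N"] = norm.at[res, "N"] if "N" in norm.columns else np.nan
        prev = res - 1
        parts["CO_prev"] = (norm.at[prev, "CO"]
                            if "CO" in norm.columns and prev in norm.index
                            else np.nan)
        complete = all(np.isfinite(v) for v in parts.values())
        score = float(np.nansum(list(parts.values())))
        rows.append({"residue": res, "z_H": parts["H"], "z_N": parts["N"],
                     "z_CO_prev": parts["CO_prev"], "composite": score,
                     "complete": complete})
    return pd.DataFrame(rows).set_index("residue")


def top_residues(scores: pd.DataFrame, z: float = 1.645) -> pd.DataFrame:
    """Residues whose composite exceeds mean + z·SD, sorted descending."""
    comp = scores["composite"]
    sd = comp.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return scores.iloc[0:0]
    cut = comp.mean() + z * sd
    sel = scores[comp > cut].copy()
    return sel.sort_values("composite", ascending=False)
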