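"""High-pressure NMR nonlinearity scoring.

Generates per-residue chemical-shift tables delta(p) = a + b p + c p^2 for
amide 1H/15N and carbonyl 13C' with 10% of residues carrying a genuine
curvature c (a pressure-favoured conformational change), fits the
quadratic per residue and nucleus, and flags the nonlinear residues via
the composite score (z-scored |c| summed over the peptide-group nuclei,
threshold mean + 1.645 SD).
"""

from lovhydra import hpnmr, synthdata as sd

spec = sd.ShiftTableSpec(n_residues=80, frac_nonlinear=0.1,
                         noise_ppm=0.002, seed=20)
table = sd.gen_shift_table(spec)
fits = hpnmr.fit_pressure_quadratic(table.data)
scores = hpnmr.composite_score(fits)
top = hpnmr.top_residues(scores)

planted = sorted(table.truth.loc[table.truth["nonlinear"], "residue"]
                 .unique())
print(f"planted nonlinear residues : {planted}")
print(f"flagged by composite score : {sorted(top.index)}")
print()
print("Flagged residues have |c| (compressibility-change curvature) far")
print("above the per-nucleus mean -- the residues undergoing a pressure-")
print("induced shift toward an excited conformational state.")
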