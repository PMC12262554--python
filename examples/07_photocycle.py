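"""Photocycle dark-state recovery kinetics and variant comparison.

Fits single-exponential recovery A(t) = a_inf + (a0 - a_inf) e^(-t/tau)
to noise-free absorbance decays generated with the printed time constants
of the wild type (67.97 s) and the slow-cycling N414Q variant (172.80 s),
then forms the slow-down factor with propagated uncertainty.
"""

import numpy as np

from lovhydra import kinetics, synthdata as sd

times = np.linspace(0.0, 600.0, 120)
wt = sd.gen_decay_series(67.97, 1.0, 0.0, times)
mut = sd.gen_decay_series(172.80, 1.0, 0.0, times)
fit_wt = kinetics.fit_exponential_recovery(wt)
fit_mut = kinetics.fit_exponential_recovery(mut)
ratio = kinetics.time_constant_ratio(fit_mut, fit_wt)

print(f"tau (wild type) : {fit_wt.tau:.2f} s")
print(f"tau (N414Q)     : {fit_mut.tau:.2f} s")
print(f"slow-down factor: {ratio['ratio']:.3f} "
      f"-> {ratio['ratio_1dp']} at one decimal")
print()
print("The mutant's 2.5-fold slower return to the dark state reflects a")
print("stabilised lit conformation.")
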