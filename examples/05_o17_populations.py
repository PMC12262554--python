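"""17O relaxometry: bulk suppression, T1 decomposition, recovery kinetics.

The bulk-suppression sequence nulls the long-T1 bulk-water signal at its
inversion-recovery zero crossing tau_zc = T1 ln(2f).  A noise-free
three-component curve built from the spectrally resolved hydration-water
T1 values (wrap 2.21 ms, bulk 7.95 ms, bound 1.69 ms) is decomposed, and
noise-free population time series with a 20 min constant are refitted.
"""

import numpy as np

from lovhydra import oxy17, synthdata as sd

print(f"zero crossing for bulk T1 7.05 ms : "
      f"{oxy17.zero_crossing(7.05):.3f} ms")
s60 = oxy17.SuppressionSettings(tau_zc=2.70, flip_deg=60.0, tr=15.0)
s150 = oxy17.SuppressionSettings(tau_zc=2.70, flip_deg=150.0, tr=15.0)
for name, s in (("theta=60 ", s60), ("theta=150", s150)):
    fast = oxy17.steady_state_amplitude(2.21, s)
    slow = oxy17.steady_state_amplitude(7.95, s)
    print(f"{name}: wrap/bulk amplitude ratio "
          f"{abs(fast) / abs(slow):8.2f}  (higher = better suppression)")

curve = sd.gen_inversion_recovery(sd.RelaxSpec())
model = oxy17.fit_T1_components(curve, k=3)
print("\nthree-component decomposition of the noise-free curve:")
for label, T1, amp, _ in model.components:
    print(f"  {label:5s}  T1 = {T1:6.2f} ms  amplitude = {amp:.3f}")

times = np.linspace(0.0, 100.0, 40)
series = {"wrap": sd.gen_decay_series(20.0, 0.2, 1.0, times,
                                      time_unit="min"),
          "bulk": sd.gen_decay_series(20.0, 1.8, 1.0, times,
                                      time_unit="min"),
          "bound": sd.gen_decay_series(20.0, 0.8, 1.0, times,
                                       time_unit="min")}
kin = oxy17.population_kinetics_fit(series)
print("\npopulation recovery after illumination off:")
for lab in ("wrap", "bulk", "bound"):
    print(f"  {lab:5s}  tau = {kin[lab]['tau']:.1f} min   "
          f"t_half = {kin[lab]['t_half']:.1f} min")
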