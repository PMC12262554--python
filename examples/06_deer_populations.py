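"""DEER extended-state populations from a two-Gaussian fit.

Simulates a dipolar trace from a distance distribution with a compact
state at 2.2 nm and a 21%-weighted extended state at 4.0 nm (modulation
depth 0.3, exponential background), fits the two-Gaussian model by
separable nonlinear least squares and reports the extended-state
population both as the mixture weight and as P(r) mass in the 3-5 nm
window.
"""

from lovhydra import deerpop, synthdata as sd

spec = sd.DeerSpec(gauss_params=((2.2, 0.15, 0.79), (4.0, 0.30, 0.21)),
                   mod_depth=0.3, bg_rate=0.05, noise_sd=0.005, seed=4)
trace = sd.gen_deer_trace(spec)
fit = deerpop.fit_two_gaussian(trace)

print(f"dipolar frequency at 2.2 nm : "
      f"{deerpop.dipolar_frequency_mhz(2.2):.2f} MHz")
for (mean, width, weight), name in zip(fit.distribution.components,
                                       ("compact ", "extended")):
    print(f"{name}: mean {mean:.2f} nm  width {width:.2f} nm  "
          f"weight {weight:.3f}")
print(f"extended weight     : {100 * fit.extended_weight:.1f}% "
      f"(truth {100 * spec.gauss_params[1][2]:.0f}%)")
print(f"mass in 3-5 nm      : {100 * fit.extended_window_fraction:.1f}%")
print(f"modulation depth    : {fit.mod_depth:.3f}   "
      f"background {fit.bg_rate:.3f} /us")
print()
print("The extended fraction quantifies how much of the protein ensemble")
print("has undocked its terminal helices (spin-label distance 3-5 nm).")
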