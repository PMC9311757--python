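"""Translocation currents, saturation and dwell time from a 1D profile.

Builds three profiles with decreasing central barriers (A > B > C) where
only C carries a deep affinity well, then predicts the current vs cis-side
concentration for each with the Kramers-integral permeability and the
single-occupancy two-state Markov model (D = 1 nm²/ns).
"""

import numpy as np

from porinflux import FES1D, TransportConfig, current_curve, reference_to_bulk


def profile(barrier, wells=()):
    z = np.linspace(-25, 25, 501)
    F = barrier * np.exp(-(z**2) / 18)
    for depth, zw in wells:
        F -= depth * np.exp(-((z - zw) ** 2) / 8)
    t = np.clip((25 - np.abs(z)) / 5, 0, 1)
    return reference_to_bulk(FES1D(z, F * (t * t * (3 - 2 * t))))


cfg = TransportConfig()  # D = 1 nm²/ns, 300 K, σ_ref = π·17² Ų
c_grid = np.geomspace(1e-6, 1e-1, 11)
cases = {
    "A (barrier 4.5)": profile(4.5),
    "B (barrier 3.5)": profile(3.5),
    "C (barrier 2.5 + well 6.0)": profile(2.5, wells=[(6.0, 5.0)]),
}

print(f"{'profile':28s} {'I(1 µM) /s':>12s} {'Imax /s':>10s} {'K_half M':>10s} "
      f"{'tau_b s':>10s}")
for name, fes in cases.items():
    cc = current_curve(fes, cfg, c_grid)
    print(f"{name:28s} {cc.current[0]:12.3g} {cc.imax:10.3g} {cc.k_half:10.3g} "
          f"{cc.rates.tau_b:10.3g}")

print("\nLower barriers carry higher low-concentration currents (C > B > A);")
print("the deep affinity well in C slows escape (large dwell time tau_b) and")
print("makes its current saturate at a much lower concentration (small K_half).")
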