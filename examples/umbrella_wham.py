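"""Umbrella sampling -> WHAM -> barrier -> Arrhenius event rates.

Windows are sampled exactly from a known test free-energy profile, WHAM
reconstructs it, and the barrier is converted to a translocation rate.
A 12 kJ/mol steric barrier (inert cargo) versus 6 kJ/mol (receptor with
favourable interactions) produces an ~11-fold selectivity in event rate.
"""
import numpy as np

from fgpore.cg_model import KB_KJMOL
from fgpore.transport_pmf import (
    RateModel, UmbrellaWindow, arrhenius_rate, barrier, make_windows, wham,
)

kBT = KB_KJMOL * 298.0
rng = np.random.default_rng(0)


def profile(z):  # double-well test potential, kJ/mol
    return 1.2 * z**4 - 3.5 * z**2 + 0.8 * z


windows = []
zg = np.linspace(-3, 3, 20001)
for w in make_windows(-2.0, 2.0, spacing=0.4, spring_k=30.0):
    logp = -(profile(zg) + w.bias(zg)) / kBT
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p); cdf /= cdf[-1]
    samples = np.interp(rng.uniform(size=20000), cdf, zg)
    windows.append(UmbrellaWindow(z0=w.z0, spring_k=30.0, samples=samples))

curve = wham(windows, bin_width=0.1)
mask = np.isfinite(curve.free_energy) & (np.abs(curve.z) < 1.8)
rms = np.sqrt(np.mean((curve.free_energy[mask] - curve.free_energy[mask].mean()
                       - profile(curve.z[mask]) + profile(curve.z[mask]).mean()) ** 2))
print(f"WHAM reconstruction error: {rms:.3f} kJ/mol RMS")
print(f"barrier of the test profile: {barrier(curve):.2f} kJ/mol")

model = RateModel(gamma0=17.0)  # per-particle prefactor, fitted in practice
r_fast = arrhenius_rate(model, 6.0)
r_slow = arrhenius_rate(model, 12.0)
print(f"receptor-like (6 kJ/mol): {r_fast:.2f} Hz; "
      f"inert cargo (12 kJ/mol): {r_slow:.2f} Hz; "
      f"selectivity ratio {r_fast / r_slow:.1f}")
# Gamma0 is a fitted per-particle constant; the prefactor-free quantity is
# the ratio: a 6 kJ/mol barrier difference converts to an ~11-fold rate
# contrast, the energetic signature of a selective pore.
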