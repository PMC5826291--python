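"""From a protein-density field to a conductance-versus-diameter curve.

Synthetic density families stand in for the simulated brushes: a
centre-peaked dense field (wildtype-like) suppresses conduction up to much
larger diameters than a uniform, less dense field (mutant-like).
"""
import numpy as np

from fgpore.conductance import (
    ConductanceCurve, ConductivityModel, bare_conductance, closed_form_curve,
    fit_sigmoids, predict_conductance, region_conductivity, threshold_diameter,
)
from fgpore.density_analysis import radial_profile
from fgpore.synthetic_data import DensityFieldSpec, gen_density

model = ConductivityModel()  # sigma_bare 2.2 nS/nm, rho_crit 85 mg/ml
diameters = np.arange(16.0, 62.0, 4.0)

for label, family, amp, wings in (("wildtype-like", "center_peaked", 100.0, 70.0),
                                  ("mutant-like", "uniform", 50.0, 0.0)):
    sig_pore, sig_acc, gs = [], [], []
    for d in diameters:
        spec = DensityFieldSpec(family=family, amplitude=amp, wings=wings,
                                pore_diameter=d, box=(80, 80, 100))
        grid = gen_density(spec)
        pore = radial_profile(grid, "pore")
        sig_pore.append(region_conductivity(pore, model, d))
        sig_acc.append(model.sigma_bare)  # open access region in this family
        gs.append(predict_conductance(pore, None, model, d))
    fits = fit_sigmoids(diameters, sig_pore, sig_acc)
    curve = closed_form_curve(fits, diameters)
    d_thr = threshold_diameter(ConductanceCurve(diameters, np.array(gs), "density"), 4.0)
    print(f"{label}: G({diameters[0]:.0f} nm) = {gs[0]:.2f} nS, "
          f"G({diameters[-1]:.0f} nm) = {gs[-1]:.1f} nS, "
          f"4 nS threshold at ~{d_thr:.0f} nm "
          f"(bare pore: {bare_conductance(diameters[-1]):.1f} nS)")
# The dense centre-peaked field keeps G < 4 nS to much larger diameters
# than the sparse uniform one -- the two-regime shape of coated pores.
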