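"""Fit a Langmuir adsorption isotherm and compute the surface dose.

The Langmuir model Gamma(c) = Gamma_max * K * c / (1 + K * c) links the
equilibrium protein concentration (g/L) to the adsorbed amount per surface
area (mg/m^2).  Gamma_max is the monolayer capacity, K the affinity.
"""

import numpy as np

from siliprot import IsothermData, fit_langmuir, langmuir_gamma, surface_dose

# surface available in the reference mixing experiment:
# 5 g/L nanoparticles in 0.2 mL with S_BET = 168 m^2/g
area = surface_dose(np_conc=5, volume=0.0002, s_bet=168)
print(f"surface dose: {area:.3f} m^2")

# synthetic isotherm around a 1.58 mg/m^2 monolayer capacity, 3% noise
rng = np.random.default_rng(8)
c_eq = np.linspace(0.1, 6.5, 12)
gamma = langmuir_gamma(c_eq, 1.58, 2.0) * (1 + rng.normal(0, 0.03, 12))
fit = fit_langmuir(IsothermData(c_eq, np.clip(gamma, 0, None)))

print(f"Gamma_max = {fit.gamma_max:.3f} +- {fit.gamma_max_stderr:.3f} mg/m^2")
print(f"K         = {fit.k_aff:.3f} +- {fit.k_aff_stderr:.3f} L/g")
print(f"residual norm = {fit.residual_norm:.4f}")
# Gamma_max near 1.58 mg/m^2 is a typical protein monolayer on silica;
# half of it is reached at c = 1/K.
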