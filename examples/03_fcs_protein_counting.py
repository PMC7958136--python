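"""Count carriers per liposome by FCS before/after SDS solubilization.

Simulates autocorrelation curves for intact proteoliposomes (slow, few
particles) and after 2% SDS (fast micelles, one protein each), fits both,
and converts the particle-number ratio into a protein:lipid stoichiometry.
"""

import protonleak as pl

cfg_before = pl.GeneratorConfig(seed=31, correlation_noise_scale=0.02)
cfg_after = pl.GeneratorConfig(seed=32, correlation_noise_scale=0.02)
before = pl.gen_fcs_curve(1.60, 1.45e-3, cfg_before, label="before-SDS")
after = pl.gen_fcs_curve(13.83, 1.0e-4, cfg_after, label="after-SDS")

fit_b = pl.fit_autocorrelation(before)
fit_a = pl.fit_autocorrelation(after)
print(f"before SDS: n = {fit_b.n:5.2f} particles, D = {fit_b.D:6.1f} um^2/s")
print(f"after  SDS: n = {fit_a.n:5.2f} particles, D = {fit_a.D:6.1f} um^2/s")

n_per = pl.proteins_per_liposome(fit_a.n, fit_b.n)
stoich = pl.protein_lipid_ratio(n_per, r_nm=50.0, A_L_nm2=0.6)
print(f"proteins per liposome = {n_per:.2f}")
print(f"lipids per liposome   = {stoich.N_lipids_per_liposome:,.0f}")
print(f"protein:lipid ratio   = {stoich.one_to_display} (rho = {stoich.rho:.3g})")
print("\nEach intact liposome averages several carriers; dissolving it into")
print("single-protein micelles multiplies the particle count by that average.")
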