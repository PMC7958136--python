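"""Per-carrier H+ turnover from a pH-gradient reversal-potential shift.

Simulates I-V traces at symmetric pH and with a one-unit cis-side pH
increase, measures the zero-current shift, combines it with the
protein-mediated conductance and the FCS-derived carrier density, and
prints the turnover number in protons per carrier per second.
"""

import protonleak as pl

area = 1.13e-4  # cm^2
quiet = pl.GeneratorConfig(seed=41, noise_sd_current=0.2)
ref = pl.gen_iv_trace(1750.0, area, 0.0, 0.0, quiet)       # carrier + FA
ctl = pl.gen_iv_trace(440.0, area, 0.0, 0.0, quiet)        # FA only
shifted = pl.gen_iv_trace(1750.0, area, 0.0, 49.0, quiet)  # + delta pH = 1

g_h = (pl.fit_ohmic_conductance(ref).G_specific
       - pl.fit_ohmic_conductance(ctl).G_specific)
shift = pl.reversal_shift(pl.ShiftedIvPair(ref, shifted, delta_pH=1.0))

stoich = pl.protein_lipid_ratio(8.67, r_nm=50.0, A_L_nm2=0.6)
sigma = pl.protein_surface_density(stoich.rho, stoich.A_L_nm2)

res = pl.turnover_number(g_h, shift, sigma, delta_pH=1.0, temperature=306.0)
print(f"protein-mediated G_H = {res.G_H:7.1f} nS/cm^2")
print(f"reversal shift       = {res.delta_U_rev:7.2f} mV "
      f"(Nernst limit {res.U_nernst:.1f} mV)")
print(f"carrier density      = {res.sigma_protein:.3g} /cm^2")
print(f"H+ flux density      = {res.flux_density:.3g} mol/s/cm^2")
print(f"turnover number k    = {res.k_turnover:7.2f} H+/s per carrier")
print("\nk = (G_H * dU_rev / F) * N_A / sigma: the proton flux carried by the")
print("protein-dependent conductance, shared over the carriers present.")
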