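"""Calibrate the focal volume and convert molecule numbers to nanomolar.

A free dye of known diffusion coefficient (Atto-488, 400 um^2/s at 25 C)
pins down the beam waist; a dilution series of known concentrations against
fitted molecule numbers gives a standard curve whose inversion turns any
fitted N into a concentration.
"""

import fcsgrad as fg

# --- focal volume from a synthetic dye measurement ------------------------
true_vol = fg.FocalVolume(w_xy=0.2, k=5.0)
dye = fg.ACFPreset("dye/cytoplasm/anterior", 400.0, 400.0, 1.0,
                   n_mol=2.0, t_frac=0.1, tau_trip=3e-6)
dye_curve = fg.generate_acf(dye, true_vol, fg.default_lags(160, 1e-7, 0.1))
vol = fg.calibrate_focal_volume([dye_curve], d_known=400.0, k=5.0)
print(f"calibrated beam waist w_xy = {vol.w_xy * 1e3:.1f} nm "
      f"(generated with {true_vol.w_xy * 1e3:.0f} nm)")
print(f"effective volume V_eff = {vol.v_eff:.3f} um^3")

# --- standard curve from the dye dilution series --------------------------
# molecules per focal volume at known nM, on a known line (slope 2.1, no
# offset) as a stand-in for the measured dilution series
dilution_nM = (2.0, 5.0, 7.0, 10.0)
points = [(c, 2.1 * c) for c in dilution_nM]
cal = fg.fit_standard_curve(points, source="dye")
print(f"\nstandard curve: n_mol = {cal.slope:.2f} * conc_nM + "
      f"{cal.intercept:.2f}  (r^2 = {cal.r2:.4f})")

# --- an unknown specimen --------------------------------------------------
curve = fg.generate_acf("bcd/cytoplasm/anterior", vol)
fit = fg.fit_acf(curve, "two_comp_triplet", vol, calibration=cal)
print(f"\nspecimen: fitted N = {fit.params.n_mol:.1f} molecules in the "
      f"focal volume")
print(f"estimated concentration = {fit.conc_nM:.2f} nM")
print("The concentration is what the gradient profiles are measured in;")
print("it links FCS amplitudes to the gradient models.")
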