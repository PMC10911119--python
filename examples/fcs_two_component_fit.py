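"""Fit one- and two-component diffusion models to synthetic FCS curves.

Generates lightly noisy autocorrelation curves for the anterior and
posterior cytoplasm presets, shows that a single diffusing species cannot
explain them, and reports the recovered fast/slow components and the
effective diffusion coefficient in each region.
"""

import numpy as np

import fcsgrad as fg

vol = fg.FocalVolume(w_xy=0.2, k=5.0)
lags = fg.default_lags(200, 1e-6, 1.0)

d_eff = {}
for region in ("anterior", "posterior"):
    curve = fg.generate_acf(f"bcd/cytoplasm/{region}", vol, lags,
                            fg.NoiseSpec(scale=0.01, seed=7))
    cm = fg.compare_models(curve, vol)
    two = cm.fits["two_comp"]
    print(f"{region} cytoplasm: preferred model = {cm.preferred} "
          f"(chi2 improvement {100 * cm.improvement:.1f}%)")
    print(f"  D_fast = {two.d_fast:5.2f} um^2/s   f_fast = "
          f"{100 * two.f_fast:4.1f}%   D_slow = {two.d_slow:.2f} um^2/s")
    print(f"  D_eff  = {two.d_eff:5.2f} um^2/s")
    d_eff[region] = two.d_eff

print(f"\nposterior/anterior D_eff ratio = "
      f"{d_eff['posterior'] / d_eff['anterior']:.2f}")
print("A ratio well above 1 means the morphogen is effectively more mobile")
print("in the dim posterior than near its anterior source.")

# are per-measurement D_eff values distinguishable between regions?
rng = np.random.default_rng(0)
groups = {}
for region in ("anterior", "posterior"):
    values = []
    for s in range(8):
        noisy = fg.generate_acf(f"bcd/cytoplasm/{region}", vol, lags,
                                fg.NoiseSpec(scale=0.02, seed=s))
        values.append(fg.fit_acf(noisy, "two_comp_triplet", vol,
                                 n_restarts=3, seed=s).d_eff)
    groups[region] = fg.GroupSample(np.array(values), region)

p = fg.permutation_test(groups["anterior"], groups["posterior"],
                        n_perm=5000, seed=1)
print(f"\ntwo-sided permutation test on per-measurement D_eff: p = {p:.4g}")
print("(small p: the anterior/posterior mobility difference is not noise)")
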