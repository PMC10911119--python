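"""Simulate gradient formation: classic SDD versus two dynamic modes.

Solves both models from an empty embryo, compares how close each is to its
own steady state at the posterior after 90 minutes, and checks that the
two-component steady profile is still exponential over most of the axis.
"""

import numpy as np

import fcsgrad as fg

x = fg.default_grid(500.0, 2.0)
t90 = np.array([90.0 * 60.0])

# two-component model with the measured cytoplasmic diffusivities
p2 = fg.bcd_two_component_params()
steady2 = fg.two_component_steady_state(p2, x_grid=x)
field2 = fg.solve_two_component(p2, x, t90)
ratio2 = fg.distance_from_steady_state(
    field2, fg.GradientProfile(x, steady2.rho_total[-1]))

# SDD with the matched anterior effective diffusion coefficient
p1 = fg.matched_sdd_params(p2)
field1 = fg.solve_sdd(p1, x, t90)
ratio1 = fg.distance_from_steady_state(field1, fg.sdd_steady_state(p1, x))

i450 = np.argmin(np.abs(x - 450.0))
print(f"SDD model (D = {p1.d} um^2/s): lambda = {p1.decay_length:.0f} um")
print(f"fraction of steady state reached at x = 450 um after 90 min:")
print(f"  SDD           : {ratio1[-1, i450]:.2f}")
print(f"  two-component : {ratio2[-1, i450]:.2f}")
print("The two-component model is closer to 1: its fast form ferries")
print("molecules to the posterior sooner than a single effective species.")

prof = fg.GradientProfile(x, steady2.rho_total[-1])
dec = fg.fit_exponential_decay(prof, (50.0, 300.0))
print(f"\ntwo-component steady profile on [50, 300] um: "
      f"lambda = {dec.lambda_um:.0f} um, r^2 = {dec.r2:.4f}")
print("r^2 near 1: despite two species and space-varying D, the gradient")
print("still looks exponential across most of the embryo.")

frac = steady2.rho_f[-1] / steady2.rho_total[-1]
i50 = np.argmin(np.abs(x - 50.0))
print(f"\nlocal fast fraction at x=50 um: {100 * frac[i50]:.0f}%   "
      f"at x=450 um: {100 * frac[i450]:.0f}%")
print("(matching the FCS measurements: 65% anterior, 78% posterior)")
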