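# fcsgrad

Tools for dissecting how a morphogen gradient forms when the morphogen has
more than one diffusive state. The package was built around the Bicoid (Bcd)
gradient of the early *Drosophila* embryo — an anterior-to-posterior
exponential gradient whose protein, measured by fluorescence correlation
spectroscopy (FCS), moves as a mixture of a fast (~13–19 µm²/s) and a slow
(~1 µm²/s) species whose proportions change along the axis — but every piece
is generic: it is aimed at anyone who needs to fit two-component FCS curves,
calibrate them to absolute concentrations, and ask whether a
synthesis–diffusion–degradation (SDD) style model with spatially varying
dynamics can explain a measured gradient.

## What it computes

**FCS side.** Autocorrelation curves are modelled with the standard
confocal 3D diffusion form with an optional triplet (dark-state) term,

```
G(τ) = (1/N) · [1 + T/(1−T) e^(−τ/τ_T)] · Σᵢ fᵢ (1+τ/τ_Dᵢ)⁻¹ (1+τ/(K²τ_Dᵢ))⁻¹ᐟ²
```

with N molecules in the focal volume, triplet fraction T, structure
parameter K and per-species diffusion times τ_Dᵢ, converted to diffusion
coefficients via D = w_xy²/(4τ_D). The package fits one- and two-component
variants by weighted least squares with seeded multi-starts, compares them,
calibrates the beam waist from a dye of known D, converts molecule numbers
to nM through a standard curve, and compares groups of measurements with a
two-sided permutation test. The headline summary statistic is the effective
diffusion coefficient `D_eff = f_fast·D_fast + f_slow·D_slow`.

**Gradient side.** The classic SDD model
`∂ρ/∂t = D ∂²ρ/∂x² + j·1[x<x_s] − μρ` (zero-flux boundaries, exponential
steady state with decay length λ = √(D/μ)) and a two-component extension in
which fast and slow cytoplasmic forms interconvert, both diffusivities vary
linearly along the axis, and the fast→slow rate saturates with local
concentration, β(ρ_T) = β₀ρ_T/(ρ₀+ρ_T):

```
∂ρ_f/∂t = ∂x(D_f(x)∂x ρ_f) + j·1[x<x_s] − β(ρ_T)ρ_f + αρ_s − μ_f ρ_f
∂ρ_s/∂t = ∂x(D_s(x)∂x ρ_s) + β(ρ_T)ρ_f − αρ_s − μ_s ρ_s
```

Solvers use a conservative finite-volume discretisation and a stiff BDF
integrator; fluorophore maturation is a co-diffusing dark→bright conversion.
Either model can be fitted to a measured profile by Nelder–Mead, wrapped in
a resample-and-refit bootstrap that turns inter-embryo scatter into
parameter uncertainties. A synthetic-data module generates every input from
presets that transcribe the measured parameter values, so the whole
pipeline runs without external data.

## Worked example

```
$ python examples/gradient_simulation.py
SDD model (D = 8.8 um^2/s): lambda = 162 um
fraction of steady state reached at x = 450 um after 90 min:
  SDD           : 0.53
  two-component : 0.60
The two-component model is closer to 1: its fast form ferries
molecules to the posterior sooner than a single effective species.

two-component steady profile on [50, 300] um: lambda = 177 um, r^2 = 0.9983
r^2 near 1: despite two species and space-varying D, the gradient
still looks exponential across most of the embryo.

local fast fraction at x=50 um: 65%   at x=450 um: 78%
(matching the FCS measurements: 65% anterior, 78% posterior)
```

The first block is the kinetic argument for multiple dynamic modes: with a
single effective diffusivity of 8.8 µm²/s the posterior is only 53% of the
way to steady state after 90 minutes, while the two-component model —
identical effective anterior mobility, but with a fast form that escapes
conversion at low posterior concentrations — reaches 60%. The second block
shows this speed-up costs nothing in shape: the steady gradient remains
log-linear (r² ≈ 0.998) over [50, 300] µm. The last line confirms the
model's local fast fractions reproduce the FCS measurements it was built
from.

The other example scripts cover curve fitting and model comparison
(`fcs_two_component_fit.py`), focal-volume and concentration calibration
(`concentration_calibration.py`), and bootstrap profile fitting
(`bootstrap_gradient_fit.py`). A thin CLI (`fcsgrad calibrate | fit-acf |
simulate | fit-gradient | synth`) exposes the batch operations.

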