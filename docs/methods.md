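# Methods

This note records the models implemented in `fcsgrad`, the conventions and
defaults chosen where more than one was defensible, and what the synthetic
data used by the test suite does and does not emulate.

## FCS autocorrelation model

Curves are modelled with the confocal Gaussian-volume form for free 3D
diffusion of one or two species with an optional triplet state:

G(τ) = (1/N)·[1 + T/(1−T)·e^(−τ/τ_T)]·Σᵢ fᵢ·(1+τ/τ_Dᵢ)⁻¹·(1+τ/(K²τ_Dᵢ))^(−1/2),
Σfᵢ = 1.

Two triplet conventions circulate; we use the normalised prefactor, so
G(0) = 1/(N(1−T)) and the fitted N is the true mean molecule number. The
structure parameter K (axial/lateral 1/e² ratio) is fixed at its
calibration value during specimen fits — floating K in a two-component fit
trades off against the slow diffusion time and destabilises both. Diffusion
times convert to coefficients via D = w_xy²/(4τ_D).

Normalisation for qualitative curve comparison is
(G(τ)−G(∞))/(G(0)−G(∞)), with G(0) read at the lag nearest 10⁻⁴ s and
G(∞) nearest 1 s (configurable); it is affine-invariant and idempotent.

### Fitting

Weighted least squares (weights 1/σ² when a per-lag s.d. is available,
otherwise unweighted) with bound-constrained least-squares minimisation
(lmfit), restarted from 10 seeded log-space perturbations of a heuristic
initial guess; the best reduced χ² wins. Fractions are bounded to
[0.01, 0.99] and results at a bound are flagged; components are reported
fast-first, re-sorting after the fit if the diffusion times cross. Model
selection prefers the two-component model only when its reduced χ² improves
on the one-component fit by more than 5% *and* both fractions exceed 0.05 —
a numeric stand-in for the usual qualitative residual inspection; without
the threshold the richer model would win on any noise.

### Calibration

The focal volume is calibrated by fitting a one-component(+triplet) model
to a free-dye curve and setting w_xy = √(4·D_known·τ_D). The default dye
coefficient is 400 µm²/s (Atto-488 in water at 25 °C, literature value);
it is an argument, not a constant. Concentration calibration is an ordinary
least-squares line of fitted molecule number against known concentration
(nM); estimation inverts the line. Both the dye dilution series
(2/5/7/10 nM) and protein standards (3/4/6/15 nM) enter as plain
(conc, N) tables.

### Group comparison

Two-sided permutation test on the difference of group means. When the
number of arrangements C(n_a+n_b, n_a) is within the permutation budget the
null distribution is enumerated exhaustively and the p-value is exact
(identity arrangement included); otherwise p = (1+k)/(n_perm+1) with k the
number of sampled permutations at least as extreme (the add-one convention,
so p is never 0). Ties are counted as extreme using a 10⁻¹² relative
tolerance.

## Gradient models

Single-species SDD: ∂ρ/∂t = D∂²ρ/∂x² + j·1[x<x_s] − μρ on x ∈ [0, L],
zero-flux at both poles, ρ≡0 at t=0 (fertilisation). Defaults: x_s = 30 µm,
L = 500 µm, μ = 1/(50 min) (the eGFP lifetime in the early embryo). The
steady state is piecewise analytic (cosh in the source region, a
cosh((L−x)/λ) tail, λ = √(D/μ)) and is evaluated in exponentially scaled
form so steep-gradient parameter excursions during fitting cannot overflow.

Two-component model: fast and slow forms with linear-in-x diffusivities
D_f(x), D_s(x) (anterior → posterior endpoint values), constant slow→fast
rate α, saturating fast→slow rate β(ρ_T) = β₀ρ_T/(ρ₀+ρ_T), degradation
μ_s, μ_f, and production into the fast pool (newly translated protein is
assumed mobile; a registry switch moves the source to the slow pool or
splits it). The linear D(x) and saturating β(ρ_T) are the simplest forms
consistent with the measurements (mobility rising toward the posterior;
conversion to the slow form strongest where concentration is high);
alternates (constant D, β linear in ρ_T) are selectable per parameter set
so model variants can be compared through one interface. Whether D truly
varies with position or with local concentration is not distinguishable
from the data the model is built on; the linear-in-x form is a
phenomenological choice.

Fluorophore maturation is a first-order, co-diffusing dark→bright
conversion with k_mat = 1/(45 min); the "observed" field is the bright
fraction, co-solved with the totals (a fixed-delay alternative is not
PDE-compatible). With uniform production switched on at t=0 and transport
and degradation off, the bright fraction at t = 1/k is
1 − (1−e⁻¹) = e⁻¹ ≈ 0.368; the test suite pins this closed form.

### Numerics

Method of lines on a uniform cell-centred grid with a conservative
finite-volume flux form of ∂x(D(x)∂xρ) — with spatially varying D the
discrete total mass is conserved exactly, and the test suite verifies drift
< 0.1% over 150 simulated minutes with sources and sinks off. The source
indicator is discretised by fractional cell overlap with [0, x_s], which
keeps the integrated production rate grid-independent (sampling the
indicator at cell centres costs a first-order error in the effective
source width). Time integration is BDF (`scipy.integrate.solve_ivp`) with a
sparse Jacobian pattern; defaults Δx = 1 µm, rtol 10⁻⁶, atol 10⁻⁹. The
solver-oracle test compares the relaxed numeric steady state with the
analytic one to <1% L2 over [50, 450] µm and checks the error at least
halves per grid halving. Tests and the bootstrap run at Δx = 2–5 µm, which
the refinement study shows is already within a fraction of a percent of the
fine-grid solution.

The two-component steady state is obtained by relaxing the transient
solver to 12 lifetimes and verifying the last two snapshots agree to 0.1%.

### Profile fitting and the bootstrap

The objective is the unweighted sum of squared residuals between the
simulated observed profile (at a configurable readout time, or the steady
state) and the data at the data positions; a log-scale option exists. The
production rate j absorbs arbitrary intensity units, so profiles are fitted
unnormalised. Minimisation is Nelder–Mead on log-transformed parameters
(all are positive), convergence by simplex size 10⁻⁶ (relative, because of
the log transform), maximum 2000 iterations; simulation failures during the
search return a large penalty instead of aborting. The bootstrap draws each
replicate as independent per-position Gaussians N(mean, sd) truncated at
zero — mean ≫ sd in the data regime, so the truncation bias is negligible —
refits from the same initial guess with a seed spawned deterministically
from the master seed, and summarises converged replicates (flagged if more
than 20% fail). 100 replicates is the default. Fit precision along the
axis is reported as |model−data|/data per position (the y-axis formula for
such comparisons is not standardised; this is the plain relative residual).

Decay lengths come from a least-squares line on log intensity inside a
window, default [50, 300] µm — anterior of the window the source region
dominates, posterior of it the profile flattens into noise.

## Synthetic data

Presets transcribe the measured two-component parameters per construct,
compartment and region (wild-type Bcd cytoplasm: D_fast 13.0/18.8 µm²/s
and f_fast 65/78% anterior/posterior, D_slow 1 µm²/s; nuclear, NLS,
NLS+homeodomain and DNA-binding-mutant values likewise). Where only a range
was measured the preset takes the midpoint and keeps the range in metadata.
Molecule numbers per focal volume fall from anterior (~20–40) to posterior
(~4–10), emulating the lower posterior signal; the absolute values are
declared defaults, not measurements. Triplet parameters (T = 0.15,
τ_T = 4 µs) are typical eGFP photophysics.

ACF noise is multiplicative Gaussian with a relative scale, optionally
decaying with lag. Real FCS noise is lag-correlated with a known
variance structure; this generator makes no attempt at that correlation
structure, so recovery tests quantify robustness to amplitude noise only.
Profile noise multiplies the simulated profile by independent per-position
Gaussian factors per synthetic embryo (default 10%, 3 embryos) — it
emulates inter-embryo intensity scatter but not systematic illumination
gradients, background misestimation or nuclear-segmentation error.

The default two-component parameter set uses the measured diffusivities
and lifetime; the unmeasured exchange constants were set once so that the
local kinetic-equilibrium fast fraction of the relaxed steady profile
matches the FCS values at the measurement regions (~0.65 at x = 50 µm,
~0.78 at x = 450 µm): α = 0.02 s⁻¹, β₀ = 0.013 s⁻¹, ρ₀ = 82 in the
concentration units set by j = 1. The exchange timescale (~1–2 min) is
faster than transport across a decay length, which is what makes the local
fractions well-defined; it is otherwise unconstrained.

Passing tests on these synthetics demonstrate internal consistency —
generator, fitter and solvers agree, with noise propagated honestly — not
agreement with any particular embryo: the experimental fit parameters
behind the published profile fits are not reproducible from public
information, so the pipeline is validated by recovery from synthetic data
generated at the measured parameter values.

## Known limitations

* 1D geometry: no embryo curvature, cytoplasmic flow, nuclear
  import/export or mitotic redistribution; the nuclear-bound pool is
  treated as stationary and only cytoplasmic transport is modelled.
* Anomalous-diffusion fits (scale-dependent D) are deliberately excluded;
  the two-component model is the simpler description and the two cannot be
  distinguished on these data.
* The profile-fit objective assumes independent residuals across
  positions; spatially correlated experimental error would make the
  bootstrap s.d. optimistic.
* `two_component_steady_state` relaxes the PDE rather than solving the
  steady BVP directly; for μ → 0 it becomes expensive and eventually
  refuses (steady state requires positive degradation).
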