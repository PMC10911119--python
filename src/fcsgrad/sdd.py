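"""Synthesis-diffusion-degradation (SDD) models of gradient formation.

The classic SDD model for a morphogen concentration rho(x, t) on the
anterior-posterior axis x in [0, L] is

    d rho / dt = D d2 rho / dx2  +  j * 1[x < x_s]  -  mu * rho

with zero-flux boundaries at both poles.  Its steady state is piecewise
analytic and, away from the source region, decays exponentially with decay
length lambda = sqrt(D / mu).

The two-component extension tracks a fast (rho_f) and a slow (rho_s)
cytoplasmic form that interconvert.  Both diffusivities may vary linearly
along the axis (faster towards the posterior, as measured by FCS), and the
fast-to-slow transition rate saturates with the local total concentration
rho_T = rho_s + rho_f,

    beta(rho_T) = beta0 * rho_T / (rho0 + rho_T),

so conversion to the slow form is strongest near the anterior where the
morphogen is abundant:

    d rho_f / dt = d/dx( D_f(x) d rho_f /dx ) + j*1[x<x_s]
                   - beta(rho_T) rho_f + alpha rho_s - mu_f rho_f
    d rho_s / dt = d/dx( D_s(x) d rho_s /dx )
                   + beta(rho_T) rho_f - alpha rho_s - mu_s rho_s

Fluorophore maturation is modelled as a co-diffusing dark-to-bright
first-order conversion at rate k_mat; the "observed" field is the bright
fraction only.  Numerics: method of lines on a conservative finite-volume
grid (flux form, so spatially varying D conserves mass exactly in the
discretisation), integrated with a stiff BDF solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .acf import ValidationError
from .profiles import GradientProfile

#: degradation rate 1/(50 min), the eGFP lifetime in the early embryo
MU_DEFAULT = 1.0 / (50.0 * 60.0)
#: first-order maturation rate for a ~45 min mean folding time
K_MAT_DEFAULT = 1.0 / (45.0 * 60.0)


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SDDParams:
    """Single-species SDD parameters (µm, s units)."""

    d: float
    mu: float = MU_DEFAULT
    j: float = 1.0
    x_s: float = 30.0
    l: float = 500.0
    k_mat: float = 0.0

    def __post_init__(self) -> None:
        if min(self.d, self.mu, self.j, self.x_s, self.l) <= 0:
            raise ValidationError("d, mu, j, x_s, l must be positive")
        if self.k_mat < 0:
            raise ValidationError("k_mat must be >= 0")
        if self.x_s >= self.l:
            raise ValidationError("source width x_s must be below l")

    @property
    def decay_length(self) -> float:
        """Steady-state decay length lambda = sqrt(D/mu), µm."""
        return math.sqrt(self.d / self.mu)


@dataclass(frozen=True)
class TwoComponentSDDParams:
    """Two interconverting species with linearly varying diffusivities.

    ``d_f_ant``/``d_f_post`` are the fast-species diffusion coefficients at
    the anterior (x=0) and posterior (x=L) poles, likewise ``d_s_*`` for the
    slow species.  ``beta0``/``rho0`` parameterise the saturating fast-to-
    slow transition, ``alpha`` the constant slow-to-fast rate.  Registry
    switches: ``diffusion_form`` in {linear, constant} (constant uses the
    anterior values), ``transition_form`` in {saturating, linear}
    (linear: beta = beta0 * rho_T / rho0), ``source_target`` in
    {fast, slow, split}.
    """

    d_f_ant: float
    d_f_post: float
    d_s_ant: float = 1.0
    d_s_post: float = 1.0
    beta0: float = 0.0
    rho0: float = 1.0
    alpha: float = 0.0
    mu_s: float = MU_DEFAULT
    mu_f: float = MU_DEFAULT
    j: float = 1.0
    x_s: float = 30.0
    l: float = 500.0
    k_mat: float = 0.0
    diffusion_form: str = "linear"
    transition_form: str = "saturating"
    source_target: str = "fast"

    def __post_init__(self) -> None:
        if min(self.d_f_ant, self.d_f_post) <= 0:
            raise ValidationError("fast diffusivities must be positive")
        if self.d_s_ant < 0 or self.d_s_post < 0:
            raise ValidationError("slow diffusivities must be >= 0")
        if self.d_f_ant < self.d_s_ant or self.d_f_post < self.d_s_post:
            raise ValidationError("fast diffusivity must be >= slow")
        if min(self.beta0, self.alpha) < 0 or self.rho0 <= 0:
            raise ValidationError("beta0, alpha >= 0 and rho0 > 0 required")
        if min(self.mu_s, self.mu_f) < 0 or self.j <= 0:
            raise ValidationError("mu >= 0 and j > 0 required")
        if not (0 < self.x_s < self.l):
            raise ValidationError("require 0 < x_s < l")
        if self.k_mat < 0:
            raise ValidationError("k_mat must be >= 0")
        if self.diffusion_form not in ("linear", "constant"):
            raise ValidationError("diffusion_form must be linear|constant")
        if self.transition_form not in ("saturating", "linear"):
            raise ValidationError("transition_form must be saturating|linear")
        if self.source_target not in ("fast", "slow", "split"):
            raise ValidationError("source_target must be fast|slow|split")


@dataclass
class SimulationField:
    """Solved concentration fields over (t, x); arrays are (n_t, n_x)."""

    x: np.ndarray
    t: np.ndarray
    rho_s: np.ndarray
    rho_f: np.ndarray
    observed: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def rho_total(self) -> np.ndarray:
        return self.rho_s + self.rho_f

    def total_mass(self) -> np.ndarray:
        """Spatial integral of rho_total at each output time.

        Uses the cell-sum quadrature of the finite-volume scheme (uniform
        grid assumed), which is the exactly conserved discrete quantity.
        """
        h = self.x[1] - self.x[0]
        return self.rho_total.sum(axis=1) * h


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def linear_diffusion_profile(
    x: np.ndarray | float, d_ant: float, d_post: float, l: float
) -> np.ndarray | float:
    """Linearly interpolated diffusivity D(x) = D_ant + (D_post-D_ant) x/L."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa > l):
        raise ValidationError("x must lie within [0, l]")
    out = d_ant + (d_post - d_ant) * xa / l
    return float(out) if np.isscalar(x) else out


def transition_rate(
    rho_t: np.ndarray | float,
    beta0: float,
    rho0: float,
    form: str = "saturating",
) -> np.ndarray | float:
    """Concentration-dependent fast-to-slow transition rate beta(rho_T)."""
    r = np.asarray(rho_t, dtype=float)
    if np.any(r < 0):
        raise ValidationError("concentration must be non-negative")
    if form == "saturating":
        out = beta0 * r / (rho0 + r)
    elif form == "linear":
        out = beta0 * r / rho0
    else:
        raise ValidationError(f"unknown transition form {form!r}")
    return float(out) if np.isscalar(rho_t) else out


def diffusion_time(x_rms: float, d: float, c: float = 4.0) -> float:
    """Time to diffuse an r.m.s. distance: t = x_rms^2 / (c D), seconds.

    c depends on dimensionality (c=4 for effectively 2D movement near the
    embryo surface).
    """
    if min(x_rms, d, c) <= 0:
        raise ValidationError("x_rms, d, c must be positive")
    return x_rms**2 / (c * d)


def survival_fraction(t: float, lifetime: float) -> float:
    """Fraction of molecules not yet degraded after time t: exp(-t/lifetime)."""
    if t < 0 or lifetime <= 0:
        raise ValidationError("t >= 0 and lifetime > 0 required")
    return math.exp(-t / lifetime)


# ---------------------------------------------------------------------------
# discretisation helpers
# ---------------------------------------------------------------------------

def default_grid(l: float = 500.0, dx: float = 1.0) -> np.ndarray:
    """Cell-centre grid on [0, l] with spacing dx."""
    n = int(round(l / dx))
    return (np.arange(n) + 0.5) * (l / n)


def _face_positions(x: np.ndarray) -> np.ndarray:
    # interior faces between cell centres of a uniform grid
    return 0.5 * (x[:-1] + x[1:])


def _source_weights(x: np.ndarray, x_s: float) -> np.ndarray:
    """Fractional overlap of each cell with the source region [0, x_s].

    Sampling the indicator at cell centres would round the source width to a
    multiple of the grid spacing; the exact overlap keeps the integrated
    production rate grid-independent.
    """
    h = x[1] - x[0]
    return np.clip((x_s - (x - 0.5 * h)) / h, 0.0, 1.0)


def _transport_operator(
    x: np.ndarray, d_face: np.ndarray
) -> Callable[[np.ndarray], np.ndarray]:
    """Conservative zero-flux divergence of D(x) grad rho on a uniform grid."""
    h = x[1] - x[0]
    coeff = d_face / h**2

    def op(rho: np.ndarray) -> np.ndarray:
        flux = coeff * (rho[1:] - rho[:-1])  # inward flux across faces
        out = np.empty_like(rho)
        out[0] = flux[0]
        out[-1] = -flux[-1]
        out[1:-1] = flux[1:] - flux[:-1]
        return out

    return op


def _field_sparsity(n_fields: int, m: int) -> sparse.csr_matrix:
    tri = sparse.diags_array([np.ones(m - 1), np.ones(m), np.ones(m - 1)],
                             offsets=(-1, 0, 1))
    eye = sparse.eye_array(m)
    blocks = [
        [tri if i == j else eye for j in range(n_fields)]
        for i in range(n_fields)
    ]
    return sparse.csr_matrix(sparse.block_array(blocks))


def _integrate(
    rhs: Callable, y0: np.ndarray, t_out: np.ndarray,
    sparsity: sparse.csr_matrix, rtol: float, atol: float,
) -> np.ndarray:
    t_out = np.asarray(t_out, dtype=float)
    if t_out.ndim != 1 or t_out.size == 0 or np.any(np.diff(t_out) <= 0):
        raise ValidationError("t_out must be a non-empty increasing array")
    t0 = 0.0 if t_out[0] > 0 else t_out[0]
    sol = solve_ivp(
        rhs, (t0, t_out[-1]), y0, method="BDF", t_eval=t_out,
        jac_sparsity=sparsity, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"PDE integration failed: {sol.message}")
    return sol.y.T  # (n_t, n_state)


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def solve_sdd(
    p: SDDParams,
    x_grid: np.ndarray | None = None,
    t_out: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> SimulationField:
    """Solve the single-species SDD model from rho=0 at t=0.

    The species is reported in the ``rho_f`` slot (``rho_s`` is zero).  With
    ``p.k_mat > 0`` a co-diffusing bright field is co-solved and returned as
    ``observed``.
    """
    x = default_grid(p.l) if x_grid is None else np.asarray(x_grid, float)
    if t_out is None:
        t_out = np.linspace(0.0, 150 * 60.0, 31)
    m = x.size
    op = _transport_operator(x, np.full(m - 1, p.d))
    src = p.j * _source_weights(x, p.x_s)
    mature = p.k_mat > 0

    if not mature:
        def rhs(_t: float, y: np.ndarray) -> np.ndarray:
            return op(y) + src - p.mu * y

        y0 = np.zeros(m)
        ys = _integrate(rhs, y0, t_out, _field_sparsity(1, m), rtol, atol)
        rho = ys
        observed = None
    else:
        def rhs(_t: float, y: np.ndarray) -> np.ndarray:
            rho, b = y[:m], y[m:]
            drho = op(rho) + src - p.mu * rho
            db = op(b) - p.mu * b + p.k_mat * (rho - b)
            return np.concatenate([drho, db])

        y0 = np.zeros(2 * m)
        ys = _integrate(rhs, y0, t_out, _field_sparsity(2, m), rtol, atol)
        rho, observed = ys[:, :m], ys[:, m:]

    return SimulationField(
        x=x, t=np.asarray(t_out, float), rho_s=np.zeros_like(rho), rho_f=rho,
        observed=observed, meta={"model": "sdd", "params": p},
    )


def solve_two_component(
    p: TwoComponentSDDParams,
    x_grid: np.ndarray | None = None,
    t_out: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    y0: np.ndarray | None = None,
) -> SimulationField:
    """Solve the coupled fast/slow system from rho=0 at t=0 (or ``y0``)."""
    x = default_grid(p.l) if x_grid is None else np.asarray(x_grid, float)
    if t_out is None:
        t_out = np.linspace(0.0, 150 * 60.0, 31)
    m = x.size
    xf = _face_positions(x)
    if p.diffusion_form == "linear":
        df_face = linear_diffusion_profile(xf, p.d_f_ant, p.d_f_post, p.l)
        ds_face = linear_diffusion_profile(xf, p.d_s_ant, p.d_s_post, p.l)
    else:
        df_face = np.full(m - 1, p.d_f_ant)
        ds_face = np.full(m - 1, p.d_s_ant)
    op_f = _transport_operator(x, df_face)
    op_s = _transport_operator(x, ds_face)
    indicator = _source_weights(x, p.x_s)
    if p.source_target == "fast":
        src_f, src_s = p.j * indicator, 0.0 * indicator
    elif p.source_target == "slow":
        src_f, src_s = 0.0 * indicator, p.j * indicator
    else:
        src_f = src_s = 0.5 * p.j * indicator

    def beta_of(rho_t: np.ndarray) -> np.ndarray:
        rho_t = np.maximum(rho_t, 0.0)
        if p.transition_form == "saturating":
            return p.beta0 * rho_t / (p.rho0 + rho_t)
        return p.beta0 * rho_t / p.rho0

    mature = p.k_mat > 0
    n_fields = 4 if mature else 2

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        rho_f, rho_s = y[:m], y[m : 2 * m]
        beta = beta_of(rho_f + rho_s)
        ex_fs = beta * rho_f - p.alpha * rho_s  # net fast -> slow exchange
        drho_f = op_f(rho_f) + src_f - ex_fs - p.mu_f * rho_f
        drho_s = op_s(rho_s) + src_s + ex_fs - p.mu_s * rho_s
        if not mature:
            return np.concatenate([drho_f, drho_s])
        b_f, b_s = y[2 * m : 3 * m], y[3 * m :]
        ex_b = beta * b_f - p.alpha * b_s
        db_f = op_f(b_f) - ex_b - p.mu_f * b_f + p.k_mat * (rho_f - b_f)
        db_s = op_s(b_s) + ex_b - p.mu_s * b_s + p.k_mat * (rho_s - b_s)
        return np.concatenate([drho_f, drho_s, db_f, db_s])

    if y0 is None:
        y0 = np.zeros(n_fields * m)
    ys = _integrate(rhs, y0, t_out, _field_sparsity(n_fields, m), rtol, atol)
    observed = ys[:, 2 * m :].reshape(ys.shape[0], 2, m).sum(axis=1) if mature else None
    return SimulationField(
        x=x, t=np.asarray(t_out, float),
        rho_f=ys[:, :m], rho_s=ys[:, m : 2 * m], observed=observed,
        meta={"model": "two_comp", "params": p},
    )


# ---------------------------------------------------------------------------
# steady states and derived metrics
# ---------------------------------------------------------------------------

def sdd_steady_state(
    p: SDDParams, x: np.ndarray | None = None
) -> GradientProfile:
    """Closed-form steady state of the constant-D SDD model.

    Inside the source region the profile is j/mu + A cosh(x/lambda); outside
    it is B cosh((L-x)/lambda), with A and B fixed by continuity of value
    and flux at x = x_s and zero flux at both poles.  For x_s << x << L this
    decays as exp(-x/lambda).
    """
    if x is None:
        x = default_grid(p.l)
    x = np.asarray(x, dtype=float)
    lam = p.decay_length
    a = p.x_s / lam
    c = p.l / lam
    amp = p.j / p.mu
    # exponentially scaled forms: stable for steep gradients (lam << L)
    denom = 1.0 - math.exp(-2.0 * c)
    inside = amp * (
        1.0
        - math.exp(-a) * (1.0 - math.exp(-2.0 * (c - a))) / denom
        * np.cosh(np.minimum(x, p.x_s) / lam)
    )
    sinh_a = 0.5 * (1.0 - math.exp(-2.0 * a))  # sinh(a) * exp(-a)
    outside = (
        amp * sinh_a / denom
        * np.exp((p.x_s - x) / lam)
        * (1.0 + np.exp(-2.0 * (p.l - x) / lam))
    )
    mean = np.where(x < p.x_s, inside, outside)
    return GradientProfile(x=x, mean=mean, meta={"model": "sdd", "params": p})


def two_component_steady_state(
    p: TwoComponentSDDParams,
    x_grid: np.ndarray | None = None,
    horizon_factor: float = 12.0,
    rtol: float = 1e-6,
) -> SimulationField:
    """Relax the two-component system to steady state numerically.

    Integrates to ``horizon_factor`` degradation lifetimes and checks the
    last two snapshots agree to 0.1% in L2; returns the final field (one
    output time).
    """
    mu_min = min(p.mu_s, p.mu_f)
    if mu_min <= 0:
        raise ValidationError("steady state requires positive degradation")
    t_end = horizon_factor / mu_min
    t_out = np.array([0.8 * t_end, t_end])
    fld = solve_two_component(p, x_grid=x_grid, t_out=t_out, rtol=rtol)
    last, prev = fld.rho_total[-1], fld.rho_total[-2]
    drift = np.linalg.norm(last - prev) / max(np.linalg.norm(last), 1e-300)
    if drift > 1e-3:
        raise RuntimeError(
            f"not yet at steady state after {t_end:g}s (drift {drift:.2e})"
        )
    return SimulationField(
        x=fld.x, t=fld.t[-1:], rho_s=fld.rho_s[-1:], rho_f=fld.rho_f[-1:],
        observed=None if fld.observed is None else fld.observed[-1:],
        meta=dict(fld.meta, steady=True),
    )


def maturation_observe(
    field: SimulationField, k_mat: float | None = None
) -> np.ndarray:
    """The mature (bright) fluorophore field of a simulation.

    With maturation off (``k_mat == 0`` or no bright field solved) every
    molecule is visible and the observed field is ``rho_total``.
    """
    if k_mat is not None and k_mat < 0:
        raise ValidationError("k_mat must be >= 0")
    if k_mat == 0 or field.observed is None:
        return field.rho_total
    return field.observed


def distance_from_steady_state(
    field: SimulationField, steady: GradientProfile
) -> np.ndarray:
    """Relative approach to steady state, rho(x,t) / rho_ss(x), per (t, x).

    A value of 1 means the position has reached steady state.  Positions
    where the steady profile vanishes are returned as NaN.
    """
    ss = steady.interp(field.x)
    out = np.full_like(field.rho_total, np.nan)
    ok = ss > 0
    out[:, ok] = field.rho_total[:, ok] / ss[ok]
    return out


#: registry of gradient models: parameter class, transient solver, steady state
MODEL_REGISTRY: dict[str, dict] = {
    "sdd": {
        "params": SDDParams,
        "solve": solve_sdd,
        "steady": sdd_steady_state,
    },
    "two_comp": {
        "params": TwoComponentSDDParams,
        "solve": solve_two_component,
        "steady": two_component_steady_state,
    },
}
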