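"""Fitting gradient models to AP-axis profiles by bootstrap resampling.

The fitting procedure mirrors how noisy inter-embryo profiles are handled in
practice: each bootstrap replicate draws an independent Gaussian profile from
the measured per-position mean and s.d. (truncated at zero), fits the chosen
gradient model to it by Nelder-Mead simplex minimisation of the sum of
squared residuals, and the replicate ensemble yields a mean and s.d. for
every free parameter.  Positive-constrained parameters are searched in log
space.  Decay lengths are extracted by a least-squares line on log intensity
inside a window that excludes the source region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize, stats

from .acf import ValidationError
from .profiles import GradientProfile
from .sdd import (
    MODEL_REGISTRY,
    default_grid,
    maturation_observe,
    sdd_steady_state,
    solve_sdd,
    solve_two_component,
    two_component_steady_state,
)

_PENALTY = 1e30


# ---------------------------------------------------------------------------
# profile pre-processing
# ---------------------------------------------------------------------------

def background_correct(
    profile: GradientProfile,
    method: str = "outside_embryo",
    background: float | GradientProfile = 0.0,
) -> GradientProfile:
    """Subtract background from a raw intensity profile.

    ``outside_embryo``: subtract a scalar background estimated outside the
    embryo (s.d. unchanged).  ``paired_channel``: subtract a paired no-GFP
    channel profile position by position; its s.d. combines in quadrature.
    Corrected means are clipped at zero.
    """
    if method == "outside_embryo":
        if not np.isscalar(background):
            raise ValidationError("outside_embryo expects a scalar background")
        mean = np.clip(profile.mean - float(background), 0.0, None)
        sd = None if profile.sd is None else profile.sd.copy()
    elif method == "paired_channel":
        if not isinstance(background, GradientProfile):
            raise ValidationError("paired_channel expects a background profile")
        if background.x.shape != profile.x.shape or not np.allclose(
            background.x, profile.x
        ):
            raise ValidationError("background grid incompatible with profile")
        mean = np.clip(profile.mean - background.mean, 0.0, None)
        if profile.sd is None:
            sd = None
        elif background.sd is None:
            sd = profile.sd.copy()
        else:
            sd = np.hypot(profile.sd, background.sd)
    else:
        raise ValidationError(f"unknown background method {method!r}")
    return GradientProfile(profile.x.copy(), mean, sd,
                           None if profile.n is None else profile.n.copy(),
                           dict(profile.meta, background=method))


def resample_profile(
    profile: GradientProfile, seed: int | np.random.Generator = 0
) -> GradientProfile:
    """One bootstrap replicate: independent N(mean, sd) draw per position,
    truncated at zero.  With sd identically zero the mean profile returns."""
    if profile.sd is None:
        raise ValidationError("profile has no per-position s.d. to resample")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    draw = rng.normal(profile.mean, profile.sd)
    draw = np.clip(draw, 0.0, None)
    return GradientProfile(profile.x.copy(), draw, profile.sd.copy(),
                           None if profile.n is None else profile.n.copy(),
                           dict(profile.meta, resampled=True))


# ---------------------------------------------------------------------------
# forward evaluation of a registered model
# ---------------------------------------------------------------------------

def _build_params(model_id: str, values: Mapping[str, float]):
    cls = MODEL_REGISTRY[model_id]["params"]
    return cls(**values)


def evaluate_model(
    model_id: str,
    values: Mapping[str, float],
    x_data: np.ndarray,
    fit_time: float | None = 150 * 60.0,
    dx: float = 2.0,
    scale: float = 1.0,
) -> np.ndarray:
    """Simulated observed profile of a registered model at the data positions.

    ``fit_time`` is the developmental time (s, from t=0 at fertilisation) at
    which the profile is read out; ``None`` evaluates the steady state (the
    SDD steady state is analytic, the two-component one is relaxed
    numerically).  ``scale`` is an optional intensity factor absorbing
    arbitrary fluorescence units on top of the production rate.
    """
    p = _build_params(model_id, values)
    if fit_time is None:
        if model_id == "sdd":
            model = sdd_steady_state(p, np.asarray(x_data, float)).mean
        else:
            fld = two_component_steady_state(p, x_grid=default_grid(p.l, dx))
            obs = maturation_observe(fld, p.k_mat)
            model = np.interp(x_data, fld.x, obs[-1])
    else:
        grid = default_grid(p.l, dx)
        t_out = np.array([fit_time])
        if model_id == "sdd":
            fld = solve_sdd(p, x_grid=grid, t_out=t_out)
        else:
            fld = solve_two_component(p, x_grid=grid, t_out=t_out)
        obs = maturation_observe(fld, p.k_mat)
        model = np.interp(x_data, fld.x, obs[-1])
    return scale * model


# ---------------------------------------------------------------------------
# single fit and bootstrap
# ---------------------------------------------------------------------------

@dataclass
class ProfileFitResult:
    model_id: str
    params: dict
    free_names: tuple[str, ...]
    objective: float
    converged: bool
    nfev: int
    seed: int | None = None


@dataclass
class BootstrapFitResult:
    """Per-replicate fitted parameter vectors with mean/s.d. summaries."""

    model_id: str
    replicates: list[ProfileFitResult]
    param_mean: dict = field(default_factory=dict)
    param_sd: dict = field(default_factory=dict)
    flagged: bool = False

    @property
    def n_boot(self) -> int:
        return len(self.replicates)

    @property
    def n_converged(self) -> int:
        return sum(r.converged for r in self.replicates)


def fit_model_to_profile(
    model_id: str,
    profile: GradientProfile,
    free_params: Mapping[str, float],
    fixed_params: Mapping[str, float] | None = None,
    fit_time: float | None = 150 * 60.0,
    dx: float = 2.0,
    log_scale: bool = False,
    maxiter: int = 2000,
    seed: int | None = None,
) -> ProfileFitResult:
    """Fit a registered gradient model to one profile with Nelder-Mead.

    ``free_params`` maps parameter names to initial values (all gradient
    parameters are positive, so the simplex runs on their logarithms);
    ``fixed_params`` are held at the given values.  The objective is the sum
    of squared residuals on linear-scale concentrations (``log_scale=True``
    switches to log concentrations).  A simulation failure during the search
    is replaced by a large penalty rather than aborting.
    """
    if model_id not in MODEL_REGISTRY:
        raise ValidationError(f"unknown model {model_id!r}")
    fixed = dict(fixed_params or {})
    names = tuple(free_params.keys())
    if not names:
        raise ValidationError("need at least one free parameter")
    x0 = np.log([float(free_params[k]) for k in names])
    data = profile.mean
    if log_scale:
        pos = data > 0
        if pos.sum() < 3:
            raise ValidationError("too few positive points for log objective")

    def objective(z: np.ndarray) -> float:
        values = dict(fixed)
        values.update({k: float(np.exp(v)) for k, v in zip(names, z)})
        try:
            model = evaluate_model(model_id, values, profile.x, fit_time, dx)
        except (ValidationError, RuntimeError, OverflowError, TypeError):
            return _PENALTY
        if not np.all(np.isfinite(model)):
            return _PENALTY
        if log_scale:
            m = model[pos]
            if np.any(m <= 0):
                return _PENALTY
            r = np.log(m) - np.log(data[pos])
        else:
            r = model - data
        return float(np.dot(r, r))

    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        # convergence by simplex size: parameters are log-transformed, so
        # xatol 1e-6 is a relative tolerance; no separate objective tolerance
        options={"maxiter": maxiter, "xatol": 1e-6, "fatol": np.inf,
                 "adaptive": len(names) > 2},
    )
    fitted = dict(fixed)
    fitted.update({k: float(np.exp(v)) for k, v in zip(names, res.x)})
    return ProfileFitResult(
        model_id=model_id, params=fitted, free_names=names,
        objective=float(res.fun),
        converged=bool(res.success and res.fun < _PENALTY),
        nfev=int(res.nfev), seed=seed,
    )


def bootstrap_fit(
    model_id: str,
    profile: GradientProfile,
    free_params: Mapping[str, float],
    fixed_params: Mapping[str, float] | None = None,
    n_boot: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> BootstrapFitResult:
    """Resample-and-refit bootstrap (default 100 replicates).

    Each replicate is an independent truncated-Gaussian resampling of the
    profile, fitted from the same initial guess; replicate seeds are spawned
    deterministically from the master ``seed``.  Summaries are computed over
    converged replicates only; the result is flagged when more than 20% of
    replicates fail to converge.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if profile.sd is None:
        raise ValidationError("bootstrap requires a profile with s.d.")
    children = np.random.SeedSequence(seed).spawn(n_boot)
    replicates: list[ProfileFitResult] = []
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rep = resample_profile(profile, np.random.default_rng(child))
        fit = fit_model_to_profile(
            model_id, rep, free_params, fixed_params, seed=rep_seed,
            **fit_kwargs,
        )
        replicates.append(fit)
    good = [r for r in replicates if r.converged]
    names = replicates[0].free_names
    mean: dict = {}
    sd: dict = {}
    if good:
        for k in names:
            vals = np.array([r.params[k] for r in good])
            mean[k] = float(vals.mean())
            sd[k] = float(vals.std(ddof=1)) if len(good) > 1 else 0.0
    flagged = len(good) < 0.8 * n_boot
    return BootstrapFitResult(model_id, replicates, mean, sd, flagged)


# ---------------------------------------------------------------------------
# fit diagnostics
# ---------------------------------------------------------------------------

def fit_precision_profile(
    fitted_profile: GradientProfile, data_profile: GradientProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position relative precision |model - data| / data.

    The model profile is interpolated onto the data positions; positions
    where the data vanish are excluded.  Lower is better.
    """
    model = fitted_profile.interp(data_profile.x)
    ok = data_profile.mean != 0
    x = data_profile.x[ok]
    prec = np.abs(model[ok] - data_profile.mean[ok]) / np.abs(
        data_profile.mean[ok]
    )
    return x, prec


@dataclass(frozen=True)
class DecayFit:
    """Exponential-decay fit A exp(-x/lambda) on a window of the profile."""

    amplitude: float
    lambda_um: float
    window: tuple[float, float]
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.lambda_um <= 0:
            raise ValidationError("decay length must be positive")


def fit_exponential_decay(
    profile: GradientProfile, window: tuple[float, float] = (50.0, 300.0)
) -> DecayFit:
    """Least-squares line on log(mean) against x inside ``window``.

    The default window [50, 300] µm excludes the source region and the flat
    posterior tail; the decay length is -1/slope.  Non-positive values are
    excluded; fewer than 3 usable points is an error.
    """
    x_min, x_max = window
    if x_min >= x_max:
        raise ValidationError("window must be (x_min, x_max) with x_min < x_max")
    mask = (profile.x >= x_min) & (profile.x <= x_max) & (profile.mean > 0)
    if mask.sum() < 3:
        raise ValidationError("fewer than 3 positive points in the window")
    x = profile.x[mask]
    logy = np.log(profile.mean[mask])
    fit = stats.linregress(x, logy)
    if fit.slope >= 0:
        raise ValidationError("profile does not decay inside the window")
    return DecayFit(
        amplitude=float(np.exp(fit.intercept)),
        lambda_um=float(-1.0 / fit.slope),
        window=(float(x_min), float(x_max)),
        r2=float(fit.rvalue**2),
        n_points=int(mask.sum()),
    )
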