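"""Weighted nonlinear ACF fitting, curve averaging and group comparison.

Fitting is weighted least squares (weights 1/g_sd^2 when a per-lag standard
deviation is available) with bound-constrained Levenberg-Marquardt-style
minimisation via lmfit, restarted from several seeded initialisations to
avoid shallow local minima.  Model selection between the one- and
two-component diffusion models follows the reduced chi-square with an
improvement threshold, mirroring the qualitative residual comparison used
when choosing between the models by eye.

Group comparisons use a two-sided permutation test on the difference of
group means, exhaustively enumerated when the number of arrangements is
small and otherwise Monte-Carlo sampled with the add-one (Phipson-Smyth)
convention so the p-value is never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import lmfit
import numpy as np

from .acf import (
    ACFCurve,
    ConcentrationCalibration,
    DiffusionModelParams,
    FocalVolume,
    ValidationError,
    acf_model,
    effective_diffusion,
    estimate_concentration,
    tau_to_diffusion,
)

MODEL_IDS = ("one_comp", "one_comp_triplet", "two_comp", "two_comp_triplet")


@dataclass
class FCSFitResult:
    """Fitted ACF model parameters and derived quantities."""

    params: DiffusionModelParams
    model_id: str
    chi2_red: float
    residuals: np.ndarray
    param_sd: dict = field(default_factory=dict)
    d_values: tuple[float, ...] = ()
    d_eff: float = float("nan")
    conc_nM: float | None = None
    converged: bool = True
    message: str = ""
    at_bound: bool = False
    structure_parameter: float = float("nan")

    @property
    def f_fast(self) -> float:
        return self.params.components[0][0]

    @property
    def d_fast(self) -> float:
        return self.d_values[0]

    @property
    def d_slow(self) -> float:
        return self.d_values[-1]


@dataclass
class GroupSample:
    """A labelled collection of scalar measurements (e.g. D_eff per run)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValidationError("group sample must be non-empty")


# ---------------------------------------------------------------------------
# curve averaging
# ---------------------------------------------------------------------------

def average_curves(curves: Sequence[ACFCurve]) -> ACFCurve:
    """Mean curve with per-lag s.d. across measurements.

    Curves on different lag grids are resampled onto the overlap of the first
    curve's grid by linear interpolation in log lag time.
    """
    if len(curves) == 0:
        raise ValidationError("no curves to average")
    ref = curves[0]
    same_grid = all(
        c.lags.shape == ref.lags.shape and np.allclose(c.lags, ref.lags)
        for c in curves
    )
    if same_grid:
        lags = ref.lags.copy()
        stack = np.vstack([c.g for c in curves])
    else:
        lo = max(c.lags[0] for c in curves)
        hi = min(c.lags[-1] for c in curves)
        if lo >= hi:
            raise ValidationError("curves have no overlapping lag range")
        mask = (ref.lags >= lo) & (ref.lags <= hi)
        lags = ref.lags[mask]
        loglags = np.log(lags)
        stack = np.vstack(
            [np.interp(loglags, np.log(c.lags), c.g) for c in curves]
        )
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    meta = dict(ref.meta)
    meta["n_averaged"] = len(curves)
    return ACFCurve(lags, mean, sd, meta)


# ---------------------------------------------------------------------------
# ACF fitting
# ---------------------------------------------------------------------------

def _initial_guess(curve: ACFCurve, model_id: str) -> dict:
    g0 = float(np.max(curve.g[: max(3, curve.g.size // 50)]))
    g0 = max(g0, 1e-12)
    n0 = 1.0 / g0
    half = g0 / 2.0
    below = np.nonzero(curve.g <= half)[0]
    tau_half = float(curve.lags[below[0]]) if below.size else float(
        curve.lags[curve.lags.size // 2]
    )
    init = {"n_mol": n0, "t_frac": 0.12, "tau_trip": 3e-6}
    if model_id.startswith("two"):
        init.update(
            f_fast=0.7, tau_fast=tau_half / 5.0, tau_slow=tau_half * 20.0
        )
    else:
        init.update(tau_d=tau_half)
    return init


def _make_params(
    model_id: str,
    init: dict,
    fit_structure_parameter: bool,
    k: float,
) -> lmfit.Parameters:
    p = lmfit.Parameters()
    p.add("n_mol", value=init["n_mol"], min=1e-8, max=1e8)
    triplet = model_id.endswith("triplet")
    p.add("t_frac", value=init["t_frac"] if triplet else 0.0,
          min=0.0, max=0.6, vary=triplet)
    p.add("tau_trip", value=init["tau_trip"], min=1e-8, max=1e-3, vary=triplet)
    if model_id.startswith("two"):
        p.add("f_fast", value=init["f_fast"], min=0.01, max=0.99)
        p.add("tau_fast", value=init["tau_fast"], min=1e-8, max=10.0)
        p.add("tau_slow", value=init["tau_slow"], min=1e-8, max=10.0)
    else:
        p.add("tau_d", value=init["tau_d"], min=1e-8, max=10.0)
    p.add("k_struct", value=k, min=1.0, max=20.0, vary=fit_structure_parameter)
    return p


def _params_to_model(v: dict, model_id: str) -> DiffusionModelParams:
    if model_id.startswith("two"):
        comps = ((v["f_fast"], v["tau_fast"]), (1.0 - v["f_fast"], v["tau_slow"]))
        comps = tuple(sorted(comps, key=lambda c: c[1]))
    else:
        comps = ((1.0, v["tau_d"]),)
    return DiffusionModelParams(
        n_mol=v["n_mol"],
        components=comps,
        t_frac=v["t_frac"],
        tau_trip=v["tau_trip"],
    )


def fit_acf(
    curve: ACFCurve,
    model_id: str = "two_comp_triplet",
    vol: FocalVolume | None = None,
    init: DiffusionModelParams | None = None,
    n_restarts: int = 10,
    seed: int = 0,
    fit_structure_parameter: bool = False,
    calibration: ConcentrationCalibration | None = None,
) -> FCSFitResult:
    """Fit a diffusion model to one ACF curve.

    The structure parameter K is fixed at its calibration value by default
    (``fit_structure_parameter=False``), which is standard practice and
    avoids degeneracy in two-component fits.  ``n_restarts`` seeded
    multi-starts perturb the initial guess in log space; the best reduced
    chi-square wins.  With ``calibration`` given, the fitted molecule number
    is converted to a concentration in nM.
    """
    if model_id not in MODEL_IDS:
        raise ValidationError(f"unknown model_id {model_id!r}; use {MODEL_IDS}")
    if vol is None:
        vol = FocalVolume(w_xy=0.2, k=5.0)
    weights = None
    if curve.g_sd is not None and np.all(curve.g_sd > 0):
        weights = 1.0 / curve.g_sd

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        v = pars.valuesdict()
        p = _params_to_model(v, model_id)
        model = acf_model(curve.lags, p, FocalVolume(vol.w_xy, v["k_struct"]))
        r = model - curve.g
        return r * weights if weights is not None else r

    if init is not None:
        guess = {"n_mol": init.n_mol, "t_frac": max(init.t_frac, 0.01),
                 "tau_trip": init.tau_trip}
        comps = init.sorted_fast_first().components
        if model_id.startswith("two") and len(comps) == 2:
            guess.update(f_fast=comps[0][0], tau_fast=comps[0][1],
                         tau_slow=comps[1][1])
        else:
            guess.update(tau_d=comps[0][1])
            if model_id.startswith("two"):
                guess.update(f_fast=0.7, tau_fast=comps[0][1] / 5.0,
                             tau_slow=comps[0][1] * 20.0)
    else:
        guess = _initial_guess(curve, model_id)

    rng = np.random.default_rng(seed)
    best = None
    message = ""
    for trial in range(max(1, n_restarts)):
        g = dict(guess)
        if trial > 0:  # log-space jitter around the base guess
            for key in ("n_mol", "tau_trip", "tau_fast", "tau_slow", "tau_d"):
                if key in g:
                    g[key] = g[key] * math.exp(rng.normal(0.0, 0.7))
            if "f_fast" in g:
                g["f_fast"] = float(np.clip(g["f_fast"] + rng.normal(0, 0.15),
                                            0.05, 0.95))
            g["t_frac"] = float(np.clip(g["t_frac"] + rng.normal(0, 0.05),
                                        0.01, 0.5))
        pars = _make_params(model_id, g, fit_structure_parameter, vol.k)
        try:
            out = lmfit.minimize(residual, pars, method="least_squares")
        except Exception as exc:  # noqa: BLE001 - keep searching other starts
            message = str(exc)
            continue
        if best is None or out.chisqr < best.chisqr - 1e-15:
            best = out

    if best is None:
        dummy = DiffusionModelParams(1.0, ((1.0, 1e-3),))
        return FCSFitResult(
            params=dummy, model_id=model_id, chi2_red=float("inf"),
            residuals=np.full_like(curve.g, np.nan), converged=False,
            message=f"all restarts failed: {message}",
        )

    v = best.params.valuesdict()
    fitted = _params_to_model(v, model_id).sorted_fast_first()
    vol_out = FocalVolume(vol.w_xy, v["k_struct"])
    d_values = tuple(tau_to_diffusion(t, vol_out) for _, t in fitted.components)
    if fitted.n_components == 2:
        d_eff = effective_diffusion(fitted.components[0][0], d_values[0],
                                    d_values[1])
    else:
        d_eff = d_values[0]
    n = curve.g.size
    chi2_red = best.chisqr / max(n - best.nvarys, 1)
    param_sd = {
        name: (par.stderr if par.stderr is not None else float("nan"))
        for name, par in best.params.items() if par.vary
    }
    at_bound = False
    if model_id.startswith("two"):
        at_bound = not (0.011 < v["f_fast"] < 0.989)
    conc = (estimate_concentration(calibration, fitted.n_mol)
            if calibration is not None else None)
    return FCSFitResult(
        params=fitted,
        model_id=model_id,
        chi2_red=float(chi2_red),
        residuals=np.asarray(best.residual, dtype=float),
        param_sd=param_sd,
        d_values=d_values,
        d_eff=float(d_eff),
        conc_nM=conc,
        converged=bool(best.success),
        message=best.message or "",
        at_bound=at_bound,
        structure_parameter=float(v["k_struct"]),
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    fits: dict[str, FCSFitResult]
    preferred: str
    improvement: float
    residual_lag1: dict[str, float]


def _lag1_autocorr(r: np.ndarray) -> float:
    r = r - r.mean()
    denom = float(np.dot(r, r))
    if denom == 0:
        return 0.0
    return float(np.dot(r[:-1], r[1:]) / denom)


def compare_models(
    curve: ACFCurve,
    vol: FocalVolume | None = None,
    triplet: bool = True,
    improvement_threshold: float = 0.05,
    min_fraction: float = 0.05,
    seed: int = 0,
) -> ModelComparison:
    """Fit one- and two-component models and pick the preferred one.

    The two-component model is preferred only when its reduced chi-square
    improves on the one-component fit by more than ``improvement_threshold``
    (fractionally) and both fitted fractions exceed ``min_fraction``;
    otherwise the simpler model wins.  Structured residuals show up in the
    lag-1 residual autocorrelation diagnostic.
    """
    suffix = "_triplet" if triplet else ""
    one = fit_acf(curve, "one_comp" + suffix, vol, seed=seed)
    two = fit_acf(curve, "two_comp" + suffix, vol, seed=seed)
    fits = {"one_comp": one, "two_comp": two}
    lag1 = {k: _lag1_autocorr(f.residuals) for k, f in fits.items()}
    preferred = "one_comp"
    improvement = 0.0
    if one.converged and two.converged and one.chi2_red > 0:
        improvement = (one.chi2_red - two.chi2_red) / one.chi2_red
        f_fast = two.params.components[0][0]
        fractions_ok = min(f_fast, 1.0 - f_fast) > min_fraction
        if improvement > improvement_threshold and fractions_ok:
            preferred = "two_comp"
    elif two.converged and not one.converged:
        preferred = "two_comp"
    return ModelComparison(fits, preferred, improvement, lag1)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    a: GroupSample | Sequence[float],
    b: GroupSample | Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided permutation test on the difference of group means.

    When the number of distinct arrangements C(n_a+n_b, n_a) does not exceed
    ``n_perm`` the null distribution is enumerated exhaustively and the
    p-value is the exact proportion of arrangements at least as extreme as
    the observed split.  Otherwise ``n_perm`` random permutations are drawn
    and p = (1 + #{|delta_perm| >= |delta_obs|}) / (n_perm + 1).
    """
    xa = a.values if isinstance(a, GroupSample) else np.asarray(a, float).ravel()
    xb = b.values if isinstance(b, GroupSample) else np.asarray(b, float).ravel()
    if xa.size == 0 or xb.size == 0:
        raise ValidationError("both groups must be non-empty")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    pooled = np.concatenate([xa, xb])
    if np.all(pooled == pooled[0]):
        return 1.0
    na, n = xa.size, pooled.size
    obs = abs(xa.mean() - xb.mean())
    tol = 1e-12 * max(1.0, obs)
    total = math.comb(n, na)
    pooled_sum = pooled.sum()

    def delta_from_sum_a(sum_a: float) -> float:
        return abs(sum_a / na - (pooled_sum - sum_a) / (n - na))

    if total <= n_perm:
        count = 0
        for idx in combinations(range(n), na):
            if delta_from_sum_a(pooled[list(idx)].sum()) >= obs - tol:
                count += 1
        return count / total

    rng = np.random.default_rng(seed)
    # vectorised random permutations: argsort of uniform draws
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    sums_a = pooled[order[:, :na]].sum(axis=1)
    deltas = np.abs(sums_a / na - (pooled_sum - sums_a) / (n - na))
    count = int(np.count_nonzero(deltas >= obs - tol))
    return (1 + count) / (n_perm + 1)
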