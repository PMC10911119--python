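"""Closed-form confocal FCS autocorrelation models and calibration.

The measured quantity in fluorescence correlation spectroscopy is the
normalised intensity autocorrelation G(tau).  For free 3D diffusion of one or
two species through a 3D-Gaussian confocal detection volume, with optional
reversible shelving of the fluorophore in a dark (triplet) state, the model is

    G(tau) = (1/N) * [1 + T/(1-T) * exp(-tau/tau_T)]
                 * sum_i f_i * (1 + tau/tau_Di)^-1 * (1 + tau/(K^2 tau_Di))^-1/2

where N is the mean number of molecules in the effective volume, T the triplet
fraction, tau_T its relaxation time, f_i the molar fraction of species i,
tau_Di its lateral diffusion time and K the structure parameter (axial over
lateral 1/e^2 radius).  The triplet prefactor is the normalised convention, so
G(0) = 1 / (N (1 - T)).

Diffusion times convert to diffusion coefficients through the lateral beam
waist: D = w_xy^2 / (4 tau_D).  Concentrations follow from N via a standard
curve of known concentrations against fitted molecule numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats


class ValidationError(ValueError):
    """Raised when a curve or parameter set violates its invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_COMPARTMENTS = {"nucleus", "cytoplasm", "unknown"}
_REGIONS = {"anterior", "posterior", "unknown"}


@dataclass
class ACFCurve:
    """One FCS measurement: lag times (s) and correlation amplitudes.

    ``g_sd`` is the optional per-lag standard deviation (present on averaged
    curves).  ``meta`` carries compartment/region/genotype/cycle/duration.
    """

    lags: np.ndarray
    g: np.ndarray
    g_sd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.g_sd is not None:
            self.g_sd = np.asarray(self.g_sd, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.lags.ndim != 1 or self.lags.size == 0:
            raise ValidationError("lags must be a non-empty 1-D array")
        if self.lags.shape != self.g.shape:
            raise ValidationError("lags and g must have equal length")
        if not np.all(self.lags > 0):
            raise ValidationError("lags must be strictly positive")
        if not np.all(np.diff(self.lags) > 0):
            raise ValidationError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValidationError("g must be finite")
        if self.g_sd is not None:
            if self.g_sd.shape != self.g.shape:
                raise ValidationError("g_sd must match g in length")
            if not np.all(self.g_sd >= 0):
                raise ValidationError("g_sd must be non-negative")
        comp = self.meta.get("compartment")
        if comp is not None and comp not in _COMPARTMENTS:
            raise ValidationError(f"unknown compartment {comp!r}")
        reg = self.meta.get("region")
        if reg is not None and reg not in _REGIONS:
            raise ValidationError(f"unknown region {reg!r}")


@dataclass(frozen=True)
class FocalVolume:
    """Confocal detection volume: lateral 1/e^2 radius w_xy (µm) and K."""

    w_xy: float
    k: float = 5.0

    def __post_init__(self) -> None:
        if self.w_xy <= 0:
            raise ValidationError("w_xy must be positive")
        if self.k <= 0:
            raise ValidationError("structure parameter K must be positive")

    @property
    def v_eff(self) -> float:
        """Effective volume pi^{3/2} w_xy^3 K in µm^3."""
        return math.pi ** 1.5 * self.w_xy ** 3 * self.k


@dataclass(frozen=True)
class DiffusionModelParams:
    """Parameters of the 1- or 2-component triplet diffusion model.

    ``components`` is a tuple of (fraction, diffusion time in s), ordered
    fast-first (smallest tau_D first).  Fractions must sum to 1.
    """

    n_mol: float
    components: tuple[tuple[float, float], ...]
    t_frac: float = 0.0
    tau_trip: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_mol <= 0:
            raise ValidationError("n_mol must be positive")
        if not (0 <= self.t_frac < 1):
            raise ValidationError("triplet fraction must be in [0, 1)")
        if self.tau_trip <= 0:
            raise ValidationError("tau_trip must be positive")
        if len(self.components) not in (1, 2):
            raise ValidationError("1 or 2 diffusive components supported")
        fracs = [f for f, _ in self.components]
        taus = [t for _, t in self.components]
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValidationError("component fractions must be in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError("component fractions must sum to 1")
        if any(t <= 0 for t in taus):
            raise ValidationError("diffusion times must be positive")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def sorted_fast_first(self) -> "DiffusionModelParams":
        comps = tuple(sorted(self.components, key=lambda c: c[1]))
        return replace(self, components=comps)


@dataclass(frozen=True)
class ConcentrationCalibration:
    """Linear standard curve: n_mol = slope * conc_nM + intercept."""

    slope: float
    intercept: float
    source: str = ""
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("calibration slope must be positive")


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def acf_model(
    lags: np.ndarray | Sequence[float],
    p: DiffusionModelParams,
    vol: FocalVolume,
) -> np.ndarray:
    """Evaluate the triplet 3D-diffusion ACF model at the given lags (s)."""
    tau = np.asarray(lags, dtype=float)
    if tau.size == 0 or not np.all(tau > 0):
        raise ValidationError("lags must be positive")
    diff = np.zeros_like(tau)
    for f, tau_d in p.components:
        diff += f / ((1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (vol.k**2 * tau_d)))
    trip = 1.0
    if p.t_frac > 0:
        trip = 1.0 + p.t_frac / (1.0 - p.t_frac) * np.exp(-tau / p.tau_trip)
    return trip * diff / p.n_mol


def normalize_acf(
    curve: ACFCurve, lag0: float = 1e-4, lag_inf: float = 1.0
) -> ACFCurve:
    """Normalise a curve as (G(tau) - G(inf)) / (G(0) - G(inf)).

    G(0) and G(inf) are read at the lags nearest ``lag0`` and ``lag_inf``
    (conventionally 1e-4 s and 1 s).  The result is 1 at ``lag0`` and 0 at
    ``lag_inf`` and is invariant under affine rescaling of the amplitudes.
    """
    if lag0 >= lag_inf:
        raise ValidationError("lag0 must be smaller than lag_inf")
    if lag0 < curve.lags[0] or lag_inf > curve.lags[-1]:
        raise ValidationError(
            f"curve spans [{curve.lags[0]:g}, {curve.lags[-1]:g}] s; "
            f"cannot normalise at {lag0:g}/{lag_inf:g} s"
        )
    i0 = int(np.argmin(np.abs(curve.lags - lag0)))
    i1 = int(np.argmin(np.abs(curve.lags - lag_inf)))
    g0, ginf = curve.g[i0], curve.g[i1]
    span = g0 - ginf
    if span == 0:
        raise ValidationError("G(0) equals G(inf); cannot normalise flat curve")
    g = (curve.g - ginf) / span
    g_sd = curve.g_sd / abs(span) if curve.g_sd is not None else None
    return ACFCurve(curve.lags.copy(), g, g_sd, dict(curve.meta))


def tau_to_diffusion(tau_d: float, vol: FocalVolume) -> float:
    """Diffusion coefficient D = w_xy^2 / (4 tau_D), in µm^2/s."""
    if tau_d <= 0:
        raise ValidationError("tau_d must be positive")
    return vol.w_xy**2 / (4.0 * tau_d)


def diffusion_to_tau(d: float, vol: FocalVolume) -> float:
    """Inverse of :func:`tau_to_diffusion`: tau_D = w_xy^2 / (4 D)."""
    if d <= 0:
        raise ValidationError("D must be positive")
    return vol.w_xy**2 / (4.0 * d)


def effective_diffusion(f_fast: float, d_fast: float, d_slow: float) -> float:
    """Fraction-weighted effective diffusion D_eff = f D_fast + (1-f) D_slow."""
    if not (0 <= f_fast <= 1):
        raise ValidationError("f_fast must be in [0, 1]")
    if d_fast < d_slow or d_slow < 0:
        raise ValidationError("require d_fast >= d_slow >= 0")
    return f_fast * d_fast + (1.0 - f_fast) * d_slow


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

#: literature free-diffusion coefficient of Atto-488 in water at 25 °C
ATTO488_D = 400.0  # µm^2/s


def calibrate_focal_volume(
    dye_curves: Sequence[ACFCurve],
    d_known: float = ATTO488_D,
    k: float | None = None,
) -> FocalVolume:
    """Calibrate the focal volume from dye curves of known diffusivity.

    The averaged dye curve is fitted with a one-component model (triplet
    included); the fitted diffusion time gives w_xy = sqrt(4 D_known tau_D).
    ``k`` fixes the structure parameter; when None it is floated in the fit.
    """
    # local import: fcs_fit depends on this module
    from .fitting import average_curves, fit_acf

    if len(dye_curves) == 0:
        raise ValidationError("need at least one dye curve")
    if d_known <= 0:
        raise ValidationError("d_known must be positive")
    curve = average_curves(dye_curves) if len(dye_curves) > 1 else dye_curves[0]
    # fit with a provisional volume; only tau_d and optionally K matter here
    provisional = FocalVolume(w_xy=0.2, k=k if k is not None else 5.0)
    res = fit_acf(
        curve,
        model_id="one_comp_triplet",
        vol=provisional,
        fit_structure_parameter=(k is None),
    )
    if not res.converged:
        raise RuntimeError(f"dye-curve fit failed: {res.message}")
    tau_d = res.params.components[0][1]
    k_out = res.structure_parameter if k is None else k
    return FocalVolume(w_xy=math.sqrt(4.0 * d_known * tau_d), k=k_out)


def fit_standard_curve(
    points: Sequence[tuple[float, float]], source: str = ""
) -> ConcentrationCalibration:
    """Ordinary least-squares line of molecule number against concentration.

    ``points`` are (concentration in nM, fitted n_mol) pairs, e.g. from a
    dilution series of dye or purified eGFP.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or len(np.unique(pts[:, 0])) < 2:
        raise ValidationError("need >= 2 points with distinct concentrations")
    fit = stats.linregress(pts[:, 0], pts[:, 1])
    return ConcentrationCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        source=source,
        r2=float(fit.rvalue**2),
    )


def estimate_concentration(cal: ConcentrationCalibration, n_mol: float) -> float:
    """Invert the standard curve: concentration (nM) for a molecule number."""
    return (n_mol - cal.intercept) / cal.slope
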