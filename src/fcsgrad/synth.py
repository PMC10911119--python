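"""Synthetic FCS curves and gradient profiles for every pipeline input.

Presets transcribe the measured two-component diffusion parameters of
eGFP-tagged Bicoid and its control/mutant constructs in the early embryo:
fast and slow diffusion coefficients, the fast fraction, and a typical
molecule number per focal volume (higher in the anterior, lower in the
posterior where the signal is dimmer).  Where only a range was measured the
preset takes the midpoint and records the range in its metadata.

Noise on ACF curves is multiplicative Gaussian with a relative scale that
may decay with lag time; profile noise emulates inter-embryo variability as
independent multiplicative Gaussian perturbations of the simulated profile,
averaged over a small number of embryos.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .acf import (
    ACFCurve,
    DiffusionModelParams,
    FocalVolume,
    ValidationError,
    acf_model,
    diffusion_to_tau,
    effective_diffusion,
)
from .profiles import GradientProfile
from .profilefit import evaluate_model
from .sdd import MU_DEFAULT, SDDParams, TwoComponentSDDParams


@dataclass(frozen=True)
class ACFPreset:
    """Two-component diffusion parameters for one genotype/compartment/region."""

    label: str
    d_fast: float
    d_slow: float
    f_fast: float
    n_mol: float = 10.0
    t_frac: float = 0.15
    tau_trip: float = 4e-6
    meta: Mapping[str, object] = field(default_factory=dict)

    def to_params(self, vol: FocalVolume) -> DiffusionModelParams:
        """Convert diffusivities to diffusion times through a focal volume."""
        comps = (
            (self.f_fast, diffusion_to_tau(self.d_fast, vol)),
            (1.0 - self.f_fast, diffusion_to_tau(self.d_slow, vol)),
        )
        return DiffusionModelParams(
            n_mol=self.n_mol, components=comps,
            t_frac=self.t_frac, tau_trip=self.tau_trip,
        )

    @property
    def d_eff(self) -> float:
        return effective_diffusion(self.f_fast, self.d_fast, self.d_slow)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian ACF noise.

    ``scale`` is the relative s.d. at the shortest lag; ``lag_exponent``
    makes the relative noise decay as (lag/min_lag)^(-lag_exponent/2).
    """

    kind: str = "multiplicative_gaussian"
    scale: float = 0.02
    lag_exponent: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative_gaussian"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValidationError("noise scale must be >= 0")


_PRESETS: tuple[ACFPreset, ...] = (
    # wild-type Bcd: fast cytoplasmic mode speeds up towards the posterior,
    # the slow mode (~FRAP-scale) is uniform
    ACFPreset("bcd/cytoplasm/anterior", 13.0, 1.0, 0.65, n_mol=20,
              meta={"d_fast_sd": 2.6, "f_fast_sd": 0.08}),
    ACFPreset("bcd/cytoplasm/posterior", 18.8, 1.0, 0.78, n_mol=4,
              meta={"d_fast_sd": 2.5, "f_fast_sd": 0.06}),
    ACFPreset("bcd/nucleus/anterior", 9.0, 0.25, 0.55, n_mol=25,
              meta={"d_slow_range": (0.2, 0.3), "d_eff_range": (4, 6)}),
    ACFPreset("bcd/nucleus/posterior", 12.0, 0.25, 0.70, n_mol=5,
              meta={"d_slow_range": (0.2, 0.3), "d_eff_range": (7, 10)}),
    # eGFP::NLS control: mostly fast everywhere
    ACFPreset("nls/cytoplasm/anterior", 20.0, 1.0, 0.875, n_mol=30,
              meta={"f_fast_range": (0.80, 0.95)}),
    ACFPreset("nls/cytoplasm/posterior", 20.0, 1.0, 0.95, n_mol=8,
              meta={"f_fast_range": (0.80, 0.95)}),
    ACFPreset("nls/nucleus/anterior", 15.0, 0.5, 0.80, n_mol=40,
              meta={"slow_fraction_note": "~20% slow in anterior nuclei"}),
    ACFPreset("nls/nucleus/posterior", 15.0, 0.5, 0.95, n_mol=10),
    # NLS + Bcd homeodomain: ~50/50 split, slowed ~2.5-fold relative to NLS
    ACFPreset("nlsbcdhd/cytoplasm/anterior", 8.0, 1.0, 0.50, n_mol=25),
    ACFPreset("nlsbcdhd/cytoplasm/posterior", 8.0, 1.0, 0.50, n_mol=6),
    ACFPreset("nlsbcdhd/nucleus/anterior", 6.0, 0.5, 0.50, n_mol=30),
    ACFPreset("nlsbcdhd/nucleus/posterior", 6.0, 0.5, 0.50, n_mol=8),
    # DNA-binding mutant N51A: cytoplasm unchanged, nuclei faster
    ACFPreset("bcd_n51a/cytoplasm/anterior", 13.0, 1.0, 0.65, n_mol=20),
    ACFPreset("bcd_n51a/cytoplasm/posterior", 18.8, 1.0, 0.78, n_mol=4),
    ACFPreset("bcd_n51a/nucleus/anterior", 11.0, 1.0, 0.70, n_mol=25,
              meta={"d_eff_range": (7, 9)}),
    ACFPreset("bcd_n51a/nucleus/posterior", 14.0, 1.0, 0.77, n_mol=5,
              meta={"d_eff_range": (9, 13)}),
)


def preset_registry() -> dict[str, ACFPreset]:
    """All presets keyed by ``genotype/compartment/region`` label."""
    return {p.label: p for p in _PRESETS}


def get_preset(label: str) -> ACFPreset:
    reg = preset_registry()
    if label not in reg:
        raise ValidationError(
            f"unknown preset {label!r}; available: {sorted(reg)}"
        )
    return reg[label]


def default_lags(n: int = 200, lo: float = 1e-6, hi: float = 1.0) -> np.ndarray:
    """Log-spaced lag grid (s) covering triplet through diffusive decays."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def generate_acf(
    preset: ACFPreset | str,
    vol: FocalVolume | None = None,
    lags: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> ACFCurve:
    """Generate one (optionally noisy) ACF curve from a preset.

    With ``noise=None`` or kind "none" the curve equals the closed-form
    model exactly; otherwise each amplitude is perturbed multiplicatively by
    seeded Gaussian noise, and the per-lag noise s.d. is attached as
    ``g_sd``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if vol is None:
        vol = FocalVolume(w_xy=0.2, k=5.0)
    if lags is None:
        lags = default_lags()
    params = preset.to_params(vol)
    g = acf_model(lags, params, vol)
    genotype, compartment, region = (preset.label.split("/") + ["unknown"] * 3)[:3]
    meta = {
        "preset": preset.label, "genotype": genotype,
        "compartment": compartment, "region": region,
        "d_fast": preset.d_fast, "d_slow": preset.d_slow,
        "f_fast": preset.f_fast,
    }
    if noise is None or noise.kind == "none" or noise.scale == 0:
        return ACFCurve(np.asarray(lags, float), g, None, meta)
    rng = np.random.default_rng(noise.seed)
    rel = noise.scale * (np.asarray(lags) / lags[0]) ** (-noise.lag_exponent / 2)
    sigma = rel * np.abs(g)
    noisy = g * (1.0 + rel * rng.standard_normal(g.shape))
    meta["noise_scale"] = noise.scale
    return ACFCurve(np.asarray(lags, float), noisy, sigma, meta)


# ---------------------------------------------------------------------------
# gradient-model parameter presets and profile generation
# ---------------------------------------------------------------------------

def bcd_two_component_params(**overrides) -> TwoComponentSDDParams:
    """Default Bcd-like two-component gradient parameters.

    Diffusivities are the measured cytoplasmic values (fast 13.0 -> 18.8
    µm²/s anterior to posterior, slow 1.0 µm²/s throughout); both species
    degrade at 1/(50 min).  The exchange rates are set so that at local
    kinetic equilibrium the fast fraction is ~65% at the anterior
    measurement region (x ~ 50 µm) and ~78% at the posterior one (x ~ 450
    µm): alpha = 0.02 1/s, a saturating fast-to-slow rate with beta0 = 0.013
    1/s, and rho0 = 82 placed between the anterior and posterior
    concentration scales of the steady profile at j = 1.
    """
    defaults = dict(
        d_f_ant=13.0, d_f_post=18.8, d_s_ant=1.0, d_s_post=1.0,
        beta0=0.013, rho0=82.0, alpha=0.02,
        mu_s=MU_DEFAULT, mu_f=MU_DEFAULT,
        j=1.0, x_s=30.0, l=500.0, k_mat=0.0,
    )
    defaults.update(overrides)
    return TwoComponentSDDParams(**defaults)


def matched_sdd_params(
    two: TwoComponentSDDParams | None = None, d: float | None = None, **overrides
) -> SDDParams:
    """Single-species SDD parameters matched to a two-component set.

    ``d`` defaults to the anterior effective diffusion coefficient of the
    wild-type cytoplasmic presets (f_fast*D_fast + f_slow*D_slow = 8.8
    µm²/s).
    """
    if two is None:
        two = bcd_two_component_params()
    if d is None:
        ant = get_preset("bcd/cytoplasm/anterior")
        d = ant.d_eff
    defaults = dict(d=d, mu=two.mu_f, j=two.j, x_s=two.x_s, l=two.l,
                    k_mat=two.k_mat)
    defaults.update(overrides)
    return SDDParams(**defaults)


def _params_to_values(params) -> dict:
    if dataclasses.is_dataclass(params) and not isinstance(params, type):
        return dataclasses.asdict(params)
    return dict(params)


def generate_profile(
    model_id: str,
    params,
    noise_rel: float = 0.1,
    n_embryos: int = 3,
    seed: int = 0,
    x_data: np.ndarray | None = None,
    fit_time: float | None = 150 * 60.0,
    dx: float = 2.0,
) -> GradientProfile:
    """Simulate a gradient and emulate an n-embryo mean +/- s.d. profile.

    ``params`` is a model parameter dataclass or mapping for the registered
    ``model_id``.  Each synthetic embryo multiplies the simulated profile by
    independent per-position Gaussian factors (1 + noise_rel * N(0,1)),
    truncated at zero; the returned profile is their per-position mean and
    s.d.  ``noise_rel=0`` returns the simulation exactly with zero s.d.
    """
    if n_embryos < 1:
        raise ValidationError("n_embryos must be >= 1")
    if noise_rel < 0:
        raise ValidationError("noise_rel must be >= 0")
    values = _params_to_values(params)
    if x_data is None:
        x_data = np.arange(10.0, values.get("l", 500.0), 10.0)
    base = evaluate_model(model_id, values, x_data, fit_time=fit_time, dx=dx)
    if noise_rel == 0:
        return GradientProfile(
            x_data, base, np.zeros_like(base),
            np.full(base.shape, n_embryos),
            {"model": model_id, "noise_rel": 0.0},
        )
    rng = np.random.default_rng(seed)
    embryos = base * (1.0 + noise_rel * rng.standard_normal((n_embryos,
                                                             base.size)))
    embryos = np.clip(embryos, 0.0, None)
    mean = embryos.mean(axis=0)
    sd = embryos.std(axis=0, ddof=1) if n_embryos > 1 else np.zeros_like(mean)
    return GradientProfile(
        x_data, mean, sd, np.full(mean.shape, n_embryos),
        {"model": model_id, "noise_rel": noise_rel, "seed": seed},
    )
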