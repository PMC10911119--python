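"""CSV and config I/O.

ACF curves travel as CSV with columns ``lag_s, g[, g_sd]`` and metadata in
``# key: value`` comment lines at the top of the file; gradient profiles as
``x_um, mean, sd, n``.  Units are part of the header names and are never
silently coerced.  Run configuration is flat INI (key = value under
``[model]``, ``[params]`` and ``[fit]`` sections).
"""

from __future__ import annotations

import configparser
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acf import ACFCurve, ValidationError
from .profiles import GradientProfile
from .sdd import MODEL_REGISTRY

_META_KEYS = ("compartment", "region", "genotype", "cycle", "duration_s")


def _read_comment_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    for key in ("duration_s",):
        if key in meta:
            meta[key] = float(meta[key])
    if "cycle" in meta and meta["cycle"] != "unknown":
        meta["cycle"] = int(meta["cycle"])
    return meta


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no data rows")


def _check_increasing(values: np.ndarray, column: str, path) -> None:
    bad = np.nonzero(np.diff(values) <= 0)[0]
    if bad.size:
        row = int(bad[0]) + 2  # 1-based, counting the prior row
        raise ValidationError(
            f"{path}: column {column!r} not strictly increasing at data row {row}"
        )


def read_acf_csv(path: str | Path) -> ACFCurve:
    """Read one ACF curve; ``# key: value`` header lines become metadata."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ("lag_s", "g"), path)
    lags = df["lag_s"].to_numpy(float)
    if np.any(lags <= 0):
        row = int(np.nonzero(lags <= 0)[0][0]) + 2
        raise ValidationError(f"{path}: non-positive lag_s at data row {row}")
    _check_increasing(lags, "lag_s", path)
    g_sd = df["g_sd"].to_numpy(float) if "g_sd" in df.columns else None
    if g_sd is not None and np.any(g_sd < 0):
        row = int(np.nonzero(g_sd < 0)[0][0]) + 2
        raise ValidationError(f"{path}: negative g_sd at data row {row}")
    return ACFCurve(lags, df["g"].to_numpy(float), g_sd,
                    _read_comment_meta(path))


def write_acf_csv(curve: ACFCurve, path: str | Path) -> None:
    path = Path(path)
    cols = {"lag_s": curve.lags, "g": curve.g}
    if curve.g_sd is not None:
        cols["g_sd"] = curve.g_sd
    with open(path, "w") as fh:
        for key in _META_KEYS:
            if key in curve.meta:
                fh.write(f"# {key}: {curve.meta[key]}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")


def read_profile_csv(path: str | Path) -> GradientProfile:
    """Read an AP-axis profile (columns x_um, mean[, sd, n])."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    _require_columns(df, ("x_um", "mean"), path)
    x = df["x_um"].to_numpy(float)
    _check_increasing(x, "x_um", path)
    sd = df["sd"].to_numpy(float) if "sd" in df.columns else None
    if sd is not None and np.any(sd < 0):
        row = int(np.nonzero(sd < 0)[0][0]) + 2
        raise ValidationError(f"{path}: negative sd at data row {row}")
    n = df["n"].to_numpy() if "n" in df.columns else None
    return GradientProfile(x, df["mean"].to_numpy(float), sd, n,
                           _read_comment_meta(path))


def write_profile_csv(profile: GradientProfile, path: str | Path) -> None:
    path = Path(path)
    cols = {"x_um": profile.x, "mean": profile.mean}
    if profile.sd is not None:
        cols["sd"] = profile.sd
    if profile.n is not None:
        cols["n"] = profile.n
    with open(path, "w") as fh:
        for key, value in profile.meta.items():
            if isinstance(value, (str, int, float)):
                fh.write(f"# {key}: {value}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")


def write_field_csv(field, path: str | Path) -> None:
    """Write a SimulationField in long format (x, t, rho_s, rho_f, observed)."""
    nt, nx = field.rho_f.shape
    rows = {
        "t_s": np.repeat(field.t, nx),
        "x_um": np.tile(field.x, nt),
        "rho_f": field.rho_f.ravel(),
        "rho_s": field.rho_s.ravel(),
    }
    if field.observed is not None:
        rows["observed"] = field.observed.ravel()
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parsed INI configuration for a simulation or gradient fit."""

    model_id: str
    params: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    path: Path | None = None

    @property
    def config_hash(self) -> str:
        """Hash of the raw config file, for run logging."""
        if self.path is None:
            return "none"
        return hashlib.sha256(self.path.read_bytes()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat INI config.

    Required: ``[model] id``; ``[params]`` keys must be accepted by the
    model's parameter class (validated by constructing it); ``[fit]`` keys
    are passed through (``free`` is a comma-separated list of parameter
    names, ``n_boot``/``seed`` integers, other values floats).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    cp = configparser.ConfigParser()
    cp.read(path)
    if "model" not in cp or "id" not in cp["model"]:
        raise ValidationError(f"{path}: missing [model] id")
    model_id = cp["model"]["id"]
    if model_id not in MODEL_REGISTRY:
        raise ValidationError(
            f"{path}: unknown model {model_id!r}; "
            f"registered: {sorted(MODEL_REGISTRY)}"
        )
    params: dict = {}
    if "params" in cp:
        for key, raw in cp["params"].items():
            try:
                params[key] = float(raw)
            except ValueError:
                params[key] = raw  # registry switches are strings
    # construct once to validate names and invariants
    try:
        MODEL_REGISTRY[model_id]["params"](**params)
    except TypeError as exc:
        raise ValidationError(f"{path}: bad [params] block: {exc}") from exc
    fit: dict = {}
    if "fit" in cp:
        for key, raw in cp["fit"].items():
            if key in ("n_boot", "seed", "maxiter"):
                fit[key] = int(raw)
            elif key == "free":
                fit[key] = [s.strip() for s in raw.split(",") if s.strip()]
            elif key == "log_scale":
                fit[key] = cp["fit"].getboolean(key)
            else:
                fit[key] = float(raw)
    return RunConfig(model_id=model_id, params=params, fit=fit, path=path)
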