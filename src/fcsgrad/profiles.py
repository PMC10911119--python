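"""Gradient profile container shared by the model and fitting layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acf import ValidationError


@dataclass
class GradientProfile:
    """AP-axis profile: position x (µm from the anterior pole), mean
    intensity (arbitrary units or nM), per-position s.d. across embryos and
    the number of embryos contributing per position."""

    x: np.ndarray
    mean: np.ndarray
    sd: np.ndarray | None = None
    n: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.n is not None:
            self.n = np.asarray(self.n)
        self.validate()

    def validate(self) -> None:
        if self.x.ndim != 1 or self.x.size == 0:
            raise ValidationError("x must be a non-empty 1-D array")
        if self.x.shape != self.mean.shape:
            raise ValidationError("x and mean must have equal length")
        if not np.all(np.diff(self.x) > 0):
            raise ValidationError("x must be strictly increasing")
        if not np.all(np.isfinite(self.mean)):
            raise ValidationError("mean must be finite")
        if self.sd is not None:
            if self.sd.shape != self.mean.shape:
                raise ValidationError("sd must match mean in length")
            if not np.all(self.sd >= 0):
                raise ValidationError("sd must be non-negative")

    def interp(self, x_new: np.ndarray) -> np.ndarray:
        """Linear interpolation of the mean onto new positions."""
        return np.interp(np.asarray(x_new, dtype=float), self.x, self.mean)
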