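"""Spectral pre-treatments: SNV and Savitzky-Golay derivatives.

Six variants are supported, mirroring the standard chemometrics menu for
solid-wood NIR work: raw spectra, standard normal variate (SNV), first and
second Savitzky-Golay derivatives (order-2 local polynomial, 15-point
window by default), and SNV followed by each derivative.

Conventions worth noting:

* SNV divides by the sample standard deviation (n-1 divisor).
* Derivatives are taken with respect to wavenumber in physical units, so
  a first derivative is in absorbance per cm^-1 regardless of whether the
  axis ascends or descends.
* Edge points whose full window does not fit are dropped, truncating the
  axis by (window-1)/2 points per side: fabricated edge values would
  otherwise leak into variable selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectraSet
from .errors import ConfigError, DegenerateSpectrumError

#: the six pre-treatment variants
METHODS = ("raw", "snv", "sg1", "sg2", "snv_sg1", "snv_sg2")


@dataclass(frozen=True)
class PreprocessConfig:
    """Pre-treatment choice plus Savitzky-Golay settings.

    ``sg_window`` is the odd number of points in the moving window and
    ``sg_polyorder`` the order of the local polynomial fit.
    """

    method: str = "snv_sg1"
    sg_window: int = 15
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(f"unknown pre-treatment {self.method!r}; choose from {METHODS}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError(
                f"sg_window must be odd and > sg_polyorder (got {self.sg_window}, "
                f"polyorder {self.sg_polyorder})"
            )
        deriv = self.derivative_order
        if deriv and self.sg_polyorder < deriv:
            raise ConfigError(
                f"sg_polyorder {self.sg_polyorder} below derivative order {deriv}"
            )

    @property
    def derivative_order(self) -> int:
        return {"sg1": 1, "sg2": 2, "snv_sg1": 1, "snv_sg2": 2}.get(self.method, 0)

    @property
    def uses_snv(self) -> bool:
        return self.method in ("snv", "snv_sg1", "snv_sg2")


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-spectrum centering and unit scaling.

    Each row x is mapped to (x - mean(x)) / sd(x) with the sample
    (n-1 divisor) standard deviation, which removes any additive offset
    and multiplicative scatter factor exactly.
    """
    A = s.absorbance
    if A.shape[1] < 2:
        raise DegenerateSpectrumError("SNV needs at least 2 points per spectrum")
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        bad = [s.sample_ids[i] for i in zero]
        raise DegenerateSpectrumError(f"constant spectra (zero variance), cannot SNV: {bad}")
    return s.with_absorbance((A - mu) / sd)


def sg_derivative(
    s: SpectraSet, deriv: int, window: int = 15, polyorder: int = 2
) -> SpectraSet:
    """Savitzky-Golay derivative with edge truncation.

    Fits an order-``polyorder`` polynomial in a ``window``-point moving
    window and evaluates its ``deriv``-th derivative at the centre point,
    scaled by the physical wavenumber spacing. The (window-1)/2 points at
    each end, where the window does not fit, are dropped from both the
    matrix and the axis.
    """
    if window % 2 == 0:
        raise ConfigError(f"window must be odd (got {window})")
    if polyorder < deriv:
        raise ConfigError(f"polyorder {polyorder} below derivative order {deriv}")
    if polyorder >= window:
        raise ConfigError(f"polyorder {polyorder} must be < window {window}")
    if s.n_wavenumbers < window:
        raise ConfigError(
            f"spectrum has {s.n_wavenumbers} points, fewer than window {window}"
        )
    step = s.spacing
    d = savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=abs(step), axis=1,
    )
    # savgol differentiates along the index; a descending axis flips the sign
    # of odd-order derivatives taken with respect to wavenumber.
    if step < 0 and deriv % 2 == 1:
        d = -d
    half = (window - 1) // 2
    return s.with_absorbance(d[:, half:-half], s.wavenumbers[half:-half].copy())


def apply_pretreatment(s: SpectraSet, cfg: PreprocessConfig) -> SpectraSet:
    """Apply one of the six pre-treatment variants.

    Composition order for the combined variants is SNV first, then the
    derivative. ``raw`` returns the input unchanged.
    """
    out = s
    if cfg.uses_snv:
        out = snv(out)
    d = cfg.derivative_order
    if d:
        out = sg_derivative(out, d, cfg.sg_window, cfg.sg_polyorder)
    return out
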