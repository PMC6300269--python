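"""Gravitational expansion gradients and the peribronchial-lung conversion.

In the supine posture lung expansion has a dorso-ventral gradient, so the
difference ``dE = E_SL - E_pb`` between a segment's distal parenchymal
expansion and its feeding airway's peribronchial expansion depends
systematically on their vertical offset ``dh``.  A per-subject,
per-condition ordinary-least-squares fit of ``dE`` on ``dh`` removes that
dependence; the intercept is the height-adjusted mean difference
``dE_mean`` (dE at dh = 0).

``dE_mean`` grows with whole-lung expansion ``E_Lung``: peribronchial
parenchyma expands less than distal parenchyma as the lung inflates.  The
conversion factor

    k_bar = (1 - dE_mean,P / E_Lung,P) / (1 - dE_mean,T / E_Lung,T)

translates a normalised peribronchial-expansion change into a normalised
lung-volume change (used as a multiplier for the closure-volume
prediction and as a divisor when mapping residual volume back to
peribronchial expansion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GradientFit",
    "ConversionFactor",
    "delta_e",
    "fit_vertical_gradient",
    "fit_de_mean_vs_elung",
    "conversion_factor",
]


@dataclass(frozen=True)
class GradientFit:
    """OLS fit of dE on dh; the intercept is dE_mean (dE adjusted to dh=0)."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    @property
    def de_mean(self) -> float:
        return self.intercept


@dataclass(frozen=True)
class ConversionFactor:
    """Peribronchial <-> lung volume conversion factor with audit inputs."""

    k_bar: float
    de_mean_p: float
    e_lung_p: float
    de_mean_t: float
    e_lung_t: float


def delta_e(e_sl: float, e_pb: float) -> float:
    """Expansion difference dE = E_SL - E_pb (segment minus peribronchial)."""
    if e_sl <= 0 or e_pb <= 0:
        raise ValueError("expansions must be positive")
    return e_sl - e_pb


def _ols(x: np.ndarray, y: np.ndarray, min_n: int) -> GradientFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < min_n:
        raise ValueError(f"need at least {min_n} points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all abscissa values equal")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    # constant response: the fit is exact, report r^2 = 1
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    r2 = min(max(r2, 0.0), 1.0)
    return GradientFit(slope=slope, intercept=intercept, r_squared=r2, n=n)


def fit_vertical_gradient(dh, de) -> GradientFit:
    """Per-subject, per-condition OLS of dE on dh (unweighted, >= 3 airways)."""
    return _ols(dh, de, min_n=3)


def fit_de_mean_vs_elung(e_lung, de_mean) -> GradientFit:
    """OLS of dE_mean on E_Lung across subject-conditions (reporting fit)."""
    return _ols(e_lung, de_mean, min_n=2)


def conversion_factor(
    de_mean_p: float, e_lung_p: float, de_mean_t: float, e_lung_t: float
) -> ConversionFactor:
    """Compute k_bar from a subject's own P and T values.

    Requires positive E_Lung values and dE_mean < E_Lung in both
    conditions (otherwise the peribronchial level would be non-positive).
    """
    if e_lung_p <= 0 or e_lung_t <= 0:
        raise ValueError("E_Lung values must be positive")
    num = 1.0 - de_mean_p / e_lung_p
    den = 1.0 - de_mean_t / e_lung_t
    if den <= 0 or num <= 0:
        raise ValueError("dE_mean must be smaller than E_Lung in both conditions")
    return ConversionFactor(
        k_bar=num / den,
        de_mean_p=de_mean_p,
        e_lung_p=e_lung_p,
        de_mean_t=de_mean_t,
        e_lung_t=e_lung_t,
    )
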