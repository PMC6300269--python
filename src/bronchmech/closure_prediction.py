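"""Subject-level closure and gas-trapping predictions.

Two whole-lung quantities are predicted from per-airway mechanics:

* ``critical_volume_change`` — the normalised lung-volume rise ``dV_C/TLC``
  at which the subject's least stable segmental airway (lowest iso-volume
  lumen ``A_i*/A_o,T``) reaches its critical peribronchial expansion,
  ``dV_C/TLC = (E_pbCrit/E_pb,T - E_pb,B/E_pb,T) * k_bar``.

* ``trapped_volume`` — the gas volume trapped behind segmental airways that
  close during a forced exhalation to residual volume, as a fraction of
  baseline FVC.  An airway closes during the manoeuvre when its critical
  expansion (FVC variant, wall area at TLC) exceeds the peribronchial
  expansion at RV, ``E_pb,RV = (RV_P/TLC)/k_bar`` with
  ``RV_P = TLC - FVC_P``.

The printed form of the trapping sum carries no per-segment volume weight,
which makes every closing airway contribute a whole-lung-scale volume.
The default ``weighted`` mode therefore multiplies each closing airway's
excess by the fractional lung volume of its subtended segment at TLC;
``literal`` mode reproduces the unweighted sum.  Both are reported side by
side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClosurePrediction",
    "SubjectVolumes",
    "residual_volume_post",
    "critical_volume_change",
    "expansion_at_rv",
    "trapped_volume",
]


@dataclass(frozen=True)
class SubjectVolumes:
    """Per-subject spirometric and CT volumes (litres)."""

    tlc: float
    fvc_b: float
    fvc_p: float
    mlv_b: float
    mlv_p: float

    def __post_init__(self) -> None:
        if not (0 < self.fvc_p <= self.fvc_b < self.tlc):
            raise ValueError("require 0 < FVC_P <= FVC_B < TLC")
        if not (0 < self.mlv_b < self.tlc):
            raise ValueError("require 0 < MLV_B < TLC")


@dataclass(frozen=True)
class ClosurePrediction:
    """Subject-level prediction bundle."""

    delta_vc_over_tlc: float
    rv_p: float
    e_pb_rv: float
    closing_airways: tuple = field(default_factory=tuple)
    v_tr_over_fvc_b: float = 0.0
    mode: str = "weighted"


def residual_volume_post(tlc: float, fvc_p: float) -> float:
    """Post-challenge residual volume RV_P = TLC - FVC_P (litres)."""
    if fvc_p >= tlc:
        raise ValueError("FVC_P must be smaller than TLC")
    if fvc_p <= 0 or tlc <= 0:
        raise ValueError("volumes must be positive")
    return tlc - fvc_p


def critical_volume_change(
    e_crit_least_stable: float, e_pb_b_over_t: float, k_bar: float
) -> float:
    """dV_C/TLC for the least stable airway's closure threshold."""
    if k_bar <= 0:
        raise ValueError("k_bar must be positive")
    return (e_crit_least_stable - e_pb_b_over_t) * k_bar


def expansion_at_rv(rv_p: float, tlc: float, k_bar: float) -> float:
    """Normalised peribronchial expansion at residual volume."""
    if k_bar <= 0:
        raise ValueError("k_bar must be positive")
    if tlc <= 0 or rv_p < 0:
        raise ValueError("invalid volumes")
    return (rv_p / tlc) / k_bar


def trapped_volume(
    e_crit_fvc,
    segment_fractions=None,
    *,
    k_bar: float,
    rv_p: float,
    tlc: float,
    fvc_b: float,
    mode: str = "weighted",
) -> tuple[float, np.ndarray]:
    """Gas trapped behind closing airways during an FVC, over FVC_B.

    Parameters
    ----------
    e_crit_fvc : sequence of float
        Per-airway critical expansion ratios (FVC variant); airways with no
        defined closure (non-positive RD or no-closure flag) enter as NaN
        and never close.
    segment_fractions : sequence of float, optional
        Fractional lung volume at TLC subtended by each airway; required in
        ``weighted`` mode, must sum to <= 1.
    mode : {"weighted", "literal"}

    Returns
    -------
    (v_tr_over_fvc_b, closing) : float and boolean array marking the
    closing set ``J = {j : e_crit_fvc_j > E_pb,RV}`` (strict inequality;
    ties do not close).
    """
    e = np.asarray(list(e_crit_fvc), dtype=float)
    if e.size == 0:
        raise ValueError("empty mechanics list")
    if mode not in ("weighted", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    if fvc_b <= 0:
        raise ValueError("FVC_B must be positive")
    e_rv = expansion_at_rv(rv_p, tlc, k_bar)
    closing = np.nan_to_num(e, nan=-np.inf) > e_rv
    # negative excesses never accumulate: an airway just past its closure
    # threshold traps no measurable volume
    excess = np.where(closing, np.maximum(e / k_bar - rv_p / tlc, 0.0), 0.0)
    if mode == "weighted":
        if segment_fractions is None:
            raise ValueError("weighted mode requires segment fractions")
        f = np.asarray(list(segment_fractions), dtype=float)
        if f.shape != e.shape:
            raise ValueError("segment fractions must match mechanics list")
        if np.any(f < 0) or f.sum() > 1.0 + 1e-9:
            raise ValueError("segment fractions must be non-negative and sum to <= 1")
        total = float(np.sum(f * excess))
    else:
        total = float(np.sum(excess))
    return total * tlc / fvc_b, closing
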