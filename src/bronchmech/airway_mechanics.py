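"""Per-airway mechanics of airway-parenchyma interdependence.

The state of a segmental airway is tracked in the plane of normalised outer
area ``a = A_o/A_o,T`` versus normalised peribronchial expansion to the 2/3
power, ``e^(2/3) = (E_pb/E_pb,T)^(2/3)`` (the exponent keeps an area-like
quantity against a volume-like one).  Between post-challenge mean lung
volume (P) and total lung capacity (T) the relationship is taken as linear
for a constricted airway; its chord slope is the relative distensibility

    RD = (1 - A_o,P/A_o,T) / (1 - (E_pb,P/E_pb,T)^(2/3)),

RD = 1 meaning the airway tracks its surrounding parenchyma, RD < 1 a
relatively stiffer airway.  Extrapolating the line back to the baseline
expansion gives the iso-volume outer area ``A_o*`` the airway would have
had, had the peribronchial expansion not risen after the challenge;
subtracting the (constant B->P) wall area gives the iso-volume lumen
``A_i*``, whose sign flags airways that would have closed outright.
Setting the lumen to zero and solving for expansion gives the critical
peribronchial expansion for closure, with the wall area taken at P for the
mean-lung-volume variant and at T for the forced-vital-capacity variant.

All area ratios are normalised by ``A_o,T`` in a single site: functions
accept raw mm^2 at the interface and divide internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VALID_OK",
    "RD_NONPOSITIVE",
    "CLAMPED_ABOVE",
    "NO_CLOSURE",
    "AirwayMechanics",
    "relative_distensibility",
    "isovolume_outer_area",
    "isovolume_lumen",
    "critical_expansion_mlv",
    "critical_expansion_fvc",
    "subject_min_lumen",
    "compute_airway_mechanics",
]

TWO_THIRDS = 2.0 / 3.0

# validity flags; clamping is always explicit, never silent
VALID_OK = "ok"
RD_NONPOSITIVE = "rd_nonpositive"
CLAMPED_ABOVE = "clamped_above"
NO_CLOSURE = "no_closure"


@dataclass(frozen=True)
class AirwayMechanics:
    """Derived per-airway quantities (all ratios normalised by A_o,T)."""

    rd: float
    a_star_o: float
    a_star_i: float
    e_crit_mlv: float | None
    e_crit_fvc: float | None
    flag_mlv: str
    flag_fvc: str
    closure_flag_baseline: bool

    @property
    def validity_flag(self) -> str:
        return RD_NONPOSITIVE if self.rd <= 0 else self.flag_mlv


def relative_distensibility(a_o_p: float, a_o_t: float, e_pb_p: float, e_pb_t: float) -> float:
    """Chord slope RD of normalised outer area vs normalised expansion^(2/3)."""
    if a_o_t <= 0:
        raise ValueError("A_o,T must be positive")
    if e_pb_t <= 0 or e_pb_p <= 0:
        raise ValueError("peribronchial expansions must be positive")
    ratio = e_pb_p / e_pb_t
    if ratio == 1.0:
        raise ValueError("E_pb,P equals E_pb,T: RD undefined")
    return (1.0 - a_o_p / a_o_t) / (1.0 - ratio**TWO_THIRDS)


def isovolume_outer_area(
    a_o_p: float,
    a_o_t: float,
    rd: float,
    e_pb_b: float,
    e_pb_p: float,
    e_pb_t: float,
) -> float:
    """Outer area ratio A_o*/A_o,T had peribronchial expansion stayed at baseline.

    Extrapolates the constant-RD line from the measured P state back to the
    baseline expansion:
    ``A_o*/A_o,T = A_o,P/A_o,T - RD * ((E_pb,P/E_pb,T)^(2/3) - (E_pb,B/E_pb,T)^(2/3))``.
    """
    if a_o_t <= 0:
        raise ValueError("A_o,T must be positive")
    if min(e_pb_b, e_pb_p, e_pb_t) <= 0:
        raise ValueError("peribronchial expansions must be positive")
    return a_o_p / a_o_t - rd * ((e_pb_p / e_pb_t) ** TWO_THIRDS - (e_pb_b / e_pb_t) ** TWO_THIRDS)


def isovolume_lumen(a_star_o: float, a_w_p: float, a_o_t: float) -> float:
    """Lumen ratio A_i*/A_o,T = A_o*/A_o,T - A_w,P/A_o,T.

    Negative values are physically meaningful: the smooth-muscle force
    exceeds the parenchymal tethering available at baseline expansion, so
    the airway would have been fully closed.
    """
    if a_o_t <= 0:
        raise ValueError("A_o,T must be positive")
    return a_star_o - a_w_p / a_o_t


def critical_expansion_mlv(
    e_pb_b_over_t: float, a_star_i: float, rd: float
) -> tuple[float | None, str]:
    """Critical expansion ratio E_pbCrit/E_pb,T for closure (wall area at P).

    Solves the constant-RD line for the expansion at which A_o = A_w:
    ``x = (E_pb,B/E_pb,T)^(2/3) - (A_i*/A_o,T)/RD`` and
    ``E_pbCrit/E_pb,T = x^(3/2)``.  ``x > 1`` is clamped to 1 (closure above
    TLC expansion) and flagged; ``x < 0`` means the airway never closes
    before full deflation and returns ``None``.
    """
    if rd <= 0:
        return None, RD_NONPOSITIVE
    x = e_pb_b_over_t**TWO_THIRDS - a_star_i / rd
    if x > 1.0:
        return 1.0, CLAMPED_ABOVE
    if x < 0.0:
        return None, NO_CLOSURE
    return x**1.5, VALID_OK


def critical_expansion_fvc(a_w_t: float, a_o_t: float, rd: float) -> tuple[float | None, str]:
    """Critical expansion ratio for closure during forced exhalation.

    Wall area taken at TLC (walls are thicker at T than at MLV):
    ``x = 1 - (1 - A_w,T/A_o,T)/RD``, same clamp/none rules as the MLV
    variant.
    """
    if rd <= 0:
        return None, RD_NONPOSITIVE
    if not (0 < a_w_t <= a_o_t):
        raise ValueError("require 0 < A_w,T <= A_o,T")
    x = 1.0 - (1.0 - a_w_t / a_o_t) / rd
    if x > 1.0:  # cannot occur for a_w_t <= a_o_t, kept for symmetry
        return 1.0, CLAMPED_ABOVE
    if x < 0.0:
        return None, NO_CLOSURE
    return x**1.5, VALID_OK


def subject_min_lumen(a_star_i_values) -> tuple[float, float]:
    """Subject-level minimum of A_i*/A_o,T and its mean - 2 SD variant.

    Returns ``(min, mean - 2 * sample SD)``; the two track each other
    closely across subjects and both identify the least stable airway.
    """
    v = np.asarray(list(a_star_i_values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two airways")
    sd = float(np.std(v, ddof=1))
    return float(v.min()), float(v.mean() - 2.0 * sd)


def compute_airway_mechanics(
    *,
    a_o_p: float,
    a_o_t: float,
    a_w_p: float,
    a_w_t: float,
    e_pb_b: float,
    e_pb_p: float,
    e_pb_t: float,
) -> AirwayMechanics:
    """Full per-airway derivation from raw areas (mm^2) and expansions."""
    rd = relative_distensibility(a_o_p, a_o_t, e_pb_p, e_pb_t)
    a_star_o = isovolume_outer_area(a_o_p, a_o_t, rd, e_pb_b, e_pb_p, e_pb_t)
    a_star_i = isovolume_lumen(a_star_o, a_w_p, a_o_t)
    e_b = e_pb_b / e_pb_t
    e_crit_mlv, flag_mlv = critical_expansion_mlv(e_b, a_star_i, rd)
    e_crit_fvc, flag_fvc = critical_expansion_fvc(a_w_t, a_o_t, rd)
    return AirwayMechanics(
        rd=rd,
        a_star_o=a_star_o,
        a_star_i=a_star_i,
        e_crit_mlv=e_crit_mlv,
        e_crit_fvc=e_crit_fvc,
        flag_mlv=flag_mlv,
        flag_fvc=flag_fvc,
        closure_flag_baseline=a_star_i < 0,
    )
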