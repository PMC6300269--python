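"""Voxel-level lung CT morphometry.

Implements Hounsfield-unit gas-fraction densitometry and the regional
expansion measures built on it:

* ``gas_fraction`` — fractional air content of a voxel,
  ``F_gas = (HU_blood - HU) / (HU_blood - HU_air)``.
* ``expansion`` — mean gas-to-tissue volume ratio ``E = <F_gas/(1-F_gas)>``
  over a region of interest; the regional measure of parenchymal
  distension (peribronchial ``E_pb``, segmental ``E_SL``, whole-lung
  ``E_Lung``).
* ``build_parenchyma_mask`` — lung minus airway/vessel trees, thresholded
  to the parenchymal HU window (both bounds inclusive).
* ``peribronchial_roi`` — spherical peribronchial sampling region around
  an airway centre point, with iterative tissue-volume matching across
  imaging conditions.
* ``delta_h`` — gravity-axis distance between an airway centre and its
  segment centre, normalised by lung dorso-ventral height.

Geometry conventions: volumes are dense numpy arrays with an accompanying
voxel ``spacing`` in mm; the world coordinate of voxel index ``i`` along an
axis is ``i * spacing`` (mm).  Sphere membership is decided by the voxel
centre (no partial-volume weighting).  Areas are mm^2, regional volumes mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DensitometryConstants",
    "DEFAULT_CONSTANTS",
    "PeribronchialROI",
    "gas_fraction",
    "expansion",
    "lung_expansion",
    "build_parenchyma_mask",
    "equivalent_diameter",
    "sphere_mask",
    "peribronchial_roi",
    "delta_h",
    "expansion_bounds",
]


@dataclass(frozen=True)
class DensitometryConstants:
    """Reference HU values for densitometry and the parenchymal HU window."""

    hu_blood: float = 65.0
    hu_air: float = -1000.0
    mask_lo: float = -950.0
    mask_hi: float = -400.0

    def __post_init__(self) -> None:
        if not (self.hu_air < self.mask_lo < self.mask_hi < self.hu_blood):
            raise ValueError(
                "require hu_air < mask_lo < mask_hi < hu_blood, got "
                f"{self.hu_air}, {self.mask_lo}, {self.mask_hi}, {self.hu_blood}"
            )


DEFAULT_CONSTANTS = DensitometryConstants()


def gas_fraction(
    hu,
    constants: DensitometryConstants = DEFAULT_CONSTANTS,
    *,
    out_of_range: str = "clamp",
):
    """Fractional air content of voxels with attenuation ``hu``.

    ``F_gas = (HU_blood - HU)/(HU_blood - HU_air)``; 0 at blood, 1 at air.

    Parameters
    ----------
    hu : array_like
        Attenuation values in HU.
    out_of_range : {"clamp", "raise"}
        Policy for values outside ``[hu_air, hu_blood]``.  Inside a
        parenchymal mask the window guarantees the range, so ``raise`` is
        appropriate there; ``clamp`` elsewhere.
    """
    hu = np.asarray(hu, dtype=float)
    lo, hi = constants.hu_air, constants.hu_blood
    if out_of_range == "raise":
        if np.any((hu < lo) | (hu > hi)):
            raise ValueError(f"HU outside [{lo}, {hi}]")
    elif out_of_range == "clamp":
        hu = np.clip(hu, lo, hi)
    else:
        raise ValueError(f"unknown out_of_range policy {out_of_range!r}")
    return (constants.hu_blood - hu) / (constants.hu_blood - constants.hu_air)


def expansion(
    volume: np.ndarray,
    roi_mask: np.ndarray,
    constants: DensitometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Mean gas-to-tissue volume ratio ``E`` over an ROI.

    ``E = mean(F_gas / (1 - F_gas))`` over the ROI voxels.  Raises if the
    ROI is empty or if any voxel has ``F_gas >= 1`` (impossible inside a
    -950-bounded parenchymal mask).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    f = gas_fraction(np.asarray(volume)[roi_mask], constants, out_of_range="clamp")
    if np.any(f >= 1.0):
        raise ValueError("F_gas >= 1 inside ROI (gas-to-tissue ratio undefined)")
    return float(np.mean(f / (1.0 - f)))


def lung_expansion(
    volume: np.ndarray,
    parenchyma_mask: np.ndarray,
    constants: DensitometryConstants = DEFAULT_CONSTANTS,
) -> float:
    """Whole-lung expansion ``E_Lung``: voxel-average gas-to-tissue ratio."""
    return expansion(volume, parenchyma_mask, constants)


def expansion_bounds(constants: DensitometryConstants = DEFAULT_CONSTANTS) -> tuple[float, float]:
    """Attainable ``E`` range inside the parenchymal HU window.

    With the default -950/-400 window this is [0.775, 20.3].
    """

    def _e(hu: float) -> float:
        f = float(gas_fraction(hu, constants))
        return f / (1.0 - f)

    return _e(constants.mask_hi), _e(constants.mask_lo)


def build_parenchyma_mask(
    lung_mask: np.ndarray,
    airway_mask: np.ndarray,
    vessel_mask: np.ndarray,
    volume: np.ndarray,
    constants: DensitometryConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Lung parenchyma mask: lung minus trees, inside the HU window.

    ``(lung \\ airway \\ vessel) & (mask_lo <= HU <= mask_hi)`` with both
    bounds inclusive.  Raises if the result is empty.
    """
    lung = np.asarray(lung_mask, dtype=bool)
    mask = lung & ~np.asarray(airway_mask, dtype=bool) & ~np.asarray(vessel_mask, dtype=bool)
    hu = np.asarray(volume)
    mask &= (hu >= constants.mask_lo) & (hu <= constants.mask_hi)
    if not mask.any():
        raise ValueError("parenchyma mask is empty")
    return mask


def equivalent_diameter(area_mm2: float) -> float:
    """Diameter of a circle with the given area (mm)."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area_mm2 / math.pi)


def sphere_mask(
    shape: Sequence[int],
    spacing: Sequence[float],
    center_mm: Sequence[float],
    diameter_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside the sphere.

    Voxel-centre-in-sphere rule; the centre of voxel ``i`` along axis ``k``
    is ``i * spacing[k]``.  Evaluated on a bounding-box crop for speed.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    r = diameter_mm / 2.0
    out = np.zeros(shape, dtype=bool)
    lo = np.maximum(np.ceil((center - r) / spacing).astype(int), 0)
    hi = np.minimum(np.floor((center + r) / spacing).astype(int), np.array(shape) - 1)
    if np.any(lo > hi):
        return out
    axes = [np.arange(lo[k], hi[k] + 1) * spacing[k] - center[k] for k in range(3)]
    d2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    out[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = d2 <= r * r
    return out


@dataclass
class PeribronchialROI:
    """Spherical peribronchial sampling region around an airway centre.

    ``f_s`` is the sampled fraction: parenchymal ROI volume over the
    theoretical volume (sphere minus an intersecting cylinder of
    cross-sectional area ``A_o``).
    """

    center_mm: tuple[float, float, float]
    diameter_mm: float
    tissue_volume_ml: float
    gas_volume_ml: float
    e_pb: float
    f_s: float
    n_voxels: int
    mask: np.ndarray = field(repr=False)

    @property
    def roi_volume_ml(self) -> float:
        """Geometric voxel volume of the ROI (tissue + gas)."""
        return self.tissue_volume_ml + self.gas_volume_ml


def _roi_at_diameter(volume, parenchyma_mask, spacing, center_mm, d, a_o_mm2, constants):
    mask = sphere_mask(volume.shape, spacing, center_mm, d) & parenchyma_mask
    vox_ml = float(np.prod(np.asarray(spacing, dtype=float))) / 1000.0
    n = int(mask.sum())
    if n == 0:
        return mask, n, 0.0, 0.0, float("nan"), 0.0
    f = gas_fraction(np.asarray(volume)[mask], constants, out_of_range="clamp")
    f = np.clip(f, None, np.nextafter(1.0, 0.0))
    gas_ml = float(f.sum()) * vox_ml
    tissue_ml = n * vox_ml - gas_ml
    e_pb = float(np.mean(f / (1.0 - f)))
    theoretical_ml = (math.pi / 6.0 * d**3 - a_o_mm2 * d) / 1000.0
    f_s = (n * vox_ml) / theoretical_ml if theoretical_ml > 0 else float("nan")
    return mask, n, tissue_ml, gas_ml, e_pb, f_s


def peribronchial_roi(
    volume: np.ndarray,
    parenchyma_mask: np.ndarray,
    center_mm: Sequence[float],
    a_o_mm2: float,
    spacing: Sequence[float],
    reference_tissue_ml: float | None = None,
    constants: DensitometryConstants = DEFAULT_CONSTANTS,
    *,
    tissue_tolerance: float = 0.05,
    max_iter: int = 60,
) -> PeribronchialROI:
    """Extract the peribronchial ROI around an airway centre point.

    Baseline call (``reference_tissue_ml=None``): sphere diameter is four
    times the equivalent diameter of a circle with area ``A_o``.  Follow-up
    calls: the diameter is adjusted by bisection within [1x, 8x] the
    equivalent diameter until the ROI parenchymal tissue volume is within
    ``tissue_tolerance`` (default 5%) of the reference, so that
    approximately the same tissue is sampled in every condition.
    """
    d_eq = equivalent_diameter(a_o_mm2)
    parenchyma_mask = np.asarray(parenchyma_mask, dtype=bool)
    center = tuple(float(c) for c in center_mm)

    def build(d):
        return _roi_at_diameter(volume, parenchyma_mask, spacing, center, d, a_o_mm2, constants)

    if reference_tissue_ml is None:
        d = 4.0 * d_eq
        mask, n, tissue, gas, e_pb, f_s = build(d)
        if n == 0:
            raise ValueError("baseline peribronchial ROI contains no parenchyma")
        return PeribronchialROI(center, d, tissue, gas, e_pb, f_s, n, mask)

    ref = float(reference_tissue_ml)
    if ref <= 0:
        raise ValueError("reference tissue volume must be positive")
    lo, hi = 1.0 * d_eq, 8.0 * d_eq
    t_lo = build(lo)[2]
    t_hi = build(hi)[2]
    if t_lo > ref * (1 + tissue_tolerance) or t_hi < ref * (1 - tissue_tolerance):
        worst = min(abs(t_lo / ref - 1), abs(t_hi / ref - 1))
        raise ValueError(
            "tissue-volume matching cannot bracket reference within "
            f"[1x, 8x] equivalent diameter (best mismatch {worst:.1%})"
        )
    best = None
    for _ in range(max_iter):
        d = 0.5 * (lo + hi)
        res = build(d)
        tissue = res[2]
        mismatch = abs(tissue / ref - 1.0)
        if best is None or mismatch < best[0]:
            best = (mismatch, d, res)
        if mismatch <= tissue_tolerance:
            break
        if tissue < ref:
            lo = d
        else:
            hi = d
    mismatch, d, (mask, n, tissue, gas, e_pb, f_s) = best
    if mismatch > tissue_tolerance:
        raise ValueError(
            f"tissue-volume matching failed: achieved mismatch {mismatch:.1%} "
            f"exceeds {tissue_tolerance:.0%}"
        )
    return PeribronchialROI(center, d, tissue, gas, e_pb, f_s, n, mask)


def delta_h(
    airway_center_mm: Sequence[float],
    segment_center_mm: Sequence[float],
    lung_height_mm: float,
    *,
    axis: int = -1,
) -> float:
    """Normalised gravity-axis distance between segment and airway centres.

    ``(segment_z - airway_z) / lung_height`` with z the dorso-ventral
    (gravity) axis, ventral = increasing coordinate in the supine posture.
    Positive when the subtended segment is non-dependent relative to its
    feeding airway.
    """
    if lung_height_mm <= 0:
        raise ValueError("lung height must be positive")
    za = float(np.asarray(airway_center_mm, dtype=float)[axis])
    zs = float(np.asarray(segment_center_mm, dtype=float)[axis])
    return (zs - za) / float(lung_height_mm)
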