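"""Morphological descriptors of a segmented stem section.

Raw quantities (areas, perimeter, bundle shape) come from pixel counting
and region properties.  Rind thickness and parenchyma cell size are
measured by granulometry with square structuring elements: thickness from
a binary opening granulometry of the rind mask, cell size from grey-level
closing granulometry inside a parenchyma region.  Estimation formulas
correct for cutting damage: the rind area can be rebuilt from thickness x
perimeter (minus a cohort calibration offset), and the stem area from the
rebuilt rind when rind pieces are missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours, regionprops

from .segmentation import RoiSet, square_closing, square_opening, um_to_odd_px

#: Grey-level closing granulometry range for parenchyma cell sizing (um).
CELL_SIZE_RANGE_UM = (18.0, 207.0)
CELL_SIZE_STEP_UM = 7.26
#: Maximum structuring-element size for rind thickness granulometry (um).
RIND_MAX_SIZE_UM = 1456.0

UM2_PER_PX = None  # computed per-call from pixel size


class MorphometryError(ValueError):
    pass


@dataclass
class StemDescriptors:
    """Per-section morphological and stereological quantities.

    Areas in cm^2 unless stated; Vi_A in mm^2; Ri_T in um.
    """

    St_A_measured: float = float("nan")
    St_A: float = float("nan")
    St_P_mm: float = float("nan")
    Ri_A_measured: float = float("nan")
    Ri_A_est: float = float("nan")
    Ri_T_um: float = float("nan")
    Pa_A: float = float("nan")
    Pa_middle_A: float = float("nan")
    Vb_A: float = float("nan")
    Vi_A_mean_mm2: float = float("nan")
    Vi_E_mean: float = float("nan")
    Vb_N: float = float("nan")
    Vb_D_per_cm2: float = float("nan")
    rel_Pa_pct: float = float("nan")
    rel_Ri_pct: float = float("nan")
    rel_Vb_pct: float = float("nan")
    rind_damaged: bool = False

    def as_dict(self) -> dict[str, float | bool]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class GranulometricCurve:
    """Percentage of grey-level variation per structuring-element size."""

    sizes_um: tuple[float, ...]
    values_pct: tuple[float, ...]
    roi_label: str = ""
    transform: str = "closing"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.sizes_um) != len(self.values_pct):
            raise MorphometryError("sizes and values length mismatch")
        if not self.degenerate:
            total = float(np.sum(self.values_pct))
            if abs(total - 100.0) > 1e-6:
                raise MorphometryError(f"curve must sum to 100, got {total}")


@dataclass(frozen=True)
class CellSizeStats:
    mean_size_um: float
    sd_size_um: float
    roi_label: str = ""


# ---------------------------------------------------------------------------
# pixel-counting descriptors
# ---------------------------------------------------------------------------

def _contour_perimeter_px(mask: np.ndarray) -> float:
    """Contour length via sub-pixel iso-contours of a lightly smoothed mask.

    Smoothing removes the rasterisation staircase, keeping both smooth
    (disk) and polygonal (square) shapes within ~1% of their true length.
    """
    smooth = ndi.gaussian_filter(mask.astype(float), 1.0, mode="constant")
    contours = find_contours(smooth, 0.5)
    return float(sum(np.hypot(*np.diff(c, axis=0).T).sum() for c in contours))

def measure_basic(rois: RoiSet) -> StemDescriptors:
    """Areas by pixel counting and stem perimeter by Crofton contour length."""
    if not rois.whole_stem.any():
        raise MorphometryError("empty whole_stem mask")
    px_um = rois.pixel_size_um
    cm2 = (px_um / 10_000.0) ** 2
    d = StemDescriptors()
    d.St_A_measured = float(rois.whole_stem.sum()) * cm2
    d.Ri_A_measured = float(rois.rind.sum()) * cm2
    d.Pa_A = float(rois.parenchyma.sum()) * cm2
    d.Pa_middle_A = float(rois.parenchyma_middle.sum()) * cm2
    d.Vb_A = float(rois.bundles_all.sum()) * cm2
    d.St_P_mm = _contour_perimeter_px(rois.whole_stem) * px_um / 1000.0
    d.rind_damaged = rois.rind_damaged
    return d


# ---------------------------------------------------------------------------
# granulometry
# ---------------------------------------------------------------------------

def _granulometric_volumes(img: np.ndarray, roi: np.ndarray, transform: str,
                           widths_px: Sequence[int]) -> np.ndarray:
    """Sum of grey levels over the ROI after each transform size.

    ``V[0]`` is the untransformed sum; ``V[k]`` follows the k-th size.
    """
    op = {"closing": square_closing, "opening": square_opening}[transform]
    img = np.asarray(img, dtype=float)
    sums = [float(img[roi].sum())]
    for w in widths_px:
        sums.append(float(op(img, w)[roi].sum()))
    return np.asarray(sums)


def graylevel_granulometry(img: np.ndarray, roi: np.ndarray,
                           transform: str = "closing",
                           sizes_um: Sequence[float] | None = None,
                           pixel_size_um: float = 3.63,
                           roi_label: str = "") -> GranulometricCurve:
    """Grey-level granulometric curve over a region of interest.

    Closings of increasing square size sieve dark objects: the increase in
    the summed grey level at each step reflects the amount of objects of
    that size.  Increments are corrected for the residual background trend
    (constant offset estimated over the largest-size quartile), floored at
    zero and renormalised to sum to 100.
    """
    if transform not in ("closing", "opening"):
        raise MorphometryError(f"unknown transform {transform!r}")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise MorphometryError("empty ROI")
    if sizes_um is None:
        lo, hi = CELL_SIZE_RANGE_UM
        sizes_um = list(np.arange(lo, hi + 1e-9, CELL_SIZE_STEP_UM))
    sizes_um = [float(s) for s in sizes_um]
    if any(b <= a for a, b in zip(sizes_um, sizes_um[1:])):
        raise MorphometryError("sizes_um must be strictly increasing")
    widths = [um_to_odd_px(s, pixel_size_um) for s in sizes_um]
    if max(widths) >= min(roi.shape):
        raise MorphometryError("largest structuring element exceeds the image")

    volumes = _granulometric_volumes(img, roi, transform, widths)
    increments = np.diff(volumes)
    if transform == "opening":
        increments = -increments

    if np.allclose(increments, 0):
        return GranulometricCurve(tuple(sizes_um), tuple(0.0 for _ in sizes_um),
                                  roi_label=roi_label, transform=transform,
                                  degenerate=True)

    # constant-offset background: the sieving signal has died out at the
    # largest sizes, any residual slope there is background drift
    q = max(1, len(increments) // 4)
    baseline = float(np.min(increments[-q:]))
    corrected = np.clip(increments - baseline, 0.0, None)
    total = corrected.sum()
    if total <= 0:
        return GranulometricCurve(tuple(sizes_um), tuple(0.0 for _ in sizes_um),
                                  roi_label=roi_label, transform=transform,
                                  degenerate=True)
    values = corrected / total * 100.0
    return GranulometricCurve(tuple(sizes_um), tuple(float(v) for v in values),
                              roi_label=roi_label, transform=transform)


def granulometry_stats(curve: GranulometricCurve) -> CellSizeStats:
    """Grey-level mean size and standard deviation of a normalised curve."""
    if curve.degenerate:
        raise MorphometryError("undefined-stats: degenerate granulometric curve")
    sizes = np.asarray(curve.sizes_um)
    weights = np.asarray(curve.values_pct) / 100.0
    mean = float(np.sum(sizes * weights))
    sd = float(math.sqrt(max(0.0, np.sum((sizes - mean) ** 2 * weights))))
    return CellSizeStats(mean_size_um=mean, sd_size_um=sd, roi_label=curve.roi_label)


def rind_thickness(rind: np.ndarray, pixel_size_um: float,
                   max_size_um: float = RIND_MAX_SIZE_UM,
                   step_px: int = 2) -> float:
    """Mean rind thickness (um) from binary opening granulometry.

    Square openings of increasing size erode the rind band; the mean of
    the resulting (area-weighted) size distribution measures the average
    band width.
    """
    rind = np.asarray(rind, dtype=bool)
    if not rind.any():
        raise MorphometryError("empty rind mask")
    max_width = um_to_odd_px(max_size_um, pixel_size_um)
    widths = list(range(1, max_width + 1, step_px))
    mask = rind.astype(np.uint8)
    areas = [float(rind.sum())]
    for w in widths:
        if w >= min(rind.shape):
            break
        areas.append(float((square_opening(mask, w) > 0)[rind].sum()))
    areas = np.asarray(areas)
    removed = -np.diff(areas)  # area removed entering each size
    removed = np.clip(removed, 0.0, None)
    if removed.sum() <= 0:
        # nothing sieved below max size: thickness at least the max probe
        return float(widths[-1] * pixel_size_um)
    sizes_um = np.asarray(widths[:len(removed)], dtype=float) * pixel_size_um
    return float(np.sum(sizes_um * removed) / removed.sum())


# ---------------------------------------------------------------------------
# estimation formulas
# ---------------------------------------------------------------------------

def estimate_rind_area(Ri_T_um: float, St_P_mm: float,
                       diff_est_meas_cm2: float = 0.0) -> float:
    """Rind area (cm^2) rebuilt as thickness x perimeter minus calibration."""
    if Ri_T_um <= 0 or St_P_mm <= 0:
        raise MorphometryError("thickness and perimeter must be positive")
    est = Ri_T_um * St_P_mm * 1e-5 - diff_est_meas_cm2  # um*mm -> cm^2
    if est < 0:
        import warnings
        warnings.warn("estimated rind area clipped to 0", stacklevel=2)
        return 0.0
    return est


def compute_diff_est_meas(
    sections: Iterable[tuple[float, float, float, bool]],
) -> float:
    """Cohort calibration offset (cm^2) for the rind-area estimate.

    ``sections`` yields ``(Ri_T_um, St_P_mm, Ri_A_measured_cm2,
    rind_damaged)``; the mean excess of thickness x perimeter over the
    measured area across undamaged sections is returned.  The excess is
    positive in practice because bundles still attached to the rind
    inflate the thickness measurement.
    """
    diffs = [t * p * 1e-5 - a for t, p, a, damaged in sections if not damaged]
    if not diffs:
        raise MorphometryError("estimation-unavailable: no undamaged section")
    return float(np.mean(diffs))


def estimate_stem_area(St_A_measured: float, Ri_A_measured: float,
                       Ri_A_est: float, rind_damaged: bool) -> float:
    """Stem area; substitutes the rebuilt rind when rind pieces are missing."""
    if not rind_damaged:
        return St_A_measured
    return St_A_measured - Ri_A_measured + Ri_A_est


def bundle_morphology(bundles_individual: np.ndarray,
                      pixel_size_um: float) -> tuple[list[float], list[float], float, float]:
    """Per-bundle area (mm^2) and elongation; returns lists plus their means.

    Elongation is the minor/major axis ratio of the equivalent ellipse,
    in (0, 1] (1 = isotropic).
    """
    labels = np.asarray(bundles_individual)
    if labels.max() == 0:
        raise MorphometryError("empty bundle label map")
    mm2 = (pixel_size_um / 1000.0) ** 2
    areas, elongs = [], []
    for rp in regionprops(labels):
        areas.append(float(rp.area) * mm2)
        major = rp.axis_major_length
        elongs.append(float(rp.axis_minor_length / major) if major > 0 else 1.0)
    return areas, elongs, float(np.mean(areas)), float(np.mean(elongs))


def bundle_count_density(Vb_A_cm2: float, Vi_A_mean_mm2: float,
                         St_A_cm2: float) -> tuple[float, float]:
    """Bundle count (total area / mean individual area) and density per cm^2."""
    if Vi_A_mean_mm2 <= 0:
        raise MorphometryError("mean individual bundle area must be positive")
    if St_A_cm2 <= 0:
        raise MorphometryError("stem area must be positive")
    Vb_N = (Vb_A_cm2 * 100.0) / Vi_A_mean_mm2  # cm^2 -> mm^2
    return Vb_N, Vb_N / St_A_cm2


def describe_section(rois: RoiSet, img: np.ndarray,
                     diff_est_meas_cm2: float = 0.0,
                     cell_sizes_um: Sequence[float] | None = None,
                     ) -> tuple[StemDescriptors, dict[str, CellSizeStats], dict[str, GranulometricCurve]]:
    """Full descriptor extraction for one section.

    Returns the descriptor record, cell-size statistics per parenchyma
    region, and the underlying granulometric curves.
    """
    d = measure_basic(rois)
    d.Ri_T_um = rind_thickness(rois.rind, rois.pixel_size_um) if rois.rind.any() else float("nan")
    if rois.rind.any():
        d.Ri_A_est = estimate_rind_area(d.Ri_T_um, d.St_P_mm, diff_est_meas_cm2)
    d.St_A = estimate_stem_area(d.St_A_measured, d.Ri_A_measured, d.Ri_A_est, d.rind_damaged)
    if rois.bundles_individual.max() > 0:
        _, _, d.Vi_A_mean_mm2, d.Vi_E_mean = bundle_morphology(
            rois.bundles_individual, rois.pixel_size_um)
        d.Vb_N, d.Vb_D_per_cm2 = bundle_count_density(d.Vb_A, d.Vi_A_mean_mm2, d.St_A)
    rind_for_rel = d.Ri_A_est if d.rind_damaged and np.isfinite(d.Ri_A_est) else d.Ri_A_measured
    d.rel_Pa_pct = d.Pa_A / d.St_A * 100.0
    d.rel_Ri_pct = rind_for_rel / d.St_A * 100.0
    d.rel_Vb_pct = d.Vb_A / d.St_A * 100.0

    stats: dict[str, CellSizeStats] = {}
    curves: dict[str, GranulometricCurve] = {}
    for label, roi in (("parenchyma_middle", rois.parenchyma_middle),
                       ("parenchyma_near_rind", rois.parenchyma_near_rind)):
        if not roi.any():
            continue
        curve = graylevel_granulometry(img, roi, "closing", cell_sizes_um,
                                       rois.pixel_size_um, roi_label=label)
        curves[label] = curve
        if not curve.degenerate:
            stats[label] = granulometry_stats(curve)
    return d, stats, curves
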