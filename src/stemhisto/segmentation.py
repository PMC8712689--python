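"""Tissue segmentation of stem cross-section images.

The workflow turns a darkfield grey image (or a fluorescence sum-intensity
image) into seven regions of interest: whole stem, all tissue (stem minus
section holes), rind, individualised vascular bundles, all vascular
bundles, parenchyma, and its two distance-defined sub-regions (near the
rind / middle).  Dense tissues (rind + bundles) are contrasted from the
thin-walled parenchyma by an alternating sequential filter, thresholded,
then split into rind vs bundles by size analysis: bundle size is the mode
of the object area distribution away from the epidermis, and external
fragments larger than ``rind_mode_multiplier`` times that mode are merged
into the rind.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage as ndi
from scipy.stats import gaussian_kde
from skimage.filters import threshold_otsu

DEFAULT_PIXEL_SIZE_UM = 3.63


class SegmentationError(RuntimeError):
    """Raised when a segmentation stage cannot produce a usable result."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation workflow.

    Thresholds are Otsu by default; pass a float to pin a stage to a fixed
    grey level (the acquisition workflow was semi-automated and allowed
    operator overrides).
    """

    stem_threshold: float | str = "otsu"
    #: "background" derives the hole level from off-stem pixel statistics
    #: (holes are absent tissue, so they sit at the background intensity);
    #: "otsu" splits the in-stem histogram; a float pins the level.
    hole_threshold: float | str = "background"
    asf_sizes_um: tuple[float, ...] = (3.63, 7.26, 10.89)
    rind_mode_multiplier: float = 5.0
    epidermis_exclusion_um: float = 1000.0
    near_rind_max_um: float = 500.0
    middle_min_um: float = 1000.0
    external_margin_px: int = 2
    bundle_size_window: tuple[float, float] = (0.2, 5.0)
    min_eligible_objects: int = 3

    def __post_init__(self) -> None:
        if not self.near_rind_max_um < self.middle_min_um:
            raise ValueError("near_rind_max_um must be below middle_min_um")
        sizes = tuple(self.asf_sizes_um)
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("asf_sizes_um must be strictly increasing")


@dataclass
class RoiSet:
    """The seven tissue masks plus the individual-bundle label map."""

    whole_stem: np.ndarray
    all_tissue: np.ndarray
    rind: np.ndarray
    bundles_individual: np.ndarray
    bundles_all: np.ndarray
    parenchyma: np.ndarray
    parenchyma_near_rind: np.ndarray
    parenchyma_middle: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    rind_damaged: bool = False

    def validate(self) -> None:
        """Assert the partition invariants; raises AssertionError on breach."""
        ws = self.whole_stem.astype(bool)
        assert not np.any(self.all_tissue & ~ws), "all_tissue escapes whole_stem"
        assert not np.any(self.rind & ~ws), "rind escapes whole_stem"
        assert not np.any(self.bundles_all & ~ws), "bundles escape whole_stem"
        assert not np.any(self.rind & self.bundles_all), "rind overlaps bundles"
        expected = ws & ~(self.rind.astype(bool) | self.bundles_all.astype(bool))
        assert np.array_equal(self.parenchyma.astype(bool), expected), \
            "parenchyma is not the exact complement of rind+bundles in the stem"
        assert not np.any((self.bundles_individual > 0) & ~self.bundles_all.astype(bool)), \
            "individual bundles escape bundles_all"
        assert not np.any(self.parenchyma_near_rind & ~self.parenchyma.astype(bool))
        assert not np.any(self.parenchyma_middle & ~self.parenchyma.astype(bool))
        assert not np.any(self.parenchyma_near_rind & self.parenchyma_middle), \
            "near-rind and middle parenchyma overlap"

    def save(self, outdir: str | Path, prefix: str = "roi") -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mask_names = [
            "whole_stem", "all_tissue", "rind", "bundles_all",
            "parenchyma", "parenchyma_near_rind", "parenchyma_middle",
        ]
        files = {}
        for name in mask_names:
            fn = f"{prefix}_{name}.tif"
            tifffile.imwrite(outdir / fn, getattr(self, name).astype(np.uint8) * 255)
            files[name] = fn
        fn = f"{prefix}_bundles_individual.tif"
        tifffile.imwrite(outdir / fn, self.bundles_individual.astype(np.uint16))
        files["bundles_individual"] = fn
        manifest = outdir / f"{prefix}_manifest.json"
        manifest.write_text(json.dumps({
            "files": files,
            "pixel_size_um": self.pixel_size_um,
            "rind_damaged": self.rind_damaged,
        }, indent=2))
        return manifest

    @classmethod
    def load(cls, manifest_path: str | Path) -> "RoiSet":
        manifest_path = Path(manifest_path)
        meta = json.loads(manifest_path.read_text())
        outdir = manifest_path.parent
        arrays = {}
        for name, fn in meta["files"].items():
            arr = np.asarray(tifffile.imread(outdir / fn))
            arrays[name] = arr.astype(np.int32) if name == "bundles_individual" else arr > 0
        return cls(pixel_size_um=float(meta["pixel_size_um"]),
                   rind_damaged=bool(meta.get("rind_damaged", False)), **arrays)


# ---------------------------------------------------------------------------
# separable square morphology (fast moving min/max)
# ---------------------------------------------------------------------------

def _square_erosion(img: np.ndarray, width: int) -> np.ndarray:
    return ndi.minimum_filter(img, size=width, mode="reflect")


def _square_dilation(img: np.ndarray, width: int) -> np.ndarray:
    return ndi.maximum_filter(img, size=width, mode="reflect")


def square_opening(img: np.ndarray, width: int) -> np.ndarray:
    """Grey-level opening with a ``width`` x ``width`` square."""
    return _square_dilation(_square_erosion(img, width), width)


def square_closing(img: np.ndarray, width: int) -> np.ndarray:
    """Grey-level closing with a ``width`` x ``width`` square."""
    return _square_erosion(_square_dilation(img, width), width)


def um_to_odd_px(size_um: float, pixel_size_um: float) -> int:
    """Convert a physical structuring-element size to the nearest odd pixel width."""
    w = max(1, round(size_um / pixel_size_um))
    return int(w if w % 2 == 1 else w + 1)


def _resolve_threshold(values: np.ndarray, spec: float | str, stage: str) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if spec != "otsu":
        raise ValueError(f"unknown threshold method {spec!r} for {stage}")
    if values.size == 0 or np.ptp(values) == 0:
        raise SegmentationError(f"{stage}: degenerate histogram, cannot threshold")
    return float(threshold_otsu(values))


# ---------------------------------------------------------------------------
# workflow stages
# ---------------------------------------------------------------------------

def segment_whole_stem(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Whole-stem mask: threshold, keep the largest component, fill holes."""
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise SegmentationError("empty image")
    thr = _resolve_threshold(img.ravel(), params.stem_threshold, "whole_stem")
    fg = img > thr
    if not fg.any():
        raise SegmentationError(f"whole_stem: empty foreground at threshold {thr:.4g}")
    labels, n = ndi.label(fg, structure=np.ones((3, 3)))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    return ndi.binary_fill_holes(fg)


def segment_all_tissue(img: np.ndarray, whole_stem: np.ndarray,
                       params: SegmentationParams) -> np.ndarray:
    """Remove section holes (dark tears) from the whole-stem mask.

    Holes are regions of missing tissue, so their intensity matches the
    image background: the default threshold is the off-stem background
    level plus three standard deviations.
    """
    img = np.asarray(img, dtype=float)
    inside = img[whole_stem]
    if inside.size == 0:
        raise SegmentationError("whole_stem mask is empty")
    if np.ptp(inside) == 0:
        return whole_stem.copy()
    spec = params.hole_threshold
    if spec == "background":
        outside = img[~whole_stem]
        if outside.size == 0:
            return whole_stem.copy()
        thr = float(outside.mean() + 3.0 * outside.std())
    else:
        thr = _resolve_threshold(inside, spec, "all_tissue")
    return whole_stem & ~(img <= thr)


def enhance_rind_bundles(img: np.ndarray, params: SegmentationParams,
                         pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> np.ndarray:
    """Alternating sequential filter contrasting dense tissue from parenchyma.

    At each size (increasing) a closing is followed by an opening with
    square structuring elements; thin bright parenchyma walls are removed
    while solid rind and bundle regions keep their intensity.
    """
    out = np.asarray(img, dtype=float)
    for size_um in params.asf_sizes_um:
        width = um_to_odd_px(2 * size_um, pixel_size_um)  # half-width -> full width
        if width >= min(out.shape):
            raise ValueError(f"structuring element ({width} px) larger than image {out.shape}")
        out = square_opening(square_closing(out, width), width)
    return out


def threshold_rind_bundles(enhanced: np.ndarray, all_tissue: np.ndarray,
                           threshold: float | str = "otsu") -> np.ndarray:
    """Binary mask of dense tissue inside ``all_tissue``."""
    if not np.any(all_tissue):
        raise SegmentationError("all_tissue mask is empty")
    values = np.asarray(enhanced, dtype=float)[all_tissue]
    thr = _resolve_threshold(values, threshold, "rind_bundles")
    mask = all_tissue & (np.asarray(enhanced) > thr)
    if not mask.any() or mask.sum() == all_tissue.sum():
        raise SegmentationError(f"rind_bundles: degenerate threshold {thr:.4g}")
    return mask


def _component_areas_and_labels(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return np.array([]), labels, 0
    areas = ndi.sum_labels(np.ones_like(labels, dtype=float), labels,
                           index=np.arange(1, n + 1))
    return areas, labels, n


def _distribution_mode(areas: np.ndarray) -> float:
    """Mode of an area sample: log-KDE for >= 10 objects, histogram otherwise."""
    if areas.size >= 10 and np.ptp(areas) > 0:
        logs = np.log(areas)
        kde = gaussian_kde(logs)  # Silverman-like bandwidth (scott default is close)
        grid = np.linspace(logs.min(), logs.max(), 512)
        return float(np.exp(grid[np.argmax(kde(grid))]))
    if np.ptp(areas) == 0:
        return float(areas[0])
    counts, edges = np.histogram(areas, bins="fd")
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def bundle_area_mode(dense_mask: np.ndarray, whole_stem: np.ndarray,
                     params: SegmentationParams,
                     pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Typical bundle area (mm^2): mode of object areas away from the epidermis.

    Only connected components whose centroid lies more than
    ``epidermis_exclusion_um`` inside the stem contour contribute.
    """
    areas_px, labels, n = _component_areas_and_labels(dense_mask)
    if n == 0:
        raise SegmentationError("insufficient-objects: dense mask is empty")
    depth = ndi.distance_transform_edt(whole_stem) * pixel_size_um
    centroids = ndi.center_of_mass(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    rows = np.clip(np.round([c[0] for c in centroids]).astype(int), 0, labels.shape[0] - 1)
    cols = np.clip(np.round([c[1] for c in centroids]).astype(int), 0, labels.shape[1] - 1)
    eligible = depth[rows, cols] > params.epidermis_exclusion_um
    if eligible.sum() < params.min_eligible_objects:
        raise SegmentationError(
            f"insufficient-objects: only {int(eligible.sum())} components beyond "
            f"{params.epidermis_exclusion_um} um from the epidermis")
    mm2 = (pixel_size_um / 1000.0) ** 2
    return _distribution_mode(areas_px[eligible] * mm2)


def classify_rind_bundles(dense_mask: np.ndarray, mode_area_mm2: float,
                          whole_stem: np.ndarray, params: SegmentationParams,
                          pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split dense tissue into rind and vascular bundles by size analysis.

    Returns ``(rind, bundles_individual, bundles_all)``.  External
    fragments (touching the stem contour) larger than
    ``rind_mode_multiplier`` times the mode are merged into the rind;
    everything else is a bundle.  Bundles within the individual size
    window become labels of ``bundles_individual``.
    """
    if mode_area_mm2 <= 0:
        raise ValueError("mode_area_mm2 must be positive")
    areas_px, labels, n = _component_areas_and_labels(dense_mask)
    mm2 = (pixel_size_um / 1000.0) ** 2
    depth_px = ndi.distance_transform_edt(whole_stem)
    rind = np.zeros_like(dense_mask, dtype=bool)
    lo, hi = params.bundle_size_window
    individual = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for i in range(1, n + 1):
        comp = labels == i
        area = areas_px[i - 1] * mm2
        external = bool((depth_px[comp] <= params.external_margin_px).any())
        if external and area > params.rind_mode_multiplier * mode_area_mm2:
            rind |= comp
        elif not external and lo * mode_area_mm2 <= area <= hi * mode_area_mm2:
            individual[comp] = next_label
            next_label += 1
    if not rind.any():
        warnings.warn("no rind fragment found; section may be a rind-free fragment",
                      stacklevel=2)
    bundles_all = dense_mask & ~rind
    return rind, individual, bundles_all


def derive_parenchyma_rois(whole_stem: np.ndarray, all_tissue: np.ndarray,
                           rind: np.ndarray, bundles_all: np.ndarray,
                           params: SegmentationParams,
                           pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parenchyma and its two distance bands from the rind.

    near-rind: distance to the rind below ``near_rind_max_um``;
    middle: above ``middle_min_um``.  The band in between belongs to the
    parenchyma but to neither sub-region.  Sub-regions are intersected
    with ``all_tissue`` (holes are absent tissue, not lumen).
    """
    parenchyma = whole_stem & ~(rind | bundles_all)
    if not parenchyma.any():
        raise SegmentationError("empty parenchyma")
    if rind.any():
        dist_um = ndi.distance_transform_edt(~rind) * pixel_size_um
    else:
        dist_um = np.full(whole_stem.shape, np.inf)
    measurable = parenchyma & all_tissue
    near = measurable & (dist_um < params.near_rind_max_um)
    middle = measurable & (dist_um > params.middle_min_um)
    return parenchyma, near, middle


def segment_section(img: np.ndarray, params: SegmentationParams | None = None,
                    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> RoiSet:
    """Run the full workflow on a darkfield or sum-intensity image."""
    params = params or SegmentationParams()
    whole_stem = segment_whole_stem(img, params)
    all_tissue = segment_all_tissue(img, whole_stem, params)
    enhanced = enhance_rind_bundles(img, params, pixel_size_um)
    dense = threshold_rind_bundles(enhanced, all_tissue)
    mode_area = bundle_area_mode(dense, whole_stem, params, pixel_size_um)
    rind, individual, bundles_all = classify_rind_bundles(
        dense, mode_area, whole_stem, params, pixel_size_um)
    parenchyma, near, middle = derive_parenchyma_rois(
        whole_stem, all_tissue, rind, bundles_all, params, pixel_size_um)
    rois = RoiSet(
        whole_stem=whole_stem, all_tissue=all_tissue, rind=rind,
        bundles_individual=individual, bundles_all=bundles_all,
        parenchyma=parenchyma, parenchyma_near_rind=near,
        parenchyma_middle=middle, pixel_size_um=pixel_size_um,
        rind_damaged=rind_coverage(rind, whole_stem) < 0.95,
    )
    rois.validate()
    return rois


def rind_coverage(rind: np.ndarray, whole_stem: np.ndarray,
                  margin_px: int = 3) -> float:
    """Fraction of the stem contour covered by rind (damage heuristic)."""
    contour = whole_stem & ~ndi.binary_erosion(whole_stem, iterations=margin_px)
    if not contour.any():
        return 0.0
    near_rind = ndi.binary_dilation(rind, iterations=margin_px)
    return float((contour & near_rind).sum() / contour.sum())
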