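"""Per-tissue autofluorescence pseudospectra.

A pseudospectrum is the vector of mean intensities over the 11 channels
for one tissue region.  Processing order is fixed: channel-dependent
background subtraction first, then (parenchyma only) division by the
cell-wall density, then section-level normalisation by the mean of the
four tissue means so that sections of different thickness become
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .channels import CANONICAL_CHANNELS, MultispectralImage

TISSUES = ("rind", "bundles", "parenchyma_near_rind", "parenchyma_middle")
PARENCHYMA_TISSUES = ("parenchyma_near_rind", "parenchyma_middle")


class PseudospectrumError(ValueError):
    pass


@dataclass(frozen=True)
class Pseudospectrum:
    """11 channel means for one tissue, with correction-state flags."""

    values: tuple[float, ...]
    tissue: str
    n_pixels: int = 0
    background_corrected: bool = False
    density_corrected: bool = False
    section_normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != len(CANONICAL_CHANNELS):
            raise PseudospectrumError(f"expected 11 values, got {len(self.values)}")
        if self.tissue not in TISSUES + ("background",):
            raise PseudospectrumError(f"unknown tissue {self.tissue!r}")
        arr = np.asarray(self.values)
        if not self.background_corrected and np.any(arr < 0):
            raise PseudospectrumError("raw pseudospectrum has negative values")
        if self.background_corrected and arr.size and arr.max() > 0:
            if arr.min() < -0.01 * arr.max() - 1e-12:
                # slight negatives are expected after subtraction; large ones
                # indicate a background estimated from signal-bearing pixels
                import warnings
                warnings.warn("strongly negative channel after background "
                              "subtraction", stacklevel=2)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def channel_mean(self) -> float:
        return float(self.array.mean())


def _roi_channel_means(ms: MultispectralImage, roi: np.ndarray) -> np.ndarray:
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise PseudospectrumError("empty region of interest")
    return np.array([float(ms[c][roi].mean()) for c in CANONICAL_CHANNELS])


def background_spectrum(ms: MultispectralImage,
                        bg_rois: Iterable[np.ndarray],
                        min_pixels: int = 100) -> Pseudospectrum:
    """Channel-wise mean over pooled signal-free regions."""
    rois = [np.asarray(r, dtype=bool) for r in bg_rois]
    if not rois:
        raise PseudospectrumError("need at least one background region")
    pooled = np.zeros(ms.shape, dtype=bool)
    for r in rois:
        if r.sum() < min_pixels:
            raise PseudospectrumError(
                f"background region has {int(r.sum())} px, need >= {min_pixels}")
        pooled |= r
    values = _roi_channel_means(ms, pooled)
    return Pseudospectrum(tuple(values), tissue="background",
                          n_pixels=int(pooled.sum()))


def auto_background_rois(ms: MultispectralImage, whole_stem: np.ndarray,
                         fraction: float = 0.01) -> list[np.ndarray]:
    """Surrogate for manual background picking: darkest pixels off the stem."""
    total = np.zeros(ms.shape)
    for c in CANONICAL_CHANNELS:
        total += ms[c]
    outside = ~np.asarray(whole_stem, dtype=bool)
    if not outside.any():
        raise PseudospectrumError("stem fills the image; no background available")
    cutoff = np.quantile(total[outside], fraction)
    return [outside & (total <= cutoff)]


def tissue_pseudospectrum(ms: MultispectralImage, roi: np.ndarray,
                          bg: Pseudospectrum, tissue: str) -> Pseudospectrum:
    """Background-subtracted channel means over a tissue region."""
    if bg.tissue != "background":
        raise PseudospectrumError("bg must be a background-typed pseudospectrum")
    values = _roi_channel_means(ms, roi) - bg.array
    return Pseudospectrum(tuple(values), tissue=tissue,
                          n_pixels=int(np.asarray(roi, dtype=bool).sum()),
                          background_corrected=True)


def density_correct(spec: Pseudospectrum, Cw_D_pct: float) -> Pseudospectrum:
    """Divide a parenchyma spectrum by its cell-wall density (fraction).

    This rescales the tissue mean to an estimate of the intensity of the
    walls alone, removing the lumen dilution.
    """
    if spec.tissue not in PARENCHYMA_TISSUES:
        raise PseudospectrumError(
            f"density correction applies to parenchyma only, not {spec.tissue!r}")
    if Cw_D_pct <= 0:
        raise PseudospectrumError("cell wall density must be positive")
    factor = Cw_D_pct / 100.0
    return replace(spec, values=tuple(spec.array / factor), density_corrected=True)


def section_normalize(specs: Mapping[str, Pseudospectrum],
                      ) -> tuple[dict[str, Pseudospectrum], float]:
    """Normalise the four tissue spectra of one section.

    The factor is the mean over tissues of each spectrum's mean over the
    11 channels; dividing by it removes the section-level intensity scale
    (thickness effect) while preserving between-tissue contrast.
    """
    if sorted(specs) != sorted(TISSUES):
        raise PseudospectrumError(f"need exactly the four tissues {TISSUES}, got {sorted(specs)}")
    for t in PARENCHYMA_TISSUES:
        if not specs[t].density_corrected:
            raise PseudospectrumError(f"{t} spectrum must be density-corrected first")
    for t, s in specs.items():
        if not s.background_corrected:
            raise PseudospectrumError(f"{t} spectrum must be background-corrected first")
    Fn = float(np.mean([specs[t].channel_mean for t in TISSUES]))
    if Fn <= 0:
        raise PseudospectrumError(f"normalization-failure: Fn = {Fn}")
    normalized = {
        t: replace(s, values=tuple(s.array / Fn), section_normalized=True)
        for t, s in specs.items()
    }
    return normalized, Fn


def section_pseudospectra(ms: MultispectralImage, rois, bg: Pseudospectrum,
                          Pm_CD_pct: float, Pr_CD_pct: float,
                          ) -> tuple[dict[str, Pseudospectrum], float]:
    """Full per-section spectra pipeline from an ROI set.

    ``rois`` needs ``rind``, ``bundles_all``, ``parenchyma_near_rind`` and
    ``parenchyma_middle`` masks.
    """
    specs = {
        "rind": tissue_pseudospectrum(ms, rois.rind, bg, "rind"),
        "bundles": tissue_pseudospectrum(ms, rois.bundles_all, bg, "bundles"),
        "parenchyma_near_rind": tissue_pseudospectrum(
            ms, rois.parenchyma_near_rind, bg, "parenchyma_near_rind"),
        "parenchyma_middle": tissue_pseudospectrum(
            ms, rois.parenchyma_middle, bg, "parenchyma_middle"),
    }
    specs["parenchyma_near_rind"] = density_correct(specs["parenchyma_near_rind"], Pr_CD_pct)
    specs["parenchyma_middle"] = density_correct(specs["parenchyma_middle"], Pm_CD_pct)
    return section_normalize(specs)
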