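"""Synthetic stem cross-section phantoms with full ground truth.

No image of the original study is publicly deposited, so validation runs
on generated phantoms: an annular rind, elliptical vascular bundles with
dense sheaths scattered in the pith, and a parenchyma mosaic of polygonal
cells (smaller near the rind) built from a centroidal Voronoi
tessellation.  Phantoms come with truth masks satisfying the ROI-set
invariants, per-tissue fluorescence signatures and the generating
parameters, so every pipeline stage can be scored against known answers.

All randomness flows from a single integer seed; identical parameters and
seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .channels import (BASELINE_CHANNELS, CANONICAL_CHANNELS,
                       MultispectralImage)
from .segmentation import RoiSet

#: Ratio of a hexagonal cell's area to the square of its across-flats
#: diameter; fixes the seed count so Lloyd-relaxed cells hit the target size.
_HEX_AREA_FACTOR = 0.866

#: Cell-size parameters are targets for the *grey-level size* measured by
#: square-structuring-element sieving.  A roundish cell of geometric
#: diameter D is removed once the square matches its max inscribed square
#: (about 0.72 D for relaxed Voronoi cells), so mosaic spacing is scaled
#: up by this factor to make the sieved size hit the requested value.
_SIEVE_CALIBRATION = 1.50


class PhantomError(RuntimeError):
    pass


def _default_signatures() -> dict[str, tuple[float, ...]]:
    """Per-tissue 11-channel emission signatures (zero at baseline channels).

    Parenchyma is UV-dominant, rind and bundles visible-dominant, with the
    rind strongest under visible excitation.
    """
    def sig(**kw: float) -> tuple[float, ...]:
        vec = {c: 0.0 for c in CANONICAL_CHANNELS}
        vec.update(kw)
        assert all(vec[c] == 0.0 for c in BASELINE_CHANNELS)
        return tuple(vec[c] for c in CANONICAL_CHANNELS)

    return {
        "rind": sig(U1b=30, U1g=25, U2b=35, U2g=30, U2r=20, BLg=60, BLr=55, GRr=45),
        "bundles": sig(U1b=35, U1g=28, U2b=40, U2g=32, U2r=18, BLg=50, BLr=45, GRr=35),
        "parenchyma_near_rind": sig(U1b=90, U1g=70, U2b=95, U2g=60, U2r=15, BLg=25, BLr=18, GRr=10),
        "parenchyma_middle": sig(U1b=100, U1g=80, U2b=110, U2g=70, U2r=18, BLg=30, BLr=22, GRr=12),
    }


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, optics and noise of a generated stem section."""

    stem_radius_um: float = 2300.0
    rind_thickness_um: float = 280.0
    n_bundles: int = 30
    #: bundles riding the rind's inner edge; anatomically part of the rind,
    #: they make its inner contour bumpy, which inflates thickness-based
    #: area estimates exactly as attached bundles do in real sections
    n_peripheral_bundles: int = 14
    bundle_major_um: float = 340.0
    bundle_minor_um: float = 260.0
    bundle_jitter_pct: float = 10.0
    cell_diameter_middle_um: float = 70.0
    cell_diameter_near_rind_um: float = 50.0
    wall_thickness_px: int = 1
    near_rind_band_um: float = 500.0
    hole_fraction: float = 0.0
    missing_rind_arc_deg: float = 0.0
    pixel_size_um: float = 3.63
    wall_intensity: float = 200.0
    lumen_intensity: float = 40.0
    background_intensity: float = 5.0
    noise_sd: float = 2.0
    section_gain: float = 1.0
    tissue_signatures: Mapping[str, tuple[float, ...]] = field(
        default_factory=_default_signatures)
    background_offsets: tuple[float, ...] = (
        8, 6, 9, 7, 5, 4, 6, 5, 3, 4, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_diameter_near_rind_um < self.cell_diameter_middle_um:
            raise PhantomError("near-rind cells must be smaller than middle cells")
        if not 0 <= self.hole_fraction < 1:
            raise PhantomError("hole_fraction must be in [0, 1)")
        if not 0 <= self.missing_rind_arc_deg <= 180:
            raise PhantomError("missing_rind_arc_deg must be in [0, 180]")
        if self.rind_thickness_um >= self.stem_radius_um:
            raise PhantomError("rind thicker than the stem radius")
        for tissue, vec in self.tissue_signatures.items():
            if len(vec) != len(CANONICAL_CHANNELS):
                raise PhantomError(f"signature of {tissue} must have 11 values")
            for name, v in zip(CANONICAL_CHANNELS, vec):
                if name in BASELINE_CHANNELS and v != 0:
                    raise PhantomError(
                        f"signature of {tissue} must be zero at baseline channel {name}")


@dataclass
class PhantomOutput:
    darkfield: np.ndarray
    multispectral: MultispectralImage
    truth_rois: RoiSet
    truth: dict
    params: PhantomParams


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _centroidal_labels(region: np.ndarray, diam_map_px: np.ndarray,
                       rng: np.random.Generator, n_iter: int = 2) -> np.ndarray:
    """Voronoi cell mosaic over ``region`` with locally targeted cell size.

    Seeds are drawn with density 1/d(x)^2 (rejection sampling), then a few
    Lloyd iterations move each seed to its cell centroid, which mimics the
    regular polygonal look of parenchyma.
    """
    coords = np.argwhere(region)
    if coords.shape[0] == 0:
        raise PhantomError("empty parenchyma region")
    d = diam_map_px[region]
    target_n = int(np.sum(1.0 / (_HEX_AREA_FACTOR * d ** 2)))
    if target_n < 4:
        raise PhantomError("region too small for the requested cell size")
    dmin2 = float(np.min(d)) ** 2
    accept_p = dmin2 / d ** 2
    # oversample then thin to target_n with the spatial acceptance profile
    weights = accept_p / accept_p.sum()
    idx = rng.choice(coords.shape[0], size=target_n, replace=False, p=weights)
    seeds = coords[idx].astype(float)

    labels = np.zeros(region.shape, dtype=np.int32)
    for _ in range(n_iter + 1):
        tree = cKDTree(seeds)
        _, assign = tree.query(coords, workers=-1)
        labels[region] = assign + 1
        sums = np.zeros((seeds.shape[0], 2))
        counts = np.zeros(seeds.shape[0])
        np.add.at(sums, assign, coords)
        np.add.at(counts, assign, 1)
        nonzero = counts > 0
        seeds = seeds.copy()
        seeds[nonzero] = sums[nonzero] / counts[nonzero, None]
    return labels


def _cell_walls(labels: np.ndarray, thickness_px: int) -> np.ndarray:
    """Binary wall map: pixels whose 4-neighbour has a different label."""
    walls = np.zeros(labels.shape, dtype=bool)
    walls[:, :-1] |= (labels[:, :-1] != labels[:, 1:]) & (labels[:, :-1] > 0) & (labels[:, 1:] > 0)
    walls[:-1, :] |= (labels[:-1, :] != labels[1:, :]) & (labels[:-1, :] > 0) & (labels[1:, :] > 0)
    if thickness_px > 1:
        walls = ndi.maximum_filter(walls, size=thickness_px + 1)
    return walls


def _place_bundles(params: PhantomParams, pith_radius_px: float,
                   shape: tuple[int, int], rng: np.random.Generator,
                   max_tries: int = 20000) -> np.ndarray:
    """Non-overlapping elliptical bundle label map inside the pith."""
    px = params.pixel_size_um
    a = params.bundle_major_um / 2 / px
    b = params.bundle_minor_um / 2 / px
    jit = params.bundle_jitter_pct / 100.0
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    protrude = params.bundle_major_um / 2 / px if params.n_peripheral_bundles else 0.0
    clearance = 4.0  # px between bundle edge and rind or other bundles
    placed: list[tuple[float, float, float]] = []  # (y, x, max radius)
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    tries = 0
    while len(placed) < params.n_bundles:
        tries += 1
        if tries > max_tries:
            raise PhantomError(
                f"generation-failure: placed {len(placed)}/{params.n_bundles} bundles")
        r = pith_radius_px - a - clearance - protrude
        if r <= 0:
            raise PhantomError("bundles do not fit inside the pith")
        rad = np.sqrt(rng.uniform(0, 1)) * r
        ang = rng.uniform(0, 2 * np.pi)
        y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        ai = a * (1 + rng.uniform(-jit, jit))
        bi = b * (1 + rng.uniform(-jit, jit))
        rmax = max(ai, bi)
        if any(np.hypot(y - py, x - px_) < rmax + pr + clearance
               for py, px_, pr in placed):
            continue
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - x) * ct + (yy - y) * st
        v = -(xx - x) * st + (yy - y) * ct
        inside = (u / ai) ** 2 + (v / bi) ** 2 <= 1.0
        labels[inside] = len(placed) + 1
        placed.append((y, x, rmax))
    return labels


def _peripheral_bundles(params: PhantomParams, rind_inner_px: float,
                        shape: tuple[int, int],
                        rng: np.random.Generator) -> np.ndarray:
    """Radially oriented ellipses straddling the rind's inner edge.

    Half of each ellipse overlaps the annulus and half bulges into the
    pith, so the rind's inner contour becomes bumpy.
    """
    mask = np.zeros(shape, dtype=bool)
    if params.n_peripheral_bundles <= 0:
        return mask
    px = params.pixel_size_um
    a = params.bundle_major_um / 2 / px
    b = params.bundle_minor_um / 2 / px
    jit = params.bundle_jitter_pct / 100.0
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    base = rng.uniform(0, 2 * np.pi)
    step = 2 * np.pi / params.n_peripheral_bundles
    for k in range(params.n_peripheral_bundles):
        ang = base + k * step + rng.uniform(-0.2, 0.2) * step
        y, x = cy + rind_inner_px * np.sin(ang), cx + rind_inner_px * np.cos(ang)
        ai = a * (1 + rng.uniform(-jit, jit))
        bi = b * (1 + rng.uniform(-jit, jit))
        ct, st = np.cos(ang), np.sin(ang)  # major axis along the radius
        u = (xx - x) * ct + (yy - y) * st
        v = -(xx - x) * st + (yy - y) * ct
        mask |= (u / ai) ** 2 + (v / bi) ** 2 <= 1.0
    return mask


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def generate_phantom(params: PhantomParams | None = None) -> PhantomOutput:
    """Build a darkfield image, an 11-channel stack and their ground truth."""
    params = params or PhantomParams()
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size_um
    margin_px = 12
    R = params.stem_radius_um / px
    n = int(2 * (R + margin_px))
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - cy, xx - cx)

    disk = rr <= R
    rind_inner = R - params.rind_thickness_um / px
    rind = disk & (rr > rind_inner)
    peripheral = _peripheral_bundles(params, rind_inner, (n, n), rng) & disk
    rind |= peripheral
    pith = (rr <= rind_inner) & ~peripheral

    if params.missing_rind_arc_deg > 0:
        theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        start = float(rng.uniform(0, 360))
        span = (theta - start) % 360.0 < params.missing_rind_arc_deg
        rind &= ~span
    whole_stem = pith | rind

    bundles = _place_bundles(params, rind_inner, (n, n), rng)
    bundles_all = bundles > 0

    parenchyma = pith & ~bundles_all
    dist_to_rind_um = ndi.distance_transform_edt(~rind) * px
    band = params.near_rind_band_um
    diam_px = np.where(dist_to_rind_um < band,
                       params.cell_diameter_near_rind_um,
                       params.cell_diameter_middle_um) * _SIEVE_CALIBRATION / px
    cell_labels = _centroidal_labels(parenchyma, diam_px, rng)
    walls = _cell_walls(cell_labels, params.wall_thickness_px) & parenchyma

    # section holes: random disks punched out of the parenchyma
    holes = np.zeros((n, n), dtype=bool)
    if params.hole_fraction > 0:
        target = params.hole_fraction * parenchyma.sum()
        hole_r = 3 * params.cell_diameter_middle_um / px
        guard = 0
        while holes.sum() < target and guard < 200:
            guard += 1
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform(0, 1)) * max(rind_inner - hole_r - 2, 1)
            y, x = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
            blob = (np.hypot(yy - y, xx - x) <= hole_r) & parenchyma
            holes |= blob
    all_tissue = whole_stem & ~holes

    # darkfield rendering: walls and dense tissue bright, lumens dim
    wall_frac = np.zeros((n, n))
    wall_frac[walls] = 1.0
    wall_frac[rind] = 1.0
    wall_frac[bundles_all] = 1.0
    darkfield = np.full((n, n), params.background_intensity)
    darkfield[parenchyma] = params.lumen_intensity
    darkfield[wall_frac > 0] = params.wall_intensity
    texture = rng.normal(1.0, 0.03, size=(n, n))
    darkfield[rind] *= texture[rind]
    darkfield[holes] = params.background_intensity
    darkfield = np.clip(darkfield + rng.normal(0, params.noise_sd, (n, n)), 0, None)

    # fluorescence: walls emit per-tissue signatures; lumens and holes dark
    emit = np.zeros((n, n))
    emit[wall_frac > 0] = 1.0
    emit[holes] = 0.0
    tissue_masks = {
        "rind": rind,
        "bundles": bundles_all,
        "parenchyma_near_rind": parenchyma & (dist_to_rind_um < band) & ~holes,
        "parenchyma_middle": parenchyma & (dist_to_rind_um >= band) & ~holes,
    }
    channels: dict[str, np.ndarray] = {}
    for i, ch in enumerate(CANONICAL_CHANNELS):
        grid = np.full((n, n), float(params.background_offsets[i]))
        for tissue, mask in tissue_masks.items():
            sig = params.tissue_signatures[tissue][i]
            if sig:
                grid += sig * params.section_gain * emit * mask
        grid += rng.normal(0, params.noise_sd, (n, n))
        channels[ch] = np.clip(grid, 0, None)
    ms = MultispectralImage(channels, pixel_size_um=px)

    near = parenchyma & all_tissue & (dist_to_rind_um < band)
    middle = parenchyma & all_tissue & (dist_to_rind_um > 2 * band)
    truth_rois = RoiSet(
        whole_stem=whole_stem, all_tissue=all_tissue, rind=rind,
        bundles_individual=bundles, bundles_all=bundles_all,
        parenchyma=parenchyma, parenchyma_near_rind=near,
        parenchyma_middle=middle, pixel_size_um=px,
        rind_damaged=params.missing_rind_arc_deg > 0,
    )
    truth_rois.validate()

    cm2 = (px / 10_000.0) ** 2
    truth = {
        "stem_area_cm2": float(whole_stem.sum()) * cm2,
        "rind_area_cm2": float(rind.sum()) * cm2,
        "bundle_area_cm2": float(bundles_all.sum()) * cm2,
        "parenchyma_area_cm2": float(parenchyma.sum()) * cm2,
        "hole_area_cm2": float(holes.sum()) * cm2,
        "n_bundles": int(params.n_bundles),
        "bundle_mean_area_mm2": float(bundles_all.sum() / params.n_bundles)
                                * (px / 1000.0) ** 2,
        "cell_diameter_middle_um": params.cell_diameter_middle_um,
        "cell_diameter_near_rind_um": params.cell_diameter_near_rind_um,
        "wall_pixel_fraction_middle": float(
            walls[tissue_masks["parenchyma_middle"]].mean())
            if tissue_masks["parenchyma_middle"].any() else float("nan"),
        "tissue_signatures": {t: tuple(v) for t, v in params.tissue_signatures.items()},
        "background_offsets": tuple(params.background_offsets),
        "holes": holes,
        "walls": walls,
    }
    return PhantomOutput(darkfield=darkfield, multispectral=ms,
                         truth_rois=truth_rois, truth=truth, params=params)


# ---------------------------------------------------------------------------
# composition table
# ---------------------------------------------------------------------------

def generate_composition_table(n_lines: int = 14, seed: int = 0,
                               kl_range: tuple[float, float] = (15.0, 21.0),
                               pca_range: tuple[float, float] = (1.0, 2.0),
                               fa_range: tuple[float, float] = (0.50, 0.72),
                               cw_range: tuple[float, float] = (47.0, 64.0)):
    """Synthetic per-line composition table with realistic ranges.

    Digestibility falls with lignin content; after conversion to relative
    phenolics the closure constraint induces the strong negative
    lignin / para-coumaric correlation seen in real data.
    """
    import pandas as pd
    if n_lines < 4:
        raise PhantomError("need at least 4 lines")
    rng = np.random.default_rng(seed)
    kl = rng.uniform(*kl_range, n_lines)
    pca = rng.uniform(*pca_range, n_lines)
    fa = rng.uniform(*fa_range, n_lines)
    cw = rng.uniform(*cw_range, n_lines)
    iv = np.clip(62.0 - 1.6 * kl + rng.normal(0, 1.5, n_lines), 20.0, 50.0)
    df = pd.DataFrame({
        "line_id": [f"S{i+1:02d}" for i in range(n_lines)],
        "cell_wall_pct_dm": np.round(cw, 1),
        "klason_lignin_pct_cw": np.round(kl, 2),
        "ester_pca_pct_cw": np.round(pca, 2),
        "ester_fa_pct_cw": np.round(fa, 2),
        "ivcwd_pct": np.round(iv, 1),
    })
    total = df["klason_lignin_pct_cw"] + df["ester_pca_pct_cw"] + df["ester_fa_pct_cw"]
    df["kl_rel"] = df["klason_lignin_pct_cw"] / total * 100.0
    df["pca_rel"] = df["ester_pca_pct_cw"] / total * 100.0
    df["fa_rel"] = df["ester_fa_pct_cw"] / total * 100.0
    return df
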