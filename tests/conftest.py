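import numpy as np
import pytest

from stemhisto.morphometry import describe_section
from stemhisto.segmentation import SegmentationParams, segment_section
from stemhisto.synthetic_stem import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size phantom (~1.2k px) shared by recovery tests."""
    return generate_phantom(PhantomParams(seed=1))


@pytest.fixture(scope="session")
def default_rois(default_phantom):
    return segment_section(default_phantom.darkfield,
                           pixel_size_um=default_phantom.params.pixel_size_um)


@pytest.fixture(scope="session")
def default_described(default_phantom, default_rois):
    return describe_section(default_rois, default_phantom.darkfield)


@pytest.fixture(scope="session")
def small_params():
    """Small, fast phantom for structural tests."""
    return PhantomParams(stem_radius_um=1200.0, rind_thickness_um=220.0,
                         n_bundles=8, n_peripheral_bundles=6, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return generate_phantom(small_params)


@pytest.fixture(scope="session")
def small_seg_params():
    # small phantoms have no pith deeper than 1 mm; relax the exclusion zone
    return SegmentationParams(epidermis_exclusion_um=400.0)


@pytest.fixture(scope="session")
def small_rois(small_phantom, small_seg_params):
    return segment_section(small_phantom.darkfield, small_seg_params,
                           pixel_size_um=small_phantom.params.pixel_size_um)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


# naive sliding-window morphology: the independent oracle used against the
# separable min/max implementation (scipy 'reflect' == numpy 'symmetric')

def naive_erosion(img: np.ndarray, width: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view
    pad = width // 2
    padded = np.pad(np.asarray(img, dtype=float), pad, mode="symmetric")
    return sliding_window_view(padded, (width, width)).min(axis=(-1, -2))


def naive_dilation(img: np.ndarray, width: int) -> np.ndarray:
    from numpy.lib.stride_tricks import sliding_window_view
    pad = width // 2
    padded = np.pad(np.asarray(img, dtype=float), pad, mode="symmetric")
    return sliding_window_view(padded, (width, width)).max(axis=(-1, -2))


def naive_closing(img: np.ndarray, width: int) -> np.ndarray:
    return naive_erosion(naive_dilation(img, width), width)


def naive_opening(img: np.ndarray, width: int) -> np.ndarray:
    return naive_dilation(naive_erosion(img, width), width)
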