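"""Multispectral autofluorescence image model.

A multispectral image holds 11 named fluorescence channels obtained by
merging four filter-cube RGB captures (UV excitations U1 and U2, visible
excitations BL and GR).  The red channel of the U1 capture is discarded at
assembly because it carries the excitation Rayleigh band.  Channels are
kept in a fixed canonical order so that pseudospectra and stored stacks
are comparable across sections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

#: Canonical channel order (high to low excitation energy, b/g/r per filter).
CANONICAL_CHANNELS: tuple[str, ...] = (
    "U1b", "U1g",
    "U2b", "U2g", "U2r",
    "BLb", "BLg", "BLr",
    "GRb", "GRg", "GRr",
)

#: Channels with no physical emission (below the excitation wavelength).
#: They carry only background and are kept as a baseline in pseudospectra.
BASELINE_CHANNELS: frozenset[str] = frozenset({"BLb", "GRb", "GRg"})

FILTERS: tuple[str, ...] = ("U1", "U2", "BL", "GR")

#: Filters whose captures receive the visible-gain multiplier at assembly.
VISIBLE_FILTERS: frozenset[str] = frozenset({"BL", "GR"})

#: Named channel subsets for sum-intensity images.
CHANNEL_PRESETS: dict[str, tuple[str, ...]] = {
    "all": CANONICAL_CHANNELS,
    "visible": ("BLg", "BLr", "GRr"),
}

DEFAULT_PIXEL_SIZE_UM = 2.78
DEFAULT_VISIBLE_GAIN = 2.0


class ChannelError(ValueError):
    """Invalid channel name or inconsistent channel data."""


@dataclass(frozen=True)
class FilterCapture:
    """One RGB acquisition through a single fluorescence filter cube."""

    filter_name: str
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self) -> None:
        if self.filter_name not in FILTERS:
            raise ChannelError(f"unknown filter {self.filter_name!r}; expected one of {FILTERS}")
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if len(shapes) != 1:
            raise ChannelError(f"RGB grids of filter {self.filter_name} differ in shape: {shapes}")
        for name, grid in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            if np.any(np.asarray(grid) < 0):
                raise ChannelError(f"{self.filter_name} {name} grid contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


@dataclass
class MultispectralImage:
    """11-channel fluorescence stack with canonical channel order."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    visible_gain: float = DEFAULT_VISIBLE_GAIN
    baseline_channels: frozenset[str] = field(default=BASELINE_CHANNELS)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_CHANNELS if c not in self.channels]
        extra = [c for c in self.channels if c not in CANONICAL_CHANNELS]
        if missing or extra:
            raise ChannelError(f"channel set mismatch: missing={missing}, unexpected={extra}")
        # re-order storage canonically
        self.channels = {c: np.asarray(self.channels[c], dtype=float) for c in CANONICAL_CHANNELS}
        shapes = {g.shape for g in self.channels.values()}
        if len(shapes) != 1:
            raise ChannelError(f"channel grids differ in shape: {shapes}")
        if self.pixel_size_um <= 0:
            raise ChannelError("pixel_size_um must be positive")
        for c, g in self.channels.items():
            if np.any(g < 0):
                raise ChannelError(f"channel {c} contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def stack(self) -> np.ndarray:
        """Return the channels as a (11, H, W) array in canonical order."""
        return np.stack([self.channels[c] for c in CANONICAL_CHANNELS])

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ChannelError(f"unknown channel {name!r}") from None


def assemble_multispectral(
    captures: Iterable[FilterCapture],
    visible_gain: float = DEFAULT_VISIBLE_GAIN,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> MultispectralImage:
    """Merge the four filter captures into an 11-channel image.

    The BL and GR captures are multiplied by ``visible_gain`` (their raw
    intensities are much lower than under UV excitation) and the U1 red
    channel is dropped.
    """
    captures = list(captures)
    seen = [c.filter_name for c in captures]
    if sorted(seen) != sorted(FILTERS):
        raise ChannelError(f"need exactly one capture per filter {FILTERS}, got {seen}")
    shapes = {c.shape for c in captures}
    if len(shapes) != 1:
        raise ChannelError(f"captures differ in shape: {shapes}")
    if visible_gain <= 0:
        raise ChannelError("visible_gain must be positive")

    by_filter = {c.filter_name: c for c in captures}
    grids: dict[str, np.ndarray] = {}
    for name in CANONICAL_CHANNELS:
        filt, band = name[:2], name[2]
        cap = by_filter[filt]
        grid = {"r": cap.red, "g": cap.green, "b": cap.blue}[band]
        gain = visible_gain if filt in VISIBLE_FILTERS else 1.0
        grids[name] = np.asarray(grid, dtype=float) * gain
    return MultispectralImage(grids, pixel_size_um=pixel_size_um, visible_gain=visible_gain)


def composite_rgb(ms: MultispectralImage) -> np.ndarray:
    """Colour rendering of the stack as an (H, W, 3) float array.

    red = mean(U2r, BLr, GRr); green = mean(U1g, U2g, BLg);
    blue = mean(U1b, U2b).
    """
    red = (ms["U2r"] + ms["BLr"] + ms["GRr"]) / 3.0
    green = (ms["U1g"] + ms["U2g"] + ms["BLg"]) / 3.0
    blue = (ms["U1b"] + ms["U2b"]) / 2.0
    return np.stack([red, green, blue], axis=-1)


def sum_image(ms: MultispectralImage, subset: str | Sequence[str] = "all") -> np.ndarray:
    """Per-pixel sum of intensities over a channel subset.

    ``subset`` is either a preset name (``"all"``, ``"visible"``) or an
    explicit collection of canonical channel names.
    """
    if isinstance(subset, str):
        try:
            names: Sequence[str] = CHANNEL_PRESETS[subset]
        except KeyError:
            raise ChannelError(
                f"unknown preset {subset!r}; presets are {sorted(CHANNEL_PRESETS)}"
            ) from None
    else:
        names = list(subset)
        if not names:
            raise ChannelError("channel subset must be non-empty")
        unknown = [n for n in names if n not in CANONICAL_CHANNELS]
        if unknown:
            raise ChannelError(f"unknown channel names {unknown}")
    out = np.zeros(ms.shape, dtype=float)
    for n in names:
        out += ms[n]
    return out


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def write_multispectral(ms: MultispectralImage, path: str | Path) -> Path:
    """Write the stack as a multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, ms.stack().astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "channels": list(CANONICAL_CHANNELS),
        "pixel_size_um": ms.pixel_size_um,
        "visible_gain": ms.visible_gain,
        "baseline_channels": sorted(ms.baseline_channels),
    }, indent=2))
    return path


def read_multispectral(path: str | Path) -> MultispectralImage:
    """Read a stack written by :func:`write_multispectral`."""
    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim != 3 or stack.shape[0] != len(CANONICAL_CHANNELS):
        raise ChannelError(f"expected an (11, H, W) stack, got shape {stack.shape}")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: Mapping[str, object] = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        order = list(meta.get("channels", CANONICAL_CHANNELS))
        if order != list(CANONICAL_CHANNELS):
            raise ChannelError(f"sidecar channel order {order} is not canonical")
    return MultispectralImage(
        {c: stack[i] for i, c in enumerate(CANONICAL_CHANNELS)},
        pixel_size_um=float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
        visible_gain=float(meta.get("visible_gain", DEFAULT_VISIBLE_GAIN)),
    )


def write_composite_rgb(ms: MultispectralImage, path: str | Path) -> Path:
    """Write an 8-bit RGB rendering after per-image max scaling."""
    rgb = composite_rgb(ms)
    peak = float(rgb.max())
    scaled = np.zeros_like(rgb) if peak == 0 else rgb / peak
    path = Path(path)
    tifffile.imwrite(path, (scaled * 255).astype(np.uint8))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"scaling": "per-image max", "max_intensity": peak}))
    return path
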