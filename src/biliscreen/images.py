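"""Image review, uniform-region selection and RGB intensity extraction.

A study image is an 8-bit RGB patch of neonatal glabella skin. The analysis
marks the most uniform square region of each patch, screens it for quality
(saturation, local artifacts such as hair, region size), and summarises the
red, green and blue channel intensities over the region. Intensities live on
the usual 0-255 digital scale, channel order is red/green/blue, and pixel
coordinates are row-major with a 0-based top-left origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "CHANNELS",
    "SkinImage",
    "RegionMask",
    "ChannelSummary",
    "QcThresholds",
    "QcReport",
    "select_uniform_region",
    "qc_image",
    "extract_intensity",
    "block_summaries",
    "read_image",
    "write_image",
    "write_mask",
    "summary_row",
]

logger = logging.getLogger(__name__)

CHANNELS = ("red", "green", "blue")

#: acquisition methods used in the study this pipeline models
METHODS = ("direct", "dermatoscope", "dermatoscope_filter")


class ImageError(ValueError):
    """Raised for malformed images, masks or incompatible arguments."""


@dataclass
class SkinImage:
    """An 8-bit RGB skin patch with acquisition metadata.

    ``pixels`` has shape (height, width, 3), dtype uint8, channel order RGB.
    """

    pixels: np.ndarray
    method: str = "dermatoscope"
    subject_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageError(f"pixels must be (h, w, 3); got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ImageError(f"image must be at least 8x8; got {px.shape[:2]}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ImageError("pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        if self.method not in METHODS:
            raise ImageError(f"unknown acquisition method {self.method!r}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class RegionMask:
    """Boolean grid marking the analysed uniform area of one image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.dtype != bool:
            raise ImageError("mask must be a 2-D boolean array")
        self.mask = m

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class ChannelSummary:
    """Per-channel location summaries over an analysed region.

    Each statistic is a length-3 array in red/green/blue order.
    ``aggregation_block`` is 1 for raw-pixel summaries and the block side for
    block-averaged summaries.
    """

    mean: np.ndarray
    median: np.ndarray
    p25: np.ndarray
    p75: np.ndarray
    n_pixels: int
    aggregation_block: int = 1

    def channel(self, name: str) -> dict:
        i = CHANNELS.index(name)
        return {
            "mean": float(self.mean[i]),
            "median": float(self.median[i]),
            "p25": float(self.p25[i]),
            "p75": float(self.p75[i]),
        }


@dataclass
class QcThresholds:
    """Quality-control limits for an analysed region.

    ``max_saturated_fraction``: highest tolerated share of region pixels with
    any channel at 255. ``max_artifact_fraction``: highest tolerated share of
    pixels deviating more than ``artifact_k`` channel standard deviations from
    the region mean (a local analogue of the population outlier rule).
    ``max_region_sd`` optionally caps the mean within-region channel SD; it is
    disabled by default.
    """

    max_saturated_fraction: float = 0.05
    max_artifact_fraction: float = 0.10
    min_region_pixels: int = 16
    artifact_k: float = 3.0
    max_region_sd: Optional[float] = None


@dataclass
class QcReport:
    passed: bool
    reasons: list
    saturated_fraction: float
    artifact_fraction: float

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


def _window_sums(arr: np.ndarray, k: int) -> np.ndarray:
    """Sums of all k-by-k windows of a 2-D array via a summed-area table."""
    s = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=s[1:, 1:])
    return s[k:, k:] - s[:-k, k:] - s[k:, :-k] + s[:-k, :-k]


def select_uniform_region(image: SkinImage, window_side: int = 16) -> RegionMask:
    """Mark the most uniform square window of the image.

    Scans every window position and returns the one minimising the sum over
    channels of the within-window pixel variance (population variance). Ties
    are broken by the smallest row, then column, of the window's top-left
    corner, so the result is deterministic. This automates the manual
    "most uniform area" marking of the original protocol.
    """
    h, w = image.height, image.width
    if window_side < 4:
        raise ImageError("window_side must be at least 4")
    if window_side > min(h, w):
        raise ImageError(
            f"window_side {window_side} exceeds image size {h}x{w}"
        )
    k = window_side
    npix = float(k * k)
    score = np.zeros((h - k + 1, w - k + 1), dtype=np.float64)
    px = image.pixels.astype(np.float64)
    for c in range(3):
        s1 = _window_sums(px[:, :, c], k)
        s2 = _window_sums(px[:, :, c] ** 2, k)
        score += s2 / npix - (s1 / npix) ** 2
    # argmin on the flattened array returns the first minimum in row-major
    # order, which is exactly the (row, column) tie-break rule.
    r0, c0 = np.unravel_index(int(np.argmin(score)), score.shape)
    mask = np.zeros((h, w), dtype=bool)
    mask[r0 : r0 + k, c0 : c0 + k] = True
    return RegionMask(mask)


def qc_image(
    image: SkinImage,
    mask: RegionMask,
    thresholds: QcThresholds | None = None,
) -> QcReport:
    """Screen an analysed region for inadmissible quality.

    Fails on excess saturation (any channel at 255), excess local artifact
    pixels (deviating more than ``artifact_k`` channel SDs from the region
    mean), a region below the minimum pixel count, or — if configured — low
    uniformity (mean within-region channel SD above ``max_region_sd``).
    """
    t = thresholds or QcThresholds()
    if mask.mask.shape != image.pixels.shape[:2]:
        raise ImageError("mask shape does not match image")
    reasons: list[str] = []
    vals = image.pixels[mask.mask].astype(np.float64)  # (n, 3)
    n = vals.shape[0]
    if n < t.min_region_pixels:
        return QcReport(False, ["region_too_small"], 0.0, 0.0)
    saturated = float(np.mean(np.any(image.pixels[mask.mask] == 255, axis=1)))
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)  # population SD, denominator n
    dev = np.abs(vals - mean)
    # a zero-SD channel cannot flag artifacts (everything equals the mean)
    with np.errstate(invalid="ignore"):
        flagged = np.any((dev > t.artifact_k * sd) & (sd > 0), axis=1)
    artifact = float(np.mean(flagged))
    if saturated > t.max_saturated_fraction:
        reasons.append("saturation_excess")
    if artifact > t.max_artifact_fraction:
        reasons.append("artifact_excess")
    if t.max_region_sd is not None and float(sd.mean()) > t.max_region_sd:
        reasons.append("low_uniformity")
    return QcReport(len(reasons) == 0, reasons, saturated, artifact)


def _summarise(vals: np.ndarray, n_pixels: int, block: int) -> ChannelSummary:
    """Location summaries of an (n, 3) array of channel values."""
    # linear interpolation between order statistics, stated so results are
    # reproducible across implementations
    q = np.percentile(vals, [25.0, 50.0, 75.0], axis=0, method="linear")
    return ChannelSummary(
        mean=vals.mean(axis=0),
        median=q[1],
        p25=q[0],
        p75=q[2],
        n_pixels=n_pixels,
        aggregation_block=block,
    )


def extract_intensity(image: SkinImage, mask: RegionMask) -> ChannelSummary:
    """Per-channel mean/median/quartiles over the masked pixels.

    The mean is the exact arithmetic mean of the 8-bit values, computed in
    float64 with no rounding.
    """
    if mask.mask.shape != image.pixels.shape[:2]:
        raise ImageError("mask shape does not match image")
    if not mask.mask.any():
        raise ImageError("empty mask")
    vals = image.pixels[mask.mask].astype(np.float64)
    return _summarise(vals, vals.shape[0], 1)


def block_summaries(
    image: SkinImage, mask: RegionMask, block_side: int
) -> ChannelSummary:
    """Summaries over non-overlapping block means instead of raw pixels.

    The mask's bounding box is tiled with ``block_side``-square blocks from
    its top-left corner; only blocks lying fully inside the mask contribute.
    Each block's value is its per-channel pixel mean; the summary statistics
    are then taken over block values. Blocks of side 2-4 average 4-16 pixels.
    """
    if block_side not in (2, 3, 4):
        raise ImageError("block_side must be 2, 3 or 4")
    if mask.mask.shape != image.pixels.shape[:2]:
        raise ImageError("mask shape does not match image")
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise ImageError("empty mask")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    b = block_side
    block_vals = []
    for r in range(r0, r1 - b + 1, b):
        for c in range(c0, c1 - b + 1, b):
            sub = mask.mask[r : r + b, c : c + b]
            if sub.all():
                block_vals.append(
                    image.pixels[r : r + b, c : c + b].astype(np.float64).mean(axis=(0, 1))
                )
    if len(block_vals) < 2:
        raise ImageError(
            f"fewer than 2 complete {b}x{b} blocks inside the mask"
        )
    vals = np.asarray(block_vals)
    return _summarise(vals, len(block_vals) * b * b, b)


def read_image(path: str | Path, method: str = "dermatoscope") -> SkinImage:
    """Read an 8-bit RGB image (PNG/TIFF/JPEG) as a SkinImage.

    JPEG is accepted with a warning: lossy compression perturbs the channel
    intensities the analysis depends on.
    """
    path = Path(path)
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        logger.warning("JPEG input %s: lossy compression perturbs intensities", path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return SkinImage(arr, method=method, subject_id=path.stem)


def write_image(image: SkinImage, path: str | Path) -> None:
    """Write as 8-bit RGB PNG (no alpha)."""
    Image.fromarray(image.pixels, mode="RGB").save(Path(path), format="PNG")


def write_mask(mask: RegionMask, path: str | Path) -> None:
    """Write as single-channel PNG, 255 inside the region."""
    Image.fromarray(mask.mask.astype(np.uint8) * 255, mode="L").save(
        Path(path), format="PNG"
    )


def summary_row(
    subject_id: str, method: str, summary: ChannelSummary
) -> list[dict]:
    """Flatten a ChannelSummary into per-channel CSV rows."""
    rows = []
    for i, ch in enumerate(CHANNELS):
        rows.append(
            {
                "subject_id": subject_id,
                "method": method,
                "channel": ch,
                "mean": float(summary.mean[i]),
                "median": float(summary.median[i]),
                "p25": float(summary.p25[i]),
                "p75": float(summary.p75[i]),
                "n_pixels": summary.n_pixels,
                "aggregation_block": summary.aggregation_block,
            }
        )
    return rows
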