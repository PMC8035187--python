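"""Immunofluorescence quantification inside a ventral-horn ROI.

Two published readouts are implemented: threshold-based percent-positive
pixel area of a marker channel (e.g. IBA1, GFAP) after scalar background
subtraction, and the viral transduction yield, i.e. the percentage of
ChAT-immunopositive motor neurons co-labelled with the tdTomato reporter.

Images are single-plane 2-D intensity arrays (Z-stacks are assumed already
maximum-projected); the ROI is a polygon in pixel coordinates (row, col).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

from .errors import ConfigurationError, UndefinedMetricError


@dataclass
class CellRecord:
    """Ground-truth or scored cell: centroid plus marker positivity flags."""

    centroid: tuple[float, float]  # (row, col) pixels
    chat_positive: bool
    tdtomato_positive: bool


@dataclass
class HistologyField:
    """One imaged field: named channels, an ROI polygon, and cell records."""

    channels: dict[str, np.ndarray]
    roi: np.ndarray  # (k, 2) polygon vertices, (row, col)
    cell_records: list[CellRecord] = field(default_factory=list)
    pixel_size_um: float = 0.5
    background: float = 0.0
    suggested_threshold: float = 100.0

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ConfigurationError("all channels must share one image shape")
        self.roi = np.asarray(self.roi, dtype=float)
        if self.roi.ndim != 2 or self.roi.shape[1] != 2 or self.roi.shape[0] < 3:
            raise ConfigurationError("ROI must be a polygon of >= 3 (row, col) vertices")


def roi_mask(image_shape: tuple[int, int], roi: np.ndarray) -> np.ndarray:
    mask = polygon2mask(image_shape, np.asarray(roi, dtype=float))
    if not mask.any():
        raise ConfigurationError("ROI polygon covers no pixels")
    return mask


def percent_positive_area(
    image: np.ndarray,
    roi: np.ndarray,
    threshold: float,
    background: float = 0.0,
) -> float:
    """Percent of ROI pixels whose background-subtracted intensity exceeds
    the threshold.

    A pixel is positive when ``intensity - background > threshold``; the
    result is 100 x (positive pixels in ROI) / (pixels in ROI).
    """
    if threshold < background:
        raise ConfigurationError("threshold must be >= background")
    image = np.asarray(image, dtype=float)
    mask = roi_mask(image.shape, roi)
    positive = (image - background) > threshold
    return 100.0 * float(np.count_nonzero(positive & mask)) / float(np.count_nonzero(mask))


def transduction_yield(cells: list[CellRecord]) -> float:
    """Percent of ChAT-positive cells that are also tdTomato-positive."""
    chat = [c for c in cells if c.chat_positive]
    if not chat:
        raise UndefinedMetricError("transduction yield undefined without ChAT+ cells")
    co = sum(1 for c in chat if c.tdtomato_positive)
    return 100.0 * co / len(chat)


def field_metrics(
    fld: HistologyField,
    marker_channel: str | None = None,
    threshold: float | None = None,
) -> dict[str, float]:
    """Standard per-field report: percent-positive area and transduction yield."""
    out: dict[str, float] = {}
    thr = fld.suggested_threshold if threshold is None else threshold
    channels = [marker_channel] if marker_channel else [
        ch for ch in fld.channels if ch != "tdTomato"
    ]
    for ch in channels:
        if ch not in fld.channels:
            raise ConfigurationError(f"channel {ch!r} not present in field")
        out[f"percent_area_{ch}"] = percent_positive_area(
            fld.channels[ch], fld.roi, thr, fld.background
        )
    if fld.cell_records:
        out["transduction_yield_pct"] = transduction_yield(fld.cell_records)
    return out
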