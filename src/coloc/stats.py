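"""Per-region co-localization statistics for two-channel images.

Two classical pixel-intensity statistics are computed inside each region of
interest, over the paired intensities :math:`R_i` (channel 1) and
:math:`G_i` (channel 2):

Pearson's correlation coefficient (PCC)

.. math::
    \\mathrm{PCC} = \\frac{\\sum_i (R_i-\\bar R)(G_i-\\bar G)}
        {\\sqrt{\\sum_i (R_i-\\bar R)^2 \\; \\sum_i (G_i-\\bar G)^2}}

Mean subtraction makes PCC independent of the background level; it measures
both co-occurrence and proportionality of the two signals and lies in
[-1, 1].

Manders overlap coefficient (MOC)

.. math::
    \\mathrm{MOC} = \\frac{\\sum_i R_i G_i}
        {\\sqrt{\\sum_i R_i^2 \\; \\sum_i G_i^2}}

No mean is subtracted, so MOC lies in [0, 1] for non-negative intensities
and measures co-occurrence without requiring a linear relationship.

Undefined cases (zero variance for PCC, an all-zero channel for MOC) yield
``nan`` with a logged warning rather than an exception, so a batch table
over many regions stays rectangular even when one region is degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .image_io import RasterImage, get_channel
from .roi import ROILabels

logger = logging.getLogger("coloc")

STATISTICS = ("pcc", "moc")


@dataclass(frozen=True)
class PixelPairs:
    """Paired channel intensities extracted from one region of interest."""

    r: np.ndarray
    g: np.ndarray
    roi_id: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=np.float64).ravel()
        g = np.asarray(self.g, dtype=np.float64).ravel()
        if r.size != g.size or r.size < 1:
            raise ValueError("r and g must have equal length >= 1")
        if self.roi_id < 1:
            raise ValueError("roi_id must be a positive label")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "g", g)


def pearson(r: np.ndarray, g: np.ndarray) -> float:
    """Pearson's correlation coefficient of two intensity vectors.

    Returns ``nan`` (with a warning) when either channel has zero variance,
    since the denominator vanishes.
    """
    r = np.asarray(r, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    if r.size != g.size:
        raise ValueError("channel vectors must have equal length")
    if r.size < 2:
        raise ValueError("PCC needs at least 2 pixel pairs")
    dr = r - r.mean()
    dg = g - g.mean()
    denom = np.sqrt(np.sum(dr * dr) * np.sum(dg * dg))
    if denom == 0.0:
        logger.warning("PCC undefined: zero variance in at least one channel")
        return float("nan")
    return float(np.sum(dr * dg) / denom)


def manders(r: np.ndarray, g: np.ndarray) -> float:
    """Manders overlap coefficient of two non-negative intensity vectors.

    Returns ``nan`` (with a warning) when either channel is identically
    zero.
    """
    r = np.asarray(r, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    if r.size != g.size:
        raise ValueError("channel vectors must have equal length")
    if r.size < 1:
        raise ValueError("MOC needs at least 1 pixel pair")
    if r.min() < 0.0 or g.min() < 0.0:
        raise ValueError("MOC is defined for non-negative intensities")
    denom = np.sqrt(np.sum(r * r) * np.sum(g * g))
    if denom == 0.0:
        logger.warning("MOC undefined: at least one channel is all zero")
        return float("nan")
    return float(np.sum(r * g) / denom)


def intensities_by_roi(
    img: RasterImage,
    labels: ROILabels,
    ch1: int = 1,
    ch2: int = 2,
) -> list[PixelPairs]:
    """Extract positionally aligned channel intensities for every region.

    Returns one :class:`PixelPairs` per positive label, in label order;
    background pixels are excluded.
    """
    if labels.labels.shape != (img.height, img.width):
        raise ValueError(
            f"labels shape {labels.labels.shape} does not match image shape {(img.height, img.width)}"
        )
    if ch1 == ch2:
        raise ValueError("ch1 and ch2 must be different channels")
    plane1 = get_channel(img, ch1)
    plane2 = get_channel(img, ch2)
    out: list[PixelPairs] = []
    for roi_id in range(1, labels.n_selected + 1):
        sel = labels.labels == roi_id
        out.append(PixelPairs(plane1[sel], plane2[sel], roi_id))
    return out


_STAT_FUNCS = {"pcc": pearson, "moc": manders}


def coloc_test(
    img: RasterImage,
    labels: ROILabels,
    statistics: Iterable[str] = STATISTICS,
    ch1: int = 1,
    ch2: int = 2,
) -> pd.DataFrame:
    """Compute the requested statistics for every region of interest.

    Returns a table with one row per region plus an ``"average"`` row (the
    unweighted mean over regions, ignoring undefined values), and one column
    per requested statistic.  Full precision is retained; rounding is left
    to presentation.
    """
    stats: Sequence[str] = tuple(statistics)
    if not stats:
        raise ValueError("at least one statistic must be requested")
    unknown = set(stats) - set(STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics {sorted(unknown)}; available: {STATISTICS}")

    rows = []
    for pairs in intensities_by_roi(img, labels, ch1, ch2):
        row: dict[str, object] = {"roi": pairs.roi_id}
        for name in stats:
            if name == "pcc" and pairs.r.size < 2:
                logger.warning("PCC undefined for single-pixel ROI %d", pairs.roi_id)
                row[name] = float("nan")
            else:
                row[name] = _STAT_FUNCS[name](pairs.r, pairs.g)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["roi", *stats])
    avg = {"roi": "average", **{name: table[name].mean(skipna=True) for name in stats}}
    return pd.concat([table, pd.DataFrame([avg])], ignore_index=True)
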