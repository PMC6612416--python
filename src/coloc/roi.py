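"""Region-of-interest selection by percentile thresholding and morphology.

The selection pipeline mirrors the interactive workflow a microscopist uses
to isolate cells from a dark background:

1. project the merge image to grayscale,
2. keep pixels strictly above a percentile threshold,
3. ``shrink`` (binary erosion) and ``grow`` (binary dilation) to trim or pad
   the selection,
4. ``fill`` gaps (morphological closing) and ``clean`` specks (opening),
5. label 4-connected components and keep the ``n`` largest, ranked by pixel
   count.

All morphological steps use a ``size x size`` square structuring element;
pixels outside the image count as background for both erosion and dilation,
which prevents phantom growth at the borders.  A size of 0 or 1 is the
identity, so every step can be switched off independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

from .image_io import RasterImage, to_grayscale

logger = logging.getLogger("coloc")

# 4-connectivity: regions touching only diagonally are distinct cells
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the ROI selection pipeline.

    Attributes
    ----------
    threshold
        Percentile in [0, 100]; pixels strictly above this percentile of the
        grayscale image are foreground.
    shrink, grow, fill, clean
        Square structuring-element sizes in pixels for erosion, dilation,
        closing and opening respectively; 0 skips the step.
    n
        Number of largest connected regions to keep (>= 1).
    """

    threshold: float = 50.0
    shrink: int = 5
    grow: int = 0
    fill: int = 0
    clean: int = 0
    n: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 100.0:
            raise ValueError(f"threshold must be a percentile in [0, 100], got {self.threshold}")
        for name in ("shrink", "grow", "fill", "clean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class ROILabels:
    """Integer label matrix: 0 = background, 1..n_selected = regions.

    Positive labels are contiguous and ranked by descending pixel count, so
    region 1 is always the largest.  Each positive label is a single
    4-connected component.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be a 2D integer array")
        object.__setattr__(self, "labels", lab.astype(np.int32))

    @property
    def n_selected(self) -> int:
        return int(self.labels.max(initial=0))

    def region_sizes(self) -> np.ndarray:
        """Pixel count of each region, indexed by label 1..n_selected."""
        return np.bincount(self.labels.ravel(), minlength=self.n_selected + 1)[1:]


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def threshold_mask(plane: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground = pixels strictly greater than the ``threshold``-th
    percentile of all pixel values in ``plane``.

    The percentile is computed by linear interpolation between order
    statistics (numpy's default), and the comparison is strict, so a
    constant plane yields an empty mask for any threshold.
    """
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    plane = np.asarray(plane, dtype=np.float64)
    cutoff = np.percentile(plane, threshold)
    return plane > cutoff


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def _check_mask_size(mask: np.ndarray, size: int) -> np.ndarray:
    if size < 0:
        raise ValueError(f"structuring element size must be >= 0, got {size}")
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2D array")
    return mask.astype(bool)


def erode(mask: np.ndarray, size: int) -> np.ndarray:
    """Binary erosion ("shrink") with a size x size square element."""
    mask = _check_mask_size(mask, size)
    if size <= 1:
        return mask.copy()
    return ndi.binary_erosion(mask, structure=np.ones((size, size), bool), border_value=0)


def dilate(mask: np.ndarray, size: int) -> np.ndarray:
    """Binary dilation ("grow") with a size x size square element."""
    mask = _check_mask_size(mask, size)
    if size <= 1:
        return mask.copy()
    return ndi.binary_dilation(mask, structure=np.ones((size, size), bool))


def fill_gaps(mask: np.ndarray, size: int) -> np.ndarray:
    """Morphological closing ("fill"): dilate then erode with one element.

    Bridges gaps and holes narrower than the element without changing the
    outline of large structures.
    """
    return erode(dilate(mask, size), size)


def clean_specks(mask: np.ndarray, size: int) -> np.ndarray:
    """Morphological opening ("clean"): erode then dilate with one element.

    Removes foreground specks smaller than the element without changing the
    outline of large structures.
    """
    return dilate(erode(mask, size), size)


# ---------------------------------------------------------------------------
# labeling and selection
# ---------------------------------------------------------------------------

def label_components(mask: np.ndarray) -> ROILabels:
    """Label 4-connected components, ranked 1..k by descending pixel count.

    Ties in size are broken by the smaller row-major index of each
    component's first pixel, so the output is fully deterministic.
    """
    mask = np.asarray(mask).astype(bool)
    raw, k = ndi.label(mask, structure=_CROSS)
    if k == 0:
        return ROILabels(np.zeros(mask.shape, dtype=np.int32))
    sizes = np.bincount(raw.ravel())[1:]  # per raw label 1..k
    # first row-major occurrence of each raw label
    flat = raw.ravel()
    order_of_first = np.full(k + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    order_of_first[flat[nz[::-1]]] = nz[::-1]
    rank = sorted(range(1, k + 1), key=lambda lab: (-sizes[lab - 1], order_of_first[lab]))
    remap = np.zeros(k + 1, dtype=np.int32)
    for new, old in enumerate(rank, start=1):
        remap[old] = new
    return ROILabels(remap[raw])


def select_rois(img: RasterImage, params: SelectionParams) -> ROILabels:
    """Run the full selection pipeline on a merge image.

    Pipeline: grayscale -> threshold -> shrink -> grow -> fill -> clean ->
    label -> keep the ``n`` largest components relabeled 1..m with
    m = min(n, components found).

    An empty post-morphology mask returns all-zero labels with a logged
    warning rather than raising, so that batch runs survive a bad parameter
    choice on one image.
    """
    gray = to_grayscale(img)
    mask = threshold_mask(gray, params.threshold)
    mask = erode(mask, params.shrink)
    mask = dilate(mask, params.grow)
    mask = fill_gaps(mask, params.fill)
    mask = clean_specks(mask, params.clean)
    labelled = label_components(mask)
    if labelled.n_selected == 0:
        logger.warning(
            "ROI selection produced an empty mask (threshold=%s, shrink=%s, grow=%s, fill=%s, clean=%s)",
            params.threshold, params.shrink, params.grow, params.fill, params.clean,
        )
        return labelled
    out = labelled.labels.copy()
    out[out > params.n] = 0
    return ROILabels(out)


# ---------------------------------------------------------------------------
# label-image interchange
# ---------------------------------------------------------------------------

def save_labels(labels: ROILabels, path) -> None:
    """Write labels as a single-channel 16-bit PNG or TIFF (label = pixel value)."""
    if labels.n_selected > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit export")
    iio.imwrite(str(path), labels.labels.astype(np.uint16))


def load_labels(path) -> ROILabels:
    """Read a label image written by :func:`save_labels`."""
    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim != 2:
        raise ValueError(f"label image must be single-channel, got shape {arr.shape}")
    return ROILabels(arr.astype(np.int32))
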