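"""Diagnostic figures: ROI overview and pixel-intensity quality check.

Two views support the judgment calls of a co-localization analysis: the
overview shows *where* the selected regions sit on the image, and the
intensity check shows *whether* the two channels' pixel intensities behave
the way the statistics assume (points near the diagonal, overlapping
distributions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
from scipy.stats import gaussian_kde

from .image_io import RasterImage, get_channel
from .roi import ROILabels
from .stats import intensities_by_roi

logger = logging.getLogger("coloc")

PANEL_KINDS = ("merge", "pixel-set", "channel-overlay", "scatter", "density")


@dataclass(frozen=True)
class Panel:
    kind: str
    data: dict[str, Any]
    title: str


@dataclass(frozen=True)
class FigureSpec:
    """Ordered description of the panels a rendering operation produced."""

    panels: tuple[Panel, ...]


def roi_boundaries(labels: ROILabels) -> np.ndarray:
    """Boolean mask of region boundary pixels.

    A boundary pixel is a foreground pixel with at least one 4-neighbor
    outside its own region (image borders count as outside).
    """
    lab = labels.labels
    padded = np.pad(lab, 1, constant_values=0)
    fg = lab > 0
    boundary = np.zeros_like(fg)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr : 1 + dr + lab.shape[0], 1 + dc : 1 + dc + lab.shape[1]]
        boundary |= fg & (neigh != lab)
    return boundary


def _as_rgb(img: RasterImage) -> np.ndarray:
    """Merge view: channels mapped onto RGB (extra channels ignored)."""
    rgb = np.zeros((img.height, img.width, 3))
    for k in range(min(3, img.n_channels)):
        rgb[:, :, k] = img.pixels[:, :, k]
    return rgb


def render_roi_overview(
    img: RasterImage,
    labels: ROILabels,
    out: str | Path | None = None,
) -> FigureSpec:
    """Render the four-panel ROI overview.

    Panels, in order: the merge image; the binary pixel set of the selected
    regions; channels 1 and 2 in grayscale with region boundaries overlaid.
    Written to ``out`` (PNG/PDF by extension) when given.
    """
    if labels.labels.shape != (img.height, img.width):
        raise ValueError("labels shape does not match image shape")
    if labels.n_selected == 0:
        logger.warning("rendering ROI overview with zero selected regions")
    boundary = roi_boundaries(labels)
    pixel_set = labels.labels > 0
    panels = [
        Panel("merge", {"rgb": _as_rgb(img)}, "Merge"),
        Panel("pixel-set", {"mask": pixel_set}, "Pixel set"),
        Panel("channel-overlay", {"plane": get_channel(img, 1), "boundary": boundary}, "Channel 1"),
        Panel("channel-overlay", {"plane": get_channel(img, min(2, img.n_channels)), "boundary": boundary}, "Channel 2"),
    ]
    if out is not None:
        _draw_overview(panels, Path(out))
    return FigureSpec(tuple(panels))


def render_intensity_check(
    img: RasterImage,
    labels: ROILabels,
    ch1: int = 1,
    ch2: int = 2,
    out: str | Path | None = None,
) -> FigureSpec:
    """Render the two-panel intensity quality check.

    Panel 1 scatters (channel-1, channel-2) intensities colored by region;
    panel 2 shows per-channel Gaussian-kernel density curves (Silverman
    bandwidth) pooled over all regions.  Raises when no region is selected.
    """
    if labels.n_selected == 0:
        raise ValueError("no regions of interest selected: nothing to plot")
    pairs = intensities_by_roi(img, labels, ch1, ch2)
    r_all = np.concatenate([p.r for p in pairs])
    g_all = np.concatenate([p.g for p in pairs])
    roi_ids = np.concatenate([np.full(p.r.size, p.roi_id) for p in pairs])

    densities = {}
    for name, values in (("ch1", r_all), ("ch2", g_all)):
        if np.ptp(values) == 0:
            logger.warning("constant intensities in %s: density curve skipped", name)
            densities[name] = (np.array([]), np.array([]))
            continue
        kde = gaussian_kde(values, bw_method="silverman")
        pad = 4 * kde.factor * values.std(ddof=1)
        grid = np.linspace(values.min() - pad, values.max() + pad, 512)
        densities[name] = (grid, kde(grid))

    panels = [
        Panel("scatter", {"r": r_all, "g": g_all, "roi": roi_ids}, "Pixel intensities"),
        Panel("density", {"ch1": densities["ch1"], "ch2": densities["ch2"]}, "Intensity distribution"),
    ]
    if out is not None:
        _draw_check(panels, Path(out))
    return FigureSpec(tuple(panels))


# ---------------------------------------------------------------------------
# matplotlib rendering (imported lazily so array-level use needs no backend)
# ---------------------------------------------------------------------------

def _draw_overview(panels: list[Panel], out: Path) -> None:
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 8))
    for ax, panel in zip(axes.ravel(), panels):
        ax.set_title(panel.title)
        ax.set_axis_off()
        if panel.kind == "merge":
            ax.imshow(panel.data["rgb"])
        elif panel.kind == "pixel-set":
            ax.imshow(panel.data["mask"], cmap="gray", vmin=0, vmax=1)
        else:
            ax.imshow(panel.data["plane"], cmap="gray", vmin=0, vmax=1)
            by, bx = np.nonzero(panel.data["boundary"])
            ax.plot(bx, by, ".", color="red", markersize=1)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)


def _draw_check(panels: list[Panel], out: Path) -> None:
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    sc = panels[0].data
    ax1.scatter(sc["r"], sc["g"], c=sc["roi"], s=4, cmap="viridis", alpha=0.5)
    ax1.set_xlabel("channel 1 intensity")
    ax1.set_ylabel("channel 2 intensity")
    ax1.set_title(panels[0].title)
    dn = panels[1].data
    for name, color in (("ch1", "magenta"), ("ch2", "green")):
        grid, dens = dn[name]
        if grid.size:
            ax2.plot(grid, dens, color=color, label=name)
    ax2.set_xlabel("intensity")
    ax2.set_ylabel("density")
    ax2.set_title(panels[1].title)
    ax2.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
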