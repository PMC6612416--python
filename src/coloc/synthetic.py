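"""Synthetic two-channel fluorescence images with known ground truth.

The generator emulates the standard co-localization study input: blob-like
cells of near-uniform brightness on a dark, weakly noisy background, imaged
in two channels whose signals share a controllable true pixel correlation.

Model
-----
Each blob is a flat-top disk (optionally with a Gaussian edge skirt of width
``edge_sigma``) of a given peak intensity.  Within the blob support the
signal carries a zero-mean multiplicative Gaussian texture (relative
standard deviation ``texture``) that plays the role of sub-cellular
intensity structure; the two channels' texture fields are mixed as

    t2 = rho * t1 + sqrt(1 - rho^2) * t2'

with ``t1``, ``t2'`` independent, so that — before read-out noise and
clipping — the Pearson correlation of the two channels over any single
blob's pixels is exactly ``rho``.  Independent Gaussian read-out noise of
standard deviation ``noise_sd`` is then added to each channel and the
result clipped to [0, 1]; noise slightly attenuates the realized
correlation and clipping introduces a mild bias at the extremes.

The returned ground truth labels the flat-top disks by descending pixel
count, matching the ranking convention of the ROI selection pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .image_io import RasterImage
from .roi import ROILabels, save_labels


@dataclass(frozen=True)
class Blob:
    """One circular cell: center (row, col), radius and peak intensity."""

    row: float
    col: float
    radius: float
    peak: float


def _default_blobs() -> list[Blob]:
    # three well-separated cells occupying ~9% of the default 256x256 frame
    return [
        Blob(70.0, 70.0, 30.0, 0.75),
        Blob(170.0, 90.0, 25.0, 0.70),
        Blob(110.0, 185.0, 19.0, 0.65),
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of a generated two-channel image pair.

    Attributes
    ----------
    rho
        True inter-channel correlation of the blob texture, in [-1, 1].
    background
        Dark-field intensity; must be below every blob peak.
    noise_sd
        Per-channel Gaussian read-out noise standard deviation.
    texture
        Relative standard deviation of the within-blob texture (fraction of
        the blob peak).
    edge_sigma
        Gaussian skirt width in pixels outside the flat core; 0 = sharp edge.
    """

    height: int = 256
    width: int = 256
    blobs: tuple[Blob, ...] = field(default_factory=lambda: tuple(_default_blobs()))
    rho: float = 0.8
    background: float = 0.05
    noise_sd: float = 0.01
    texture: float = 0.1
    edge_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("height and width must be >= 1")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")
        if self.noise_sd < 0 or self.texture < 0 or self.edge_sigma < 0:
            raise ValueError("noise_sd, texture and edge_sigma must be >= 0")
        if not self.blobs:
            raise ValueError("at least one blob is required")
        for b in self.blobs:
            if not 0.0 < b.peak <= 1.0:
                raise ValueError(f"blob peak must be in (0, 1], got {b.peak}")
            if b.radius <= 0:
                raise ValueError(f"blob radius must be > 0, got {b.radius}")
            if not (b.radius <= b.row <= self.height - 1 - b.radius
                    and b.radius <= b.col <= self.width - 1 - b.radius):
                raise ValueError(f"blob at ({b.row}, {b.col}) with radius {b.radius} does not fit the frame")
        if not 0.0 <= self.background < min(b.peak for b in self.blobs):
            raise ValueError("background must be in [0, 1) and below every blob peak")


def _profile_and_mask(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic blob profile (max over blobs) and true disk mask (int labels by blob index)."""
    rows = np.arange(spec.height, dtype=np.float64)[:, None]
    cols = np.arange(spec.width, dtype=np.float64)[None, :]
    profile = np.zeros((spec.height, spec.width))
    blob_ix = np.zeros((spec.height, spec.width), dtype=np.int32)
    for i, b in enumerate(spec.blobs, start=1):
        d = np.hypot(rows - b.row, cols - b.col)
        p = np.where(d <= b.radius, b.peak, 0.0)
        if spec.edge_sigma > 0:
            skirt = b.peak * np.exp(-((d - b.radius) ** 2) / (2 * spec.edge_sigma**2))
            p = np.where(d > b.radius, skirt, p)
        take = p > profile
        profile = np.where(take, p, profile)
        blob_ix[d <= b.radius] = i
    return profile, blob_ix


def generate_pair(spec: SyntheticSpec) -> tuple[RasterImage, ROILabels]:
    """Generate a two-channel image and its ground-truth region labels.

    Identical specs (including the seed) yield bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    profile, blob_ix = _profile_and_mask(spec)

    t1 = rng.standard_normal(profile.shape)
    t2 = spec.rho * t1 + np.sqrt(max(0.0, 1.0 - spec.rho**2)) * rng.standard_normal(profile.shape)
    sig1 = profile * (1.0 + spec.texture * t1)
    sig2 = profile * (1.0 + spec.texture * t2)

    if spec.noise_sd > 0:
        n1 = rng.normal(0.0, spec.noise_sd, profile.shape)
        n2 = rng.normal(0.0, spec.noise_sd, profile.shape)
    else:
        n1 = n2 = 0.0

    ch1 = np.clip(spec.background + sig1 + n1, 0.0, 1.0)
    ch2 = np.clip(spec.background + sig2 + n2, 0.0, 1.0)
    img = RasterImage(np.stack([ch1, ch2], axis=-1))

    # rank ground-truth blobs by pixel count, largest first, to match the
    # labeling convention of the selection pipeline
    sizes = np.bincount(blob_ix.ravel(), minlength=len(spec.blobs) + 1)[1:]
    rank = sorted(range(1, len(spec.blobs) + 1), key=lambda i: -sizes[i - 1])
    remap = np.zeros(len(spec.blobs) + 1, dtype=np.int32)
    for new, old in enumerate(rank, start=1):
        remap[old] = new
    return img, ROILabels(remap[blob_ix])


def save_fixture(spec: SyntheticSpec, directory: str | Path, stem: str = "fixture") -> dict[str, Path]:
    """Persist a generated pair as an 8-bit PNG, a label TIFF and a YAML sidecar.

    Returns the paths written, keyed by role (image, labels, spec).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img, labels = generate_pair(spec)
    rgb = np.zeros((spec.height, spec.width, 3))
    rgb[:, :, 0] = img.pixels[:, :, 0]
    rgb[:, :, 1] = img.pixels[:, :, 1]
    paths = {
        "image": directory / f"{stem}.png",
        "labels": directory / f"{stem}_labels.tif",
        "spec": directory / f"{stem}.yaml",
    }
    iio.imwrite(paths["image"], (np.round(rgb * 255)).astype(np.uint8))
    save_labels(labels, paths["labels"])
    meta = {
        "height": spec.height,
        "width": spec.width,
        "blobs": [{"row": b.row, "col": b.col, "radius": b.radius, "peak": b.peak} for b in spec.blobs],
        "rho": spec.rho,
        "background": spec.background,
        "noise_sd": spec.noise_sd,
        "texture": spec.texture,
        "edge_sigma": spec.edge_sigma,
        "seed": spec.seed,
    }
    paths["spec"].write_text(yaml.safe_dump(meta, sort_keys=False))
    return paths


def load_spec(path: str | Path) -> SyntheticSpec:
    """Read a YAML sidecar (as written by :func:`save_fixture`) back into a spec."""
    meta = yaml.safe_load(Path(path).read_text())
    blobs = tuple(Blob(**b) for b in meta.pop("blobs"))
    return SyntheticSpec(blobs=blobs, **meta)
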