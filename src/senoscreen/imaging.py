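"""Viable-cell counting from two-channel fluorescence fields.

A field carries a nuclear-stain channel (DAPI) and a cell-body channel
(rhodamine-phalloidin).  Nuclei are segmented with an adaptive Otsu
threshold on the nuclear channel; the cell-body mask comes from a
minimum-cross-entropy (Li) threshold of the illumination-corrected
cytoplasm channel.  Nuclei lacking cytoplasm signal are dead cells that
survived the wash steps and are excluded from the viable count.

Both thresholding primitives are exact exhaustive optimizers of their
respective objectives over a discretized (256-bin) histogram, so they can
be validated bin-for-bin against brute-force enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure


class DegenerateHistogramError(ValueError):
    """Raised when an image has fewer than two distinct intensity values."""


@dataclass
class ImageField:
    """Two-channel intensity raster for one microscope field.

    Attributes
    ----------
    nuclei_channel, cytoplasm_channel
        2-D arrays of identical shape; non-negative intensities.
    pixel_depth
        Bit depth of the acquisition (informational).
    plate, well, field
        Acquisition identifiers.
    """

    nuclei_channel: np.ndarray
    cytoplasm_channel: np.ndarray
    pixel_depth: int = 16
    plate: str = ""
    well: str = ""
    field: int = 0

    def __post_init__(self) -> None:
        self.nuclei_channel = np.asarray(self.nuclei_channel)
        self.cytoplasm_channel = np.asarray(self.cytoplasm_channel)
        if self.nuclei_channel.shape != self.cytoplasm_channel.shape:
            raise ValueError("channel shapes differ")
        if self.nuclei_channel.ndim != 2:
            raise ValueError("channels must be 2-D")


@dataclass
class SegmentationConfig:
    """Tunable segmentation settings (defaults for the synthetic scale)."""

    tile_size: int = 128
    n_bins: int = 256
    threshold_bounds: tuple[float, float] = (0.7, 1.5)  # per-tile clamp, x global Otsu
    min_object_px: int = 30
    overlap_fraction: float = 0.5  # nucleus counted live iff >= this fraction lies in cytoplasm
    median_size: int = 3
    background_sigma: float | None = None  # default: image_width / 8
    # a field is called empty unless the Otsu foreground mean exceeds the
    # background mean by this many background standard deviations; on a
    # signal-free field Otsu merely bisects the noise (separation ~1.6 sd)
    min_separation_sigma: float = 5.0


@dataclass
class CellCountResult:
    """Per-field segmentation outcome."""

    live_count: int
    dead_excluded_count: int
    nuclei_labels: np.ndarray | None = None
    cytoplasm_mask: np.ndarray | None = None
    degenerate: bool = False
    plate: str = ""
    well: str = ""
    field: int = 0


# ---------------------------------------------------------------------------
# histogram helpers


def _histogram(image: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts and bin centers over the observed min-max range."""
    data = np.asarray(image, dtype=float).ravel()
    lo, hi = data.min(), data.max()
    if lo == hi:
        raise DegenerateHistogramError("constant image: no threshold exists")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(float), centers


def threshold_otsu(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold: the histogram cut maximizing between-class variance.

    Returns the intensity (a bin center) such that ``image > t`` is the
    bright class.  Every candidate cut is evaluated, so the result is the
    exact discrete optimizer.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant.
    """
    counts, centers = _histogram(image, n_bins)
    return _otsu_from_histogram(counts, centers)


def _otsu_from_histogram(counts: np.ndarray, centers: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    s0 = np.cumsum(counts * centers)[:-1]
    s1 = (counts * centers).sum() - s0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = s1 / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # cut k assigns bins <= k to the dark class; threshold is the center of bin k
    return float(centers[int(np.argmax(between))])


def threshold_min_cross_entropy(image: np.ndarray, n_bins: int = 256) -> float:
    """Li's minimum cross-entropy threshold, exhaustive over histogram cuts.

    The cross entropy between the image and its two-level reconstruction,

        CE(t) = sum_{g<=t} g h(g) log(g / mu_0) + sum_{g>t} g h(g) log(g / mu_1),

    is evaluated at every cut; the argmin is returned.  Intensities are
    shifted to be strictly positive before taking logs and the threshold is
    shifted back.
    """
    counts, centers = _histogram(image, n_bins)
    return _li_from_histogram(counts, centers)


def _li_from_histogram(counts: np.ndarray, centers: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    offset = 0.0
    if centers[0] <= 0:
        # log requires positive support; shift by one bin width past zero
        offset = -centers[0] + (centers[1] - centers[0])
    g = centers + offset
    w = counts * g
    s0 = np.cumsum(w)[:-1]
    n0 = np.cumsum(counts)[:-1]
    s1 = w.sum() - s0
    n1 = counts.sum() - n0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / n0
        mu1 = s1 / n1
        # sum g h log g is constant in t; minimize the variable part
        crit = -(s0 * np.log(mu0) + s1 * np.log(mu1))
    crit[~np.isfinite(crit)] = np.inf
    return float(centers[int(np.argmin(crit))])


def threshold_otsu_adaptive(
    image: np.ndarray,
    tile_size: int = 128,
    n_bins: int = 256,
    bounds: tuple[float, float] = (0.7, 1.5),
) -> np.ndarray:
    """Per-tile Otsu thresholds, bilinearly interpolated to a full surface.

    Tiles with degenerate (constant) histograms inherit the global
    threshold, and per-tile values are clamped to ``bounds`` x the global
    threshold so that tiles containing only background noise cannot drop
    their threshold to the noise floor.  With a single tile this reduces
    to the global Otsu value everywhere.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    global_t = threshold_otsu(image, n_bins)
    rows = max(1, h // tile_size)
    cols = max(1, w // tile_size)
    r_edges = np.linspace(0, h, rows + 1).astype(int)
    c_edges = np.linspace(0, w, cols + 1).astype(int)
    tile_t = np.empty((rows, cols))
    for i in range(rows):
        for j in range(cols):
            tile = image[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]]
            try:
                tile_t[i, j] = threshold_otsu(tile, n_bins)
            except DegenerateHistogramError:
                tile_t[i, j] = global_t
    if bounds is not None:
        tile_t = np.clip(tile_t, bounds[0] * global_t, bounds[1] * global_t)
    if rows == 1 and cols == 1:
        return np.full((h, w), tile_t[0, 0])
    # bilinear interpolation from tile centers, clamped at the borders
    r_centers = (r_edges[:-1] + r_edges[1:]) / 2.0
    c_centers = (c_edges[:-1] + c_edges[1:]) / 2.0
    rr = np.interp(np.arange(h), r_centers, np.arange(rows))
    cc = np.interp(np.arange(w), c_centers, np.arange(cols))
    surface = ndimage.map_coordinates(
        tile_t, np.meshgrid(rr, cc, indexing="ij"), order=1, mode="nearest"
    )
    return surface


def correct_illumination(
    image: np.ndarray,
    median_size: int = 3,
    background_sigma: float | None = None,
) -> np.ndarray:
    """Flatten smooth illumination falloff while preserving the global mean.

    The image is median-filtered (salt/shot suppression), divided by a
    Gaussian-blur background estimate (sigma defaults to width/8), and
    rescaled so the output mean equals the input mean.  A constant image is
    returned unchanged; an all-zero image additionally emits a warning.
    """
    image = np.asarray(image, dtype=float)
    if not image.any():
        warnings.warn("all-zero image: illumination correction skipped", stacklevel=2)
        return image.copy()
    if background_sigma is None:
        background_sigma = image.shape[1] / 8.0
    med = ndimage.median_filter(image, size=median_size)
    background = ndimage.gaussian_filter(med, sigma=background_sigma)
    background = np.maximum(background, np.finfo(float).tiny)
    flat = med / background
    return flat * (image.mean() / flat.mean())


def segment_and_count_field(
    field: ImageField, cfg: SegmentationConfig | None = None
) -> CellCountResult:
    """Segment one field and classify each nucleus as live or dead.

    Nuclei are connected components of the adaptive-Otsu mask of the
    nuclear channel (components under ``min_object_px`` discarded).  The
    cytoplasm mask is the Li threshold of the illumination-corrected
    cytoplasm channel.  A nucleus is live iff at least
    ``overlap_fraction`` of its pixels fall inside the cytoplasm mask.

    Degenerate thresholds (constant channels) and fields whose nuclear
    channel carries no detectable foreground (Otsu class separation below
    ``min_separation_sigma`` background standard deviations) yield a
    zero-count result with ``degenerate=True`` rather than an exception.
    """
    cfg = cfg or SegmentationConfig()
    nuc = np.asarray(field.nuclei_channel, dtype=float)
    try:
        global_t = threshold_otsu(nuc, cfg.n_bins)
    except DegenerateHistogramError:
        return CellCountResult(0, 0, degenerate=True,
                               plate=field.plate, well=field.well, field=field.field)
    background = nuc[nuc <= global_t]
    foreground = nuc[nuc > global_t]
    separation = foreground.mean() - background.mean() if foreground.size else 0.0
    if separation < cfg.min_separation_sigma * max(background.std(), np.finfo(float).tiny):
        return CellCountResult(0, 0, degenerate=True,
                               plate=field.plate, well=field.well, field=field.field)
    try:
        surface = threshold_otsu_adaptive(
            field.nuclei_channel, cfg.tile_size, cfg.n_bins, cfg.threshold_bounds
        )
    except DegenerateHistogramError:
        return CellCountResult(0, 0, degenerate=True,
                               plate=field.plate, well=field.well, field=field.field)
    nuclei_mask = np.asarray(field.nuclei_channel, dtype=float) > surface
    labels = measure.label(nuclei_mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= cfg.min_object_px)
    keep = keep[keep != 0]

    corrected = correct_illumination(
        field.cytoplasm_channel, cfg.median_size, cfg.background_sigma
    )
    try:
        li = threshold_min_cross_entropy(corrected, cfg.n_bins)
    except DegenerateHistogramError:
        return CellCountResult(0, 0, degenerate=True,
                               plate=field.plate, well=field.well, field=field.field)
    cyto_mask = corrected > li
    # a signal-free cytoplasm channel (e.g. a field of dead cells) would
    # otherwise have Li bisect the noise and flood half the field
    cyto_bg = corrected[~cyto_mask]
    cyto_fg = corrected[cyto_mask]
    cyto_sep = cyto_fg.mean() - cyto_bg.mean() if cyto_fg.size else 0.0
    if cyto_sep < cfg.min_separation_sigma * max(cyto_bg.std(), np.finfo(float).tiny):
        cyto_mask = np.zeros_like(cyto_mask)

    live = 0
    dead = 0
    # fraction of each nucleus overlapping the cytoplasm mask
    if keep.size:
        overlap = ndimage.labeled_comprehension(
            cyto_mask, labels, keep, np.mean, float, 0.0
        )
        live = int(np.sum(overlap >= cfg.overlap_fraction))
        dead = int(keep.size - live)

    pruned = np.where(np.isin(labels, keep), labels, 0)
    return CellCountResult(
        live_count=live,
        dead_excluded_count=dead,
        nuclei_labels=pruned,
        cytoplasm_mask=cyto_mask,
        plate=field.plate,
        well=field.well,
        field=field.field,
    )


def aggregate_well(field_results: list[CellCountResult] | list[int]) -> int:
    """Total viable-cell count for a well: the sum over its fields."""
    if not field_results:
        raise ValueError("a well needs at least one field")
    total = 0
    for r in field_results:
        total += r.live_count if isinstance(r, CellCountResult) else int(r)
    return total
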