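"""Percent c-fos-positive cell quantification from two-channel section images.

Sections carry a nuclear stain channel (for cell detection) and a signal
channel (in-situ hybridisation product).  Quantification follows the
background-ratio rule: nuclei are segmented inside a region of interest
(ROI); the detection threshold for the signal channel is the mean intensity
of a 500 µm² background patch multiplied by a signal-to-background ratio;
a cell is positive when enough of its area carries above-threshold signal;
the result is the percentage of positive cells in the ROI.

The cell detector is a smooth → threshold → split-touching-nuclei → size
filter pipeline built on scikit-image primitives, with every knob exposed in
:class:`QuantConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, feature, filters, measure, segmentation

__all__ = [
    "SectionImage",
    "CellDetection",
    "QuantResult",
    "QuantConfig",
    "detect_cells",
    "compute_threshold",
    "classify_cells",
    "quantify_roi",
    "read_section_tiff",
    "roi_mask",
]


@dataclass
class SectionImage:
    """Two-channel section raster with physical pixel size."""

    nuclear_channel: np.ndarray
    signal_channel: np.ndarray
    pixel_size_um: float
    section_id: str = ""
    animal_id: str = ""
    group: str = "none"

    def __post_init__(self) -> None:
        self.nuclear_channel = np.asarray(self.nuclear_channel, dtype=float)
        self.signal_channel = np.asarray(self.signal_channel, dtype=float)
        if self.nuclear_channel.shape != self.signal_channel.shape:
            raise ValueError("channels must share a shape")
        if self.nuclear_channel.ndim != 2:
            raise ValueError("channels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear_channel.shape


@dataclass
class CellDetection:
    """One segmented nucleus."""

    label: int
    centroid: tuple[float, float]        # (row, col) pixels
    pixels: tuple[np.ndarray, np.ndarray]  # row and col index arrays
    area_um2: float
    mean_signal: float


@dataclass
class QuantResult:
    roi_id: str
    n_cells: int
    n_positive: int
    percent_positive: float              # NaN when n_cells == 0
    threshold: float
    background_mean: float
    ratio: float

    @property
    def defined(self) -> bool:
        return self.n_cells > 0


@dataclass
class QuantConfig:
    """All tunable quantification parameters.

    The signal-to-background ``ratio`` multiplies the background patch mean
    to give the positivity threshold; it is deliberately prominent because
    reported percentages depend on it directly.
    """

    ratio: float = 2.0
    background_area_um2: float = 500.0
    min_positive_fraction: float = 0.1   # fraction of cell pixels above threshold
    smooth_sigma_um: float = 1.0
    min_cell_area_um2: float = 12.0
    max_cell_area_um2: float = 400.0
    min_peak_distance_um: float = 4.0
    nuclear_threshold: float | None = None   # None -> Otsu inside the ROI
    min_contrast_sds: float = 4.0            # foreground-background separation
                                             # required to accept the Otsu split


def roi_mask(shape: tuple[int, int], polygon) -> np.ndarray:
    """Boolean mask for a polygon given as (x, y) vertices, origin top-left,
    0-based pixel coordinates (GeoJSON-style ordering)."""
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2:
        raise ValueError("polygon must be an (n, 2) array of (x, y) vertices")
    rc = np.column_stack([poly[:, 1], poly[:, 0]])   # (row, col)
    return draw.polygon2mask(shape, rc)


def detect_cells(img: SectionImage, roi, config: QuantConfig | None = None) -> list[CellDetection]:
    """Segment nuclei from the nuclear channel inside a ROI polygon.

    Pipeline: Gaussian smoothing, global (Otsu) threshold, connected
    components, marker-based watershed splitting of touching nuclei, then
    size filtering in µm².  An empty ROI yields an empty list; a ROI outside
    the image is an error.
    """
    cfg = config or QuantConfig()
    poly = np.asarray(roi, dtype=float)
    if (poly[:, 0].max() < 0 or poly[:, 1].max() < 0
            or poly[:, 0].min() >= img.shape[1] or poly[:, 1].min() >= img.shape[0]):
        raise ValueError("ROI polygon lies outside the image")
    mask = roi_mask(img.shape, roi)
    if not mask.any():
        return []

    px = img.pixel_size_um
    sigma = cfg.smooth_sigma_um / px
    smoothed = filters.gaussian(img.nuclear_channel, sigma=sigma, preserve_range=True)
    vals = smoothed[mask]
    if cfg.nuclear_threshold is not None:
        thr = cfg.nuclear_threshold
    else:
        if np.ptp(vals) <= 0:
            return []
        thr = filters.threshold_otsu(vals)
        # contrast guard: Otsu on pure noise splits at ~2-3 sd; genuine nuclei
        # sit far above the background population
        bg_vals = vals[vals <= thr]
        fg_vals = vals[vals > thr]
        if fg_vals.size == 0 or bg_vals.size == 0:
            return []
        if fg_vals.mean() - bg_vals.mean() < cfg.min_contrast_sds * max(
                bg_vals.std(), 1e-12):
            return []
    binary = (smoothed > thr) & mask
    if not binary.any():
        return []

    distance = ndi.distance_transform_edt(binary)
    min_dist = max(1, int(round(cfg.min_peak_distance_um / px)))
    peaks = feature.peak_local_max(
        distance, min_distance=min_dist, labels=binary, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = measure.label(binary)
    else:
        labels = segmentation.watershed(-distance, markers, mask=binary)

    out: list[CellDetection] = []
    area_px_min = cfg.min_cell_area_um2 / px ** 2
    area_px_max = cfg.max_cell_area_um2 / px ** 2
    for region in measure.regionprops(labels):
        if not area_px_min <= region.area <= area_px_max:
            continue
        rows, cols = np.nonzero(labels == region.label)
        out.append(CellDetection(
            label=int(region.label),
            centroid=tuple(region.centroid),
            pixels=(rows, cols),
            area_um2=float(region.area * px ** 2),
            mean_signal=float(img.signal_channel[rows, cols].mean()),
        ))
    return out


def _window_means_vars(arr: np.ndarray, mask: np.ndarray, side: int):
    """Means and variances of all side×side windows fully inside ``mask``,
    via integral images."""
    ok = ndi.uniform_filter(mask.astype(float), size=side, mode="constant") > 0.999
    m1 = ndi.uniform_filter(arr, size=side, mode="constant")
    m2 = ndi.uniform_filter(arr * arr, size=side, mode="constant")
    var = np.clip(m2 - m1 * m1, 0.0, None)
    return m1, var, ok


def compute_threshold(
    img: SectionImage,
    background_roi,
    config: QuantConfig | None = None,
) -> tuple[float, float]:
    """Positivity threshold from a background patch.

    Scans square windows of ``background_area_um2`` inside the background ROI
    and takes the window with minimal signal variance (the most homogeneous
    patch, for reproducibility); the threshold is ``ratio`` times its mean
    signal intensity.  Returns ``(threshold, background_mean)``.
    """
    cfg = config or QuantConfig()
    mask = roi_mask(img.shape, background_roi)
    px = img.pixel_size_um
    side = max(2, int(round(np.sqrt(cfg.background_area_um2) / px)))
    if mask.sum() < side * side:
        raise ValueError(
            f"background ROI smaller than the {cfg.background_area_um2:g} µm² patch")
    means, vars_, ok = _window_means_vars(img.signal_channel, mask, side)
    if not ok.any():
        raise ValueError("no full background patch fits inside the background ROI")
    vv = np.where(ok, vars_, np.inf)
    r, c = np.unravel_index(int(np.argmin(vv)), vv.shape)
    bg_mean = float(means[r, c])
    return cfg.ratio * bg_mean, bg_mean


def classify_cells(
    cells: list[CellDetection],
    img: SectionImage,
    threshold: float,
    min_fraction: float = 0.1,
) -> np.ndarray:
    """Positivity flags: a cell is positive when at least ``min_fraction`` of
    its pixels carry signal above the threshold."""
    flags = np.zeros(len(cells), dtype=bool)
    for i, cell in enumerate(cells):
        sig = img.signal_channel[cell.pixels]
        flags[i] = (sig > threshold).mean() >= min_fraction
    return flags


def quantify_roi(
    img: SectionImage,
    roi,
    background_roi,
    config: QuantConfig | None = None,
    roi_id: str = "roi",
) -> QuantResult:
    """Full per-ROI quantification: detect → threshold → classify → percent.

    With zero detected cells the percentage is undefined (NaN), explicitly
    distinct from 0 %.
    """
    cfg = config or QuantConfig()
    threshold, bg_mean = compute_threshold(img, background_roi, cfg)
    cells = detect_cells(img, roi, cfg)
    flags = classify_cells(cells, img, threshold, cfg.min_positive_fraction)
    n = len(cells)
    npos = int(flags.sum())
    return QuantResult(
        roi_id=roi_id,
        n_cells=n,
        n_positive=npos,
        percent_positive=(100.0 * npos / n) if n else float("nan"),
        threshold=float(threshold),
        background_mean=bg_mean,
        ratio=cfg.ratio,
    )


def read_section_tiff(
    path: str | Path,
    pixel_size_um: float,
    nuclear_page: int = 0,
    signal_page: int = 1,
    **meta,
) -> SectionImage:
    """Read a single- or multi-page TIFF into a :class:`SectionImage`.

    Multi-page or 3-D TIFFs are indexed by page/leading axis; 2-D images can
    serve as both channels only if nuclear_page == signal_page == 0.
    """
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        pages = [arr]
    elif arr.ndim == 3:
        # accept channel-first or channel-last
        if arr.shape[0] <= 8:
            pages = [arr[i] for i in range(arr.shape[0])]
        else:
            pages = [arr[..., i] for i in range(arr.shape[-1])]
    else:
        raise ValueError(f"unsupported TIFF shape {arr.shape}")
    return SectionImage(
        nuclear_channel=pages[nuclear_page],
        signal_channel=pages[signal_page],
        pixel_size_um=pixel_size_um,
        **meta,
    )
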