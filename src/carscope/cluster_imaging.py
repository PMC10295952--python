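"""Submicron receptor-cluster quantification on apical-membrane images.

Pipeline: lognormal-based exclusion of outlier cells by mean image
intensity, thresholding of the masked membrane, watershed splitting of
touching clusters (flooding from regional maxima of the smoothed
intensity), then per-cluster and per-cell metrics: cluster count per
10 um^2 of membrane, individual cluster areas and integrated intensities,
and mean intensities inside/outside clusters normalized to the whole-mask
mean.

A ground-truthed synthetic generator renders membrane images with
lognormally sized clusters of elevated receptor density over a diffuse
background, blurred by a Gaussian PSF with Poisson counting noise, so the
segmentation pipeline can be validated against known cluster counts and
areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import h_maxima
from skimage.measure import regionprops_table
from skimage.segmentation import watershed

__all__ = [
    "MembraneImage",
    "ClusterTable",
    "SyntheticMembraneConfig",
    "exclude_outlier_cells",
    "segment_clusters",
    "cluster_metrics",
    "generate_membrane_image",
    "read_membrane_tiff",
    "write_membrane_tiff",
]


@dataclass
class MembraneImage:
    """A 2D apical-membrane intensity image with its membrane mask."""

    image: np.ndarray
    pixel_size: float  # um
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValueError("image must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.mask is None:
            self.mask = np.ones(self.image.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.image.shape:
                raise ValueError("mask shape must match image shape")

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2


@dataclass
class ClusterTable:
    """Per-cluster measurements plus per-cell summary metrics.

    ``clusters`` columns: label, area_um2, integrated_intensity,
    centroid_row, centroid_col.
    """

    clusters: pd.DataFrame
    count_per_10um2: float
    norm_mean_inside: float
    norm_mean_outside: float
    total_intensity: float
    masked_area_um2: float

    def __post_init__(self) -> None:
        if len(self.clusters) and np.any(self.clusters["area_um2"] <= 0):
            raise ValueError("cluster areas must be positive")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_csv(self, path_or_buf) -> None:
        """Write the per-cluster table with the summary metrics as columns."""
        df = self.clusters.copy()
        df["count_per_10um2"] = self.count_per_10um2
        df["norm_mean_inside"] = self.norm_mean_inside
        df["norm_mean_outside"] = self.norm_mean_outside
        df["total_intensity"] = self.total_intensity
        df["masked_area_um2"] = self.masked_area_um2
        df.to_csv(path_or_buf, index=False)


@dataclass(frozen=True)
class SyntheticMembraneConfig:
    """Ground-truthed synthetic membrane field.

    Default geometry: a 10 x 10 um field at 40 nm pixels with an 80 nm
    PSF sigma (super-resolution-like lateral resolution).  Cluster radii
    are lognormal; receptor surface density is elevated inside clusters
    relative to the diffuse monomer background outside.
    """

    field_size: float = 10.0  # um
    pixel_size: float = 0.04  # um
    n_clusters: int = 40
    radius_median: float = 0.2  # um
    radius_sigma_log: float = 0.25
    density_inside: float = 300.0  # molecules / um^2
    density_outside: float = 15.0
    brightness: float = 50.0  # expected counts per molecule
    psf_sigma: float = 0.08  # um
    background: float = 5.0  # counts / pixel
    poisson_noise: bool = True
    min_separation: float = 0.1  # um edge-to-edge, keeps clusters resolvable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_median <= 0:
            raise ValueError("cluster radii must be positive")
        if self.density_inside <= self.density_outside:
            raise ValueError("inside density must exceed outside density")
        if self.field_size <= 0 or self.pixel_size <= 0:
            raise ValueError("field and pixel sizes must be positive")


def exclude_outlier_cells(mean_intensities, k: float = 2.5) -> np.ndarray:
    """Keep/exclude flags from a lognormal fit of per-cell mean intensities.

    Fits a Gaussian to log intensities and flags cells beyond
    mean +/- k standard deviations in log space.  Returns a boolean array,
    True = keep.
    """
    x = np.asarray(mean_intensities, dtype=np.float64)
    if x.size < 5:
        raise ValueError("need at least 5 cells for outlier screening")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("mean intensities must be positive and finite")
    logx = np.log(x)
    mu, sd = logx.mean(), logx.std(ddof=1)
    if sd == 0:
        return np.ones(x.size, dtype=bool)
    return np.abs(logx - mu) <= k * sd


def _resolve_threshold(values: np.ndarray, threshold_spec) -> float:
    """Threshold from a spec: a number, 'otsu', 'q:<quantile>' or 'mad:<k>'.

    'otsu' suits images with a substantial cluster area fraction; 'mad:k'
    (median + k * 1.4826 * MAD, a robust background estimate) is preferable
    when clusters cover only a small fraction of the membrane and the
    intensity histogram is dominated by its background mode.
    """
    if isinstance(threshold_spec, (int, float)) and not isinstance(threshold_spec, bool):
        return float(threshold_spec)
    if threshold_spec == "otsu":
        return float(threshold_otsu(values))
    if isinstance(threshold_spec, str) and threshold_spec.startswith("q:"):
        q = float(threshold_spec[2:])
        if not (0 < q < 1):
            raise ValueError("quantile threshold must be in (0, 1)")
        return float(np.quantile(values, q))
    if isinstance(threshold_spec, str) and threshold_spec.startswith("mad:"):
        k = float(threshold_spec[4:])
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        return med + k * 1.4826 * mad
    if isinstance(threshold_spec, str) and threshold_spec.startswith("rise:"):
        # fraction of the rise from the background (median) to the bright
        # cluster cores (99.5th percentile); 'rise:0.5' cuts clusters near
        # their half-maximum contour, which tracks the true cluster edge
        # for PSF-blurred objects larger than the PSF
        f = float(threshold_spec[5:])
        if not (0 < f < 1):
            raise ValueError("rise fraction must be in (0, 1)")
        med = float(np.median(values))
        hi = float(np.quantile(values, 0.995))
        return med + f * (hi - med)
    raise ValueError(f"unknown threshold spec: {threshold_spec!r}")


def segment_clusters(
    image: MembraneImage,
    threshold_spec="otsu",
    min_size: int = 4,
    smooth_sigma: float = 1.2,
    marker_h: float | str = "auto",
) -> np.ndarray:
    """Threshold + watershed segmentation of membrane clusters.

    Foreground pixels (above threshold, within the mask, on the smoothed
    image) are split into clusters by watershed flooding of the inverted
    smoothed intensity, seeded at its h-maxima: regional maxima whose
    prominence exceeds ``marker_h``, so counting-noise ripples on a
    cluster plateau do not seed spurious basins while genuinely distinct
    clusters (separated by a deep saddle) are still split.  ``"auto"``
    sets h to 30% of the threshold-to-background rise.  Clusters smaller
    than ``min_size`` pixels are discarded.  Returns an integer label map
    (0 = background).  An empty foreground yields an all-zero map.
    """
    smoothed = ndi.gaussian_filter(image.image, smooth_sigma)
    vals = smoothed[image.mask]
    if vals.size == 0:
        raise ValueError("empty membrane mask")
    thr = _resolve_threshold(vals, threshold_spec)
    fg = (smoothed > thr) & image.mask
    if not fg.any():
        return np.zeros(image.image.shape, dtype=np.int32)

    if marker_h == "auto":
        background = float(np.median(vals))
        marker_h = max(0.3 * (thr - background), 1e-6)
    maxima = h_maxima(smoothed, marker_h)
    markers, _ = ndi.label(maxima & fg)
    labels = watershed(-smoothed, markers=markers, mask=fg).astype(np.int32)
    if min_size > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_size)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return remap[labels]


def cluster_metrics(
    labels: np.ndarray,
    image: MembraneImage,
) -> ClusterTable:
    """Per-cluster areas/intensities and per-cell summary metrics.

    Counts are reported per 10 um^2 of masked membrane; inside/outside
    mean intensities are normalized to the whole-mask mean so that a
    uniform image gives 1.0 for both.
    """
    mask = image.mask
    if not mask.any():
        raise ValueError("empty membrane mask")
    labels = np.where(mask, labels, 0)
    img = image.image
    masked_area = float(mask.sum()) * image.pixel_area

    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size:
        props = regionprops_table(
            labels, intensity_image=img,
            properties=("label", "area", "intensity_mean", "centroid"),
        )
        df = pd.DataFrame(props)
        df["area_um2"] = df["area"] * image.pixel_area
        df["integrated_intensity"] = df["intensity_mean"] * df["area"]
        df = df.rename(columns={"centroid-0": "centroid_row", "centroid-1": "centroid_col"})
        df = df[["label", "area_um2", "integrated_intensity", "centroid_row", "centroid_col"]]
    else:
        df = pd.DataFrame(
            columns=["label", "area_um2", "integrated_intensity", "centroid_row", "centroid_col"]
        )

    inside = mask & (labels > 0)
    outside = mask & (labels == 0)
    whole_mean = float(img[mask].mean())
    norm_in = float(img[inside].mean()) / whole_mean if inside.any() and whole_mean else float("nan")
    norm_out = float(img[outside].mean()) / whole_mean if outside.any() and whole_mean else float("nan")
    return ClusterTable(
        clusters=df,
        count_per_10um2=len(df) * 10.0 / masked_area,
        norm_mean_inside=norm_in,
        norm_mean_outside=norm_out,
        total_intensity=float(img[mask].sum()),
        masked_area_um2=masked_area,
    )


def generate_membrane_image(
    config: SyntheticMembraneConfig,
) -> tuple[MembraneImage, pd.DataFrame]:
    """Render a synthetic membrane field with known cluster ground truth.

    Cluster centres are placed uniformly with non-overlap enforced by
    rejection; radii are lognormal.  The receptor density map (elevated
    inside clusters) is converted to expected counts, convolved with the
    Gaussian PSF, offset by the background, and optionally Poisson-noised.

    Returns the image and a ground-truth table with one row per cluster
    (center_x_um, center_y_um, radius_um, area_um2).
    """
    rng = np.random.default_rng(config.seed)
    n_pix = int(round(config.field_size / config.pixel_size))
    margin = config.radius_median * math.exp(2 * config.radius_sigma_log)

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    max_attempts = 200 * max(config.n_clusters, 1)
    while len(centers) < config.n_clusters:
        if attempts >= max_attempts:
            raise RuntimeError(
                "could not place non-overlapping clusters; reduce count or radii"
            )
        attempts += 1
        r = config.radius_median * math.exp(rng.normal(0.0, config.radius_sigma_log))
        x, y = rng.uniform(margin, config.field_size - margin, size=2)
        if all(
            (x - cx) ** 2 + (y - cy) ** 2 >= (r + cr + config.min_separation) ** 2
            for (cx, cy), cr in zip(centers, radii)
        ):
            centers.append((x, y))
            radii.append(r)

    yy, xx = np.mgrid[0:n_pix, 0:n_pix]
    xs = (xx + 0.5) * config.pixel_size
    ys = (yy + 0.5) * config.pixel_size
    density = np.full((n_pix, n_pix), config.density_outside, dtype=np.float64)
    for (cx, cy), r in zip(centers, radii):
        density[(xs - cx) ** 2 + (ys - cy) ** 2 <= r**2] = config.density_inside

    expected = density * config.pixel_size**2 * config.brightness
    blurred = ndi.gaussian_filter(expected, config.psf_sigma / config.pixel_size)
    lam = blurred + config.background
    img = rng.poisson(lam).astype(np.float64) if config.poisson_noise else lam

    truth = pd.DataFrame(
        {
            "center_x_um": [c[0] for c in centers],
            "center_y_um": [c[1] for c in centers],
            "radius_um": radii,
            "area_um2": [math.pi * r**2 for r in radii],
        }
    )
    membrane = MembraneImage(
        image=img,
        pixel_size=config.pixel_size,
        metadata={"seed": config.seed, "synthetic": True},
    )
    return membrane, truth


def write_membrane_tiff(image: MembraneImage, path) -> None:
    """Write a single-plane TIFF (float32) with the pixel size in metadata."""
    tifffile.imwrite(
        path, image.image.astype(np.float32),
        metadata={"pixel_size_um": image.pixel_size},
    )


def read_membrane_tiff(path, pixel_size: float, mask=None) -> MembraneImage:
    """Read a single-plane TIFF as a MembraneImage."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError("expected a single-plane 2D TIFF")
    return MembraneImage(image=np.asarray(arr, dtype=np.float64), pixel_size=pixel_size, mask=mask)
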