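"""Per-cell quantification of multichannel microscopy stacks.

Implements the measurement chain used to score nanoparticle uptake in
adherent cells imaged by laser scanning microscopy:

* label-free cell outlines from the bright-field channel (local-variance
  texture -> median smoothing -> IsoData threshold -> cleanup),
* masked-pixel statistics: mean fluorescence intensity (MFI), Pearson
  correlation between two channels, and the voxel "uptake load" (count of
  in-cell voxels above an IsoData threshold of the in-cell intensity
  pool),
* uptake kinetics as the ordinary least-squares slope of MFI over time,
* a "vicinity" score for endocytosis-inhibition experiments: the mean
  fluorescence in an extracellular rim whose area is 20% of the cell
  (cell + rim = 120% of the cell), expressed as fold change over a
  background annulus 15 um away from the cell boundary.

Masks are computed per z-slice and pooled across slices of a cell for
the voxel statistics.  All geometry is reported in um; intensities are
treated as linear.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import linregress
from skimage.filters import median as _median_filter
from skimage.morphology import disk, remove_small_objects
from skimage.measure import label as _cc_label

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "CellMask",
    "RimRegions",
    "QuantRecord",
    "SlopeEstimate",
    "segment_brightfield",
    "pearson",
    "isodata_threshold",
    "uptake_load",
    "mfi",
    "uptake_slope",
    "make_rim_regions",
    "rim_enrichment",
    "quantify_stack",
]


class ImagingError(ValueError):
    pass


class UndefinedCorrelationError(ImagingError):
    """Pearson r is undefined because a channel is constant."""


class DegenerateHistogramError(ImagingError):
    """IsoData threshold is undefined for constant input."""


class EmptyRegionError(ImagingError):
    pass


@dataclass
class ImageStack:
    """Calibrated multichannel (z-)stack, pixels ordered (z, c, y, x)."""

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size: float  # um/px
    z_step: float = 1.0  # um
    time_index: float | None = None  # acquisition time, min

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 3:  # single z-slice
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 4:
            raise ImagingError("pixels must be (z, c, y, x) or (c, y, x)")
        if self.pixels.shape[1] != len(self.channel_names):
            raise ImagingError(
                f"{self.pixels.shape[1]} channels in array vs "
                f"{len(self.channel_names)} channel names"
            )
        if not self.pixel_size > 0:
            raise ImagingError("pixel_size must be > 0")
        if np.any(self.pixels < 0):
            raise ImagingError("intensities must be >= 0")

    @property
    def n_z(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """(z, y, x) array of one channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ImagingError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None
        return self.pixels[:, idx]

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            self.pixels.astype(np.float32),
            imagej=True,
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={
                "axes": "ZCYX",
                "unit": "um",
                "spacing": self.z_step,
                "Labels": list(self.channel_names) * self.n_z,
            },
        )

    @classmethod
    def from_tiff(
        cls,
        path,
        channel_names: list[str] | None = None,
        pixel_size: float | None = None,
        z_step: float | None = None,
    ) -> "ImageStack":
        """Read an ImageJ-style hyperstack (TZCYX/ZCYX/CYX axis order)."""
        import tifffile

        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            data = series.asarray()
            axes = series.axes
            meta = tf.imagej_metadata or {}
            if pixel_size is None:
                page = tf.pages[0]
                res = page.tags.get("XResolution")
                if res is not None and res.value[0]:
                    pixel_size = res.value[1] / res.value[0]
                else:
                    raise ImagingError("pixel size not in TIFF tags; pass pixel_size")
            if z_step is None:
                z_step = float(meta.get("spacing", 1.0))

        # normalise axis order to ZCYX
        axes = axes.replace("S", "C")
        if "T" in axes:
            data = np.moveaxis(data, axes.index("T"), 0)[0]
            axes = axes.replace("T", "")
        for ax in "ZC":
            if ax not in axes:
                data = data[None]
                axes = ax + axes
        data = np.moveaxis(data, [axes.index(a) for a in "ZCYX"], [0, 1, 2, 3])
        if channel_names is None:
            channel_names = [f"ch{i}" for i in range(data.shape[1])]
        return cls(data, channel_names, pixel_size=pixel_size, z_step=z_step)


@dataclass
class CellMask:
    """Binary region of one cell, per z-slice."""

    label: int
    mask: np.ndarray  # (z, y, x) boolean
    pixel_size: float  # um/px
    touches_border: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim == 2:
            self.mask = self.mask[None]
        if not self.mask.any():
            raise ImagingError("cell mask is empty")

    @property
    def footprint(self) -> np.ndarray:
        """2-D union of the mask across z."""
        return self.mask.any(axis=0)

    @property
    def area(self) -> float:
        """Footprint area in um^2."""
        return float(self.footprint.sum()) * self.pixel_size**2

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid of the footprint, um."""
        cy, cx = ndimage.center_of_mass(self.footprint)
        return (cx * self.pixel_size, cy * self.pixel_size)


@dataclass
class RimRegions:
    """Extracellular scoring regions of one cell (2-D footprints)."""

    vicinity: np.ndarray  # boolean, area ~ 0.20 x cell area
    background: np.ndarray  # boolean annulus ~15 um out
    pixel_size: float

    def __post_init__(self) -> None:
        if (self.vicinity & self.background).any():
            raise ImagingError("vicinity and background overlap")


@dataclass
class QuantRecord:
    """One per-cell, per-channel measurement."""

    cell_id: int
    channel: str
    load: int
    mfi: float
    time: float | None = None
    pearson_vs: str | None = None
    pearson_r: float | None = None
    rim_fold: float | None = None
    background_mean: float | None = None


@dataclass
class SlopeEstimate:
    """OLS slope of MFI over time (the uptake rate readout, Delta)."""

    delta: float  # MFI units per minute
    intercept: float
    r_squared: float
    n_points: int


# --------------------------------------------------------------------------
# masking


def _local_variance(image: np.ndarray, radius: int) -> np.ndarray:
    """Local variance in a (2r+1)^2 window (texture detector)."""
    img = image.astype(np.float64)
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(img, size)
    mean_sq = ndimage.uniform_filter(img * img, size)
    return np.maximum(mean_sq - mean * mean, 0.0)


def segment_brightfield(
    stack: ImageStack,
    variance_radius: int = 4,
    median_radius: int = 6,
    min_area: float = 50.0,
    brightfield: str = "brightfield",
) -> list[CellMask]:
    """Cell outlines from bright-field texture, one mask per cell.

    Per z-slice: local-variance filter -> median filter -> IsoData
    threshold of the variance map -> fill holes -> drop objects smaller
    than ``min_area`` (um^2).  Slices are linked into cells by footprint
    overlap with the first slice.  Returns an empty list (with a warning)
    when nothing textured is found.
    """
    bf = stack.channel(brightfield)
    min_px = int(round(min_area / stack.pixel_size**2))
    per_slice: list[np.ndarray] = []
    for z in range(stack.n_z):
        var = _local_variance(bf[z], variance_radius)
        var = _median_filter(var, disk(median_radius))
        try:
            thr = isodata_threshold(var.ravel())
        except DegenerateHistogramError:
            per_slice.append(np.zeros(bf[z].shape, dtype=int))
            continue
        binary = var > thr
        binary = ndimage.binary_fill_holes(binary)
        binary = remove_small_objects(binary, max_size=min_px - 1)
        per_slice.append(_cc_label(binary))

    ref = per_slice[0]
    n_cells = int(ref.max())
    if n_cells == 0:
        # fall back to whichever slice found the most objects
        zi = int(np.argmax([lab.max() for lab in per_slice]))
        ref = per_slice[zi]
        n_cells = int(ref.max())
    if n_cells == 0:
        warnings.warn("bright-field segmentation found no cells", stacklevel=2)
        return []

    masks = []
    ny, nx = stack.shape_yx
    border = np.zeros((ny, nx), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for cell_lab in range(1, n_cells + 1):
        ref_region = ref == cell_lab
        mask3d = np.zeros((stack.n_z, ny, nx), dtype=bool)
        for z, lab in enumerate(per_slice):
            # take the slice component with the largest overlap
            overlapping = np.bincount(lab[ref_region], minlength=int(lab.max()) + 1)
            overlapping[0] = 0
            if overlapping.sum() == 0:
                continue
            mask3d[z] = lab == int(np.argmax(overlapping))
        if not mask3d.any():
            continue
        touches = bool((mask3d.any(axis=0) & border).any())
        masks.append(
            CellMask(label=cell_lab, mask=mask3d, pixel_size=stack.pixel_size, touches_border=touches)
        )
    return masks


# --------------------------------------------------------------------------
# masked-pixel statistics


def pearson(x, y) -> float:
    """Pearson correlation r of paired masked-pixel intensities.

    r = sum((x-xbar)(y-ybar)) / sqrt(sum((x-xbar)^2) sum((y-ybar)^2)).
    Raises :class:`UndefinedCorrelationError` when either channel is
    constant (zero denominator) -- deliberately distinct from r = 0.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ImagingError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ImagingError("need at least 2 paired pixels")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("constant channel: Pearson r undefined")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def isodata_threshold(values, tol: float = 0.5, max_iter: int = 500) -> float:
    """Iterative intermeans (IsoData) threshold of an intensity pool.

    Starting from the global mean, iterate
    T <- (mean(values <= T) + mean(values > T)) / 2
    until the change is below ``tol`` intensity units.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise DegenerateHistogramError("empty intensity pool")
    if v.min() == v.max():
        raise DegenerateHistogramError("constant intensity pool")
    t = float(v.mean())
    for _ in range(max_iter):
        below = v[v <= t]
        above = v[v > t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def _pooled_in_mask(stack: ImageStack, mask: CellMask, channel: str) -> np.ndarray:
    ch = stack.channel(channel)
    m = mask.mask
    if m.shape[0] != ch.shape[0]:
        m = np.broadcast_to(mask.footprint, ch.shape)
    vals = ch[m]
    if vals.size == 0:
        raise EmptyRegionError("empty cell mask")
    return vals


def uptake_load(stack: ImageStack, mask: CellMask, channel: str) -> int:
    """Voxel count above the IsoData threshold of the in-cell pool.

    The threshold is computed per cell from the masked intensities pooled
    across z, so the load is robust to between-cell background shifts.
    """
    vals = _pooled_in_mask(stack, mask, channel)
    thr = isodata_threshold(vals)
    return int(np.count_nonzero(vals > thr))


def mfi(stack: ImageStack, mask: CellMask, channel: str) -> float:
    """Mean fluorescence intensity over in-mask voxels."""
    return float(_pooled_in_mask(stack, mask, channel).mean())


def uptake_slope(times, mfis) -> SlopeEstimate:
    """OLS fit of MFI against time; the slope is the uptake rate Delta."""
    times = np.asarray(times, dtype=float)
    mfis = np.asarray(mfis, dtype=float)
    if times.shape != mfis.shape or times.size < 3:
        raise ImagingError("need >= 3 matched (time, MFI) points")
    if np.ptp(mfis) == 0:
        return SlopeEstimate(0.0, float(mfis[0]), 0.0, times.size)
    fit = linregress(times, mfis)
    return SlopeEstimate(
        delta=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=int(times.size),
    )


# --------------------------------------------------------------------------
# vicinity rim


def make_rim_regions(
    mask: CellMask,
    stack: ImageStack,
    *,
    other_masks: list[CellMask] | None = None,
    rim_area_fraction: float = 0.20,
    background_distance: float = 15.0,
    background_width: float = 1.0,
    neighbor_clearance: float = 3.0,
) -> RimRegions:
    """Vicinity rim (20% of cell area) and background annulus (15 um out).

    The vicinity is built from the Euclidean distance transform outside
    the cell: the nearest extracellular pixels are taken in distance-rank
    order until the rim holds ``rim_area_fraction`` of the cell's
    footprint area, so cell + rim cover 120% of the cell.  The background
    is a ``background_width``-um-wide annulus whose inner edge lies
    ``background_distance`` um from the cell boundary.  Pixels inside any
    other cell are excluded from both regions, and the background
    additionally keeps ``neighbor_clearance`` um of clearance from other
    cells so their membrane-adjacent signal cannot contaminate it.
    """
    ps = stack.pixel_size
    cell = mask.footprint
    others = np.zeros(cell.shape, dtype=bool)
    for other in other_masks or []:
        if other.label != mask.label:
            others |= other.footprint
    occupied = cell | others

    dist = ndimage.distance_transform_edt(~cell, sampling=ps)
    outside = ~occupied & (dist > 0)

    n_rim = int(round(rim_area_fraction * cell.sum()))
    cand = np.flatnonzero(outside)
    if cand.size < n_rim:
        warnings.warn("vicinity rim clipped by image bounds / neighbours", stacklevel=2)
        n_rim = cand.size
    if n_rim == 0:
        raise EmptyRegionError("no extracellular pixels available for the rim")
    order = np.argsort(dist.ravel()[cand], kind="stable")
    vicinity = np.zeros(cell.shape, dtype=bool)
    vicinity.ravel()[cand[order[:n_rim]]] = True

    background = (
        outside
        & (dist >= background_distance)
        & (dist < background_distance + background_width)
        & ~vicinity
    )
    if others.any():
        dist_others = ndimage.distance_transform_edt(~others, sampling=ps)
        background &= dist_others >= neighbor_clearance
    if not background.any():
        raise EmptyRegionError(
            f"background annulus at {background_distance} um fully clipped"
        )
    return RimRegions(vicinity=vicinity, background=background, pixel_size=ps)


def rim_enrichment(stack: ImageStack, rims: RimRegions, channel: str) -> float:
    """Mean vicinity intensity as fold change over the background mean."""
    ch = stack.channel(channel)
    vic = ch[:, rims.vicinity]
    bg = ch[:, rims.background]
    if vic.size == 0 or bg.size == 0:
        raise EmptyRegionError("empty rim region")
    bg_mean = float(bg.mean())
    if bg_mean == 0:
        raise ImagingError("zero background mean: fold change undefined")
    return float(vic.mean()) / bg_mean


# --------------------------------------------------------------------------
# pipeline


def quantify_stack(
    stack: ImageStack,
    np_channels: list[str],
    *,
    masks: list[CellMask] | None = None,
    pearson_pairs: list[tuple[str, str]] | None = None,
    rim_channel: str | None = None,
    segmentation_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Run the full per-cell quantification and return a tidy table.

    One row per cell x NP channel with load, MFI, optional Pearson r
    against a paired channel and optional rim enrichment.  Cells touching
    the image border keep their load/MFI but are skipped for rim scoring.
    """
    if masks is None:
        masks = segment_brightfield(stack, **(segmentation_kwargs or {}))
    pearson_pairs = pearson_pairs or []
    records = []
    for cm in masks:
        pr: dict[str, tuple[str, float]] = {}
        for ch_a, ch_b in pearson_pairs:
            a = _pooled_in_mask(stack, cm, ch_a)
            b = _pooled_in_mask(stack, cm, ch_b)
            try:
                pr[ch_a] = (ch_b, pearson(a, b))
            except UndefinedCorrelationError:
                pr[ch_a] = (ch_b, np.nan)
        rims = None
        if rim_channel is not None and not cm.touches_border:
            try:
                rims = make_rim_regions(cm, stack, other_masks=masks)
            except EmptyRegionError as exc:
                logger.warning("cell %d: rim skipped (%s)", cm.label, exc)
        for ch in np_channels:
            vs, r = pr.get(ch, (None, None))
            rim_fold = bg_mean = None
            if rims is not None and (rim_channel == ch or rim_channel == "all"):
                rim_fold = rim_enrichment(stack, rims, ch)
                bg_mean = float(stack.channel(ch)[:, rims.background].mean())
            try:
                load = uptake_load(stack, cm, ch)
            except DegenerateHistogramError:
                load = 0
            records.append(
                QuantRecord(
                    cell_id=cm.label,
                    channel=ch,
                    load=load,
                    mfi=mfi(stack, cm, ch),
                    time=stack.time_index,
                    pearson_vs=vs,
                    pearson_r=r,
                    rim_fold=rim_fold,
                    background_mean=bg_mean,
                )
            )
    return pd.DataFrame([vars(r) for r in records])
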