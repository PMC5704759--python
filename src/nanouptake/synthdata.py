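"""Synthetic microscopy stacks with complete ground truth.

Emulates the study system -- an adherent macrophage monolayer imaged as a
bright-field + fluorescence z-stack -- well enough to exercise every
quantification routine with known answers:

* bright-field: smoothly varying background with speckle-textured
  elliptical cells (the texture is what the variance-filter segmentation
  keys on),
* NP fluorescence channels: diffraction-limited spots (2-px-sigma
  Gaussian kernels, lognormal amplitudes) accumulating linearly in time
  as Poisson counts with mean rate*t, with a controllable true
  colocalization fraction rho between the two NP channels (shared spots
  share coordinates) and an optional overlap with an organelle-marker
  channel,
* noise: Poisson shot noise on the signal plus additive Gaussian read
  noise,
* an endocytosis-inhibition scene where NP fluorescence sits as
  extracellular aggregates in the cell's vicinity rim instead of inside
  the cell.

Everything is deterministic given the seed.  The ground truth records
cell masks, spot placements, true colocalization fraction, and a
measurement-model "true load" (voxels above the IsoData threshold of the
noiseless stack inside the true mask) -- the voxel load is defined by the
thresholding instrument, so its truth is the noise-free measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging import (
    CellMask,
    ImageStack,
    DegenerateHistogramError,
    isodata_threshold,
    make_rim_regions,
)

__all__ = [
    "SceneSpec",
    "UptakeSpec",
    "GroundTruth",
    "generate_scene",
    "generate_uptake_stack",
    "generate_inhibitor_scene",
]

BRIGHTFIELD = "brightfield"
NP1 = "NP1"
NP2 = "NP2"
MARKER = "marker"

_SPOT_SIGMA_PX = 2.0


class PlacementError(RuntimeError):
    """Cells could not be placed without overlap."""


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, texture and noise of one synthetic field of view."""

    shape: tuple[int, int] = (512, 512)  # (ny, nx) px
    n_z: int = 3
    pixel_size: float = 0.2  # um/px
    z_step: float = 1.0  # um
    n_cells: int = 6
    cell_radius_um: tuple[float, float] = (6.0, 9.0)
    bf_background: float = 1000.0
    texture_amplitude: float = 200.0
    fluor_background: float = 20.0
    gaussian_noise_sd: float = 3.0
    poisson_gain: float = 1.0  # photons per intensity unit; 0 disables shot noise
    border_margin_um: float = 18.0  # keeps rims inside the field
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class UptakeSpec:
    """Linear-uptake kinetics of the fluorescence channels.

    Spot counts per cell and channel are Poisson with mean ``rate * t``
    (spots/cell/hour), mirroring the linear uptake trends of the study;
    ``coloc_fraction`` rho of the rate is shared between NP1 and NP2
    (identical spot coordinates), and ``marker_overlap`` of each
    channel's spots land inside organelle-marker blobs.
    """

    rates: dict[str, float] = field(default_factory=lambda: {NP1: 8.0, NP2: 8.0})
    coloc_fraction: float = 0.0
    marker_overlap: float = 0.0
    spot_amplitude_median: float = 150.0
    spot_amplitude_sigma_ln: float = 0.25
    n_marker_blobs: int = 5
    marker_blob_radius_um: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if not 0.0 <= self.marker_overlap <= 1.0:
            raise ValueError("marker_overlap must lie in [0, 1]")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("uptake rates must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows about the emitted stack."""

    masks: list[CellMask]
    spots: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    # spots[channel][cell_label] -> (n, 4) array of (z, y_px, x_px, amplitude)
    coloc_fraction: float | None = None
    true_load: dict[str, dict[int, int]] = field(default_factory=dict)
    rim_fold: float | None = None
    noiseless: np.ndarray | None = None  # (z, c, y, x)

    def spot_count(self, channel: str, label: int) -> int:
        return len(self.spots.get(channel, {}).get(label, ()))


# --------------------------------------------------------------------------


def _place_cells(spec: SceneSpec, rng: np.random.Generator, max_tries: int = 2000):
    """Non-overlapping ellipse parameters (cy, cx, ry, rx, theta) in px."""
    ny, nx = spec.shape
    margin = spec.border_margin_um / spec.pixel_size
    r_lo, r_hi = (r / spec.pixel_size for r in spec.cell_radius_um)
    placed: list[tuple[float, float, float, float, float]] = []
    tries = 0
    while len(placed) < spec.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed {len(placed)}/{spec.n_cells} cells in {max_tries} tries"
            )
        tries += 1
        r_mean = rng.uniform(r_lo, r_hi)
        ecc = rng.uniform(0.75, 1.0)
        ry, rx = r_mean * ecc, r_mean / ecc
        r_max = max(ry, rx)
        if margin + r_max >= ny - margin - r_max or margin + r_max >= nx - margin - r_max:
            continue  # cell cannot fit the field at all; counts as a try
        cy = rng.uniform(margin + r_max, ny - margin - r_max)
        cx = rng.uniform(margin + r_max, nx - margin - r_max)
        theta = rng.uniform(0, np.pi)
        # centre-distance separation with a safety gap so rims stay disjoint
        gap = 3.0 / spec.pixel_size
        if all(
            np.hypot(cy - p[0], cx - p[1]) > r_max + max(p[2], p[3]) + gap
            for p in placed
        ):
            placed.append((cy, cx, ry, rx, theta))
    return placed


def _ellipse_mask(shape, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _speckle(shape, amplitude, rng, smooth_sigma=1.0) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, shape)
    tex = ndimage.gaussian_filter(noise, smooth_sigma)
    return amplitude * tex / max(tex.std(), 1e-12)


def _apply_noise(noiseless: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    out = noiseless
    if spec.poisson_gain > 0:
        out = rng.poisson(np.maximum(out, 0.0) * spec.poisson_gain) / spec.poisson_gain
    if spec.gaussian_noise_sd > 0:
        out = out + rng.normal(0.0, spec.gaussian_noise_sd, out.shape)
    return np.maximum(out, 0.0)


def generate_scene(spec: SceneSpec) -> tuple[ImageStack, GroundTruth]:
    """Bright-field-only scene: textured elliptical cells, no fluorescence."""
    rng = spec.rng()
    ny, nx = spec.shape
    ellipses = _place_cells(spec, rng) if spec.n_cells > 0 else []

    masks: list[CellMask] = []
    bf_plane = np.full((ny, nx), spec.bf_background, dtype=np.float64)
    for i, ell in enumerate(ellipses, start=1):
        m2d = _ellipse_mask((ny, nx), *ell)
        texture = _speckle((ny, nx), spec.texture_amplitude, rng)
        bf_plane[m2d] += texture[m2d]
        masks.append(
            CellMask(
                label=i,
                mask=np.broadcast_to(m2d, (spec.n_z, ny, nx)).copy(),
                pixel_size=spec.pixel_size,
            )
        )

    noiseless = np.broadcast_to(bf_plane, (spec.n_z, 1, ny, nx)).copy()
    pixels = _apply_noise(noiseless, spec, rng)
    stack = ImageStack(
        pixels, [BRIGHTFIELD], pixel_size=spec.pixel_size, z_step=spec.z_step
    )
    return stack, GroundTruth(masks=masks, noiseless=noiseless)


def _render_spots(volume: np.ndarray, spots: np.ndarray, sigma: float) -> None:
    """Add Gaussian kernels (in place) at (z, y, x, amplitude) rows."""
    half = int(np.ceil(4 * sigma))
    _, ny, nx = volume.shape
    ax = np.arange(-half, half + 1)
    kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    for z, y, x, amp in spots:
        yi, xi = int(round(y)), int(round(x))
        y0, y1 = max(yi - half, 0), min(yi + half + 1, ny)
        x0, x1 = max(xi - half, 0), min(xi + half + 1, nx)
        volume[int(z), y0:y1, x0:x1] += amp * kernel[
            y0 - yi + half : y1 - yi + half, x0 - xi + half : x1 - xi + half
        ]


def _sample_positions(rng, region: np.ndarray, n: int) -> np.ndarray:
    idx = np.flatnonzero(region)
    if idx.size == 0 or n == 0:
        return np.empty((0, 2))
    chosen = rng.choice(idx, size=n, replace=True)
    ys, xs = np.unravel_index(chosen, region.shape)
    jitter = rng.uniform(-0.5, 0.5, (n, 2))
    return np.column_stack([ys, xs]) + jitter


def _true_loads(
    noiseless: np.ndarray, channel_idx: int, masks: list[CellMask]
) -> dict[int, int]:
    """Measurement-model truth: noiseless in-mask voxels above IsoData."""
    loads: dict[int, int] = {}
    for cm in masks:
        vals = noiseless[:, channel_idx][cm.mask]
        try:
            thr = isodata_threshold(vals)
            loads[cm.label] = int(np.count_nonzero(vals > thr))
        except DegenerateHistogramError:
            loads[cm.label] = 0
    return loads


def generate_uptake_stack(
    spec: SceneSpec,
    uptake: UptakeSpec,
    t_hours: float,
) -> tuple[ImageStack, GroundTruth]:
    """Four-channel stack after ``t_hours`` of linear NP uptake.

    Channels: bright-field, NP1, NP2, organelle marker.  Spot counts per
    cell are Poisson(rate * t); a Poisson(rho * rate * t) subset shares
    coordinates (including the z-slice) between the two NP channels, so
    each channel's marginal count keeps mean rate * t while the expected
    shared fraction is rho.  Spots distribute uniformly over the z-stack,
    emulating endosomes through the cell volume.
    """
    if t_hours < 0:
        raise ValueError("t_hours must be >= 0")
    rng = spec.rng()
    bf_stack, truth = generate_scene(spec)
    ny, nx = spec.shape
    channels = [BRIGHTFIELD, NP1, NP2, MARKER]
    noiseless = np.zeros((spec.n_z, len(channels), ny, nx))
    noiseless[:, 0] = truth.noiseless[:, 0]
    noiseless[:, 1:] = spec.fluor_background

    # organelle-marker blobs per cell
    marker_region = np.zeros((ny, nx), dtype=bool)
    blob_r = uptake.marker_blob_radius_um / spec.pixel_size
    for cm in truth.masks:
        interior = ndimage.binary_erosion(
            cm.footprint, iterations=max(int(blob_r) + 1, 1)
        )
        centres = _sample_positions(rng, interior, uptake.n_marker_blobs)
        for cy, cx in centres:
            marker_region |= _ellipse_mask((ny, nx), cy, cx, blob_r, blob_r, 0.0)
    marker_plane = np.where(marker_region, 4.0 * spec.fluor_background, 0.0)
    noiseless[:, channels.index(MARKER)] += marker_plane[None]

    def draw_amplitudes(n: int) -> np.ndarray:
        return uptake.spot_amplitude_median * np.exp(
            rng.normal(0.0, uptake.spot_amplitude_sigma_ln, n)
        )

    rho = uptake.coloc_fraction
    spots: dict[str, dict[int, np.ndarray]] = {NP1: {}, NP2: {}}
    for cm in truth.masks:
        cell_region = cm.footprint
        in_marker = cell_region & marker_region
        rate1 = uptake.rates.get(NP1, 0.0)
        rate2 = uptake.rates.get(NP2, 0.0)
        shared_rate = rho * min(rate1, rate2)
        n_shared = rng.poisson(shared_rate * t_hours)
        n_only = {
            NP1: rng.poisson((rate1 - shared_rate) * t_hours),
            NP2: rng.poisson((rate2 - shared_rate) * t_hours),
        }

        def place(n: int) -> np.ndarray:
            """(n, 3) rows of (z, y, x)."""
            if n == 0:
                return np.empty((0, 3))
            n_in_marker = rng.binomial(n, uptake.marker_overlap) if in_marker.any() else 0
            pos_m = _sample_positions(rng, in_marker, n_in_marker)
            pos_c = _sample_positions(rng, cell_region, n - n_in_marker)
            pos = np.vstack([pos_m, pos_c])
            zs = rng.integers(0, spec.n_z, size=n)
            return np.column_stack([zs, pos])

        shared_pos = place(n_shared)
        # shared spots share brightness too: both labels scale with the
        # particle content of the common endosome
        shared_amps = draw_amplitudes(len(shared_pos))
        for ch in (NP1, NP2):
            own_pos = place(n_only[ch])
            pos = np.vstack([shared_pos, own_pos])
            amps = np.concatenate([shared_amps, draw_amplitudes(len(own_pos))])
            cell_spots = np.column_stack([pos, amps]) if len(pos) else np.empty((0, 4))
            spots[ch][cm.label] = cell_spots
            _render_spots(noiseless[:, channels.index(ch)], cell_spots, _SPOT_SIGMA_PX)

    pixels = _apply_noise(noiseless, spec, rng)
    stack = ImageStack(
        pixels,
        channels,
        pixel_size=spec.pixel_size,
        z_step=spec.z_step,
        time_index=t_hours * 60.0,
    )
    truth = GroundTruth(
        masks=truth.masks,
        spots=spots,
        coloc_fraction=rho,
        true_load={
            ch: _true_loads(noiseless, channels.index(ch), truth.masks)
            for ch in (NP1, NP2)
        },
        noiseless=noiseless,
    )
    return stack, truth


def generate_inhibitor_scene(
    spec: SceneSpec,
    blocked: bool,
    rim_intensity_fold: float = 3.0,
    uptake: UptakeSpec | None = None,
    t_hours: float = 1.0,
) -> tuple[ImageStack, GroundTruth]:
    """Endocytosis-inhibition scenario for the vicinity-rim score.

    When ``blocked``, NP fluorescence is deposited as extracellular
    aggregates filling the cell's vicinity rim (area 20% of the cell) at
    ``rim_intensity_fold`` x the fluorescence background, and
    intracellular signal is suppressed; otherwise the cells take up spots
    normally and the extracellular space stays at background.
    """
    uptake = uptake or UptakeSpec()
    if not blocked:
        stack, truth = generate_uptake_stack(spec, uptake, t_hours)
        truth.rim_fold = 1.0
        return stack, truth

    rng = spec.rng()
    bf_stack, truth = generate_scene(spec)
    ny, nx = spec.shape
    channels = [BRIGHTFIELD, NP1, NP2, MARKER]
    noiseless = np.zeros((spec.n_z, len(channels), ny, nx))
    noiseless[:, 0] = truth.noiseless[:, 0]
    noiseless[:, 1:] = spec.fluor_background

    ref = ImageStack(
        np.zeros((spec.n_z, 1, ny, nx)), [BRIGHTFIELD], pixel_size=spec.pixel_size
    )
    for cm in truth.masks:
        rims = make_rim_regions(cm, ref, other_masks=truth.masks)
        for ch in (NP1, NP2):
            ci = channels.index(ch)
            noiseless[:, ci][:, rims.vicinity] = rim_intensity_fold * spec.fluor_background

    pixels = _apply_noise(noiseless, spec, rng)
    stack = ImageStack(
        pixels, channels, pixel_size=spec.pixel_size, z_step=spec.z_step
    )
    truth = GroundTruth(masks=truth.masks, rim_fold=rim_intensity_fold, noiseless=noiseless)
    return stack, truth
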