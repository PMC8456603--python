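"""Fluorescence-image quantitation.

Implements the image pipeline used for motor-localization and
microtubule measurements: Phansalkar local thresholding, connected-
component particle analysis on the masked original image, localization
area, motors-per-microtubule-length (bound-particle count over skeleton
length), bundle intensity, spindle-length categorization, and a minimal
greedy nearest-neighbour frame-to-frame particle linker.

The Phansalkar threshold for a pixel with local mean m and local
standard deviation s (computed in a square window of half-width
``radius`` on the image min–max normalized to [0, 1]) is

    T = m * (1 + p * exp(-q * m) + k * (s / r - 1))

with canonical defaults k=0.25, r=0.5, p=2, q=10, radius 15 px.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .motility import Track, TrackSet

__all__ = [
    "ImageField",
    "Particle",
    "SpindleMeasure",
    "phansalkar_mask",
    "analyze_particles",
    "localization_area",
    "motors_per_mt_length",
    "bundle_intensity",
    "skeleton_length_um",
    "measure_spindles",
    "link_particles",
    "PHANSALKAR_DEFAULTS",
]

PHANSALKAR_DEFAULTS = {"radius": 15, "k": 0.25, "r": 0.5, "p": 2.0, "q": 10.0}


@dataclass
class ImageField:
    pixels: np.ndarray       # 2-D grayscale, a.u.
    pixel_size_um: float     # µm per pixel
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")


@dataclass(frozen=True)
class Particle:
    id: int
    pixel_count: int
    area_um2: float
    mean_intensity: float
    centroid_um: tuple[float, float]  # (row, col) in µm


@dataclass(frozen=True)
class SpindleMeasure:
    cell_id: str
    n_poles: int
    length_um: float | None
    category: str  # monopolar | short | long


def _normalize(img: np.ndarray) -> np.ndarray:
    """Map pixel values into [0, 1]: identity when already there, else min–max."""
    lo, hi = float(img.min()), float(img.max())
    if lo >= 0.0 and hi <= 1.0:
        return img
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def phansalkar_mask(
    image: ImageField,
    radius: int = 15,
    k: float = 0.25,
    r: float = 0.5,
    p: float = 2.0,
    q: float = 10.0,
) -> np.ndarray:
    """Binary foreground mask by the Phansalkar local threshold.

    A pixel is foreground iff its normalized value strictly exceeds
    T = m (1 + p e^{-q m} + k (s/r - 1)).  Local statistics use a square
    (2·radius+1)² window with reflective boundary handling.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = _normalize(image.pixels)
    size = 2 * radius + 1
    # clip: the filters can return tiny negatives on constant-zero regions,
    # which would flip the strict > comparison at T = 0
    m = np.clip(ndimage.uniform_filter(img, size=size, mode="reflect"), 0.0, None)
    m2 = ndimage.uniform_filter(img * img, size=size, mode="reflect")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    thresh = m * (1.0 + p * np.exp(-q * m) + k * (s / r - 1.0))
    return img > thresh


def analyze_particles(
    image: ImageField,
    mask: np.ndarray,
    min_pixels: int = 4,
) -> list[Particle]:
    """8-connected components of the mask, measured on the original image."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.pixels.shape:
        raise ValueError("mask shape does not match image shape")
    labels = measure.label(mask, connectivity=2)
    px = image.pixel_size_um
    out = []
    for rp in measure.regionprops(labels, intensity_image=image.pixels):
        if rp.num_pixels < min_pixels:
            continue
        out.append(
            Particle(
                id=int(rp.label),
                pixel_count=int(rp.num_pixels),
                area_um2=float(rp.num_pixels) * px * px,
                mean_intensity=float(rp.intensity_mean),
                centroid_um=(float(rp.centroid[0]) * px, float(rp.centroid[1]) * px),
            )
        )
    return out


def localization_area(
    image: ImageField, min_pixels: int = 4, **threshold_params
) -> float:
    """Total area (µm²) occupied by signal after local thresholding."""
    mask = phansalkar_mask(image, **threshold_params)
    particles = analyze_particles(image, mask, min_pixels=min_pixels)
    return float(sum(pt.area_um2 for pt in particles))


def skeleton_length_um(mask: np.ndarray, pixel_size_um: float) -> float:
    """Length of the skeleton of a binary mask, in µm.

    The skeleton is reduced to unit steps between 8-neighbours; axial
    steps count one pixel, diagonal steps √2 pixels.
    """
    skel = morphology.skeletonize(np.asarray(mask, dtype=bool))
    if not skel.any():
        return 0.0
    # pairs of adjacent skeleton pixels, counted once per pair
    ax = np.count_nonzero(skel[:, :-1] & skel[:, 1:]) + np.count_nonzero(
        skel[:-1, :] & skel[1:, :]
    )
    diag = np.count_nonzero(skel[:-1, :-1] & skel[1:, 1:]) + np.count_nonzero(
        skel[:-1, 1:] & skel[1:, :-1]
    )
    n_edges = ax + diag
    if n_edges == 0:  # single isolated pixel
        return pixel_size_um
    return (ax + math.sqrt(2) * diag) * pixel_size_um


def motors_per_mt_length(
    motor_particles: list[Particle],
    mt_mask: np.ndarray,
    pixel_size_um: float,
) -> float:
    """Density of microtubule-bound motor particles per µm of MT.

    A particle counts as bound when its centroid falls on, or within one
    pixel of, the microtubule mask; the denominator is the skeleton length
    of that mask.
    """
    mt_mask = np.asarray(mt_mask, dtype=bool)
    if not mt_mask.any():
        raise ValueError("empty microtubule mask: density undefined")
    near = ndimage.binary_dilation(mt_mask, structure=np.ones((3, 3), dtype=bool))
    count = 0
    for pt in motor_particles:
        i = int(round(pt.centroid_um[0] / pixel_size_um))
        j = int(round(pt.centroid_um[1] / pixel_size_um))
        if 0 <= i < near.shape[0] and 0 <= j < near.shape[1] and near[i, j]:
            count += 1
    length = skeleton_length_um(mt_mask, pixel_size_um)
    return count / length


def bundle_intensity(
    image: ImageField, min_pixels: int = 4, **threshold_params
) -> list[float]:
    """Mean original-image intensity of each detected MT / MT-bundle."""
    mask = phansalkar_mask(image, **threshold_params)
    particles = analyze_particles(image, mask, min_pixels=min_pixels)
    return [pt.mean_intensity for pt in particles]


def measure_spindles(poles_per_cell: dict[str, list[tuple[float, float]]]) -> list[SpindleMeasure]:
    """Spindle length and category per cell from pole coordinates (µm).

    One pole → monopolar; two poles → Euclidean distance, categorized as
    short (< 2 µm) or long (≥ 2 µm; the measure-zero boundary at exactly
    2 µm goes to "long").
    """
    out = []
    for cell_id, poles in poles_per_cell.items():
        if len(poles) == 1:
            out.append(SpindleMeasure(cell_id, 1, None, "monopolar"))
        elif len(poles) == 2:
            (x1, y1), (x2, y2) = poles
            length = math.hypot(x2 - x1, y2 - y1)
            out.append(
                SpindleMeasure(
                    cell_id, 2, length, "short" if length < 2.0 else "long"
                )
            )
        else:
            raise ValueError(f"cell {cell_id}: expected 1 or 2 poles, got {len(poles)}")
    return out


def link_particles(
    frames: list[np.ndarray],
    max_jump_um: float,
    frame_interval_s: float = 1.0,
) -> TrackSet:
    """Greedy nearest-neighbour linking of per-frame 1-D positions (µm).

    Frames are time-ordered arrays of particle positions along the MT
    axis.  Each active track is extended by its nearest unclaimed
    detection within ``max_jump_um``; unmatched detections start new
    tracks.  Positions are returned in nm.
    """
    active: list[tuple[list[float], list[float]]] = []  # (times, positions)
    finished: list[tuple[list[float], list[float]]] = []
    for fi, positions in enumerate(frames):
        t = fi * frame_interval_s
        det = [float(x) for x in np.atleast_1d(np.asarray(positions, dtype=float))]
        claimed = [False] * len(det)
        # candidate links sorted globally by distance
        cands = []
        for ti, (_, xs) in enumerate(active):
            for di, x in enumerate(det):
                dist = abs(x - xs[-1])
                if dist <= max_jump_um:
                    cands.append((dist, ti, di))
        cands.sort()
        extended = [False] * len(active)
        for _, ti, di in cands:
            if extended[ti] or claimed[di]:
                continue
            active[ti][0].append(t)
            active[ti][1].append(det[di])
            extended[ti] = True
            claimed[di] = True
        still = []
        for ti, tr in enumerate(active):
            (still if extended[ti] else finished).append(tr)
        active = still
        for di, x in enumerate(det):
            if not claimed[di]:
                active.append(([t], [x]))
    finished.extend(active)
    tracks = [
        Track(f"track_{i:04d}", np.array(ts), np.array(xs) * 1000.0)
        for i, (ts, xs) in enumerate(finished)
        if len(ts) >= 2
    ]
    return TrackSet(tracks)
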