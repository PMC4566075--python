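"""Motion correction and ROI extraction.

Registration estimates an integer-pixel (dy, dx) translation per frame by
phase cross-correlation against a reference, in two passes: a first pass
aligned to the initial frame, then a refinement pass against the mean of
the first 10 registered frames.  The two-pass scheme gives a low-noise
reference without the smearing a naive multi-frame mean suffers on a
drifting movie.

ROI extraction runs a Laplacian-of-Gaussian band-pass over a temporal
summary image and thresholds it at ``mean + c * sd``; the resulting seed
blobs are then grown to the full bright structure by an intensity
(Otsu) mask, so ROI pixel sets follow cell outlines rather than the
band-pass response.  ROIs are classified as round stalk cross-sections or
elongated lateral processes from their circularity and best-fit-ellipse
aspect ratio, and a fixed n x n grid partition is provided for
neuronal-sensor movies where per-cell segmentation is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.registration import phase_cross_correlation
from scipy import ndimage as ndi

from .core import MovieStack, Roi, RoiMap, roi_circularity

__all__ = [
    "RegistrationResult",
    "register_movie",
    "laplacian_roi_masks",
    "classify_roi_shape",
    "grid_roi_masks",
]


@dataclass
class RegistrationResult:
    movie: MovieStack
    shifts: np.ndarray  # (n_frames, 2) estimated (dy, dx) displacement per frame
    rejected: bool  # True when any |shift| exceeded the rejection bound


def _estimate_shift(reference: np.ndarray, frame: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) displacement of ``frame`` relative to ``reference``."""
    shift, _, _ = phase_cross_correlation(reference, frame, upsample_factor=1)
    # phase_cross_correlation returns the translation that maps `frame` onto
    # `reference`; the frame's own displacement is its negation.
    return int(round(-shift[0])), int(round(-shift[1]))


def register_movie(
    movie: MovieStack, reject_shift_px: float = 20.0, n_reference_frames: int = 10
) -> RegistrationResult:
    """Correct X-Y translation per frame; report shifts and a rejection flag.

    Each frame is translated by the negated estimated displacement (circular
    shift).  A single-frame movie is returned unchanged with a zero shift.
    """
    data = np.asarray(movie.data)
    if not np.isfinite(data.astype(np.float64)).all():
        raise ValueError("movie contains non-finite pixels")
    n = movie.n_frames
    if n == 1:
        return RegistrationResult(movie, np.zeros((1, 2), dtype=int), False)

    frames = data.astype(np.float32)
    shifts = np.zeros((n, 2), dtype=int)
    # Pass 1: align everything to the first frame.
    reference = frames[0]
    registered = np.empty_like(frames)
    for i in range(n):
        dy, dx = _estimate_shift(reference, frames[i])
        shifts[i] = (dy, dx)
        registered[i] = np.roll(frames[i], (-dy, -dx), axis=(0, 1))
    # Pass 2: refine against the mean of the first registered frames.
    reference = registered[: min(n_reference_frames, n)].mean(axis=0)
    for i in range(n):
        dy, dx = _estimate_shift(reference, frames[i])
        shifts[i] = (dy, dx)
        registered[i] = np.roll(frames[i], (-dy, -dx), axis=(0, 1))

    out = registered
    if np.issubdtype(data.dtype, np.integer):
        out = np.round(registered).astype(data.dtype)
    rejected = bool(np.abs(shifts).max() > reject_shift_px)
    return RegistrationResult(
        MovieStack(out, movie.frame_rate_hz, movie.t0_s), shifts, rejected
    )


def _summary_image(movie: MovieStack | np.ndarray, method: str) -> np.ndarray:
    if isinstance(movie, MovieStack):
        data = movie.data.astype(np.float64)
    else:
        data = np.asarray(movie, dtype=np.float64)
        if data.ndim == 2:
            return data
    if method == "mean":
        return data.mean(axis=0)
    if method == "sd":
        return data.std(axis=0)
    raise ValueError(f"unknown summary method {method!r}")


def laplacian_roi_masks(
    movie: MovieStack | np.ndarray,
    sigma: float = 2.5,
    threshold_sd: float = 2.0,
    min_area: int = 6,
    summary: str = "mean",
    refine: bool = True,
) -> RoiMap:
    """Segment bright structures from a movie (or a 2-D summary image).

    A negated Laplacian-of-Gaussian at scale ``sigma`` highlights blob- and
    ridge-like bright structures; pixels above ``mean + threshold_sd * sd``
    of the filtered image become detection seeds.  With ``refine`` (the
    default) each seed is expanded to its containing connected component of
    the Otsu foreground of the summary image, so the reported pixel sets
    track the full structure.  Components smaller than ``min_area`` pixels
    are discarded.  A constant image yields zero ROIs.
    """
    img = _summary_image(movie, summary)
    empty = RoiMap(labels=np.zeros(img.shape, dtype=np.int32), rois=[])
    if np.ptp(img) == 0:
        return empty

    filt = -ndi.gaussian_laplace(img, sigma=sigma)
    thr = filt.mean() + threshold_sd * filt.std()
    seeds = filt > thr
    seeds = remove_small_objects(seeds, max_size=min_area - 1)
    if not seeds.any():
        return empty

    if refine:
        fg = img > threshold_otsu(img)
        fg = remove_small_objects(fg, max_size=min_area - 1)
        comp = cc_label(fg, connectivity=2)
        keep = np.unique(comp[seeds & (comp > 0)])
        mask = np.isin(comp, keep) & (comp > 0)
        labelled = cc_label(mask, connectivity=2)
    else:
        labelled = cc_label(seeds, connectivity=2)

    # relabel sequentially, dropping anything below min_area
    out = np.zeros(img.shape, dtype=np.int32)
    rois: list[Roi] = []
    next_id = 1
    for region in regionprops(labelled):
        if region.area < min_area:
            continue
        mask = labelled == region.label
        out[mask] = next_id
        rois.append(
            Roi(next_id, np.argwhere(mask), classify_roi_shape(mask), roi_circularity(mask))
        )
        next_id += 1
    return RoiMap(labels=out, rois=rois)


def classify_roi_shape(
    mask: np.ndarray, circularity_cutoff: float = 0.7, aspect_cutoff: float = 2.0
) -> str:
    """'stalk' for round compact ROIs, 'lateral_process' for elongated ones.

    A ROI is a stalk iff its circularity (4*pi*A/P**2) is at least
    ``circularity_cutoff`` *and* its best-fit-ellipse aspect ratio is at
    most ``aspect_cutoff``; anything else is a lateral process.
    """
    mask = np.asarray(mask).astype(bool)
    props = regionprops(mask.astype(np.uint8))
    if not props or props[0].area < 2:
        raise ValueError("degenerate ROI: need at least 2 pixels to classify shape")
    p = props[0]
    circ = roi_circularity(mask)
    aspect = np.inf if p.axis_minor_length == 0 else p.axis_major_length / p.axis_minor_length
    if circ >= circularity_cutoff and aspect <= aspect_cutoff:
        return "stalk"
    return "lateral_process"


def grid_roi_masks(rows: int, cols: int, n_squares: int = 16) -> RoiMap:
    """Partition the field of view into ``n_squares`` congruent square ROIs.

    ``n_squares`` must be a perfect square and both dimensions divisible by
    its square root (e.g. a 256 x 256 field into 16 squares of 64 x 64).
    """
    k = int(round(np.sqrt(n_squares)))
    if k * k != n_squares:
        raise ValueError(f"n_squares={n_squares} is not a perfect square")
    if rows % k or cols % k:
        raise ValueError(f"field {rows}x{cols} not divisible into {k}x{k} squares")
    hr, hc = rows // k, cols // k
    labels = np.zeros((rows, cols), dtype=np.int32)
    rois = []
    rid = 1
    for i in range(k):
        for j in range(k):
            sl = (slice(i * hr, (i + 1) * hr), slice(j * hc, (j + 1) * hc))
            labels[sl] = rid
            mask = labels == rid
            # tiny squares can have a degenerate rasterised perimeter
            try:
                circ = roi_circularity(mask)
            except ValueError:
                circ = float("nan")
            rois.append(Roi(rid, np.argwhere(mask), "grid", circ))
            rid += 1
    return RoiMap(labels=labels, rois=rois)
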