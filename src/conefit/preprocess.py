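"""Normalisation, filtering, arithmetic and movement stabilisation.

These are the steps that surround the decomposition: per-pixel z-scoring
before PCA, baseline (fold-change) normalisation on the time-series branch,
spatial Gaussian smoothing for noisy recordings, a segment-respecting
temporal moving average, elementwise movie arithmetic (e.g. forming
excitation-ratio movies or subtracting controls), and integer-shift
alignment of concatenated recordings by cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FormatError
from .movie_io import MovieMatrix

__all__ = [
    "NormStats",
    "StimulusWindow",
    "zscore",
    "fold_change",
    "spatial_gauss",
    "gaussian_kernel",
    "temporal_filter",
    "image_arithmetic",
    "stabilise",
]


@dataclass
class NormStats:
    """Per-pixel mean/standard deviation used for z-scoring.

    ``sigma`` uses the sample (n-1) convention. Zero-variance pixels (dead
    camera pixels, masked regions) are flagged; their columns are zeroed
    rather than rejected so they can never win any later selection step.
    """

    mu: np.ndarray
    sigma: np.ndarray
    zero_variance: np.ndarray  # boolean mask over pixels

    def __post_init__(self) -> None:
        if np.any(self.sigma < 0):
            raise ValueError("sigma entries must be >= 0")


@dataclass
class StimulusWindow:
    """Pre-stimulus baseline interval for one recording segment.

    ``baseline`` is the half-open frame interval ``[a, b)`` *relative to the
    start of the segment*; ``stimulus_onset`` likewise. Requires
    ``0 <= a < b <= stimulus_onset``.
    """

    baseline: tuple[int, int]
    stimulus_onset: int
    segment: int = 0

    def __post_init__(self) -> None:
        a, b = self.baseline
        if not (0 <= a < b <= self.stimulus_onset):
            raise ValueError(
                f"invalid window: baseline [{a},{b}) must precede onset "
                f"{self.stimulus_onset}"
            )


def zscore(movie: MovieMatrix) -> tuple[MovieMatrix, NormStats]:
    """Z-score every pixel time series: subtract its mean, divide by its SD.

    Uses the sample (ddof=1) standard deviation. Output columns have mean 0
    and SD 1; constant columns become all-zero and are flagged in the
    returned :class:`NormStats`.
    """
    if movie.m < 2:
        raise ValueError("z-scoring needs at least 2 frames")
    mu = movie.data.mean(axis=0)
    sigma = movie.data.std(axis=0, ddof=1)
    zero = sigma == 0.0
    denom = np.where(zero, 1.0, sigma)
    out = (movie.data - mu) / denom
    out[:, zero] = 0.0
    return movie.with_data(out), NormStats(mu=mu, sigma=sigma, zero_variance=zero)


def fold_change(
    movie: MovieMatrix,
    windows: list[StimulusWindow],
    divide: bool = False,
) -> MovieMatrix:
    """Subtract (optionally divide by) the pre-stimulus baseline mean.

    For every segment that has a window, each pixel's mean over the baseline
    interval is subtracted from the whole segment, highlighting
    stimulus-evoked changes. With ``divide=True`` the result is additionally
    divided by the baseline mean (a dF/F variant); zero baselines then raise
    an error naming how many pixels are affected. Segments without a window
    pass through unchanged.
    """
    slices = movie.segment_slices()
    out = movie.data.copy()
    for win in windows:
        if not (0 <= win.segment < movie.n_segments):
            raise ValueError(f"window refers to segment {win.segment}, "
                             f"movie has {movie.n_segments}")
        seg = slices[win.segment]
        seg_len = seg.stop - seg.start
        a, b = win.baseline
        if b > seg_len or win.stimulus_onset > seg_len:
            raise ValueError(
                f"window [{a},{b}) / onset {win.stimulus_onset} outside "
                f"segment {win.segment} of length {seg_len}"
            )
        base = movie.data[seg.start + a : seg.start + b].mean(axis=0)
        out[seg] -= base
        if divide:
            zero = base == 0.0
            if np.any(zero):
                idx = np.flatnonzero(zero)
                raise ValueError(
                    f"zero baseline mean at {idx.size} pixel(s), "
                    f"first at pixel {idx[0]}"
                )
            out[seg] /= base
    return movie.with_data(out)


def gaussian_kernel(width: int) -> np.ndarray:
    """Normalised 2-D Gaussian on a ``width x width`` support, sigma=width/4."""
    if width < 1 or width % 2 == 0:
        raise ValueError(f"kernel width must be odd and >= 1, got {width}")
    sigma = width / 4.0
    ax = np.arange(width) - width // 2
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def spatial_gauss(movie: MovieMatrix, width: int) -> MovieMatrix:
    """Smooth every frame with a truncated Gaussian kernel (reflect-padded).

    The kernel has support ``width x width`` with sigma = width/4 and sums to
    one, so constant frames pass through unchanged.
    """
    kernel = gaussian_kernel(width)
    frames = movie.frames()
    # kernel extended with a singleton time axis: one call filters all frames
    out = ndimage.convolve(frames, kernel[None, :, :], mode="reflect")
    return movie.with_data(out.reshape(movie.m, movie.n))


def temporal_filter(movie: MovieMatrix, width: int) -> MovieMatrix:
    """Centred moving average along time, independently per segment.

    Edge frames use shrunken windows (the intersection of the centred window
    with the segment), so segment boundaries never bleed into each other.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError(f"width must be odd and >= 1, got {width}")
    shortest = min(s.stop - s.start for s in movie.segment_slices())
    if width > shortest:
        raise ValueError(
            f"width {width} exceeds shortest segment length {shortest}"
        )
    if width == 1:
        return movie.with_data(movie.data.copy())
    half = width // 2
    out = np.empty_like(movie.data)
    for seg in movie.segment_slices():
        block = movie.data[seg]
        L = block.shape[0]
        csum = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        lo = np.maximum(np.arange(L) - half, 0)
        hi = np.minimum(np.arange(L) + half + 1, L)
        out[seg] = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    return movie.with_data(out)


def image_arithmetic(a: MovieMatrix, b: MovieMatrix, op: str) -> MovieMatrix:
    """Elementwise add/subtract/ratio of two equally shaped movies.

    ``ratio`` is how dual-excitation recordings (e.g. 340 nm / 380 nm) are
    combined into the calcium-proportional signal.
    """
    if a.data.shape != b.data.shape or (a.height, a.width) != (b.height, b.width):
        raise FormatError(
            f"shape mismatch: {a.data.shape} ({a.height}x{a.width}) vs "
            f"{b.data.shape} ({b.height}x{b.width})"
        )
    if op == "add":
        return a.with_data(a.data + b.data)
    if op == "subtract":
        return a.with_data(a.data - b.data)
    if op == "ratio":
        zero = b.data == 0.0
        if np.any(zero):
            raise ValueError(
                f"ratio denominator is zero at {int(zero.sum())} entries"
            )
        return a.with_data(a.data / b.data)
    raise ValueError(f"unknown op {op!r}")


def stabilise(
    movie: MovieMatrix, search_radius: int = 10
) -> tuple[MovieMatrix, list[tuple[int, int]]]:
    """Align concatenated recordings to the first by integer translation.

    For each segment after the first, the mean frame is compared to the first
    segment's mean frame at every integer shift within ``search_radius``
    (exhaustive search); the shift maximising the normalised 2-D
    cross-correlation over the overlap wins (ties toward the smaller shift).
    The whole segment is then translated by that shift, with vacated border
    pixels filled from the segment's per-pixel temporal mean. Returns the
    aligned movie and one ``(dy, dx)`` per segment (first is ``(0, 0)``).
    """
    if search_radius >= min(movie.height, movie.width) / 2:
        raise ValueError(
            f"search radius {search_radius} too large for "
            f"{movie.height}x{movie.width} frames"
        )
    slices = movie.segment_slices()
    frames = movie.frames()
    ref = frames[slices[0]].mean(axis=0)
    out = movie.data.copy().reshape(movie.m, movie.height, movie.width)
    shifts: list[tuple[int, int]] = [(0, 0)]
    for seg in slices[1:]:
        mean_img = frames[seg].mean(axis=0)
        dy, dx = _best_shift(ref, mean_img, search_radius)
        shifts.append((dy, dx))
        if (dy, dx) != (0, 0):
            fill = mean_img  # per-pixel temporal mean of this segment
            out[seg] = _shift_frames(frames[seg], dy, dx, fill)
    aligned = movie.with_data(out.reshape(movie.m, movie.n))
    return aligned, shifts


def _best_shift(ref: np.ndarray, img: np.ndarray, radius: int) -> tuple[int, int]:
    """Exhaustive integer-shift search maximising Pearson correlation on overlap."""
    h, w = ref.shape
    best_score = -np.inf
    best_shift = (0, 0)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            # shifting img by (dy, dx): img[y-dy, x-dx] lands on (y, x)
            ys = slice(max(dy, 0), h + min(dy, 0))
            xs = slice(max(dx, 0), w + min(dx, 0))
            ys_src = slice(max(-dy, 0), h + min(-dy, 0))
            xs_src = slice(max(-dx, 0), w + min(-dx, 0))
            a = ref[ys, xs].ravel()
            b = img[ys_src, xs_src].ravel()
            a = a - a.mean()
            b = b - b.mean()
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            score = float(a @ b / denom) if denom > 0 else 0.0
            # ties (within fp noise) go to the smaller-magnitude shift
            if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12
                and (abs(dy) + abs(dx), dy, dx)
                < (abs(best_shift[0]) + abs(best_shift[1]), *best_shift)
            ):
                best_score = max(best_score, score)
                best_shift = (dy, dx)
    return best_shift


def _shift_frames(
    frames: np.ndarray, dy: int, dx: int, fill_img: np.ndarray
) -> np.ndarray:
    """Translate a frame stack by (dy, dx), filling vacated pixels from fill_img."""
    m, h, w = frames.shape
    out = np.empty_like(frames)
    out[:] = fill_img[None, :, :]
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[:, ys, xs] = frames[:, ys_src, xs_src]
    return out
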