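"""Movie and label-map containers plus file I/O.

An imaging movie is held as an ``m x n`` matrix: one row per frame, one
column per pixel time series. Frames are flattened **row-major** with pixel
index ``p = row * width + col`` (0-based); every spatial map produced by the
package uses the same convention, so images and matrices can be reshaped
back and forth without transposition surprises.

Movies may be concatenations of several recordings from the same animal;
``segment_bounds`` keeps the frame ranges of the constituent recordings so
that time-local operations (baseline normalisation, temporal filtering,
movement stabilisation) can respect recording boundaries.

Supported on-disk formats are multi-page grayscale TIFF (8/16-bit integer
or 32-bit float) and plain delimited text; time series and label maps are
written as CSV, label maps additionally as integer TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

from .errors import FormatError

__all__ = [
    "MovieMatrix",
    "LabelMap",
    "read_movie",
    "write_movie",
    "concat_movies",
    "write_timeseries",
    "read_timeseries",
    "write_label_map",
    "read_label_map",
]


@dataclass
class MovieMatrix:
    """An imaging movie as an ``m x n`` matrix plus its image geometry.

    Parameters
    ----------
    data:
        ``(m, n)`` float array; row ``t`` is frame ``t`` flattened row-major.
    height, width:
        Image geometry; ``n == height * width``.
    segment_bounds:
        Strictly increasing frame indices partitioning ``[0, m)`` into
        concatenated recordings. Defaults to the single segment ``[0, m]``.
    frame_rate_hz:
        Optional acquisition rate (honeybee recordings are typically 4-5 Hz).
    """

    data: np.ndarray
    height: int
    width: int
    segment_bounds: list[int] = field(default=None)  # type: ignore[assignment]
    frame_rate_hz: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError(f"movie data must be 2-D, got shape {self.data.shape}")
        m, n = self.data.shape
        if n != self.height * self.width:
            raise FormatError(
                f"n={n} pixels inconsistent with geometry {self.height}x{self.width}"
            )
        if not np.all(np.isfinite(self.data)):
            bad = int(np.count_nonzero(~np.isfinite(self.data)))
            raise FormatError(f"movie contains {bad} non-finite entries")
        if self.segment_bounds is None:
            self.segment_bounds = [0, m]
        self.segment_bounds = [int(b) for b in self.segment_bounds]
        sb = self.segment_bounds
        if sb[0] != 0 or sb[-1] != m or any(a >= b for a, b in zip(sb, sb[1:])):
            raise FormatError(f"invalid segment_bounds {sb} for m={m}")
        if self.frame_rate_hz is not None and self.frame_rate_hz <= 0:
            raise FormatError("frame_rate_hz must be positive")

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @property
    def n_segments(self) -> int:
        return len(self.segment_bounds) - 1

    def frames(self) -> np.ndarray:
        """View of the movie as an ``(m, height, width)`` stack."""
        return self.data.reshape(self.m, self.height, self.width)

    def segment_slices(self) -> list[slice]:
        sb = self.segment_bounds
        return [slice(a, b) for a, b in zip(sb, sb[1:])]

    @classmethod
    def from_frames(
        cls,
        frames: np.ndarray,
        segment_bounds: Sequence[int] | None = None,
        frame_rate_hz: float | None = None,
    ) -> "MovieMatrix":
        frames = np.asarray(frames)
        if frames.ndim != 3:
            raise FormatError("expected an (m, h, w) frame stack")
        m, h, w = frames.shape
        return cls(
            frames.reshape(m, h * w).astype(np.float64),
            height=h,
            width=w,
            segment_bounds=list(segment_bounds) if segment_bounds is not None else None,
            frame_rate_hz=frame_rate_hz,
        )

    def with_data(self, data: np.ndarray) -> "MovieMatrix":
        """Copy of this movie carrying new pixel data, same geometry/segments."""
        return MovieMatrix(
            data,
            height=self.height,
            width=self.width,
            segment_bounds=list(self.segment_bounds),
            frame_rate_hz=self.frame_rate_hz,
        )


@dataclass
class LabelMap:
    """Integer image assigning each pixel to a cluster; 0 means unassigned."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label map must be a 2-D integer image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("label map must have an integer dtype")
        if self.labels.min(initial=0) < 0:
            raise FormatError("labels must be >= 0")
        self.labels = self.labels.astype(np.int32)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))


def flatten_index(row: int, col: int, width: int) -> int:
    """Pixel index of ``(row, col)`` under the package-wide row-major convention."""
    return row * width + col


def unflatten_index(p: int, width: int) -> tuple[int, int]:
    return divmod(p, width)


def read_movie(path: str | Path, layout: str = "tiff_stack") -> MovieMatrix:
    """Read a movie from a multi-page TIFF or a delimited text matrix.

    ``delimited_matrix`` files start with a header line ``height,width``
    followed by one comma-separated row of ``height*width`` values per frame.
    Non-finite values are rejected rather than imputed, so upstream
    corruption stays visible.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if layout == "tiff_stack":
        with tifffile.TiffFile(path) as tif:
            pages = []
            shape0 = None
            for i, page in enumerate(tif.pages):
                arr = page.asarray()
                if arr.ndim != 2:
                    raise FormatError(f"page {i} of {path} is not a grayscale image")
                if shape0 is None:
                    shape0 = arr.shape
                elif arr.shape != shape0:
                    raise FormatError(
                        f"page {i} of {path} has shape {arr.shape}, "
                        f"expected {shape0} as on page 0"
                    )
                pages.append(arr)
        if not pages:
            raise FormatError(f"{path} contains no image pages")
        return MovieMatrix.from_frames(np.stack(pages))
    if layout == "delimited_matrix":
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            try:
                h, w = (int(tok) for tok in header.replace(",", " ").split())
            except ValueError as exc:
                raise FormatError(
                    f"{path}: header line must give 'height,width', got {header!r}"
                ) from exc
            try:
                data = np.loadtxt(fh, delimiter=",", ndmin=2)
            except ValueError as exc:
                raise FormatError(f"{path}: malformed data line ({exc})") from exc
        return MovieMatrix(data, height=h, width=w)
    raise ValueError(f"unknown layout {layout!r}")


def write_movie(movie: MovieMatrix, path: str | Path, layout: str = "tiff_stack") -> None:
    """Write a movie as a multi-page float32 TIFF or a delimited text matrix."""
    path = Path(path)
    if layout == "tiff_stack":
        tifffile.imwrite(path, movie.frames().astype(np.float32), photometric="minisblack")
    elif layout == "delimited_matrix":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{movie.height},{movie.width}\n")
            np.savetxt(fh, movie.data, delimiter=",", fmt="%.17g")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def concat_movies(movies: Sequence[MovieMatrix]) -> MovieMatrix:
    """Stack recordings from the same preparation into one movie.

    Each input contributes its frame range to ``segment_bounds`` (inputs that
    are themselves concatenations keep their internal boundaries).
    """
    if not movies:
        raise ValueError("need at least one movie")
    h, w = movies[0].height, movies[0].width
    for i, mv in enumerate(movies):
        if (mv.height, mv.width) != (h, w):
            raise FormatError(
                f"movie {i} geometry {mv.height}x{mv.width} != {h}x{w}"
            )
    data = np.vstack([mv.data for mv in movies])
    bounds = [0]
    for mv in movies:
        offset = bounds[-1]
        bounds.extend(offset + b for b in mv.segment_bounds[1:])
    return MovieMatrix(
        data,
        height=h,
        width=w,
        segment_bounds=bounds,
        frame_rate_hz=movies[0].frame_rate_hz,
    )


def write_timeseries(
    T: np.ndarray, path: str | Path, names: Sequence[str] | None = None
) -> None:
    """Write an ``m x c`` time-series matrix as CSV, one column per signal."""
    T = np.asarray(T, dtype=np.float64)
    if T.ndim != 2:
        raise FormatError("time-series matrix must be 2-D")
    if T.size and not np.all(np.isfinite(T)):
        raise FormatError("time-series matrix contains non-finite entries")
    c = T.shape[1]
    if names is None:
        names = [f"signal_{i}" for i in range(c)]
    if len(names) != c:
        raise FormatError("one name per column required")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(names) + "\n")
        if c:
            for row in T:
                fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a CSV written by :func:`write_timeseries`; returns (matrix, names)."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        names = header.split(",") if header else []
        rows = [line.rstrip("\n") for line in fh if line.strip() != ""]
    c = len(names)
    if c == 0:
        return np.empty((len(rows), 0)), []
    data = np.array(
        [[float(tok) for tok in row.split(",")] for row in rows], dtype=np.float64
    )
    if rows and data.shape[1] != c:
        raise FormatError(f"{path}: row width {data.shape[1]} != header width {c}")
    if not rows:
        data = np.empty((0, c))
    return data, names


def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    """Write a label map; format chosen by extension (.tif/.tiff or .csv)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, label_map.labels.astype(np.int32), photometric="minisblack")
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, label_map.labels, delimiter=",", fmt="%d")
    else:
        raise ValueError(f"unsupported label-map extension: {path.suffix}")


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return LabelMap(np.asarray(tifffile.imread(path)).astype(np.int32))
    if path.suffix.lower() == ".csv":
        return LabelMap(np.loadtxt(path, delimiter=",", ndmin=2).astype(np.int32))
    raise ValueError(f"unsupported label-map extension: {path.suffix}")
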