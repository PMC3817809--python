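"""Artificial imaging movies with known ground truth.

The generator emulates the benchmark used to validate the extraction
pipeline: 16 known source time series are assigned to circular, spatially
contiguous and partially overlapping pixel clusters laid out on a grid; in
regions of overlap the signals add; i.i.d. Gaussian pixel noise of standard
deviation ``sigma_noise`` is superimposed. Two source flavours are
available, mirroring the two kinds of recordings made from a living bee:

``odours``
    stimulus-locked double-exponential response transients with shared onset
    frames (each source responds to a random subset of the stimuli, with
    per-onset amplitudes in [0.5, 1.5] and a per-source decay constant in
    [5, 20] frames) on top of a small AR(1) background — high peak
    amplitudes right after stimulation;
``idle``
    smoothed AR(1) spontaneous background activity only — lower amplitudes.

Each source column is standardised to mean 0, SD 1 and then shifted by its
minimum so it is entirely non-negative. Sources are distinct but not
perfectly uncorrelated; pairwise |Pearson rho| < 0.5 is enforced by
rejection sampling. All randomness flows from a single seed through
``numpy.random.SeedSequence`` children (sources, geometry jitter, noise), so
identical specs give bit-identical movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .movie_io import LabelMap, MovieMatrix

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_sources", "generate_movie"]

MAX_REJECTION_TRIES = 200
_RHO_LIMIT = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one artificial dataset.

    Defaults implant 16 sources on a 4x4 grid of discs of radius 9 px in a
    60x60 image over 400 frames; adjacent discs overlap (centre spacing
    ~13.7 px < 2r), putting roughly 15% of in-disc pixels into overlap
    zones. Set ``cluster_radius`` at or below half the centre spacing (e.g.
    6) for non-overlapping clusters.
    """

    n_sources: int = 16
    m: int = 400
    height: int = 60
    width: int = 60
    cluster_radius: float = 9.0
    sigma_noise: float = 0.3
    source_kind: str = "odours"
    seed: int = 0
    stimulus_onsets: tuple[int, ...] | None = None
    centres: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_sources < 2:
            raise ValueError("need at least 2 sources")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.source_kind not in ("odours", "idle"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        if self.m < 16:
            raise ValueError("need at least 16 frames")

    def onsets(self) -> tuple[int, ...]:
        """Shared stimulus onset frames (8 evenly spaced stimuli by default)."""
        if self.stimulus_onsets is not None:
            return self.stimulus_onsets
        step = max(self.m // 8, 4)
        return tuple(step // 2 + i * step for i in range(8) if step // 2 + i * step < self.m)

    def grid_centres(self) -> list[tuple[int, int]]:
        """Disc centres: an approximately square grid with margin = radius."""
        if self.centres is not None:
            return list(self.centres)
        g = int(np.ceil(np.sqrt(self.n_sources)))
        r = self.cluster_radius
        if 2 * r >= min(self.height, self.width):
            raise ValueError("cluster_radius too large for the image")
        ys = np.round(np.linspace(r, self.height - 1 - r, g)).astype(int)
        xs = np.round(np.linspace(r, self.width - 1 - r, g)).astype(int)
        centres = [(int(y), int(x)) for y in ys for x in xs]
        return centres[: self.n_sources]


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated movie.

    ``U`` (m x n_sources) holds the implanted source time series; ``masks``
    the pixel-index set of each source's disc; ``membership`` a boolean
    (n_sources x n) matrix (a pixel may belong to several overlapping
    discs); ``noise`` the realised noise field, so
    ``movie.data - noise == U-weighted mask sum`` exactly.
    """

    U: np.ndarray
    masks: list[np.ndarray]
    membership: np.ndarray
    noise: np.ndarray
    spec: SyntheticSpec

    @property
    def n_sources(self) -> int:
        return self.U.shape[1]

    def overlap_pixels(self) -> np.ndarray:
        """Pixels belonging to two or more sources."""
        return np.flatnonzero(self.membership.sum(axis=0) >= 2)

    def pure_pixels(self, j: int) -> np.ndarray:
        """Pixels belonging to source j and to no other source."""
        only_j = self.membership[j] & (self.membership.sum(axis=0) == 1)
        return np.flatnonzero(only_j)

    def label_map(self) -> LabelMap:
        """Ground-truth map: pure pixels labelled 1..n_sources, others 0."""
        counts = self.membership.sum(axis=0)
        labels = np.zeros(self.membership.shape[1], dtype=np.int32)
        for j in range(self.n_sources):
            pure = self.membership[j] & (counts == 1)
            labels[pure] = j + 1
        return LabelMap(labels.reshape(self.spec.height, self.spec.width))


def _standardise_shift(u: np.ndarray) -> np.ndarray:
    u = (u - u.mean()) / u.std(ddof=1)
    return u - u.min()


def _odour_source(
    rng: np.random.Generator, m: int, onsets: Sequence[int]
) -> np.ndarray:
    """One odour-response source: transients at a random onset subset plus a
    small individual AR(1) background."""
    tau_r = 2.0
    tau_d = float(rng.uniform(5.0, 20.0))
    participate = rng.random(len(onsets)) < 0.35
    if not participate.any():
        participate[rng.integers(len(onsets))] = True
    amps = rng.uniform(0.5, 1.5, size=len(onsets))
    t = np.arange(m, dtype=float)
    u = np.zeros(m)
    for onset, on, amp in zip(onsets, participate, amps):
        if not on:
            continue
        dt = t - onset
        shape = np.where(dt >= 0, np.exp(-dt / tau_d) - np.exp(-dt / tau_r), 0.0)
        peak = shape.max()
        if peak > 0:
            u += amp * shape / peak
    u += 0.05 * _ar1(rng, m, phi=0.8)
    return u


def _idle_source(rng: np.random.Generator, m: int) -> np.ndarray:
    """Spontaneous-activity source: smoothed AR(1) background fluctuations."""
    u = _ar1(rng, m, phi=0.9)
    kernel = np.ones(5) / 5.0
    return np.convolve(u, kernel, mode="same")


def _ar1(rng: np.random.Generator, m: int, phi: float) -> np.ndarray:
    eps = rng.standard_normal(m)
    u = np.empty(m)
    u[0] = eps[0] / np.sqrt(1 - phi**2)
    for i in range(1, m):
        u[i] = phi * u[i - 1] + eps[i]
    return u


def generate_sources(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Generate the ``m x n_sources`` ground-truth source matrix U.

    Each column has mean 0 and sample SD 1 before the non-negativity shift
    and minimum exactly 0 after it. Pairwise |Pearson rho| < 0.5 between
    accepted sources is enforced by rejection; if a source cannot be placed
    within the retry budget an error suggests increasing ``m``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    onsets = spec.onsets()
    cols: list[np.ndarray] = []
    centred: list[np.ndarray] = []
    for j in range(spec.n_sources):
        for _ in range(MAX_REJECTION_TRIES):
            raw = (
                _odour_source(rng, spec.m, onsets)
                if spec.source_kind == "odours"
                else _idle_source(rng, spec.m)
            )
            cand = raw - raw.mean()
            cand /= np.linalg.norm(cand)
            if all(abs(float(cand @ prev)) < _RHO_LIMIT for prev in centred):
                centred.append(cand)
                cols.append(_standardise_shift(raw))
                break
        else:
            raise RuntimeError(
                f"could not generate source {j} with pairwise |rho| < "
                f"{_RHO_LIMIT} after {MAX_REJECTION_TRIES} tries; "
                "try more frames (larger m)"
            )
    return np.column_stack(cols)


def _disc_mask(
    centre: tuple[int, int], radius: float, height: int, width: int
) -> np.ndarray:
    cy, cx = centre
    yy, xx = np.mgrid[0:height, 0:width]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 < radius**2
    return np.flatnonzero(inside.ravel())


def generate_movie(spec: SyntheticSpec) -> tuple[MovieMatrix, SyntheticTruth]:
    """Generate an artificial movie and its ground truth.

    A pixel inside a single disc carries that source's time series exactly;
    a pixel inside several discs carries their sum (additive mixing); all
    pixels receive i.i.d. Gaussian noise with SD ``sigma_noise``. Every
    source is guaranteed at least one pure pixel (a pixel it alone covers),
    matching the model assumption that pure sources are observable.
    """
    ss = np.random.SeedSequence(spec.seed)
    src_seq, noise_seq = ss.spawn(2)
    U = generate_sources(spec, np.random.default_rng(src_seq))

    n = spec.height * spec.width
    centres = spec.grid_centres()
    if len(centres) < spec.n_sources:
        raise ValueError("not enough grid positions for the requested sources")
    membership = np.zeros((spec.n_sources, n), dtype=bool)
    masks: list[np.ndarray] = []
    for j in range(spec.n_sources):
        mask = _disc_mask(centres[j], spec.cluster_radius, spec.height, spec.width)
        if mask.size == 0:
            raise ValueError(f"cluster {j} has no pixels inside the image")
        masks.append(mask)
        membership[j, mask] = True
    counts = membership.sum(axis=0)
    for j in range(spec.n_sources):
        if not np.any(membership[j] & (counts == 1)):
            raise ValueError(
                f"source {j} has no pure pixel; reduce cluster_radius or "
                "spread the centres"
            )

    clean = U @ membership.astype(np.float64)
    noise = np.random.default_rng(noise_seq).normal(
        0.0, spec.sigma_noise, size=(spec.m, n)
    ) if spec.sigma_noise > 0 else np.zeros((spec.m, n))
    movie = MovieMatrix(clean + noise, height=spec.height, width=spec.width)
    truth = SyntheticTruth(
        U=U, masks=masks, membership=membership, noise=noise, spec=spec
    )
    return movie, truth


def with_noise(spec: SyntheticSpec, sigma: float) -> SyntheticSpec:
    """Copy of a spec at a different noise level (same seed and geometry)."""
    return replace(spec, sigma_noise=sigma)
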