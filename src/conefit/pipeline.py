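"""End-to-end pipelines combining preprocessing and decomposition.

Two branches mirror the typical workflow on concatenated recordings:

* the **map branch** — stabilise -> (optional spatial filter) -> z-score ->
  PCA -> cone fitting -> refinement -> induced clustering — yields the
  glomerular map and the refined spatial coefficient maps;
* the **time-series branch** — stabilise -> fold change -> back-projection
  onto the refined maps — yields full-length, baseline-normalised signal
  time series for the same spatial maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decomposition import (
    FactorModel,
    PCAModel,
    RefinedModel,
    back_project,
    cone_fitting,
    induced_clustering,
    low_rank_movie,
    pca,
    refine,
)
from .movie_io import LabelMap, MovieMatrix
from .preprocess import NormStats, StimulusWindow, fold_change, spatial_gauss, stabilise, zscore

__all__ = ["ExtractionResult", "extract_sources", "timeseries_branch"]


@dataclass
class ExtractionResult:
    """Everything the map branch produces, from PCA model to label map."""

    pca: PCAModel
    factors: FactorModel
    refined: RefinedModel
    label_map: LabelMap
    norm: NormStats
    shifts: list[tuple[int, int]] | None = None


def extract_sources(
    movie: MovieMatrix,
    k: int = 50,
    c: int = 50,
    seed: int = 0,
    min_similarity: float = 0.5,
    min_members: int = 2,
    sampling_fraction: float = 1.0,
    spatial_width: int | None = None,
    stabilise_first: bool = False,
    search_radius: int = 10,
) -> ExtractionResult:
    """Run the map branch on a movie and return all intermediate models.

    ``k``/``c`` default to 50, suitable for antennal-lobe recordings where
    20-40 glomeruli are visible; both are clamped to the movie dimensions.
    Cone fitting runs on the PCA-reduced representation; refinement and the
    induced clustering use the full-length z-scored movie. Since ``c`` is
    deliberately chosen above the expected source count, surplus basis
    signals that attract only themselves are pruned (``min_members=2``);
    pass ``min_members=1`` to keep every nonempty cluster.
    """
    shifts = None
    if stabilise_first:
        movie, shifts = stabilise(movie, search_radius=search_radius)
    if spatial_width is not None:
        movie = spatial_gauss(movie, spatial_width)
    z, stats = zscore(movie)
    k_eff = min(k, z.m, z.n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # rank truncation is fine here
        pca_model = pca(z, k=k_eff, sampling_fraction=sampling_fraction, seed=seed)
        factors = cone_fitting(pca_model.reduced(), c=min(c, z.n), seed=seed)
    refined = refine(z, factors, min_similarity=min_similarity, min_members=min_members)
    label_map = induced_clustering(refined.S_hat, (movie.height, movie.width))
    return ExtractionResult(
        pca=pca_model,
        factors=factors,
        refined=refined,
        label_map=label_map,
        norm=stats,
        shifts=shifts,
    )


def timeseries_branch(
    movie: MovieMatrix,
    refined: RefinedModel,
    windows: list[StimulusWindow] | None = None,
    divide: bool = False,
) -> np.ndarray:
    """Full-length time series for refined maps on a baseline-normalised movie.

    Applies fold-change normalisation (if windows are given) to the raw
    movie and back-projects it onto the refined spatial maps, solving
    ``min_T ||A - T Ŝ||_F``. Returns the m x c' time-series matrix.
    """
    if windows:
        movie = fold_change(movie, windows, divide=divide)
    return back_project(movie, refined.S_hat)


def reconstruct(refined: RefinedModel) -> MovieMatrix:
    """Denoised low-rank movie from refined factors (thin alias)."""
    return low_rank_movie(refined)
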