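"""The computational core: PCA reduction, convex-cone column selection,
signal refinement, induced clustering, back-projection and low-rank movies.

The underlying model is a non-negative mixture: the movie matrix ``A``
(frames x pixels) is assumed to satisfy ``A = T S + N`` where the columns of
``T`` are *pure* source time series actually present in ``A`` (pixels at the
centres of glomeruli), ``S`` is non-negative (pixels at glomerulus fringes
are additive mixtures of neighbouring sources), and ``N`` is noise. The pure
sources are then the extreme vectors of the convex cone containing the data,
and a greedy forward selection with non-negative downdating (cone fitting)
recovers them. PCA is used first to reduce the time dimension; refinement
afterwards averages out the residual noise and discards mixed pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np

from .errors import ConvergenceError, FormatError
from .movie_io import LabelMap, MovieMatrix, write_timeseries

__all__ = [
    "PCAModel",
    "FactorModel",
    "RefinedModel",
    "pca",
    "cone_fitting",
    "nested_prefix_check",
    "refine",
    "induced_clustering",
    "back_project",
    "low_rank_movie",
    "save_factor_model",
    "save_refined_model",
]


@dataclass
class PCAModel:
    """Top-k principal components of a movie.

    ``components`` holds the k principal-component *images* (k x n,
    orthonormal rows); ``loadings`` the corresponding time courses (m x k,
    orthogonal columns whose norms are the singular values); ``eigenvalues``
    the variances ``sigma_r^2 / (m - 1)``, nonincreasing.
    """

    components: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    k: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be nonincreasing")

    @property
    def m(self) -> int:
        return self.loadings.shape[0]

    @property
    def n(self) -> int:
        return self.components.shape[1]

    def reduced(self) -> np.ndarray:
        """The k x n reduced pixel representation used for cone fitting.

        Row r is the r-th component image scaled by its singular value, i.e.
        the coordinates of every pixel time series in the orthonormal basis
        of the top-k time courses. Column geometry (norms, inner products of
        the projected data) is preserved exactly.
        """
        sigma = np.sqrt(self.eigenvalues * (self.m - 1))
        return sigma[:, None] * self.components


@dataclass
class FactorModel:
    """Result of cone fitting: selected basis time series and non-negative maps.

    ``T`` (m' x c) holds the selected columns of the *original* input matrix,
    unit-normalised; ``S`` (c x n) the accumulated non-negative coefficient
    rows; ``source_pixels`` the pixel index each basis column was selected
    from, in selection ``order``.
    """

    T: np.ndarray
    S: np.ndarray
    order: list[int]
    source_pixels: list[int]
    init_seed: int

    def __post_init__(self) -> None:
        if self.T.shape[1] != self.S.shape[0]:
            raise FormatError("T and S disagree on the number of components")
        norms = np.linalg.norm(self.T, axis=0)
        if self.T.size and np.any(np.abs(norms - 1.0) > 1e-10):
            raise ValueError("columns of T must be unit-norm")
        if np.any(self.S < 0):
            raise ValueError("S must be non-negative")
        if len(set(self.source_pixels)) != len(self.source_pixels):
            raise ValueError("source pixels must be distinct")

    @property
    def c(self) -> int:
        return self.T.shape[1]


@dataclass
class RefinedModel:
    """Refined signals and disjoint-support maps after postprocessing.

    ``T_hat`` (m x c') holds the averaged (refined) source signals; ``S_hat``
    (c' x n) their spatial coefficient maps with pairwise disjoint supports;
    ``members[r]`` the pixels averaged into signal r; ``unassigned`` the
    "white" pixels that were not close enough to any pure source (mixed or
    background pixels). ``kept`` maps each refined signal back to the index
    of the basis signal it refines.
    """

    T_hat: np.ndarray
    S_hat: np.ndarray
    members: list[np.ndarray]
    unassigned: np.ndarray
    kept: list[int]
    height: int
    width: int
    segment_bounds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        supports = [np.flatnonzero(row) for row in self.S_hat]
        seen: set[int] = set()
        for sup in supports:
            if seen.intersection(sup.tolist()):
                raise ValueError("S_hat rows must have disjoint supports")
            seen.update(sup.tolist())
        for r, mem in enumerate(self.members):
            if mem.size == 0:
                raise ValueError(f"refined signal {r} has no member pixels")

    @property
    def c(self) -> int:
        return self.T_hat.shape[1]


def _as_matrix(A) -> np.ndarray:
    return A.data if isinstance(A, MovieMatrix) else np.asarray(A, dtype=np.float64)


def pca(
    movie,
    k: int,
    sampling_fraction: float = 1.0,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 50_000,
) -> PCAModel:
    """Top-k PCA of a (z-scored) movie by iterative deflation.

    Components are extracted one at a time by power iteration on the Gram
    matrix of the smaller movie dimension, deflating after each converged
    component — the same fixed point as NIPALS (one NIPALS sweep is one
    multiplication by ``A Aᵀ``), but with the per-iteration cost independent
    of the larger dimension. If the matrix turns out to have numerical rank
    ``< k``, the model is truncated to the rank with a warning.

    With ``sampling_fraction < 1``, components are first estimated on a
    uniformly sampled pixel subset (without replacement, seeded by ``seed``)
    and then extended to all pixels by projecting the full matrix onto the
    estimated time-course subspace. ``sampling_fraction == 1`` takes the
    exact path; the seed then has no effect.

    The caller is expected to have centred or z-scored the movie; the
    function operates on the matrix as given.
    """
    A = _as_matrix(movie)
    m, n = A.shape
    if not (1 <= k <= min(m, n)):
        raise ValueError(f"k={k} outside [1, min(m,n)={min(m, n)}]")
    if not (0.0 < sampling_fraction <= 1.0):
        raise ValueError("sampling_fraction must be in (0, 1]")

    if sampling_fraction < 1.0:
        rng = np.random.default_rng(seed)
        n_s = max(k, int(np.ceil(sampling_fraction * n)))
        idx = np.sort(rng.choice(n, size=n_s, replace=False))
        t_hat, _ = _power_deflate(A[:, idx], k, tol, max_iter, axis=0)
        # extend to all pixels: project A onto the sampled time-course
        # subspace, then re-diagonalise the small k x n projection
        B = t_hat.T @ A
        _, sb, Vtb = np.linalg.svd(B, full_matrices=False)
        components = Vtb[:k]
        loadings = A @ components.T
        components, loadings = _fix_signs(components, loadings)
        sigma = np.linalg.norm(loadings, axis=0)
        order = np.argsort(-sigma, kind="stable")
        components, loadings, sigma = components[order], loadings[:, order], sigma[order]
        return PCAModel(components, loadings, sigma**2 / (m - 1), k=components.shape[0])

    if m <= n:
        t_hat, lam = _power_deflate(A, k, tol, max_iter, axis=0)
        k_eff = t_hat.shape[1]
        sigma = np.sqrt(lam)
        components = (t_hat.T @ A) / sigma[:, None]
        components, _ = _fix_signs(components, t_hat * sigma)
        loadings = A @ components.T
    else:
        v_hat, lam = _power_deflate(A, k, tol, max_iter, axis=1)
        k_eff = v_hat.shape[1]
        sigma = np.sqrt(lam)
        components, _ = _fix_signs(v_hat.T, A @ v_hat)
        loadings = A @ components.T
    if k_eff < k:
        warnings.warn(
            f"matrix has numerical rank {k_eff} < k={k}; "
            f"returning {k_eff} components",
            RuntimeWarning,
        )
    return PCAModel(components, loadings, sigma**2 / (m - 1), k=k_eff)


def _fix_signs(components: np.ndarray, loadings: np.ndarray):
    """Orient each component so its largest-|entry| is positive (determinism)."""
    comps = components.copy()
    loads = loadings.copy()
    for r in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[r])))
        if comps[r, j] < 0:
            comps[r] = -comps[r]
            loads[:, r] = -loads[:, r]
    return comps, loads


def _power_deflate(
    A: np.ndarray, k: int, tol: float, max_iter: int, axis: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deflated power iteration on the Gram matrix along ``axis``.

    axis=0: iterate on G = A Aᵀ (returns orthonormal time courses, m x k').
    axis=1: iterate on G = Aᵀ A (returns orthonormal pixel vectors, n x k').
    Returns (eigenvectors, Gram eigenvalues = squared singular values),
    truncated at the numerical rank.
    """
    G = A @ A.T if axis == 0 else A.T @ A
    G = np.ascontiguousarray(G)
    d = G.shape[0]
    k = min(k, d)
    rank_tol = max(np.trace(G), 1.0) * 1e-13
    vecs: list[np.ndarray] = []
    vals: list[float] = []
    for r in range(k):
        if np.trace(G) <= rank_tol:
            break
        t = G[:, int(np.argmax(np.linalg.norm(G, axis=0)))].copy()
        nt = np.linalg.norm(t)
        if nt <= rank_tol:
            break
        t /= nt
        lam = 0.0
        delta = np.inf
        for _ in range(max_iter):
            t_new = G @ t
            lam = float(np.linalg.norm(t_new))
            if lam <= rank_tol:
                break
            t_new /= lam
            delta = min(
                float(np.linalg.norm(t_new - t)), float(np.linalg.norm(t_new + t))
            )
            t = t_new
            if delta <= tol:
                break
        else:
            raise ConvergenceError(
                f"component {r} did not converge in {max_iter} iterations "
                f"(achieved tolerance {delta:.3e}, requested {tol:.3e})"
            )
        if lam <= rank_tol:
            break
        # polish orthogonality against previously extracted eigenvectors
        for prev in vecs:
            t -= (prev @ t) * prev
        nt = np.linalg.norm(t)
        if nt <= np.sqrt(rank_tol):
            break
        t /= nt
        lam = float(t @ G @ t)
        if lam <= rank_tol:
            break
        vecs.append(t)
        vals.append(lam)
        G -= lam * np.outer(t, t)
    if not vecs:
        raise ValueError("matrix is numerically zero; no components to extract")
    return np.column_stack(vecs), np.asarray(vals)


def cone_fitting(A, c: int, seed: int = 0) -> FactorModel:
    """Greedy selection of extreme-vector columns with non-negative downdating.

    Runs ``c`` iterations on the (typically PCA-reduced) matrix ``A``. At
    iteration r the current column ``p`` of the residual is unit-normalised
    into ``t``; its non-negative spatial mapping ``s0+ = max(Aᵣᵀ t, 0)`` is
    recorded, and the residual is downdated by ``t s0+ᵀ`` — removing the
    chosen column and everything explainable by conic combination with it.
    The next column is the residual column of largest Euclidean norm (ties
    toward the smallest index). The first column is chosen as the one at
    maximal Euclidean distance from a uniformly drawn random column (seeded),
    a hull point that avoids starting from a mixed-signal column.

    ``T`` stores the *original* selected columns unit-normalised; ``S`` the
    accumulated ``s0+`` rows. If the residual becomes numerically zero before
    ``c`` columns are found, the model is returned early with a warning.
    """
    A = _as_matrix(A)
    m, n = A.shape
    if not (1 <= c <= n):
        raise ValueError(f"c={c} outside [1, n={n}]")
    norm0 = np.linalg.norm(A)
    if norm0 == 0.0:
        raise ValueError("A has no nonzero column")
    zero_tol = 1e-12 * max(1.0, norm0)

    rng = np.random.default_rng(seed)
    j0 = int(rng.integers(n))
    dist = np.linalg.norm(A - A[:, [j0]], axis=0)
    p = int(np.argmax(dist))  # argmax returns the smallest index on ties

    R = A.copy()
    T_cols: list[np.ndarray] = []
    S_rows: list[np.ndarray] = []
    source_pixels: list[int] = []
    for r in range(c):
        col = R[:, p]
        cn = np.linalg.norm(col)
        if cn <= zero_tol:
            warnings.warn(
                f"residual numerically zero after {r} of {c} components; "
                "returning the components found",
                RuntimeWarning,
            )
            break
        t = col / cn
        s = R.T @ t
        s0 = np.maximum(s, 0.0)
        T_cols.append(A[:, p] / np.linalg.norm(A[:, p]))
        S_rows.append(s0)
        source_pixels.append(p)
        R -= np.outer(t, s0)
        col_norms = np.linalg.norm(R, axis=0)
        if col_norms.max() <= zero_tol and r + 1 < c:
            warnings.warn(
                f"residual numerically zero after {r + 1} of {c} components; "
                "returning the components found",
                RuntimeWarning,
            )
            break
        p = int(np.argmax(col_norms))
    return FactorModel(
        T=np.column_stack(T_cols),
        S=np.vstack(S_rows),
        order=list(range(len(T_cols))),
        source_pixels=source_pixels,
        init_seed=seed,
    )


def nested_prefix_check(model_c1: FactorModel, model_c2: FactorModel) -> bool:
    """True iff the smaller model is an exact selection prefix of the larger.

    Cone fitting with a fixed starting point returns nested bases: the r-th
    selected column does not depend on the total number requested. Both
    models must come from the same matrix and seed.
    """
    if model_c1.init_seed != model_c2.init_seed:
        raise ValueError("models were fitted with different seeds")
    small, big = sorted((model_c1, model_c2), key=lambda mdl: mdl.c)
    c1 = small.c
    return (
        small.source_pixels == big.source_pixels[:c1]
        and small.order == big.order[:c1]
    )


def refine(
    A_full: MovieMatrix,
    model: FactorModel,
    assign_metric: str = "cosine",
    min_similarity: float = 0.5,
    min_members: int = 1,
) -> RefinedModel:
    """Average out residual noise and discard mixed pixels.

    Each pixel time series is compared (cosine similarity in the full time
    domain) with every selected pure-source time series, i.e. the full-length
    movie columns at the selected source pixels. A pixel joins the closest
    source provided the similarity reaches ``min_similarity``; otherwise it
    stays unassigned ("white") — this is what excludes additive mixtures at
    glomerulus fringes and background pixels. The refined signal ``t̂ᵣ`` is
    the mean time series over the members of source r, and row r of ``Ŝ``
    holds each member pixel's least-squares coefficient on ``t̂ᵣ`` (zero
    elsewhere), giving pairwise disjoint supports. Sources that attract no
    members are dropped; with ``min_members > 1``, clusters smaller than
    that are also dropped (a refined signal is an average — a cluster of one
    pixel averages nothing and is typically a stray non-glomerular signal).
    If no cluster reaches ``min_members`` all nonempty clusters are kept, so
    heavily degraded recordings still return a (noisy) model.
    """
    if assign_metric != "cosine":
        raise ValueError(f"unknown assign_metric {assign_metric!r}")
    if model.c == 0:
        raise ValueError("empty factor model")
    if not (0.0 <= min_similarity <= 1.0):
        raise ValueError("min_similarity must be in [0, 1]")
    A = A_full.data
    m, n = A.shape
    basis = A[:, model.source_pixels]
    basis_norm = np.linalg.norm(basis, axis=0)
    if np.any(basis_norm == 0):
        raise ValueError("a selected source pixel has an all-zero time series")
    basis_unit = basis / basis_norm

    col_norms = np.linalg.norm(A, axis=0)
    nonzero = col_norms > 0
    cos = np.full((n, model.c), -np.inf)
    cos[nonzero] = (A[:, nonzero].T @ basis_unit) / col_norms[nonzero, None]

    best = np.argmax(cos, axis=1)  # ties -> smallest r
    best_sim = cos[np.arange(n), best]
    # small numerical slack so exact duplicates pass a min_similarity of 1.0
    assigned_mask = nonzero & (best_sim >= min_similarity - 1e-12)

    clusters = {
        r: np.flatnonzero(assigned_mask & (best == r)) for r in range(model.c)
    }
    clusters = {r: mem for r, mem in clusters.items() if mem.size > 0}
    if min_members > 1 and any(m.size >= min_members for m in clusters.values()):
        clusters = {r: m for r, m in clusters.items() if m.size >= min_members}

    members: list[np.ndarray] = []
    kept: list[int] = []
    T_cols: list[np.ndarray] = []
    S_rows: list[np.ndarray] = []
    for r, mem in sorted(clusters.items()):
        t_hat = A[:, mem].mean(axis=1)
        s_row = np.zeros(n)
        denom = float(t_hat @ t_hat)
        s_row[mem] = (A[:, mem].T @ t_hat) / denom
        members.append(mem)
        kept.append(r)
        T_cols.append(t_hat)
        S_rows.append(s_row)
    if not members:
        raise ValueError(
            "no pixel reached min_similarity for any source; "
            "lower min_similarity or denoise first"
        )
    in_member = np.zeros(n, dtype=bool)
    in_member[np.concatenate(members)] = True
    unassigned = np.flatnonzero(~in_member)
    return RefinedModel(
        T_hat=np.column_stack(T_cols),
        S_hat=np.vstack(S_rows),
        members=members,
        unassigned=unassigned,
        kept=kept,
        height=A_full.height,
        width=A_full.width,
        segment_bounds=list(A_full.segment_bounds),
    )


def induced_clustering(S: np.ndarray, geometry: tuple[int, int]) -> LabelMap:
    """Label each pixel by the map row with its highest coefficient.

    Labels are 1-based; pixels whose column of ``S`` is all zero get label 0;
    ties break toward the smallest row index.
    """
    S = np.asarray(S, dtype=np.float64)
    if np.any(S < 0):
        raise ValueError("S must be non-negative")
    h, w = geometry
    if S.shape[1] != h * w:
        raise FormatError(f"S has {S.shape[1]} columns, geometry implies {h * w}")
    labels = np.argmax(S, axis=0) + 1
    labels[np.all(S == 0, axis=0)] = 0
    return LabelMap(labels.reshape(h, w).astype(np.int32))


def back_project(A_full, S: np.ndarray) -> np.ndarray:
    """Full-length time series for spatial maps computed in reduced space.

    Solves ``min_T ||A - T S||_F``, i.e. ``T = A S⁺``. With orthonormal rows
    of ``S`` this is just ``A Sᵀ``. Requires ``S`` to have full row rank.
    """
    A = _as_matrix(A_full)
    S = np.asarray(S, dtype=np.float64)
    c = S.shape[0]
    if np.linalg.matrix_rank(S) < c:
        raise ValueError(f"S is rank-deficient (rank < c={c})")
    return A @ np.linalg.pinv(S)


def low_rank_movie(refined: RefinedModel) -> MovieMatrix:
    """Denoised movie ``A_c = T̂ Ŝ`` (rank at most c')."""
    data = refined.T_hat @ refined.S_hat
    return MovieMatrix(
        data,
        height=refined.height,
        width=refined.width,
        segment_bounds=list(refined.segment_bounds) or None,
    )


def save_factor_model(model: FactorModel, out_dir: str | Path) -> None:
    """Serialise a factor model as a directory of CSVs plus a JSON meta file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_timeseries(model.T, out / "T.csv")
    write_timeseries(model.S.T, out / "S.csv", names=[f"map_{r}" for r in model.order])
    meta = {
        "c": model.c,
        "order": model.order,
        "source_pixels": model.source_pixels,
        "init_seed": model.init_seed,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def save_refined_model(refined: RefinedModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_timeseries(refined.T_hat, out / "T.csv")
    write_timeseries(
        refined.S_hat.T, out / "S.csv", names=[f"map_{r}" for r in refined.kept]
    )
    with open(out / "members.csv", "w", encoding="utf-8") as fh:
        fh.write("signal,pixel\n")
        for r, mem in zip(refined.kept, refined.members):
            for p in mem:
                fh.write(f"{r},{p}\n")
    meta = {
        "c": refined.c,
        "kept": refined.kept,
        "height": refined.height,
        "width": refined.width,
        "segment_bounds": refined.segment_bounds,
        "n_unassigned": int(refined.unassigned.size),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
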