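# conefit

Automated source extraction for calcium-imaging movies of the insect
antennal lobe (AL). Odours are encoded in the AL as activity patterns
across glomeruli — spheroidal functional units whose pixels carry
correlated time series. Given a movie of such activity, `conefit` finds
the glomerulus positions and estimates their signals without manual
region-of-interest selection, producing:

* a **glomerular map** (a functional segmentation of the image plane),
* **pure glomerular time series** (signals free of mixing with neighbours),
* a **denoised low-rank reconstruction** of the movie for visualisation.

It is aimed at insect-olfaction labs working with Fura-2-style ratiometric
recordings, but applies to any movie in which spatially compact units emit
correlated, additively mixing signals.

## The model and algorithm

A movie is an `m x n` matrix `A` (frames x pixels) obeying a non-negative
mixture model

```
A = T S⁰⁺ + N
```

where the columns of `T` are **pure source time series actually present in
`A`** (pixels at glomerulus centres), `S⁰⁺ ≥ 0` holds the spatial
coefficients (fringe pixels are additive mixtures of neighbouring
glomeruli, caused by light scatter), and `N` is noise. The pure sources are
the **extreme vectors of the convex cone** containing the data: every mixed
pixel is a conic (non-negative) combination of them, but they themselves
are not reducible.

The pipeline:

1. **z-score** each pixel time series and reduce the time dimension with
   **top-k PCA** (iterative, deflation-based; optional seeded pixel
   sampling for speed).
2. **Cone fitting** — a greedy forward selection of `c` extreme columns:
   at each step the chosen column `t⁽ʳ⁾` is unit-normalised, its
   non-negative spatial mapping `s⁽ʳ⁾⁰⁺ = max(Aᵣᵀ t⁽ʳ⁾, 0)` is recorded,
   and the residual is downdated, `Aᵣ₊₁ = Aᵣ − t⁽ʳ⁾ s⁽ʳ⁾⁰⁺`; the next
   column is the residual column of largest norm. Selections are nested:
   the r-th basis vector does not depend on `c`.
3. **Refinement** — each pixel is assigned to the closest basis signal by
   cosine similarity, provided the similarity reaches a threshold
   (`min_similarity`, default 0.5); mixed fringe pixels fail the threshold
   and stay unassigned ("white"). The refined signal `t̂⁽ʳ⁾` is the mean
   over its member pixels, which averages `N` out. The refined maps `Ŝ`
   have disjoint supports and induce the glomerular map
   (`label(p) = argmax_r Ŝ[r, p]`).
4. **Back-projection** `T = A S⁺` recovers full-length time series for maps
   computed in PCA space, and `A_c = T̂ Ŝ` is the denoised reconstruction.

Defaults `k = c = 50` suit AL recordings with 20–40 visible glomeruli.

## Worked example

```python
import conefit as cf

movie, truth = cf.generate_movie(cf.SyntheticSpec(seed=42))
res = cf.extract_sources(movie, k=20, c=20, seed=42)
score = cf.correlation_score(res.refined.T_hat, truth.U)
print(res.refined.c, round(score.corr, 3))
```

Running `examples/simulate_and_map.py` (this code with reporting) prints:

```
movie: 400 frames x 3600 pixels (60x60), 16 implanted sources
recovered 17 refined signals
mean best-match Pearson correlation vs ground truth: 0.960
glomerular map: 17 clusters, 400 unassigned (white) pixels
```

The generator implanted 16 sources on overlapping discs with noise SD 0.3;
the pipeline recovered 17 refined signals (one surplus basis split a
cluster) whose time series correlate 0.96 on average with the implanted
sources. The 400 white pixels are background and the seams where
neighbouring discs overlap — exactly the mixed pixels the model says should
be discarded, not unmixed. The other examples show the noise sweep
(`noise_robustness.py`) and the time-series/reconstruction branch
(`timeseries_and_reconstruction.py`).

## Command line

```
conefit simulate --out sim --seed 1            # artificial movie + ground truth
conefit map sim/movie.tif --out map --k 20 --c 20 --seed 1
conefit timeseries sim/movie.tif --out ts --k 20 --c 20 --seed 1
conefit reconstruct sim/movie.tif --out rec --k 20 --c 20 --seed 1
conefit evaluate --out eval --sigmas 0.1,0.5,1.0,2.0 --reps 5 --seed 1
```

Each run writes a `manifest.json` with every parameter and an input content
hash; identical input + config + seed reproduce byte-identical outputs.

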