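# Methods

## Model

An imaging movie is an `m x n` matrix `A` with one row per frame and one
column per pixel time series; frames are flattened row-major
(`p = row * width + col`). The working assumption is a non-negative
mixture: each pixel either carries one pure glomerular signal (glomerulus
centres), or an additive mixture of neighbouring pure signals (fringes,
through light scatter), plus i.i.d. noise:

    A = T S⁰⁺ + N,   S⁰⁺ ≥ 0, columns of T are columns of A.

Pure signals are the extreme vectors of the convex cone spanned by the
data — not expressible as conic combinations of other columns — so source
extraction becomes extreme-vector selection rather than generic blind
separation. No independence or non-Gaussianity assumptions are made, and
mixed pixels are *discarded*, never unmixed: only the pure signals matter
for analysing glomerular response patterns.

## Pipeline and parameters

Processing order in the map branch is stabilise → (optional spatial
filter) → z-score → PCA → cone fitting → refinement → induced clustering.
The time-series branch instead normalises the raw movie by fold change
(per-segment baseline subtraction, optional division) and back-projects it
onto the refined maps.

Parameters that matter:

| parameter | default | meaning |
|---|---|---|
| `k` | 50 | PCA components kept. Signals concentrate in top components; too small loses glomeruli, too large defeats the reduction. |
| `c` | 50 | basis signals selected. Uncritical (selections are nested); choose above the expected glomerulus count (20–40 in AL recordings) to absorb non-glomerular objects. |
| `min_similarity` | 0.5 | cosine threshold for pixel → source assignment in refinement. Higher values whiten more fringe/mixed pixels; for two sources with correlation ρ an additive mixture has cosine `sqrt((1+ρ)/2)` to either pure signal, so thresholds above ~0.87 whiten all pairwise seams when |ρ| < 0.5. |
| `min_members` | 1 (`refine`), 2 (pipeline) | minimum cluster size for a refined signal. A refined signal is an average over member pixels; a single-pixel cluster averages nothing and is usually a surplus basis that latched onto a background pixel (with `c` above the true source count such bases are expected). If no cluster reaches the floor, all nonempty clusters are kept so heavily degraded movies still return a model. |
| `sampling_fraction` | 1.0 | PCA pixel-sampling speedup; components estimated on a seeded uniform pixel subset, then extended to all pixels by projection. |
| spatial filter width | off; 7 for noisy data | truncated Gaussian support in pixels, σ = width/4, reflect padding, kernel normalised to sum 1. |
| stabiliser radius | 10 px | exhaustive integer-shift search window for aligning concatenated recordings (normalised cross-correlation of segment mean frames). |

## Numerical choices

* **z-score** uses the sample (n−1) standard deviation; exactly constant
  columns become all-zero and are flagged rather than rejected (dead camera
  pixels are common and must never win a selection step).
* **PCA** is computed by deflated power iteration on the Gram matrix of the
  smaller movie dimension — the same fixed point as NIPALS (one NIPALS
  sweep equals one multiplication by `A Aᵀ`), with per-iteration cost
  independent of the pixel count. Convergence tolerance 1e-9 on the
  iterate, generous iteration cap; genuine non-convergence raises with the
  achieved tolerance. If the movie has numerical rank below `k` (e.g.
  noise-free synthetic data) the model truncates to the rank with a
  warning. Component signs are fixed (largest-magnitude entry positive) for
  determinism. Eigenvalues are reported as variances `σ²/(m−1)`.
* **Cone fitting** stores in `T` the *original* (un-downdated) selected
  columns, unit-normalised; `S` accumulates the non-negative rows
  `s⁽ʳ⁾⁰⁺`. The initial column is the one at maximal Euclidean distance
  from a uniformly drawn random column (seeded); argmax ties break toward
  the smallest index. The residual Frobenius norm decreases monotonically
  (`‖Aᵣ₊₁‖² = ‖Aᵣ‖² − ‖s⁽ʳ⁾⁰⁺‖²`), and a selected column's residual is
  exactly zeroed, so selections never repeat. A numerically zero residual
  before `c` selections returns the columns found, with a warning.
* **Refinement** measures closeness as cosine similarity between
  *full-length* (not PCA-reduced) pixel series and the full-length series
  at the selected source pixels; assignment requires similarity ≥
  `min_similarity` (with 1e-12 slack so exact duplicates pass a threshold
  of 1.0). All-zero pixels are always unassigned. `Ŝ` holds each member's
  least-squares coefficient on its cluster mean, zero elsewhere, giving
  disjoint supports by construction.
* **Back-projection** solves `min_T ‖A − T S‖_F` via the pseudoinverse and
  requires `S` to have full row rank.
* **Induced clustering** labels are 1-based argmax over map rows, 0 for
  all-zero columns, ties toward the smaller row.

## Synthetic benchmark

The generator emulates the artificial-data validation: 16 ground-truth
sources on a 4x4 grid of circular, partially overlapping discs (radius 9 px
in a 60x60 image, centre spacing ≈ 13.7 px, ~15% of in-disc pixels in
overlap zones; every source keeps at least one pure pixel), 400 frames,
additive mixing in overlaps, i.i.d. Gaussian pixel noise of SD
`sigma_noise`. Source time series are parametric stand-ins for real
recordings, in two flavours:

* **odours** — double-exponential response transients (rise 2 frames,
  per-source decay uniform in [5, 20] frames) locked to 8 shared stimulus
  onsets, each source responding to a random onset subset with per-onset
  amplitudes in [0.5, 1.5], plus a small AR(1) background (weight 0.05);
* **idle** — smoothed AR(1) spontaneous fluctuations only, giving lower
  peak amplitudes than odour responses.

Each column is standardised (mean 0, sample SD 1) and shifted by its
minimum to be non-negative. Pairwise |Pearson ρ| < 0.5 is enforced by
rejection sampling — sources are distinct but not uncorrelated. All
randomness derives from one seed via `SeedSequence` children (sources,
noise), so a spec is bit-reproducible.

What the generator does **not** emulate: photobleaching, movement
artefacts, ratio-formation noise physics, non-disc glomerulus shapes, and
the heavy-tailed spatial noise correlations of real cameras. Passing tests
therefore demonstrate correctness of the algorithmic machinery under the
stated mixture model, not performance on any particular real preparation.

## Evaluation

Recovery is scored as the mean, over recovered refined signals, of the
best Pearson correlation against any implanted source (many-to-one
matching; an optional one-to-one assignment variant exists for
diagnostics). The denominator is the number of *recovered* signals. The
noise sweep regenerates a fresh movie per (σ, replicate), runs the full
pipeline at k = c = 20 with 5 replicates by default, and pairs the
filtered/unfiltered arms on identical movies. Under these conditions the
unfiltered pipeline scores ≈ 0.9 or better for σ ≤ 1, collapses at σ = 2
(clusters shrink to near-singletons), and is restored at σ = 2 by width-7
Gaussian smoothing — the qualitative robustness pattern the method is
designed to show.

## Known limitations

* The greedy initialisation (farthest column from a random draw) seeks a
  hull vector but can seed from a *mixed* pixel when sources are mutually
  anticorrelated and, in the noise-free limit, when z-scoring makes all
  column norms equal (the argmax over residual norms is then degenerate).
  Downstream refinement still recovers signals well (scores stay high),
  but individual basis columns are not guaranteed pure; the mixed-pixel
  exclusion guarantee holds with respect to pure bases.
* Stabilisation is integer-shift only; subpixel motion and rotation are out
  of scope.
* Ambiguities resolved as design choices: refinement distances are computed
  in full time space (not PCA space); `T` stores original rather than
  downdated columns; the temporal filter is a segment-respecting moving
  average.
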