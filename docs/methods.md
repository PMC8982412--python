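# Methods

## Model and procedure

The pipeline treats each gene pair ("bigenic edge") of a gene
expression matrix as a 2-D point cloud over samples and asks two
questions: does the cloud decompose into distinct subpopulations, and
do the two genes carry (nearly) the same information about each
sample?  An edge enters the network only if both answers are yes.

Stages, each a pure function of its inputs and configuration:

1. **Shared grid.** One discretization serves the whole matrix: domain
   [0, ⌈global max⌉] per axis, bin width *r*.  Only non-negative
   expression is admitted; a matrix maximum of 18.89 yields 19, 38 or
   76 bins per dimension at *r* = 1, 0.5, 0.25.  A per-edge grid would
   make blob scales and MI partitions incomparable across edges, so
   the grid is global.  Bins are half-open [k·r, (k+1)·r) with a
   closed top bin; values outside the domain (possible when a grid is
   reused on new data) are dropped and counted, never clamped.
2. **Edge image.** Pairwise-complete samples are counted into the
   grid (missing values are deleted per edge, not per matrix, to
   preserve the rest of the data).  The count mass always equals the
   number of retained samples.
3. **Intensity scaling.** Counts pass through ln(1+x) and are divided
   by their maximum, giving intensities in [0, 1] with maximum exactly
   1.  The log compression is deliberate: subpopulation sizes in
   grouped compendia differ by an order of magnitude (60 vs 869
   samples in the kidney-like default), and on a max-normalized raw
   count image the minority subpopulation's response falls below any
   fixed detector threshold.  Compression bounds the dynamic range so
   detection depends on a subpopulation's presence, not its share of
   the samples.  It can be disabled (`log_compress=False`) to
   threshold on raw relative density.
4. **Blob detection.**  Three scale-space detectors, each scanning
   (row, col, σ):
   - LoG: −σ²·∇²(G<sub>σ</sub> ∗ I), the canonical scale-normalized response;
   - DoG: (G<sub>σᵢ</sub> ∗ I − G<sub>σᵢ₊₁</sub> ∗ I)/(ratio − 1) on a geometric σ
     ladder, the standard LoG approximation;
   - DoH: σ⁴·det(Hessian(G<sub>σ</sub> ∗ I)).
   Candidates are 26-neighbourhood maxima of the response stack above
   `response_threshold`; overlapping candidates (disks of radius √2·σ,
   or σ for DoH) are pruned keeping the stronger response, with exact
   ties broken by (row, col, σ) order so output is deterministic.
   Smoothing uses reflective boundaries; centers may lie on borders.
5. **Inclusion rule.** An edge is multimodal when ≥ `k_required`
   (default 2) of the 3 detectors each report ≥ `min_blobs` (default
   2) blobs.  The 2-of-3 rule absorbs DoH's known insensitivity to
   subpopulations smaller than ~3 bins across or elongated along a
   diagonal (a ridge has a near-zero Hessian determinant).
6. **Scoring.** The edge score is the normalized mutual information
   of the two genes' bin-index partitions over the same grid, in nats,
   normalized by the arithmetic mean of the entropies (geometric, min
   and max normalizations are available).  NMI is 0 by convention when
   either gene is constant.  Using the imaging grid as the MI
   discretization means the image and the score describe the same
   quantization of the data.  The default score uses all samples; a
   per-blob mode assigns samples to detected blobs (strongest response
   first, nearest center on ties, blobs under 10 samples skipped) and
   averages per-blob NMIs — kept as an option because the two modes
   select nearly identical networks.
7. **Thresholding.** Edge kept iff multimodal and NMI ≥ τ = 0.97.

A silhouette coefficient ((b − a)/max(a, b), singletons scoring 0) is
exposed as a cluster-separation diagnostic; it is not part of the
default edge rule.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `resolution` | 0.5 | expression units / bin | best balance of pattern resolution vs count sparsity at ~10³ samples; 1 and 0.25 are first-class presets |
| `min_sigma`, `max_sigma` | 1, n_bins/4 | bins | subpopulations narrower than a bin or wider than a quarter image are not meaningful modes |
| `num_sigma` | 10 | — | LoG/DoH scale sampling |
| `sigma_ratio` | 1.6 | — | conventional DoG ladder ratio |
| `response_threshold` | 0.05 | response units | on compressed, max-normalized images; lower = more sensitive |
| `overlap` | 0.5 | fraction | disk-overlap pruning limit |
| `min_blobs`, `k_required` | 2, 2 | — | the 2-of-3 multimodality rule |
| `mi_threshold` (τ) | 0.97 | — | NMI inclusion threshold |
| `min_samples` | 30 | samples | pairwise-complete floor per edge, the field's customary minimum for calling a mode |

All detector and scoring settings are recorded in the network metadata
and the run manifest.

## What the synthetic generator emulates — and what it does not

The generator mimics the statistical shape of a unified, jointly
normalized bulk compendium: non-negative bounded values (default max
18.89, so the fixture reproduces the 19/38/76 grid sizes), several
sample groups (default 158/60/475/236 — one normal and three tumour
subtypes, 929 samples), and three pair patterns:

- **null** — independent Gamma(shape 2, scale 2) draws clipped to the
  range (right-skewed, like log-scale FPKM backgrounds);
- **linear** — gene_b = gene_a + N(0, noise_sd), a globally correlated
  unimodal pair;
- **multimodal** — designated group(s) at bivariate mean μ₁, the rest
  at μ₂ with ‖μ₁ − μ₂‖ = separation (default 8 units); within each
  subpopulation both genes share one latent N(0, noise_sd = 0.5)
  deviation.

The shared latent is the key design choice.  An NMI threshold of 0.97
at bin-level discretization keeps an edge only when each gene's bin
(nearly) determines the other's.  If the within-cluster variation of
the two genes were independent, the only shared information would be
the cluster indicator itself, and the binned NMI of a planted pair
would sit near 0.3 regardless of cluster separation — no generative
parameter choice with independent noise can cross 0.97.  Modelling the
within-cluster deviation as common biological variation (identical for
both genes, zero observation noise by default; a `jitter_sd` parameter
adds per-gene noise when wanted) makes planted pairs bin-deterministic
and hence scoreable near 1, which is precisely the kind of tightly
coupled multimodal edge the threshold is designed to keep.  The cost
is realism: planted clusters are diagonal streaks (width 0, length
~4σ) rather than round clouds.  Passing tests therefore demonstrate
that the pipeline recovers strongly coupled multimodal pairs and
rejects linear and null pairs under these idealized conditions; they
do not establish recall on real tumour compendia, where within-cluster
coupling is imperfect and the NMI of true condition-specific pairs can
fall anywhere below 1.

Clipping at the range bounds (rather than rejection sampling) slightly
inflates boundary bins.  The generator does not model counts,
library-size effects, batch structure, or gene–gene correlation beyond
the planted pairs.

## Numerical choices

- MI in nats; term-by-term double sum over the contingency table with
  0·log 0 = 0; NMI clipped to [0, 1] against rounding.
- The detectors are implemented directly on separable Gaussian
  filtering (scipy.ndimage) so that responses, thresholds, pruning and
  tie-breaking follow the documented contract exactly; the test suite
  checks the scale-space maxima against an exhaustive brute-force
  response scan and cross-checks against skimage's LoG/DoG detectors
  on clean images.
- Local maxima use a 3×3×3 neighbourhood with clamped borders, so a
  maximum may sit at the smallest or largest scale or at an image
  border; plateau points are all candidates and collapse during
  pruning (first in (row, col, σ) order survives among equals).
- Grid construction requires the resolution to divide the integer
  domain bound exactly and suggests the nearest valid resolution
  otherwise.
- Degenerate inputs: all-zero images are an error for normalization
  and empty for detection; edges with fewer than `min_samples`
  pairwise-complete samples are recorded as skipped with a reason, not
  scored; self-pairs are rejected; evaluation order and worker count
  cannot affect results because each edge is a pure function.

## Problem sizes

All-pairs evaluation is quadratic in gene count (~1.8×10⁸ pairs for a
19,216-gene matrix), so genome-scale runs need the variance/floor gene
prefilter or chunked parallel execution (`--threads`).  The bundled
benchmarks use 100-gene matrices (4,950 pairs, ~0.5 min single-core)
for planted-pattern recovery and 50-gene matrices for the duplicated
orientation runs; these sizes exercise every code path while keeping
the suite quick.

## Known limitations

- DoH contributes little on minority or streak-like subpopulations;
  with `k_required=3` the pipeline becomes very conservative.
- The NMI threshold 0.97 presumes near-deterministic bin coupling;
  real multimodal pairs with substantial independent noise score far
  lower and need a lower τ (the threshold is fully configurable).
- A fixed absolute `response_threshold` interacts with the intensity
  scaling: with `log_compress=False`, minority subpopulations below
  ~15% of the majority's peak density become undetectable.
- The per-blob scoring mode depends on blob geometry (disk membership)
  and can leave samples unassigned between blobs.
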