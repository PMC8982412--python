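# edgecrafting

Gene coexpression network construction for bulk RNA-seq, built on an
image-analysis view of each gene pair.  Instead of asking whether two
genes correlate linearly across samples, the method asks whether the
joint distribution of their expression values contains **distinct
subpopulations of samples** — the signature of condition-specific
(e.g. tumour-subtype-specific) differential coexpression — and whether
the two genes are mutually informative.

## Who this is for

Researchers constructing gene relationship networks from a normalized
gene expression matrix (GEM: genes × samples, non-negative values such
as log-scale FPKM) who want to capture **nonlinear, multimodal**
bigenic relationships that Pearson/Spearman-based tools miss, without
fitting Gaussian mixture models per pair.

## The method

For every unordered gene pair (*g<sub>a</sub>*, *g<sub>b</sub>*):

1. **Binning.** The samples' (*x<sub>a</sub>*, *x<sub>b</sub>*) values
   are counted into a square image on a grid shared by the whole
   matrix: the domain is [0, ⌈max expression⌉] per axis, divided into
   bins of width *r*.  A matrix with maximum 18.89 gives 19×19,
   38×38 or 76×76 images at *r* = 1, 0.5 (default), 0.25.
2. **Blob detection.** After `ln(1+x)` compression and
   max-normalization, three scale-space detectors — Laplacian of
   Gaussian (LoG), difference of Gaussians (DoG) and determinant of
   the Hessian (DoH) — locate bright, roughly circular subpopulations
   as maxima of a scale-normalized response over (row, col, σ).
3. **Inclusion rule.** The pair is *multimodal* when at least **2 of
   the 3** detectors each find **2 or more** blobs.
4. **Scoring.** The pair's score is the normalized mutual information
   between the two genes' bin-level partitions *U*, *V* of the samples,

   MI(U,V) = Σ<sub>i</sub> Σ<sub>j</sub> (|U<sub>i</sub>∩V<sub>j</sub>|/N) · ln( N·|U<sub>i</sub>∩V<sub>j</sub>| / (|U<sub>i</sub>|·|V<sub>j</sub>|) ),
   NMI = MI / mean(H(U), H(V)) ∈ [0, 1],

   and the edge enters the network when NMI ≥ τ (default **0.97**).

Edge selection is orientation-invariant: flipping which gene sits on
which axis mirrors the image, and both blob counts and NMI are
symmetric under that mirror (`verify_orientation_invariance` re-runs a
whole matrix both ways to prove it).  A silhouette coefficient
(*b* − *a*)/max(*a*, *b*) is provided as a cluster-separation
diagnostic.

## Worked example

`examples/build_network.py` generates a 40-gene synthetic compendium
shaped like a unified normal+tumour kidney GEM (929 samples in 4
phenotype groups; 5 planted multimodal, 5 linear, 10 null pairs) and
runs the pipeline at defaults:

```
GEM: 40 genes x 929 samples (4 phenotype groups)
evaluated 780 gene pairs -> 5 edges over 10 genes
  G0000 -- G0001  NMI=1.000  blobs LoG/DoG/DoH = 2/2/0
  G0002 -- G0003  NMI=1.000  blobs LoG/DoG/DoH = 2/2/0
  G0004 -- G0005  NMI=1.000  blobs LoG/DoG/DoH = 2/2/0
  G0006 -- G0007  NMI=1.000  blobs LoG/DoG/DoH = 2/2/0
  G0008 -- G0009  NMI=1.000  blobs LoG/DoG/DoH = 2/2/0
recovery of planted multimodal pairs: precision=1.00 recall=1.00
```

The 5 reported edges are exactly the planted multimodal pairs: LoG and
DoG each saw both sample subpopulations (DoH misses small or elongated
ones, which is why agreement of only 2 of 3 detectors is required), and
the two genes of each pair determine each other's expression bin
(NMI = 1).  Linear pairs look blob-multimodal along their diagonal band
but fail the NMI threshold; null pairs fail both criteria.

The other example scripts show the per-pair image and blobs
(`edge_image_and_blobs.py`), the score's analytic anchors
(`mi_scores.py`) and the orientation experiment
(`orientation_check.py`).

## Command line

```bash
edgecrafting simulate --out-prefix bench --seed 1          # synthetic GEM + truth
edgecrafting run --gem bench.gem.tsv --out network.tsv \
    --resolution 0.5 --mi-threshold 0.97 [--graphml network.graphml]
edgecrafting verify-orientation --gem bench.gem.tsv
```

`run` writes a sorted edge-list TSV (`gene_a, gene_b, nmi, blobs_log,
blobs_dog, blobs_doh, n_passing_methods`), optional GraphML, and a JSON
manifest echoing the configuration and pair counts.

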