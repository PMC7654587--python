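# Methods

## Model and assumptions

`radialct` infers the radial arrangement of chromosome territories (CTs)
from the inter-chromosomal part of a genome-wide Hi-C contact matrix.
The underlying assumptions are:

* A population Hi-C map averages over many nuclei whose CT *radial*
  preferences are consistent while angular arrangements are not;
  trans-contact frequency between two CTs therefore reflects their
  expected spatial proximity, which is highest for pairs of central
  territories.
* Most trans contacts are random-ligation background. Only the strongest
  interactions — above the 95th percentile of all observed interactions —
  carry territory-specific signal. This percentile is not arbitrary: the
  calibration scan shows the correlation between real and
  shuffle-randomized chromosome-pair strong counts, and between real
  counts and the chromosome-length product, decaying as the threshold
  rises and stabilizing near the 90th–95th percentile.
* Contact data cannot resolve the absolute center→periphery direction:
  PC1 orientation, and mirror-image layout clusters, are intrinsic
  ambiguities. The package reports them (sign conventions, cluster
  correlation signs) rather than guessing; an anchor chromosome with
  independently known peripheral position (chrX in human lymphoblastoid
  data) can resolve the direction.

A homolog-averaged map cannot distinguish the two copies of a
chromosome; "territory" throughout means the population- and
homolog-averaged position.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `percentile` | 95 | strong-contact threshold percentile (observed, zero-free population; upper triangle incl. diagonal) |
| `n_shuffles` | 5 | upper-triangle value shuffles for the random-ligation control |
| `n_s` | 1000 | layout models in the ensemble (50 in desk-scale tests) |
| `fr_iterations` | 500 | force-layout iterations per model |
| `gravity` | 1.0 | spring constant pulling nodes to the layout centroid |
| `mve_epsilon` | 1e-3 | Khachiyan approximation tolerance |
| `k_range` | 2–15 | K-means candidate cluster counts |
| `loess_span`, `loess_degree` | 0.75, 2 | tuning smoother (tricube weights) |
| ICE `tol`, `max_iter` | 1e-6 (row-sum CV), 200 | balancing convergence |

## Numerical and design choices

**ICE.** Plain iterative row/column balancing to uniform coverage,
rescaled so the output total equals the input total. Bins with zero
coverage must be filtered first; absent an explicit mappability flag, a
zero raw row sum marks a bin unmappable (such bins collect no valid read
pairs, the operational signature of repetitive regions).

**Percentile population.** Structural zeros produced by bin filtering
would dominate a percentile over all entries, so exact zeros are
excluded by default (`include_zeros` restores the literal all-entries
reading). Linear interpolation between order statistics.

**Random-ligation shuffle.** "Shuffling the bins" is implemented as a
uniform permutation of upper-triangle entry values (diagonal included)
over upper-triangle positions, mirrored to keep symmetry. This conserves
the total read count and dynamic range exactly while destroying all
positional structure; the alternative row/column-relabeling reading is
available (`mode="labels"`) but preserves marginals instead. Note that
the conserved total is the unordered-pair (upper-triangle) sum: a value
moving between diagonal and off-diagonal changes the doubled full-matrix
sum but not the read count. Five sequential shuffles are performed for
fidelity; one is statistically sufficient.

**PCA.** Rows of the 23×23 trans pattern matrix are samples; columns are
mean-centered; no column standardization (the raw count pattern is the
signal). The eigendecomposition is deterministic, and signs are fixed by
convention — PC1 oriented so corr(PC1, length) ≥ 0, PC2 so its
largest-magnitude loading is positive — making runs reproducible while
the anchor mechanism handles the biological direction. Ties in the
|corr| comparison classify as length, the pattern toward which
unstructured data drifts.

**Force layout.** No installed package provides a weighted 3D
Fruchterman–Reingold layout with central gravity, so it is implemented
here (numba-jitted kernels): classic repulsion `k²/d` between all node
pairs with `k = (1/n)^{1/3}`, attraction `w·d²/k` along edges with
weights normalized to unit mean, plus a spring to the instantaneous
centroid (gravity 1.0) that also bounds disconnected components. Initial
coordinates are uniform in the unit cube from the seeded RNG;
displacements are capped by a linearly cooling temperature (0.1 → 0).
Self-loops carry no layout information and are dropped; bins with no
strong edge are excluded, and a chromosome losing all bins aborts with
an explicit error. Individual layouts are stochastic by design; only
ensemble statistics are meaningful, which is why layout parameters
(iteration count, gravity) affect single models much more than the
clustered consensus.

**Minimum-volume ellipsoid.** Khachiyan's barycentric ascent to a
(1+ε)-approximate enclosing ellipsoid; the shape matrix is rescaled so
the farthest point lies exactly on the surface, guaranteeing enclosure.
Coplanar degenerate point sets get a ridge-regularized fit with a
warning. Distances are min-max normalized per model to remove
between-model scale heterogeneity; if all CT centers of mass are
equidistant from the center the distances are set to 0.5 with a warning.

**Deterministic K-means.** Initial centroids follow a density-pair
scheme: repeatedly take the closest pair of unassigned points, grow the
group by nearest neighbors to n/k, and use its mean; Lloyd iterations
then proceed without randomness, so a fixed distance matrix always
yields identical labels. An empty cluster is re-seeded at the point
farthest from its nearest centroid. The cluster count comes from the
knee of the inertia curve (a kneedle-style detector on the normalized,
flipped curve, sensitivity 1.0 — implemented in-house) refined by the
best mean silhouette among the knee ±2; a featureless curve falls back
to the global silhouette maximum with a warning. Cluster selection ties
break toward the larger cluster, then the lower id; clusters below 5
models are excluded.

**Tuning.** P (PC1 of the chromosome correlation matrix of the selected
cluster) is oriented so corr(P, M) ≥ 0 — making the result invariant to
the arbitrary PCA sign — and min-max scaled to [0, 1] so it is
commensurate with M before the weighted combination. Gene density and
length are min-max normalized before entering the reference vector; the
`exp(1 − GD)` term is used exactly as written, un-rescaled. The loess
smoother is authored in-house (statsmodels lowess is degree-1 only):
tricube weights over the span fraction of nearest neighbors, local
polynomial of degree 2; its degree-1 mode is cross-checked against
statsmodels lowess in the tests. A span too small to support the
polynomial raises.

## Synthetic data: what it emulates and what it does not

The generator plants 23 territory centers in a unit nucleus with radial
coordinates monotone in the organizing property (gene-rich or short
chromosomes inward; equal rank spacing between 0.2 and 0.9 plus Gaussian
jitter, sd 0.05). Counts are Poisson:

* cis follows a power-law genomic-distance decay (`cis_scale` 1000 at
  adjacent bins, exponent 1), the dominant signal as in real Hi-C;
* trans means are `trans_scale` (15) times the *population-average*
  contact propensity of the two planted radii — the exponential decay
  kernel (decay length 0.5 nucleus radii) averaged over the isotropic
  relative angle by Gauss–Legendre quadrature. Averaging over angles,
  rather than fixing one configuration, reflects what a sequencing
  experiment over millions of nuclei measures and is what makes the
  planted radial signal recoverable at all;
* a uniform background supplies `noise_fraction` (0.3) of total reads,
  emulating random ligation.

These rates give roughly 70/30 cis/trans reads and strong-contact
behavior (trans tails overlapping the far-cis floor) comparable to
deeply sequenced human maps at 2.5 Mb. The default "small-genome mode"
divides hg19 chromosome lengths by 10 at a 250 kb bin size, reproducing
the bin structure of real data binned at 2.5 Mb (~1230 bins) at modest
simulation cost; test fixtures that shrink the genome further use a
steeper cis exponent (1.7) to preserve the cis/trans overlap that long
chromosomes otherwise provide.

Not emulated: TADs, A/B compartment checkerboards, copy-number and
mappability biases, nuclear-shape anisotropy of contact ranges, or
read-level artifacts. Passing recovery tests therefore demonstrates that
the pipeline extracts a planted radial signal through realistic noise
and its own full stack — not that real nuclei lack confounders the
generator omits.

## Problem sizes used in the test suite

Classification and random-control panels use 20 seeds of the default
~1230-bin maps; the calibration scan uses 10 seeds over the 45th–95th
percentile grid; the full ensemble run uses 50 models at 500 iterations.
The quenched nature of a single shuffle means randomized-ensemble
distance distributions vary between shuffle realizations; the
source-invariance check is therefore a paired comparison (cross-source
versus same-source KS distances) rather than an absolute bound.

## Known limitations

* The inward/outward orientation of the selected cluster is reported via
  the sign of its property correlation, never auto-corrected.
* Chromosome-level inference only: no sub-chromosomal (compartment or
  locus) radial positions.
* The 95th percentile is a calibrated default, not a universal constant;
  library complexity, read depth and cis/trans ratio shift the optimum,
  which is why the calibration scan is part of the toolkit.
* Tuning is neutral-to-helpful on average but can shave a few
  hundredths off an already near-perfect consensus profile; it is most
  useful when the ensemble consensus is noisy.
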