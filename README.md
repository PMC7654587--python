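# radialct

Inference of chromosome-territory (CT) radial organization from
genome-wide Hi-C contact matrices.

In interphase nuclei each chromosome occupies a discrete territory, and
territories are arranged radially: lymphoblastoid-like spherical nuclei
tend to place gene-rich chromosomes centrally (a *gene-density*
organization), while fibroblast-like ellipsoidal nuclei place short
chromosomes centrally (a *length* organization). Inter-chromosomal
(trans) Hi-C contacts are sparse and noisy, but after aggressive
thresholding they retain enough signal to recover this radial
arrangement. `radialct` implements that inference for anyone with a
binned genome-wide contact matrix (the tested operating point is human
data at 2.5 Mb, hg19, 22 autosomes + chrX; chrY is excluded).

## Method

Given an ICE-balanced contact matrix `H` (entries `h_ij`):

1. **Strong contacts.** Threshold at `h_cut`, the 95th percentile of the
   observed genome-wide interactions: `s_ij = h_ij` if `h_ij > h_cut`,
   else 0. The percentile is calibrated by comparing, across thresholds,
   chromosome-pair strong counts of the real matrix against a matched
   random-ligation matrix (produced by shuffling the raw matrix's
   upper-triangle values five times, then re-balancing) and against the
   pairwise product of chromosome lengths.
2. **Pattern matrix.** Count strong bin pairs per chromosome pair
   (`CHR_STRONG`, a 23×23 count matrix) and zero the diagonal
   (`CHR_TRANS`).
3. **PCA ordering.** PCA on the rows of `CHR_TRANS` projects each
   chromosome onto PC1; the ordering along PC1 recovers the radial
   ordering, and the larger of |corr(PC1, gene density)| and
   |corr(PC1, length)| identifies the organization type.
4. **3D network ensemble.** Treat `S` as a weighted graph (bins =
   nodes), draw `n_s` independent 3D Fruchterman–Reingold layouts with
   central gravity (default `n_s` = 1000), fit a minimum-volume
   enclosing ellipsoid (Khachiyan) per layout as the nuclear envelope,
   and record each CT's center-of-mass distance from the ellipsoid
   center, min-max normalized per model: a distance matrix `D`
   (`n_s` × 23).
5. **Cluster selection.** Deterministic K-means on `D` (k chosen by the
   inertia-curve knee refined by silhouette in its vicinity); keep the
   cluster whose mean profile has the highest |Pearson r| with the
   inferred organizing property. Mirror-oriented clusters (inverted
   radial ordering, which contact data cannot disambiguate) are
   reported, not silently fixed.
6. **Property tuning.** With `D'` the selected cluster, combine its mean
   profile `M` and the PC1 projection `P` of its chromosome–chromosome
   correlation matrix as `C = W1·M + W2·P`, where `W1, W2` are the
   normalized variance fractions of PC1 and PC2. Build a property
   reference `R = W1·exp(1 − GD) + W2·LN` (weights swapped for a length
   organization; GD, LN min-max-normalized gene density and length) and
   loess-smooth `C` against `R` to obtain the tuned radial profile.

A synthetic-data generator (`radialct.synthetic`) produces binned maps
with planted radial organization, realistic cis dominance and a tunable
random-ligation background, so the whole pipeline can be exercised and
validated without external downloads.

## Worked example

```sh
radialct simulate --organization gene_density --seed 1 --out-prefix sim
radialct run --matrix sim.matrix.tsv --bins sim.bins.tsv \
             --props sim.props.tsv --n-models 50 --seed 100 --outdir out
```

The run log ends with (abridged):

```
strong: h_cut=18.4569
order: inferred_type=gene_density r_gd=-0.909 r_len=0.402
ensemble: 50 models
cluster: k=3 selected=0 r=-0.662 (t=23)
tune: W1=0.709 W2=0.291
```

Reading the numbers: the 95th-percentile threshold lands at 18.5
balanced counts; PC1 of the trans pattern correlates much more strongly
with gene density (|r| = 0.91) than with length (0.40), so the map is
classified as gene-density organized — correctly, since that is what the
simulation planted. Of the 50 layout models, the selected 23-model
cluster's mean radial profile correlates with gene density at |r| = 0.66
(the sign only reflects the arbitrary inward/outward orientation), and
the tuned profile in `out/tuned.tsv` correlates with the planted radial
positions at r = 0.95 (versus 0.86 before tuning).

The same stages are available as library functions
(`radialct.threshold_strong`, `radialct.pca_project`,
`radialct.ensemble_distance_matrix`, `radialct.cluster_models`,
`radialct.tune_profile`, ...) and as individual subcommands
(`simulate`, `randomize`, `strong`, `order`, `ensemble`, `cluster`,
`tune`, `run`).

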