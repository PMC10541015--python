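# Methods notes

This note records the model assumptions, parameter choices and numerical
conventions behind `histomap`, and what the synthetic test bed does and does
not establish.

## Pipeline model and assumptions

The pipeline treats a whole-slide image as a lattice of independent square
tiles and assumes that morphologic identity is captured by per-tile summary
statistics ("histomic fingerprints"). Spatial coherence of the resulting
partitions is an emergent property — tiles of one histologic pattern have
similar fingerprints — not an explicit constraint: no spatial regularization
is applied, matching the underlying method.

- **Tiling.** Tiles are non-overlapping, 0-based, half-open, row-major.
  Partial edge tiles are dropped rather than padded so that every fingerprint
  is computed on identically sized input. Working pyramid level defaults to
  the level nearest 0.5 µm/px when metadata is present (a ×20 scan), else
  level 0. Default tile side 512 px; the CLI exposes it because the useful
  scale depends on whether cytologic or architectural patterns are of
  interest.
- **Background filter.** A tile is discarded only when mean HSV saturation
  < 0.05 **and** grayscale SD < 4/255. The conjunction is deliberately
  conservative (tissue edges are kept unless clearly blank), and both
  thresholds are exposed; setting them to 0 disables filtering entirely,
  since whether blank tiles should enter clustering is context-dependent.
- **Feature extraction.** Extractors are pluggable behind a registry keyed by
  name with a declared output dimension that is enforced on every tile. The
  reference `cnn512` extractor produces the 512-dim global-average-pooling
  output of a fixed-weight, He-initialized random-convolution network
  (3→32→128→512 channels); untrained convolutional features are a standard
  deterministic baseline, and a fine-tuned pathology backbone can be
  registered as a drop-in replacement. The `texture` extractor (d=64) is the
  workhorse for tests; its layout is documented on `TextureFeaturizer`.
- **Scaling.** Features are z-scored per column with the *population* SD,
  which keeps the two-tile edge case and the constant-column guard well
  defined. Constant columns are mapped to zeros rather than dropped so
  feature indices remain stable for activation mapping. Scaling an already
  scaled matrix is a state error, not a no-op.
- **Clustering.** Ward linkage on Euclidean distances of the scaled rows
  (Ward requires Euclidean geometry). The full linkage record is retained,
  so any coarser cut is recoverable without re-clustering and cuts are
  nested. Labels are renumbered 1..k by descending cluster size, ties broken
  by smallest member tile index — a pure relabeling chosen so outputs are
  byte-reproducible; dendrogram order would be an equally valid convention.
- **Defaults k = 9 / k = 7.** Single-slide maps default to k = 9; the
  multislide workflow uses k = 7 per slide, the point at which
  human-discernible pattern variation tends to saturate. Cluster-validity
  indices are intentionally *not* used to pick k automatically — they are
  unstable across tissue contexts — so the silhouette sweep is advisory only.
- **Heterogeneity score.** Pearson r between region-mean *scaled* vectors,
  computed across features. Scaling-before-averaging matches the stated
  pipeline order (scale, then cluster, then summarize); a raw-mean variant
  can be obtained by computing profiles from an unscaled matrix. The
  semiquantitative categories use midpoints of the calibrated category means
  (cutpoints 0.45 / 0.65 / 0.795): the calibration reports category means
  and one boundary (moderate–severe at r < 0.74), not a full decision rule,
  so the midpoint convention is documented and configurable.
- **Multislide merge.** Regions are agglomerated on 1 − r with average
  linkage — the standard correlation-heatmap convention; the linkage is a
  parameter because the original procedure states only "hierarchical
  clustering". K is always user-supplied. Enrichment uses a one-vs-rest
  2×L chi-square per specimen-cluster (a global K×L test is also reported),
  replaced by a seeded 10,000-shuffle permutation test whenever any expected
  count is below 5 (Cochran's rule); Benjamini–Hochberg companions are
  attached across clusters.
- **Feature ranking.** Mann–Whitney U (two-sided) per feature, in-region vs
  rest-of-slide, BH-corrected across the d features. The rank test was
  preferred over the t-test (available as a switch) because rectified
  deep-feature activations are heavy-tailed. FAMs are one value per tile —
  the scaled feature, min–max normalized over tissue tiles — with the
  normalization recorded so renders are reproducible.

## Synthetic data: what it emulates and what it does not

`synthetic.generate_slide` plants rectangular regions that differ in exactly
the statistics the pipeline consumes: nuclear density (homogeneous Poisson
process, mean expressed per 64-px reference tile), nucleus size (ellipses,
Gaussian-distributed radii), eosin background tone, and the correlation
length of a multiplicative noise field. Defaults (`default_prototypes`):
densities 40 / 8 / 22 nuclei per reference tile, radii 2.5 / 4.5 / 3.2 px,
three distinguishable pink-range tones — values chosen once as a plausible
hypercellular-tumor / sparse-tissue / intermediate-pattern triplet. Nuclei
are drawn with soft (blurred) edges so gradient and blob statistics behave
as they do on stained tissue.

The generator does **not** emulate anatomy (gland formation, infiltration
fronts), stain physics, scanner artifacts (folds, blur bands), or pyramidal
file structure. A green recovery test therefore establishes that the
clustering machinery separates regions that differ in density/tone/texture
statistics — not that any particular extractor is sufficient for real
histology.

Two deliberate test-bed variants exist:

- `default_prototypes()` — subtle contrasts; used for the recovery and
  ordering benchmarks (median ARI, correlation ordering), where imperfect
  per-seed recovery is expected and acceptable.
- `strong_prototypes()` plus the `align_px` cohort option — obvious low-power
  contrasts and region boundaries snapped to the tile lattice. This is the
  "well separated" regime that the exact multislide-recovery guarantee is
  premised on: mixed-content boundary tiles sit between prototypes in feature
  space and would violate the premise, so the benchmark verifies the
  separation condition (between-class center distance > within-class spread)
  before asserting exact recovery. The multislide benchmark over-segments
  each slide at k = 7 and lets the merge regroup sub-regions, mirroring the
  intended multislide workflow.

Benchmarks run on slides of a few hundred pixels (24–50 tiles at 64-px
tiles). The structural claims checked (tile-lattice geometry, linkage
equivalence, matrix shape/symmetry, calibration of the ranking null) are
size-independent; runtimes quoted for full WSIs do not apply.

## Numerical conventions and degenerate inputs

- Ward tree cuts use exact-k tree cutting; k = n yields singletons.
- Silhouette on a matrix whose rows are all identical is undefined; scores
  are reported as 0 with a warning.
- A constant region-mean vector has undefined correlations; entries are NaN
  with a warning (never coerced to 0), the diagonal stays 1.
- k-means subdivision: k-means++ init, 10 restarts, seeded; the largest
  sub-cluster keeps the parent label, the rest are appended after k.
- Permutation p-values use the add-one estimator (1 + #{perm ≥ obs}) /
  (1 + N), with a 1e-12 slack on the ≥ comparison to absorb chi-square
  rounding.
- PCA retains min(n − 1, d) components, so explained-variance fractions sum
  to 1 and full reconstruction is exact to numerical precision.
- LoG filter responses on constant tiles are zero only up to kernel
  truncation (~1e-4); tests treat them with an absolute tolerance.

## Known limitations

- No openslide binding: SVS/pyramidal TIFF are read via `tifffile`; NDPI
  files beyond what tifffile parses, and vendor-specific metadata, are not
  supported. The working level is loaded fully into memory, which bounds
  practical slide size at this implementation's desk scale.
- The shipped extractors are deterministic stand-ins. The intended
  production configuration — a pathology-fine-tuned CNN — must be registered
  by the user; its weights are not distributable here.
- `categorize_r` approximates a human-calibrated ordinal scale with fixed
  cutpoints; it should not be read as a measurement of perceptual severity.
- Stain normalization and cross-section registration are out of scope.
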