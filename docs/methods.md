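# Methods

This note documents the models and procedures `nucfuse` implements, the
parameter defaults and why they were chosen, the numerical conventions,
and what the synthetic benchmarks do and do not establish.

## Coordinate and label conventions

Boxes are 0-based, half-open pixel intervals (`xmin ≤ x < xmax`), which
makes areas and image indexing exact; a `dialect` flag on the annotation
readers converts 1-based inclusive exports at the I/O boundary. Two labels
are reserved: **ambiguous** (a rater may emit it, but no true nucleus is
ambiguous, so it is never inferable as truth) and **undetected** (a
pseudo-label meaning the rater saw the field of view but placed no box at
that location). The default taxonomy maps five main classes — tumor,
fibroblast, lymphocyte, plasma cell, other — onto super-classes tumor /
stromal / sTILs, with "other" kept as a configurable catch-all; the raw
label vocabulary is configuration because studies differ in granularity.

## Bootstrapped suggestions

The suggestion pipeline runs per field of view:

1. **Macenko stain unmixing.** Optical density `OD = −ln((I+1)/256)`;
   tissue pixels (‖OD‖ > 0.15) are projected onto their top-2 singular
   plane; the robust extreme angles (1st/99th percentile) give two unit
   stain vectors; hematoxylin is the vector with the lower blue/red OD
   ratio (hematoxylin absorbs red and green strongly). Concentrations are
   non-negative least squares against the full image.
2. **Per-region thresholding.** The hematoxylin map is Gaussian-smoothed
   with σ = 2 px inside lymphocyte-rich regions (lymphocytic and
   plasmacytic infiltrates — densely packed small nuclei) and σ = 5 px
   elsewhere; a global Otsu threshold is computed within each region
   class's pixels only, making the threshold robust to region-specific
   staining. The smoothing parameter is interpreted as a standard
   deviation in pixels (its stated unit); a `sigma_is_variance` flag
   converts if the alternative reading is wanted.
3. **Splitting.** 8-connected components (3×3 structuring element), then
   marker-controlled watershed on the negative Euclidean distance
   transform, with peak local maxima (minimum distance 10 px) as markers.
   A component whose smoothed distance surface yields no peak keeps a
   marker at its distance argmax rather than vanishing. Objects under
   300 px² are removed and labels compacted.
4. **Class bootstrapping.** Each object's region is the majority region
   label under its mask. The region's predominant cell type is inherited
   directly (tumor→tumor cell, infiltrates→lymphocyte/plasma cell,
   necrosis and other→other) except in stroma, which hosts both
   fibroblasts and scattered sTILs: an object is called fibroblast iff its
   shape is spindle-like — aspect ratio (minor/major ellipse axis) in
   [0.40, 0.55] **and** circularity `4πA/P²` in [0.70, 0.80], both closed
   bands — otherwise the configured stromal fallback class (default
   lymphocyte). The perimeter in circularity comes from the sub-pixel
   marching-squares boundary polygon, cross-checked in tests against an
   independent 8-connected boundary-chain walk. Note the bands target
   rough real nuclei: ideal smooth ellipses at aspect 0.5 have circularity
   ≈ 0.84, so on clean synthetic scenes the rule rarely fires and the
   fallback dominates — which the tests exercise deliberately via
   constructed shape values.

Stratified FOV sampling fills four strata — single-dominant-class,
two-balanced-classes, bootstrap-vs-refined discordance, and a "difficult"
pool built from the top 5% of fields by low-confidence detections and by
extreme-size detections. The three named strata each target 16.7% of the
selection, rounded to the nearest integer, with the difficult pool
absorbing the residual (100 fields → 17/17/17/49); eligibility for the
first two strata uses a dominant-share threshold of 0.75 and a top-two
balance ratio of 0.75. When confidence columns are absent the difficult
pool falls back to uniform sampling with a warning.

## Anchor clustering

Within one field of view, annotations are agglomerated bottom-up on
similarity IOU with **complete (maximum) linkage**: two clusters may merge
only while the *minimum* cross-pair IOU stays ≥ t\* (default 0.25). A
merge whose union would contain two annotations from the same participant
is forbidden (distance ∞) — the participant meant two distinct nuclei.
Linkage is maintained incrementally with the complete-linkage
Lance–Williams update `sim(new, k) = min(sim(i,k), sim(j,k))`; since
complete-linkage similarity only decreases under merging, pairs already
below t\* are dropped outright, which keeps the algorithm near-linear on
sparse scenes. Determinism: initial singletons are ordered by
annotation id, merges take the highest current similarity with ties broken
by smallest cluster-id pair in creation order. Equivalence with an
exhaustive reference that re-scans all admissible pairs from scratch at
every step is asserted over hundreds of random scenes.

Each cluster is summarized by its **medoid** — the member box maximizing
summed IOU to the others (ties to the smallest annotation id) — so every
anchor proposal is a box a rater actually drew.

**Label matrix semantics.** Entry (anchor, rater) is the member's raw
label; "undetected" if the rater attended the FOV but placed no box at
that location; missing if they never attended. One subtlety: under
merge-blocking, a duplicate annotation seeds a *rival* cluster that
partitions the crowd, and the strict reading (any attending non-member
votes "undetected") floods genuinely well-detected nuclei with spurious
"undetected" votes — in simulation roughly a quarter of well-detected
nuclei were inferred as non-nuclei this way. We therefore treat a rater
whose box overlaps the anchor medoid at IOU ≥ 0.25 but was assigned to a
rival cluster as *missing* (their detection is real but its attribution
between the rivals is ambiguous), not "undetected". The strict behavior
remains available via `overlap_threshold=None`.

## Truth inference

Dawid–Skene latent-class model: anchor *i* has true state
`T_i ∈ classes ∪ {undetected}` with prior `p`; rater *j* emits labels
through a row-stochastic confusion `π_j` over
`classes ∪ {ambiguous, undetected}` (rectangular: "ambiguous" is emitted,
never true). EM config defaults: initial diagonal quality 0.7, 70
iterations, ε = 10⁻⁶ smoothing added to M-step counts to prevent
zero-probability lock-in. Each iteration runs the E-step first — so the
0.7 initialization is actually operative in the first posterior — then the
M-step; the class prior is seeded from observed label frequencies. The
observed-data log-likelihood is recorded at every E-step and is
non-decreasing (asserted on every test run). The iteration count is fixed
rather than convergence-based for exact reproducibility; an early-stop
tolerance can be layered on by reducing `n_iterations`.

With identical raters the first E-step is exactly majority voting (each
vote contributes the same log-odds). After fitting, EM re-weights raters
by their *estimated* reliabilities, so on a small fraction (≈0.1–1%,
concentrated on one-vote margins) of strict-majority anchors the fitted
model deliberately disagrees with plain majority vote; this is expected
estimator behavior, not a defect, and the test suite pins both facts: exact
equivalence at one iteration, ≥99% agreement at 70.

Click-approval inference reuses the same EM core with a binary label set
(clicked / not clicked) and returns the posterior probability that each
suggested boundary is correct.

**Anchor acceptance:** an anchor is a real nucleus iff (i) ≥ 2
pathologists contributed members and (ii) the pathologist-inferred truth's
argmax is not "undetected"; both rules are applied per multi-rater dataset
independently. Inference runs separately per rater group (pathologists vs
non-pathologists), which structurally guarantees no cross-contamination of
reliability estimates.

**Super-class aggregation** sums posterior probability over member
classes; "undetected" carries through, and rows remain normalized.

## Agreement analytics

- **Krippendorff α** (nominal) from the coincidence matrix; items with
  fewer than two labels are excluded; undefined (error) when no item has
  two labels. Implemented in-package because the computation must handle
  arbitrary missingness; verified against hand-computed coincidence counts
  and chance-level simulation.
- **Cohen κ** `(p_o − p_e)/(1 − p_e)` with missing pairs dropped; when
  `p_e = 1` (both raters constant, same label) κ is 1 if agreement is
  perfect, otherwise undefined. Cross-checked against scikit-learn.
- Verbal bands at the standard cut-points (≤0 poor/chance, then steps of
  0.2 up to near-perfect). Agreement values are reported in [−1, 1];
  display-scale (×100) fields are provided since published values are
  typically quoted that way.
- **Detection PR** by greedy one-to-one matching in decreasing IOU order
  at a configurable threshold (default 0.5); greedy agrees with the exact
  Hungarian matching on non-ambiguous scenes (tested). Recall counts only
  anchors in fields the participant attended.
- **Classification**: multiclass MCC and one-vs-rest AUROC averaged micro
  (pooled decisions) and macro (per-class mean); classes absent from the
  reference are excluded from the macro mean with a warning. On fixtures
  where errors concentrate in rare classes, micro > macro by construction.
- **Bootstrap CIs**: percentile intervals over 1,000 resamples by default,
  seeded. **Tests**: two-sided Mann-Whitney U (unpaired) and Wilcoxon
  signed-rank (paired) via scipy.
- **MDS**: classical principal-coordinates embedding of dissimilarity
  1 − κ (double-centering + eigendecomposition — deliberately classical
  rather than SMACOF), with Kruskal stress-1 reported; verified against
  scikit-bio's PCoA up to per-axis sign.

## Redundancy simulation

Anchors and the reference labels stay fixed; each realization retains k of
the 18 non-pathologist raters per field (uniform, without replacement, no
constraint on how many fields one rater keeps), masks the others' entries
to missing (a removed rater did not attend), re-runs EM on the thinned
matrix, and scores the inferred labels against the fixed reference. The
default score is the per-class agreement rate (plus an "overall" row);
MCC is available. Seeds derive counter-style from the master seed as
`SeedSequence([master, k, realization])`, so any single realization is
reproducible in isolation. Summaries report the median with a
bootstrapped 95% notch interval. On the default heterogeneous crowd the
median accuracy rises steeply from k = 2 to k = 6 and saturates beyond —
the curve the sweep exists to measure.

## Synthetic data

Scenes place elliptical nuclei (class-specific semi-axis and aspect-ratio
priors at 40× scale, e.g. lymphocytes ~22 px across and nearly round,
fibroblasts elongated at aspect 0.42–0.55) into a Voronoi region layout
whose cells are allocated proportionally to each region's nucleus load;
each nucleus lands in its home region with probability 0.93. A
configurable fraction of nuclei is constructively forced to touch a
neighbor (centers closer than the sum of minor semi-axes), exercising the
do-not-link machinery; non-touching pairs keep a minimum boundary gap
(default 3 px; separated-scene configs raise it to 18 px, comfortably
above 3σ of the coarse smoothing scale). Placement degrades gracefully
under unlucky draws (forced-touch → free placement → halved gap) before
declaring the density infeasible.

Rendering follows Beer–Lambert: nuclei emit hematoxylin density 0.9,
tissue a uniform eosin background 0.18, through the standard H&E stain
vectors with additive Gaussian OD noise; intensity `I = 256·exp(−OD) − 1`
is the exact inverse of the unmixing convention, so noise-free round trips
are tight.

Simulated raters detect each nucleus independently with class-specific
sensitivity, emit labels through a personal confusion matrix, jitter each
box edge with truncated Gaussian noise (boxes stay valid and inside the
field), and occasionally annotate a nucleus twice. The default crowd
mirrors the reliability structure the fusion model assumes:
non-pathologists with confusion diagonals 0.6–0.9 and depressed
fibroblast sensitivity (sparse, lightly stained nuclei are missed more),
pathologists at 0.85–0.97. Study-condition constants used throughout the
benchmarks: clustering threshold t\* = 0.25, 18 non-pathologists for the
redundancy sweep, 1,000-realization capability with 200 used in the test
suite, EM at 0.7/70.

**What the synthetic benchmarks do not show.** The generator reproduces
the *statistical* structure of multi-rater annotation (sensitivity,
confusion, jitter, duplicates) but not the *visual* difficulty of real
histology: no texture, chromatin patterns, staining artifacts, overlapping
tissue, or rater biases correlated across nuclei. Passing benchmarks
therefore validate the fusion machinery — clustering, EM, acceptance,
metrics — under its own model assumptions, not the field performance of
the suggestion pipeline on real slides, which requires real data.

## Problem sizes in the benchmark suite

Chosen as the package's own test conditions: clustering oracle equivalence
on 200 scenes of ≤8 boxes; do-not-link fuzzing over 1,000 crowds with
duplicate rates up to 0.3; threshold monotonicity on 50 scenes; EM
recovery at 500 anchors × 20 raters over 20 seeds; segmentation recovery
on 100 rendered 384×384 scenes; redundancy at k ∈ {2, 4, 6, 10, 18} with
200 realizations each; end-to-end recovery on 20 scenes with 15 raters.
`scripts/acceptance.py` re-runs the same computations at moderately
reduced replication (printed alongside each number as `n`).

## Known limitations

- The demotion step of constrained clustering is realized as
  merge-blocking; on adversarial exact-tie configurations other
  bookkeeping choices could yield a different (still constraint-valid)
  partition.
- Macenko unmixing assumes both stains are present with angular spread;
  near-monochrome images degrade gracefully but the recovered second stain
  is poorly determined.
- The average-precision summarization of detection PR curves is not fixed
  by convention here; the package exposes per-participant precision/recall
  and leaves AP definitions to the caller.
- Redundancy simulations reuse fixed anchors from the full crowd; very low
  k does not re-cluster, matching the study design it models (a fixed
  frame of reference) but not a from-scratch collection at low redundancy.
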