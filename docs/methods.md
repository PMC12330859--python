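# Methods

## The parcellation problem

Given co-registered 4D BOLD acquisitions from a cohort, the package divides a
seed structure (the neonatal thalamus in the motivating application) into k
functional territories.  Each seed voxel is described not by its location but
by its *connectivity profile*: the vector of Pearson correlations between its
time series and R target ROIs spread over the rest of the brain.  Voxels
whose profiles point in the same direction — that talk to the same places, in
the same proportions — are grouped by k-means under cosine distance.  A
winner-takes-all (WTA) baseline assigns each voxel instead to the single
merged lobe (temporal, parietal, frontal, occipital, limbic) with the
largest partial correlation.

## Functional connectivity

Per subject, the BOLD series is conditioned in a fixed order: the first 5
volumes are discarded (steady-state settling), each volume is smoothed with
a 3 mm FWHM Gaussian (sigma converted to voxel units per axis from the
affine; reflect boundary), every voxel series is low-pass filtered at
0.08 Hz, and z-scored (population SD).  The low-pass is a 4th-order
Butterworth run forward-backward (`sosfiltfilt`), so it is zero-phase and
the stopband attenuation doubles; the family and order are package defaults,
configurable.  Correlation is invariant to the z-score step — the pipeline
asserts this as a cross-check — but the step keeps intermediate volumes on
the scale FC is computed on.  When an analysis mask is supplied, the
temporal stages run only on in-mask voxels (the rest are zeroed); on long
acquisitions filtering the full grid would dominate runtime while
contributing nothing downstream.

FC of a seed voxel to an ROI is the **mean of voxel-wise correlations**:
Pearson r between the seed voxel and every ROI voxel, averaged over the ROI.
For z-scored series this equals a dot product with the ROI's mean z-scored
series, which is how it is computed.  This is deliberately *not* the
correlation with the ROI's mean raw series; that order is used only for
ROI-ROI matrices, which are defined on ROI-averaged time series.  Profiles
are Fisher-Z transformed (arctanh, with |r| clipped at 1 − 1e−7 so z stays
finite on degenerate synthetic inputs) before any averaging across subjects.

For the WTA baseline, each lobe's signal is the mean series over all voxels
of its ROIs; the partial correlation of a voxel with lobe l controls for the
other lobes by residualizing both series on them (with intercept) and
correlating the residuals.  Rank-deficient lobe designs are an error.

## Clustering

Cosine k-means is realized as spherical k-means: profile rows are
unit-normalized, centroids are renormalized means, assignment maximizes the
dot product.  Zero-norm rows are pre-assigned label 0 and excluded.
Initialization is k-means++ (on the unit sphere, where squared Euclidean
distance is an affine function of cosine distance, so Euclidean k-means++
seeding is the cosine seeding); the best of `n_init = 10` runs by the
objective Σ(1 − cos) is kept, with `max_iter = 300`, `tol = 1e-6`.  Empty
clusters are reseeded at the worst-fit point.  The objective is
non-increasing across Lloyd iterations and the run is deterministic given
the seed.

WTA is an argmax over the lobe partial correlations, ties resolving to the
earliest lobe in the fixed axis order (temporal first).

## Bootstrap consensus and uncertainty

*Subjects bootstraps* (default 40) each draw ⌈0.75·N⌉ subjects without
replacement, average their Fisher-Z profiles, and re-cluster.  *Timepoints
bootstraps* (default 10, over a fixed subset of 25 subjects) each draw
⌊0.75·t⌋ timepoints without replacement, preserving temporal order so the
low-pass structure survives, and recompute FC.  Ceil for subjects (never
empty at small cohorts), floor for timepoints — both conventions are fixed
and tested.

Replicates are aligned to a reference (the first member by default; an
external reference parcellation may be designated for cross-cohort runs) by
maximizing total voxel overlap over label permutations, solved exactly as a
linear assignment problem on negative overlap counts.  Overlap counts rather
than IoU are the default cost — the intent is to maximize agreement voxels —
with the matrix zero-padded square so ensembles with empty labels still
match.  The consensus takes the per-voxel majority label, ties to the
smallest label id (deterministic and order-independent).

Per-voxel uncertainty is the complement of the majority proportion,
U(v) = 1 − N_c*(v)/N_total ∈ [0, 1 − 1/N_total]: 0 where every replicate
agrees.  The scalar summary Ū sums U(v) over consensus-cluster voxels and
divides by the group's subject count so that groups of different size are
comparable.  (The source formulation of U(v) is typographically ambiguous
between a complement and a reciprocal of the proportion; the complement is
adopted because the normalized summary and the bounded [0, 1) rendering of
border uncertainty both require it.)

Variability across an ensemble is the coefficient of variation (sample
sd/mean) of the per-cluster IoU over all unordered replicate pairs, averaged
over clusters ("mean CoV of IoU").  Clusters empty in every member are
excluded and reported; a single replicate pair or a zero mean IoU is flagged
degenerate rather than silently reported as 0 or ∞.  Silhouette scores use
the cosine metric, matching the clusterer.  `select_k` tabulates both
bootstrap schemes plus silhouette mean ± sd over a k grid (default 2–7) and
deliberately names no winner: the choice of k is an analyst decision.

As a final cleaning step, connected components (26-connectivity) smaller
than 16 voxels are absorbed into a neighbouring cluster when more than half
of their face-adjacent outside neighbours carry one single other label.
Out-of-mask neighbours count in the denominator but can never dominate, so
components at the structure boundary are left alone.  The operation runs to
a fixed point (hence idempotent) and never introduces new labels.  Pruning
is applied after the consensus vote; a per-bootstrap variant is available.

## Reported metrics

* **Cluster profiles** — per ROI, the median FC inside each cluster per
  subjects-bootstrap, averaged over bootstraps, then z-scored across the ROI
  axis; |z| > 1 flags significantly connected/disconnected regions.  L/R ROI
  columns can be averaged first (the reporting convention).
* **Relative volumes** — cluster voxels over labelled seed voxels, mean ± sd
  (ddof 1) across bootstraps; rows sum to 1 per replicate.
* **Symmetry index** — mirror left labels across the mid-sagittal grid plane
  onto the right and count agreements, and vice versa; the mean of the two
  agreement rates.  Mirrored voxels landing outside the opposite mask count
  as disagreement.  Phantoms are constructed midline-aligned; real data must
  be in a midline-aligned template space.
* **Laterality** — Ri = mean FC(right seed → right ROIs) / mean FC(left seed
  → left ROIs); Rc the crossed pairing.  Signed FC by default (the ratio
  form near 1 is only meaningful on signed means; an absolute-value variant
  is a flag).  Midline ROIs are excluded.
* **Global seed connectivity** — mean |FC| per ROI over all seed voxels of
  all pooled subjects, bilaterally averaged per ROI pair; midline ROIs
  unmerged; no bootstrapping.
* **ROI-ROI connectivity** — per group, correlation matrices of ROI-averaged
  series, averaged over a fixed number of subjects; consecutive-group
  difference matrices (consecutive meaning adjacent in the declared group
  order, which is treated as opaque); a global scalar = mean |off-diagonal|.

## The synthetic phantom

The phantom plants everything the pipeline is supposed to find.  Two
hemispheric boxes (a convex stand-in for the thalamus) are split into k_true
contiguous sub-regions by Voronoi cells of farthest-point-sampled sites —
convexity of the box guarantees contiguity — mirrored across the mid-sagittal
plane when symmetry is on.  Disjoint ROI boxes ring the volume in bilateral
pairs with configurable lobe assignments.  Each ROI carries an independent
unit-variance white Gaussian source (two ROIs may share a source via
`roi_source_map`, used to test ROI-ROI structure); each seed voxel carries
the mixture of sources given by its sub-region's row of the nonnegative
`profile_matrix` (rows pairwise separated by ≥ 0.2 in cosine distance), plus
i.i.d. noise of standard deviation `noise_sd`.  Near sub-region borders the
mixing rows are blended linearly in the Euclidean distance to the nearest
voxel of another sub-region: 50/50 at the border face, pure at depth
`border_mix_width` + 1.  Blended voxels are flagged, and recovery scores
exclude them — right at a border the planted label is genuinely ambiguous.

Default conditions: 24³ grid of 2 mm voxels, TR 0.392 s, 600 timepoints,
k_true = 3 with 6 ROIs, noise_sd 0.5.  The reference studies
(`knit.studies`) fix the anatomy seed and scale up: truth recovery uses
k_true = 5, 10 subjects, 600 timepoints, unit noise and 40 bootstraps; the
KNIT-vs-WTA comparison uses four clusters of which two have mixed two-lobe
profiles (one sharing its lobes with dominant single-lobe clusters — the
configuration a lobe-argmax cannot represent as its own cluster — and one
mixing two otherwise unused lobes, whose internal WTA boundary is noise-
driven and therefore asymmetric), sharp borders, and noise_sd 2 so that
voxel-level noise rather than shared sampling error decides the WTA
competition.  Trend studies use three-cluster phantoms at 400–2400
timepoints with a handful of cohort replicates; problem sizes are chosen so
the whole suite runs in minutes on one core.

What the phantom does *not* emulate: hemodynamic autocorrelation (sources
are white; a common linear filter leaves correlation structure unchanged, so
the low-pass stage is validated separately on sinusoids), motion and field
artifacts, spatially correlated physiological noise, and age-dependent
signal models.  Passing tests therefore demonstrate the correctness of the
machinery — FC estimation, clustering, matching, voting, uncertainty and
metric formulas — under the generative model the method assumes, not
robustness to real-world confounds.

## Seeds and determinism

One master seed fans out to every stage through a fixed SeedSequence-based
derivation (`derive_seed(master, stream, ...)`), so any subject, bootstrap
or stage is reproducible in isolation and results do not depend on execution
order.  Reruns with the same config and inputs produce byte-identical tables
and voxel-identical label volumes; the run manifest records config,
checksums and package version.

## Numerical choices and degenerate inputs

Constant time series inside the analysis mask are an error (their
correlation is undefined), outside it they are zeroed silently.  Fisher-Z
clipping at |r| = 1 − 1e−7 is logged when triggered.  Grids must agree in
shape and affine to 1e−4 — registration is out of scope, and silently
resampling would hide errors.  k-means ties and vote ties have fixed,
documented tie-breaks; k = 1 is accepted by the clusterer (trivially one
cluster) though pipeline runs require k ≥ 2.  BOLD data are processed as
float64 regardless of file dtype.

## Known limitations

The mean-of-correlations FC order is quadratic in ROI size only through a
mean, so it is cheap, but it differs numerically from correlation-with-mean;
users comparing against other toolboxes should check which order those use.
The symmetry index requires a mid-sagittal grid plane (or half-voxel offset
handled by nearest-voxel reflection).  The WTA baseline inherits the lobe
definitions of the ROI set; with fewer than five populated lobe groups it
operates on those present.  Bootstrap ensembles hold all member label
vectors in memory, which is fine for seed structures (10³–10⁴ voxels) but
not intended for whole-brain parcellations.
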