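# Methods

## Scope

gliograph implements the analysis half of a resting-state connectomics
study of glioma cohorts: from per-subject ROI timeseries to thresholded
functional graphs, seven nodal metrics, and whole-brain / hemispheric /
lobar group statistics, plus a synthetic cohort generator that stands in
for patient data.  Voxel-level preprocessing (realignment, slice timing,
spatial normalization, smoothing), hemodynamic modeling and clinical-score
analysis are out of scope; inputs are assumed to be ROI-level series that
such a preprocessing chain would produce.

## Synthetic cohorts

### Covariance model

Each group's N-ROI spatial structure is a block correlation matrix over the
parcellation:

| pair type                           | parameter            | default |
|-------------------------------------|----------------------|---------|
| same hemisphere, same lobe          | `base_r_within_lobe` | 0.35    |
| same hemisphere, different lobe     | `base_r_within_hemi` | 0.02    |
| homotopic (left/right mirror)       | `base_r_homotopic`   | 0.50    |
| other cross-hemisphere              | `base_r_background`  | 0.02    |

This puts each hemisphere in a small-world-like regime — cliquish lobar
modules plus sparse long-range coupling — with strong callosal (homotopic)
mirroring.  The background default is kept at the within-hemisphere
inter-lobe level: a *larger* cross-hemisphere background is not a valid
correlation structure here (the global left-minus-right contrast mode would
get negative variance, making the matrix indefinite).  A constructed matrix
is checked for positive definiteness; an indefinite one is repaired by
clipping eigenvalues at 1e-8 and rescaling to unit diagonal (logged), and
the build fails if the repair moves any entry by more than 0.05.

Group effects are signed increments on blocks of the left (ipsilateral,
tumor-bearing) or right hemisphere:

* **LGG**: `delta_left_global = +0.06` on left inter-lobe pairs and
  `delta_local = -0.10` on left within-lobe pairs.  Together these encode a
  shift from locality to global integration, which maps onto the target
  signature: left global efficiency up, left local efficiency and
  clustering down.  A uniform inter-lobe boost alone is *non-monotone* in
  mean clustering (new neighbors arrive already interconnected at the
  boosted rate), so the within-lobe attenuation is what makes the
  clustering decrease robust.
* **HGG**: `delta_right = -0.04` on all right intra-hemispheric pairs,
  the remote-disconnection pattern; it lowers right degree and cost.
* **HC**: all deltas zero (enforced).

When an effect carries a tumor-location label, the two left-hemisphere
deltas are restricted to pairs involving that lobe, and subjects generated
under it carry the label; this drives the lobar analysis.

Effect magnitudes are calibrated so that at the default cohort sizes
(30 LGG / 30 HGG / 20 HC) the planted signatures are recovered essentially
always, with calibration done analytically: after band-pass filtering the
Fisher-z sampling sd is approximately `1/sqrt(beta*T)` with `beta` the kept
band fraction (0.45 at the defaults), and an edge-probability calculation
per block then predicts each metric's shift.  The deltas are design
constants of the generator, not estimates of clinical effect sizes.

### Temporal model

Subject data are stationary Gaussian AR(1) series:
`x_t = phi*x_{t-1} + sqrt(1-phi^2)*e_t`, `e_t ~ N(0, Sigma)`, with `x_0`
drawn from the stationary law.  The marginal spatial covariance equals
`Sigma` exactly and every series has lag-1 autocorrelation `phi`
(`ar_coeff`, default 0.3 — moderate smoothness at TR 2.5 s).  This is the
simplest process with fMRI-like low-frequency content inside the
0.01–0.1 Hz band; it has no hemodynamic response, no motion or physiological
artifacts, no spatial noise gradients and no non-stationarity.  Passing
tests on these cohorts therefore demonstrates correctness of the analysis
given its statistical assumptions, not robustness to real-data artifacts.

Ages are Gaussian (means 48/40/62 years for HC/LGG/HGG, sd 10); tumor sizes
(product of perpendicular diameters, cm²) are Gaussian (mean 12, sd 6)
truncated above 0.5 — these exist only to exercise the confound screen.
Tumor-location labels default to the study's distribution over frontal /
temporal / parietal / insular (no occipital).  Per-subject seeds are
`master_seed + crc32(subject_id) mod 2^31`, so any subject can be
regenerated without replaying the cohort, and the whole cohort is a pure
function of `(parcellation, spec, effects, master_seed)`.

## Connectivity

Denoising is detrend → optional confound regression (intercept always
included, rank-checked) → hard spectral masking keeping `low_hz ≤ f ≤
high_hz` on the discrete grid (deterministic, idempotent; ringing of a
brick-wall filter is accepted and documented rather than hidden behind an
unstated filter family).  Correlations are clipped at ±(1 − 1e-7) before
`atanh` so degenerate inputs stay finite (|z| ≤ 8.4); zero-variance columns
(detected with a relative tolerance, since a constant stored in floats
carries rounding noise) produce a logged warning and a zeroed row/column.
`T_effective = T`: no scrubbing, since outlier censoring belongs to the
excluded voxel-level preprocessing.

## Graphs and metrics

The edge rule treats the threshold as a one-sided test statistic on the
Fisher-z scale: `z_stat = atanh(r)*sqrt(T_eff - 3) > 2` **and** one-sided
`p = 1 - Phi(z_stat) < 0.05`.  Reading the threshold as raw Fisher z
(`atanh(r) > 2`, i.e. r > 0.964) would produce near-empty graphs and make
the paired p-condition meaningless; the statistic reading makes both
clauses meaningful and sample-size aware.  With defaults and `T_eff ≥ 8`
the p-clause is implied by the z-clause (one-sided p at z_stat = 2 is
0.0228), which is asserted in tests.  Negative correlations never create
edges by default (`positive_only`); a two-sided variant exists for
sensitivity analysis.

Metrics are computed on the boolean adjacency with hand-written BFS /
Brandes algorithms (numba-compiled inner loops with a pure-numpy fallback;
both paths are the same algorithm).  Conventions for degenerate cases,
chosen to keep every metric finite and group means well-defined:

* isolated nodes: path length 0, clustering 0, local efficiency 0;
* path length averages over *reachable* nodes only — the harmonic treatment
  of disconnection already lives in global efficiency;
* clustering and local efficiency are 0 for degree < 2;
* betweenness is normalized by (n−1)(n−2)/2 so it is a ratio in [0, 1].

Hemispheric networks are rebuilt from the hemisphere's z submatrix rather
than cut out of the whole-brain graph; with a value threshold the two
constructions coincide (tested).

## Group statistics

The normality gate runs Jarque–Bera (`JB = n/6*(S² + (K−3)²/4)`, biased
moment estimators, chi-squared 2 df) on both samples at
`alpha_normality = 0.05` (the gate's alpha is a free choice; 0.05 is the
conventional default).  Both pass → two-tailed pooled-variance Student t
(pooled, not Welch, matching the named test; Welch available by flag);
otherwise two-tailed Mann–Whitney U, exact enumeration when
`n_a*n_b ≤ 400` without ties, tie-corrected normal approximation otherwise.
Groups smaller than 8 cannot be gated (JB needs n ≥ 8) and route to
Mann–Whitney.  An all-identical pooled sample yields p = 1 by convention,
logged.  The left-vs-right contrast is paired per subject (each subject
contributes both hemispheres); its non-normal branch is the Wilcoxon
signed-rank test, the paired analogue of Mann–Whitney.  An unpaired variant
is available by flag.

FDR families (BH step-up, statsmodels): hemispheric — the seven metrics
within each (scope, pairing); lobar — the nodes of a lobe within each
(lobe, metric, pairing); connectograms — the N−1 targets of a seed.  The
family choices are recorded in the output metadata (scope/pairing columns);
nothing in the method fixes them uniquely, and per-metric node families
match how lobar results are tabulated.  Note that BH *adjusted values* are
not idempotent (re-adjusting adjusted p-values can change them); only
monotonicity and domination of raw p are guaranteed and tested.

The lobar design restricts each patient group to subjects carrying the
lobe's tumor-location label and tests every node of that lobe in both
hemispheres on the whole-brain network, skipping comparisons with fewer
than 3 subjects a side (logged).  Under the null, each BH family still
rejects *something* with probability ≈ alpha (Simes), so a multi-lobe null
cohort is expected to show occasional stray significances at the family
rate — a property of FDR control, demonstrated by a dedicated test.

Connectograms use a one-sample two-sided t-test of the group's Fisher z
against zero per target — the standard second-level seed analysis; the
choice of second-level estimator is otherwise unconstrained.  Significant
lobar nodes seed the pipeline's connectograms, and significant-connection
counts are compared across groups with the two-tailed Student t.

The confound screen standardizes each network-mean metric and reports
Pearson correlation, covariance and regression slope against age and tumor
size over patients.  Covariance is computed on range-normalized variables
so it is unit-free and bounded (z-scoring both variables would just
reproduce the correlation); rows are flagged above |corr| 0.4 or |cov| 0.2.
A constant covariate is reported as undefined rather than silently dropped.

## Pipeline

`run_all` executes simulate → connect → graph → analyze over one run
directory; every intermediate is plain TSV (floats printed at %.10g), each
stage re-checks its inputs and fails naming the missing file, and a
run manifest records config, master seed, package versions and a sha256 per
file.  Two runs with the same config are hash-identical.

## Problem sizes used by the test suite and acceptance script

Deep Monte-Carlo checks are scaled to what they measure: calibration
properties (null rejection rate, p-uniformity) use reduced cohorts
(20 ROIs, 10 subjects/group, T = 60) because test calibration is
size-free; planted-effect recovery runs at the full study scale (136 ROIs,
30/30/20, T = 160) over 100 seeded replicates in the test suite and 40 in
the acceptance script; lobar specificity uses frontal-only cohorts
(20 HC / 15 frontal LGG) at full ROI count.  Metric correctness is checked
against two independent oracles — a Floyd–Warshall + exhaustive
path-enumeration implementation and networkx — on hundreds of random
graphs at 1e-10.

## Known limitations

* The generator's block-uniform covariance and AR(1) noise omit every
  real-data nuisance the excluded preprocessing handles; the package's
  guarantees are about the analysis, not about robustness to artifacts.
* Planted effect sizes are calibrated for detectability at study scale,
  deliberately larger than what patient data would show.
* Negative-correlation edges, weighted-graph metrics, proportional-density
  thresholding and community detection are out of scope.
* The paired/unpaired choice for left-vs-right, the FDR family for the
  lobar tables and the connectogram second-level estimator are documented
  package choices among defensible alternatives, switchable where a flag is
  noted.
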