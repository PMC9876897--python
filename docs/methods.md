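# Methods

## Scope

`lexload` implements a searchlight-RSA pipeline for three-way bilingual
reading designs (Chinese word / English word / Chinese pinyin, 40 trials
each): behavioral dissimilarity matrices, voxel-wise partial-rank
correlation maps on trial-wise beta volumes, cluster-extent group
inference, the cognitive-load statistic, cross-language overlap,
LOSO-SVR language-type decoding with absence-rMSE recursive feature
elimination, and load–behavior association. Upstream steps — acquisition,
preprocessing, first-level GLM beta estimation, embedding training — are
out of scope: beta volumes, unit decompositions and embedding vectors are
inputs. Because subject-level imaging data for this design are typically
confidential, a first-class synthetic-data generator produces every input
the pipeline consumes, with known ground truth for recovery testing.

## Behavioral dissimilarity

Unit-overlap dissimilarity between multisets `a`, `b` is
`1 − s/(|a|+|b|)` with `s` the multiset intersection (per-token minimum
counts). This reproduces the two hand-checkable reference pairs exactly
(0.818 for a 6/5-unit pair sharing 2 units; 0.917 for a 6/6-unit pair
sharing 1). Decisions:

* shared units are counted once per matched pair — a unit appearing
  twice on one side and once on the other contributes one match;
* tokens are compared by exact string equality after Unicode NFC
  normalization (decompositions arrive as text; how tone marks are
  tokenized is the data-preparation step's choice);
* the diagonal is forced to 0 although the formula gives 0.5 for a
  self-pair: diagonals never enter any analysis and the zero-diagonal
  convention keeps the matrix a valid RDM.

Semantic dissimilarity is `1 − cosine`, range [0, 2]. Embeddings are
consumed, never trained; the typical provenance (300-d skip-gram vectors,
window 5) is metadata of the input, not of this package.

## Searchlight

Spheres are boundary-inclusive (center-to-center mm distance ≤ radius,
default 6 mm), matching the common searchlight convention and the exact
lattice count (123 offsets with i²+j²+k² ≤ 9 on a 2-mm grid). Spheres
with fewer than 10 in-mask voxels are skipped (NaN) — rank correlations
on smaller patterns are unstable; the threshold is configurable.

The low-variation filter drops voxels with across-trial SD < 1/8 × |mean|.
The variation measure (SD of trial betas) is this package's reading of
an underspecified rule and is logged as such.

Neural RDM entries are `1 − Spearman ρ` between trial patterns (ranks
across voxels, average ranks on ties). The component map comes from the
partial Pearson correlation of the rank-transformed neural lower
triangle with the rank-transformed target RDM given the other two
component RDMs, computed by residual regression (QR); a test verifies
equivalence with the inverse-correlation-matrix route to 1e-10. The
one-tailed p uses the t approximation with df = m − 2 − k (m = n(n−1)/2
pairs, k = 2 controls). The RDM pairs are not independent, so this p is
approximate: measured empirically, the voxel-wise false-positive rate at
α = 0.05 is ≈ 0.055 on pure noise. A permutation option (joint
row/column shuffling of the neural RDM) exists for small runs.
Fisher r-to-z (`atanh`) is applied to every coefficient; |r| ≥ 1 clamps
to ±(1 − 1e-7) with a warning.

## Group inference and loads

Group maps are voxel-wise one-tailed one-sample t tests (H1: mean z > 0)
over subjects with data (≥ 3 required per voxel). Cluster-extent
thresholding keeps suprathreshold (p < α, default 0.05 uncorrected)
connected components of size **strictly greater** than the minimum
(default 10 — a literal reading of "cluster size > 10", applied
identically at subject and group level). Connectivity defaults to
18 (edge-connected), configurable among {6, 18, 26}.

Cognitive load = Σ z over a subject's significantly positive voxels;
the voxel count is returned alongside (validation variant). Loads are
non-negative by construction and exactly zero on empty masks.

Overlap maps are voxel-wise ANDs of two significance masks with per-ROI
counts; the reported "peak" is the max-statistic voxel when a statistic
map is supplied, else the centroid snapped to a member voxel (the peak
definition is not standardized; this choice is recorded here).

The subsample-stability check recomputes group-mean loads on random
subject subsets and Pearson-correlates the 9 (condition × component)
cell means with the full sample. The permutation extent test uses the
difference in group-map significant-voxel extent as its statistic (the
statistic is an assumption, flagged in the output dict) with label
shuffling and p = (1 + #null ≥ observed)/(1 + n_perm).

## Decoding

Features: per sample (= one condition of one subject), the sum of the
subject's z map inside ROI ∩ component mask for each (ROI, component).
The component masks are group significance masks computed from
**training subjects only**, combined across conditions by union (the
combination rule is an assumption of this implementation); the held-out
subject's features use the same training-derived mask, and a mutation
test asserts that corrupting held-out maps changes neither masks nor
training features.

SVR uses a linear kernel, C = 1, ε = 0.1, features standardized on
training folds only (hyperparameters are unstated in the design this
emulates; linear + default regularization keeps the model interpretable
under RFE and deterministic). Regression outputs snap to the nearest
valid label, ties toward the lower label — for a pair this is the
midpoint threshold.

RFE: absence-rMSE of a feature is the leave-one-sample-out rMSE of the
model refit without it (higher = more important). Features are ranked by
descending absence-rMSE (ties broken by name for determinism), features
whose absence lowers the error below the full model are flagged, then
all features are removed one by one in ascending importance with the
negative rMSE recorded at each remaining-feature count. The knee of that
curve (maximum perpendicular distance from the chord joining the
endpoints, on min-max-normalized axes) selects the count; a flatness
tolerance below which "no informative knee" is reported guards the
degenerate all-noise case.

## Load–behavior statistics

The two-way repeated-measures ANOVA uses the classical within-subject
decomposition (subject, condition, component, interaction strata; each
effect tested against its subject-interaction error term). No sphericity
correction is applied by default — a Greenhouse–Geisser option exists
behind a flag. Post hoc contrasts are paired t tests between components
within each condition, Bonferroni-corrected over the pairwise family
(family size recorded in the output).

Adjusted RT removes a per-subject additive offset estimated from a model
with a fixed condition effect and sum-to-zero subject effects; in the
balanced complete case this equals subject-mean centering plus the grand
mean. Subjects observed in fewer than two conditions are dropped with a
warning.

The load–RT association is, per (condition, component), the partial
Pearson correlation across subjects of the cell's load with that
condition's adjusted RT, controlling the other two components' loads in
the same condition. The control set is configurable and labeled as an
assumption in every output; the Bonferroni family defaults to 3 (the
components within a condition) and is always recorded.

## Synthetic data

The generator emulates the study design: 3 conditions × 40 trials,
2-mm isotropic voxels, a 20³ grid, a toy atlas of up to 30 cubic
5×5×5-voxel regions, and a behavioral table. Its defaults are the
emulated conditions, not tuning knobs.

**Stimuli** have unit multisets of sizes 3–8 over a 30-symbol alphabet
per condition (so pairwise overlap varies), and unit-norm embeddings
drawn from a per-condition cluster center plus noise; items are
guaranteed distinct or an error names the required alphabet size.

**Planted geometry.** For each (region, condition, component) with
effect size r > 0, the target behavioral RDM is embedded by classical
(Torgerson) multidimensional scaling into min(10, n−1) latent
dimensions — deterministic, with negative eigenvalues clipped, which is
the rank-preserving fallback for non-Euclidean RDMs. Each in-region
voxel receives a random linear readout of the latent coordinates
(unit-variance per voxel), mixed with white noise:
`pattern = w·signal + (1−w)·noise`. The weight `w` is calibrated
empirically — 200 Monte-Carlo draws per point of an 11-point weight
grid, curve forced monotone, inverted by interpolation — so the expected
Spearman correlation between the local neural RDM and the target RDM
tracks r to about ±0.05. The construction's ceiling is ≈ 0.8 (finite
voxel count plus the cosine-vs-distance mismatch of correlation-based
RDMs on an MDS embedding); requests above the ceiling clamp to pure
signal with a logged warning. When several components are planted in the
same (region, condition) the signals add and the residual noise weight
is floored at 0.05; calibration is exact only for single-component
planting. Out-of-region voxels, and all other conditions' trials, are
pure noise (SD = `noise_sd`). Per-subject effect sizes are jittered by
`subject_sd` (default 0.05) and clipped to [0, 1].

**Null geometry.** The analysis mask is the union of the atlas regions
and 20 pure-noise islands of exactly 10 voxels each (a 2×2×3 box minus
two corners; every pair of island voxels is within 3 voxels, so each
island voxel's 6-mm sphere is exactly the island — a valid searchlight
at the 10-voxel minimum). Because searchlight spheres overlap almost
completely within a compact neighborhood, a contiguous noise volume
behaves as a single correlated unit whose group-level excursions can
flood a map; splitting the noise volume into many small, mutually
distant islands makes the effective number of independent spatial units
equal the island count. An island that crosses threshold entirely forms
a 10-voxel cluster, which the "extent strictly > 10" rule removes —
exactly the scale of noise that rule exists to discard; the voxel-wise
(pre-cluster) false-positive rate is unaffected and is what the null
calibration test measures. `region_gap_voxels ≥ 4` keeps spheres
centered in one structure from touching another (no signal bleed); the
default gap of 1 packs regions densely for the demo configuration, where
one-plane bleed between adjacent structures is accepted and documented.

**Behavior.** Reaction times are log-normal with condition geometric
means 968 / 1182 / 1497 ms (Chinese word < English word < pinyin, the
ordering the emulated design reports), subject offsets of SD 0.10 and
trial noise of SD 0.20 on the log scale; accuracy is the mean of 40
Bernoulli(0.98) trials (ceiling by design, so accuracy is not modeled
downstream). Age-of-acquisition groups split subjects 45% early / 55%
late, mirroring the emulated cohort's 23/28 ratio.

**Problem sizes.** The default configuration uses 20 subjects — chosen
as this package's desk-scale default; the emulated cohort is larger
(n = 51) and nothing in the code depends on the smaller default. Tests
use 3–20 subjects depending on what the property needs.

**What the generator does not emulate:** BOLD time series, HRF
convolution, head motion, physiological noise, spatial autocorrelation
of scanner noise, anatomical variability, and real atlas geometry.
Passing tests therefore demonstrate the *pipeline's* correctness and
statistical calibration on idealized inputs, not robustness to real
acquisition artifacts.

## Determinism and degenerate inputs

Identical config + seed reproduce datasets bit-for-bit (single
`numpy` Generator, fixed iteration order). Constant searchlight patterns
give NaN map entries; all-NaN spheres are skipped and logged; a
constant RDM makes rank correlations undefined and is reported as
missing with a warning; zero across-subject variance yields ±inf t
sentinels (p = 0 for positive means, p = 0.5 for all-zero maps);
residuals explained by controls to numerical precision (≤ 1e-8
relative) are treated as exactly zero partial correlation. Collinear
control RDMs raise an error naming the problem.

## Known limitations

* The parametric p for RDM correlations ignores the dependence among
  the n(n−1)/2 pairs (slightly anti-conservative, ≈ 0.055 at nominal
  0.05); the permutation option is exact but slow for whole volumes.
* Planted effect sizes above ≈ 0.8 are not attainable by the
  MDS-plus-readout construction and clamp to the ceiling.
* Cluster-extent thresholding with uncorrected voxel p controls neither
  voxel- nor cluster-level family-wise error; it reproduces the emulated
  design's inference, not a recommendation.
* The 3-class decoder treats ordinal integer labels as a regression
  target; pairwise runs are the primary read-out.
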