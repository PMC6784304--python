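# Methods

`handoverid` asks how much a short hand-over motion reveals about the person
performing it. The observable is the joint-angle time course of one right
hand during one hand-over trial: 20 rotational degrees of freedom (two at
each digit's basal joint, one at each of the two more distal joints, five
digits), sampled at `dt` seconds per step. Global hand translation and
rotation are deliberately excluded — absolute pose varies with seating and
posture and mostly carries noise about the question of interest.

Three factor groups compete to explain trajectory variation:

1. **participant identity** — who moved;
2. **experimental condition** — five binary factors crossed in a full 2^5
   factorial (platform present/absent, big/small beaker, direct/indirect
   hand-over, full/empty content, left/right giver), each condition repeated
   `replicates` times per pair in randomized order;
3. **participant properties** — physical/cultural fields and Big Five
   personality scores, constant per person.

The pipeline quantifies each group's grip on the trajectories:
DTW dissimilarities → nonmetric MDS → (a) supervised LVQ classification under
two cross-validation schemes, (b) unsupervised SOM coding followed by MANOVA
and mutual-information analysis.

## Synthetic study generator

The original motion-capture recordings are not publicly deposited, so the
package ships a generator that emulates their *statistical structure*; all
downstream stages also accept real joint-angle exports in the documented
text format.

Per (trial, role) the generator sums, in radians:

* a smooth reach–grasp–release base template per channel (Gaussian bell per
  channel, giver acting early in the trial, receiver late, distal joints
  lagging proximal ones);
* an **identity signature** drawn once per participant: constant channel
  offsets (scale `sigma_identity`) plus bell/sine shape coefficients (scale
  `0.5·sigma_identity`). Offsets dominate deliberately so the signature
  survives the temporal inversion caused by the giver-side factor;
* **condition effects**: the giver-side factor inverts the whole time
  course (a side switch mirrors the movement geometry); the other four
  factors add signed per-factor channel patterns (scale `sigma_condition`)
  with bell or half-sine time profiles;
* a **trait effect** linear in standardized profile fields (scale
  `sigma_trait`). Standardization uses fixed reference means/scales matched
  to the sampling distributions of the profile generator, so a trajectory is
  a deterministic function of (seed, trial, profile, role) without needing
  cohort statistics. Binary fields (gender, health) enter as ±1; profession
  is excluded (unordered categories have no linear encoding);
* i.i.d. Gaussian noise (`sigma_noise`), then a smooth monotone time warp
  whose sup-gradient is bounded so monotonicity is guaranteed
  (`warp_jitter` < 1), making DTW alignment non-trivial.

Trajectory length is drawn per trial from `t_range` (default 80–120 samples
at `dt` = 0.01 s, i.e. 0.8–1.2 s of movement — a plausible reach-and-release
duration; no sampling rate or duration is prescribed by the study design,
so these are package choices).

Defaults encode the hierarchy under study: `sigma_identity` 0.6,
`sigma_condition` 0.25, `sigma_trait` 0.0, `sigma_noise` 0.08,
`warp_jitter` 0.08. `sigma_trait` defaults to zero because the central
empirical finding this package operationalizes is that participant
properties have no influence on the trajectories separable from identity;
positive values are available for power exploration.

Tracking failure is modeled as a per-trial Bernoulli flag, not corrupted
data — failed trials are discarded, not repaired. `failure_rate` applies to
the pairs listed in `failing_pairs` and `base_failure_rate` (default 0) to
all others; `GeneratorConfig.study_scale()` reproduces the full layout of
5 pairs (10 participants) in which the last pair fails completely, so the
validity filter retains 8 participants. The filter excludes any participant
whose failure fraction exceeds `failure_threshold` (default 0.5) and drops
all trials involving an excluded participant (a failure confuses the two
right hands, invalidating the trial for both).

What the generator does **not** emulate: joint-limit constraints, kinematic
coupling between digits, velocity profiles of real reaches, marker occlusion
artifacts, or any biomechanically validated hand model. Passing tests
therefore show that the *analysis chain* recovers a planted effect hierarchy
of realistic shape — not that it would behave identically on real captures.

## DTW dissimilarities

The local cost between two time points is the unsquared Euclidean norm of
the 20-channel angle difference (units: radians), accumulated over monotone
warping paths with unit diagonal/horizontal/vertical steps and both
endpoints anchored. No band or slope constraint is applied by default; an
optional Sakoe–Chiba half-width is exposed for speed. Accumulated cost is
not normalized by default; the optional normalization divides by
T_a + T_b. Channels enter in raw radians; a pooled per-channel z-scoring
switch exists for data with heterogeneous channel scales. The matrix is
computed on the upper triangle only, so symmetry and the zero diagonal hold
exactly by construction. The inner loop is JIT-compiled (numba).

## Nonmetric MDS

Kruskal's normalized stress-1,

    stress1 = sqrt( Σ_{i<j} (d_ij − d̂_ij)² / Σ_{i<j} d_ij² ),

with configuration distances d and disparities d̂, is minimized by
alternating (i) monotone regression — the least-squares non-decreasing fit
of the configuration distances in the rank order of the input
dissimilarities, via pool-adjacent-violators, ties handled by Kruskal's
primary approach (tied dissimilarities mutually unconstrained, implemented
by sub-ordering ties by distance) — and (ii) a SMACOF/Guttman majorization
step toward the disparities. The default start is classical (Torgerson)
scaling; termination when the stress decrease falls below `tol_fun` OR the
maximum coordinate change falls below `tol_x` OR `max_iter` is reached
(defaults 1e-4 / 1e-4 / 200, one replicate). A step that would increase
stress-1 is rejected and iteration stops, so the accepted-iteration stress
sequence is non-increasing by construction. Embeddings are defined only up
to rigid motion; all comparisons in tests use inter-point distances or
Procrustes-style alignment.

Requested dimensionalities default to {1, 2, 3, 20}: 1–3 feed the
mutual-information analysis and visualization, 20 feeds classification and
the SOM/MANOVA stage.

## LVQ classification and cross-validation

LVQ1 with prototypes initialized at class-conditional means plus a small
seeded jitter; the winning prototype is attracted to matching-label samples
and repelled otherwise, learning rate decaying linearly. One prototype per
class by default. Prediction is nearest-prototype (Euclidean), ties to the
lowest prototype index.

Classification consumes the 20-dimensional projection. This is a deliberate
choice: with 8 participants × 2 roles the data form ~16 clusters, and a
3-dimensional projection (stress ≈ 0.17 at full scale) demonstrably merges
some of them — even a nearest-neighbour rule on the 3-D coordinates errs
~12% where the raw DTW matrix and 10/20-D projections support error-free
identification. Three dimensions remain the visualization default.

Two fold schemes: *trialwise* (seeded near-equal random folds over trials,
default 8) tests recognition of a factor for known participants;
*participantwise* (one fold per participant) tests generalization to an
unseen person. Each held-out fold is scored by its error fraction and the
asymptotic significance (chi-square test of independence, no continuity
correction) of the true × predicted cross-tabulation; a table with a single
row or column yields p = 1 with a degeneracy flag — this happens routinely
in participantwise folds, where the true label is constant within a person.
Folds whose training complement lacks a class are skipped and logged. The
report carries fold means and the fold count per factor.

A structural caveat the tests document: under leave-one-participant-out
with a binary trait balanced across the cohort, the training set is always
biased *against* the held-out person's trait value, so "no recognition"
manifests as error well above zero with degenerate significance — not as a
clean 50%. Chance-level claims are therefore tested at the participant
level (majority vote per person, binomial against 1/2, pooled over seeds).

## SOM coding

An eight-axis map with two units per axis: 2^8 = 256 units. With two units
per axis the lattice is the {0,1}^8 hypercube; inter-unit lattice distance
is Hamming distance and the neighbourhood function is Gaussian in it (a
hexagonal arrangement is not realizable with two units per axis — this
reading is deliberate). Classic online training: per sample, the
best-matching unit (BMU) and its lattice neighbours move toward the sample;
learning rate and radius decay linearly (defaults: 10 epochs, lr 0.5,
radius 2.0). Each trajectory is coded by its BMU's 8-tuple position
(row, column, plane, cube, tesseract, penteract, hexeract, hepteract),
binary 0/1, which the MANOVA consumes as numeric dependent variables.
Units are stored in lexicographic coordinate order so distance ties resolve
to the lexicographically smallest tuple.

Under cross-validation the coding of each fold comes from a map trained on
its complement. For the per-fold MANOVA, the fold-trained map codes *all*
trials: a held-out fold contains one participant only, so a participant
term is estimable only on the full coded set.

## Mutual information

Histogram ("descriptor") estimation in two passes: descriptors are fixed
per variable first (categorical: one cell per category; continuous:
Sturges-style ceil(1 + log2 n) cells over the sample range; constant
samples: one cell, zero entropy), then every pairwise estimate reuses them.
The plug-in estimate uses base-2 logarithms (bits) and is corrected by the
first-order Miller–Madow bias term (Rx−1)(Ry−1)/(2 N ln 2), with Rx, Ry the
occupied marginal cell counts — the package's reading of an "N-unbiased"
histogram estimate. The uncorrected estimate is non-negative and satisfies
I(x, x) = H(x), so the matrix diagonal dominates each row; the corrected
estimate can dip slightly below zero for independent variables, which is
expected behaviour of bias-corrected estimators. The MI matrix covers
participant properties, identity, the five condition factors, and every
projection component at dimensionalities 1/2/3/20; the heatmap colours
cells by the percentile rank of their value.

## MANOVA

The 8 binary BMU coordinates are the responses of a multivariate linear
model; terms are categorical (reference coding) or numeric regressors.
Per term, the hypothesis matrix H is the residual-SSCP difference between
the model without the term and the full model (Type II; the balanced
synthetic designs make the SS types coincide), E is the full-model residual
SSCP, and the eigenvalues of E⁻¹H yield Pillai's trace, Wilks' lambda, the
Hotelling–Lawley trace and Roy's largest root, with the standard
approximate-F transforms (Rao's F for Wilks; McKeon's approximation — the
SAS convention — for Hotelling–Lawley; an upper-bound F for Roy). With a
1-dimensional response all four reduce exactly to the one-way ANOVA F.
Fitting uses least squares via a rank-revealing solver, so rank-deficient
designs are handled: a term adding no column space beyond the rest of the
model gets q = 0 and p = 1. A singular error matrix raises an error naming
the offending response columns; the pipeline pre-selects a maximal set of
response columns whose residuals are linearly independent.

Backward model reduction repeatedly drops the candidate term with the
largest Wilks p ≥ α (worst case over folds; ties broken by candidate
order) until every retained term is significant in every fold or none
remain. `fixed_terms` stay in the model without being candidates. This
distinction matters scientifically: in a properties-only model the
participant-constant traits proxy identity and many survive (with 8
participants at most 7 independent property regressors fit beside the
intercept — the degrees of freedom between participants); with participant
identity held fixed, every participant-constant trait is completely
redundant and falls out immediately. The pipeline reports the former
(the classical table shape); the hierarchy battery asserts the latter.

## Pipeline, seeding, problem sizes

A single global seed is fanned out through a counter-based scheme (CRC32 of
stage/entity keys into a `SeedSequence`) so stages draw independent but
reproducible streams; re-running with the same configuration reproduces
every numeric artifact bit for bit. All tabular outputs are delimited text
with header rows; figures are side artifacts only. The run manifest records
the configuration, its hash, the seed and library versions.

The full-size default (4 pairs × 96 trials × both roles = 768 trajectories,
T ∈ [80, 120]) runs the complete pipeline in roughly two minutes on one
CPU. The repeated hierarchy battery uses a reduced size per seed — 4 pairs
× 32 trials (one replicate), T ∈ [40, 60], 256 trajectories — which keeps
ten seeded runs near one minute while preserving the full participant
structure.

## Known limitations

* Phenomenological trajectories: no inverse kinematics, no marker-level
  simulation, no joint-limit enforcement.
* The DTW accumulated cost is treated strictly as a dissimilarity; it is
  not a metric (the triangle inequality can fail), which nonmetric MDS
  tolerates by design.
* The stress minimizer is SMACOF-based; equivalence with other NMDS
  implementations holds at the level of the stress-1 criterion, not
  iterate for iterate.
* Approximate-F p-values for Roy's largest root are upper bounds
  (anti-conservative), as in standard software.
* With eight participants, property effects are structurally confounded
  with identity; the package quantifies this (see the MANOVA section)
  rather than resolving it — resolving it would need many more
  participants.
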