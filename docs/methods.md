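# Methods

## The model

A metabolic covariance network is a group-level graph over a fixed set of
brain regions. For each pair of regions, the edge weight is the correlation
of regional tracer uptake measured **across the subjects of one group** —
one network per group, never per subject. This package builds such networks
from either regional uptake matrices directly or from volumetric images plus
an integer parcellation, and then characterizes and compares their topology.

The full chain is:

1. **Preprocessing** (images mode): subjects with a right-sided focus are
   mirrored across the left-right axis so all foci are ipsilateral;
   isotropic Gaussian smoothing (FWHM 5 mm by default, `sigma = fwhm /
   (2 sqrt(2 ln 2))` per axis in voxel units); division by the mean
   intensity of a cerebellar reference region; label-wise voxel averaging
   into a subjects × regions matrix. Images are assumed to already share a
   common space and voxel grid — co-registration and template normalization
   are upstream of this package.
2. **Network construction**: the n × n matrix of partial correlations
   (each pair controlling for all remaining regions), and separately a
   seeded analysis of plain Pearson correlations between the insula and
   every other node with exact t-based p-values (`t = r sqrt((n-2)/(1-r²))`,
   df = n − 2), Bonferroni-corrected over the 52 seed tests, negative
   correlations discarded.
3. **Topology**: the weighted network is binarized at each density in
   5%…50% (step 5%) by keeping the strongest positive weights; global
   (Cp, Lp, Eglob, hierarchy, synchronization, and gamma/lambda/sigma
   against rewired nulls) and nodal (clustering, degree, local efficiency,
   betweenness) statistics are computed per density and summarized by the
   trapezoidal AUC over the actual density abscissa.
4. **Group comparison**: Welch t-tests with Holm correction on regional
   uptake, and a subject-relabeling permutation test on network-metric AUC
   differences.

## Partial correlations with fewer subjects than regions

With 17 subjects and 53 regions the sample covariance is singular, so
"controlling for all remaining nodes" is not defined through a plain
inverse. The correlation matrix R is therefore shrunk toward the identity,
`R* = (1 - λ) R + λ I`, with λ estimated by the Schafer–Strimmer analytic
formula (`λ* = Σ Var(r_ij) / Σ r_ij²` over distinct pairs, clipped to
[0, 1]) — a Ledoit–Wolf-style estimator whose target is diagonal on the
correlation scale, making the estimate invariant to per-region affine
rescaling. Partial correlations are then read off the inverse:
`ρ_ij = -Ω_ij / sqrt(Ω_ii Ω_jj)`, `Ω = (R*)⁻¹`. The intensity actually used
is recorded in the network metadata, and a user-supplied intensity
(including 0, for n ≫ p) can be forced. With λ = 0 this reduces exactly to
the classical regress-out definition (verified in the tests against an
explicit residual-correlation oracle).

No p-values are attached to the partial correlations themselves; the
network is density-thresholded downstream, and significance machinery is
reserved for the seed analysis where df = n − 2 is well-defined.

## Thresholding and graph statistics

At density d, `k = round(d · n(n-1)/2)` edges are kept: negative weights
are zeroed first, survivors are ranked by weight with ties broken by
ascending node-index pair (bit-reproducible), and the kept edges are
binarized. If fewer than k strictly positive weights exist the graph is
built from all of them and a warning is emitted; on small-sample partial
correlation matrices this routinely happens near d = 0.5, where roughly
half the weights are negative.

Conventions on sparse or disconnected graphs, chosen to keep every summary
finite across the whole density sweep:

* Lp averages shortest-path lengths over **connected pairs only**;
* Eglob counts disconnected pairs as 0 (mean of 1/d over all pairs);
* local efficiency of a node is the global efficiency of its
  neighbor-induced subgraph, 0 for degree < 2;
* clustering is triangles / (k(k-1)/2), 0 for degree < 2;
* betweenness is unnormalized Brandes betweenness (fractional for tied
  shortest paths);
* synchronization is the Laplacian eigenratio λ₂/λ_max of the combinatorial
  Laplacian; a disconnected graph has λ₂ = 0 and synchronization 0;
* hierarchy is β in C(k) ∝ k^(−β), the negative least-squares slope of
  log C on log k over nodes with k ≥ 2 and C > 0, reported as NaN when
  fewer than two eligible nodes exist or the eligible degrees are all
  equal. Hierarchy and synchronization follow the standard definitions; the
  exact formulas used by any particular toolbox vary, and these are the
  package's explicit choices.

## Null models

Small-world statistics are normalized against Maslov–Sneppen surrogates:
repeated double-edge swaps (a,b),(c,d) → (a,d),(c,b) on four distinct
nodes, accepted only when neither target edge exists, which preserves every
node's degree exactly. Each surrogate performs `10 |E|` successful swaps
(community-standard mixing) with at most `100 |E|` attempts before partial
mixing is accepted and logged; the attained swap counts appear in the run
report. The orientation of the second edge is randomized per attempt — with
a fixed canonical orientation the chain is biased and collapses null
clustering well below the Erdős–Rényi expectation (this failure mode is
pinned by a test asserting that an ER source has sigma ≈ 1 against its own
ensemble). Defaults: 100 surrogates per density; gamma = Cp/⟨Cp_null⟩,
lambda = Lp/⟨Lp_null⟩, sigma = gamma/lambda.

## Group inference

Each group's network is a single object, so two-sample tests cannot be
applied to its metrics directly. Inference on metric AUCs uses subject
relabeling: pooled subjects are repeatedly split into pseudo-groups of the
original sizes, both networks and the AUC difference are recomputed, and
the two-sided p-value is `(1 + #{|null| ≥ |obs|}) / (n_perm + 1)`
(add-one, so p > 0). When the number of distinct relabelings is at most
n_perm, all of them are enumerated and the p-value is exact and
seed-independent. Null-normalized metrics (gamma/lambda/sigma) can be
permuted too but rebuild their null ensembles inside every relabeling, so
their default surrogate count inside the permutation loop is small (20).

Regional uptake is compared with Welch t-tests (group sizes and variances
differ) restricted to the regions showing significant insula covariance in
the patient group, Holm-corrected over that subset; all tests two-sided at
α = 0.05.

## The synthetic generators

The generator draws each group's uptake matrix from a multivariate Gaussian
parameterized by its **precision matrix**, because partial correlations are
what the downstream network measures: Ω starts as I/base_variance and each
specified edge sets `Ω_ij = -ρ sqrt(Ω_ii Ω_jj)`, so the implied partial
correlation equals ρ exactly (a round-trip identity tested to 1e-10).
Positive definiteness is validated, never repaired silently.

Default study conditions mirror the motivating design: 17 patient-like and
14 control-like subjects over 53 nodes. On the reference-normalized scale
the baseline regional mean is 1.0 with between-subject SD 0.1
(base_variance 0.01). The control-like group is regionally independent.
The epileptic-like group combines:

* **insular hub**: partial correlation 0.2 between the insula and ten
  opercular/temporo-parietal/basal-ganglia partners;
* **local modules**: partial correlation 0.2 within three 4-region
  anatomical modules (inferior-frontal/parietal, temporo-limbic, basal
  ganglia) — the "excess of local connections" phenotype. Positive
  definiteness caps uniform coupling in an m-clique at ρ < 1/(m−1), which
  is why local coupling lives in small modules rather than one large one;
* **hypometabolism**: mean shift −0.05 (−0.5 SD) in the insula and its
  partners.

The implied marginal insula-partner correlations are ≈ 0.76–0.87, so at
n = 17 several insula edges survive Bonferroni correction in most draws
while the independent control group yields essentially none — the seeded
contrast the pipeline is designed to exhibit.

What the generator does **not** emulate: PET point-spread and scanner
noise, anatomical region shapes (phantoms are axis-aligned blocks),
registration error, and — importantly — whatever covariance geometry gives
real patient networks their elevated clustering. At these sample sizes,
pure-noise partial-correlation networks are themselves highly clustered
(sampling noise in correlations is transitively consistent), and inverting
the shrunk correlation matrix explains away a module's shared variance, so
PD-feasible Gaussian structure does not raise node-averaged clustering or
local efficiency above the control baseline. Passing tests therefore
demonstrate correctness and calibration of the machinery and the
seed/hub/sigma/betweenness phenotypes, not a full reproduction of every
group-level contrast reported on real data.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to keep the full suite comfortably
re-runnable on one CPU: type-I-error calibration of the permutation test
uses 200 dataset pairs with 199 permutations over a reduced 4-density grid;
the qualitative two-group comparison uses 9 replicates with 50 null
surrogates per density; seed-test calibration uses 2000 replicates; oracle
checks enumerate 200 random graphs with at most 7 nodes. Tie-breaks
(thresholding, edge ordering) are deterministic by node index; all
randomness flows from explicit integer seeds; permutation and null-ensemble
child seeds are derived through `numpy` SeedSequence spawning.

## Known limitations

* Partial correlations at p > n depend on the shrinkage choice; the study
  that motivated this pipeline did not state its regularization, so the
  estimator here is a documented implementation choice, not a
  reconstruction.
* Densities near 50% on small-sample partial-correlation networks cannot
  always be realized with positive weights (see thresholding above).
* The permutation test assumes exchangeability of subjects under the null;
  covariate adjustment (age, sex) is out of scope.
* Weighted-graph variants, modularity/community structure, and covariance-
  matrix null models are not implemented.
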