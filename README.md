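# metacov

Metabolic covariance network analysis for interictal FDG-PET.

In focal epilepsy, interictal PET shows not only regional hypometabolism but
disturbed *metabolic coupling*: the degree to which regional tracer uptake
covaries across subjects. `metacov` builds these group-level covariance
networks and characterizes their topology — for imaging groups studying
epileptic networks, and for anyone who needs a tested, reproducible
implementation of the covariance-network methodology (regional extraction,
partial-correlation estimation at p > n, density-sweep graph analysis
against degree-preserving nulls, and permutation-based group comparison).

## The method

For one group of subjects, the network over n regions (default: 53
left-hemisphere nodes — 39 neocortical AAL regions, 6 subcortical, 8
ascending-arousal brainstem nuclei) has edge weights

    ρ_ij = −Ω_ij / sqrt(Ω_ii Ω_jj),     Ω = ((1−λ) R + λ I)⁻¹

the partial correlation of regions i and j controlling for all others,
computed from the subjects × regions uptake matrix's correlation matrix R
with Schafer–Strimmer analytic shrinkage λ (required because n_subjects <
n_regions). A seeded analysis tests plain Pearson correlations between the
insula and each other region (t-based p, df = n−2, Bonferroni over 52
tests, negative correlations omitted).

The weighted network is binarized at densities 5%…50% (step 5%); at each
density the pipeline computes mean clustering Cp, characteristic path
length Lp, global efficiency, hierarchy, synchronization (Laplacian
eigenratio), and nodal clustering/degree/local-efficiency/betweenness, plus
gamma = Cp/⟨Cp_null⟩, lambda = Lp/⟨Lp_null⟩ and small-worldness
σ = gamma/lambda against Maslov–Sneppen degree-preserving surrogates. Each
metric's density curve is summarized by its trapezoidal AUC, and group
differences in AUC are tested by subject-relabeling permutation.

A synthetic-data module generates two-group uptake matrices from
multivariate Gaussians whose precision matrix encodes configurable partial
correlations (an insular hub plus local modules for the epileptic-like
group, independence for controls), and block phantoms (NIfTI image + label
volumes) for testing the voxel-level stages. See `docs/methods.md` for the
full model description and design choices.

## Worked example

```python
import metacov as mc

table = mc.make_region_table()                      # 53 nodes, seed = insula
ep = mc.simulate_uptake(table, 17, mc.default_epileptic_coupling(seed=7))
hc = mc.simulate_uptake(table, 14, mc.default_control_coupling(seed=8))

edges = mc.seed_result_table(mc.seed_correlations(ep, "insula"))
print("patient insula edges surviving Bonferroni:", int(edges.significant.sum()))

net = mc.partial_correlation_matrix(ep)
print("shrinkage used:", round(net.meta["shrinkage"], 3))

g = mc.threshold_by_density(net, 0.20)
gamma, lam, sigma = mc.normalized_small_world(g, n_null=100, seed=1)
print(f"gamma={gamma:.2f} lambda={lam:.2f} sigma={sigma:.2f}")
```

prints

```
patient insula edges surviving Bonferroni: 8
shrinkage used: 0.786
gamma=1.48 lambda=1.03 sigma=1.44
```

Eight of the insula's ten planted couplings survive the corrected threshold
(the generator gives the partners marginal r ≈ 0.8; the independent control
group yields zero on this seed), about 79% shrinkage is needed with 17
subjects and 53 regions, and at 20% density the patient network is modestly
small-world (σ > 1: more clustered than its degree-matched nulls at
comparable path length).

The same chain runs end to end from the shell:

```
metacov run-all --seed 7 --out results/run
metacov simulate --seed 7 --out data/
metacov extract --manifest m.tsv --labels labels.nii --regions regions.tsv \
                --fwhm 5 --reference-id 54 --out uptake.tsv
metacov compare --uptake-a ep.tsv --uptake-b hc.tsv --metric sigma --n-perm 1000 --seed 7
```

`run-all` writes the region table, uptake matrices, both networks (CSV +
estimator metadata), seed-edge tables, per-density metric tables with AUC
summaries, null-ensemble summaries, the regional and permutation
comparisons, and a run report with seeds, shrinkage intensities, attained
swap counts and per-file hashes. Re-running an identical config reproduces
every output byte for byte.

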