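# Methods

`idpcompare` compares conformational ensembles of two sequence variants of an
intrinsically disordered protein (IDP) through three complementary lenses:
a kernel-classifier *affinity axis* in backbone torsion space, exponential
random graph models (ERGMs) of residue contact networks, and Markov
coarse-graining of trajectories.  This note documents the models, the
numerical choices, and what the synthetic study conditions do and do not
establish.

## Torsion features and circular statistics

All conformations are represented by their backbone dihedrals phi_i and
psi_i (radians in (-pi, pi], 1-based residue indexing; E22 is index 22 for
the packaged amyloid-beta 1-40 tables).  For any analysis that needs a
metric, each angle theta is expanded into its real and imaginary components
(cos theta, sin theta), so a 40-residue chain carrying all 80 angles yields
160 features.  Euclidean distance in this encoded space respects angular
wrap-around, which is why clustering, SVM kernels, and support-vector
pairing all operate there.

Conventions worth knowing:

- The circular difference d(a, b) is the signed displacement from a to b in
  (-pi, pi]; the antipodal tie (|d| = pi) deterministically returns +pi.
- Circular means are the argument of the mean resultant vector.  CIs use a
  normal approximation on the wrapped deviations from the mean
  (mean +/- 1.96 x circular SE), adequate for the small dispersions these
  analyses produce; a numerically zero resultant length flags the mean as
  undefined.
- Structures parsed from PDB files drop the undefined terminal angles
  (phi_1, psi_last), giving 156 features for a 40-residue chain; synthetic
  sets carry the full 80 angles (160 features).  Both conventions are
  supported because real data cannot supply the terminal dihedrals.
- Dihedral signs follow the standard convention (cis = 0, trans = pi;
  cross-checked against Bio.PDB and mdtraj).

## SVM affinity axis

An RBF-kernel SVC separates the two variants' encoded conformations; the
signed decision value of a conformation is its affinity score (positive =
toward the designated positive class).  Hyperparameters come from a seeded,
stratified grid-search CV (defaults: gamma in 2^-9..2^1 x 1/n_features,
cost in 2^-3..2^7; ties prefer smaller cost, then larger bandwidth).
Sine/cosine features are already bounded, so no standardization is applied.

The decision surface is interrogated two ways:

1. **Support-vector pairing.**  Cross-class support vectors are greedily
   matched by Euclidean distance in the encoded space, closest pair first,
   each vector used at most once.  Per-angle circular differences over the
   pairs, with per-angle 95% CIs (no multiplicity correction by default; a
   Benjamini-Hochberg layer is available), localize where the two variants'
   backbone geometries systematically differ.  Two estimator properties
   matter in practice:
   - When the cost parameter is small enough that every training point is a
     support vector, the pairing is a complete matching and the per-angle
     mean difference is an unbiased estimate of the population shift (the
     pair sum telescopes to the difference of class means).  At larger
     costs the support vectors concentrate near the decision boundary and
     the estimated shift *attenuates* — we measured a planted 0.35 rad
     shift reading as ~0.20 rad at cost 1.  Shift-recovery analyses should
     therefore use the soft-margin (low-cost) end of the grid.
   - Matching makes pair members positively correlated, so pair-scatter CIs
     are mildly anticonservative: null-angle coverage is ~0.91-0.94 at 160
     features (nominal 0.95), worse at lower dimension.
2. **Orrery linearization.**  Affinity scores are regressed (centered,
   minimum-norm least squares, so small rank-deficient sets remain
   well-defined) on the encoded features; each angle's sine/cosine
   coefficient pair (beta, beta') is re-expressed as b sin(theta - y) with
   b = sqrt(beta^2 + beta'^2) and y = atan2(-beta', beta), the quadrant-safe
   identity obtained by expanding b sin(theta - y).

## Protein structure networks

A PSN places one node per residue and an edge between residues i, j
whenever some atom pair is closer than 1.2 x the sum of its van der Waals
radii (strict inequality; Alvarez radii; hydrogens included when present,
`heavy_atoms_only` available).  Backbone edges (i, i+1) are always present
and flagged; they form the fixed support for everything downstream.
Contact detection uses a KD-tree with an exact per-pair radius check, which
is identical to the all-pairs scan it is tested against.

Per-residue k-core numbers (largest k such that the node survives in the
k-core) summarize local cohesion; ensembles are contrasted with Welch tests
on per-residue core means and with two-proportion z-tests (continuity
corrected, Fisher fallback at expected counts < 5) on per-dyad edge
frequencies, at alpha = 0.05 without multiplicity correction by default.

## ERGM with integrated Laplace prior

The contact ensemble of each variant is modelled as

    Pr(G = g | theta, X)  propto  exp(theta^T t(g, X)),

over simple graphs containing the backbone path, with ten statistics:
edges; sum over edges of |i - j| (backbone distance); nodecov sums for
Kyte-Doolittle hydrophobicity, van der Waals volume (A^3), monoisotopic
mass (Da), and a distance-from-termini score min(i-1, N-i) normalized to
[0, 1]; a charge edge covariate (+1 same nonzero charge, -1 opposite, 0
otherwise; His neutral at pH 7); polar/nonpolar and polar/polar mixing
counts (nonpolar/nonpolar reference; nonpolar class = {A,V,L,I,P,F,M,W,G,C});
and GWESP with fixed decay tau = 0.5,
GWESP = e^tau sum_p [1 - (1 - e^-tau)^p] EP_p, where EP_p counts edges with
exactly p shared partners.

**Fitting.**  Coefficients maximize the sigma-integrated penalized
pseudo-likelihood: Laplace(0, sigma) priors on the (changescore-
standardized) coefficients, sigma ~ Inv-Gamma(kappa = 0.1, zeta = 1.1), and
the conditional Bernoulli likelihood over free dyads (logit = theta^T
Delta t at each dyad, rest of the graph held at its observed state).  The
1-D sigma integral is a Gamma integral with closed form: the integrated
log-prior is -(p + kappa) log(sum|theta| + zeta) up to a constant, and
sigma | theta is Inv-Gamma(p + kappa, sum|theta| + zeta); the reported
prior scale is its posterior mean (sum|theta| + zeta)/(p + kappa - 1), on
the standardized scale.  Using the exact integral rather than numerical
quadrature is exact, deterministic, and cheaper.

Numerics: the |.| kink is pseudo-Huber-smoothed at eps = 1e-6; L-BFGS-B is
run in a continuation scheme (eps = 1e-3 first, then 1e-6, warm-started)
because the near-kink curvature defeats a cold-started line search; a final
hard-threshold pass accepts exact zeros whenever they do not worsen the
exact objective.  Changescores are standardized to unit variance per term
with a relative-tolerance guard for the constant edges column (the density
offset).  Note that at realistic ensemble sizes the data term dominates the
prior, so exact zeros mostly appear in small-sample or null settings; the
reliable shrinkage statement is that the standardized L1 norm never exceeds
the unpenalized fit's.

**Uncertainty.**  Bayesian bootstrap with graphs as the resampled units:
m refits under Dirichlet(1,...,1) weights (assigned via a canonical graph
ordering, so summaries do not depend on list order), summarized as
posterior mean/SD and central 95% intervals for the ten coefficients and
the prior scale.  The bootstrap treats graphs as independent; ensembles
simulated for recovery checks therefore use 5-sweep thinning (see below).

**Simulation.**  Metropolis single-dyad toggles over free dyads only,
acceptance exp(+-theta^T Delta t); defaults burn = 50 sweeps, thin = 1
sweep (one sweep = one proposal per free dyad), start = backbone-only
graph.  One-sweep thinning leaves noticeable autocorrelation: parameter-
recovery experiments use thin = 5 sweeps so that bootstrap SDs (which
assume independent graphs) are honest.  Sampler correctness is validated by
exact enumeration on a 6-node model (1024 support graphs).

**Favorability.**  For models A and B with coefficient vectors theta_A,
theta_B and variant-specific covariates, f(G) = theta_B . t(G, X_B) -
theta_A . t(G, X_A) is the log probability ratio up to an additive
constant; only differences between graphs are interpretable.  Ranking the
pooled ensemble by f gives the top-5 most A-like and B-like structures.

## Markov coarse-graining and TME

Both variants' trajectories are clustered jointly (k-means on the pooled
encoded frames; each "clustering calculation" is the best of `n_init = 10`
seeded restarts, which suppresses local-optimum noise in the selection
curve).  Directed transition counts Z_ij are accumulated within each
trajectory separately; row-wise Jeffreys (Dirichlet 1/2) priors give
posterior-mean transitions c_ij = (Z_ij + 0.5)/(N_i + k/2), whose rows sum
to one by algebra, with unobserved rows uniform.

The **Total Markov Error** of a trajectory under a solution and transition
matrix C is the summed one-step prediction error: from each frame's
cluster, predict the next cluster through C, represent the prediction by a
member conformation of that cluster, and measure the Euclidean distance to
the actually observed next frame.  `sampled` mode draws cluster and member
(member pools default to the pooled joint solution; per-variant pools are
available); `expected` mode accumulates the exact expectation
sum_j c_ij meanDist(x_{t+1}, members of j) and is the deterministic default
for model selection.  The first frame seeds the walk and accrues no error.
TME penalizes both coarsening loss (too few clusters) and transition-
estimation error (too many, via the prior mass leaking to distant
clusters), so its minimum selects k; `select_k` averages the summed TME of
all trajectories (each variant's trajectory scored under its own
transition matrix estimated from the joint solution) over `reps`
clusterings per k and returns the argmin with its best solution.

Diagnostics: elbow curves (mean distance to center vs k) and mean
silhouette widths, s(i) = (b(i) - a(i))/max(a(i), b(i)) with the singleton
convention s = 0, estimated from seeded subsamples whose values are exact
against the full data.  Transition graphs annotate per-cluster populations,
variant-fraction color scalars, medoid frames, and directed counts; the
proximity graph maps pairwise center distances through a logistic function
(midpoint = median pairwise distance, slope = 1/SD of the distances, both
exposed) to grayscale values that increase with distance.

## Synthetic study conditions

The generators supply every input the analyses would normally take from
molecular dynamics, with known ground truth:

- **Conformations / trajectories.**  Shared von Mises basins over all
  angles (default concentration 8, about 20 degrees of spread); variants
  differ only through per-angle shifts and their basin transition matrices.
  The default two-variant system (`two_variant_spec`) uses four basins at
  canonical Ramachandran regions (alpha, beta, PPII, left-alpha), a
  0.35 rad shift at psi_22 for the mutant, symmetric switching at rate
  0.05 for variant A and basin-dependent dwell times (rates 0.02-0.08) for
  variant B — near-identical marginals, different kinetics.
  `shift_only_spec` is the single-basin variant used for shift-recovery
  experiments, where the injected shift is the *only* class difference.
  Trajectories are hidden-Markov chains with the hidden path returned as
  ground truth; frames are 2 ps apart.
- **Fibril-like sets** concentrate tightly (concentration 64) on a
  reference angle vector, by default the (variant-A-like) beta basin, so
  affinity transfer has a known expected sign.
- **Toy structures** place one sphere per residue (carbon radius), with
  consecutive spheres at 0.9x the contact threshold and a penalized stress
  optimization pulling target contacts below and pushing all other pairs
  above threshold; the result is verified exactly by a PSN round-trip and
  rejected as unrealizable otherwise.
- **PSN ensembles** come from the Metropolis ERGM sampler.

Randomness: each spec holds one master seed; operation calls derive
deterministic sub-streams keyed by operation tag and call index, so a fixed
call sequence is bit-reproducible, and every operation accepts an explicit
seed override.

Problem sizes in the shipped tests and the acceptance script (1000
conformations per class, 300 simulated 40-node PSNs, 1000-frame
trajectories per variant, k scanned over 2..8 with 5 replicates) are chosen
so the full battery runs on a single CPU at desk scale while leaving the
recovery checks well-powered.

**What the synthetic conditions do not show.**  The generators emulate the
statistical regime of the analyses (near-identical circular marginals,
sparse interior-clustered contact graphs, metastable switching), not the
physics that produces it: no force field, solvent, annealing, or secondary
structure; no intra-basin dynamics (within-basin frames are exchangeable);
angles are independent within a basin, whereas real backbones are locally
correlated.  Passing recovery tests therefore validates the estimators and
their implementations, not claims about any particular protein system.

## Known limitations

- The pseudo-likelihood is an approximation for dependence terms (GWESP);
  at very strong clustering its mode can drift from the true-likelihood
  mode.  The fitting target follows the pseudo-likelihood by design.
- Bootstrap SDs require approximately independent graphs; heavily
  autocorrelated MCMC output will make them optimistic.
- Per-angle CIs from matched SV pairs are mildly anticonservative (see
  above); the optional BH layer controls the false discovery rate across
  angles but does not repair the per-angle level.
- The TME optimum is well-defined only when transition estimation is
  data-limited; with very long trajectories the curve flattens for
  k above the true basin count.
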