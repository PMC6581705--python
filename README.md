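# idpcompare

Comparative analysis of intrinsically disordered protein (IDP)
conformational ensembles.  IDPs such as amyloid-beta lack stable secondary
structure, so standard structure-comparison tools (DSSP classes, RMSD to a
fold) say little about how two sequence variants — say wild type versus a
point mutant — actually differ.  `idpcompare` implements three
complementary, model-based views of that question, plus a synthetic-data
module with known ground truth so the whole pipeline runs and validates at
desk scale:

1. **SVM affinity axis** — an RBF-kernel classifier on sine/cosine-encoded
   backbone dihedrals (phi_i, psi_i) defines a characteristic axis; the
   decision value f(x) = sum_i alpha_i y_i K(x_i, x) + b scores any
   conformation's net affinity for one variant.  Matched cross-class
   support-vector pairs localize the angles that shift across the decision
   boundary, and regressing scores on features yields per-angle
   b sin(theta - y) ("orrery") gradient coefficients.
2. **Protein structure networks + Bayesian ERGM** — residue contact graphs
   (edge iff some atom pair is closer than 1.2x the summed van der Waals
   radii), k-core profiles, and an exponential random graph model
   Pr(G = g) ∝ exp(theta^T t(g, X)) over graphs containing the backbone
   path, with ten physico-chemical and topological terms (edges, backbone
   distance, hydrophobicity, charge mixing, polarity mixing, volume, mass,
   termini distance, GWESP(0.5)).  Fitting maximizes a pseudo-likelihood
   under Laplace(0, sigma) priors with sigma ~ Inv-Gamma(0.1, 1.1)
   integrated out in closed form; a Bayesian bootstrap over graphs supplies
   posterior summaries, and the log favorability ratio
   f(G) = theta_B·t(G, X_B) − theta_A·t(G, X_A) ranks which contact
   patterns each variant prefers.
3. **Markov coarse-graining** — joint k-means over both variants'
   trajectories in encoded torsion space; transition matrices with Jeffreys
   posterior means c_ij = (Z_ij + 0.5)/(N_i + k/2); and cluster-number
   selection by the Total Markov Error (TME), the summed one-step
   prediction error of the cluster-level Markov chain against the observed
   trajectory.

## Worked example

Recover a planted 0.35 rad shift at psi_22 from two synthetic variants that
differ *only* by that shift:

```python
from idpcompare.affinity import (fit_affinity_model, pair_support_vectors,
                                 sv_pair_angle_differences)
from idpcompare.synthetic import sample_conformations, shift_only_spec
from idpcompare.torsion import encode_circular

spec = shift_only_spec(seed=11)          # 40 residues, shift at psi_22
wt  = encode_circular(sample_conformations(spec, "WT", 1000))
mut = encode_circular(sample_conformations(spec, "MUT", 1000))

grid = {"gamma": [1 / 160], "cost": [0.125]}   # soft-margin end of the grid
model = fit_affinity_model(wt, mut, tuning_grid=grid, folds=3, seed=0)
pairs = pair_support_vectors(model)
table = sv_pair_angle_differences(pairs, model.angle_labels)
print(table[(table.residue == 22) & (table.angle_type == "psi")])
```

```
    residue angle_type      mean        lo        hi  flag  p_value
43       22        psi  0.352     0.324     0.379        1  ...
```

The planted angle's circular mean difference is 0.352 rad with a 95% CI of
(0.324, 0.379): it contains the injected 0.35 and excludes zero
(flag = +1), while the 79 unshifted angles' CIs mostly cover zero
(coverage ~0.85-0.94 across seeds; matched pairs make the CIs mildly
anticonservative — see `docs/methods.md`).  The same pattern at cost 1.0 reads only ~0.20 rad — support vectors
then concentrate at the decision boundary and attenuate the shift, which is
why shift-recovery analyses use the low-cost end of the grid (see
`docs/methods.md`).

An end-to-end synthetic run of all five stages (generation, featurization,
affinity, PSN/ERGM, clustering), with every table artifact and a manifest:

```bash
idpcompare run --seed 42 --outdir demo_out
```

## Layout

- `src/idpcompare/torsion.py` — dihedrals, circular statistics, encoding
- `src/idpcompare/affinity.py` — SVM axis, SV pairing, PCA, orrery
- `src/idpcompare/psn.py` — contact networks, k-cores, contrasts
- `src/idpcompare/ergm.py` — statistics, MAP fit, bootstrap, sampler,
  favorability
- `src/idpcompare/markov.py` — joint k-means, TME, transition graphs
- `src/idpcompare/synthetic.py` — ground-truth generators
- `src/idpcompare/properties.py` — residue property and radius tables
- `src/idpcompare/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
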