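# confpot

Conformer-level chemical potential prediction for flexible C/H/O
compounds: **MBTR** descriptors of 3-D conformers, **RS-maximin**
reference selection and the **Extreme Minimal Learning Machine (EMLM)**
distance-based regressor, applied to ranking and filtering conformer
ensembles by predicted chemical potential in multiple solvents.

## Who this is for

Condensed-phase thermodynamics workflows (continuum-solvation models such
as COSMO-RS) need DFT calculations for many conformers of every compound,
and the conformer count explodes with molecular flexibility.  The
conformer's pseudochemical potential μ (kcal/mol) in a solvent measures
how favourably it interacts with the medium and correlates strongly with
its intramolecular hydrogen-bond count — positively in water, negatively
in nonpolar media.  `confpot` trains a cheap machine-learning surrogate
for μ so that high-μ conformers can be discarded *between conformer
sampling and the first DFT step*, keeping only the low-μ head of the
ensemble for expensive quantum chemistry.

## The model

A conformer with atoms at positions {R_i} is encoded as a fixed-length
many-body tensor representation: Gaussian-broadened distributions of
atomic numbers (k=1), pair distances d_ij weighted by exp(−s₂ d_ij)
(k=2), and angles θ_ijk weighted by exp(−s₃(d_ij + d_jk + d_ik)) (k=3),
discretized per element-tuple channel on fixed grids.  Defaults:
σ₁ = 0.04, σ₂ = 0.025 Å with s₂ = 0.5, σ₃ = 0.12 rad with s₃ = 0.8.

The EMLM predicts from Euclidean distances to m fixed reference
conformers:

    ŷ(x) = [ ‖x − r₁‖, …, ‖x − r_m‖ ] · W,     H W = Y (least squares)

with references chosen by RS-maximin (start at the point closest to the
data mean, then greedily add the point farthest from the selected set),
features min-max scaled to [0, 1] and targets to [−1, 1] on training
data.  The reference count (default 25% of the training set) is the only
hyperparameter.  One model predicts all solvents at once.

A synthetic-data module generates idealized polyol conformer ensembles
whose per-conformer targets follow μ = a_s·nHB + b_s + noise (nHB = the
intramolecular H-bond count), so the whole pipeline is testable without
any quantum chemistry.  See `docs/methods.md` for the full account.

## Worked example

```python
from confpot import MBTRConfig, emlm_fit, evaluate_model, mbtr_encode_ensemble
from confpot.synthetic import SyntheticSpec, generate_ensemble

config = MBTRConfig.conformer_profile()
train = generate_ensemble(SyntheticSpec(n_molecules=30, conformers_per_molecule=15, seed=1))
test  = generate_ensemble(SyntheticSpec(n_molecules=6,  conformers_per_molecule=15, seed=99))

desc  = mbtr_encode_ensemble(train.conformers, config)
model = emlm_fit(desc.features, train.targets.loc[desc.keys],
                 reference_fraction=0.25, mbtr_fingerprint=desc.config_fingerprint)
print(evaluate_model(model, test.conformers, test.targets, config).summary())
```

prints (`examples/02_train_and_evaluate.py`):

```
solvent  rmse(kcal/mol)
water    1.088
pure     0.672
wiom     0.595
```

— the held-out root-mean-square error per solvent, in kcal/mol, on
molecules the model never saw.  The synthetic targets carry 0.5 kcal/mol
of noise, so the nonpolar solvents approach the noise floor at this small
training size; water, whose μ spans three times more per hydrogen bond,
retains a larger error.  Filtering an ensemble then takes three lines
(`examples/03_filter_ensemble.py`):

```
kept 6 of 20 conformers (water, lowest 30%)
conformer with the lowest true mu: 8; retained: True
```

The `examples/` directory holds one short script per capability
(encoding, training/evaluation, filtering, PCA of descriptor space), and
the `confpot` command exposes the same workflow as subcommands
(`synth`, `encode`, `train`, `predict`, `filter`, `evaluate`) driven by a
single TOML config.

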