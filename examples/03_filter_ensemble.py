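"""Filter a conformer ensemble before expensive quantum chemistry.

The intended workflow: sample conformers, predict their chemical potentials,
discard the high-potential tail, and pass only the survivors to DFT /
continuum-solvation calculations.  This script trains a model, then filters
a fresh 20-conformer ensemble down to its most promising 30%.
"""

from confpot import SelectionPolicy, filter_ensemble
from confpot.experiments import train_reference_model
from confpot.synthetic import SyntheticSpec, generate_ensemble

model, config = train_reference_model(seed=7)

ensemble = generate_ensemble(SyntheticSpec(n_molecules=1, conformers_per_molecule=20, seed=1234))
policy = SelectionPolicy(solvent="water", keep_fraction=0.3)
kept, report = filter_ensemble(ensemble.conformers, model, config, policy)

print(f"kept {len(kept)} of {len(ensemble.conformers)} conformers (water, lowest 30%)")
print("\npredicted mu_water (kcal/mol), kept conformers first:")
print(report.to_frame()[["water", "kept"]].round(2).to_string())

true_best = ensemble.metadata["true_water"].idxmin()
print(f"\nconformer with the lowest true mu: {true_best[1]}; "
      f"retained: {true_best in {r.key for r in kept}}")
# Discarded conformers are listed with their predictions so the cut can be
# audited; keep fractions should stay generous because later workflow steps
# (duplicate removal after DFT) thin the ensemble further.
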