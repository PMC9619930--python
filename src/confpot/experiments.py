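"""Self-contained synthetic studies: parameter recovery, size extrapolation
and selection utility.

These protocols exercise the full pipeline (generate -> encode -> maximin ->
fit -> predict -> evaluate/filter) on ensembles from :mod:`confpot.synthetic`
at desk scale.  They are used both by the test suite and by the
reproduction script, so the problem sizes are deliberately modest:
50 training molecules x 20 conformers, 10 held-out molecules, and the
:meth:`~confpot.mbtr.MBTRConfig.conformer_profile` descriptor.

All randomness derives from the ``seed`` arguments; identical seeds give
identical results.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .conformer_select import SelectionPolicy, filter_ensemble
from .emlm import EMLMModel, emlm_fit, emlm_predict
from .evaluation import linear_rescale_fit, rmse
from .mbtr import MBTRConfig, mbtr_encode_ensemble
from .synthetic import SyntheticSpec, generate_ensemble

__all__ = [
    "recovery_experiment",
    "extrapolation_experiment",
    "selection_experiment",
    "train_reference_model",
]

SOLVENTS = ["water", "pure", "wiom"]

# study sizes: a scaled-down emulation of a train/test split by molecule
N_TRAIN_MOLECULES = 50
N_TEST_MOLECULES = 10
CONFORMERS_PER_MOLECULE = 20
REFERENCE_FRACTION = 0.25


def _spec(seed: int, n_molecules: int, **overrides) -> SyntheticSpec:
    return replace(
        SyntheticSpec(seed=seed, n_molecules=n_molecules,
                      conformers_per_molecule=CONFORMERS_PER_MOLECULE),
        **overrides,
    )


def train_reference_model(
    seed: int,
    config: MBTRConfig | None = None,
    **spec_overrides,
) -> tuple[EMLMModel, MBTRConfig]:
    """Train one EMLM on a fresh synthetic training ensemble."""
    config = config or MBTRConfig.conformer_profile()
    train = generate_ensemble(_spec(seed, N_TRAIN_MOLECULES, **spec_overrides))
    desc = mbtr_encode_ensemble(train.conformers, config)
    model = emlm_fit(
        desc.features,
        train.targets.loc[desc.keys][SOLVENTS],
        reference_fraction=REFERENCE_FRACTION,
        seed=seed,
        mbtr_fingerprint=desc.config_fingerprint,
    )
    return model, config


def recovery_experiment(
    base_seed: int = 1,
    n_seeds: int = 5,
    config: MBTRConfig | None = None,
) -> pd.DataFrame:
    """Held-out accuracy of the full pipeline, pooled over ``n_seeds`` runs.

    For each seed: train on 50 molecules x 20 conformers, predict 10 unseen
    molecules x 20 conformers (split is by molecule — training and test
    molecules come from independent generator draws).  Returns one row per
    solvent with the pooled held-out RMSE against the noisy targets
    (kcal/mol) and the pooled Spearman rank correlation between predictions
    and the noise-free true chemical potential.
    """
    config = config or MBTRConfig.conformer_profile()
    preds: list[pd.DataFrame] = []
    targets: list[pd.DataFrame] = []
    truths: list[pd.DataFrame] = []
    for k in range(n_seeds):
        seed = base_seed + 1000 * k
        model, _ = train_reference_model(seed, config)
        test = generate_ensemble(_spec(seed + 500_000, N_TEST_MOLECULES))
        desc = mbtr_encode_ensemble(test.conformers, config)
        p = emlm_predict(model, desc.features, keys=desc.keys,
                         fingerprint=desc.config_fingerprint)
        preds.append(p.reset_index(drop=True))
        targets.append(test.targets.loc[p.index][SOLVENTS].reset_index(drop=True))
        truths.append(
            test.metadata.loc[p.index][[f"true_{s}" for s in SOLVENTS]].reset_index(drop=True)
        )
    P = pd.concat(preds, ignore_index=True)
    Y = pd.concat(targets, ignore_index=True)
    T = pd.concat(truths, ignore_index=True)
    rows = {}
    for s in SOLVENTS:
        rows[s] = {
            "rmse": rmse(P[s], Y[s]),
            "spearman_true": spearmanr(P[s], T[f"true_{s}"]).statistic,
            "n": len(P),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "solvent"
    return out


def extrapolation_experiment(
    seed: int = 1,
    config: MBTRConfig | None = None,
) -> pd.DataFrame:
    """Size extrapolation: train on 6-10 heavy atoms, test on 16-20.

    The model then extrapolates outside its training size range: absolute
    predictions drift but stay linearly related to the true values, so the
    report carries, per solvent, the Pearson correlation, the raw RMSE and
    the RMSE after the OLS rescale ``calc ~ a*pred + b``.
    """
    config = config or MBTRConfig.conformer_profile()
    model, _ = train_reference_model(seed, config)
    # larger oxidation products carry proportionally more hydroxyls
    test = generate_ensemble(
        _spec(seed + 500_000, N_TEST_MOLECULES,
              chain_length_range=(16, 20), hydroxyl_range=(6, 10),
              torsion_count_range=(3, 5))
    )
    desc = mbtr_encode_ensemble(test.conformers, config)
    preds = emlm_predict(model, desc.features, keys=desc.keys,
                         fingerprint=desc.config_fingerprint)
    calc = test.targets.loc[preds.index]
    rows = {}
    for s in SOLVENTS:
        p = preds[s].to_numpy()
        c = calc[s].to_numpy()
        a, b, r_scaled = linear_rescale_fit(p, c)
        rows[s] = {
            "pearson_r": pearsonr(p, c).statistic,
            "rmse": rmse(p, c),
            "rmse_scaled": r_scaled,
            "slope": a,
            "intercept": b,
            "n": len(p),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "solvent"
    return out


def selection_experiment(
    seed: int = 1,
    n_trials: int = 200,
    keep_fraction: float = 0.3,
    solvent: str = "water",
    config: MBTRConfig | None = None,
) -> dict:
    """Conformer-filtering utility: how often does the kept set retain the
    best conformer?

    One model is trained at the recovery settings; each trial generates a
    fresh single-molecule ensemble of 20 conformers, filters it down to
    ``keep_fraction`` by predicted chemical potential in ``solvent``, and
    scores success when the kept set contains a conformer of minimal true
    (noise-free) chemical potential.  Returns the retention rate over
    ``n_trials`` trials.
    """
    config = config or MBTRConfig.conformer_profile()
    model, _ = train_reference_model(seed, config)
    policy = SelectionPolicy(solvent=solvent, top_n=None, keep_fraction=keep_fraction)
    hits = 0
    for t in range(n_trials):
        trial = generate_ensemble(_spec(seed + 600_000 + t, 1))
        true_mu = trial.metadata[f"true_{solvent}"]
        best = set(true_mu[true_mu == true_mu.min()].index)
        kept, _report = filter_ensemble(trial.conformers, model, config, policy)
        if best & {r.key for r in kept}:
            hits += 1
    return {"retention_rate": hits / n_trials, "n_trials": n_trials,
            "keep_fraction": keep_fraction, "solvent": solvent}
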