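"""Applied workflow: rank a conformer ensemble by predicted chemical
potential and keep the low-mu head before expensive quantum chemistry.

This is the intended insertion point of the model: between conformer
sampling and the first DFT calculations of a continuum-solvation workflow.
High-chemical-potential conformers can be discarded up front; the number
kept should stay generous, since later duplicate filtering thins the set
further.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .emlm import EMLMModel, emlm_predict
from .io_structures import ConformerRecord, geometry_sanity_check
from .mbtr import MBTRConfig, mbtr_encode_ensemble

__all__ = [
    "SelectionPolicy",
    "FilterReport",
    "stride_subsample",
    "rank_conformers",
    "filter_ensemble",
]


@dataclass(frozen=True)
class SelectionPolicy:
    """How to rank and how much to keep.

    ``solvent`` names the ranking solvent, or ``"min_over_solvents"`` to rank
    by each conformer's minimum mu across all solvents.  Exactly one of
    ``top_n`` / ``keep_fraction`` applies (``top_n`` wins when both are set).
    ``sanity_filter`` drops geometrically defective conformers before
    prediction; the keep budget then applies to the survivors.
    """

    solvent: str = "water"
    top_n: int | None = None
    keep_fraction: float | None = 0.5
    sanity_filter: bool = True

    def __post_init__(self) -> None:
        if self.top_n is None and self.keep_fraction is None:
            raise ValueError("set top_n or keep_fraction")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.keep_fraction is not None and not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")


def stride_subsample(records: Sequence, k: int = 10) -> list:
    """Every k-th item in input order (indices 0, k, 2k, ...).

    Mirrors selecting a constant-interval subset of conformers by their
    sampling-program numbering; file order is the canonical order.
    """
    if k < 1:
        raise ValueError("stride k must be >= 1")
    return list(records[::k])


def rank_conformers(predictions: pd.DataFrame, policy: SelectionPolicy) -> list:
    """Keys sorted by ascending predicted mu in the policy solvent.

    Stable: ties preserve input order.  ``min_over_solvents`` ranks by the
    per-conformer minimum across all solvent columns.
    """
    if policy.solvent == "min_over_solvents":
        score = predictions.min(axis=1)
    else:
        if policy.solvent not in predictions.columns:
            raise ValueError(
                f"solvent {policy.solvent!r} not among predictions "
                f"{list(predictions.columns)}"
            )
        score = predictions[policy.solvent]
    order = score.sort_values(kind="stable").index
    return list(order)


@dataclass
class FilterReport:
    """Audit trail of one filtering run: predictions for every conformer."""

    kept_keys: list
    discarded_keys: list
    predictions: pd.DataFrame  # all surviving conformers, ranking order
    sanity_failures: list

    def to_frame(self) -> pd.DataFrame:
        out = self.predictions.copy()
        out["kept"] = [k in set(self.kept_keys) for k in out.index]
        return out


def filter_ensemble(
    records: Sequence[ConformerRecord],
    model: EMLMModel,
    config: MBTRConfig,
    policy: SelectionPolicy,
) -> tuple[list[ConformerRecord], FilterReport]:
    """Predict, rank and keep the lowest-mu conformers.

    Returns the kept records (in ranking order) and a report listing the
    predicted mu of every surviving conformer plus any sanity failures.
    The kept set always contains the conformer with the lowest predicted mu.
    If the keep budget exceeds the surviving ensemble, everything is kept
    with a warning (keeping too few conformers is the costly failure mode).
    """
    sanity_failures = []
    survivors = list(records)
    if policy.sanity_filter:
        survivors = []
        for record in records:
            if geometry_sanity_check(record):
                survivors.append(record)
            else:
                sanity_failures.append(record.key)
    if not survivors:
        return [], FilterReport([], [], pd.DataFrame(), sanity_failures)

    desc = mbtr_encode_ensemble(survivors, config)
    preds = emlm_predict(model, desc.features, keys=desc.keys,
                         fingerprint=desc.config_fingerprint)
    ranked = rank_conformers(preds, policy)

    n = len(survivors)
    if policy.top_n is not None:
        keep = policy.top_n
    else:
        keep = math.ceil(policy.keep_fraction * n)
    if keep > n:
        warnings.warn(
            f"keep budget {keep} exceeds surviving ensemble of {n}; keeping all",
            stacklevel=2,
        )
        keep = n

    kept_keys = ranked[:keep]
    discarded_keys = ranked[keep:]
    by_key = {r.key: r for r in survivors}
    kept_records = [by_key[k] for k in kept_keys]
    report = FilterReport(kept_keys, discarded_keys, preds.loc[ranked], sanity_failures)
    return kept_records, report
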