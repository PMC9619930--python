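"""Model evaluation: per-solvent RMSE, linear rescaling and PCA projection.

For molecules inside the training size range the raw RMSE between predicted
and calculated chemical potential is the headline metric.  For molecules
larger than anything in the training data the model extrapolates: absolute
values drift, but predicted and calculated values stay linearly related, so
the evaluation also supports fitting ``calc ~ a*pred + b`` and reporting the
RMSE after that rescale.  PCA of descriptor space is provided to visualize
whether test ensembles live inside the training feature region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .emlm import EMLMModel, emlm_predict
from .io_structures import ConformerRecord, geometry_sanity_check
from .mbtr import MBTRConfig, mbtr_encode_ensemble

__all__ = [
    "EvalReport",
    "rmse",
    "linear_rescale_fit",
    "pca_project",
    "evaluate_model",
]


def rmse(pred: np.ndarray, calc: np.ndarray) -> float:
    """Root-mean-square error between two equally long vectors (kcal/mol)."""
    pred = np.asarray(pred, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if pred.shape != calc.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("pred and calc must be equal-length non-empty vectors")
    if not (np.all(np.isfinite(pred)) and np.all(np.isfinite(calc))):
        raise ValueError("non-finite values in rmse inputs")
    return float(np.sqrt(np.mean((pred - calc) ** 2)))


def linear_rescale_fit(pred: np.ndarray, calc: np.ndarray) -> tuple[float, float, float]:
    """OLS fit ``calc ~ a*pred + b``; returns (a, b, rmse after rescale).

    Used when the model extrapolates beyond its training size range:
    predictions then track the calculated values linearly but not in
    absolute terms, and the rescaled RMSE measures the remaining scatter.
    """
    pred = np.asarray(pred, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if pred.shape != calc.shape or pred.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 points")
    if np.ptp(pred) == 0:
        raise ValueError("predictions are constant; slope undefined")
    a, b = np.polyfit(pred, calc, deg=1)
    return float(a), float(b), rmse(a * pred + b, calc)


def pca_project(features: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA of descriptor rows.

    Returns ``(scores, explained_variance_ratio)`` with components ordered by
    decreasing variance.  Sign convention: the largest-magnitude loading of
    each component is positive, so scores are reproducible across runs.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs at least two rows")
    if not 1 <= n_components <= min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components out of range")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_components):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] *= -1.0
    return scores, pca.explained_variance_ratio_


@dataclass
class EvalReport:
    """Per-solvent evaluation summary."""

    per_solvent: pd.DataFrame  # index: solvent; columns: rmse, n [, a, b, rmse_scaled]
    excluded: list[tuple[str, str]]  # conformers dropped by the sanity screen
    predictions: pd.DataFrame  # per-conformer predicted mu used for the metrics

    def summary(self) -> str:
        lines = ["solvent  rmse(kcal/mol)" + ("  rmse_scaled" if "rmse_scaled" in self.per_solvent else "")]
        for solvent, row in self.per_solvent.iterrows():
            line = f"{solvent:8s} {row['rmse']:.3f}"
            if "rmse_scaled" in row.index:
                line += f"  (scaled {row['rmse_scaled']:.3f}, fit a={row['a']:.3f} b={row['b']:.3f})"
            lines.append(line)
        if self.excluded:
            lines.append(f"excluded by sanity screen: {len(self.excluded)}")
        return "\n".join(lines)


def evaluate_model(
    model: EMLMModel,
    records: Sequence[ConformerRecord],
    targets: pd.DataFrame,
    config: MBTRConfig,
    rescale: bool = False,
    sanity_screen: bool = True,
) -> EvalReport:
    """Predict a test ensemble and score it against calculated targets.

    Conformers failing the geometric sanity screen are excluded from the
    metrics and listed in the report (defective geometries produce absurd
    predictions and would dominate the RMSE).  With ``rescale=True`` the
    report adds the linear fit ``calc ~ a*pred + b`` and the rescaled RMSE
    per solvent.
    """
    excluded: list[tuple[str, str]] = []
    kept: list[ConformerRecord] = []
    for record in records:
        if sanity_screen and not geometry_sanity_check(record):
            excluded.append(record.key)
        else:
            kept.append(record)
    keys = [r.key for r in kept]
    common = [k for k in keys if k in targets.index]
    if not common:
        raise ValueError("no overlap between ensemble keys and target table")
    kept = [r for r in kept if r.key in targets.index]

    desc = mbtr_encode_ensemble(kept, config)
    preds = emlm_predict(model, desc.features, keys=desc.keys,
                         fingerprint=desc.config_fingerprint)
    calc = targets.loc[preds.index]

    rows = {}
    for solvent in model.solvent_labels:
        if solvent not in calc.columns:
            continue
        p = preds[solvent].to_numpy()
        c = calc[solvent].to_numpy()
        row = {"rmse": rmse(p, c), "n": len(p)}
        if rescale:
            a, b, r_scaled = linear_rescale_fit(p, c)
            row.update({"a": a, "b": b, "rmse_scaled": r_scaled})
        rows[solvent] = row
    report = pd.DataFrame(rows).T
    report.index.name = "solvent"
    return EvalReport(per_solvent=report, excluded=excluded, predictions=preds)
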