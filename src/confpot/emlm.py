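"""Extreme Minimal Learning Machine: distance-based (ridge) regression.

The model maps a descriptor vector x to targets through its Euclidean
distances to a fixed set of m reference points r_1..r_m chosen from the
training data:

    y_hat(x) = [ ||x - r_1||, ..., ||x - r_m|| ] @ W

W is the least-squares solution of H W = Y on the training set, where
H_ij = ||x_i - r_j|| (minimum-norm via SVD when lambda = 0, ridge
otherwise).  References are picked by RS-maximin: start at the point
closest to the data mean, then greedily add the point whose minimum
distance to the selected set is largest.  Features are minmax-scaled to
[0, 1] and targets to [-1, 1] on the training data; test-time features
outside the training range deliberately map outside [0, 1] so that
extrapolation stays visible.

The only real hyperparameter is m (``reference_fraction``); 25% of the
training data is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "MinMaxScaler",
    "EMLMModel",
    "maximin_select",
    "fit_feature_scaler",
    "emlm_fit",
    "emlm_predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = "1"


@dataclass
class MinMaxScaler:
    """Per-column affine map onto a fixed output range.

    Columns that are constant on the fitting data map to the midpoint of the
    output range and invert back to the constant; no clamping is applied, so
    out-of-range inputs map outside the range by design.
    """

    data_min: np.ndarray
    data_max: np.ndarray
    lo: float = 0.0
    hi: float = 1.0

    @classmethod
    def fit(cls, X: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("need a 2-D matrix with at least one row")
        return cls(X.min(axis=0), X.max(axis=0), lo, hi)

    @property
    def _span(self) -> np.ndarray:
        return self.data_max - self.data_min

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self._span
        out = np.empty_like(X)
        nonconst = span > 0
        scale = np.where(nonconst, span, 1.0)
        out = self.lo + (X - self.data_min) / scale * (self.hi - self.lo)
        mid = (self.lo + self.hi) / 2.0
        out[..., ~nonconst] = mid
        return out

    def invert(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self._span
        nonconst = span > 0
        scale = np.where(nonconst, span, 1.0)
        out = self.data_min + (X - self.lo) / (self.hi - self.lo) * scale
        out[..., ~nonconst] = np.broadcast_to(self.data_min, out.shape)[..., ~nonconst]
        return out


def fit_feature_scaler(features: np.ndarray, lo: float = 0.0, hi: float = 1.0) -> MinMaxScaler:
    """Fit a [lo, hi] minmax scaler on training features."""
    return MinMaxScaler.fit(features, lo, hi)


def maximin_select(features: np.ndarray, m: int) -> list[int]:
    """RS-maximin greedy reference selection.

    The first index is the row closest (Euclidean) to the mean of all rows;
    each subsequent index maximizes the minimum distance to the rows already
    selected.  Ties break toward the lowest row index, making the output
    deterministic.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a non-empty 2-D matrix")
    n = X.shape[0]
    if not 1 <= m <= n:
        raise ValueError(f"m must satisfy 1 <= m <= {n}, got {m}")
    mean = X.mean(axis=0)
    d0 = np.linalg.norm(X - mean, axis=1)
    first = int(np.argmin(d0))  # argmin takes the lowest index on ties
    selected = [first]
    min_dist = np.linalg.norm(X - X[first], axis=1)
    for _ in range(1, m):
        min_dist[selected] = -1.0  # never reselect
        nxt = int(np.argmax(min_dist))
        selected.append(nxt)
        d_new = np.linalg.norm(X - X[nxt], axis=1)
        np.minimum(min_dist, d_new, out=min_dist)
    return selected


@dataclass
class EMLMModel:
    """A trained EMLM: references, scalers and per-solvent weights."""

    reference_descriptors: np.ndarray  # (m, d) raw (unscaled) feature space
    reference_keys: list[tuple[str, str]]
    feature_scaler: MinMaxScaler
    target_scalers: dict[str, MinMaxScaler]
    weights: np.ndarray  # (m [+1 bias], n_solvents)
    solvent_labels: list[str]
    mbtr_fingerprint: str
    ridge_lambda: float = 0.0
    include_bias: bool = False
    training_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.reference_descriptors.shape[0]
        expected = m + (1 if self.include_bias else 0)
        if self.weights.shape != (expected, len(self.solvent_labels)):
            raise ValueError("weights shape inconsistent with references/solvents")


def _distance_features(
    scaled_X: np.ndarray, scaled_refs: np.ndarray, include_bias: bool
) -> np.ndarray:
    H = cdist(scaled_X, scaled_refs)
    if include_bias:
        H = np.hstack([H, np.ones((H.shape[0], 1))])
    return H


def _solve(H: np.ndarray, Y: np.ndarray, ridge_lambda: float) -> np.ndarray:
    if ridge_lambda > 0:
        A = H.T @ H + ridge_lambda * np.eye(H.shape[1])
        return np.linalg.solve(A, H.T @ Y)
    W, *_ = np.linalg.lstsq(H, Y, rcond=1e-10)
    return W


def emlm_fit(
    train_features: np.ndarray,
    train_targets: pd.DataFrame | np.ndarray,
    reference_fraction: float | int = 0.25,
    ridge_lambda: float = 0.0,
    seed: int = 0,
    *,
    solvent_labels: Sequence[str] | None = None,
    keys: Sequence[tuple[str, str]] | None = None,
    mbtr_fingerprint: str = "",
    include_bias: bool = False,
) -> EMLMModel:
    """Train an EMLM on descriptor rows and per-solvent targets.

    ``reference_fraction`` is either a fraction of the training set (0, 1]
    or an explicit reference count m.  ``seed`` is recorded for provenance;
    the fit itself is deterministic.
    """
    X = np.asarray(train_features, dtype=float)
    if isinstance(train_targets, pd.DataFrame):
        solvent_labels = list(train_targets.columns)
        if keys is None:
            keys = list(train_targets.index)
        Y = train_targets.to_numpy(dtype=float)
    else:
        Y = np.asarray(train_targets, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if solvent_labels is None:
            solvent_labels = [f"target{i}" for i in range(Y.shape[1])]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("features and targets must have aligned rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("NaN or Inf in training inputs")
    n = X.shape[0]
    if isinstance(reference_fraction, float) and reference_fraction <= 1.0:
        m = max(1, int(round(reference_fraction * n)))
    else:
        m = int(reference_fraction)
    if not 1 <= m <= n:
        raise ValueError(f"reference count {m} outside [1, {n}]")

    feature_scaler = MinMaxScaler.fit(X, 0.0, 1.0)
    Xs = feature_scaler.apply(X)
    ref_idx = maximin_select(Xs, m)
    refs_scaled = Xs[ref_idx]

    target_scalers: dict[str, MinMaxScaler] = {}
    Ys = np.empty_like(Y)
    for j, label in enumerate(solvent_labels):
        sc = MinMaxScaler.fit(Y[:, j : j + 1], -1.0, 1.0)
        target_scalers[label] = sc
        Ys[:, j : j + 1] = sc.apply(Y[:, j : j + 1])

    H = _distance_features(Xs, refs_scaled, include_bias)
    W = _solve(H, Ys, ridge_lambda)

    ref_keys = (
        [tuple(keys[i]) for i in ref_idx] if keys is not None else [("", str(i)) for i in ref_idx]
    )
    return EMLMModel(
        reference_descriptors=X[ref_idx].copy(),
        reference_keys=ref_keys,
        feature_scaler=feature_scaler,
        target_scalers=target_scalers,
        weights=W,
        solvent_labels=list(solvent_labels),
        mbtr_fingerprint=mbtr_fingerprint,
        ridge_lambda=ridge_lambda,
        include_bias=include_bias,
        training_metadata={"n_train": n, "m_references": m, "seed": seed},
    )


def emlm_predict(
    model: EMLMModel,
    features: np.ndarray,
    keys: Sequence[tuple[str, str]] | None = None,
    fingerprint: str | None = None,
) -> pd.DataFrame:
    """Predict chemical potentials (kcal/mol) for descriptor rows.

    Returns a DataFrame with one column per solvent, indexed by
    (molecule_id, conformer_id) when ``keys`` is given.  If ``fingerprint``
    is supplied it must match the fingerprint the model was trained with.
    """
    if fingerprint is not None and model.mbtr_fingerprint and fingerprint != model.mbtr_fingerprint:
        raise ValueError(
            f"descriptor fingerprint {fingerprint} does not match the model's "
            f"{model.mbtr_fingerprint}; re-encode with the training config"
        )
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    index = (
        pd.MultiIndex.from_tuples(list(keys), names=["molecule_id", "conformer_id"])
        if keys is not None
        else pd.RangeIndex(X.shape[0])
    )
    if X.shape[0] == 0:
        return pd.DataFrame(np.zeros((0, len(model.solvent_labels))),
                            columns=model.solvent_labels, index=index)
    Xs = model.feature_scaler.apply(X)
    refs_scaled = model.feature_scaler.apply(model.reference_descriptors)
    H = _distance_features(Xs, refs_scaled, model.include_bias)
    Ys = H @ model.weights
    Y = np.empty_like(Ys)
    for j, label in enumerate(model.solvent_labels):
        Y[:, j : j + 1] = model.target_scalers[label].invert(Ys[:, j : j + 1])
    return pd.DataFrame(Y, columns=model.solvent_labels, index=index)


# -- persistence -----------------------------------------------------------
# Single-file .npz archive: dense arrays plus one JSON metadata entry
# (version, fingerprint, solvents, hyperparameters, scaler ranges).


def save_model(model: EMLMModel, path: str | Path) -> None:
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "solvent_labels": model.solvent_labels,
        "mbtr_fingerprint": model.mbtr_fingerprint,
        "ridge_lambda": model.ridge_lambda,
        "include_bias": model.include_bias,
        "training_metadata": model.training_metadata,
        "reference_keys": [list(k) for k in model.reference_keys],
        "feature_range": [model.feature_scaler.lo, model.feature_scaler.hi],
        "target_range": [-1.0, 1.0],
    }
    arrays = {
        "reference_descriptors": model.reference_descriptors,
        "weights": model.weights,
        "feat_min": model.feature_scaler.data_min,
        "feat_max": model.feature_scaler.data_max,
        "meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    for j, label in enumerate(model.solvent_labels):
        sc = model.target_scalers[label]
        arrays[f"target_min_{j}"] = sc.data_min
        arrays[f"target_max_{j}"] = sc.data_max
    path = Path(path)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path: str | Path) -> EMLMModel:
    path = Path(path)
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:  # corrupt/truncated archive
        raise ValueError(f"cannot read model file {path}: {exc}") from exc
    if "meta_json" not in arrays:
        raise ValueError(f"{path} is not a confpot model file")
    meta = json.loads(bytes(arrays["meta_json"]).decode())
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {meta.get('format_version')!r} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    lo, hi = meta["feature_range"]
    feature_scaler = MinMaxScaler(arrays["feat_min"], arrays["feat_max"], lo, hi)
    target_scalers = {
        label: MinMaxScaler(arrays[f"target_min_{j}"], arrays[f"target_max_{j}"], -1.0, 1.0)
        for j, label in enumerate(meta["solvent_labels"])
    }
    return EMLMModel(
        reference_descriptors=arrays["reference_descriptors"],
        reference_keys=[tuple(k) for k in meta["reference_keys"]],
        feature_scaler=feature_scaler,
        target_scalers=target_scalers,
        weights=arrays["weights"],
        solvent_labels=meta["solvent_labels"],
        mbtr_fingerprint=meta["mbtr_fingerprint"],
        ridge_lambda=meta["ridge_lambda"],
        include_bias=meta["include_bias"],
        training_metadata=meta["training_metadata"],
    )
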