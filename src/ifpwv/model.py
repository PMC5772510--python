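"""Subsampled-bagging ensemble of single-hidden-layer networks for PWV.

The regressor maps the selected feature set to carotid-femoral pulse
wave velocity (m/s).  Aggregation is bagging *without* replacement:
each of ``n_estimators`` members trains on a random 66% subsample of
the training rows, and the ensemble prediction is the arithmetic mean
of the member outputs.  Each member is a single-hidden-layer network
(tanh hidden units, one per input feature by default; linear output)
fit by a batch optimizer of the L2-penalized squared-error objective
(penalty 0.01, 100 epochs).  Rows left out of a member's bag provide
the out-of-bag (OOB) RMSE trace used to judge convergence: the trace
flattens once additional members stop reducing the aggregate error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor

from .features import V_NAMES

__all__ = [
    "EnsembleConfig",
    "EnsembleModel",
    "stratified_split",
    "train_ensemble",
    "predict",
    "oob_rmse_trace",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Bagging and base-learner settings (defaults follow the method)."""

    n_estimators: int = 1000
    subsample_fraction: float = 0.66
    hidden_units: int | None = None  # None -> number of input features
    epochs: int = 100
    weight_penalty: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction < 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.hidden_units is not None and self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.n_estimators < 1 or self.epochs < 1:
            raise ValueError("n_estimators and epochs must be >= 1")
        if self.weight_penalty < 0:
            raise ValueError("weight_penalty must be non-negative")


@dataclass
class EnsembleModel:
    """A trained bag of base regressors with its standardization state."""

    members: list
    feature_names: tuple[str, ...]
    mean_: np.ndarray
    scale_: np.ndarray
    inbag: list[np.ndarray]
    config: EnsembleConfig
    oob_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    # member predictions on the training rows, cached for OOB analysis
    _train_pred: np.ndarray | None = None
    _train_y: np.ndarray | None = None


def stratified_split(
    records: pd.DataFrame,
    test_fraction: float = 0.2,
    n_bins: int = 10,
    seed: int = 0,
    pwv_col: str = "PWV_measured",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold back a test set whose PWV distribution follows the population.

    Rows are binned by PWV quantiles and split stratified by bin, so
    both partitions mirror the overall PWV distribution.  Falls back to
    a single bin (plain random split) with a warning when there are too
    few rows to fill the bins.
    """
    if pwv_col not in records.columns:
        raise ValueError(f"records lack a {pwv_col!r} column")
    pwv = records[pwv_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(pwv)):
        raise ValueError("PWV must be present and finite for every record")
    n = len(records)
    n_test = int(round(test_fraction * n))
    if n_test < n_bins * 2 or n < 4 * n_bins:
        warnings.warn(
            f"too few records (n={n}) for {n_bins} PWV bins; "
            "falling back to an unstratified split",
            stacklevel=2,
        )
        bins = np.zeros(n, dtype=int)
    else:
        bins = pd.qcut(pwv, q=n_bins, labels=False, duplicates="drop")
    train_idx, test_idx = train_test_split(
        np.arange(n),
        test_size=n_test,
        random_state=seed,
        stratify=bins,
        shuffle=True,
    )
    return records.iloc[np.sort(train_idx)], records.iloc[np.sort(test_idx)]


def _as_matrix(
    records: pd.DataFrame | np.ndarray, feature_names: tuple[str, ...]
) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        missing = [c for c in feature_names if c not in records.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {', '.join(missing)}")
        return records.loc[:, list(feature_names)].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(records, dtype=float))
    if X.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} feature columns, got {X.shape[1]}"
        )
    return X


def train_ensemble(
    records: pd.DataFrame,
    config: EnsembleConfig | None = None,
    feature_names: tuple[str, ...] = V_NAMES,
    target: str = "PWV_measured",
) -> EnsembleModel:
    """Fit the bagged network ensemble on complete-case training rows.

    Features are z-scored with statistics from the *full* training set
    (applied to inputs only); each member then trains on
    ``floor(subsample_fraction * N)`` distinct rows.  The run is
    bit-reproducible for a fixed ``(data, config, seed)``.
    """
    config = config or EnsembleConfig()
    X = _as_matrix(records, feature_names)
    y = records[target].to_numpy(dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite feature or target values; clean data first")
    n = len(y)
    n_bag = int(np.floor(config.subsample_fraction * n))
    if n_bag < 2:
        raise ValueError(f"subsample of {n_bag} rows is too small to train on")

    mean_ = X.mean(axis=0)
    scale_ = X.std(axis=0)
    scale_[scale_ == 0.0] = 1.0
    Z = (X - mean_) / scale_
    hidden = config.hidden_units or X.shape[1]

    ss = np.random.SeedSequence(config.seed)
    members: list[MLPRegressor] = []
    inbag: list[np.ndarray] = []
    train_pred = np.empty((config.n_estimators, n))
    for child in ss.spawn(config.n_estimators):
        rng = np.random.default_rng(child)
        idx = rng.choice(n, size=n_bag, replace=False)
        net = MLPRegressor(
            hidden_layer_sizes=(hidden,),
            activation="tanh",
            solver="lbfgs",
            alpha=config.weight_penalty,
            max_iter=config.epochs,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence at the epoch cap is expected
            net.fit(Z[idx], y[idx])
        members.append(net)
        inbag.append(np.sort(idx))
        train_pred[len(members) - 1] = net.predict(Z)

    model = EnsembleModel(
        members=members,
        feature_names=tuple(feature_names),
        mean_=mean_,
        scale_=scale_,
        inbag=inbag,
        config=config,
        _train_pred=train_pred,
        _train_y=y,
    )
    model.oob_trace = oob_rmse_trace(model)
    return model


def predict(
    model: EnsembleModel, records: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """Ensemble PWV prediction (m/s): mean over member outputs.

    DataFrame inputs are matched to the training columns by name, so
    column order does not matter.
    """
    X = _as_matrix(records, model.feature_names)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    Z = (X - model.mean_) / model.scale_
    preds = np.stack([m.predict(Z) for m in model.members])
    return preds.mean(axis=0)


def oob_rmse_trace(model: EnsembleModel) -> np.ndarray:
    """Cumulative out-of-bag RMSE after each bagging iteration.

    Entry ``k`` (1-based) aggregates, for every training row, the mean
    prediction of those members among the first ``k`` whose bag excluded
    the row; rows that were in every bag so far carry no OOB prediction
    yet and are left out of that entry's RMSE (NaN entry if no row is
    OOB yet).
    """
    if model._train_pred is None or model._train_y is None:
        raise ValueError("model was not trained in-session; OOB data unavailable")
    P = model._train_pred
    y = model._train_y
    m, n = P.shape
    oob = np.ones((m, n), dtype=bool)
    for k, idx in enumerate(model.inbag):
        oob[k, idx] = False
    cum_sum = np.cumsum(np.where(oob, P, 0.0), axis=0)
    cum_cnt = np.cumsum(oob, axis=0)
    trace = np.full(m, np.nan)
    for k in range(m):
        have = cum_cnt[k] > 0
        if not np.any(have):
            continue
        pred_k = cum_sum[k, have] / cum_cnt[k, have]
        trace[k] = float(np.sqrt(np.mean((pred_k - y[have]) ** 2)))
    return trace
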