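"""Blood-pressure regression harness and sensitivity metric.

The study's clinical training source (invasive arterial-line pressures
paired with PPG features) is not redistributable, so the harness pairs

* the study's *preprocessing rules* — windows whose systolic/diastolic
  range within 30 s exceeds 20/12 mmHg are discarded, per-feature 3-sd
  outliers removed, and features min-max rescaled to [0, 1];
* a *synthetic training generator* with a controllable linear-plus-noise
  dependence of systolic/diastolic pressure on the features, whose planted
  ground truth makes the harness testable offline;
* a model-agnostic fit/predict contract with reference adapters mirroring
  the study's three algorithms (Gaussian-kernel SVM with kernel scale 1.5,
  bagged regression trees, and a single-hidden-layer network with 100
  units);
* the sensitivity metric: the standard deviation of a trained model's
  predictions across the synthetic cohort.  True pressures for synthetic
  records are unknown, so prediction spread, not error, quantifies how
  strongly patient/device factors leak into a model's output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import BaggingRegressor
from sklearn.model_selection import KFold, train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "TARGETS",
    "SYS_RANGE_MAX_MMHG",
    "DIA_RANGE_MAX_MMHG",
    "SensitivityReport",
    "make_model",
    "preprocess_training",
    "generate_synthetic_training",
    "evaluate_split",
    "sensitivity_analysis",
    "BPModel",
]

TARGETS = ("systolic_bp", "diastolic_bp")
RANGE_COLS = ("window_sys_range", "window_dia_range")
SYS_RANGE_MAX_MMHG = 20.0
DIA_RANGE_MAX_MMHG = 12.0
OUTLIER_SD = 3.0
BP_BOUNDS_MMHG = (20.0, 300.0)


class _SkModel(Protocol):
    def fit(self, X, y): ...
    def predict(self, X): ...


@dataclass
class BPModel:
    """One regressor per pressure target behind a single fit/predict surface."""

    estimators: dict[str, _SkModel]
    fitted: bool = False

    def fit(self, X: np.ndarray, y: pd.DataFrame | np.ndarray) -> "BPModel":
        y = pd.DataFrame(y, columns=list(TARGETS)) if not isinstance(y, pd.DataFrame) else y
        for t in TARGETS:
            self.estimators[t].fit(np.asarray(X), np.asarray(y[t]))
        self.fitted = True
        return self

    def predict(self, X: np.ndarray) -> pd.DataFrame:
        if not self.fitted:
            raise ValueError("model is not fitted")
        return pd.DataFrame({t: self.estimators[t].predict(np.asarray(X)) for t in TARGETS})


def make_model(kind: str, seed: int = 0) -> BPModel:
    """Reference adapters: 'svm', 'trees', 'nn' (or 'linear' for testing).

    The SVM uses a Gaussian kernel with kernel scale 1.5 (gamma = 1/1.5^2)
    on standardized features; the network has one hidden layer of 100
    units.  These mirror the study's configurations but, trained on
    synthetic data, make no claim to its clinical error statistics.
    """
    if kind == "svm":
        est = make_pipeline(StandardScaler(), SVR(kernel="rbf", gamma=1.0 / 1.5**2))
    elif kind == "trees":
        est = BaggingRegressor(
            DecisionTreeRegressor(random_state=seed), n_estimators=30, random_state=seed
        )
    elif kind == "nn":
        est = make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=(100,), solver="lbfgs", max_iter=500, random_state=seed
            ),
        )
    elif kind == "linear":
        from sklearn.linear_model import LinearRegression

        est = LinearRegression()
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return BPModel({t: clone(est) for t in TARGETS})


def _feature_columns(df: pd.DataFrame) -> list[str]:
    skip = set(TARGETS) | set(RANGE_COLS)
    return [c for c in df.columns if c not in skip and pd.api.types.is_numeric_dtype(df[c])]


def preprocess_training(samples: pd.DataFrame) -> pd.DataFrame:
    """Apply the training-data preprocessing rules, in order.

    1. discard windows with systolic range > 20 mmHg or diastolic range
       > 12 mmHg;
    2. remove samples with any feature beyond 3 standard deviations of the
       surviving set;
    3. min-max rescale every feature to [0, 1] (degenerate constant
       features rescale to 0 with a warning).

    Raises if no samples survive.
    """
    df = samples.copy()
    feats = _feature_columns(df)
    if RANGE_COLS[0] in df.columns:
        keep = (df[RANGE_COLS[0]] <= SYS_RANGE_MAX_MMHG) & (
            df[RANGE_COLS[1]] <= DIA_RANGE_MAX_MMHG
        )
        df = df.loc[keep]
    if len(df) == 0:
        raise ValueError("no samples survive the window-range filter")
    X = df[feats]
    sd = X.std(ddof=1).replace(0, np.nan)
    z = (X - X.mean()).abs().div(sd)
    df = df.loc[(z.fillna(0) <= OUTLIER_SD).all(axis=1)]
    if len(df) == 0:
        raise ValueError("no samples survive outlier removal")
    out = df.copy()
    for c in feats:
        span = out[c].max() - out[c].min()
        if span == 0:
            import warnings

            warnings.warn(f"feature {c!r} is constant; rescaled to 0", stacklevel=2)
            out[c] = 0.0
        else:
            out[c] = (out[c] - out[c].min()) / span
    return out


def generate_synthetic_training(
    n: int,
    seed: int = 0,
    coefficients: dict[str, np.ndarray] | None = None,
    noise_sd: float = 5.0,
    *,
    n_features: int = 8,
) -> pd.DataFrame:
    """Synthetic (features, blood pressure) pairs with planted ground truth.

    Features are drawn from ranges matching the PWA extractor's output
    (widths of a few hundred ms, ratios of a few units, rescaled-amplitude
    features); pressures are a linear combination of the features plus
    i.i.d. Gaussian noise of sd ``noise_sd`` mmHg around physiologic
    intercepts (120/80).  The planted coefficients are stored in
    ``DataFrame.attrs["ground_truth"]``.
    """
    if n < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    cols = [f"f{i}" for i in range(n_features)]
    # loosely emulate PWA feature scales: times (s), ratios, amplitudes
    scales = np.resize([0.2, 0.6, 3.0, 1.0, 0.1, 2.2, 0.4, 1.5], n_features)
    X = rng.uniform(0.2, 1.0, size=(n, n_features)) * scales
    if coefficients is None:
        coefficients = {
            "systolic_bp": rng.normal(0.0, 8.0, n_features),
            "diastolic_bp": rng.normal(0.0, 5.0, n_features),
        }
    intercepts = {"systolic_bp": 120.0, "diastolic_bp": 80.0}
    df = pd.DataFrame(X, columns=cols)
    for t in TARGETS:
        y = intercepts[t] + X @ np.asarray(coefficients[t]) + rng.normal(0.0, noise_sd, n)
        df[t] = np.clip(y, *BP_BOUNDS_MMHG)
    df[RANGE_COLS[0]] = rng.uniform(0.0, 10.0, n)
    df[RANGE_COLS[1]] = rng.uniform(0.0, 6.0, n)
    df.attrs["ground_truth"] = {
        "coefficients": {t: np.asarray(coefficients[t]).tolist() for t in TARGETS},
        "intercepts": intercepts,
        "noise_sd": noise_sd,
    }
    return df


def evaluate_split(
    model: BPModel,
    samples: pd.DataFrame,
    train_fraction: float = 0.7,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Train on a 70% split with k-fold cross-validation, test on the rest.

    Returns a frame indexed by target with columns ``mean_error`` and
    ``error_sd`` (mmHg) on the held-out split plus the cross-validated
    ``cv_error_sd`` on the training portion — the summary format of the
    sphygmomanometer-validation standard (mean error against its < 5 mmHg
    bound, error sd against 8 mmHg).
    """
    feats = _feature_columns(samples)
    if len(samples) < folds:
        raise ValueError("fewer samples than folds")
    X = samples[feats].to_numpy()
    y = samples[list(TARGETS)]
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, train_size=train_fraction, random_state=seed
    )
    cv_err = {t: [] for t in TARGETS}
    for tr_idx, va_idx in KFold(folds, shuffle=True, random_state=seed).split(Xtr):
        # deepcopy, not sklearn clone: the contract is any fit/predict object
        m = BPModel({t: copy.deepcopy(model.estimators[t]) for t in TARGETS})
        m.fit(Xtr[tr_idx], ytr.iloc[tr_idx])
        pred = m.predict(Xtr[va_idx])
        for t in TARGETS:
            cv_err[t].extend((pred[t].to_numpy() - ytr.iloc[va_idx][t].to_numpy()).tolist())
    model.fit(Xtr, ytr)
    pred = model.predict(Xte)
    rows = {}
    for t in TARGETS:
        err = pred[t].to_numpy() - yte[t].to_numpy()
        rows[t] = {
            "mean_error": float(err.mean()),
            "error_sd": float(err.std(ddof=1)) if len(err) > 1 else 0.0,
            "cv_error_sd": float(np.std(cv_err[t], ddof=1)),
        }
    return pd.DataFrame(rows).T


@dataclass(frozen=True)
class SensitivityReport:
    """Prediction spread of one model across the synthetic cohort (mmHg)."""

    model: str
    prediction_sd: dict[str, float]
    n_records: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.prediction_sd.values()):
            raise ValueError("standard deviations must be non-negative")


def sensitivity_analysis(
    model: BPModel, cohort_features: pd.DataFrame, label: str = "model"
) -> SensitivityReport:
    """Standard deviation of predicted pressures over the synthetic cohort.

    A model insensitive to the patient/device factors spanned by the cohort
    produces near-constant predictions (sd near 0); a sensitive model's
    predictions spread.  Invariant to row order and to duplicating the
    cohort (population-sd convention).
    """
    if not model.fitted:
        raise ValueError("model must be fitted before sensitivity analysis")
    feats = _feature_columns(cohort_features)
    if len(cohort_features) < 2:
        raise ValueError("need at least two cohort rows")
    pred = model.predict(cohort_features[feats].to_numpy())
    sds = {t: float(pred[t].std(ddof=0)) for t in TARGETS}
    return SensitivityReport(label, sds, len(cohort_features))
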