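"""MLP risk probabilities and low/middle/high risk stratification.

A three-layer multilayer perceptron (inputs → one hidden layer → one
logistic output) maps four worker-level variables — occupational category,
era of first dust exposure, duration of dust exposure, and cumulative dust
exposure — to a probability of developing CWP. Risk classes are assigned by
two probability cutoffs: ``p < c_low`` is low risk, ``p ≥ c_high`` high
risk, the rest middle risk (a boundary value always goes to the upper
class). The cutoffs are calibrated so that the high-risk pool covers the
projected future case load expanded by 50 %, and the low-risk pool matches a
designated low-risk reference population.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import ClassVar, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

CATEGORY_LEVELS = ("tunneling", "mining", "combining", "helping")
ERA_LEVELS = ("1970-", "1980-", "1990-")

#: Original input variables and how many encoded columns each spans.
FEATURE_VARIABLES = (
    "occupational_category",
    "era_of_first_exposure",
    "duration_of_exposure",
    "cumulative_dust_exposure",
)


class CalibrationError(ValueError):
    """Threshold calibration cannot satisfy its constraints."""


@dataclass
class FeatureEncoder:
    """One-hot + standardization encoding with stored parameters."""

    log_cde: bool = True
    duration_mean: float = 0.0
    duration_sd: float = 1.0
    cde_mean: float = 0.0
    cde_sd: float = 1.0
    fitted: bool = False

    def _cde_values(self, df: pd.DataFrame) -> np.ndarray:
        cde = df["cde"].to_numpy(dtype=float)
        return np.log1p(cde) if self.log_cde else cde

    def fit(self, df: pd.DataFrame) -> "FeatureEncoder":
        dur = df["total_duration"].to_numpy(dtype=float)
        cde = self._cde_values(df)
        self.duration_mean, self.duration_sd = float(dur.mean()), float(dur.std() or 1.0)
        self.cde_mean, self.cde_sd = float(cde.mean()), float(cde.std() or 1.0)
        self.fitted = True
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("encoder not fitted")
        bad_cat = set(df["category"]) - set(CATEGORY_LEVELS)
        bad_era = set(df["era"]) - set(ERA_LEVELS)
        if bad_cat or bad_era:
            raise ValueError(f"unseen categorical level: {bad_cat | bad_era}")
        n = len(df)
        X = np.zeros((n, 9))
        cat_idx = {c: i for i, c in enumerate(CATEGORY_LEVELS)}
        era_idx = {e: i for i, e in enumerate(ERA_LEVELS)}
        X[np.arange(n), [cat_idx[c] for c in df["category"]]] = 1.0
        X[np.arange(n), [4 + era_idx[e] for e in df["era"]]] = 1.0
        X[:, 7] = (df["total_duration"].to_numpy(float) - self.duration_mean) / self.duration_sd
        X[:, 8] = (self._cde_values(df) - self.cde_mean) / self.cde_sd
        if not np.isfinite(X).all():
            raise ValueError("non-finite features after encoding")
        return X

    #: Encoded-column index groups per original input variable.
    GROUPS: ClassVar[Mapping[str, tuple[int, ...]]] = {
        "occupational_category": (0, 1, 2, 3),
        "era_of_first_exposure": (4, 5, 6),
        "duration_of_exposure": (7,),
        "cumulative_dust_exposure": (8,),
    }


@dataclass
class RiskModel:
    """A trained risk network with its encoding and training metadata."""

    clf: MLPClassifier
    encoder: FeatureEncoder
    hidden_units: int
    seed: int
    split_ratio: float = 0.7

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        return self.clf.predict_proba(self.encoder.transform(df))[:, 1]

    def save(self, path: str | Path) -> None:
        payload = {
            "hidden_units": self.hidden_units,
            "seed": self.seed,
            "split_ratio": self.split_ratio,
            "activation": self.clf.activation,
            "encoder": {
                "log_cde": self.encoder.log_cde,
                "duration_mean": self.encoder.duration_mean,
                "duration_sd": self.encoder.duration_sd,
                "cde_mean": self.encoder.cde_mean,
                "cde_sd": self.encoder.cde_sd,
            },
            "coefs": [c.tolist() for c in self.clf.coefs_],
            "intercepts": [b.tolist() for b in self.clf.intercepts_],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "RiskModel":
        payload = json.loads(Path(path).read_text())
        enc = FeatureEncoder(**payload["encoder"], fitted=True)
        clf = MLPClassifier(
            hidden_layer_sizes=(payload["hidden_units"],),
            activation=payload["activation"],
        )
        # minimal refit-free restoration
        clf.coefs_ = [np.asarray(c) for c in payload["coefs"]]
        clf.intercepts_ = [np.asarray(b) for b in payload["intercepts"]]
        clf.n_layers_ = len(clf.coefs_) + 1
        clf.n_outputs_ = 1
        clf.out_activation_ = "logistic"
        clf.classes_ = np.array([0, 1])
        clf._label_binarizer = None
        model = cls(
            clf=clf,
            encoder=enc,
            hidden_units=payload["hidden_units"],
            seed=payload["seed"],
            split_ratio=payload["split_ratio"],
        )
        return model


def split_data(
    df: pd.DataFrame, ratio: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive train/validation split (default 7:3)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if len(df) < 10:
        raise ValueError("need at least 10 records to split")
    perm = np.random.default_rng(seed).permutation(len(df))
    n_train = int(round(len(df) * ratio))
    return df.iloc[perm[:n_train]].copy(), df.iloc[perm[n_train:]].copy()


def train_model(
    train: pd.DataFrame,
    *,
    hidden_units: int = 9,
    seed: int = 0,
    max_iter: int = 300,
    label_column: str = "cwp_status",
    log_cde: bool = True,
) -> RiskModel:
    """Fit the MLP on a training frame with feature and label columns.

    The hidden layer uses tanh, the output is logistic; training is
    reproducible from the seed.
    """
    y = train[label_column].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    encoder = FeatureEncoder(log_cde=log_cde).fit(train)
    X = encoder.transform(train)
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden_units,),
        activation="tanh",
        solver="adam",
        max_iter=max_iter,
        random_state=seed,
        tol=1e-5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are expected
        clf.fit(X, y)
    return RiskModel(clf=clf, encoder=encoder, hidden_units=hidden_units, seed=seed)


def predict_risk(
    model: RiskModel, workers: pd.DataFrame, id_column: str = "worker_id"
) -> pd.DataFrame:
    """Per-worker predicted CWP probability."""
    probs = model.predict_proba(workers)
    return pd.DataFrame({"worker_id": workers[id_column].to_numpy(), "probability": probs})


@dataclass(frozen=True)
class ConfusionMetrics:
    """Accuracy / sensitivity / specificity with their counts."""

    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    tp: int
    tn: int
    n_pos: int
    n_neg: int

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


def confusion_metrics(
    probabilities: np.ndarray, labels: np.ndarray, cutoff: float
) -> ConfusionMetrics:
    """Threshold the probabilities at ``cutoff`` (≥ is positive) and score."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("empty label vector")
    pred = np.asarray(probabilities) >= cutoff
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    return ConfusionMetrics(
        accuracy_pct=100.0 * (tp + tn) / labels.size,
        sensitivity_pct=100.0 * tp / n_pos if n_pos else float("nan"),
        specificity_pct=100.0 * tn / n_neg if n_neg else float("nan"),
        tp=tp,
        tn=tn,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def variable_importance(
    model: RiskModel,
    data: pd.DataFrame,
    *,
    label_column: str = "cwp_status",
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance per original input variable, normalized to 1.

    All encoded columns of a categorical variable are permuted jointly; the
    importance is the mean increase in log-loss, floored at 0.
    """
    rng = np.random.default_rng(seed)
    X = model.encoder.transform(data)
    y = data[label_column].to_numpy(dtype=int)
    base = log_loss(y, model.clf.predict_proba(X)[:, 1], labels=[0, 1])
    raw = {}
    for var, cols in FeatureEncoder.GROUPS.items():
        cols = list(cols)
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            perm = rng.permutation(len(X))
            Xp[:, cols] = X[np.ix_(perm, cols)]
            deltas.append(
                log_loss(y, model.clf.predict_proba(Xp)[:, 1], labels=[0, 1]) - base
            )
        raw[var] = max(0.0, float(np.mean(deltas)))
    total = sum(raw.values())
    if total == 0:
        warnings.warn("all permutation importances are zero; returning zeros")
        return pd.Series(raw)
    return pd.Series({k: v / total for k, v in raw.items()})


def protected_pool_target(projected_total: float, expansion: float = 0.5) -> int:
    """High-risk pool size: the projected case load expanded by 50 %."""
    if projected_total <= 0:
        raise ValueError("projected_total must be positive")
    return int(round(projected_total * (1.0 + expansion)))


@dataclass(frozen=True)
class ThresholdCalibration:
    c_low: float
    c_high: float
    target_high: int
    n_high: int
    n_low: int


def calibrate_thresholds(
    probabilities: np.ndarray,
    projected_total: float,
    low_pool_size: int,
    grid: Sequence[float] | None = None,
    *,
    expansion: float = 0.5,
) -> ThresholdCalibration:
    """Choose (c_low, c_high) so the high-risk pool approximates the
    expanded projected case load and the low-risk pool approximates the
    designated low-risk population.

    Ties on the grid are broken toward the lower cutoff (a larger protected
    pool, a smaller low-risk pool).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability vector")
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
    grid = np.sort(np.asarray(grid, dtype=float))
    target_high = protected_pool_target(projected_total, expansion)

    n_high = np.array([(p >= c).sum() for c in grid])
    i_high = int(np.argmin(np.abs(n_high - target_high)))  # first = lowest cutoff
    if n_high[i_high] == 0 and target_high > 0:
        raise CalibrationError(
            f"no cutoff on the grid captures any worker (target {target_high})"
        )
    c_high = float(grid[i_high])

    low_candidates = grid[grid < c_high]
    if low_candidates.size == 0:
        raise CalibrationError("no grid value below c_high available for c_low")
    n_low = np.array([(p < c).sum() for c in low_candidates])
    i_low = int(np.argmin(np.abs(n_low - low_pool_size)))
    return ThresholdCalibration(
        c_low=float(low_candidates[i_low]),
        c_high=c_high,
        target_high=target_high,
        n_high=int(n_high[i_high]),
        n_low=int(n_low[i_low]),
    )


def classify_risk(
    assessments: pd.DataFrame, c_low: float, c_high: float
) -> pd.DataFrame:
    """Partition workers into low / middle / high by their probability."""
    if not c_low < c_high:
        raise ValueError("require c_low < c_high")
    p = assessments["probability"].to_numpy(dtype=float)
    cls = np.where(p >= c_high, "high", np.where(p < c_low, "low", "middle"))
    out = assessments.copy()
    out["risk_class"] = cls
    out["c_low"] = c_low
    out["c_high"] = c_high
    return out
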