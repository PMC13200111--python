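"""Per-axis gradient-boosted prediction of delivered spot positions.

Two independent regressors — one per steering axis — learn the delivered
isocenter-plane coordinate from plan-level features only: planned x and y,
nominal beam energy, treatment date (ordinal days since campaign start) and
treatment room.  Horizontal and vertical steering use separate magnets, and
the cross-axis deviation correlation is negligible, so per-axis models lose
nothing while keeping each model's target one-dimensional.

Generalisation to *future* sessions is what matters for prospective QA, so
evaluation uses a temporal split: every session in the final calendar month
of the campaign is held out.

The estimator is scikit-learn compatible (``fit``/``predict``/``get_params``)
and wraps :class:`xgboost.XGBRegressor` with squared-error objective,
500 trees and learning rate 0.1 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBRegressor

from .compare import ProjectionFactors, match_spots
from .errors import ValidationError
from .log_io import DeliverySession
from .plan_io import IonPlan

FEATURES = ["planned_x", "planned_y", "energy", "date_ordinal", "room_code"]

#: beam-energy bands (MeV) used for the per-band evaluation breakdown
ENERGY_BANDS = [(90.0, 110.0, "90-109"), (110.0, 120.0, "110-119"), (120.0, 130.0, "120-129")]


@dataclass
class ModelConfig:
    """Gradient-boosting hyperparameters (squared-error objective)."""

    n_trees: int = 500
    learning_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValidationError("learning_rate must be in (0, 1]")


class SpotPositionRegressor(RegressorMixin, BaseEstimator):
    """Gradient-boosted regressor for one delivered spot coordinate.

    Parameters
    ----------
    n_trees : int, default 500
        Number of boosting rounds.
    learning_rate : float, default 0.1
        Shrinkage applied to each tree's contribution.
    seed : int, default 0
        Random seed; training is deterministic given the seed and data.

    Attributes
    ----------
    model_ : fitted :class:`xgboost.XGBRegressor`
    feature_names_ : list of str, feature order seen during fit
    """

    def __init__(self, n_trees: int = 500, learning_rate: float = 0.1, seed: int = 0):
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X, y = validate_data(self, X, y, y_numeric=True)
        self.feature_names_ = (
            names if names is not None else [f"f{i}" for i in range(X.shape[1])]
        )
        if np.ptp(y) == 0:
            warnings.warn("target is constant; model will predict a constant", stacklevel=2)
        self.model_ = XGBRegressor(
            n_estimators=self.n_trees,
            learning_rate=self.learning_rate,
            objective="reg:squarederror",
            random_state=self.seed,
            tree_method="hist",
            n_jobs=1,
        )
        self.model_.fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = validate_data(self, X, reset=False)
        return self.model_.predict(X).astype(float)

    def feature_importance(self) -> dict[str, float]:
        """Gain-based feature importance, normalised to fractions summing to 1."""
        check_is_fitted(self, "model_")
        imp = np.asarray(self.model_.feature_importances_, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        return dict(zip(self.feature_names_, imp.tolist()))


def build_features(
    plan: IonPlan,
    sessions: list[DeliverySession],
    f: ProjectionFactors = ProjectionFactors(),
) -> pd.DataFrame:
    """One row per delivered spot across all sessions.

    Feature columns per :data:`FEATURES`; targets ``target_x``/``target_y``
    are the delivered coordinates projected to the isocenter plane; ``room``
    and ``date`` metadata columns are carried for splitting and breakdowns.
    """
    if not sessions:
        raise ValidationError("no sessions supplied")
    start = min(s.date for s in sessions)
    rooms = sorted({s.room for s in sessions})
    room_code = {r: i for i, r in enumerate(rooms)}
    frames = []
    for s in sessions:
        m = match_spots(plan, s)
        frames.append(
            pd.DataFrame(
                {
                    "room": s.room,
                    "date": pd.Timestamp(s.date),
                    "planned_x": m.planned_x,
                    "planned_y": m.planned_y,
                    "energy": m.energy,
                    "date_ordinal": (s.date - start).days,
                    "room_code": room_code[s.room],
                    "target_x": m.x_spm * f.f_x,
                    "target_y": m.y_spm * f.f_y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def temporal_split(rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out every session in the final calendar month as the test set."""
    dates = pd.to_datetime(rows["date"])
    periods = dates.dt.to_period("M")
    if periods.nunique() < 2:
        raise ValidationError("campaign spans a single calendar month; cannot split")
    last = periods.max()
    test_mask = (periods == last).to_numpy()
    train, test = rows[~test_mask], rows[test_mask]
    train_rooms, test_rooms = set(train["room"]), set(test["room"])
    for room in sorted(train_rooms - test_rooms):
        warnings.warn(f"room {room} has no sessions in the final month", stacklevel=2)
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train_axis_model(
    rows: pd.DataFrame, axis: str, cfg: ModelConfig = ModelConfig()
) -> SpotPositionRegressor:
    """Fit the per-axis position model on ``rows`` (axis 'x' or 'y')."""
    if axis not in ("x", "y"):
        raise ValidationError("axis must be 'x' or 'y'")
    if len(rows) < 100:
        raise ValidationError(f"need >= 100 training rows, got {len(rows)}")
    est = SpotPositionRegressor(
        n_trees=cfg.n_trees, learning_rate=cfg.learning_rate, seed=cfg.seed
    )
    return est.fit(rows[FEATURES], rows[f"target_{axis}"].to_numpy())


@dataclass
class EvalReport:
    """Held-out performance of the per-axis position models."""

    n: int
    mse_x: float
    mse_y: float
    r2_x: float | None
    r2_y: float | None
    euclid_mean: float
    euclid_max: float
    #: Pearson correlation of the (dx, dy) delivered-minus-planned deviations
    cross_axis_r: float
    by_room_date: pd.DataFrame
    by_energy_band: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mse_x": self.mse_x,
            "mse_y": self.mse_y,
            "r2_x": self.r2_x,
            "r2_y": self.r2_y,
            "euclid_mean": self.euclid_mean,
            "euclid_max": self.euclid_max,
            "cross_axis_r": self.cross_axis_r,
        }


def _metrics(a_x, p_x, a_y, p_y) -> dict:
    e = np.hypot(a_x - p_x, a_y - p_y)
    def _r2(a, p):
        return float(r2_score(a, p)) if np.ptp(a) > 0 else None
    return {
        "n": int(a_x.size),
        "mse_x": float(mean_squared_error(a_x, p_x)),
        "mse_y": float(mean_squared_error(a_y, p_y)),
        "r2_x": _r2(a_x, p_x),
        "r2_y": _r2(a_y, p_y),
        "euclid_mean": float(e.mean()),
        "euclid_max": float(e.max()),
    }


def evaluate(
    model_x: SpotPositionRegressor,
    model_y: SpotPositionRegressor,
    test_rows: pd.DataFrame,
) -> EvalReport:
    """Score both axis models on held-out rows.

    MSE is (1/n) sum (A_t - P_t)^2 and R^2 = 1 - SSR/SST per axis; the
    Euclidean distance is between predicted and delivered (x, y) per spot.
    Breakdowns by (room, date) and by beam-energy band mirror the per-session
    and per-band QA views.
    """
    if len(test_rows) == 0:
        raise ValidationError("empty test set")
    test_rows = test_rows.reset_index(drop=True)
    X = test_rows[FEATURES]
    p_x = model_x.predict(X)
    p_y = model_y.predict(X)
    a_x = test_rows["target_x"].to_numpy()
    a_y = test_rows["target_y"].to_numpy()
    overall = _metrics(a_x, a_y=a_y, p_x=p_x, p_y=p_y)

    dev_x = a_x - test_rows["planned_x"].to_numpy()
    dev_y = a_y - test_rows["planned_y"].to_numpy()
    if len(test_rows) > 1 and dev_x.std() > 0 and dev_y.std() > 0:
        cross_r = float(stats.pearsonr(dev_x, dev_y).statistic)
    else:
        cross_r = float("nan")

    rows_rd = []
    for (room, date), grp in test_rows.groupby(["room", "date"], sort=True):
        idx = grp.index.to_numpy()
        m = _metrics(a_x[idx], p_x[idx], a_y[idx], p_y[idx])
        rows_rd.append({"room": room, "date": date, **m})
    by_room_date = pd.DataFrame(rows_rd)

    rows_eb = []
    for room, grp in test_rows.groupby("room", sort=True):
        for lo, hi, label in ENERGY_BANDS:
            idx = grp.index.to_numpy()[
                (grp["energy"].to_numpy() >= lo) & (grp["energy"].to_numpy() < hi)
            ]
            if idx.size == 0:
                continue
            m = _metrics(a_x[idx], p_x[idx], a_y[idx], p_y[idx])
            rows_eb.append({"room": room, "energy_band": label, **m})
    by_energy_band = pd.DataFrame(rows_eb)

    return EvalReport(
        cross_axis_r=cross_r,
        by_room_date=by_room_date,
        by_energy_band=by_energy_band,
        **overall,
    )


def feature_importance(model: SpotPositionRegressor) -> dict[str, float]:
    """Normalised gain-based importances of a fitted axis model."""
    return model.feature_importance()
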