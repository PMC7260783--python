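"""Normalized conformal regression around each point model.

The applicability domain (AD) of a QSAR model is decided with conformal
prediction.  A second random forest, the *error model*, predicts the expected
absolute residual lambda of the point model for a compound; the nonconformity
score of a compound is the scaled residual

    alpha = |y - yhat| / lambda.

Calibration-set scores are sorted, and a prediction interval at confidence
1 - eps for a new compound is yhat +- lambda * alpha*, where alpha* is the
ceil((1-eps) * (n+1))-th smallest calibration score (the standard
finite-sample order-statistic convention; the interval is infinite when that
index exceeds n).  A prediction is in-domain when the interval width
(2 * half_width) does not exceed a configured maximum, 4.0 log units by
default (predicted value +- 2.0) at confidence 0.90.

Two calibration regimes are provided: inductive conformal prediction (ICP),
which holds out a single calibration split, and cross-conformal prediction
(CCP), which rotates the calibration role over k folds and pools the scores.

The error model is trained on out-of-bag residuals of the bagged point
forest: each tree's OOB sample never trained that tree, so these residuals
are out-of-fold by construction and avoid the optimism of in-sample
residuals without extra model fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .chemstruct import Molecule, morgan2_matrix
from .curation import LigandSet
from .qsar import DEFAULT_N_TREES, GateMetrics, PointModel, derive_seed, featurize, train_point_model

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE = 0.90
DEFAULT_MAX_WIDTH = 4.0
LAMBDA_FLOOR = 0.01


@dataclass
class ErrorModel:
    """Random forest predicting the expected absolute residual (lambda)."""

    forest: RandomForestRegressor
    floor: float = LAMBDA_FLOOR

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.maximum(self.forest.predict(X), self.floor)

    def predict_mols(self, mols) -> np.ndarray:
        return self.predict(morgan2_matrix(mols))


@dataclass(frozen=True)
class CalibrationTable:
    """Sorted nonconformity scores from the calibration compounds."""

    scores: np.ndarray  # ascending

    def __post_init__(self):
        if len(self.scores) < 1:
            raise ValueError("calibration table must contain at least one score")

    @property
    def n(self) -> int:
        return len(self.scores)

    def quantile(self, confidence: float) -> float:
        """alpha* at the given confidence; +inf when n is too small."""
        if not 0 < confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        idx = math.ceil(confidence * (self.n + 1))
        if idx > self.n:
            return math.inf
        return float(self.scores[idx - 1])


@dataclass(frozen=True)
class PredictionInterval:
    """Point prediction with a conformal half-width and the AD decision."""

    midpoint: float
    half_width: float
    confidence: float
    in_domain: bool


@dataclass
class ConformalBundle:
    """Everything needed to emit one fingerprint component for an assay."""

    assay_id: str
    point: PointModel
    error: ErrorModel
    table: CalibrationTable
    gate: GateMetrics


def nonconformity(y: float, y_hat: float, lam: float) -> float:
    """Scaled absolute residual alpha = |y - y_hat| / lam."""
    if lam <= 0:
        raise ValueError(f"scaling factor lambda must be positive, got {lam}")
    return abs(y - y_hat) / lam


def train_error_model(
    train: LigandSet,
    point: PointModel,
    seed: int,
    floor: float = LAMBDA_FLOOR,
    n_trees: int | None = None,
) -> ErrorModel:
    """Fit the error-prediction forest on out-of-bag residuals of ``point``.

    ``point`` must have been trained on exactly ``train`` (its OOB
    predictions are per-training-sample).  Compounds that appeared in every
    bootstrap (no OOB prediction) fall back to their in-sample residual.
    """
    if train.size < 2:
        raise ValueError("cannot train an error model on fewer than 2 compounds")
    X, y = featurize(train)
    oob = getattr(point.forest, "oob_prediction_", None)
    if oob is None or len(oob) != len(y):
        raise ValueError("point model lacks OOB predictions for this training set")
    residuals = np.abs(y - oob)
    bad = ~np.isfinite(residuals)
    if bad.any():
        residuals[bad] = np.abs(y - point.predict(X))[bad]
    forest = RandomForestRegressor(
        n_estimators=n_trees or point.n_trees,
        max_features=1.0,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, residuals)
    return ErrorModel(forest=forest, floor=floor)


def icp_calibrate(
    point: PointModel, error: ErrorModel, calibration_set: LigandSet
) -> CalibrationTable:
    """Nonconformity scores of held-out calibration compounds, sorted."""
    if calibration_set.size == 0:
        raise ValueError("empty calibration set")
    X, y = featurize(calibration_set)
    lam = error.predict(X)
    alpha = np.abs(y - point.predict(X)) / lam
    return CalibrationTable(scores=np.sort(alpha))


def icp_train(
    ligand_set: LigandSet,
    seed: int,
    calib_fraction: float = 0.3,
    n_trees: int = DEFAULT_N_TREES,
    floor: float = LAMBDA_FLOOR,
) -> tuple[PointModel, ErrorModel, CalibrationTable]:
    """Inductive conformal prediction: one proper-training/calibration split.

    Point and error models are trained on the proper training portion only;
    the held-out calibration compounds supply the score table.
    """
    n = ligand_set.size
    n_calib = max(1, round(n * calib_fraction))
    if n - n_calib < 2:
        raise ValueError(f"ligand set of size {n} too small for ICP with calib_fraction {calib_fraction}")
    rng = np.random.default_rng(derive_seed(seed, 401))
    perm = rng.permutation(n)
    ids = ligand_set.compound_ids
    calib_ids = [ids[i] for i in sorted(perm[:n_calib])]
    proper_ids = [ids[i] for i in sorted(perm[n_calib:])]
    proper = ligand_set.subset(proper_ids)
    point = train_point_model(proper, seed=derive_seed(seed, 402), n_trees=n_trees)
    error = train_error_model(proper, point, seed=derive_seed(seed, 403), floor=floor)
    table = icp_calibrate(point, error, ligand_set.subset(calib_ids))
    return point, error, table


def ccp_train(
    ligand_set: LigandSet,
    k: int = 10,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    floor: float = LAMBDA_FLOOR,
) -> tuple[PointModel, ErrorModel, CalibrationTable]:
    """Cross-conformal prediction: rotate the calibration role over k folds.

    Every compound contributes exactly one pooled calibration score (scored
    by models trained on the other k-1 folds); the returned point and error
    models are refit on the full ligand set.
    """
    n = ligand_set.size
    if n < k:
        raise ValueError(f"ligand set size {n} < number of CCP folds {k}")
    rng = np.random.default_rng(derive_seed(seed, 501))
    fold_of = np.array([i % k for i in range(n)])
    rng.shuffle(fold_of)
    ids = ligand_set.compound_ids
    scores = []
    for f in range(k):
        held_ids = [ids[i] for i in range(n) if fold_of[i] == f]
        rest_ids = [ids[i] for i in range(n) if fold_of[i] != f]
        rest = ligand_set.subset(rest_ids)
        point_f = train_point_model(rest, seed=derive_seed(seed, 502, f), n_trees=n_trees)
        error_f = train_error_model(rest, point_f, seed=derive_seed(seed, 503, f), floor=floor)
        scores.append(icp_calibrate(point_f, error_f, ligand_set.subset(held_ids)).scores)
    table = CalibrationTable(scores=np.sort(np.concatenate(scores)))
    point = train_point_model(ligand_set, seed=derive_seed(seed, 504), n_trees=n_trees)
    error = train_error_model(ligand_set, point, seed=derive_seed(seed, 505), floor=floor)
    return point, error, table


def predict_intervals(
    point: PointModel,
    error: ErrorModel,
    table: CalibrationTable,
    X: np.ndarray,
    confidence: float = DEFAULT_CONFIDENCE,
    max_width: float = DEFAULT_MAX_WIDTH,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized intervals: (midpoints, half_widths, in_domain) for rows of X."""
    mid = point.predict(X)
    alpha_star = table.quantile(confidence)
    half = error.predict(X) * alpha_star
    in_domain = 2.0 * half <= max_width
    return mid, half, in_domain


def predict_interval(
    point: PointModel,
    error: ErrorModel,
    table: CalibrationTable,
    mol: Molecule,
    confidence: float = DEFAULT_CONFIDENCE,
    max_width: float = DEFAULT_MAX_WIDTH,
) -> PredictionInterval:
    """Conformal prediction interval and AD decision for one molecule."""
    X = morgan2_matrix([mol])
    mid, half, ok = predict_intervals(point, error, table, X, confidence, max_width)
    return PredictionInterval(
        midpoint=float(mid[0]),
        half_width=float(half[0]),
        confidence=confidence,
        in_domain=bool(ok[0]),
    )
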