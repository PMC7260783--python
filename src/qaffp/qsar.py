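"""Per-assay random-forest QSAR regression with validation gating.

Each ligand set is split 80:20 into training and test portions by stratified
sampling of activity values.  A 100-tree random-forest regressor (every
feature considered at each split) is trained on 1024-bit Morgan2 fingerprints.
Model quality is measured by

* ``q2`` — cross-validated coefficient of determination, averaged over all
  folds of repeated 10-fold cross-validation of the training set, and
* ``r0_squared`` (R'0^2) — coefficient of determination of the test-set
  predicted-vs-observed regression constrained through the origin, with slope
  k' = sum(y*yhat) / sum(yhat^2).

Only models with q2 >= 0.5 and R'0^2 >= 0.6 pass the gate and become panel
members.

Stratification for continuous activities: compounds are sorted by activity and
partitioned into consecutive blocks; members of each block are assigned to
train/test (or to folds) at random within the block, so both portions see the
whole activity range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .chemstruct import morgan2_matrix
from .curation import LigandSet

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 100
GATE_Q2_MIN = 0.5
GATE_R2_MIN = 0.6


class UndefinedStatisticError(ValueError):
    """Raised when a determination coefficient is undefined for the input."""


def derive_seed(master: int, *parts: int) -> int:
    """Stable derived seed below 2^31 from a master seed and index parts."""
    mask = 0xFFFFFFFFFFFFFFFF
    h = (int(master) * 0x9E3779B97F4A7C15) & mask
    for p in parts:
        h ^= (int(p) + 0x9E3779B9 + ((h << 6) & mask) + (h >> 2)) & mask
    return h % 2**31


@dataclass(frozen=True)
class SplitPlan:
    """Train/test split and cross-validation folds over one ligand set."""

    train_ids: list[str]
    test_ids: list[str]
    folds: list[list[str]]
    ratio: float
    seed: int


@dataclass
class PointModel:
    """Trained random-forest point-prediction model for one assay."""

    assay_id: str
    forest: RandomForestRegressor
    n_trees: int
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(X)

    def predict_mols(self, mols) -> np.ndarray:
        return self.predict(morgan2_matrix(mols))


@dataclass(frozen=True)
class GateMetrics:
    """Validation statistics and the panel-inclusion decision."""

    q2: float
    r0_squared: float
    passed: bool


def featurize(ligand_set: LigandSet) -> tuple[np.ndarray, np.ndarray]:
    """Morgan2 feature matrix and activity vector for a ligand set."""
    return morgan2_matrix(ligand_set.molecules), ligand_set.activities


def q_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - SSres/SStot.

    May be negative; equals 1 iff predictions are exact.  Undefined (raises)
    when ``y`` is constant.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("q_squared needs two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("q_squared undefined for constant observed values")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def r0_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Determination coefficient of the through-origin predicted-vs-observed fit.

    Uses slope k' = sum(y*yhat)/sum(yhat^2) and returns
    1 - sum((y - k'*yhat)^2) / sum((y - mean(y))^2).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("r0_squared needs two equal-length vectors of length >= 2")
    denom = float(np.sum(y_hat**2))
    if denom == 0.0:
        raise UndefinedStatisticError("r0_squared undefined for all-zero predictions")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("r0_squared undefined for constant observed values")
    k = float(np.sum(y * y_hat)) / denom
    return 1.0 - float(np.sum((y - k * y_hat) ** 2)) / ss_tot


def _stratified_assign(
    ids: list[str], activities: np.ndarray, n_groups: int, rng: np.random.Generator
) -> list[list[str]]:
    """Assign ids to ``n_groups`` groups, stratified by activity.

    Ids are sorted by activity (compound id as tie-break), cut into
    consecutive blocks of size ``n_groups``, and each block is dealt to the
    groups in a random order, so group sizes differ by at most one and every
    group spans the activity range.
    """
    order = sorted(range(len(ids)), key=lambda i: (activities[i], ids[i]))
    groups: list[list[str]] = [[] for _ in range(n_groups)]
    for start in range(0, len(order), n_groups):
        block = order[start : start + n_groups]
        targets = rng.permutation(n_groups)[: len(block)]
        for i, g in zip(block, targets):
            groups[g].append(ids[i])
    return groups


def stratified_split(
    ligand_set: LigandSet, ratio: float = 0.8, k: int = 10, seed: int = 0
) -> SplitPlan:
    """Activity-stratified train/test split plus k CV folds over the training set."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n = ligand_set.size
    if n < k:
        raise ValueError(f"ligand set size {n} < number of folds {k}")
    rng = np.random.default_rng(seed)
    ids = ligand_set.compound_ids
    activities = ligand_set.activities

    block = max(2, round(1.0 / (1.0 - ratio)))
    n_test_per_block = round(block * (1.0 - ratio))
    order = sorted(range(n), key=lambda i: (activities[i], ids[i]))
    train_ids: list[str] = []
    test_ids: list[str] = []
    for start in range(0, n, block):
        chunk = order[start : start + block]
        m = len(chunk)
        n_test = n_test_per_block if m == block else round(m * (1.0 - ratio))
        picked = set(rng.choice(m, size=n_test, replace=False).tolist())
        for j, i in enumerate(chunk):
            (test_ids if j in picked else train_ids).append(ids[i])

    act_of = dict(zip(ids, activities))
    train_acts = np.array([act_of[cid] for cid in train_ids])
    folds = _stratified_assign(train_ids, train_acts, k, rng)
    return SplitPlan(train_ids=train_ids, test_ids=test_ids, folds=folds, ratio=ratio, seed=seed)


def train_point_model(
    train: LigandSet, seed: int, n_trees: int = DEFAULT_N_TREES
) -> PointModel:
    """Fit the point-prediction random forest on a (sub-)ligand set.

    100 trees by default, with every feature considered at each split; trained
    with bootstrap so out-of-bag predictions are available to the error model.
    """
    if train.size < 2:
        raise ValueError("cannot train a point model on fewer than 2 compounds")
    X, y = featurize(train)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1.0,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # tiny sets can leave a sample in every bootstrap; handled downstream
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        forest.fit(X, y)
    return PointModel(assay_id=train.assay_id, forest=forest, n_trees=n_trees, seed=seed)


def cross_validated_q2(
    ligand_set: LigandSet,
    plan: SplitPlan,
    repeats: int = 10,
    n_trees: int = DEFAULT_N_TREES,
) -> float:
    """Mean per-fold q2 over ``repeats`` rounds of k-fold CV of the training set.

    The first round uses the folds recorded in ``plan``; later rounds redraw
    stratified folds from seeds derived from ``plan.seed``.  Folds with a
    constant observed activity are excluded with a warning.
    """
    k = len(plan.folds)
    train = ligand_set.subset(plan.train_ids)
    act = dict(zip(train.compound_ids, train.activities))
    fold_q2: list[float] = []
    for r in range(repeats):
        if r == 0:
            folds = plan.folds
        else:
            rng = np.random.default_rng(derive_seed(plan.seed, 101, r))
            folds = _stratified_assign(plan.train_ids, np.array([act[c] for c in plan.train_ids]), k, rng)
        for f, fold in enumerate(folds):
            fold_set = set(fold)
            fit_ids = [cid for cid in plan.train_ids if cid not in fold_set]
            model = train_point_model(
                ligand_set.subset(fit_ids), seed=derive_seed(plan.seed, 211, r, f), n_trees=n_trees
            )
            held = ligand_set.subset(fold)
            y = held.activities
            if np.ptp(y) == 0:
                logger.warning("fold %d/run %d of %s has constant activity; excluded", f, r, ligand_set.assay_id)
                continue
            fold_q2.append(q_squared(y, model.predict_mols(held.molecules)))
    if not fold_q2:
        raise UndefinedStatisticError("no usable folds for cross-validated q2")
    return float(np.mean(fold_q2))


def evaluate_and_gate(
    ligand_set: LigandSet,
    plan: SplitPlan,
    q2_min: float = GATE_Q2_MIN,
    r2_min: float = GATE_R2_MIN,
    repeats: int = 10,
    n_trees: int = DEFAULT_N_TREES,
) -> GateMetrics:
    """Compute q2 (training CV) and R'0^2 (held-out test) and apply the gate.

    The final model is refit on the entire training portion before scoring the
    test set.  ``passed`` is the conjunction q2 >= q2_min and R'0^2 >= r2_min,
    both thresholds inclusive.
    """
    q2 = cross_validated_q2(ligand_set, plan, repeats=repeats, n_trees=n_trees)
    final = train_point_model(
        ligand_set.subset(plan.train_ids), seed=derive_seed(plan.seed, 307), n_trees=n_trees
    )
    test = ligand_set.subset(plan.test_ids)
    r0 = r0_squared(test.activities, final.predict_mols(test.molecules))
    return GateMetrics(q2=q2, r0_squared=r0, passed=(q2 >= q2_min and r0 >= r2_min))
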