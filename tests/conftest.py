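import numpy as np
import pytest

from qaffp.conformal import CalibrationTable, ConformalBundle, ccp_train, icp_train
from qaffp.curation import LigandSet
from qaffp.qsar import GateMetrics
from qaffp.synthetic import generate_ligand_set, make_assay_spec


class StubPoint:
    """Point model returning fixed predictions (for exact-value tests)."""

    def __init__(self, value):
        self.value = value

    def predict(self, X):
        v = np.broadcast_to(np.asarray(self.value, dtype=float), (len(X),))
        return np.array(v)


class StubError:
    """Error model returning a fixed lambda."""

    def __init__(self, lam):
        self.lam = lam

    def predict(self, X):
        return np.full(len(X), float(self.lam))


def stub_bundle(assay_id, prediction, lam=0.1, scores=None, passed=True):
    """Conformal bundle with fully controlled predictions and calibration.

    Default calibration: 99 unit scores, so the 0.90 quantile is exactly 1.0
    and the interval half-width equals lambda.
    """
    if scores is None:
        scores = np.full(99, 1.0)
    return ConformalBundle(
        assay_id=assay_id,
        point=StubPoint(prediction),
        error=StubError(lam),
        table=CalibrationTable(scores=np.asarray(scores, dtype=float)),
        gate=GateMetrics(q2=0.8, r0_squared=0.8, passed=passed),
    )


@pytest.fixture(scope="session")
def clean_ligand_set() -> LigandSet:
    """Noise-free synthetic assay: activity is an exact function of structure."""
    return generate_ligand_set(make_assay_spec(seed=7, n_compounds=120, noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_ligand_set() -> LigandSet:
    return generate_ligand_set(make_assay_spec(seed=8, n_compounds=150, noise_sigma=0.4))


@pytest.fixture(scope="session")
def icp_models(noisy_ligand_set):
    """(point, error, table) trained once by ICP on the noisy set."""
    return icp_train(noisy_ligand_set, seed=3, calib_fraction=0.3, n_trees=50)


@pytest.fixture(scope="session")
def small_panel_bundles(clean_ligand_set, noisy_ligand_set):
    """Two real conformal bundles (small forests) for panel-level tests."""
    bundles = []
    for ls, seed in ((clean_ligand_set, 1), (noisy_ligand_set, 2)):
        point, error, table = ccp_train(ls, k=5, seed=seed, n_trees=30)
        bundles.append(
            ConformalBundle(
                assay_id=ls.assay_id if seed == 1 else ls.assay_id + "_B",
                point=point,
                error=error,
                table=table,
                gate=GateMetrics(q2=0.7, r0_squared=0.7, passed=True),
            )
        )
    return bundles
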