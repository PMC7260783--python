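"""Empirical validity studies for the conformal machinery.

The headline property of an inductive conformal predictor is marginal
validity: over the joint draw of calibration and test data, an interval at
confidence 1 - eps contains the true value with probability at least 1 - eps.
:func:`icp_coverage_study` measures exactly that on synthetic assays with a
known generative model, pooling intervals over a few independent
proper-training / calibration / test replicates so the estimate reflects the
marginal guarantee rather than a single calibration draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemstruct import morgan2_matrix
from .conformal import icp_train, predict_intervals
from .qsar import derive_seed
from .synthetic import generate_ligand_set, make_assay_spec


@dataclass(frozen=True)
class CoverageStudyResult:
    """Pooled empirical coverage per confidence level."""

    coverage: dict[float, float]
    n_intervals: int

    def binomial_se(self, confidence: float) -> float:
        return float(np.sqrt(confidence * (1 - confidence) / self.n_intervals))


def icp_coverage_study(
    seed: int,
    confidences: tuple[float, ...] = (0.80, 0.90, 0.95),
    n_replicates: int = 3,
    n_compounds: int = 5050,
    n_proper: int = 600,
    n_calibration: int = 2500,
    noise_sigma: float = 0.4,
    n_trees: int = 50,
) -> CoverageStudyResult:
    """Empirical ICP interval coverage on exchangeable synthetic test points.

    Each replicate draws an independent synthetic assay (sparse linear
    structure-activity signal plus Normal(0, ``noise_sigma``) noise), splits
    it into proper-training / calibration / test, fits the point and error
    forests, calibrates, and scores every test interval.  Coverage is pooled
    over all replicates' test intervals.
    """
    n_fit = n_proper + n_calibration
    if n_fit >= n_compounds:
        raise ValueError("n_proper + n_calibration must leave a non-empty test set")
    hits: dict[float, list[bool]] = {c: [] for c in confidences}
    for r in range(n_replicates):
        spec = make_assay_spec(
            seed=derive_seed(seed, 11, r), n_compounds=n_compounds, noise_sigma=noise_sigma
        )
        ls = generate_ligand_set(spec)
        ids = ls.compound_ids
        rng = np.random.default_rng(derive_seed(seed, 12, r))
        perm = rng.permutation(ls.size)
        fit = ls.subset([ids[i] for i in perm[:n_fit]])
        test = ls.subset([ids[i] for i in perm[n_fit:]])
        point, error, table = icp_train(
            fit,
            seed=derive_seed(seed, 13, r),
            calib_fraction=n_calibration / n_fit,
            n_trees=n_trees,
        )
        X, y = morgan2_matrix(test.molecules), test.activities
        for conf in confidences:
            mid, half, _ = predict_intervals(point, error, table, X, confidence=conf)
            hits[conf].extend(((y >= mid - half) & (y <= mid + half)).tolist())
    n_intervals = len(hits[confidences[0]])
    return CoverageStudyResult(
        coverage={c: float(np.mean(v)) for c, v in hits.items()}, n_intervals=n_intervals
    )
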