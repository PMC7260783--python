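"""Affinity-panel assembly and rv-/b-fingerprint emission.

An :class:`AffinityPanel` is the ordered collection of gated conformal QSAR
bundles; its order defines fingerprint positions.  For a molecule,

* the real-valued fingerprint (rv) is the vector of point predictions across
  the panel on the -log10 M scale, optionally imputing out-of-domain
  components by the mean of that molecule's reliable components;
* the binary fingerprint (b) sets a bit when the predicted activity lies at or
  above a cutoff (5 by default, i.e. 10 uM) — and, when the AD policy is
  ``zero_outside``, only when the prediction is also in-domain, on the grounds
  that a compound outside a model's domain is more likely to be inactive.

Recommended defaults: rv — raw values with AD ignored; b — cutoff 5, ICP AD
at confidence 0.90 with maximum interval width 4.0, out-of-domain bits zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chemstruct import Molecule, morgan2_matrix
from .conformal import (
    DEFAULT_CONFIDENCE,
    DEFAULT_MAX_WIDTH,
    ConformalBundle,
    predict_intervals,
)

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 5.0


@dataclass(frozen=True)
class AffinityPanel:
    """Ordered, gated conformal bundles defining fingerprint positions."""

    bundles: tuple[ConformalBundle, ...]

    @property
    def length(self) -> int:
        return len(self.bundles)

    @property
    def assay_ids(self) -> list[str]:
        return [b.assay_id for b in self.bundles]


@dataclass(frozen=True)
class RvFingerprint:
    values: np.ndarray  # float, -log10 M
    reliable: np.ndarray  # bool, in-domain flags
    imputed: np.ndarray  # bool


@dataclass(frozen=True)
class BitFingerprint:
    bits: np.ndarray  # uint8
    cutoff: float
    ad_used: bool


def assemble_panel(bundles: list[ConformalBundle]) -> AffinityPanel:
    """Retain gate-passing bundles, sorted by assay id for a stable order."""
    passing = [b for b in bundles if b.gate.passed]
    if not passing:
        raise ValueError("no bundle passed the quality gate; panel is empty")
    ids = [b.assay_id for b in passing]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate assay ids in panel: {dupes}")
    return AffinityPanel(bundles=tuple(sorted(passing, key=lambda b: b.assay_id)))


def panel_predict(
    panel: AffinityPanel,
    mols: list[Molecule],
    confidence: float = DEFAULT_CONFIDENCE,
    max_width: float = DEFAULT_MAX_WIDTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Point predictions and AD flags for ``mols`` across the whole panel.

    Returns ``(values, in_domain)``, each of shape (n_mols, panel.length).
    """
    X = morgan2_matrix(mols)
    values = np.empty((len(mols), panel.length))
    in_domain = np.empty((len(mols), panel.length), dtype=bool)
    for j, bundle in enumerate(panel.bundles):
        mid, _, ok = predict_intervals(
            bundle.point, bundle.error, bundle.table, X, confidence, max_width
        )
        values[:, j] = mid
        in_domain[:, j] = ok
    return values, in_domain


def rv_qaffp_matrix(
    panel: AffinityPanel,
    mols: list[Molecule],
    ad_policy: str = "ignore",
    confidence: float = DEFAULT_CONFIDENCE,
    max_width: float = DEFAULT_MAX_WIDTH,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Real-valued fingerprints for many molecules: (values, reliable, imputed)."""
    if ad_policy not in {"ignore", "impute"}:
        raise ValueError(f"unknown rv AD policy {ad_policy!r}")
    values, reliable = panel_predict(panel, mols, confidence, max_width)
    imputed = np.zeros_like(reliable)
    if ad_policy == "impute":
        for i in range(len(mols)):
            bad = ~reliable[i]
            if not bad.any():
                continue
            if bad.all():
                raise ValueError(
                    f"molecule {mols[i].smiles!r} has no reliable component; rv fingerprint undefined under impute policy"
                )
            values[i, bad] = values[i, ~bad].mean()
            imputed[i, bad] = True
    return values, reliable, imputed


def rv_qaffp(
    panel: AffinityPanel,
    mol: Molecule,
    ad_policy: str = "ignore",
    confidence: float = DEFAULT_CONFIDENCE,
    max_width: float = DEFAULT_MAX_WIDTH,
) -> RvFingerprint:
    """Real-valued affinity fingerprint of one molecule.

    With ``ad_policy="impute"``, components whose conformal interval is wider
    than ``max_width`` at ``confidence`` are replaced by the mean of the
    molecule's reliable components and flagged; with ``"ignore"`` the raw
    predictions are kept and reliability flags merely recorded.
    """
    values, reliable, imputed = rv_qaffp_matrix(panel, [mol], ad_policy, confidence, max_width)
    return RvFingerprint(values=values[0], reliable=reliable[0], imputed=imputed[0])


def b_qaffp_matrix(
    panel: AffinityPanel,
    mols: list[Molecule],
    cutoff: float = DEFAULT_CUTOFF,
    ad_policy: str = "zero_outside",
    confidence: float = DEFAULT_CONFIDENCE,
    max_width: float = DEFAULT_MAX_WIDTH,
) -> np.ndarray:
    """Binary fingerprints for many molecules, shape (n_mols, panel.length)."""
    if ad_policy not in {"none", "zero_outside"}:
        raise ValueError(f"unknown b AD policy {ad_policy!r}")
    values, in_domain = panel_predict(panel, mols, confidence, max_width)
    bits = values >= cutoff
    if ad_policy == "zero_outside":
        bits &= in_domain
    return bits.astype(np.uint8)


def b_qaffp(
    panel: AffinityPanel,
    mol: Molecule,
    cutoff: float = DEFAULT_CUTOFF,
    ad_policy: str = "zero_outside",
    confidence: float = DEFAULT_CONFIDENCE,
    max_width: float = DEFAULT_MAX_WIDTH,
) -> BitFingerprint:
    """Binary affinity fingerprint of one molecule."""
    bits = b_qaffp_matrix(panel, [mol], cutoff, ad_policy, confidence, max_width)
    return BitFingerprint(bits=bits[0], cutoff=cutoff, ad_used=(ad_policy == "zero_outside"))


def mask_assays(panel: AffinityPanel, excluded_target_ids: list[str]) -> AffinityPanel:
    """Panel with the given assays removed (benchmark-target leakage control).

    An exclusion id matches an assay either exactly or as the target prefix of
    an ``"<target>:<rest>"`` assay id.  Unknown ids are ignored with a warning.
    """
    excluded = set(excluded_target_ids)
    matched: set[str] = set()
    kept = []
    for bundle in panel.bundles:
        target = bundle.assay_id.split(":", 1)[0]
        if bundle.assay_id in excluded or target in excluded:
            matched.add(bundle.assay_id if bundle.assay_id in excluded else target)
            continue
        kept.append(bundle)
    unknown = excluded - matched
    if unknown:
        logger.warning("mask_assays: ids not present in panel, ignored: %s", sorted(unknown))
    if not kept:
        raise ValueError("masking removed every panel assay")
    return AffinityPanel(bundles=tuple(kept))


def z_standardize(matrix: np.ndarray) -> np.ndarray:
    """Column-wise Z-standardization (population SD) of a compounds x assays matrix.

    Constant columns are left as zeros with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("z_standardize needs a 2-D matrix with at least 2 rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0)  # population SD
    constant = sd == 0
    if constant.any():
        logger.warning("z_standardize: %d constant column(s) set to zeros", int(constant.sum()))
    sd_safe = np.where(constant, 1.0, sd)
    out = (matrix - mean) / sd_safe
    out[:, constant] = 0.0
    return out
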