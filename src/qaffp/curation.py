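"""Curation of raw activity records into per-assay ligand sets.

An *assay* is one organism/target/activity-type combination; the activity
table carries one row per measured compound-assay activity.  Curation keeps
only exact ("=") measurements of the four dose-response activity types at high
provenance confidence, aggregates replicate measurements per compound-assay
pair (mean, kept only when replicates agree to SD < 0.5 log units), and emits
ligand sets large enough for QSAR modeling (strictly more than 50 distinct
activity records by default).

All activities live on the -log10 molar (pChEMBL-like) scale: 5 = 10 uM,
6 = 1 uM, 7 = 100 nM, 8 = 10 nM.  A unit converter is provided for tables
reported in molar concentrations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemstruct import Molecule, SmilesParseError, parse_molecule

logger = logging.getLogger(__name__)

ALLOWED_ACTIVITY_TYPES = frozenset({"IC50", "EC50", "Ki", "Kd"})
ALLOWED_CONFIDENCE = frozenset({7, 9})

#: multiplicative factor to molar for each supported concentration unit
_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}

DEFAULT_COLUMNS = (
    "compound_id",
    "smiles",
    "assay_id",
    "activity_type",
    "relation",
    "value",
    "confidence",
)


@dataclass(frozen=True)
class ActivityRecord:
    """One measured compound-assay activity with provenance fields."""

    compound_id: str
    smiles: str
    assay_id: str
    activity_type: str
    relation: str
    value: float  # -log10 molar
    confidence: int

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValueError(f"non-finite activity value for {self.compound_id}")


@dataclass(frozen=True)
class AggregatedActivity:
    """One compound-assay pair after replicate aggregation."""

    compound_id: str
    assay_id: str
    smiles: str
    value: float


@dataclass
class LigandSet:
    """Curated compounds and activities for a single assay."""

    assay_id: str
    compounds: list[tuple[str, Molecule, float]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.compounds)

    @property
    def compound_ids(self) -> list[str]:
        return [cid for cid, _, _ in self.compounds]

    @property
    def molecules(self) -> list[Molecule]:
        return [mol for _, mol, _ in self.compounds]

    @property
    def activities(self) -> np.ndarray:
        return np.array([act for _, _, act in self.compounds], dtype=float)

    def subset(self, compound_ids: list[str]) -> "LigandSet":
        """Sub-ligand-set restricted to ``compound_ids`` (in the given order)."""
        index = {cid: (cid, mol, act) for cid, mol, act in self.compounds}
        missing = [cid for cid in compound_ids if cid not in index]
        if missing:
            raise KeyError(f"compound ids not in ligand set {self.assay_id}: {missing[:5]}")
        return LigandSet(self.assay_id, [index[cid] for cid in compound_ids])


def to_pscale(value: float, unit: str) -> float:
    """Convert a concentration in ``unit`` to the -log10 molar scale.

    ``unit="p"`` means the value is already on the -log10 molar scale and is
    returned unchanged.  10 uM -> 5.0, 1 uM -> 6.0, 100 nM -> 7.0, 10 nM -> 8.0.
    """
    if unit == "p":
        return float(value)
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unsupported unit {unit!r}; expected one of {sorted(_UNIT_TO_MOLAR)} or 'p'")
    if value <= 0:
        raise ValueError(f"concentration must be positive, got {value} {unit}")
    return float(-math.log10(value * _UNIT_TO_MOLAR[unit]))


def filter_activity_records(records: list[ActivityRecord]) -> list[ActivityRecord]:
    """Keep only records usable for QSAR modeling, preserving order.

    Kept: activity type in {IC50, EC50, Ki, Kd}, relation exactly "=", and
    confidence score 7 or 9.
    """
    kept = [
        r
        for r in records
        if r.activity_type in ALLOWED_ACTIVITY_TYPES
        and r.relation == "="
        and r.confidence in ALLOWED_CONFIDENCE
    ]
    logger.info("activity filter: %d of %d records kept", len(kept), len(records))
    return kept


def aggregate_duplicates(
    records: list[ActivityRecord], sd_cutoff: float = 0.5
) -> list[AggregatedActivity]:
    """Aggregate replicate measurements per (compound, assay) pair.

    A pair with several values keeps their mean only when the sample standard
    deviation of all annotated measurements is below ``sd_cutoff``; otherwise
    the pair is discarded entirely.  Singleton pairs are kept as-is.
    """
    groups: dict[tuple[str, str], list[ActivityRecord]] = {}
    for r in records:
        groups.setdefault((r.compound_id, r.assay_id), []).append(r)
    out: list[AggregatedActivity] = []
    n_dropped = 0
    for (cid, aid), grp in groups.items():
        values = np.array([g.value for g in grp], dtype=float)
        if len(values) > 1 and float(np.std(values, ddof=1)) >= sd_cutoff:
            n_dropped += 1
            continue
        out.append(AggregatedActivity(cid, aid, grp[0].smiles, float(values.mean())))
    if n_dropped:
        logger.info("duplicate aggregation: %d discordant pairs discarded (SD >= %.2f)", n_dropped, sd_cutoff)
    out.sort(key=lambda a: (a.assay_id, a.compound_id))
    return out


def build_ligand_sets(
    aggregated: list[AggregatedActivity], min_size: int = 50
) -> list[LigandSet]:
    """Group aggregated activities by assay into :class:`LigandSet` objects.

    Only sets with strictly more than ``min_size`` distinct compounds are
    emitted.  Unparseable SMILES drop the affected compound with a warning.
    Output is deterministic and independent of input record order: sets are
    sorted by assay id and compounds by compound id.
    """
    by_assay: dict[str, list[AggregatedActivity]] = {}
    for agg in aggregated:
        by_assay.setdefault(agg.assay_id, []).append(agg)
    sets: list[LigandSet] = []
    for assay_id in sorted(by_assay):
        compounds: list[tuple[str, Molecule, float]] = []
        for agg in sorted(by_assay[assay_id], key=lambda a: a.compound_id):
            try:
                mol = parse_molecule(agg.smiles)
            except SmilesParseError:
                logger.warning(
                    "dropping compound %s in assay %s: unparseable SMILES %r",
                    agg.compound_id, assay_id, agg.smiles,
                )
                continue
            compounds.append((agg.compound_id, mol, agg.value))
        if len(compounds) > min_size:
            sets.append(LigandSet(assay_id, compounds))
        else:
            logger.info("assay %s excluded: %d <= %d compounds", assay_id, len(compounds), min_size)
    return sets


def read_activity_table(
    path: str | Path,
    sep: str | None = None,
    column_map: dict[str, str] | None = None,
    unit_column: str | None = None,
) -> list[ActivityRecord]:
    """Read a delimited activity table into :class:`ActivityRecord` objects.

    Expected columns (renameable through ``column_map``): compound_id, smiles,
    assay_id, activity_type, relation, value, confidence.  When
    ``unit_column`` is given, values are converted from that unit column to
    the -log10 molar scale; otherwise values must already be on that scale.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in DEFAULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity table {path} is missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        value = float(row.value)
        if unit_column is not None:
            value = to_pscale(value, str(getattr(row, unit_column)))
        records.append(
            ActivityRecord(
                compound_id=str(row.compound_id),
                smiles=str(row.smiles),
                assay_id=str(row.assay_id),
                activity_type=str(row.activity_type),
                relation=str(row.relation),
                value=value,
                confidence=int(row.confidence),
            )
        )
    if unit_column is not None:
        logger.info("converted %d values from column %r to -log10 M", len(records), unit_column)
    return records


def write_activity_table(records: list[ActivityRecord], path: str | Path) -> None:
    """Write records as a CSV consumable by :func:`read_activity_table`."""
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(DEFAULT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g")
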