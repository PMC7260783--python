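"""End-to-end orchestration: curation -> gated QSAR panel -> fingerprints -> benchmarks.

A single :class:`RunConfig` holds every tunable (defaults are the recommended
settings: q2 >= 0.5 and R'0^2 >= 0.6 gating, ICP applicability domain at
confidence 0.90 with maximum interval width 4.0, binary cutoff 5) and one
master seed determines every stochastic choice, so two runs with the same
config produce identical outputs.  Each run writes an audit copy of the
resolved config next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from . import benchmarks as bm
from .chemstruct import morgan2_matrix, parse_molecule
from .conformal import ConformalBundle, ccp_train, icp_train
from .curation import (
    LigandSet,
    aggregate_duplicates,
    build_ligand_sets,
    filter_activity_records,
    read_activity_table,
)
from .fingerprint import AffinityPanel, assemble_panel, b_qaffp_matrix, mask_assays, rv_qaffp_matrix
from .qsar import derive_seed, evaluate_and_gate, stratified_split

logger = logging.getLogger(__name__)


class GateFailureError(RuntimeError):
    """Raised when no assay survives the quality gate."""


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run (defaults = recommended settings)."""

    seed: int = 0
    confidence: float = 0.90
    max_width: float = 4.0
    cutoff: float = 5.0
    ad_policy_rv: str = "ignore"
    ad_policy_b: str = "zero_outside"
    q2_min: float = 0.5
    r2_min: float = 0.6
    min_set_size: int = 50
    split_ratio: float = 0.8
    cv_folds: int = 10
    cv_repeats: int = 10
    n_trees: int = 100
    conformal_method: str = "icp"  # icp | ccp
    calib_fraction: float = 0.3
    ccp_folds: int = 10
    # benchmark-harness repetition structure (None = the kind's default)
    sim_reps: int | None = None
    class_folds: int = 5
    class_repeats: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def write_audit_copy(self, directory: str | Path) -> None:
        Path(directory).mkdir(parents=True, exist_ok=True)
        (Path(directory) / "config.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _assay_seed(config: RunConfig, assay_id: str) -> int:
    # stable per-assay seed: fold the assay id into the master seed
    h = 0
    for ch in assay_id:
        h = (h * 131 + ord(ch)) % (2**31)
    return derive_seed(config.seed, h)


def build_panel_from_sets(
    ligand_sets: list[LigandSet], config: RunConfig
) -> tuple[AffinityPanel | None, dict]:
    """Gate each ligand set and train conformal bundles for the survivors.

    Returns the panel (None when nothing passed) and a machine-readable build
    report with per-assay q2, R'0^2 and the pass flag.
    """
    bundles: list[ConformalBundle] = []
    report: dict = {"assays": {}, "n_input_sets": len(ligand_sets)}
    for ls in ligand_sets:
        seed = _assay_seed(config, ls.assay_id)
        plan = stratified_split(ls, ratio=config.split_ratio, k=config.cv_folds, seed=seed)
        gate = evaluate_and_gate(
            ls, plan, q2_min=config.q2_min, r2_min=config.r2_min,
            repeats=config.cv_repeats, n_trees=config.n_trees,
        )
        report["assays"][ls.assay_id] = {
            "n_compounds": ls.size,
            "q2": round(gate.q2, 10),
            "r0_squared": round(gate.r0_squared, 10),
            "passed": gate.passed,
        }
        if not gate.passed:
            logger.info("assay %s failed gate (q2=%.3f, R'0^2=%.3f)", ls.assay_id, gate.q2, gate.r0_squared)
            continue
        train = ls.subset(plan.train_ids)
        if config.conformal_method == "ccp":
            point, error, table = ccp_train(train, k=config.ccp_folds, seed=seed, n_trees=config.n_trees)
        elif config.conformal_method == "icp":
            point, error, table = icp_train(
                train, seed=seed, calib_fraction=config.calib_fraction, n_trees=config.n_trees
            )
        else:
            raise ValueError(f"unknown conformal method {config.conformal_method!r}")
        bundles.append(ConformalBundle(assay_id=ls.assay_id, point=point, error=error, table=table, gate=gate))
    report["n_passed"] = len(bundles)
    panel = assemble_panel(bundles) if bundles else None
    return panel, report


def save_panel(panel: AffinityPanel, report: dict, directory: str | Path, config: RunConfig) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    joblib.dump(panel, directory / "panel.joblib")
    (directory / "build_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    config.write_audit_copy(directory)


def load_panel(directory: str | Path) -> AffinityPanel:
    return joblib.load(Path(directory) / "panel.joblib")


def run_build(config: RunConfig, activity_table: str | Path, out_dir: str | Path) -> AffinityPanel:
    """Curate an activity table, gate per-assay models, and persist the panel.

    The build report is written even when every assay fails the gate, in
    which case :class:`GateFailureError` is raised.
    """
    activity_table = Path(activity_table)
    if not activity_table.exists():
        raise FileNotFoundError(f"activity table not found: {activity_table}")
    records = read_activity_table(activity_table)
    kept = filter_activity_records(records)
    aggregated = aggregate_duplicates(kept)
    sets = build_ligand_sets(aggregated, min_size=config.min_set_size)
    report_counts = {
        "n_records": len(records),
        "n_after_filter": len(kept),
        "n_after_aggregation": len(aggregated),
        "n_ligand_sets": len(sets),
    }
    panel, report = build_panel_from_sets(sets, config)
    report["curation"] = report_counts
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "build_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    config.write_audit_copy(out_dir)
    if panel is None:
        raise GateFailureError("no assay passed the quality gate; see build_report.json")
    joblib.dump(panel, out_dir / "panel.joblib")
    logger.info("panel of %d assays written to %s", panel.length, out_dir)
    return panel


def make_schemes(panel: AffinityPanel, config: RunConfig, names: list[str]) -> list[bm.FingerprintScheme]:
    """Fingerprint schemes over a panel: morgan2 (Tanimoto), b (Rogot-Goldberg), rv."""
    schemes = []
    for name in names:
        if name == "morgan2":
            schemes.append(bm.FingerprintScheme("morgan2", lambda mols: morgan2_matrix(mols), "tanimoto"))
        elif name == "b":
            schemes.append(
                bm.FingerprintScheme(
                    "b",
                    lambda mols: b_qaffp_matrix(
                        panel, mols, cutoff=config.cutoff, ad_policy=config.ad_policy_b,
                        confidence=config.confidence, max_width=config.max_width,
                    ),
                    "rogot_goldberg",
                )
            )
        elif name == "rv":
            schemes.append(
                bm.FingerprintScheme(
                    "rv",
                    lambda mols: rv_qaffp_matrix(
                        panel, mols, ad_policy=config.ad_policy_rv,
                        confidence=config.confidence, max_width=config.max_width,
                    )[0],
                    None,
                )
            )
        else:
            raise ValueError(f"unknown fingerprint scheme {name!r}")
    return schemes


def _excluded_ids_for(bench_sets: list[bm.BenchSet]) -> list[str]:
    return [b.target_id for b in bench_sets]


def run_eval(
    config: RunConfig,
    panel: AffinityPanel,
    bench_sets: list[bm.BenchSet],
    out_dir: str | Path,
    tasks: list[str],
    scheme_names: list[str],
    mask_bench_targets: bool = False,
) -> dict:
    """Run the requested harnesses for every scheme and benchmark set.

    Writes one tidy CSV per task (one row per repetition) plus a summary JSON
    including exact-Wilcoxon comparisons between scheme pairs where enough
    paired per-set values exist.  With ``mask_bench_targets`` the benchmark
    targets are removed from the panel before fingerprinting.
    """
    if not bench_sets:
        raise ValueError("no benchmark sets supplied")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    eval_panel = mask_assays(panel, _excluded_ids_for(bench_sets)) if mask_bench_targets else panel
    schemes = make_schemes(eval_panel, config, scheme_names)
    summary: dict = {"panel_length": eval_panel.length, "tasks": {}}
    for task in tasks:
        rows = []
        per_set: dict[str, dict[str, float]] = {}
        for scheme in schemes:
            if task in {"sim"} and scheme.similarity is None:
                continue
            for bench in bench_sets:
                if task == "sim":
                    res = bm.run_similarity_benchmark(
                        bench, scheme, bm.SimilarityConfig(n_reps=config.sim_reps, seed=config.seed)
                    )
                elif task == "class":
                    res = bm.run_classification_benchmark(
                        bench,
                        scheme,
                        bm.ClassificationConfig(
                            n_folds=config.class_folds,
                            n_repeats=config.class_repeats,
                            n_trees=config.n_trees,
                            seed=config.seed,
                        ),
                    )
                elif task == "hop":
                    hop = bm.run_scaffold_hopping(bench, scheme, bm.HoppingConfig(seed=config.seed))
                    rows.append(
                        {
                            "scheme": scheme.name, "target_id": bench.target_id, "repetition": 0,
                            "n_acsk_total": hop.n_acsk_total, "n_racsk": hop.n_racsk,
                            "n_retrieved": hop.n_retrieved,
                        }
                    )
                    per_set.setdefault(scheme.name, {})[bench.target_id] = hop.n_retrieved
                    continue
                else:
                    raise ValueError(f"unknown task {task!r}")
                for i, (auc, ef5) in enumerate(res.repetitions):
                    rows.append(
                        {
                            "scheme": scheme.name, "target_id": bench.target_id, "repetition": i,
                            "auc": round(auc, 10), "ef5": round(ef5, 10),
                        }
                    )
                per_set.setdefault(scheme.name, {})[bench.target_id] = res.auc_mean
        df = pd.DataFrame(rows)
        df.to_csv(out_dir / f"{task}_repetitions.csv", index=False, float_format="%.10g")
        task_summary: dict = {"per_scheme": {}}
        for scheme_name, values in per_set.items():
            task_summary["per_scheme"][scheme_name] = {
                "mean": round(float(np.mean(list(values.values()))), 10),
                "n_sets": len(values),
            }
        task_summary["wilcoxon"] = _pairwise_wilcoxon(per_set)
        summary["tasks"][task] = task_summary
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    config.write_audit_copy(out_dir)
    return summary


def _pairwise_wilcoxon(per_set: dict[str, dict[str, float]]) -> dict:
    """Two-sided exact Wilcoxon between each scheme pair on paired per-set values."""
    out: dict = {}
    names = sorted(per_set)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = sorted(set(per_set[a]) & set(per_set[b]))
            x = np.array([per_set[a][t] for t in shared])
            y = np.array([per_set[b][t] for t in shared])
            key = f"{a}_vs_{b}"
            try:
                out[key] = {"p_two_sided": round(bm.wilcoxon_exact_paired(x, y, "two_sided"), 10), "n": len(shared)}
            except ValueError as exc:
                out[key] = {"error": str(exc), "n": len(shared)}
    return out


def fingerprint_table(
    panel: AffinityPanel,
    smiles: list[str],
    mode: str,
    config: RunConfig,
) -> pd.DataFrame:
    """Fingerprint a SMILES list into a tidy table (compound rows, assay columns)."""
    mols = [parse_molecule(s) for s in smiles]
    if mode == "rv":
        values, _, _ = rv_qaffp_matrix(
            panel, mols, ad_policy=config.ad_policy_rv,
            confidence=config.confidence, max_width=config.max_width,
        )
    elif mode == "b":
        values = b_qaffp_matrix(
            panel, mols, cutoff=config.cutoff, ad_policy=config.ad_policy_b,
            confidence=config.confidence, max_width=config.max_width,
        )
    else:
        raise ValueError(f"unknown fingerprint mode {mode!r}")
    df = pd.DataFrame(values, columns=panel.assay_ids)
    df.insert(0, "smiles", [m.smiles for m in mols])
    return df
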