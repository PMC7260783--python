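"""Evaluation harnesses: similarity searching, classification, scaffold hopping.

The three tasks mirror standard ligand-based virtual-screening practice:

* similarity searching — rank a test pool by its maximum similarity (MAX
  group fusion) to a handful of query actives; heterogeneous (HET) sets use 50
  repetitions of 10 random queries plus 20% of inactives withheld into the
  training side, homogeneous (HOM) sets a single larger query set plus 10% of
  inactives;
* bioactivity classification — 5-fold cross-validation, repeated 10 times, of
  a balanced random forest on labeled actives/inactives (CLASS sets require
  strictly more than 60 of each);
* scaffold hopping — for every rich active cyclic skeleton (RACSK: a CSK with
  at least five active members) train a balanced random forest on that CSK's
  actives plus all inactives, classify the remaining actives at probability
  threshold 0.5, and count the unique CSKs retrieved across all training sets.

Performance is summarized by ROC AUC and the enrichment factor in the top 5%
of the ranked list (EF5); binary fingerprints are compared with the
Rogot-Goldberg index, structural Morgan2 fingerprints with Tanimoto.  Scheme
comparisons use the exact Wilcoxon paired signed-rank test and the
signed-rank-inverted (Hodges-Lehmann) confidence interval for the paired
difference.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .chemstruct import Molecule, NoScaffoldError, cyclic_skeleton, parse_molecule
from .ensemble import BalancedRandomForestClassifier
from .qsar import derive_seed

logger = logging.getLogger(__name__)

EF_DEFAULT_FRACTION = 0.05
WILCOXON_EXACT_MAX_N = 25


# ---------------------------------------------------------------------------
# data containers

@dataclass
class BenchSet:
    """Per-target benchmark set of active and inactive molecules."""

    target_id: str
    actives: list[Molecule]
    inactives: list[Molecule]
    kind: str  # HET | HOM | CLASS
    active_activities: Optional[np.ndarray] = None
    inactive_activities: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in {"HET", "HOM", "CLASS"}:
            raise ValueError(f"unknown benchmark kind {self.kind!r}")
        overlap = {m.smiles for m in self.actives} & {m.smiles for m in self.inactives}
        if overlap:
            raise ValueError(f"actives and inactives overlap: {sorted(overlap)[:3]}")


@dataclass(frozen=True)
class RankedList:
    """Scored test pool with binary activity labels (1 = active)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels must have equal length")

    @property
    def n_total(self) -> int:
        return len(self.scores)

    @property
    def n_actives(self) -> int:
        return int(np.sum(self.labels == 1))


@dataclass
class BenchResult:
    """AUC/EF5 evaluations with repetition structure (mean +- SEM)."""

    repetitions: list[tuple[float, float]]  # (auc, ef5) per repetition

    def _col(self, i: int) -> np.ndarray:
        return np.array([r[i] for r in self.repetitions])

    @property
    def auc_mean(self) -> float:
        return float(self._col(0).mean())

    @property
    def auc_sem(self) -> float:
        v = self._col(0)
        return float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0

    @property
    def ef5_mean(self) -> float:
        return float(self._col(1).mean())

    @property
    def ef5_sem(self) -> float:
        v = self._col(1)
        return float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0


@dataclass
class HoppingResult:
    """Retrieved-chemotype counts for one assay's scaffold-hopping run."""

    assay_id: str
    n_acsk_total: int
    n_racsk: int
    retrieved_csk_ids: frozenset[str]

    @property
    def n_retrieved(self) -> int:
        return len(self.retrieved_csk_ids)


@dataclass(frozen=True)
class FingerprintScheme:
    """A molecule encoding plus the similarity metric it is searched with."""

    name: str
    encode: Callable[[list[Molecule]], np.ndarray]
    similarity: Optional[str] = None  # "tanimoto" | "rogot_goldberg" | None


# ---------------------------------------------------------------------------
# binary similarity metrics

def _confusion_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("binary similarity needs two equal-length non-empty vectors")
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    d = int(np.sum(~x & ~y))
    return a, b, c, d


def rogot_goldberg(x: np.ndarray, y: np.ndarray) -> float:
    """Rogot-Goldberg index a/(2a+b+c) + d/(2d+b+c), crediting shared 0s too.

    A term with zero denominator (no shared-on or no shared-off information)
    contributes 0.
    """
    a, b, c, d = _confusion_counts(x, y)
    s = 0.0
    if 2 * a + b + c > 0:
        s += a / (2 * a + b + c)
    if 2 * d + b + c > 0:
        s += d / (2 * d + b + c)
    return s


def tanimoto(x: np.ndarray, y: np.ndarray) -> float:
    """Tanimoto index a/(a+b+c); defined as 0 (with a warning) for two all-zero vectors."""
    a, b, c, _ = _confusion_counts(x, y)
    if a + b + c == 0:
        logger.warning("tanimoto of two all-zero vectors; returning 0")
        return 0.0
    return a / (a + b + c)


def _bulk_counts(Q: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    Q = np.asarray(Q, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    a = Q @ P.T
    b = Q.sum(axis=1)[:, None] - a
    c = P.sum(axis=1)[None, :] - a
    d = Q.shape[1] - a - b - c
    return a, b, c, d


def similarity_matrix(Q: np.ndarray, P: np.ndarray, metric: str) -> np.ndarray:
    """All-pairs similarity between binary row-matrices Q (queries) and P (pool)."""
    a, b, c, d = _bulk_counts(Q, P)
    if metric == "tanimoto":
        denom = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(denom > 0, a / np.where(denom > 0, denom, 1), 0.0)
        return out
    if metric == "rogot_goldberg":
        d1 = 2 * a + b + c
        d2 = 2 * d + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            t1 = np.where(d1 > 0, a / np.where(d1 > 0, d1, 1), 0.0)
            t2 = np.where(d2 > 0, d / np.where(d2 > 0, d2, 1), 0.0)
        return t1 + t2
    raise ValueError(f"unknown similarity metric {metric!r}")


def max_fusion_scores(queries: np.ndarray, pool: np.ndarray, sim: str) -> np.ndarray:
    """MAX group fusion: each pool member scored by its best similarity to any query."""
    queries = np.atleast_2d(queries)
    if queries.shape[0] == 0:
        raise ValueError("MAX fusion needs at least one query")
    if np.atleast_2d(pool).shape[0] == 0:
        return np.zeros(0)
    return similarity_matrix(queries, np.atleast_2d(pool), sim).max(axis=0)


# ---------------------------------------------------------------------------
# retrieval metrics

def roc_auc(ranked: RankedList) -> float:
    """Area under the ROC curve in Mann-Whitney form, ties credited 1/2."""
    labels = np.asarray(ranked.labels)
    n_act = ranked.n_actives
    n_inact = ranked.n_total - n_act
    if n_act == 0 or n_inact == 0:
        raise ValueError("roc_auc needs at least one active and one inactive")
    ranks = rankdata(ranked.scores)
    return float((ranks[labels == 1].sum() - n_act * (n_act + 1) / 2) / (n_act * n_inact))


def enrichment_factor(
    ranked: RankedList, chi: float = EF_DEFAULT_FRACTION, tie_seed: int = 0
) -> float:
    """Enrichment factor (P_chi/N_chi)/(P_total/N_total) with N_chi = ceil(chi*N).

    Ties at the segment boundary are broken by a seeded pre-shuffle followed
    by a stable sort, so the value is reproducible and order-independent.
    """
    if not 0 < chi <= 1:
        raise ValueError("chi must be in (0, 1]")
    if ranked.n_actives < 1:
        raise ValueError("enrichment factor needs at least one active")
    n = ranked.n_total
    n_top = math.ceil(chi * n)
    perm = np.random.default_rng(tie_seed).permutation(n)
    order = perm[np.argsort(-np.asarray(ranked.scores)[perm], kind="stable")]
    p_top = int(np.sum(np.asarray(ranked.labels)[order[:n_top]] == 1))
    return (p_top / n_top) / (ranked.n_actives / n)


# ---------------------------------------------------------------------------
# exact Wilcoxon paired signed-rank machinery

def _signed_rank_counts(ranks2: np.ndarray) -> np.ndarray:
    """Exact null counts of 2*W+ over all sign assignments (DP convolution).

    ``ranks2`` are the doubled (hence integer) midranks of |differences|.
    counts[s] = number of sign assignments with 2*W+ == s; counts sum to 2^n.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_exact_paired(x: np.ndarray, y: np.ndarray, alternative: str = "two_sided") -> float:
    """Exact Wilcoxon paired signed-rank p-value by full null enumeration.

    Zero differences are dropped (with a logged count); midranks handle ties
    among the |differences|.  The null distribution of the positive-rank sum
    W+ is enumerated exactly over all 2^n sign assignments (as a convolution,
    which is equivalent to the explicit enumeration).  ``alternative="greater"``
    tests whether ``x`` tends to exceed ``y``.  Limited to n <= 25 pairs; use
    a normal-approximation test for larger samples.
    """
    if alternative not in {"greater", "less", "two_sided"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    diffs = x - y
    n_zero = int(np.sum(diffs == 0))
    if n_zero:
        logger.info("wilcoxon_exact_paired: dropping %d zero difference(s)", n_zero)
        diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise ValueError("all paired differences are zero; the test is degenerate")
    if n > WILCOXON_EXACT_MAX_N:
        raise ValueError(
            f"n={n} exceeds the exact-enumeration limit {WILCOXON_EXACT_MAX_N}; "
            "use a normal-approximation signed-rank test instead"
        )
    ranks2 = np.round(2 * rankdata(np.abs(diffs))).astype(int)
    w2 = int(ranks2[diffs > 0].sum())
    counts = _signed_rank_counts(ranks2)
    denom = 2.0**n
    p_ge = counts[w2:].sum() / denom
    p_le = counts[: w2 + 1].sum() / denom
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def paired_difference_ci(diffs: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Signed-rank-inverted (Hodges-Lehmann-style) CI for a paired location shift.

    The bounds are order statistics of the Walsh averages (d_i + d_j)/2, i<=j,
    at the exact signed-rank critical value for ``level``.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 6:
        raise ValueError("paired_difference_ci needs at least 6 pairs")
    walsh = np.sort([(diffs[i] + diffs[j]) / 2 for i in range(n) for j in range(i, n)])
    m = len(walsh)  # n(n+1)/2
    alpha = 1.0 - level
    counts = _signed_rank_counts(2 * np.arange(1, n + 1))
    cdf = np.cumsum(counts) / 2.0**n  # cdf[2w] = P(W+ <= w)
    w_values = np.arange(0, m + 1)
    probs = cdf[2 * w_values]
    below = np.flatnonzero(probs <= alpha / 2)
    if len(below) == 0:
        raise ValueError(f"confidence level {level} unattainable exactly for n={n}")
    k = int(below.max()) + 1  # 1-based order statistic
    return float(walsh[k - 1]), float(walsh[m - k])


# ---------------------------------------------------------------------------
# harness configuration

@dataclass
class SimilarityConfig:
    n_reps: Optional[int] = None  # kind default: HET 50, HOM 1
    n_queries: int = 10  # HET query actives per repetition
    query_fraction: float = 0.5  # HOM: fraction of actives used as queries
    inactive_train_fraction: Optional[float] = None  # kind default: HET 0.2, HOM 0.1
    active_test_cap: Optional[int] = None  # HOM platform-style cap; None = all
    chi: float = EF_DEFAULT_FRACTION
    seed: int = 0


@dataclass
class ClassificationConfig:
    n_folds: int = 5
    n_repeats: int = 10
    n_trees: int = 100
    min_class_size: int = 60  # strictly more than this many of each class
    chi: float = EF_DEFAULT_FRACTION
    seed: int = 0


@dataclass
class HoppingConfig:
    min_racsk_size: int = 5
    prob_threshold: float = 0.5
    n_trees: int = 100
    seed: int = 0
    #: plug-in classifier factory(seed) -> fit/predict_proba object; None = balanced RF
    classifier_factory: Optional[Callable[[int], object]] = None


# ---------------------------------------------------------------------------
# harnesses

def run_similarity_benchmark(
    bench: BenchSet, scheme: FingerprintScheme, config: SimilarityConfig | None = None
) -> BenchResult:
    """Similarity-searching evaluation with MAX fusion over query actives.

    HET protocol: per repetition, sample ``n_queries`` actives as queries and
    withhold ``inactive_train_fraction`` (default 20%) of the inactives; the
    remaining actives and inactives form the test pool.  HOM protocol: a
    single repetition using ``query_fraction`` of the actives as queries and
    10% of inactives withheld.  Pool compounds are scored by their maximum
    similarity to any query, and AUC / EF(chi) computed on the ranked pool.
    """
    config = config or SimilarityConfig()
    if scheme.similarity is None:
        raise ValueError(f"scheme {scheme.name!r} has no similarity metric; cannot search")
    is_het = bench.kind != "HOM"
    n_reps = config.n_reps if config.n_reps is not None else (50 if is_het else 1)
    inact_frac = (
        config.inactive_train_fraction
        if config.inactive_train_fraction is not None
        else (0.2 if is_het else 0.1)
    )
    n_act, n_inact = len(bench.actives), len(bench.inactives)
    n_q = config.n_queries if is_het else max(1, round(config.query_fraction * n_act))
    if n_act <= n_q:
        raise ValueError(
            f"benchmark {bench.target_id}: {n_act} actives cannot supply "
            f"{n_q} queries plus a non-empty test set"
        )
    A = np.atleast_2d(scheme.encode(bench.actives))
    I = np.atleast_2d(scheme.encode(bench.inactives))
    reps: list[tuple[float, float]] = []
    for r in range(n_reps):
        rng = np.random.default_rng(derive_seed(config.seed, 601, r))
        q_idx = rng.choice(n_act, size=n_q, replace=False)
        withheld = rng.choice(n_inact, size=round(inact_frac * n_inact), replace=False)
        test_act = np.setdiff1d(np.arange(n_act), q_idx)
        if not is_het and config.active_test_cap is not None:
            test_act = test_act[: config.active_test_cap]
        test_inact = np.setdiff1d(np.arange(n_inact), withheld)
        pool = np.vstack([A[test_act], I[test_inact]])
        labels = np.concatenate([np.ones(len(test_act)), np.zeros(len(test_inact))])
        scores = max_fusion_scores(A[q_idx], pool, scheme.similarity)
        ranked = RankedList(scores=scores, labels=labels)
        reps.append(
            (roc_auc(ranked), enrichment_factor(ranked, config.chi, tie_seed=derive_seed(config.seed, 602, r)))
        )
    return BenchResult(repetitions=reps)


def run_classification_benchmark(
    bench: BenchSet, scheme: FingerprintScheme, config: ClassificationConfig | None = None
) -> BenchResult:
    """Repeated stratified k-fold CV of a balanced random forest classifier.

    CLASS sets must provide strictly more than ``min_class_size`` compounds of
    each class.  Per fold, test compounds are ranked by the forest's
    active-class probability; AUC and EF(chi) are collected per fold and
    summarized over all folds of all repeats.
    """
    config = config or ClassificationConfig()
    n_act, n_inact = len(bench.actives), len(bench.inactives)
    if n_act <= config.min_class_size or n_inact <= config.min_class_size:
        raise ValueError(
            f"benchmark {bench.target_id}: CLASS sets need more than "
            f"{config.min_class_size} actives and inactives (got {n_act}/{n_inact})"
        )
    X = np.vstack([np.atleast_2d(scheme.encode(bench.actives)), np.atleast_2d(scheme.encode(bench.inactives))])
    y = np.concatenate([np.ones(n_act, dtype=int), np.zeros(n_inact, dtype=int)])
    reps: list[tuple[float, float]] = []
    for r in range(config.n_repeats):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=derive_seed(config.seed, 701, r))
        for f, (fit_idx, test_idx) in enumerate(skf.split(X, y)):
            clf = BalancedRandomForestClassifier(
                n_estimators=config.n_trees, random_state=derive_seed(config.seed, 702, r, f)
            )
            clf.fit(X[fit_idx], y[fit_idx])
            active_col = int(np.searchsorted(clf.classes_, 1))
            scores = clf.predict_proba(X[test_idx])[:, active_col]
            ranked = RankedList(scores=scores, labels=y[test_idx])
            reps.append(
                (roc_auc(ranked), enrichment_factor(ranked, config.chi, tie_seed=derive_seed(config.seed, 703, r, f)))
            )
    return BenchResult(repetitions=reps)


def run_scaffold_hopping(
    bench: BenchSet, scheme: FingerprintScheme, config: HoppingConfig | None = None
) -> HoppingResult:
    """Scaffold-hopping evaluation over rich active cyclic skeletons (RACSKs).

    For each RACSK (a CSK with at least ``min_racsk_size`` active members) a
    balanced random forest is trained on that CSK's actives plus all
    inactives and applied to the remaining actives; compounds classified
    active at the probability threshold contribute their CSKs to the
    retrieved set, unioned over all RACSK training sets.
    """
    config = config or HoppingConfig()
    csks: list[Optional[str]] = []
    for mol in bench.actives:
        try:
            csks.append(cyclic_skeleton(mol).csk_smiles)
        except NoScaffoldError:
            logger.warning("active %s is acyclic; excluded from scaffold hopping", mol.smiles)
            csks.append(None)
    members: dict[str, list[int]] = {}
    for i, csk in enumerate(csks):
        if csk is not None:
            members.setdefault(csk, []).append(i)
    racsks = sorted(c for c, idx in members.items() if len(idx) >= config.min_racsk_size)
    if not racsks:
        logger.info("benchmark %s has no RACSK; scaffold hopping skipped", bench.target_id)
        return HoppingResult(bench.target_id, n_acsk_total=len(members), n_racsk=0, retrieved_csk_ids=frozenset())
    A = np.atleast_2d(scheme.encode(bench.actives))
    I = np.atleast_2d(scheme.encode(bench.inactives))
    retrieved: set[str] = set()
    for j, racsk in enumerate(racsks):
        train_act = members[racsk]
        test_act = [i for i, c in enumerate(csks) if c is not None and i not in set(train_act)]
        if not test_act:
            continue
        X_fit = np.vstack([A[train_act], I])
        y_fit = np.concatenate([np.ones(len(train_act), dtype=int), np.zeros(len(I), dtype=int)])
        seed = derive_seed(config.seed, 801, j)
        if config.classifier_factory is not None:
            clf = config.classifier_factory(seed)
        else:
            clf = BalancedRandomForestClassifier(n_estimators=config.n_trees, random_state=seed)
        clf.fit(X_fit, y_fit)
        active_col = int(np.searchsorted(np.asarray(clf.classes_), 1))
        proba = np.asarray(clf.predict_proba(A[test_act]))[:, active_col]
        for i, p in zip(test_act, proba):
            if p >= config.prob_threshold:
                retrieved.add(csks[i])
    return HoppingResult(
        bench.target_id,
        n_acsk_total=len(members),
        n_racsk=len(racsks),
        retrieved_csk_ids=frozenset(retrieved),
    )


def pool_hopping_results(a: HoppingResult, b: HoppingResult) -> HoppingResult:
    """Union of retrieved CSKs from two schemes on the same assay (rv+b pooling)."""
    if a.assay_id != b.assay_id:
        raise ValueError("cannot pool hopping results from different assays")
    return HoppingResult(
        a.assay_id,
        n_acsk_total=a.n_acsk_total,
        n_racsk=a.n_racsk,
        retrieved_csk_ids=a.retrieved_csk_ids | b.retrieved_csk_ids,
    )


def ligand_overlap_fraction(bench: BenchSet, panel_ligand_smiles: set[str]) -> float:
    """Diagnostic: fraction of benchmark ligands shared with panel training ligands."""
    ligands = {m.smiles for m in bench.actives} | {m.smiles for m in bench.inactives}
    if not ligands:
        return 0.0
    return len(ligands & panel_ligand_smiles) / len(ligands)


# ---------------------------------------------------------------------------
# on-disk benchmark-set format (manifest + SMILES lists)

def write_bench_set(bench: BenchSet, directory: str | Path) -> None:
    """Write a benchmark set as actives.smi / inactives.smi plus manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mols, acts in (
        ("actives", bench.actives, bench.active_activities),
        ("inactives", bench.inactives, bench.inactive_activities),
    ):
        with open(directory / f"{name}.smi", "w") as fh:
            for i, mol in enumerate(mols):
                line = f"{mol.smiles}\t{name[:-1]}_{i}"
                if acts is not None:
                    line += f"\t{acts[i]:.6f}"
                fh.write(line + "\n")
    manifest = {"target_id": bench.target_id, "kind": bench.kind}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def load_bench_set(directory: str | Path) -> BenchSet:
    """Load a benchmark set written by :func:`write_bench_set`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())

    def read(name: str):
        mols, acts = [], []
        for line in (directory / f"{name}.smi").read_text().splitlines():
            parts = line.split("\t")
            mols.append(parse_molecule(parts[0]))
            if len(parts) > 2:
                acts.append(float(parts[2]))
        return mols, (np.array(acts) if acts else None)

    actives, act_a = read("actives")
    inactives, act_i = read("inactives")
    return BenchSet(
        target_id=manifest["target_id"],
        actives=actives,
        inactives=inactives,
        kind=manifest["kind"],
        active_activities=act_a,
        inactive_activities=act_i,
    )
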