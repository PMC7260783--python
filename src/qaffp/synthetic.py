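"""Synthetic ligand sets and benchmark sets with known ground truth.

Real activity data cannot ship with the package, so every pipeline stage is
exercised on molecules enumerated from a built-in fragment grammar: ring
cores grouped into cyclic-skeleton (CSK) families, decorated with small
substituents.  The grammar guarantees valid, diverse SMILES with controllable
scaffold families, which random SMILES strings cannot.

Two generators are provided:

* :func:`generate_ligand_set` — an assay-level ligand set whose activity is a
  sparse linear function of Morgan2 fingerprint bits plus Gaussian noise,
  clipped to the realistic pChEMBL range [3, 11].  At zero noise the
  structure-activity signal is exact, so QSAR gating must recover it; with
  permuted labels it must not.
* :func:`generate_class_set` — an active/inactive benchmark set whose actives
  are drawn from a configurable number of distinct CSK families (one of which
  is guaranteed to be a RACSK), with a shared "pharmacophore" substituent
  planted across families at a controllable rate so that scaffold hopping is
  possible exactly to the extent the generator says it is.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field

import numpy as np

from .benchmarks import BenchSet
from .chemstruct import Molecule, SmilesParseError, cyclic_skeleton, morgan2_matrix, parse_molecule
from .curation import LigandSet

logger = logging.getLogger(__name__)

ACTIVITY_RANGE = (3.0, 11.0)

#: ring-core templates grouped by CSK family; "{A}" is a branch slot,
#: "{B}" a suffix slot on the final ring atom
CORE_FAMILIES: dict[str, list[str]] = {
    "six": ["c1cc{A}ccc1{B}", "c1cc{A}cnc1{B}", "C1CC{A}CCC1{B}", "C1CC{A}CNC1{B}", "C1CC{A}OCC1{B}"],
    "five": ["c1cc{A}sc1{B}", "c1cc{A}oc1{B}", "C1CC{A}CC1{B}"],
    "naph": ["c1ccc2cc{A}ccc2c1{B}", "c1ccc2nc{A}ccc2c1{B}", "C1CCC2CC{A}CCC2C1{B}"],
    "biph": ["c1ccc(-c2cc{A}ccc2{B})cc1", "c1ccc(-c2cc{A}ncc2{B})cc1"],
    "ind56": ["c1ccc2c(c1)CC{A}C2", "c1ccc2c(c1)OC{A}C2", "c1ccc2c(c1)cc{A}[nH]2"],
    "dpm": ["c1ccc(Cc2cc{A}ccc2{B})cc1", "c1ccc(Cc2cc{A}ncc2{B})cc1"],
    "seven": ["C1CC{A}CCCC1{B}", "C1CC{A}NCCC1{B}"],
}

SUBSTITUENTS = [
    "", "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)NC", "CO", "C(F)(F)F", "S",
]

#: substituent planted on actives of class sets; shared across CSK families
#: it is the transferable activity signal that makes scaffold hops learnable
MARKER_SUBSTITUENT = "S(=O)(=O)N"


@dataclass
class SyntheticAssaySpec:
    """Generative description of one synthetic assay.

    ``weights`` is a dense float vector over the 1024 fingerprint bits (only
    ``n_signal_bits`` of them nonzero); activity = offset + bits . weights +
    Normal(0, noise_sigma), clipped to [3, 11] -log10 M.
    """

    n_compounds: int
    weights: np.ndarray
    noise_sigma: float
    activity_offset: float
    seed: int
    assay_id: str = "SYN:IC50"
    n_signal_bits: int = field(init=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (1024,):
            raise ValueError("weights must be a length-1024 vector")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        self.n_signal_bits = int(np.count_nonzero(self.weights))


def _expand(template: str, s1: str, s2: str) -> str:
    out = template.replace("{A}", f"({s1})" if s1 else "")
    return out.replace("{B}", s2)


@functools.lru_cache(maxsize=1)
def molecule_library() -> tuple[tuple[Molecule, ...], tuple[str, ...]]:
    """Deterministic enumeration of the fragment grammar.

    Returns (molecules, family_labels), deduplicated by canonical SMILES in
    enumeration order.
    """
    seen: dict[str, None] = {}
    mols: list[Molecule] = []
    labels: list[str] = []
    for family, cores in CORE_FAMILIES.items():
        for core in cores:
            for s1 in SUBSTITUENTS:
                for s2 in SUBSTITUENTS + [MARKER_SUBSTITUENT]:
                    if "{B}" not in core and s2:
                        continue
                    try:
                        mol = parse_molecule(_expand(core, s1, s2))
                    except SmilesParseError:
                        continue
                    if mol.smiles in seen:
                        continue
                    seen[mol.smiles] = None
                    mols.append(mol)
                    labels.append(family)
    logger.info("fragment grammar enumerated %d distinct molecules", len(mols))
    return tuple(mols), tuple(labels)


@functools.lru_cache(maxsize=1)
def _library_bit_frequencies() -> np.ndarray:
    mols, _ = molecule_library()
    return morgan2_matrix(list(mols)).mean(axis=0)


def make_assay_spec(
    seed: int,
    n_compounds: int = 200,
    n_signal_bits: int = 20,
    noise_sigma: float = 0.3,
    activity_offset: float = 6.0,
    assay_id: str = "SYN:IC50",
) -> SyntheticAssaySpec:
    """Draw a random sparse-weight assay spec with learnable signal bits.

    Signal bits are sampled among bits set in 10-90% of the library so that
    every signal bit actually varies across compounds.
    """
    rng = np.random.default_rng(seed)
    freq = _library_bit_frequencies()
    eligible = np.flatnonzero((freq >= 0.1) & (freq <= 0.9))
    if len(eligible) < n_signal_bits:
        raise ValueError(f"only {len(eligible)} informative bits available")
    bits = rng.choice(eligible, size=n_signal_bits, replace=False)
    weights = np.zeros(1024)
    weights[bits] = rng.uniform(0.4, 1.0, size=n_signal_bits) * rng.choice([-1.0, 1.0], size=n_signal_bits)
    return SyntheticAssaySpec(
        n_compounds=n_compounds,
        weights=weights,
        noise_sigma=noise_sigma,
        activity_offset=activity_offset,
        seed=seed,
        assay_id=assay_id,
    )


def generate_ligand_set(spec: SyntheticAssaySpec) -> LigandSet:
    """Materialize a ligand set from a :class:`SyntheticAssaySpec`.

    Deterministic for a fixed spec (seed included); activities are emitted on
    the -log10 M scale, clipped to [3, 11].
    """
    mols, _ = molecule_library()
    if spec.n_compounds > len(mols):
        raise ValueError(
            f"requested {spec.n_compounds} compounds but the fragment library holds {len(mols)}"
        )
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(mols), size=spec.n_compounds, replace=False)
    chosen = [mols[i] for i in idx]
    X = morgan2_matrix(chosen)
    activity = spec.activity_offset + X @ spec.weights
    if spec.noise_sigma > 0:
        activity = activity + rng.normal(0.0, spec.noise_sigma, size=len(activity))
    activity = np.clip(activity, *ACTIVITY_RANGE)
    compounds = [
        (f"{spec.assay_id}|CPD{i:05d}", mol, float(a))
        for i, (mol, a) in enumerate(zip(chosen, activity))
    ]
    return LigandSet(assay_id=spec.assay_id, compounds=compounds)


def _default_family_sizes(n_act: int, n_scaffolds: int, racsk_size: int = 5) -> list[int]:
    if n_act < racsk_size + (n_scaffolds - 1):
        raise ValueError(
            f"{n_act} actives cannot populate {n_scaffolds} scaffold families "
            f"with one family of >= {racsk_size}"
        )
    sizes = [racsk_size] + [1] * (n_scaffolds - 1)
    i = 0
    while sum(sizes) < n_act:
        sizes[i % n_scaffolds] += 1
        i += 1
    return sizes


def _draw_member(
    rng: np.random.Generator,
    family: str,
    marker_prob: float,
    used: set[str],
    max_tries: int = 200,
) -> Molecule:
    cores = CORE_FAMILIES[family]
    plain = [s for s in SUBSTITUENTS if s]
    for _ in range(max_tries):
        core = cores[rng.integers(len(cores))]
        s1 = MARKER_SUBSTITUENT if rng.random() < marker_prob else plain[rng.integers(len(plain))]
        s2 = SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] if "{B}" in core else ""
        try:
            mol = parse_molecule(_expand(core, s1, s2))
        except SmilesParseError:
            continue
        if mol.smiles not in used:
            used.add(mol.smiles)
            return mol
    raise ValueError(f"could not draw a fresh member of family {family!r} after {max_tries} tries")


def generate_class_set(
    n_act: int,
    n_inact: int,
    n_scaffolds: int,
    hop_signal: float = 0.9,
    seed: int = 0,
    target_id: str = "SYNCLASS",
    family_sizes: list[int] | None = None,
) -> tuple[BenchSet, dict]:
    """Active/inactive CLASS-style benchmark set with planted scaffold families.

    Actives come from ``n_scaffolds`` distinct CSK families, the first of
    which always has at least five members (a guaranteed RACSK); actives
    carry the marker substituent with probability ``hop_signal``, inactives
    almost never do, so the marker is the cross-scaffold activity signal.
    Active potencies are drawn above 6, inactive potencies below 5, on the
    -log10 M scale.  The returned manifest records the true CSK memberships
    for oracle checks.
    """
    if n_scaffolds < 2:
        raise ValueError("need at least 2 scaffold families")
    if n_scaffolds > len(CORE_FAMILIES):
        raise ValueError(f"at most {len(CORE_FAMILIES)} scaffold families available")
    families = list(CORE_FAMILIES)[:n_scaffolds]
    sizes = list(family_sizes) if family_sizes is not None else _default_family_sizes(n_act, n_scaffolds)
    if len(sizes) != n_scaffolds or sum(sizes) != n_act:
        raise ValueError("family_sizes must have one entry per scaffold family and sum to n_act")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    actives: list[Molecule] = []
    membership: dict[str, list[int]] = {}
    family_of_active: list[str] = []
    for family, size in zip(families, sizes):
        for _ in range(size):
            mol = _draw_member(rng, family, marker_prob=hop_signal, used=used)
            membership.setdefault(family, []).append(len(actives))
            family_of_active.append(family)
            actives.append(mol)
    inactives = [
        _draw_member(rng, families[int(rng.integers(len(families)))], marker_prob=0.02, used=used)
        for _ in range(n_inact)
    ]
    active_acts = rng.uniform(6.05, 9.0, size=n_act)
    inactive_acts = rng.uniform(3.0, 4.95, size=n_inact)
    family_csk = {
        fam: cyclic_skeleton(parse_molecule(_expand(CORE_FAMILIES[fam][0], "", ""))).csk_smiles
        for fam in families
    }
    csk_members = {family_csk[fam]: idx for fam, idx in membership.items()}
    manifest = {
        "target_id": target_id,
        "family_csk": family_csk,
        "memberships": csk_members,
        "racsk_csks": sorted(c for c, idx in csk_members.items() if len(idx) >= 5),
        "marker": MARKER_SUBSTITUENT,
        "hop_signal": hop_signal,
        "family_of_active": family_of_active,
    }
    bench = BenchSet(
        target_id=target_id,
        actives=actives,
        inactives=inactives,
        kind="CLASS",
        active_activities=active_acts,
        inactive_activities=inactive_acts,
    )
    return bench, manifest
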