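"""Molecule parsing, circular fingerprints, and cyclic-skeleton derivation.

All structure handling goes through RDKit.  Molecules are identified by their
canonical SMILES; the 1024-bit Morgan fingerprint of radius 2 (the RDKit
equivalent of ECFP4) is the structural encoding used both as QSAR features and
as the structural comparator in the benchmarks.

The cyclic skeleton (CSK, also called a graph framework) of a molecule is
derived from its Bemis-Murcko scaffold by converting every heavy atom to
carbon and every bond to a single bond.  Two molecules share a chemotype, for
the purposes of scaffold hopping, exactly when their CSK canonical SMILES are
equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

# RDKit is chatty about kekulization etc. on the error stream; parse failures
# are reported through SmilesParseError instead.
RDLogger.DisableLog("rdApp.error")

FP_BITS = 1024
FP_RADIUS = 2

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class NoScaffoldError(ValueError):
    """Raised when a scaffold is requested for an acyclic molecule."""


@dataclass(frozen=True)
class Molecule:
    """A parsed, canonicalized molecule."""

    smiles: str
    atom_count: int
    ring_flag: bool
    _mol: Chem.Mol = field(repr=False, compare=False)

    @property
    def rdkit_mol(self) -> Chem.Mol:
        return self._mol


@dataclass(frozen=True)
class BitVector1024:
    """Fixed-length binary fingerprint vector."""

    bits: np.ndarray  # uint8, shape (1024,)

    def __post_init__(self):
        if self.bits.shape != (FP_BITS,):
            raise ValueError(f"fingerprint must have length {FP_BITS}, got {self.bits.shape}")

    @property
    def on_count(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class CyclicSkeleton:
    """All-carbon, all-single-bond reduction of a Bemis-Murcko scaffold."""

    csk_smiles: str
    source_scaffold: str


def parse_molecule(smiles: str) -> Molecule:
    """Parse a SMILES string into a canonical :class:`Molecule`.

    Multi-fragment inputs (salts, mixtures) are reduced to the largest
    covalent fragment by heavy-atom count, with a logged warning; inputs are
    otherwise assumed to be pre-standardized.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        logger.warning(
            "multi-fragment input %r reduced to largest fragment %s",
            smiles,
            Chem.MolToSmiles(mol),
        )
    canonical = Chem.MolToSmiles(mol)
    return Molecule(
        smiles=canonical,
        atom_count=mol.GetNumHeavyAtoms(),
        ring_flag=mol.GetRingInfo().NumRings() > 0,
        _mol=mol,
    )


def morgan2_fingerprint(mol: Molecule) -> BitVector1024:
    """1024-bit Morgan fingerprint of radius 2 (ECFP4 equivalent)."""
    fp = _morgan_gen.GetFingerprintAsNumPy(mol.rdkit_mol)
    return BitVector1024(bits=fp.astype(np.uint8))


def morgan2_matrix(mols: list[Molecule]) -> np.ndarray:
    """Stack Morgan2 fingerprints into an (n, 1024) uint8 matrix."""
    if not mols:
        return np.zeros((0, FP_BITS), dtype=np.uint8)
    return np.vstack([morgan2_fingerprint(m).bits for m in mols])


def _reduce_to_carbon_skeleton(scaffold: Chem.Mol) -> str:
    rw = Chem.RWMol(scaffold)
    Chem.RemoveStereochemistry(rw)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetIsotope(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetNumRadicalElectrons(0)
        atom.SetIsAromatic(False)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    skeleton = rw.GetMol()
    Chem.SanitizeMol(skeleton)
    return Chem.MolToSmiles(skeleton)


def cyclic_skeleton(mol: Molecule) -> CyclicSkeleton:
    """Cyclic skeleton of ``mol``: its Bemis-Murcko scaffold with all heavy
    atoms converted to carbon and all bond orders set to 1.

    Atoms double-bonded to scaffold or linker atoms (carbonyl oxygens and the
    like) are retained by the scaffold extractor before the carbon reduction,
    matching common toolkit behavior.  Chirality and charges are discarded.
    """
    if not mol.ring_flag:
        raise NoScaffoldError(f"molecule {mol.smiles!r} has no ring; no scaffold defined")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol.rdkit_mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        raise NoScaffoldError(f"no Bemis-Murcko scaffold for {mol.smiles!r}")
    scaffold_smiles = Chem.MolToSmiles(scaffold)
    return CyclicSkeleton(
        csk_smiles=_reduce_to_carbon_skeleton(scaffold),
        source_scaffold=scaffold_smiles,
    )
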