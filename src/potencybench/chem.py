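"""Molecular representation: ECFP4 fingerprints and the Tanimoto kernel.

Compounds are represented by the folded 2048-bit binary circular
substructure fingerprint of radius 2 (bond diameter 4), the conventional
"ECFP4" setting, computed with RDKit's Morgan generator. Tanimoto
similarity |A∩B|/|A∪B| on the bit sets doubles as the SVR kernel: on
binary vectors it is positive semidefinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

N_BITS = 2048
_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=N_BITS)


class StructureParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the string."""

    def __init__(self, structure: str):
        self.structure = structure
        super().__init__(f"unparseable structure: {structure!r}")


def parse_mol(structure: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureParseError(structure)
    return mol


def canonical_smiles(structure: str) -> str:
    """Canonical SMILES; the identity used for duplicate detection."""
    return Chem.MolToSmiles(parse_mol(structure))


@dataclass(frozen=True)
class Fingerprint:
    """Folded binary circular fingerprint as a set of on-bit positions."""

    on_bits: frozenset[int]
    n_bits: int = N_BITS

    def __post_init__(self) -> None:
        if self.on_bits and not all(0 <= b < self.n_bits for b in self.on_bits):
            raise ValueError("bit positions out of range")

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.n_bits, dtype=np.uint8)
        if self.on_bits:
            arr[sorted(self.on_bits)] = 1
        return arr


def compute_fingerprint(structure: str) -> Fingerprint:
    """2048-bit ECFP4 fingerprint of a SMILES string.

    Deterministic and canonicalization-invariant: any SMILES spelling of
    the same molecule yields the same bit set.
    """
    mol = parse_mol(structure)
    bv = _MORGAN.GetFingerprint(mol)
    return Fingerprint(frozenset(bv.GetOnBits()))


def fingerprints_for(structures: Sequence[str]) -> list[Fingerprint]:
    return [compute_fingerprint(s) for s in structures]


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B|/|A∪B| in [0, 1].

    Both-empty fingerprints are defined as similarity 1.0 (identical
    objects); empty versus non-empty gives 0.0.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = len(a.on_bits | b.on_bits)
    if union == 0:
        return 1.0
    return len(a.on_bits & b.on_bits) / union


def pack_fingerprints(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Stack fingerprints into an (n, n_bits) float64 0/1 matrix."""
    if not fps:
        raise ValueError("empty fingerprint list")
    return np.stack([fp.to_array() for fp in fps]).astype(np.float64)


def tanimoto_matrix(fps_a: Sequence[Fingerprint], fps_b: Sequence[Fingerprint] | None = None) -> np.ndarray:
    """Pairwise Tanimoto similarities, rows = fps_a, columns = fps_b.

    Vectorised over the packed bit matrices: |A∩B| by a single matrix
    product, |A∪B| = |A| + |B| − |A∩B|. Pairs of all-zero fingerprints
    get similarity 1.0, matching :func:`tanimoto`.
    """
    A = pack_fingerprints(fps_a)
    B = A if fps_b is None else pack_fingerprints(fps_b)
    inter = A @ B.T
    counts_a = A.sum(axis=1)[:, None]
    counts_b = B.sum(axis=1)[None, :]
    union = counts_a + counts_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return sim


@dataclass
class KernelMatrix:
    """Square Tanimoto kernel bound to an ordered compound-id list."""

    values: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel matrix must be square")
        if self.ids and len(self.ids) != v.shape[0]:
            raise ValueError("id list length does not match matrix order")


def kernel_matrix(fps: Sequence[Fingerprint], ids: Sequence[str] | None = None) -> KernelMatrix:
    """Symmetric, unit-diagonal Tanimoto kernel over a fingerprint list."""
    sim = tanimoto_matrix(fps)
    np.fill_diagonal(sim, 1.0)
    return KernelMatrix(values=sim, ids=list(ids) if ids is not None else [])
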