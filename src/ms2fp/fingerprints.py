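"""Concatenated multi-family molecular fingerprints and their condensation.

A compound is encoded as the concatenation of five binary substructure
fingerprint blocks — FP3 (55 bits), FP4 (307), PubChem-width (881), MACCS
(166), Klekota-Roth-width (4860) — for a total of 6269 bits.  FP3, FP4 and
MACCS are the OpenBabel pattern fingerprints.  The PubChem/CACTVS and
Klekota-Roth key sets are external pattern libraries that are not bundled
here; those two blocks are filled by deterministic hashed substructure
fingerprints (Morgan radius-2 and RDKit path fingerprints) folded to the
published block widths, so the scheme geometry and every downstream
operation match the five-family layout.  See docs/methods.md.

On a training compound set the 6269 columns are reduced in two steps:
columns constant across all compounds are dropped, and groups of identical
columns are condensed to a single representative.  The resulting
:class:`CondensedMap` defines the output space of the prediction models and
must travel with any trained model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FingerprintScheme",
    "FingerprintVector",
    "CondensedMap",
    "compute_fingerprint",
    "compute_fingerprint_matrix",
    "remove_constant_bits",
    "condense_duplicates",
    "build_condensed_map",
    "project",
]

logger = logging.getLogger(__name__)

DEFAULT_FAMILIES = (
    ("FP3", 55),
    ("FP4", 307),
    ("PubChem", 881),
    ("MACCS", 166),
    ("KlekotaRoth", 4860),
)


@dataclass(frozen=True)
class FingerprintScheme:
    """Ordered fingerprint families and their pinned bit widths."""

    families: tuple = DEFAULT_FAMILIES

    @property
    def total_bits(self) -> int:
        return sum(width for _, width in self.families)

    def offsets(self) -> dict:
        """Start offset of each family block in the concatenated vector."""
        out, pos = {}, 0
        for name, width in self.families:
            out[name] = pos
            pos += width
        return out


@dataclass
class FingerprintVector:
    """Binary fingerprint, either full-length or condensed."""

    bits: np.ndarray
    scheme_ref: str = "default"

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("fingerprint entries must be binary")


def _canonical_mol(smiles: str):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    # round-trip through canonical SMILES so every spelling of a molecule
    # yields identical bits in every backend
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol)), Chem.MolToSmiles(mol)


def _openbabel_block(canonical_smiles: str, fpname: str, width: int) -> np.ndarray:
    from openbabel import pybel

    mol = pybel.readstring("smi", canonical_smiles)
    block = np.zeros(width, dtype=np.uint8)
    for bit in mol.calcfp(fpname).bits:  # OpenBabel bit indices are 1-based
        if 1 <= bit <= width:
            block[bit - 1] = 1
    return block


def _hashed_block(mol, kind: str, width: int) -> np.ndarray:
    from rdkit.Chem import rdFingerprintGenerator

    if kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=width)
    else:
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=width)
    fp = gen.GetFingerprint(mol)
    block = np.zeros(width, dtype=np.uint8)
    block[list(fp.GetOnBits())] = 1
    return block


def compute_fingerprint(
    smiles: str, scheme: FingerprintScheme | None = None
) -> FingerprintVector:
    """Compute the concatenated fingerprint of a molecule from its SMILES.

    The SMILES is canonicalized first, so different spellings of one
    molecule give identical vectors.  Raises ``ValueError`` naming the input
    if it does not parse.
    """
    scheme = scheme or FingerprintScheme()
    mol, canonical = _canonical_mol(smiles)
    blocks = []
    for name, width in scheme.families:
        if name in ("FP3", "FP4", "MACCS"):
            blocks.append(_openbabel_block(canonical, name, width))
        elif name == "PubChem":
            blocks.append(_hashed_block(mol, "morgan", width))
        elif name == "KlekotaRoth":
            blocks.append(_hashed_block(mol, "rdkit", width))
        else:
            raise ValueError(f"unknown fingerprint family {name!r}")
    return FingerprintVector(np.concatenate(blocks))


def compute_fingerprint_matrix(
    smiles_list: Sequence[str], scheme: FingerprintScheme | None = None
) -> np.ndarray:
    """Stack fingerprints of many compounds into a (compounds x bits) matrix."""
    scheme = scheme or FingerprintScheme()
    return np.vstack([compute_fingerprint(s, scheme).bits for s in smiles_list])


def remove_constant_bits(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split columns into (kept, dropped): a column is dropped when it is
    all-0 or all-1 across the compounds."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two compounds")
    col_sum = matrix.sum(axis=0)
    constant = (col_sum == 0) | (col_sum == matrix.shape[0])
    kept = np.flatnonzero(~constant)
    dropped = np.flatnonzero(constant)
    if kept.size == 0:
        logger.warning("every fingerprint column is constant")
    return kept, dropped


@dataclass
class CondensedMap:
    """Mapping between original fingerprint bits and condensed columns.

    ``kept_groups[j]`` lists the original bit indices whose columns were
    identical on the training compounds; column ``j`` of the condensed space
    is represented by the lowest index in the group.  Together with
    ``dropped_constant`` the groups partition the original index range.
    """

    kept_groups: list[list[int]]
    dropped_constant: list[int]
    total_bits: int
    families: tuple = DEFAULT_FAMILIES
    disagreement_count: int = field(default=0, compare=False)

    @property
    def condensed_length(self) -> int:
        return len(self.kept_groups)

    @property
    def representatives(self) -> np.ndarray:
        return np.array([g[0] for g in self.kept_groups], dtype=int)

    def validate_partition(self) -> bool:
        seen = sorted(
            [i for g in self.kept_groups for i in g] + list(self.dropped_constant)
        )
        return seen == list(range(self.total_bits))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "families": [list(f) for f in self.families],
                    "total_bits": self.total_bits,
                    "dropped": [int(i) for i in self.dropped_constant],
                    "groups": [[int(i) for i in g] for g in self.kept_groups],
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "CondensedMap":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            kept_groups=d["groups"],
            dropped_constant=d["dropped"],
            total_bits=d["total_bits"],
            families=tuple(tuple(f) for f in d["families"]),
        )


def condense_duplicates(
    matrix: np.ndarray, kept: np.ndarray, dropped: np.ndarray,
    families: tuple = DEFAULT_FAMILIES,
) -> CondensedMap:
    """Group identical kept columns of a compounds-x-bits matrix.

    Each group of duplicate columns becomes one condensed column whose
    representative is the lowest original index; groups are ordered by
    representative so the condensed layout is deterministic.
    """
    matrix = np.asarray(matrix)
    kept = np.asarray(kept, dtype=int)
    groups: dict[bytes, list[int]] = {}
    for idx in kept:
        groups.setdefault(matrix[:, idx].tobytes(), []).append(int(idx))
    kept_groups = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
    return CondensedMap(
        kept_groups=kept_groups,
        dropped_constant=[int(i) for i in dropped],
        total_bits=matrix.shape[1],
        families=families,
    )


def build_condensed_map(
    matrix: np.ndarray, families: tuple = DEFAULT_FAMILIES
) -> CondensedMap:
    """Convenience: constant-bit removal followed by duplicate condensation."""
    kept, dropped = remove_constant_bits(matrix)
    return condense_duplicates(matrix, kept, dropped, families)


def project(fp: FingerprintVector | np.ndarray, cmap: CondensedMap) -> FingerprintVector:
    """Project a full-length fingerprint into the condensed space.

    The representative bit of each group is used.  For molecules outside the
    training set a group's member bits can disagree; disagreements are
    counted on the map and logged, and the representative still decides.
    """
    bits = fp.bits if isinstance(fp, FingerprintVector) else np.asarray(fp, dtype=np.uint8)
    if bits.shape[0] != cmap.total_bits:
        raise ValueError(
            f"expected full-length fingerprint of {cmap.total_bits} bits, got {bits.shape[0]}"
        )
    disagreements = sum(
        1 for g in cmap.kept_groups if len(g) > 1 and len(set(bits[g].tolist())) > 1
    )
    if disagreements:
        cmap.disagreement_count += disagreements
        logger.debug("%d condensed groups disagree internally", disagreements)
    return FingerprintVector(bits[cmap.representatives], scheme_ref="condensed")
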