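"""Atom selection and inter-residue atom-pair enumeration.

Atoms are selected by exact (case-insensitive) atom name with a strict
pLDDT cutoff (``plddt > cutoff``); pairs are enumerated within a strict
distance cutoff (``d < cutoff``) with symmetric duplicates removed.
Note that AlphaFold3 names ion atoms by element (Ca2+ = CA, Mg2+ = MG,
K+ = K, Zn2+ = ZN), so a calcium ion is matched by atom name "CA" just
like a Cα atom unless ``polymer_only`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigError
from .structure_io import AtomRecord, StructureModel


@dataclass(frozen=True)
class AtomPairDistance:
    """One unique inter-residue atom pair within the distance cutoff.

    ``atom1``/``atom2`` are in canonical order (atom1.key <= atom2.key), so
    each unordered pair appears exactly once.
    """

    atom1: AtomRecord
    atom2: AtomRecord
    distance: float

    @property
    def plddt1(self) -> float:
        return self.atom1.plddt

    @property
    def plddt2(self) -> float:
        return self.atom2.plddt

    @property
    def min_plddt(self) -> float:
        return min(self.atom1.plddt, self.atom2.plddt)


def select_atoms(
    model: StructureModel,
    atom_name: str,
    plddt_cutoff: float,
    polymer_only: bool = False,
) -> list[AtomRecord]:
    """Atoms whose name matches ``atom_name`` (case-insensitive) with
    pLDDT strictly greater than ``plddt_cutoff``.

    With ``polymer_only=False`` (the default, matching the viewer plugins)
    ions and ligands are eligible, so selecting "CA" also captures Ca2+
    ions in AlphaFold3 output.
    """
    if not atom_name:
        raise ValueError("atom_name must be non-empty")
    name = atom_name.upper()
    return [
        a
        for a in model.atoms
        if a.atom_name.upper() == name
        and a.plddt > plddt_cutoff
        and (a.is_polymer or not polymer_only)
    ]


def _same_residue(a: AtomRecord, b: AtomRecord) -> bool:
    return a.chain_id == b.chain_id and a.residue_number == b.residue_number


def _passes_separation(a: AtomRecord, b: AtomRecord, min_sep: int) -> bool:
    if _same_residue(a, b):
        return False
    if a.chain_id != b.chain_id:
        return True  # no sequence-separation test across chains
    return abs(a.residue_number - b.residue_number) >= min_sep


def _canonical(a: AtomRecord, b: AtomRecord) -> tuple[AtomRecord, AtomRecord]:
    return (a, b) if a.key <= b.key else (b, a)


def find_pairs(
    set1: list[AtomRecord],
    set2: list[AtomRecord],
    distance_cutoff: float,
    min_sequence_separation: int = 1,
) -> list[AtomPairDistance]:
    """All unique inter-residue pairs (a in set1, b in set2) with Euclidean
    distance strictly below ``distance_cutoff``.

    Same-chain pairs must additionally satisfy
    ``|residue_number difference| >= min_sequence_separation`` (default 1:
    only intra-residue pairs are excluded; sequential neighbours are kept).
    The result is symmetric in its two arguments and sorted canonically.

    Uses a k-d tree internally; behaviour is contractually identical to the
    O(n²) brute-force enumeration.
    """
    if distance_cutoff <= 0:
        raise ConfigError(f"distance cutoff must be positive, got {distance_cutoff}")
    if min_sequence_separation < 1:
        raise ConfigError("min_sequence_separation must be >= 1")
    if not set1 or not set2:
        return []

    coords1 = np.array([a.position for a in set1], dtype=float)
    coords2 = np.array([a.position for a in set2], dtype=float)
    tree2 = cKDTree(coords2)
    neighbours = tree2.query_ball_point(coords1, r=distance_cutoff)

    found: dict[tuple, AtomPairDistance] = {}
    for i, hits in enumerate(neighbours):
        a = set1[i]
        for j in hits:
            b = set2[j]
            if a.key == b.key or not _passes_separation(a, b, min_sequence_separation):
                continue
            d = float(np.linalg.norm(coords1[i] - coords2[j]))
            if d >= distance_cutoff:  # strict "<" per the cutoff convention
                continue
            first, second = _canonical(a, b)
            found.setdefault((first.key, second.key), AtomPairDistance(first, second, d))
    return sorted(found.values(), key=lambda p: (p.atom1.key, p.atom2.key))


def brute_force_pairs(
    set1: list[AtomRecord],
    set2: list[AtomRecord],
    distance_cutoff: float,
    min_sequence_separation: int = 1,
) -> list[AtomPairDistance]:
    """Reference O(n²) enumeration with identical semantics to
    :func:`find_pairs`; the contract oracle used by the test suite."""
    if distance_cutoff <= 0:
        raise ConfigError(f"distance cutoff must be positive, got {distance_cutoff}")
    found: dict[tuple, AtomPairDistance] = {}
    for a in set1:
        for b in set2:
            if a.key == b.key or not _passes_separation(a, b, min_sequence_separation):
                continue
            d = float(
                np.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2)
            )
            if d >= distance_cutoff:
                continue
            first, second = _canonical(a, b)
            found.setdefault((first.key, second.key), AtomPairDistance(first, second, d))
    return sorted(found.values(), key=lambda p: (p.atom1.key, p.atom2.key))
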