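"""Reading AlphaFold coordinate files and exposing pLDDT scores.

AlphaFold writes its per-residue (AlphaFold2) or per-atom (AlphaFold3)
pLDDT confidence scores into the B-factor column of both its PDB and
mmCIF outputs.  This module parses either format (via gemmi), carries
the B-factor through verbatim as ``plddt``, and supports residue
renumbering back to native (full-length protein) numbering.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import gemmi

from .errors import (
    EmptyStructureError,
    FormatError,
    RenumberCollisionError,
    StructureParseError,
    UnknownChainError,
)

logger = logging.getLogger(__name__)

_PDB_EXTENSIONS = {".pdb", ".ent"}
_MMCIF_EXTENSIONS = {".cif", ".mmcif"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a predicted model.

    ``plddt`` is the value read from the B-factor / B_iso_or_equiv field,
    passed through unchanged.  ``is_polymer`` distinguishes polymer atoms
    (ATOM records) from ligands/ions/waters (HETATM records).
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    plddt: float
    is_polymer: bool

    @property
    def key(self) -> tuple[str, int, str]:
        """Canonical identity: (chain, residue number, atom name)."""
        return (self.chain_id, self.residue_number, self.atom_name)

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class StructureModel:
    """Ordered atom collection for one predicted model."""

    model_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    source_format: str = "pdb"  # {pdb, mmcif}
    plddt_granularity: str = "unknown"  # {per_residue, per_atom, unknown}

    def __len__(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.chain_id, None)
        return list(seen)

    def polymer_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_polymer]


def _infer_format(path: Path, fmt: str) -> str:
    if fmt in ("pdb", "mmcif"):
        return fmt
    if fmt != "auto":
        raise FormatError(f"unsupported format {fmt!r}; expected pdb, mmcif or auto")
    suffixes = [s.lower() for s in path.suffixes]
    ext = suffixes[-1] if suffixes else ""
    if ext in _PDB_EXTENSIONS:
        return "pdb"
    if ext in _MMCIF_EXTENSIONS:
        return "mmcif"
    raise FormatError(
        f"cannot infer coordinate format from extension {ext!r} of {path.name}; "
        "pass format='pdb' or format='mmcif'"
    )


def detect_plddt_granularity(atoms: Iterable[AtomRecord]) -> str:
    """Classify pLDDT storage as per_residue (AlphaFold2 style: every atom
    of a residue shares one value) or per_atom (AlphaFold3 style)."""
    by_residue: dict[tuple[str, int], set[float]] = {}
    for atom in atoms:
        if atom.is_polymer:
            by_residue.setdefault((atom.chain_id, atom.residue_number), set()).add(atom.plddt)
    if not by_residue:
        return "unknown"
    if all(len(values) == 1 for values in by_residue.values()):
        return "per_residue"
    return "per_atom"


def validate_plddt_range(atoms: Iterable[AtomRecord], strict: bool = False) -> None:
    """Warn (or raise, in strict mode) when B-factor values fall outside the
    pLDDT scale [0, 100] — typically a sign that a crystallographic file was
    passed instead of an AlphaFold prediction."""
    bad = [a.plddt for a in atoms if not (0.0 <= a.plddt <= 100.0)]
    if not bad:
        return
    msg = (
        f"{len(bad)} atoms carry B-factor values outside the pLDDT range "
        f"[0, 100] (observed {min(bad):.2f}..{max(bad):.2f}); is this an "
        "AlphaFold prediction?"
    )
    if strict:
        raise StructureParseError(msg)
    warnings.warn(msg, stacklevel=3)


def _structure_to_model(
    structure: gemmi.Structure, source_format: str, path: Path, strict: bool
) -> StructureModel:
    if len(structure) == 0:
        raise EmptyStructureError(f"{path}: file contains no models")
    if len(structure) > 1:
        logger.warning(
            "%s: %d models found; only the first is used (AlphaFold emits single models)",
            path,
            len(structure),
        )
    model = structure[0]
    atoms: list[AtomRecord] = []
    seen_altloc: set[tuple[str, int, str]] = set()
    for chain in model:
        for residue in chain:
            is_polymer = residue.het_flag != "H"
            for atom in residue:
                key = (chain.name, residue.seqid.num, atom.name)
                if atom.altloc and key in seen_altloc:
                    continue  # keep first altloc only
                seen_altloc.add(key)
                pos = atom.pos
                if not all(math.isfinite(v) for v in (pos.x, pos.y, pos.z)):
                    raise StructureParseError(
                        f"{path}: non-finite coordinates on atom {key}"
                    )
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        x=pos.x,
                        y=pos.y,
                        z=pos.z,
                        plddt=atom.b_iso,
                        is_polymer=is_polymer,
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path}: structure contains no atoms")
    validate_plddt_range(atoms, strict=strict)
    return StructureModel(
        model_id=structure.name or path.stem,
        atoms=atoms,
        source_format=source_format,
        plddt_granularity=detect_plddt_granularity(atoms),
    )


def read_structure(
    path: str | Path, format: str = "auto", strict: bool = False
) -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        Coordinate file.  With ``format='auto'`` the format is inferred from
        the extension (``.pdb``/``.ent`` vs ``.cif``/``.mmcif``).
    strict:
        Raise instead of warn when B-factor values fall outside [0, 100].

    Only the first model of a multi-model file is read; for atoms with
    alternate locations, the first altloc per atom name is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    coor_format = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
    try:
        structure = gemmi.read_structure(str(path), format=coor_format)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    return _structure_to_model(structure, fmt, path, strict)


def renumber_residues(
    model: StructureModel,
    offset: int | None = None,
    chain: str | None = None,
    start_at: int | None = None,
) -> StructureModel:
    """Shift residue numbers by ``offset`` (or so the first targeted residue
    becomes ``start_at``), optionally restricted to one chain.

    This mirrors renumbering a prediction that starts at residue 1 back to
    its native numbering, e.g. ``alter all, resi=str(int(resi)+642)`` in
    PyMOL or ``renumber #1 start 643`` in ChimeraX.
    """
    if not model.atoms:
        raise EmptyStructureError("cannot renumber an empty model")
    if chain is not None and chain not in model.chains():
        raise UnknownChainError(
            f"chain {chain!r} not present (chains: {', '.join(model.chains())})"
        )
    if (offset is None) == (start_at is None):
        raise ValueError("provide exactly one of offset= or start_at=")
    if start_at is not None:
        first = next(
            a.residue_number
            for a in model.atoms
            if chain is None or a.chain_id == chain
        )
        offset = start_at - first
    assert offset is not None

    new_atoms = [
        replace(a, residue_number=a.residue_number + offset)
        if (chain is None or a.chain_id == chain)
        else a
        for a in model.atoms
    ]
    keys = [a.key for a in new_atoms]
    if len(set(keys)) != len(keys):
        raise RenumberCollisionError(
            f"renumbering by {offset:+d} produces duplicate (chain, residue, atom) keys"
        )
    if any(a.residue_number <= 0 for a in new_atoms):
        warnings.warn(
            "renumbering produced non-positive residue numbers; CYANA output "
            "requires positive numbering",
            stacklevel=2,
        )
    return StructureModel(
        model_id=model.model_id,
        atoms=new_atoms,
        source_format=model.source_format,
        plddt_granularity=model.plddt_granularity,
    )


def residue_plddt_table(
    model: StructureModel,
) -> Mapping[tuple[str, int, str], float]:
    """Mean pLDDT per polymer residue (unweighted arithmetic mean over the
    residue's atoms), keyed by (chain, residue number, residue name).

    For per-residue granularity files this reproduces each residue's shared
    score; for per-atom (AlphaFold3) files it is the standard residue-level
    average.
    """
    if not model.atoms:
        raise EmptyStructureError("cannot summarize an empty model")
    sums: dict[tuple[str, int, str], list[float]] = {}
    for atom in model.atoms:
        if atom.is_polymer:
            sums.setdefault(
                (atom.chain_id, atom.residue_number, atom.residue_name), []
            ).append(atom.plddt)
    return {key: sum(v) / len(v) for key, v in sums.items()}
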