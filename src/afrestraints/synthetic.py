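"""Synthetic AlphaFold-like fixture structures.

Generates small protein chains with controllable Cα geometry (linear,
ideal α-helix, or explicit coordinates) and controllable pLDDT profiles
written into the B-factor role, exactly as AlphaFold stores its
confidence scores.  Fixtures carry full backbone atoms (N, CA, C, O) so
non-Cα selections are testable; side chains are omitted.  Optional
metal-ion records reproduce AlphaFold3's element-named ion convention
(Ca2+ = CA, Mg2+ = MG, ...), which collides with the Cα atom name.

These are geometric stand-ins for real predictions: they exercise the
file formats, filters and arithmetic, not protein physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .errors import AFRestraintsError, EmptyStructureError
from .structure_io import AtomRecord, StructureModel, detect_plddt_granularity

# ideal α-helix parameters: rise per residue (Å), twist per residue (deg),
# helix radius for Cα atoms (Å)
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3

_RESIDUE_CYCLE = (
    "ALA", "GLY", "SER", "THR", "GLU", "LYS", "LEU", "VAL", "ASP", "PHE",
)

#: AlphaFold3 names ion residues and atoms by element symbol.
ION_ELEMENTS = {"CA": "Ca", "MG": "Mg", "K": "K", "ZN": "Zn"}


@dataclass(frozen=True)
class IonSpec:
    """One metal ion appended as a non-polymer record."""

    name: str  # CA, MG, K or ZN
    position: tuple[float, float, float]
    plddt: float = 90.0


@dataclass
class FixtureSpec:
    """Specification of a synthetic structure.

    ``plddt_profile`` accepts a constant, an explicit per-residue sequence,
    ``("two_level", n_first, high, low)`` or ``("ramp", start, stop)``.
    ``backbone`` adds N/C/O atoms around each Cα (sharing the residue's
    pLDDT, as AlphaFold2 per-residue scoring does) unless
    ``per_atom_jitter`` is set, which perturbs atom scores to emulate
    AlphaFold3 per-atom granularity.  ``jitter`` adds Gaussian coordinate
    noise (Å) drawn from ``seed``.
    """

    n_residues: int = 10
    geometry: str = "linear"  # {linear, helix, coords}
    spacing: float = 3.8
    coordinates: Sequence[tuple[float, float, float]] | None = None
    plddt_profile: object = 85.0
    start_residue: int = 1
    chain_id: str = "A"
    residue_names: Sequence[str] | None = None
    backbone: bool = False
    include_ion: IonSpec | None = None
    jitter: float = 0.0
    per_atom_jitter: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues < 1:
            raise AFRestraintsError("n_residues must be >= 1")
        if self.geometry not in ("linear", "helix", "coords"):
            raise AFRestraintsError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "coords" and (
            self.coordinates is None or len(self.coordinates) != self.n_residues
        ):
            raise AFRestraintsError(
                "geometry='coords' requires one coordinate per residue"
            )
        if self.spacing <= 0:
            raise AFRestraintsError("spacing must be positive")


def resolve_plddt_profile(profile: object, n_residues: int) -> list[float]:
    """Expand a profile specification to one score per residue."""
    if isinstance(profile, (int, float)):
        values = [float(profile)] * n_residues
    elif isinstance(profile, tuple) and profile and profile[0] == "two_level":
        _, n_first, high, low = profile
        if not 0 <= n_first <= n_residues:
            raise AFRestraintsError("two_level n_first out of range")
        values = [float(high)] * n_first + [float(low)] * (n_residues - n_first)
    elif isinstance(profile, tuple) and profile and profile[0] == "ramp":
        _, start, stop = profile
        values = list(np.linspace(float(start), float(stop), n_residues))
    elif isinstance(profile, Sequence):
        values = [float(v) for v in profile]
        if len(values) != n_residues:
            raise AFRestraintsError(
                f"explicit profile has {len(values)} values for {n_residues} residues"
            )
    else:
        raise AFRestraintsError(f"unsupported plddt profile {profile!r}")
    if any(not 0.0 <= v <= 100.0 for v in values):
        raise AFRestraintsError("pLDDT profile values must lie in [0, 100]")
    return values


def _ca_trace(spec: FixtureSpec) -> np.ndarray:
    n = spec.n_residues
    if spec.geometry == "linear":
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * spec.spacing
    elif spec.geometry == "helix":
        i = np.arange(n)
        theta = np.deg2rad(HELIX_TWIST_DEG) * i
        coords = np.column_stack(
            (HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i)
        )
    else:
        coords = np.asarray(spec.coordinates, dtype=float)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.jitter, coords.shape)
    return coords


def _backbone_offsets(direction: np.ndarray) -> dict[str, np.ndarray]:
    """Fixed-geometry N/C/O placements around a Cα given the local chain
    direction; bond lengths are plausible (N-Cα 1.46 Å, Cα-C 1.52 Å)."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(d @ ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    perp = np.cross(d, ref)
    perp /= np.linalg.norm(perp)
    return {
        "N": -1.20 * d + 0.83 * perp,
        "C": 1.25 * d + 0.86 * perp,
        "O": 1.40 * d + 2.05 * perp,
    }


def generate_structure(spec: FixtureSpec) -> StructureModel:
    """Build a :class:`StructureModel` from a :class:`FixtureSpec`.

    Deterministic for a fixed seed; Cα coordinates follow the requested
    geometry exactly (before optional jitter).
    """
    spec.validate()
    ca = _ca_trace(spec)
    scores = resolve_plddt_profile(spec.plddt_profile, spec.n_residues)
    names = spec.residue_names or [
        _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)] for i in range(spec.n_residues)
    ]
    if len(names) != spec.n_residues:
        raise AFRestraintsError("residue_names length mismatch")

    rng = np.random.default_rng(spec.seed + 1)
    atoms: list[AtomRecord] = []
    for i in range(spec.n_residues):
        resnum = spec.start_residue + i
        per_atom = {"CA": scores[i]}
        positions = {"CA": ca[i]}
        if spec.backbone:
            if spec.n_residues > 1:
                nxt = ca[min(i + 1, spec.n_residues - 1)]
                prv = ca[max(i - 1, 0)]
                direction = nxt - prv
            else:
                direction = np.array([1.0, 0.0, 0.0])
            for atom_name, offset in _backbone_offsets(direction).items():
                positions[atom_name] = ca[i] + offset
                per_atom[atom_name] = scores[i]
        if spec.per_atom_jitter > 0:
            for atom_name in per_atom:
                jittered = per_atom[atom_name] + rng.normal(0, spec.per_atom_jitter)
                per_atom[atom_name] = float(np.clip(jittered, 0.0, 100.0))
        for atom_name in ("N", "CA", "C", "O"):
            if atom_name not in positions:
                continue
            pos = positions[atom_name]
            atoms.append(
                AtomRecord(
                    chain_id=spec.chain_id,
                    residue_number=resnum,
                    residue_name=names[i],
                    atom_name=atom_name,
                    element=atom_name[0],  # N, C, C, O
                    x=float(pos[0]),
                    y=float(pos[1]),
                    z=float(pos[2]),
                    plddt=round(float(per_atom[atom_name]), 2),
                    is_polymer=True,
                )
            )
    if spec.include_ion is not None:
        ion = spec.include_ion
        name = ion.name.upper()
        if name not in ION_ELEMENTS:
            raise AFRestraintsError(
                f"unsupported ion {ion.name!r}; expected one of {sorted(ION_ELEMENTS)}"
            )
        atoms.append(
            AtomRecord(
                chain_id=spec.chain_id,
                residue_number=spec.start_residue + spec.n_residues,
                residue_name=name,
                atom_name=name,
                element=name,
                x=float(ion.position[0]),
                y=float(ion.position[1]),
                z=float(ion.position[2]),
                plddt=round(float(ion.plddt), 2),
                is_polymer=False,
            )
        )
    return StructureModel(
        model_id="synthetic",
        atoms=atoms,
        source_format="pdb",
        plddt_granularity=detect_plddt_granularity(atoms),
    )


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    # gemmi's add_chain/add_residue copy their argument, so each residue and
    # chain is assembled completely before being attached; atoms of one
    # residue are contiguous in file order per the StructureModel contract.
    structure = gemmi.Structure()
    structure.name = model.model_id or "synthetic"
    gm = gemmi.Model("1")

    def flush_residue(chain: gemmi.Chain, res: gemmi.Residue | None) -> None:
        if res is not None:
            chain.add_residue(res)

    def flush_chain(chain: gemmi.Chain | None) -> None:
        if chain is not None:
            gm.add_chain(chain)

    chain: gemmi.Chain | None = None
    res: gemmi.Residue | None = None
    current: tuple[str, int] | None = None
    for atom in model.atoms:
        rkey = (atom.chain_id, atom.residue_number)
        if chain is None or atom.chain_id != chain.name:
            if chain is not None:
                flush_residue(chain, res)
                res, current = None, None
            flush_chain(chain)
            chain = gemmi.Chain(atom.chain_id)
        if rkey != current:
            flush_residue(chain, res)
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_number, " ")
            res.het_flag = "A" if atom.is_polymer else "H"
            current = rkey
        ga = gemmi.Atom()
        ga.name = atom.atom_name
        ga.element = gemmi.Element(atom.element.capitalize())
        ga.pos = gemmi.Position(atom.x, atom.y, atom.z)
        ga.b_iso = atom.plddt
        ga.occ = 1.0
        res.add_atom(ga)
    if chain is not None:
        flush_residue(chain, res)
        flush_chain(chain)
    structure.add_model(gm)
    structure.setup_entities()
    return structure


def write_fixture(model: StructureModel, path: str | Path, format: str = "pdb") -> Path:
    """Write a model as a standard-conformant PDB or mmCIF file with pLDDT
    in the B-factor column.  Reading the file back reproduces the model
    (coordinates at the format's printed precision, pLDDT exactly for
    two-decimal scores)."""
    if not model.atoms:
        raise EmptyStructureError("cannot write an empty model")
    path = Path(path)
    structure = _to_gemmi(model)
    if format == "pdb":
        structure.write_pdb(str(path))
    elif format == "mmcif":
        structure.make_mmcif_document().write_file(str(path))
    else:
        raise AFRestraintsError(f"unknown fixture format {format!r}")
    return path
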