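"""Output writers: master CSVs, CYANA .upl/.lol files, an XPLOR/CNS-style
export, and viewer command scripts.

Numeric formatting convention: distances, limits and pLDDT scores to two
decimals; gradient error factors and weighted errors to four decimals.
Files are written with LF line endings for byte-reproducible output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from .errors import WriterError
from .restraint_model import RestraintConfig, RestraintRecord

PYMOL_CSV_HEADER = (
    "Residue1_Number,Residue1_Name,Residue1_pLDDT,Residue1_Atom,"
    "Residue2_Number,Residue2_Name,Residue2_pLDDT,Residue2_Atom,"
    "Distance,Residue1_gradient_error,Residue2_gradient_error,"
    "Residue1_weighted_error,Residue2_weighted_error,Max_weighted_error,UPL,LOL"
)

CHIMERAX_CSV_HEADER = (
    "Chain1,Res1,Atom1,Chain2,Res2,Atom2,Distance,Min_pLDDT,"
    "GradientError,Wt_Error,UPL,LOL"
)

_DIALECT_PREFIX = {"pymol": "PML", "chimerax": "CX"}


@dataclass
class OutputBundle:
    """Paths of the files produced for one dialect."""

    csv_path: Path
    upl_path: Path
    lol_path: Path
    dialect: str
    viewer_script_path: Path | None = None


def _fmt_cutoff(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else str(value)


def default_output_name(config: RestraintConfig, dialect: str) -> str:
    """Master CSV filename encoding the run settings, e.g.
    ``CX_distances_CA_CA_15A_b80.csv``."""
    prefix = _DIALECT_PREFIX[dialect]
    return (
        f"{prefix}_distances_{config.atom_name1}_{config.atom_name2}_"
        f"{_fmt_cutoff(config.distance_cutoff)}A_"
        f"b{_fmt_cutoff(config.plddt_cutoff)}.csv"
    )


def default_restraint_stem(config: RestraintConfig, dialect: str) -> str:
    """Stem for the .upl/.lol pair, e.g. ``CX_AF_restraints``."""
    if config.output_stem:
        return config.output_stem
    return f"{_DIALECT_PREFIX[dialect]}_AF_restraints"


def _write_text(path: Path, lines: list[str]) -> None:
    try:
        with open(path, "w", newline="\n") as fh:
            for line in lines:
                fh.write(line + "\n")
    except OSError as exc:
        raise WriterError(f"cannot write {path}: {exc}") from exc


def _pymol_row(r: RestraintRecord) -> str:
    a1, a2 = r.pair.atom1, r.pair.atom2
    return (
        f"{a1.residue_number},{a1.residue_name},{a1.plddt:.2f},{a1.atom_name},"
        f"{a2.residue_number},{a2.residue_name},{a2.plddt:.2f},{a2.atom_name},"
        f"{r.distance:.2f},{r.gef1:.4f},{r.gef2:.4f},"
        f"{r.werr1:.4f},{r.werr2:.4f},{r.max_weighted_error:.4f},"
        f"{r.upl:.2f},{r.lol:.2f}"
    )


def _chimerax_row(r: RestraintRecord) -> str:
    a1, a2 = r.pair.atom1, r.pair.atom2
    return (
        f"{a1.chain_id},{a1.residue_number},{a1.atom_name},"
        f"{a2.chain_id},{a2.residue_number},{a2.atom_name},"
        f"{r.distance:.2f},{r.min_plddt:.2f},{r.gef_min_plddt:.4f},"
        f"{r.max_weighted_error:.4f},{r.upl:.2f},{r.lol:.2f}"
    )


def write_master_csv(
    records: list[RestraintRecord], path: str | Path, dialect: str
) -> Path:
    """Write the master CSV in the requested plugin dialect.

    The PyMOL dialect carries per-atom gradient errors and weighted errors;
    the ChimeraX dialect carries the pair's minimum pLDDT and the single
    GEF/error derived from it.  Distance, UPL and LOL agree between the two.
    """
    if dialect not in _DIALECT_PREFIX:
        raise WriterError(f"unknown dialect {dialect!r}; expected pymol or chimerax")
    path = Path(path)
    if dialect == "pymol":
        lines = [PYMOL_CSV_HEADER] + [_pymol_row(r) for r in records]
    else:
        lines = [CHIMERAX_CSV_HEADER] + [_chimerax_row(r) for r in records]
    _write_text(path, lines)
    return path


def _check_cyana_numbering(records: list[RestraintRecord]) -> None:
    for r in records:
        for atom in (r.pair.atom1, r.pair.atom2):
            if atom.residue_number <= 0:
                raise WriterError(
                    f"CYANA requires positive residue numbers; found "
                    f"{atom.residue_number} on chain {atom.chain_id} — renumber "
                    "the structure to native numbering first"
                )
    chains = {a.chain_id for r in records for a in (r.pair.atom1, r.pair.atom2)}
    if len(chains) > 1:
        warnings.warn(
            "restraints span multiple chains but CYANA output drops chain "
            "identifiers; ensure residue numbering is unique across chains",
            stacklevel=3,
        )


def _cyana_line(r: RestraintRecord, limit: float) -> str:
    a1, a2 = r.pair.atom1, r.pair.atom2
    return (
        f"{a1.residue_number} {a1.residue_name} {a1.atom_name} "
        f"{a2.residue_number} {a2.residue_name} {a2.atom_name} {limit:.2f}"
    )


def write_cyana_restraints(
    records: list[RestraintRecord], upl_path: str | Path, lol_path: str | Path
) -> tuple[Path, Path]:
    """Write CYANA upper- and lower-limit restraint files.

    Whitespace-delimited, no header; columns are residue number / residue
    name / atom name for each partner followed by the distance limit in Å
    to two decimals.  The two files hold the same pairs in the same order.
    """
    upl_path, lol_path = Path(upl_path), Path(lol_path)
    if records:
        _check_cyana_numbering(records)
    _write_text(upl_path, [_cyana_line(r, r.upl) for r in records])
    _write_text(lol_path, [_cyana_line(r, r.lol) for r in records])
    return upl_path, lol_path


def parse_cyana_restraints(path: str | Path) -> list[tuple[int, str, str, int, str, str, float]]:
    """Parse a .upl/.lol file back into tuples (used for round-trip checks
    and for feeding externally produced restraint files into QC)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise WriterError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        rows.append(
            (int(parts[0]), parts[1], parts[2], int(parts[3]), parts[4], parts[5],
             float(parts[6]))
        )
    return rows


def write_xplor_restraints(records: list[RestraintRecord], path: str | Path) -> Path:
    """XPLOR/CNS-style export: one ``assign`` statement per restraint with
    d = distance, dminus = d - lol, dplus = upl - d."""
    if not records:
        raise WriterError("no restraints to export; skip the XPLOR export")
    _check_cyana_numbering(records)
    path = Path(path)
    lines = []
    for r in records:
        a1, a2 = r.pair.atom1, r.pair.atom2
        dminus = r.distance - r.lol
        dplus = r.upl - r.distance
        lines.append(
            f"assign (resid {a1.residue_number} and name {a1.atom_name})"
            f"(resid {a2.residue_number} and name {a2.atom_name}) "
            f"{r.distance:.2f} {dminus:.2f} {dplus:.2f}"
        )
    _write_text(path, lines)
    return path


def write_viewer_script(
    records: list[RestraintRecord], path: str | Path, flavor: str
) -> Path:
    """Emit a PyMOL (.pml) or ChimeraX (.cxc) command script drawing one
    distance measurement per restraint, for visual inspection of the
    restraint network on the predicted structure."""
    if flavor not in ("pymol", "chimerax"):
        raise WriterError(f"unknown viewer flavor {flavor!r}")
    path = Path(path)
    lines = ["# distance restraints derived from an AlphaFold prediction"]
    for i, r in enumerate(records, start=1):
        a1, a2 = r.pair.atom1, r.pair.atom2
        if flavor == "pymol":
            lines.append(
                f"distance af_rest_{i}, "
                f"(chain {a1.chain_id} and resi {a1.residue_number} and name {a1.atom_name}), "
                f"(chain {a2.chain_id} and resi {a2.residue_number} and name {a2.atom_name})"
            )
        else:
            lines.append(
                f"distance /{a1.chain_id}:{a1.residue_number}@{a1.atom_name} "
                f"/{a2.chain_id}:{a2.residue_number}@{a2.atom_name}"
            )
    _write_text(path, lines)
    return path


def write_output_bundle(
    records: list[RestraintRecord],
    config: RestraintConfig,
    outdir: str | Path,
    dialect: str,
    viewer_script: str | None = None,
) -> OutputBundle:
    """Write the master CSV plus the .upl/.lol pair (and optionally a viewer
    script) for one dialect into ``outdir``, using the default filenames."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = write_master_csv(records, outdir / default_output_name(config, dialect), dialect)
    stem = default_restraint_stem(config, dialect)
    upl_path, lol_path = write_cyana_restraints(
        records, outdir / f"{stem}.upl", outdir / f"{stem}.lol"
    )
    script_path = None
    if viewer_script is not None:
        ext = "pml" if viewer_script == "pymol" else "cxc"
        script_path = write_viewer_script(records, outdir / f"{stem}.{ext}", viewer_script)
    return OutputBundle(csv_path, upl_path, lol_path, dialect, script_path)
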