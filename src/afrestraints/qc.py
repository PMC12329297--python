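"""Quality-control utilities: pLDDT confidence evaluation, distance-cutoff
sweeps, configuration validation, and the CYANA-metric discrepancy checklist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import AFRestraintsError
from .restraint_model import Finding, RestraintConfig, build_restraints
from .structure_io import StructureModel, residue_plddt_table

# pLDDT confidence bins.  AlphaFold's published interpretation uses open
# inequalities (> 90, 70-90, 50-70, < 50); boundary scores are assigned to
# the lower bin.
CONFIDENCE_BINS = (
    ("disordered", 0.0, 50.0),          # disordered or unresolved regions
    ("low", 50.0, 70.0),                # prediction may be incorrect
    ("confident_backbone", 70.0, 90.0), # well-predicted backbone
    ("very_high", 90.0, 100.0),         # confident backbone and side chains
)

BIN_LABELS = tuple(label for label, _, _ in CONFIDENCE_BINS)


def classify_confidence(plddt: float) -> str:
    """Confidence-bin label for a pLDDT score in [0, 100]."""
    if not 0.0 <= plddt <= 100.0:
        raise AFRestraintsError(f"pLDDT score must be in [0, 100], got {plddt}")
    for label, low, high in CONFIDENCE_BINS:
        if plddt <= high:
            return label
    raise AssertionError("unreachable: bins cover [0, 100]")


@dataclass
class PlddtSummary:
    """Per-residue score table plus threshold and bin statistics."""

    per_residue: pd.DataFrame  # columns: chain, residue_number, residue_name, plddt
    threshold: float
    n_residues: int
    n_above: int
    fraction_above: float
    bin_counts: dict[str, int]
    atom_name: str | None = None


def plddt_summary(
    model: StructureModel,
    atom_name: str | None = None,
    threshold: float = 80.0,
) -> PlddtSummary:
    """Summarize per-residue pLDDT scores.

    If ``atom_name`` is given (e.g. "CA"), each residue is scored by that
    atom; otherwise by the mean over the residue's atoms.  Counts use the
    strict ``> threshold`` convention of the restraint filter, so the
    fraction reported is the fraction of residues that would contribute
    atoms to restraint generation at that cutoff.
    """
    if atom_name is not None:
        name = atom_name.upper()
        rows = [
            (a.chain_id, a.residue_number, a.residue_name, a.plddt)
            for a in model.atoms
            if a.is_polymer and a.atom_name.upper() == name
        ]
        if not rows:
            import warnings

            warnings.warn(
                f"no polymer residue carries an atom named {atom_name!r}; "
                "summary is empty",
                stacklevel=2,
            )
    else:
        rows = [
            (chain, num, resname, score)
            for (chain, num, resname), score in residue_plddt_table(model).items()
        ]
    frame = pd.DataFrame(
        rows, columns=["chain", "residue_number", "residue_name", "plddt"]
    ).sort_values(["chain", "residue_number"], ignore_index=True)
    n = len(frame)
    n_above = int((frame["plddt"] > threshold).sum())
    bin_counts = {label: 0 for label in BIN_LABELS}
    for score in frame["plddt"]:
        bin_counts[classify_confidence(float(score))] += 1
    return PlddtSummary(
        per_residue=frame,
        threshold=threshold,
        n_residues=n,
        n_above=n_above,
        fraction_above=(n_above / n) if n else 0.0,
        bin_counts=bin_counts,
        atom_name=atom_name,
    )


@dataclass
class SweepResult:
    """Restraint counts as a function of distance cutoff."""

    cutoffs: list[float]
    counts: list[int]
    config: RestraintConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff_A": self.cutoffs, "n_restraints": self.counts})


def cutoff_sweep(
    model: StructureModel,
    base_config: RestraintConfig,
    cutoffs: list[float],
) -> SweepResult:
    """Run restraint generation at each distance cutoff with everything else
    fixed.  Counts are non-decreasing in the cutoff; sweeping 5-20 Å is the
    recommended way to choose the cutoff that maximizes NOE assignments."""
    from dataclasses import replace

    ordered = sorted(float(c) for c in cutoffs)
    counts = [
        len(build_restraints(model, replace(base_config, distance_cutoff=c)))
        for c in ordered
    ]
    return SweepResult(ordered, counts, base_config)


def validate_config(config: RestraintConfig) -> list[Finding]:
    """Structured validation findings for a restraint configuration
    (errors for impossible settings, warnings for inadvisable ones)."""
    return config.validate()


@dataclass
class CyanaMetrics:
    """User-supplied metrics from a CYANA structure-calculation run.

    Any field left ``None`` is skipped by :func:`flag_cyana_metrics`.
    Units: target functions in Å², RMSDs in Å, NOE levels in percent.
    """

    tf_first: float | None = None
    tf_final: float | None = None
    rmsd_first_ensemble: float | None = None
    rmsd_first_vs_final: float | None = None
    pct_discarded_longrange_noe: float | None = None
    pct_unused_noe: float | None = None


#: (field, threshold, description) — a value strictly above its threshold
#: indicates the AlphaFold model may be inconsistent with the NMR data.
CYANA_THRESHOLDS = (
    ("tf_first", 250.0, "first-cycle target function > 250"),
    ("tf_final", 10.0, "final-cycle target function > 10 Å²"),
    ("rmsd_first_ensemble", 3.0, "first-cycle ensemble RMSD > 3 Å"),
    ("rmsd_first_vs_final", 3.0, "first-vs-final cycle RMSD > 3 Å"),
    ("pct_discarded_longrange_noe", 20.0, "discarded long-range NOEs > 20%"),
    ("pct_unused_noe", 20.0, "unused NOEs > 20%"),
)


def flag_cyana_metrics(metrics: CyanaMetrics) -> list[str]:
    """Discrepancy flags for a CYANA run: one flag per indicator whose value
    exceeds its threshold.  An empty list means none of the indicators of
    model/data inconsistency fired."""
    flags = []
    for name, threshold, description in CYANA_THRESHOLDS:
        value = getattr(metrics, name)
        if value is None:
            continue
        if value < 0:
            raise AFRestraintsError(f"{name} cannot be negative, got {value}")
        if name.startswith("pct_") and value > 100:
            raise AFRestraintsError(f"{name} is a percentage, got {value}")
        if value > threshold:
            flags.append(f"{name}: {description} (observed {value:g})")
    return flags
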