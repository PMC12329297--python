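# afrestraints

Turn confident AlphaFold structure predictions into solution-NMR distance
restraints.

Solution NMR structure determination hinges on assigning NOE cross-peaks,
and long-range NOEs are notoriously hard to distinguish from noise. When a
high-confidence AlphaFold prediction of the target protein exists, its
inter-atomic distances can seed the assignment: atom pairs from confidently
predicted regions become loose distance restraints that guide programs such
as CYANA toward consistent NOE assignments without dictating the final
structure.

`afrestraints` implements that conversion as a library and a command-line
tool (`atom-distances`, named after the viewer-plugin command it mirrors):

1. **Read** the predicted structure (PDB or mmCIF). AlphaFold stores its
   pLDDT confidence score (0–100) in the B-factor column — per residue for
   AlphaFold2, per atom for AlphaFold3.
2. **Renumber** (optionally) back to native numbering, e.g. a domain
   predicted in isolation starting at residue 1 shifted to its true range.
3. **Select & pair**: keep atoms of the requested name (default Cα) with
   pLDDT > cutoff (default 80) and enumerate all unique inter-residue pairs
   closer than the distance cutoff (default 15 Å), symmetric duplicates
   removed.
4. **Weight the error**: each pair's distance error is interpolated between
   `err_min = 1.40 Å` and `err_max = 1.56 Å` (the 95% CI of Cα RMSD between
   AlphaFold2 predictions and experimental structures) through a *gradient
   error factor* computed from the pair's minimum pLDDT:

   ```
   GEF   = clamp(1 − (pLDDT_min − cutoff) / (pLDDT_max − cutoff), 0, 1)
   w_err = GEF · err_max + (1 − GEF) · err_min
   UPL   = d + w_err          (upper distance limit)
   LOL   = max(0, d − w_err)  (lower distance limit)
   ```

   With the defaults (cutoff 80, `pLDDT_max` 90) a pair whose weakest atom
   sits at the cutoff gets the full 1.56 Å error; a pair with both atoms
   ≥ 90 gets 1.40 Å.
5. **Write** a master CSV (PyMOL- or ChimeraX-plugin dialect), CYANA
   `.upl`/`.lol` restraint files, and optionally an XPLOR/CNS-style export
   and a viewer command script that draws the restraint network.

QC helpers cover the surrounding protocol: pLDDT confidence binning and
per-residue summaries, distance-cutoff sweeps (restraint count vs cutoff,
recommended range 5–20 Å and never beyond the 21.68 Å edge of AlphaFold's
distance distogram), configuration validation, and the checklist of CYANA
run metrics that signal an AlphaFold model inconsistent with the NMR data.
A synthetic-structure module generates AlphaFold-like fixtures (controlled
geometry and pLDDT profiles, PDB and mmCIF) so the whole pipeline is
testable offline.

## Worked example

Without a prediction at hand, the CLI can generate and process a synthetic
helical fixture:

```sh
$ atom-distances --fixture 20 --seed 7 --sweep 5,10,15,20 --outdir demo
sweep: 5 Å -> 19, 10 Å -> 99, 15 Å -> 135, 20 Å -> 169
135 restraints (CA-CA, < 15 Å, pLDDT > 80) -> demo
```

The sweep line shows how the restraint count grows with the distance
cutoff — the recommended way to pick the cutoff that maximizes NOE
assignments. The default 15 Å / pLDDT > 80 run produced 135 restraints and
these files:

```
$ head -3 demo/CX_distances_CA_CA_15A_b80.csv
Chain1,Res1,Atom1,Chain2,Res2,Atom2,Distance,Min_pLDDT,GradientError,Wt_Error,UPL,LOL
A,1,CA,A,2,CA,3.83,85.00,0.5000,1.4800,5.31,2.35
A,1,CA,A,3,CA,5.43,85.00,0.5000,1.4800,6.91,3.95

$ head -2 demo/CX_AF_restraints.upl demo/CX_AF_restraints.lol
==> demo/CX_AF_restraints.upl <==
1 ALA CA 2 GLY CA 5.31
1 ALA CA 3 SER CA 6.91

==> demo/CX_AF_restraints.lol <==
1 ALA CA 2 GLY CA 2.35
1 ALA CA 3 SER CA 3.95
```

Reading a row: the residue 1–2 Cα pair is 3.83 Å apart with minimum pLDDT
85.00, halfway between cutoff (80) and maximum (90), so GEF = 0.5 and the
weighted error is 1.48 Å — upper limit 3.83 + 1.48 = 5.31 Å, lower limit
3.83 − 1.48 = 2.35 Å, exactly the `.upl`/`.lol` lines. On a real
prediction, replace `--fixture` with `--input model.pdb` (or `.cif`) and,
if the prediction starts at residue 1, add `--renumber-start 643` (or the
appropriate native start) so CYANA sees native numbering.

The same pipeline is available as a library:

```python
from afrestraints import RestraintConfig, build_restraints, read_structure

model = read_structure("model.cif")
records = build_restraints(model, RestraintConfig(distance_cutoff=15, plddt_cutoff=80))
```

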