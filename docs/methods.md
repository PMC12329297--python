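# Methods

## The restraint model

The package converts inter-atomic distances measured on an AlphaFold
prediction into *loose* distance restraints for NOE assignment. The model
assumes only that (a) pLDDT, stored in the coordinate file's B-factor
column, is a usable proxy for local coordinate accuracy, and (b) the
uncertainty of a measured distance is dominated by its least-confident
atom. Under those assumptions each retained pair receives an error
interpolated linearly in the pair's minimum pLDDT:

```
GEF(p)  = clamp(1 − (p − c) / (m − c), 0, 1)        p = min pLDDT of the pair
w_err   = GEF · err_max + (1 − GEF) · err_min
UPL/LOL = d ± w_err
```

where `c` is the pLDDT cutoff and `m` the pLDDT maximum. The clamp is
required because the linear form goes negative for p > m; scores at or
above the maximum simply take the minimum error. The two representations
used by the original viewer plugins — per-atom GEF/error followed by a max
(PyMOL master CSV) versus a single GEF of the pair minimum (ChimeraX CSV) —
are algebraically identical because the interpolation is monotone; the
engine computes both in one pass and the tests assert their equality on
every generated record.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `atom_name1/2` | CA / CA | — | backbone Cα carries the calibrated error range |
| `distance_cutoff` | 15 | Å | empirically maximizes NOE assignments; sweep 5–20 Å per system |
| `plddt_cutoff` | 80 | — | strict `>`; well-predicted backbone; <70 triggers a warning (below AlphaFold's "confident" designation) |
| `plddt_max` | 90 | — | score at/above which the minimum error applies; raise the cutoff to 90 and set this to the prediction's top score for side-chain atoms |
| `err_min`–`err_max` | 1.40–1.56 | Å | 95% CI of Cα RMSD between AlphaFold2 predictions and experimental counterparts; *calibrated for Cα only* — the package exposes the knobs but recommends no values for other atoms |
| `min_sequence_separation` | 1 | residues | only intra-residue pairs excluded; sequential neighbours are genuine restraints here. No separation test across chains |
| `polymer_only` | false | — | AlphaFold3 names ion atoms by element (Ca²⁺ = "CA"), so a Cα selection deliberately captures calcium ions, matching plugin behaviour; set true to exclude them |
| `lol_floor` | 0 | Å | lower limits are floored at 0 since distance < error is otherwise negative; configurable for a van-der-Waals floor |

Boundary conventions are strict on both filters (`d < cutoff`,
`pLDDT > cutoff`) so boundary atoms behave predictably. Distance cutoffs
above 21.68 Å — the upper edge of AlphaFold's inter-residue distance
distogram — produce a warning, not an error: beyond it the network never
explicitly modelled the distance.

Confidence bins follow AlphaFold's published interpretation (>90 very
high; 70–90 confident backbone; 50–70 low; <50 disordered); the open
inequalities leave boundary scores unassigned, and we assign 50/70/90 to
the lower bin.

## Pipeline and numerical choices

Selection and pairing: atoms are matched by exact, case-insensitive name;
pairs are enumerated with a k-d tree (scipy) but the contract is the O(n²)
brute-force enumeration, kept in the package (`brute_force_pairs`) and
asserted equal (pair sets identical, distances to 1e-9 Å) on random
structures in the tests. Pairs are canonically ordered by
(chain, residue number, atom name) so symmetric duplicates collapse and
output is independent of input atom order. pLDDT values are used at full
precision throughout; rounding happens only at write time (distances,
limits and pLDDT to 2 decimals; GEF and weighted errors to 4). Files are
written with LF line endings so outputs are byte-reproducible across
platforms.

Structure reading (gemmi) uses the first model only, keeps the first
altloc per atom name, and treats ATOM records (PDB) / `group_PDB`
(mmCIF) as polymer. B-factor values outside [0, 100] — typically a
crystallographic file passed by mistake — produce a warning, or an error
in strict mode; the filters behave sanely either way. Renumbering is a
pure offset (or a start-residue convenience) applied on request only; the
tool never guesses native numbering. Offsets are bijections, so the
duplicate-key check after renumbering only fires on inputs that already
carry degenerate numbering (e.g. insertion-coded residues collapsed onto
one number). Non-positive residue numbers are permitted with a warning;
the CYANA writer rejects them with an instruction to renumber, since
CYANA requires positive numbering. Chain identifiers are dropped in CYANA
output (single-chain convention); multi-chain restraint sets trigger a
warning to make numbering unique across chains.

The CYANA run checklist (`flag_cyana_metrics`) is a pure threshold check
on user-supplied numbers — first/final-cycle target function > 250 / >
10 Å², first-cycle ensemble RMSD and first-vs-final RMSD > 3 Å, discarded
long-range or unused NOEs > 20% — the package never parses CYANA output
files, whose format varies by version. The first-cycle target-function
threshold is treated as a plain number against 250, the final cycle
against 10 Å².

## Synthetic fixtures: what they do and do not show

`synthetic.generate_structure` produces chains with exact linear or ideal
α-helical Cα geometry (rise 1.5 Å/residue, 100°/residue, radius 2.3 Å —
giving the canonical ~3.8 Å i,i+1 and ~6.2 Å i,i+4 Cα distances),
optional N/C/O backbone atoms at fixed plausible offsets, controllable
per-residue or per-atom pLDDT profiles, optional coordinate jitter under
a seed, and optional element-named metal ions reproducing the AlphaFold3
Ca²⁺/"CA" name collision. Fixtures are written as standard PDB and mmCIF
with pLDDT in the B-factor column.

These fixtures exercise the file formats, the filters, the pair
enumeration and the error arithmetic exactly; they are not folded
proteins. Passing tests therefore demonstrate that the *conversion* from
prediction to restraints is correct, not that restraints from any given
real prediction are accurate — that depends on the prediction itself,
which is why the QC checklist and the pLDDT summary exist.

Problem sizes in the test and acceptance runs are kept small (random
structures up to 200 atoms, fixtures up to ~60 residues); the method is
linear-to-quadratic in atom count and a full-size prediction runs in
seconds.

## Design choices where the ground was open

- The restraint filename stem defaults to `{PML|CX}_AF_restraints` for
  both the `.upl` and `.lol` file (overridable), picking the consistent
  variant among the plugin's slightly divergent printed names.
- The CLI defaults to the protocol's worked 15 Å cutoff rather than the
  PyMOL plugin's printed 4 Å default, which exists for generic contact
  listing rather than restraint generation.
- `gradient_error_factor` accepts a score exactly at the cutoff (returning
  1.0) even though the selection filter is strictly `>`: the endpoint is
  the limit value of the error model and is useful on its own.
- CSV precision (2 decimals for distances/limits/pLDDT, 4 for GEF/errors)
  is a declared convention of this package; the original plugins document
  their formats only as figures.
- The XPLOR/CNS export is a built-in convenience (`assign` statements with
  d, d−LOL, UPL−d); dedicated converters remain the fully featured route.

## Known limitations

- Only pLDDT is used; PAE and other inter-residue confidence measures are
  out of scope, so the error model cannot distinguish a confident pair in
  a rigid domain from two confident atoms on mobile segments.
- The 1.40–1.56 Å error range transfers only to Cα restraints.
- No NMR-ensemble handling, no stereochemistry validation, no NMR-STAR or
  ARIA dialects.
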