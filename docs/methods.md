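# Methods

## Signature model

The unit of description is the heavy atom. A mutation site's wild-type
environment is the set of heavy atoms — any chain, protein or retained
hetero group — within radius *r* of the geometric centre (unweighted mean
of heavy-atom coordinates) of the mutated residue. The environment's
pairwise Euclidean distance matrix is swept by an edge-defining cutoff
over an inclusive grid `d_min … d_max` (step `d_step`); at each cutoff
the number of unordered atom pairs at distance ≤ cutoff is recorded per
atom-class pair. Columns are therefore cumulative: monotonically
non-decreasing in the cutoff, saturating at n(n−1)/2 for the one-class
scheme. Three classification schemes segment the counts and are
concatenated by default:

- **one class** — 1 pair class; overall packing/depth;
- **binary** — polar vs hydrophobic, 3 pair classes. Mapping from the
  eight pharmacophore classes: {hydrophobic, aromatic, neutral, sulphur}
  → hydrophobic; {positive, negative, donor, acceptor} → polar;
- **pharmacophore** — 8 atom classes, 36 unordered pair classes.

The flat layout is scheme → pair class → cutoff, followed by the 8-entry
pharmacophore-change vector Δp = p(mt) − p(wt), then pH, temperature
(°C) and RSA — 21 × 40 + 8 + 3 = 851 features with the defaults.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `radius` | 10.0 Å | environment radius around the residue centre |
| `d_min, d_max, d_step` | 0.0, 10.0, 0.5 Å | cutoff grid (21 steps) |
| `schemes` | all three | which class segmentations are concatenated |
| `centre_mode` | `all_atoms` | residue centre from all heavy atoms (`side_chain` optional) |
| `include_intra_residue` | true | count atom pairs inside the mutated residue |

The 10 Å radius reflects the long-range reach the signature is designed
to capture; 0.5 Å steps are fine enough to separate hydrogen-bond-range
from packing-range counts while keeping the vector compact. Distance
bounds are inclusive (≤, with a 1e-9 float tolerance to absorb rounding),
which is part of the documented contract: test oracles share the
comparison rule, not the implementation.

### Pharmacophore table

The original atom typing behind this signature family is proprietary, so
the package ships its own explicit table (`data/pharmacophores.tsv`)
covering every heavy atom of the 20 standard residues. Ambiguous atoms
receive a single class by the priority order sulphur > positive >
negative > aromatic > hydrogen-donor > hydrogen-acceptor > hydrophobic >
neutral; consequences worth knowing: His and Trp ring nitrogens are
aromatic (the ring outranks their donor/acceptor character), hydroxyl
oxygens of Ser/Thr/Tyr are donors, charged side-chain groups carry the
charge on their N/O atoms only (guanidinium/carboxylate carbons are
neutral), and the proline backbone nitrogen — which has no amide
hydrogen — is neutral. Atoms outside the table (nucleic acids, ligands,
ions, non-standard residues) fall back to an element rule (C→hydrophobic,
N→donor, O→acceptor, S/Se→sulphur, P→negative, metals→positive,
halogens→negative) so protein–DNA interfaces contribute typed atoms.

### Structure normalization

First model of multi-model files; hydrogens and waters removed; for
alternate locations the highest-occupancy conformer is kept (ties: first
in file); hetero atoms kept but flagged (configurable). Waters are
excluded from environments while other hetero atoms are included — a
deliberate, configurable choice since upstream practice is unstated.

### Solvent accessibility

RSA = residue accessible surface area (Shrake–Rupley, probe 1.4 Å,
1000 sphere points, element-based van der Waals radii via biotite)
divided by a per-residue maximum-accessibility reference (theoretical
Gly-X-Gly values, Tien et al. 2013; `data/max_asa.tsv`), clipped to 1.
Values agree with an independent Shrake–Rupley implementation
(Biopython) to well under 1% on the helix fixture; the small residual
difference comes from radii sets and surface-point discretization, which
is also why rotation invariance of RSA is asserted to 0.02 rather than
exactly.

## Thermodynamics

ΔG = R·T·ln K_D with R = 1.9872 × 10⁻³ kcal mol⁻¹ K⁻¹; ΔΔG of binding is
ΔG(mutant) − ΔG(wild type) at one temperature, so **positive** values
mean the mutant binds more weakly. For direction-of-change
classification the package documents one uniform convention — negative
ΔΔG = destabilizing — matching stability tables where ΔΔG =
ΔG_fold(mutant) − ΔG_fold(wild type) is negative for destabilizing
mutations; `load_dataset(..., flip_sign=True)` adapts tables using the
opposite convention (including affinity-derived ΔΔG, whose raw sign runs
the other way). ΔΔG = 0 is classed destabilizing with a boundary flag.
Binding records without a temperature assume 298 K (flagged via the
record). Missing pH/temperature conditions in signatures impute 7.0 /
25 °C and are flagged in provenance.

Dataset dialects (ProTherm-, SKEMPI-, ProNIT-style and the package's
`native` round-trip format) are column maps declared in
`csmpred.datasets.DIALECTS`; temperatures normalize to Kelvin internally
(per-value `C`/`K` suffixes override the dialect default). Rows with
non-numeric text in numeric fields are logged and skipped at load; rows
with empty optional fields are kept and resolved by
`filter_single_point`, which emits one reason code per exclusion
(multi_point, malformed_code, silent, no_structure,
missing_measurement) and is idempotent. Repeated measurements of one
mutation are kept by default; `collapse_duplicates` offers a
median-collapse without claiming fidelity to any historical
deduplication.

## Learning and evaluation

Noise reduction drops zero-variance columns and (optionally, default on)
one member of each column pair with |r| > 0.999; the fitted mask is
stored in the model and reapplied to test data. Features are then
z-scored. The regression default is Gaussian-process regression with a
constant × RBF + white-noise kernel, `normalize_y`, bounded seeded
hyperparameter optimization and no restarts — the model family is given,
the exact kernel is this package's choice. The classifier default is a
random forest (the classification learner used upstream is unpublished);
`logistic` and `ridge`/`rf` alternatives are pluggable via `ModelSpec`.

Cross-validation supports k ∈ {5, 10, 20} (any k ≥ 2) with three
grouping modes. `per-mutation` uses seeded shuffled k-fold.
`per-protein` / `per-position` shuffle the distinct groups with the
protocol seed, then assign groups largest-first to the smallest fold, so
no group ever spans folds and fold sizes stay balanced. Metrics are
**pooled** over all held-out predictions (the numbers a single scatter
plot of every prediction would give), with a per-fold breakdown and a
fold map retained for audit; reports can be recomputed exactly from the
saved audit file. σ is the root-mean-square held-out error in kcal/mol —
labelled explicitly, since "standard error" is ambiguous (no
degrees-of-freedom correction is applied). AUC is rank-based and is
cross-checked in tests against an all-pairs concordance count. Optional
outlier removal drops the ⌈fraction·n⌉ largest absolute residuals
post hoc and recomputes metrics without refitting.

## Synthetic data

The generator exists because real corpora (thousands of curated
mutations over hundreds of PDB structures) cannot ship with the package.
It emulates the *shape* of the problem, not its physics:

- **point-cloud** structures: residues with protein-like composition and
  realistic heavy-atom inventories, clustered on a jittered grid at
  roughly protein density (5.5 Å centre spacing). Geometry is not
  stereochemically valid; it exercises parsing, typing, environment
  extraction and counting exactly as real structures do.
- **ideal-helix**: a 15-residue poly-alanine helix (1.5 Å rise,
  100°/turn) giving a reproducible burial gradient for RSA tests.
- **two-chain-contact**: two residue clouds with a planted closest atom
  pair at an exact, 0.001 Å-quantized interface gap.

Synthetic ΔΔG values are linear in a named subset of signature features
(packing counts at 4/7/10 Å, two binary-scheme contrasts at 8 Å, the
eight Δp entries, RSA) on z-scored scales, plus an optional quadratic
term and Gaussian noise; the defaults plant noise SD = 0.5 × signal SD,
n in the hundreds. The generator returns the noise-free signal and all
generative parameters so recovery can be scored against the truth.

What passing recovery shows — and what it does not: with noise SD =
0.5 × signal SD the correlation between a perfect predictor and the
*observed* targets is capped at 1/√1.25 ≈ 0.894, so recovery quality is
scored as ρ between pooled held-out predictions and the noise-free
generative signal (measured ≈ 0.98 at n = 500), with σ compared against
the injected noise SD (within ~10%); ρ against the observed targets
(≈ 0.87–0.88) is reported alongside. These numbers certify that the
pipeline — signatures, reduction, GP, pooling — recovers a planted
signal; they say nothing about accuracy on real thermodynamic data,
whose effect structure is not linear in these features.

The SKEMPI-style filter fixture plants 20 rows (13 valid, 2 multi-point,
1 malformed code, 1 silent, 1 missing structure id, 1 missing mutant
affinity, 1 non-numeric affinity) and writes a JSON manifest so filter
tests assert exact survivor and reason counts.

## Problem sizes

Default verification runs use structures of 12–24 residues (~100–200
atoms), 100 random environments of ≤ 60 atoms for oracle comparison, 20
end-to-end signature fixtures, n = 500 mutations with 10-fold GP
cross-validation for recovery, and 1000 randomized trials for fold
integrity — sizes chosen so the whole suite verifies on a laptop-class
single core in about a minute while still exercising every code path at
non-trivial scale.

## Known limitations

- Point-cloud fixtures are not stereochemically valid proteins; tests on
  them validate bookkeeping and invariances, not biophysics.
- The pharmacophore table is a faithful re-creation of the eight-class
  semantics, not a byte-level clone of the proprietary typing it
  replaces; single-label assignment loses donor/acceptor duality.
- mmCIF input, hydrogen placement, mutant-model building and explicit
  energy terms are out of scope by design.
- PDB numbering is taken as authored (chain + residue number + insertion
  code); mismatches between mutation codes and structures are hard
  errors, never silent renumbering.
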