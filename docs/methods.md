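# Methods

## Cross-link identification and error modeling

### CSM prefilter

Candidate cross-link spectral matches are kept when both peptide scores
are strictly above 20, the score difference is strictly above 0, and both
peptide lengths fall in the inclusive window 4–25 residues. Strict versus
inclusive boundaries follow the wording of the operating rules ("above"
versus "between"); all four bounds are `RunConfig` fields.

### Linear SVM rescoring

Each CSM carries seven features: score difference, percent of fragment
ions matched (accepted on either the 0–1 or 0–100 scale and normalized to
0–1 at ingest), precursor charge state, and the rank and length of each
peptide. Rank and length are deliberately kept per-peptide (two features
each) because collapsing them would lose information the classifier can
use. TT CSMs form the positive class and decoy-containing (TD ∪ DD) CSMs
the negative class, pooled because the decoy classes are not subdivided
anywhere downstream of the error model.

Spectra are split into random halves (seeded); features are z-standardized
on the training half; the model is an L2-regularized linear SVM
(`LinearSVC`, C = 1, squared hinge, primal) — the regularization constant
is not a published quantity, so it is fixed and recorded in the model
spec rather than tuned. The decision threshold is the smallest value at
which at most 10% of held-out decoy-containing CSMs score above it
(specificity target 0.90, configurable); tie handling is "smallest
threshold satisfying the constraint", evaluated over the unique held-out
decoy scores, with integer count comparison to avoid float-noise at exact
fractions. Separate classifiers are fit for the ETD and HCD channels; a
pooled model (`channel=None`) is the documented fallback when one channel
has too few records.

### Decoy error model and FDR

With a decoy database k times the target database size (default k = 10),
the expected wrong-TT counts at a threshold are `tf = TD/k − 2·DD/k²`
(one wrong peptide) and `ff = DD/k²` (both wrong). `tf` is clamped at
zero: the subtraction can go negative at small counts while the estimated
quantity is a nonnegative expected count. The combined estimate
`FDR = (tf + ff)/TT` counts both error kinds as false; this is the
natural reading of "wrong TT hits" and the only combination consistent
with both error formulas being reported.

FDR curves are tabulated at every unique score (or a supplied grid).
`fdr_monotone` is the q-value-style running minimum of the raw FDR over
all thresholds at or below each threshold, which is the construction that
makes the curve nonincreasing as the threshold increases; threshold
selection for a target FDR uses the monotonized curve.

CSMs are aggregated to unique residue-pair cross-links by keeping the
best-scoring CSM per canonically ordered pair across both channels
(canonical order: sorted by (protein id, residue)). Ties break by higher
svm_score, then HCD before ETD, then lexicographic spectrum id — fully
deterministic. Near-identical isoforms whose links cannot be assigned to
one member can be collapsed via an ambiguity-group mapping. FDR is
computed at both the CSM and the link level; the reported list is the TT
links at or above the reporting threshold (default SVM score 1.5), with
decoy links retained only in the accounting.

## Structural validation

Links are mapped onto Cα coordinates parsed (gemmi) from PDB or mmCIF
files via a protein→chain table with per-chain residue-number offsets
(negative offsets accommodate expression tags absent from deposited
coordinates). When a protein appears as several chain copies, the link's
distance is the minimum over all copy pairs — a cross-link is satisfied
if any copy pair satisfies it, the standard convention for homomeric or
duplicated chains. A link is unmappable (a value, not an error) when no
copy pair has both Cα atoms; self links (same protein and residue) are
flagged and excluded. The violation rate is the fraction of mappable,
non-self links with minimum distance strictly greater than the cutoff
(default 35 Å, reflecting the ~30 Å Cα–Cα reach of DSS/BS3-class
cross-linkers plus coordinate uncertainty). Solvent-accessible-surface
path distances are out of scope.

## RIP-seq enrichment

Counts are normalized to CPM (each sample scaled to 1e6). Role means are
taken across replicates on the CPM scale first, then
`enrichment = (mean_flag − mean_ctrl)/mean_input`; means-first is one of
two defensible orders and is the implemented one. CPM is used as the
abundance unit throughout because it is the only unit the floor rule
names. Genes with zero mean input CPM are left unscored rather than
infinite. The 0.5-CPM floor is strict and by default evaluated on the
mean across all samples (scope configurable to input-only), since the
sample scope of the floor is not otherwise pinned down.

Client sets are selectable two ways — `top_n` (e.g. the 529 most enriched
membrane-protein transcripts) or `score_threshold` — because the
dashed-line rule that defined the published most-enriched set is not
stated; neither mode is asserted to be "the" rule. TMD summaries report
per-bin proportions (integer bins 1–13 plus "14+") for the client set and
the floor-passing background, the multi-pass (≥ 4 TMD) fraction of each,
and the functional-category tabulation of clients. A signed log2
transform `sign(x)·log2(1+|x|)` is provided for display only, since the
raw score can be negative; every analysis quantity uses the raw score.

Batch structure, when present in the sample sheet, can be removed with a
light-weight gene-wise per-batch mean-centering in log1p-CPM space. This
replaces model-based surrogate-variable adjustment, assumes batches
differ by additive gene-wise offsets, and must not be used when batch is
confounded with sample role.

## Synthetic data: what it emulates and what it does not

`simulate_csms` draws correct matches (always TT) and incorrect matches
in two kinds: exactly one wrong peptide (the other correct, hence target)
and both wrong, split by `frac_one_wrong` (default 0.5 — both error
channels of the tf/ff model are populated). Each wrong peptide is decoy
with probability k/(k+1) independently, so both-wrong matches land
TT:TD:DD as 1 : 2k : k², and one-wrong matches land TT:TD as 1 : k —
exactly the composition the error model inverts. Features are
class-conditional Gaussians whose separation puts a linear classifier at
a realistic operating point (high sensitivity at 90% specificity);
incorrect-match features are identically distributed across decoy classes
(the core target-decoy assumption), with a `decoy_bias` knob to violate
that assumption deliberately in robustness tests. Correct CSMs draw their
residue pairs from a finite pool so links have genuine multi-CSM support.
The generator does not model spectra, retention behavior, peptide
chemistry, or search-engine score distributions; passing tests establish
the statistics conditional on the class-composition assumption, not
fidelity to any instrument.

`simulate_structure_and_links` places every residue of a toy multi-chain
structure in its own cell of a coarse grid (≥ 150 Å apart), then moves
each planted link's second residue next to its first at a distance drawn
inside the true range (8–30 Å, below the cutoff) or the violating range
(40–60 Å, above it); ranges straddling the cutoff are rejected.
Coordinates are rounded to 3 decimals before planting so a PDB
write/read round trip is exact. The planted violation fraction is
therefore exact by construction, and unmappable links reference residue
numbers beyond the modeled chains.

`simulate_counts` draws negative-binomial counts (default dispersion 0.1,
typical of bulk RNA-seq; Var = m + α·m²) around log-normal baseline
abundances for 4000 genes, with three Flag-IP and three control-IP
replicates and two input replicates. Class effects multiply the baseline
in the IP roles: soluble transcripts are depleted in both IPs,
single-pass membrane transcripts carry only nonspecific background, and
multi-pass (≥ 4 TMD) transcripts are specifically enriched. Because CPM
renormalizes each sample to its own total, the enrichment a perfect
analysis recovers is the class factor divided by the library-composition
mean of that role's factors; the generator emits this
composition-corrected value per gene (`planted_enrichment`) so recovery
is checked against the exact generating parameters. Expected library
size is equalized across samples. The generator does not model gene
length, GC, isoforms, or count correlation between roles.

## Problem sizes and numerical choices

Default analysis-scale runs use 2 000 correct and 20 000 incorrect CSMs
(≈ 660 true links), a 4-chain/60-residue toy structure with 18 true, 2
violating and 2 unmappable links, and 4 000 genes; calibration checks use
1e5 incorrect CSMs and 20 independent seeds — sizes chosen so every
statistical assertion has the power it needs while a full run stays in
seconds. All randomness flows from one seed through independently spawned
substreams; every generator is a pure function of (spec, seed).
Degenerate inputs are values, not crashes, wherever the quantity is
legitimately undefined: zero TT at a threshold gives FDR 0 with a
warning, zero mappable links flags the rate undefined, and an empty
prefilter output is allowed with a warning.

## Known limitations

* The FDR model estimates expected error counts; at very small reported
  lists the estimate is noisy, and the calibration guarantee is stated
  (and tested) in pooled form across runs.
* Enrichment inference is purely descriptive — no dispersion shrinkage,
  no differential tests; ranking and set summaries are the outputs.
* Batch centering is offset-based, not a surrogate-variable model.
* Distance validation uses Cα positions only and trusts the chain map;
  residue-numbering mismatches beyond a constant per-chain offset are not
  detected.
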