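# Methods

## Scope and model

`tcrsafe` models the preclinical off-target assessment of a TCR as a chain
of discrete, testable computations. The biological object is a TCR restricted
to one HLA class-I allele and specific for one 8–11-mer epitope (the
*cognate* peptide). The pipeline asks two safety questions: which other
peptides in a proteome could activate this TCR (peptide cross-reactivity),
and which other HLA alleles activate it regardless of peptide
(allo-reactivity).

## Fingerprinting

**Library.** The positional-scanning library contains the cognate peptide
plus every single-position substitution with each of the 19 alternative
residues: 19L+1 unique peptides for an L-mer (172 for a 9-mer). Order is
deterministic (cognate first, then position-major, substituting residues
alphabetical) so synthesis sheets and result joins are stable.

**Normalization.** Activation readouts (IFN-γ pg/ml from ELISA, or any
analogous readout such as CD137 upregulation) arrive as one 20×L matrix per
replicate plus each replicate's cognate-peptide response. Each replicate is
divided by its own cognate response *before* averaging across replicates.
The order matters: per-replicate normalization cancels inter-experiment
scale differences (different effector batches, ELISA standards), which a
normalize-after-pooling scheme would propagate into the thresholding step.
The cognate cell is forced to exactly 1.0 so the fingerprint invariant
(cognate residue always tolerated) holds by construction. No background
subtraction is applied by default; an optional per-replicate blank is
supported, and negative values arising from it are clamped to zero with a
warning rather than allowed to corrupt downstream entropy calculations.

**Thresholds.** A substitution is *tolerated* (primary set) when its
normalized response is ≥ 0.10, and *borderline* (extended set) in
[0.05, 0.10). Both lower boundaries are inclusive — "10% or more" is a
positive call. The extended set is kept separate rather than merged because
the proteome query grows multiplicatively with set sizes; the
`include_extended_in_query` flag lets users run the broader (more sensitive,
less specific) query explicitly.

**Logo weights.** The recognition profile is visualized as a Shannon
information-content logo computed from activity-derived frequencies: per
position, q(a) = activity(a) / Σ activity, I = log2(20) − H(q), letter
height = q(a)·I. Several logo weighting schemes exist (frequency-only,
Kullback–Leibler against a background, weighted low-count corrections); the
plain Shannon form was chosen because the input is a complete designed
matrix, not a sampled alignment — there are no counts to correct and no
meaningful background distribution for assay responses. Heights are emitted
as a TSV; plotting is left to the user's stack.

## Proteome scanning

The fingerprint compiles to a degenerate pattern (one residue set per
position), equivalent to a character-class regular expression, and is
matched with an overlap-permitting sliding window (regex lookahead).
Windows containing non-canonical letters (X, U, B, Z, J, O) never match —
the conservative behaviour of standard motif scanners. Candidates are
de-duplicated by sequence with all source locations aggregated, because the
safety question is about peptides, not genomic sites; per-source rows are
preserved in the report. The cognate sequence itself is always excluded
(it is the on-target), and the cognate source protein can be excluded by
accession, since the antigen itself trivially matches its own fingerprint.
Internal coordinates are 0-based half-open; reports are 1-based inclusive.

Edit distance between a candidate and the cognate is the substitution-only
(Hamming) distance on equal-length peptides. Gapped alignment is
deliberately out of scope: the scan only ever produces equal-length windows,
and length-variant recognition is probed experimentally with the
length/frame variant generator instead.

`cross_species_min_distance` reports, for a candidate, the closest
equal-length window in a second proteome (e.g. mouse) by exhaustive search,
with ties broken by file order. This quantifies whether an animal model can
report on a given human off-target at all.

## Annotation, statistics, constructs

**Binder classes** use the predictor's %rank with strict inequalities:
rank < 0.5 strong, 0.5 ≤ rank < 2 weak, else non-binder. **Activation
calls** reuse the inclusive ≥10% rule. The asymmetry (strict vs inclusive)
follows the conventional statements of the two rules.

**Group comparison** (e.g. edit distance of activating vs non-activating
candidates) is a two-sided Mann–Whitney U test. For untied pooled data with
n1+n2 ≤ 20 the p-value is exact by full enumeration of all C(n1+n2, n1)
labelings, counting labelings with |U − n1·n2/2| at least as extreme as
observed. Ties, or larger samples, fall back to the mid-rank normal
approximation with tie and continuity corrections, and the result records
which path was taken. Zero rank variance (all observations equal) returns
p = 1. The exact path can be forced or forbidden via the `method` argument,
which is how the test suite checks that the two paths agree on untied
n1 = n2 = 10 data.

**Correlation** between two activation readouts is Pearson product-moment by
default — the readouts are continuous measurements on a common normalized
scale — with Spearman available by flag for monotone-but-nonlinear
relations.

**Minigene design.** The default construct is a 30-residue window with 10
natural upstream residues, the 9-mer epitope, and 11 natural downstream
residues. A flank of exactly 10 on both sides of a 9-mer gives 29; one side
must carry the extra residue to reach a round 30-mer coding length, and the
extra residue is placed downstream (C-terminal flanking sequence is what the
proteasome acts on first when liberating the epitope's C-terminus). The
split is configurable (`total_length`, `upstream_flank`) and recorded in the
construct. Near a protein terminus the deficit is taken from the other side
to preserve total length; proteins shorter than the construct yield the
maximal window flagged `truncated`. Reporter tags (GFP etc.) are metadata
and never concatenated into the amino-acid window. The trimer cassette is
the epitope plus an AAY linker.

**Tumor volume** from three caliper diameters uses the ellipsoid formula
π/6·a·b·c (mm³) — included because in-vivo efficacy readouts sit alongside
the in-vitro screen in this workflow.

## HLA panel analysis

**Implication** is presence/absence set arithmetic: implicated = (union of
alleles of reactive lines) − (union of alleles of any non-reactive line).
Known limitation: a truly cross-reactive allele that also occurs in a line
whose response falls below the reactive-call threshold is exonerated; the
method's sensitivity is bounded by the panel's composition and the call
threshold. Reactivity calls are taken as given (the screening readout is
usually called qualitatively); the 10% rule from annotation can be used to
derive them. Lines expressing the TCR's target antigen flag their
implicated alleles as *confounded*: presentation of the cognate peptide on
the implicated allele cannot be distinguished from true allo-reactivity.

**Killing** readouts are normalized as surviving-target counts over the mean
mock-effector count (survival; killing = 1 − survival). IFN-γ reactivity and
killing are reported side by side without an automatic verdict — a line can
be reactive by cytokine but not measurably killed, and that discordance is
information, not noise to resolve.

**Population prevalence.** Genotypes are modeled as allele sets
(homozygosity ignored), matching the Hardy–Weinberg carrier computation:
P(carrier of allele with frequency f) = 1 − (1 − f)²; a set of alleles at
one locus uses Σf; loci combine by independence (no linkage disequilibrium).
Both the per-allele and the combined multi-locus outputs are reported, since
either can be the clinically relevant exclusion criterion. Panel *coverage*
applies the same arithmetic to the union of panel alleles: the fraction of
a population for which the panel can detect at least one carried allele.

**Supertypes.** A small bundled allele→supertype table (the standard
functional classification of class-I alleles into A01/A02/A03/A24/B07/...
families) supports the common observation that implicated alleles cluster
in the cognate allele's supertype. Lookups are format-normalized and any
unknown allele returns "unassigned"; the table is user-replaceable.

## Synthetic data

The generators define the conditions under which the pipeline's guarantees
are stated, and every generator is a pure function of (parameters, seed).

* **Scan matrices**: raw(p, a, rep) = cognate_level ·
  true_activity(p, a) · ε with ε lognormal, mean 1, coefficient of
  variation `noise_cv` (default 0.1 — multiplicative, heteroscedastic,
  ELISA-like). Defaults: 3 replicates, cognate level 2690 pg/ml (a typical
  cognate-response magnitude for this assay class). Planted profiles draw
  tolerated activities from [0.2, 1.0] and non-tolerated from [0, 0.02],
  i.e. well separated from both cut-offs, so exact recovery is the correct
  expectation under moderate noise.
* **Proteomes**: i.i.d. background residues (uniform 1/20 by default; a
  vertebrate-like frequency preset is bundled) with off-target peptides
  spliced in at exact, non-overlapping offsets.
* **Panels**: each line draws two alleles per locus from a 30-allele pool;
  carriers of the planted allele respond at ~2000 pg/ml, non-carriers at
  ~20 pg/ml (100:1 separation, lognormal CV 0.2); at least one carrier and
  one non-carrier are guaranteed.

What the synthetic data does *not* emulate: real response magnitudes are
peptide-specific rather than two-valued; real proteomes have strong local
composition structure (repeats, paralogs) that inflates candidate counts at
fixed pattern size; real panels have linkage between loci and population
structure in allele co-occurrence. Passing recovery tests therefore
demonstrates the correctness of the algorithms under the stated noise
model, not the expected candidate yield or implication specificity on real
data.

## Numerical choices and problem sizes

Thresholding uses plain floating-point comparison against the configured
cut-offs; normalized values are ratios of measured quantities and the forced
cognate cell is exactly 1.0, so no epsilon is applied at the boundaries.
The exact Mann–Whitney enumeration is limited to n1+n2 ≤ 20
(≤ 184 756 labelings). Scanner-vs-oracle and recovery rates in the test
suite and acceptance script use 100 randomized instances each (proteomes up
to 10 × 200 residues, 100 scan simulations, 100 panels), sizes at which the
brute-force oracles remain exact and the whole suite runs in well under a
minute.

## Known limitations

* Fingerprinting assumes positional independence: a combination of
  individually tolerated substitutions is treated as potentially
  cross-reactive, which is deliberately conservative (inclusion, not
  prediction); conversely, epitopes structurally divergent from the cognate
  peptide are invisible to this screen.
* The scanner searches exactly the FASTA it is given; isoform coverage and
  database curation are the caller's responsibility.
* MHC-binding prediction and proteasomal-cleavage scores are consumed as
  external annotations, never computed.
* Allele implication cannot separate cognate-peptide presentation on an
  implicated allele from true allo-reactivity when target-antigen-positive
  lines are used (flagged as confounded, not resolved).
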