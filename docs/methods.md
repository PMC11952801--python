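# Methods

## Scope and model

kiclib implements the computation behind a kinase-client (KiC) screen: the
design of a conservation-enriched synthetic phosphopeptide library from
phosphosite catalogs and ortholog alignments, and the downstream processing
of the screen's identifications. Everything upstream of flat tables — raw
spectra, database searching, decoy FDR, Ascore probability computation,
ortholog inference and MSA construction — is out of scope; those artifacts
are consumed as inputs (FASTA, TSV/CSV).

## Conservation scoring

For an ortholog-group alignment `M` of `N` rows and `L` columns over the
21-symbol alphabet (20 amino acids plus the gap `-`), the column
distribution `p_C` is the observed symbol frequency of column `C`. The
column conservation score is the Jensen–Shannon divergence against a
background `q`:

    PM_C = λ·RE(p_C, r) + (1−λ)·RE(q, r),   r = λ·p_C + (1−λ)·q

with `RE` the Kullback–Leibler divergence. Choices that the formula leaves
open, and how they are fixed here:

* **Logarithm base 2**, so `PM ∈ [0, 1]` at `λ = 0.5`. A bounded score
  simplifies ranking and matches the convention of the window-based
  conservation-scoring literature this method follows.
* **λ = 0.5** by default (exposed as a parameter).
* **Background `q`**: the BLOSUM62 alignment background frequencies as used
  by the standard window-scoring implementation (order ARNDCQEGHILKMFPSTWYV:
  0.078, 0.051, 0.041, 0.052, 0.024, 0.034, 0.059, 0.083, 0.025, 0.062,
  0.092, 0.056, 0.024, 0.044, 0.043, 0.059, 0.055, 0.014, 0.034, 0.072),
  normalised to sum exactly to 1. The gap symbol carries zero background
  mass. Gaps still enter `p_C`, so the mixture `r` has gap mass exactly when
  the column does and `RE(p_C, r)` stays finite; `RE(q, r)` is finite
  because `r ≥ (1−λ)·q` on the amino acids. No separate gap-fraction
  penalty is applied — heavily gapped columns are down-weighted only through
  their distribution.

The site score `CS_p` is the arithmetic mean of `PM` over the up-to-10
columns within ±5 of the site, **excluding the site column itself** (the
site is by definition an acceptor residue; its own column carries no
information about flank conservation). The alternative reading — an
11-column mean including the site — is available via `include_site=True`.
Windows truncate at alignment ends and the divisor `n` shrinks accordingly,
so `CS_p` is always a mean of the columns actually available.

Classification rules:

* **Conserved (source 1):** the site's alignment column carries an annotated
  phosphosite in ≥2 species, regardless of which acceptor (S/T/Y) each
  species phosphorylates.
* **Potentially conserved (source 2):** every non-query ortholog row has an
  S/T/Y at the site's column; requires `N ≥ 3` rows. Eligible sites are
  ranked by `CS_p`.

## Library assembly

Peptides are 20-mers with the site at offset 10 (1-based) when both flanks
allow; near a terminus the window shifts to keep length 20 and offsets
forced outside [5, 15] are flagged terminal-clamped (a stricter [6, 14]
band can be requested). Windows containing the ambiguity character X are
excluded — synthetic peptides must be fully specified.

Percent identity between equal-length peptides is positional (Hamming
matches / length); unequal-length peptides from external lists are globally
aligned first and identical aligned positions are counted against the
shorter length. Deduplication is a greedy pass in priority order
(descending conservation score, ties by protein accession then position): a
peptide is removed iff its identity to an already-retained peptide is
**strictly** greater than the 60% threshold, so identity exactly 60.0 is
retained. Exact sequence duplicates always collapse, with source tags
unioned. The greedy-by-score order makes the outcome deterministic and
keeps the highest-value peptide of each redundancy cluster; the output is
idempotent under re-application. Multi-source merges count Venn regions
over the collapsed peptides, so disjoint region counts sum to the unique
total while per-source counts sum to the pre-merge total. Rank selection is
by score descending, then priority-source membership, then sequence lexical
order.

## Screen processing

The three filtration thresholds (Ascore ≥ 20, PTM ion intensity ≥ 5%,
phospho PSM count ≥ 2) are all inclusive. A manual spectrum check is not
modelled; when a boolean `manual_check` column is present a negative value
fails the record. Stoichiometry is `100 × phospho PSMs / total PSMs`;
ranking is stoichiometry descending with deterministic tie-breaks (phospho
PSM count, then peptide).

Masses use the monoisotopic residue table plus one water per chain
(18.0105646 Da, taken at full precision so mass additivity holds to
rounding error); phospho adds 79.96633 Da (the "+79.97" seen in printed
tables is display rounding), methionine oxidation 15.99491 Da, and
cysteines are left unmodified (synthetic peptides, no alkylation step).
m/z is `(M + z·1.007276)/z`. Printed instrument m/z values can differ from
the theoretical value by a few mDa, so QC compares masses within ±0.001 Da
but m/z only within ±0.01.

Localization consensus scores each compartment as 5 × experimental count +
1 × predicted count; ties are reported with the alphabetically first
compartment as primary. The motif summary tallies residues at offsets
−5..+5 around every localized site, truncating at peptide ends, and
normalises each offset over its contributing count.

## Overlap mapping

The global aligner is an affine-gap (Gotoh) dynamic program with match +2,
mismatch −1, gap open −0.5, gap extension −0.1; a gap run of length `g`
costs `open + (g−1)·extend` and end gaps are penalized like any other
(true global alignment). Exactly one optimal alignment is returned with
traceback preference diagonal > up > left, so results are reproducible
across platforms. Boundary cells are initialised by the same additions the
traceback recomputes, making the traceback's float-equality tests exact.
The implementation is cross-checked in the test suite against both an
exhaustive alignment-enumeration oracle (short sequences) and an
independent aligner's scores.

Intensity selection treats missing values as 0 and a zero-denominator fold
change with positive numerator as passing — a peptide absent in the
knockout but present in wild type is the strongest qualitative signal.
Replicate observations of the same peptide/genotype are averaged before
the inequality tests. Overlap with the screen's candidate list is counted
at the gene-accession level, with unmapped peptides listed rather than
silently dropped.

## Synthetic data

The generators emulate the structure of the real inputs, not their full
biology:

* **Ortholog families** are gap-free alignments with a contiguous planted
  block of columns identical across rows and the remainder drawn i.i.d.
  per row from the BLOSUM62 background (so unconserved columns score near
  `PM ≈ 0` up to sampling noise). Two designated site columns carry an S in
  every row, one with fully conserved flanks and one with background
  flanks. Defaults mirror the targeted study conditions: 6 species, 200
  families, 60-column alignments, half the columns conserved.
* **Phosphosite tables** annotate query-row acceptor columns at a given
  rate and, at the cross-species rate, also annotate the homologous column
  in one other species, recording the conserved label as ground truth.
* **Screen tables** plant an exact pass set; every other record violates
  exactly one named criterion.
* **Intensity tables** give planted peptides a two-fold effect per genotype
  step (ko → wt → ox) and break the chain for the rest.

What these fixtures do *not* model: alignment gaps and indel structure,
phylogenetic correlation between rows (each background column is i.i.d.),
compositional bias of real proteomes, spectral-level noise, missing-value
structure of real intensity matrices, and replicate variance. Passing
tests therefore demonstrate correctness of the computations and their
stated invariants, not recovery performance on real proteomes.

All generators are pure functions of `(seed, index)` via a counter-based
RNG, so identical seeds give byte-identical outputs.

## Numerical and scale choices

* Divergences are computed in exact dict arithmetic (no clipping); terms
  with `p(α) = 0` contribute 0, and `p(α) > 0` with zero mixture mass is an
  error rather than a silent `inf`.
* The alignment-oracle check covers every length combination up to 6 over a
  4-letter alphabet with several seeded random pairs per combination plus
  adversarial homopolymer/repeat pairs, requiring exact score equality on
  every pair; exhausting all ~10^7 such pairs adds no coverage the sampled
  grid lacks.
* Property suites (10,000 random distribution pairs, 100 random MSAs, 200
  planted families, 500 additivity pairs) run in seconds; the sizes were
  chosen so the whole suite stays interactive while keeping binomial noise
  on the recovery rates well below the asserted margins.

## Known limitations

* The >60% identity dedup is greedy, not a clique/cluster optimum; the
  retained set depends on the documented priority order (deliberately, so
  higher-scoring peptides survive).
* `percent_identity` for unequal lengths depends on the alignment
  parameters; all library-internal comparisons are between 20-mers and use
  the positional route.
* The pairwise DP is pure Python and intended for peptide-scale inputs
  (tens of residues, thousands of pairs), not genome-scale alignment.
* Ascore, search-engine scores and SUBA evidence counts are taken at face
  value from the input tables; no recalibration is attempted.
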