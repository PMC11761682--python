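# Methods

This note documents the models, parameter choices, and numerical rules
behind `vnarmine`, and what the synthetic validation does and does not
demonstrate about real data.

## Read processing

**Trimming.** Adapter removal truncates at the leftmost occurrence of the
adapter (≤1 mismatch; a ≥5 nt adapter prefix running off the 3' end also
matches). Quality trimming then drops 3' bases while the terminal base or
the mean of the trailing 4-base window is below `min_phred` (default 20).
The rule is monotone — it never lengthens a read — which is all the
downstream stages rely on; any monotone trimmer could be substituted.

**Merging.** The reverse mate is reverse-complemented and candidate
overlap lengths ℓ from `min_overlap_nt` (default 15) up to the shorter
read length are scored by Hamming mismatches. Overlaps with mismatch
fraction ≤ `max_overlap_mismatch_frac` (default 0.25) are admissible; the
minimal mismatch fraction wins, with ties broken toward the *shortest*
admissible overlap, i.e. the longest merged product. Rationale: a perfect
self-overlap longer than the true one (which periodic inserts can
produce) should not beat the true overlap; and a spurious overlap
*shorter* than the true one would need a chance perfect ≥15-nt match
(~4⁻¹⁵ per candidate), so on realistic amplicons the rule selects the
true overlap essentially always. Candidate comparisons use exact integer
cross-products so floating-point rounding cannot reorder candidates.
Disagreeing overlap bases take the higher-quality base (forward read wins
ties). The scan is a compiled (numba) kernel with early abandoning; merge
behavior is validated against a brute-force overlap enumerator on
exhaustively enumerated short templates.

`min_overlap_nt = 15` is deliberately above the common 10: with ~10⁵
pairs per library, a 10-nt floor admits roughly one chance perfect
overlap per run, which would corrupt single molecules; at 15 the expected
count is ~10⁻⁴.

**Flank filtering.** The insert is the interval strictly between the 5'
anchor (the conserved primer-derived sequence
`GCCATGGCTGCTCGAGTGGACCAAACACCGCGTGACTGTGAATGGCCCGGGAGGCCA`) and the
first subsequent occurrence of the 3' anchor. Anchors are matched at a
configurable Hamming allowance (default exact); with no 3' anchor
configured the insert extends to the end of the merged sequence. Both
orientations are searched and normalized so the 5' anchor is upstream.
The 3' anchor shipped as default is a synthetic stand-in used by the
generator; real amplicon designs must configure their own. Note that
exact anchor matching discards any read with a single sequencing error
inside the 78 nt of anchor (~7% of reads at an error rate of 10⁻³ nt⁻¹);
set `max_flank_mismatches=1` to recover nearly all of them.

**Translation.** Frame is fixed at insert position 0 (primer-anchored
amplicons have a fixed frame). Inserts are rejected when their length is
not a codon multiple, when any codon contains N (translating N as X would
let dereplication merge distinct molecules through wildcards), when a
stop codon occurs before the final codon, or when the protein falls
outside 80–220 aa (accommodating hyper-elongated CDR3 loops of >80 aa
while excluding truncations). A stop codon in the final position is
stripped rather than rejected. QC counters track survivors of each stage
(pairs in → merged → flank pass → in-frame → no stop → length pass);
N-codon rejection is folded into the in-frame counter.

## Annotation and subtyping

Regions are anchor-based, not fixed-position, because CDR length
variation shifts absolute coordinates. Anchors: canonical Cys1 is the
first cysteine in protein positions [15, 30); FR4 is the rightmost
occurrence of the motif `DGAGT` with ≤1 mismatch (rightmost, so a chance
motif inside a long CDR3 cannot pre-empt the true framework); canonical
Cys2 is the cysteine of the last `YYC` context before FR4 — the Tyr-Tyr
context distinguishes the framework cysteine from cysteines inside CDR3.
CDR3 is the open interval between Cys2 and FR4; CDR1 and the inner
framework blocks follow Cys1 at fixed offsets (CDR1 6, FR2 8, HV2 6,
FR3a 10, HV4 5 residues). Proteins violating the architecture are
reported unannotatable with a reason rather than force-fitted.

Subtype calls use only the non-canonical cysteine counts per region and
the CDR1 conservation motif (default: a tryptophan in CDR1):

| subtype | rule |
|---|---|
| I | FR2 ≥1 and FR4 ≥1, CDR3 ≥2 and even |
| II | CDR1 ≥1 and CDR3 ≥1, FR2 = FR4 = 0, motif absent |
| III | as II, motif present |
| IV | no non-canonical cysteines |
| unclassified | anything else, incl. odd CDR3 counts with FR2/FR4 cysteines, or a missing canonical pair |

The table is exhaustive and mutually exclusive (proven by enumeration in
the tests). Odd CDR3 cysteine counts alongside FR2/FR4 cysteines are
left unclassified rather than forced into Type I, because Type I is
defined by *paired* CDR3 cysteines.

CDR3-length statistics use type-6 quantiles (linear interpolation at
h = (n+1)p, the midpoint-exclusive convention; e.g. lengths
[10, 12, 14, 16, 18] give Q1 = 11, Q3 = 17). Whiskers are Q1 − 1.5·IQR
and Q3 + 1.5·IQR clamped to the most extreme observed values inside the
fences; observations beyond the fences are the outliers.

## Clonotyping and mining

Sequence "homology" is implemented as percent identity (no substitution
matrix is involved anywhere). Equal lengths: Hamming identity. Unequal
lengths: a global alignment with match = 1, mismatch = gap = 0 —
equivalently the longest common subsequence — normalized by the longer
length; this conservative, parameter-free rule is only exercised outside
the equal-length mining path. All thresholds are strict (identity must
exceed 85/90/95), so a threshold of 100 isolates every sequence.
Threshold comparisons are done in integer arithmetic
(100·matches > t·length) to avoid float boundary artifacts.

Clonotypes and clades are single-linkage connected components of the
identity graph (complete linkage is available as an option); clades are
*defined* by components, not by cutting the reporting tree. Cluster
representatives are the highest-count member, ties broken by
lexicographic sequence then id — every downstream "top" selection in the
package uses this same deterministic tie-break, so identical inputs give
byte-identical outputs.

Differential mining takes, per library, the top 2000 most prevalent
records of one CDR3 length (per-library, not pooled, selection), pools
them with library labels, clusters at >85%, flags clades with zero
control members as target-unique, and keeps those with ≥30 unique
sequences (inclusive at 30). Candidates are ranked by their
representative's prevalence. Mining is restricted to equal-length CDR3s
to keep the identity measure unambiguous; lengths 14 and 12 are the
shipped defaults.

Report trees are UPGMA (scipy average linkage) on 1 − identity/100, with
Newick output in a canonical sibling order (lexicographically smallest
descendant leaf first) so serializations are reproducible. Equivalence
with a naive agglomerative implementation is tested on a tie-free
instance constructed from Sidon-set block sequences (all pairwise
distances distinct); under tied distances the merge order, like any
UPGMA implementation's, is tie-break-dependent.

## Correlation statistics

Pearson r (scipy) on optionally log10-transformed axes; r² alongside.
Because the appropriate axis scaling for prevalence-vs-affinity
comparisons is a judgment call, the raw-vs-log10(KD) variant is primary
and raw-raw / log-log are always emitted. No p-values are attached.
Zero-variance inputs and non-positive values under a log are errors, not
NaNs.

## Synthetic repertoire generator

The generator is first-class code: it defines the study conditions under
which the pipeline is validated.

* **Scaffold.** A fixed synthetic nurse-shark-like germline framework
  (FR1 ends in the canonical Cys1, FR3b ends in `...YYC`, FR4 starts with
  `DGAGT`) with randomized CDR1 (6 aa) and CDR3. Subtype-defining
  cysteines (and the Type III CDR1 tryptophan) are placed at fixed
  scaffold positions per the rule table, so the classifier provably
  recovers the label on clean sequences.
* **Randomization alphabets.** Randomized positions exclude C and W
  (subtype-defining) and, in CDR3, Y (which could complete a spurious
  `YYC` anchor). Lineage point mutations substitute from the 17-letter
  alphabet excluding C/W/Y and avoid the anchor residues; every variant
  is re-annotated and must reproduce the seed's CDR3 interval and
  subtype, being resampled otherwise, so the truth manifest is always
  consistent with the sequences. Non-seed variants carry at least one
  substitution: variants must be distinct sequences for the manifest's
  per-variant counts to be recoverable after dereplication.
* **Abundance.** Variant read counts are truncated-Zipf on {1..10⁴}; the
  exponent is solved (Brent) so the singleton probability equals the
  configured 0.90, matching the ~90% singleton fraction and ~99.5%
  below-10-reads fraction characteristic of a richly diverse immunized
  library. A small number of lineages (15% of background) are clonally
  expanded into 2–8 point-mutation variants.
* **CDR3 lengths.** Uniform on 5–25 aa with 0.3% tail mass on 81–90 aa.
  The uniform band places the Tukey whiskers at exactly 5 and 25 aa and
  the ultralong tail reproduces the rare "stalk-and-knob"-like outliers.
* **Subtype mix.** I/II/III/IV = 0.15/0.55/0.15/0.15 — Type II dominant,
  as observed in immunized nurse-shark repertoires.
* **Library pair.** 2000 background lineages per library (independent
  between libraries), 4 target-specific expanded lineages (40 unique
  length-14 CDR3 variants each; seed count 4000 decaying as rank⁻¹·¹,
  ≈5×10⁴ reads/library in total), and 4 shared lineages present in both
  libraries (≈0.15% sequence sharing, below the <0.2% regime in which
  differential mining is informative). Planted CDR3 mutations are capped
  so every variant stays >85% identical to its seed.
* **Reads.** Each counted molecule is reverse-translated once with
  uniform synonymous codon choice, flanked by the anchors, and emitted as
  a 2×300 bp pair with substitution errors at 10⁻³ nt⁻¹ (configurable;
  no indels) and constant Q30 qualities (a degrading-tail mode exists for
  trim tests). Amplicons too long to overlap by ≥15 nt are an error.

**What passing tests show, and what they do not.** Recovery of planted
clades and exact round-trips demonstrate that the pipeline's bookkeeping,
thresholds, and clustering do what they claim under the modeled
conditions. Real libraries additionally contain indel sequencing errors,
chimeric PCR products, position-dependent quality, codon-usage bias,
germline diversity beyond a single framework, and somatic indels in
CDRs — none of which the generator models. Results on synthetic data
therefore validate the algorithmic contract, not the biological error
robustness of any particular threshold choice.

## Determinism and problem sizes

A single seed is fanned out to per-stage seeds (CRC32 of the stage name
mixed into the seed, reduced mod 2³¹), and all stochastic components draw
from explicitly passed numpy generators; two runs with the same seed are
byte-identical, including gzip output (fixed mtime). Validation problem
sizes — ~5×10⁴ read pairs per library for round-trips, 10⁴ scaffolds for
classifier exactness, 10⁴ unique sequences for abundance calibration,
200 sequences for clustering-oracle comparisons, and exhaustive 2-letter
templates to length 12 for the merge oracle — were chosen as the
smallest scales at which the targeted statistics are stable.

## Known limitations

* Region offsets (CDR1/FR2/HV2/FR3a/HV4 lengths) are fixed scaffold
  constants; real repertoires with framework indels would need the
  offsets, windows, and motifs re-parameterized (they are module
  constants, not magic numbers).
* The `YYC` Cys2 context and `DGAGT` FR4 motif are properties of the
  synthetic germline; for a different species or library design both are
  configurable but must be chosen by the user.
* Unequal-length identity (LCS-based) is intentionally crude; mining
  avoids it by constraining to equal-length CDR3s.
* Single-linkage clades can chain in dense repertoires; the complete-
  linkage option is provided but the shipped thresholds were only
  validated for single linkage.
* The affinity panel emitted by the generator is synthetic (KD inversely
  proportional to prevalence with lognormal scatter) and exists to
  exercise the correlation code, not to claim any biological effect
  size.
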