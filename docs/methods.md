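# Methods

This note documents the models, conventions and numerical choices behind
`gtamp`, in the spirit of a methods appendix: what each stage assumes, which
parameters matter, and what the synthetic studies do and do not demonstrate.

## Fusion-read demultiplexing

A 454-style fusion read is `adapter + barcode + forward primer + insert`
(for the nifH construct shipped as constants: a 25 bp A adapter, a 10 bp
multiplex barcode and the 20 bp PolF primer). Routing is two-staged:

* **Barcode matching is exact.** The mismatch budget applies to the primer
  only; barcodes are short and designed to be mutually distant, so a single
  error is better treated as unassignable than guessed.
* **Primer matching** allows up to `max_primer_mismatch` (default 2)
  mismatches under IUPAC set semantics at the expected offset.

Assigned reads are trimmed to the insert; when a distal (reverse) primer is
configured, its reverse complement is sought in the read tail and trimmed
when found within the same budget — finding it is *not* required for
retention, because pyrosequencing reads frequently end before the distal
primer. Inserts shorter than `min_read_length` (default 300 bases) are
discarded but counted, so per-sample stage counts partition the input.
Quality scores are carried through trimming but never used for filtering:
the retention criteria are length and mismatch only.

The fully-empty layout (no adapter, zero-length barcode, no primer) is
accepted as a degenerate case and makes demultiplexing the identity on
already-trimmed reads, which keeps re-entrant pipelines safe.

## IUPAC degenerate-primer model

A degenerate primer denotes the pool of concrete oligos obtained by
substituting each code with its base set; degeneracy is the product of
per-position set sizes. Mismatch counting is *conservative set semantics*: a
site position matches iff its base set is a subset of the primer code set,
so an ambiguous reference base not fully covered by the primer counts as a
mismatch. For concrete sites this equals the minimum Hamming distance over
the expansion (property-tested against that brute force). No 3′-end
weighting is applied — coverage reports use raw mismatch counts. Binding-site
search scans every offset on the appropriate strand (reverse primers bind as
their reverse complement on the sense strand); the best site is the minimum
mismatch count with ties to the leftmost offset. Tier sets are nested by
construction. References shorter than the primer are excluded and logged.

Primer design back-translates each gap-free window of aligned residue
columns into per-column codon sets under the standard genetic code and
collapses them column-wise into the minimal covering IUPAC string. The
minimal cover may admit extra codons (that is inherent to IUPAC notation);
candidates are filtered by a degeneracy ceiling. Windows of any length ≥1
are accepted; in practice a window below ~5 residues is too short for a
usable primer and the ceiling does the real filtering.

## Frameshift-correcting alignment

The aligner is a local dynamic program of a DNA read against a protein
reference with three consumption widths per reference residue:

| op | bases | meaning | score |
|----|-------|---------|-------|
| codon | 3 | ordinary translation | BLOSUM62(aa, ref) |
| deletion-type frameshift | 2 | one base lost | best completion − penalty |
| insertion-type frameshift | 4 | one base gained | best 3-of-4 − penalty |
| reference gap | 0 | residue missing from read | affine |
| read codon insertion | 3 | residue extra in read | affine |

Defaults: BLOSUM62, gap open 11, gap extend 1 (a gap of length L costs
`11 + L`), frameshift penalty 12 per event — costlier than extending a gap,
cheaper than opening two. A frameshift's missing base is resolved over all
four bases at all three codon positions (deletion-type) or by dropping each
of the four bases (insertion-type), taking the best substitution score;
in-frame stop codons score the matrix minimum and emit `X` rather than
terminating, since sequencing errors create spurious stops. Alignment is
local: unaligned read ends are free, which also means an indel inside the
terminal codon is absorbed as end-trimming rather than called — a
fundamental identifiability limit, not a defect.

Identity is reported over the reference-residue columns of the optimal path
(substitution columns plus reference residues aligned against gaps); the
default filters keep reads longer than 100 residues (strict) with
identity ≥ 0.30. On frameshift-free reads the DP reduces exactly to local
protein–protein alignment of the translation (tested against Biopython's
aligner), and on small instances its score equals an exhaustive
single/double-indel repair oracle.

**De-novo refinement.** Frameshift *placement* is guided by the reference,
so it grows ambiguous as the nearest reference diverges: against a ~70 %
identical template, the score-optimal path occasionally resolves an indel a
codon away from the truth, substituting one or two residues. Following the
de novo mode of published frameshift correctors, `correct_reads(...,
denovo=True)` recruits frameshift-free corrected proteins observed at least
twice (abundance screening keeps one-off aberrant corrections out of the
pool) as additional templates and re-corrects reads whose nearest-reference
identity fell below 0.9; the pass iterates (default twice) so templates
recovered in round one serve reads in round two. Reported `nearest_ref` and
`identity` always refer to the real reference set — refinement only improves
the corrected protein and the frameshift count.

Reads are compared against all references (no k-mer prefilter) — adequate at
study scale; a prefilter hook would slot into `_best_against`, which already
separates the cheap score scan (numba-compiled when available, pure numpy
otherwise) from the traceback.

## Distances, clustering, trees

Aligned-protein dissimilarity uses **pairwise deletion**: differing over
comparable (both non-gap) positions, with distance 1 for pairs sharing no
comparable column. This is robust to the ragged coverage of amplicon reads;
the cost is that the denominator varies by pair.

Complete-linkage agglomeration merges while the furthest-neighbor linkage is
≤ the cutoff, guaranteeing (and asserting) max intra-cluster distance ≤
cutoff. Determinism under ties: ids are taken in lexicographic order and the
first minimal entry in row-major order is merged, i.e. the pair whose
smaller member sorts earliest. The partition is property-tested against a
naive O(n³) oracle on random matrices. The cutoff sweep reuses one
agglomeration (complete-linkage merge heights are monotone) and defines the
inflection as the cutoff maximizing the discrete second difference of the
OTU-count curve, ties to the smallest cutoff; for a degenerate flat curve
this lands on the first interior cutoff. Sweep subsampling is without
replacement and seeded.

Representatives are medoids (minimum mean distance to co-members, ties to
the smallest id). Novel flagging is exact set intersection with the supplied
reference ids. Neighbor joining is the standard agglomeration with negative
branch lengths clamped to zero (clamps logged); it reconstructs additive
matrices exactly, which is the test oracle.

Reference-guided projection (`align_to_reference`) replaces profile-HMM
alignment: each query is locally aligned to its best-scoring reference and
its residues are placed at that reference's master-alignment columns;
residues falling in insertions relative to the master are dropped and
uncovered columns become gaps. An optional coverage floor can mask sparse
columns. This preserves the "align, then trim to model columns" behavior
with no external binary; its known bias is that query-specific insertions
are invisible downstream.

## Conservation and motifs

Conservation is the modal-residue frequency per column over non-gap
residues (gaps excluded from the denominator so ragged coverage does not
dilute conservation); the consensus letter requires the modal frequency to
reach the threshold, default 0.95, else `x`. Modal ties go to the
alphabetically first residue. The motif grammar supports residue literals,
`X` (any residue), `[KR]` alternation and `{m,n}` repetition of the
preceding token; repetition is greedy (longest first, with backtracking) and
hits are leftmost non-overlapping, compiled to a regular expression after
validation with position-carrying errors. Prevalence is sequence-level
(fraction of sequences with ≥1 hit); column-level conservation is available
from the profile when the other reading is wanted.

## Community statistics

Supervised binning assigns each read to (nearest-reference genus, identity
sub-bin) with bins (0.90,1], (0.75,0.90], (0.50,0.75], [0,0.50] — upper
edges strict, so a read exactly 90 % similar falls in 75–90. Unsupervised
binning counts cluster members per sample and borrows the representative's
nearest-reference genus and sub-bin (a representative that is itself a
reference gets its own genus in the top bin). Reads lacking a nearest
reference are routed to an explicit `unassigned` OTU, never dropped.

Rarefaction subsamples each sample without replacement to a common depth
(default the minimum sample total) via seeded multivariate hypergeometric
draws, then removes empty OTUs; the analytic curve
`E[S_d] = Σ_i (1 − C(N−N_i,d)/C(N,d))` is computed in log-gamma space and
matches Monte-Carlo subsampling within 3 standard errors in the tests.
Richness uses bias-corrected Chao1, `S_obs + F1(F1−1)/(2(F2+1))` — chosen
because it is the standard nonparametric estimator from singleton/doubleton
counts; other estimators would give different absolute values, so the choice
is flagged here deliberately. Ordination is PCA (exact SVD) of
column-centred Hellinger-transformed counts; axis orientation is fixed by
making each axis's largest-magnitude loading positive. Per-OTU tests are
one-way F-tests on relative abundances (counts/depth, i.e. post-rarefaction
when used as intended) with Benjamini–Hochberg adjustment; OTUs identical
across all samples report F=0, p=1; groups with fewer than two samples are
excluded from the design (logged) and at least two replicated groups are
required. F-tests on near-constant low-count data are unreliable — rarefy to
a reasonable depth (or filter rare OTUs) before testing.

## Synthetic-data generator

The generator emulates the statistical structure of gene-targeted 454
studies with controlled, identifiable truth:

* **Families.** A random 120-residue root; each family ancestor receives
  exactly `round(L·between/2)` substitutions from the root and each member
  exactly `round(L·within/2)` from its ancestor. Exact counts (rather than
  per-site Bernoulli draws) bound the within-family diameter, so
  complete-linkage recovery at a stated cutoff is a well-posed target.
  Defaults: within 0.03, between 0.30 — species-like clusters inside
  well-separated gene families. DNA is back-translated with uniformly random
  synonymous codons; taxonomy labels one genus per family.
* **Reads.** `adapter + barcode + primer variant + insert`; primer variants
  are pool members with exactly the planted number of set-semantics
  mismatches; inserts are member DNA with Poisson(`frameshift_rate`,
  default 1.0 per read — in the range reported for soil denitrifier
  amplicons) single-base indels. Indel placement enforces identifiability of
  the planted truth: at least 9 bases from either end (a terminal-codon
  indel is indistinguishable from local end-trimming) and at least 45 bases
  apart (an insertion/deletion pair a few codons apart restores the frame
  locally, so a score-optimal corrector rightly reads through it and the
  "true" count of such a read is undefined). Constant quality 30 — quality
  models are out of scope, and no stage consumes qualities.
* **Communities.** Log-normal base abundances shared across samples,
  per-sample multiplicative log-normal noise (σ = 0.5, a realistic
  replicate-level coefficient of variation for soil communities), group
  effects multiplying designated OTUs in treatment samples, rows normalized
  to 1.

What passing the planted studies shows: the pipeline stages compose
correctly and recover controlled truth. What it does not show: behavior
under chimeras, multi-base indels, quality-correlated errors, compositional
biases of real PCR, or reference databases with phylogenetic structure —
real data keep all of those.

## Validation layout

Each operation is tested against an independent oracle where one exists:
naive agglomeration for complete linkage, min-Hamming over the expansion for
degenerate mismatches, exhaustive single/double-indel repair (on 40- and
8-residue toys, where enumeration is tractable) for the frameshift DP,
additive-matrix reconstruction for NJ, Monte-Carlo subsampling for the
analytic rarefaction curve, and closed-form F (the planted 0.1-vs-0.5,
sd 0.05, n=3/group configuration gives F = 96) for the test layer. The
planted end-to-end study (3 reference + 2 novel families, 2 samples × 40
reads, indel rate 1.0) is run over 20 seeds; these sizes keep the full suite
under a couple of minutes on one CPU while leaving every assertion at full
strength.

## Known limitations

* Frameshift resolution is reference-guided; without the de-novo pass,
  reads ~30 % divergent from every reference can carry one or two
  misresolved residues per indel.
* The projection alignment discards query insertions relative to the master
  columns; genuinely novel insertions are invisible to the distance stage.
* Chao1 is one of several defensible richness estimators; absolute
  "estimated" richness depends on that choice.
* The F-test layer assumes roughly normal within-group relative abundances;
  it is not a substitute for count-model differential abundance methods.
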