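# gtamp — gene-targeted amplicon processing

`gtamp` analyses amplicon sequencing of *ecofunctional genes* — genes that
directly encode an enzyme for a key ecological process, such as `nifH`
(nitrogen fixation), `nirK`/`nirS` (nitrite reduction in denitrification) and
the dioxin-degrading dioxygenases `dxnA1`/`dbfA1`/`carAa`. Unlike 16S rRNA
surveys, these genes are sampled with degenerate primers, sequenced as
barcoded fusion reads, and analysed in **protein space**, where residue
conservation reflects function. The package is for microbial ecologists who
want a tested, scriptable implementation of that workflow: demultiplexing and
filtering, frameshift-corrected translation, OTU clustering with
novel-cluster discovery, degenerate-primer coverage audits, conservation and
motif profiling, and community statistics comparing supervised (closest
match) with unsupervised (clustering) binning.

## The methods at the core

**Frameshift-correcting translation.** Pyrosequencing homopolymer errors
insert or delete single bases, wrecking naive translation. A DNA read is
aligned locally against a protein reference by dynamic programming in which a
reference residue may be consumed by 3 bases (scored with BLOSUM62), by 2 or
4 bases (a frameshift event, penalty 12, with the missing/extra base resolved
to the best-scoring codon), or skipped via affine gaps (open 11, extend 1).
The corrected protein is the translation along the optimal path; identity is
`matches / reference-residue columns`. Reads are kept when longer than 100
residues with ≥30 % identity to the nearest reference. A de-novo refinement
pass recruits abundant frameshift-free corrected proteins as extra templates,
which pins down frameshift placement for reads far from any reference.

**Protein-space OTUs.** Pairwise dissimilarity between aligned proteins is
`d(a,b) = #differing / #comparable` positions (pairwise gap deletion).
Complete-linkage (furthest-neighbor) agglomeration merges clusters while the
linkage ≤ the cutoff, so every OTU satisfies max intra-cluster distance ≤
cutoff. A cutoff sweep from 0 to 30 % locates the inflection (maximum
discrete second difference of the OTU-count curve) separating intra- from
inter-species homology; 5 % dissimilarity approximates species level.
Clusters containing no reference sequence are flagged *novel* — the discovery
signal of gene-targeted sequencing. Medoid representatives feed a native
neighbor-joining tree writer.

**Degenerate primers.** A primer over the IUPAC alphabet denotes a pool of
concrete oligos (degeneracy = product of per-position set sizes; e.g. PolF
`TGC GAY CCS AAR GCB GAC TC` → 2·2·2·3 = 24). A reference position matches a
primer position iff its base set ⊆ the primer's code set; coverage reports
count, per mismatch tier t ∈ {0,1,2}, the references whose best binding site
has ≤ t mismatches, rolled up by phylum/class/genus. Primers can also be
designed from conserved amino-acid windows by back-translation to the minimal
covering IUPAC string.

**Community statistics.** Reads are binned either by nearest-reference genus
with identity sub-bins (>90 %, 75–90 %, 50–75 %, <50 % similar to closest
match) or by de-novo clusters. Tables are rarefied to equal depth
(`E[S_d] = Σ_i (1 − C(N−N_i,d)/C(N,d))` gives the analytic curve), richness
is estimated with bias-corrected Chao1 `S_obs + F1(F1−1)/(2(F2+1))`, samples
are ordinated by PCA of Hellinger-transformed counts (√ relative abundance),
and per-OTU one-way F-tests across treatments are corrected by
Benjamini–Hochberg FDR.

**Synthetic studies.** `gtamp.simulate` generates the whole structure the
pipeline assumes — reference families at controlled within/between
divergence, barcoded fusion reads with planted single-base indels and
primer-site mismatch tiers, and multi-sample abundance profiles with group
effects — deterministically under a seed, so every stage is testable against
planted truth.

## Worked example

`examples/otu_clustering.py` runs the planted end-to-end study: five
sequence families (within-family divergence 3 %, between 30 %), two of them
withheld from the reference set, 80 fusion reads carrying ~1 indel each:

```
reads simulated      : 80
reads passing filters: 80
OTUs at 5% cutoff    : 5
novel clusters       : 2
indel-count recovery : 100.0% of 70 reads
cutoff sweep inflection: 4% (within-species collapse gives way to between-family structure)
```

The five planted families come back as exactly five OTUs; the two families
without references are flagged novel; every planted indel count is recovered;
and the cutoff sweep's inflection sits just above the planted within-family
divergence, where tight clusters stop collapsing into each other.

`examples/community_comparison.py` shows the statistics layer (numbers
printed by the script):

```
supervised OTUs (genus x identity bin): 16
rarefied to 404 reads per sample; 16 OTUs retained
PC1/PC2 variance explained: 82.7% / 7.2%
OTUs with raw p<0.05: 7; BH-significant: 3
```

The three significant OTUs are the identity sub-bins of the genus whose
abundance was planted to differ between treatments.

The other examples cover demultiplexing (`demultiplex_reads.py`), primer
coverage tiers (`primer_coverage.py`), single-read frameshift repair
(`frameshift_correction.py`) and conservation/motif profiling
(`conservation_motifs.py`). A thin CLI mirrors the library:
`gtamp demux|primer-coverage|framecorrect|cluster|sweep|njtree|conserve|rarefy|diversity|ordinate|test|simulate`.

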