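# Methods

## Relative quantitation and trajectory classification

Spectral counts from label-free LC-MS are converted to *relative amounts*
per sample: `scale × count / count_albumin`, with `scale = 100` by default.
Albumin is used as the reference because its plasma level is essentially
pregnancy-invariant; the constant itself is arbitrary (it cancels in every
ratio), so it is configurable and only matters for synthetic runs.  A
sample whose albumin count is zero cannot be normalised and is flagged
invalid rather than silently dropped.

Trimester summaries are arithmetic means over the samples available in the
trimester; a missing cell (e.g. the marmoset subject whose third-trimester
sample does not exist because of a premature birth) reduces `n`, it is not
a zero.  "Undetectable" means exactly 0 after normalisation — spectral
counting produces hard zeros below the detection limit.  Fold ratios
`m2/m1` and `m3/m1` are computed from full-precision means and additionally
reported rounded to two decimals (the print convention); they are undefined
for an undetectable baseline, which is reported as a sentinel flag.

The trajectory classifier is a pure function of `(m1, m2, m3)`:

* category 1 (increase): `m1 > 0` and `max(m2, m3)/m1 > 2`, or `m1 = 0`
  and `max(m2, m3) ≥ 1`; sub-label `1a` if `m2` is the maximum of the three
  means, else `1b`;
* category 2 (decrease): `m1 > 0` and `min(m2, m3)/m1 < 0.5` (a later zero
  qualifies); `2a` if `m2` is the minimum, else `2b`;
* otherwise `unchanged`.

Both thresholds are strict inequalities; exactly doubling or exactly
halving is `unchanged`.  A protein satisfying both clauses (e.g. up
three-fold then to zero) is assigned by testing the increase clause first —
the order the rules are stated in.  Every call records a rule trace naming
the clause that fired.

t-tests are two-sample, two-tailed; Welch by default (the equal-variance
variant is selectable, since the spreadsheet tool originally used for these
tables does not record which variant produced its p-values — printed
p-values are therefore not expected to reproduce exactly and are not part
of any golden check).  PCA follows chemometrics conventions: samples are
observations, proteins variables; columns are mean-centred and by default
scaled to unit variance; scores/loadings come from the SVD of the processed
matrix, with at most `min(n_samples − 1, n_proteins)` components, a
deterministic sign convention (largest-magnitude loading positive), and
constant columns carrying zero weight.

### Golden data and its print precision

The packaged per-sample serum tables (26 human and 24 marmoset proteins)
are entered once from print at two-decimal precision.  Each printed sample
value therefore carries ±0.005 of rounding error, and a ratio of trimester
means recomputed from them is only constrained to the interval
`[(mт − 0.005)/(m1 + 0.005), (mт + 0.005)/(m1 − 0.005)]` (±0.005 on the
printed ratio itself).  The golden tests assert the printed ratio columns
fall inside that interval — 71 of the 80 defined ratios match to two
decimals outright — rather than demanding exact equality that rounded
inputs cannot guarantee.  One source-table row (inter-alpha-trypsin
inhibitor heavy chain H3, means 1.40/0.68/2.59) is printed in the `2b`
block although its minimum falls in the second trimester, which the stated
legend assigns to `2a`; the classifier follows the legend, and the golden
block-membership test documents this single discrepancy by failing on it.

## Bait-region partition and identity

Coordinates are 1-based inclusive throughout; regions are
I = `[1, bait_start−1]`, II = `[bait_start, bait_end]`,
III = `[bait_end+1, L]`.  Exact bait coordinates were never published per
sequence, so the shipped configuration carries the partition in the
pairwise human–marmoset *alignment frame*, chosen to reproduce the
published region-length denominators: protein 682/56/753 (PZP, L = 1491)
and 542/44/724 (A2ML1, L = 1310); nucleotide bait windows are
codon-consistent (168 = 3×56, 132 = 3×44).  Length fractions are reported
to one decimal with standard rounding (hence 3.4 % for the 44/1310 A2ML1
bait, where the source table prints 3.3).

Pairwise global alignment uses BLOSUM62 with affine gaps (open −11,
extend −1) for proteins and match/mismatch 2/−3 (open −5, extend −2) for
nucleotides; IUPAC ambiguity codes are accepted and can only score as
mismatches; of co-optimal alignments the aligner's first (deterministic)
traceback is taken.  Per-region identity assigns each alignment column to
the region of its reference coordinate (insertions against the reference
sit with the region they precede).  The default denominator is the region
length in reference residues, the convention of the published homology
table (e.g. 34/56); `aligned-columns` is available and makes identity
symmetric in the two sequences.  This global-alignment surrogate replaces
the original local-alignment tool, so small deviations from published
percentages on real accessions are expected and documented.  Multi-taxon
input uses a deliberately lightweight progressive alignment (pairwise
against the running consensus, guide order = input order), adequate for the
closely related ortholog sets analysed here but not a substitute for a full
MSA program.

## Cleavage rule engine

Rules are data (packaged YAML), one entry per protease, each a set of
positive clauses, exception clauses and override clauses over the six slots
P4…P2′; the engine fires at P1 position *i* (1-based, cut after residue
*i*) iff an override matches, or a positive clause matches and no exception
does.  Cleavage never crosses a terminus (both P1 and P1′ must exist);
ambiguous residues (X/B/Z/U/J/O) never satisfy a required set and never
trigger an exception.  The encoded specificities follow the public
documentation of the standard in-silico digestion tool (Keil-style rules),
including trypsin's higher-order exception triplets and the
proline-context exceptions of pepsin; the high-specificity chymotrypsin
and pH > 2 pepsin variants are the defaults of the 13-enzyme panel, with
the low-specificity/pH 1.3 variants shipped but off by default.
Accessibility is computed on the full-length sequence and then intersected
with the bait window (so edge residues see their true flanking context); a
protein's cell is `+` iff at least one site's P1 lies in region II, and the
per-cell site counts are retained.  Because the rule tables are data,
any discrepancy against the reference tool is auditable and fixable without
code changes.

## Distances, trees, bootstrap

p-distance is the mismatch fraction over pairwise-complete columns
(pairwise gap deletion — complete deletion would discard most of a short
bait sub-alignment); the Poisson correction `−ln(1−p)` is the default for
proteins, with `p ≥ 1` raising an explicit infinite-distance error naming
the pair.  Neighbor joining is the Saitou–Nei algorithm with two
deterministic conventions: Q-criterion ties break on the lexicographically
smallest pair of cluster labels (a cluster is labelled by its smallest
leaf), and a negative branch-length estimate is clamped to zero with the
deficit moved to the sibling edge, preserving their sum.  On additive
matrices these conventions are inert and the generating tree is recovered
exactly.  Bootstrap supports resample alignment columns with replacement
(`numpy` Generator seeded by the caller); the resampling stream depends
only on seed and alignment length, and taxa are processed in sorted label
order, so supports are invariant to input order.  The whole-vs-bait report
computes both distance matrices and the per-pair ratio bait/whole, guarded
(absent) when the whole-sequence distance is zero or the bait window is
all-gap for the pair.

## SNP densities

Variants arrive pre-annotated (position, consequence, MAF) in an explicit
coordinate basis (protein residues or mRNA nucleotides); the default screen
keeps MAF ≥ 1 %.  Densities are `100 × count/length` per region, with
duplicate positions counted once by default (toggleable).  The published
density figures are not reproducible from the published counts and lengths
under any single denominator convention, so the report always emits counts,
lengths and basis alongside the percentages, plus two explicit enrichment
ratios (bait vs whole and bait vs flank) so any convention can be audited.

## Synthetic data

`gen_abundance` plants trajectory categories via trimester fold profiles
(1a: 1/5/2.5, 1b: 1/2/5, 2a: 1/0.25/0.5, 2b: 1/0.5/0.25, unchanged: 1/1/1 —
clearing the 2× and 0.5× rules with a margin comparable to the printed
tables), multiplies by lognormal noise (σ = 0.3 by default, the standard
multiplicative model for spectral counts), rounds to integer counts against
a constant albumin channel of 480, and zeroes relative amounts below a
detection limit of 0.5, which also creates the
undetectable-baseline/second-trimester-surge pattern for a configurable
fraction of category-1 proteins.  `gen_homolog_pair` substitutes amino
acids per residue with probability `r_out` (default 0.05) outside and
`r_bait` (default 0.4) inside a 56-residue bait window of a 1491-residue
protein — the published pair's geometry — re-encoding codons so the emitted
protein is always the translation of the emitted CDS, and records true
per-region mismatch counts; optional codon deletions model indels.
`gen_snps` places variants independently per position at `base_rate`
(default 0.01) outside and `base_rate × enrichment` (default 3×) inside the
bait window, with a configurable missense fraction and MAFs straddling the
1 % filter threshold.  Every generator is a pure function of config + seed.

What the simulators do **not** emulate: peptide-level MS noise and shared
peptides, alignment uncertainty (indel-free pairs by default), linkage or
selection structure in variants, and real phylogenetic correlation among
taxa.  Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not performance on real data.

## Problem sizes and tolerances

The recovery experiments run at the geometry of the published comparison:
trajectory recovery on 200 planted proteins × 10 seeds (pass ≥ 90 %);
bait-vs-flank identity ordering on 100 seeds at `r_out = 0.05`,
`r_bait = 0.4` (pass ≥ 95/100); SNP enrichment 3× recovered as the mean
bait/flank density ratio over 200 seeds within 10 %; neighbor joining on 50
random additive matrices of 4–10 taxa (exact recovery); bootstrap with
100–500 replicates.  Numerical tie-breaks and degenerate inputs (empty
sequences, all-gap windows, constant matrices, zero-variance groups) have
defined behaviour described above and are covered by tests.

## Known limitations

* Checks against the real NCBI accession sequences (whole-protein ~90 %
  identity, 34/56 bait identity, the 13 × 4 accessibility matrix,
  whole ~0.04 vs bait ~0.26 distances) need those sequences downloaded;
  this repository ships no third-party sequence data, so those comparisons
  run only when a user supplies the FASTA files.
* The progressive aligner is a consensus-based approximation; for deep or
  gappy ortholog sets use an external MSA and feed the alignment in.
* Printed p-values of the source tables are not golden-tested (unknown
  t-test variant; see above).
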