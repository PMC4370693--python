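# Methods

This note documents the models, parameter choices and numerical decisions
behind `linckit`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Identification pipeline

A transcript unit (TU) is a genome-mapped transcript with one or more
placements, each a list of exon blocks (internally 0-based half-open; GFF3
converts at the boundary, SNP positions stay 1-based). The filter chain and
its defaults:

| step | rule | default |
|---|---|---|
| map | every nucleotide aligned, 0 mismatches; all perfect placements kept | — |
| gene_nat | any 1-bp block overlap with a `gene` or `NAT` feature removes the TU, strand-agnostic | — |
| repeat | same, against `repeat` features | — |
| flank500 | overlap with gene intervals extended both sides | 500 nt |
| orf | remove if any six-frame stop-free codon run reaches the threshold; no start codon required; codons containing N are never stops but count toward length | 300 nt |
| length | keep length ≥ threshold (strict "less than" discards) | 200 nt |
| screens | four pluggable homology/coding screens | see below |
| cluster | greedy longest-first clustering, representative = longest | 95% identity |

Multi-placement TUs are counted once in sequence-level filters and checked
at every locus in interval filters; removal at any locus removes the TU
(the conservative reading of "overlapping TUs were discarded").

**Screens.** External database searches (protein databases,
coding-potential classifiers, nucleotide databases, structural-RNA
catalogues) are abstracted behind one interface. The built-in screen flags
a TU iff it shares an exact k-mer with a library sequence — nucleotide
k = 30 (forward or reverse complement) for nucleotide screens, peptide
k = 10 on six-frame translations for protein screens. A supplied external
hit table (e.g. from a real BLAST run with an E-value cutoff) replaces the
built-in screen verbatim. At toy scale a chance 30-mer collision has
probability < 10⁻⁹, so the screens are deterministic in practice.

**Cluster identity** is 1 − edits/len(shorter) of the end-gap-free (infix)
alignment of the shorter sequence inside the longer, computed with edlib
over both strands. This makes a 900-nt copy with 4% substitutions inside a
1000-nt original score 0.96 — the intended behavior for "redundant copy"
collapsing — whereas counting terminal gaps would dilute identity with the
length difference. Word-heuristic shortcuts of production clustering tools
are deliberately not reproduced.

**Chromosome distribution** is a Pearson chi-square goodness-of-fit of
per-chromosome lincRNA counts with k−1 degrees of freedom. Whether the
published analysis used an equal-per-chromosome or length-proportional
expectation is not recorded; `length_proportional` is the default and
`equal` is available. The published p-value cannot be recomputed without
the per-chromosome counts, which were only shown graphically.

## Expression

RPKM = count·10⁹/(library_size × length). The four expression classes
follow the boundary convention of the results narrative (low ≤ 5 <
moderate ≤ 10 < high ≤ 20 < very high); the methods narrative of the same
study states half-open-from-below intervals, and that variant is available
via `convention="methods"` (at exactly 5 the two texts contradict each
other; "methods" here reads 5 as moderate). τ is undefined (None) for an
all-zero profile rather than 0, so silent genes are never called
tissue-specific. KS p-values use the asymptotic distribution; exact
small-sample p-values are out of scope.

## miRNA target scoring

The scorer enumerates antisense alignments of each miRNA (18–26 nt)
against every lincRNA window: the ungapped alignment plus all single-gap
variants (a gap in either strand) at miRNA positions 3′ of `gap_after`
(default 17, max one gap). Penalties per miRNA position: Watson–Crick 0;
G:U(T) wobble; mismatch; gap — weighted by whether the position lies in the
essential region (positions 2–17). Scores are computed for all windows at
once via per-position penalty vectors (a few hundred vector adds per pair),
and the minimum-penalty alignment per (miRNA, lincRNA) with penalty ≤ 2.5
is reported. Both strand representations of the target are scanned, so the
result is invariant under strand representation; coordinates are always
reported on the given sequence, descending for antisense sites.

**Ledger calibration.** The exact penalty ledger behind the published
scores is not public, so the defaults were frozen by fitting candidate
ledgers to the 18 published cucumber miRNA–lincRNA alignments with printed
totals (`linckit.calibration`). The unique best ledger —

mismatch 1.0 / 0.5, wobble 0.5 / 0.3, gap 1.0 / 0.5 (essential / outside)

— reproduces 17 of 18 printed scores exactly, including every
perfect-complement row (0) and the near-perfect rows (1, 0.8). The one
discordant row (csa-miR162a/CU6NC2683, printed 2.2, scored 2.3) is the only
row with a 5′-terminal (position 1) wobble; no other row constrains that
feature, so it is unresolvable from the published data — either terminal
wobbles carry a special weight or the printed value is a typo. Note the
outside wobble weight is 0.3, not half of 0.5: the outside down-weighting
is per pair state, which is why the parameterization is a six-entry ledger
rather than a single outside multiplier. One published target line whose
characters were garbled in text extraction was reconstructed from perfect
complementarity (its row is all Watson–Crick with score 0).

## Co-expression network and annotation

Pairs are tested on the variance-filtered matrix (top 75% by variance,
ties broken by gene id). The p-value of Pearson's r is Fisher's asymptotic
test, p = 2(1 − Φ(|atanh r|·√(n−3))), Bonferroni-adjusted by the number of
tested pairs m. The 5% correlation tails are exactly ⌊0.05·m⌋ pairs per
tail computed over *all tested pairs* (not the p-surviving subset), with
deterministic tie-breaking, so the edge count can never exceed 10% of m.
Edges between two lincRNAs are retained but do not count toward hub status.

MCL runs on the unweighted adjacency with self-loops (standard practice):
column-normalize, then iterate expansion (matrix squaring) and inflation
(entry-wise power 2.0, renormalize, prune entries < 10⁻⁶) until the
column-wise change falls below 10⁻⁸ or 100 iterations (non-convergence
returns the current clustering with a warning). Modules are the connected
components of the converged matrix's support; a module is *reported* when
it has ≥ 10 protein-coding members and ≥ 1 lincRNA. The inflation constant
is not recorded in the study being reproduced; 2.0 is the conventional
default and is configurable.

GO enrichment is the hypergeometric upper tail P(X ≥ k) over the terms
observed in the query set, with Benjamini–Hochberg FDR (the study says
"FDR-corrected" without naming a method) at 0.05.

## Neutrality analysis

S counts columns with ≥ 2 distinct A/C/G/T after dropping gaps and N. π
and k̂ use pairwise deletion (sites missing in either member of a pair are
excluded for that pair), matching the quoted configuration of the original
analysis tooling; with complete data the implementation switches to an
exact per-column decomposition (k̂ = Σ_cols [C(n,2) − Σ_b C(c_b,2)]/C(n,2)),
which keeps 100-accession scans fast. D follows the standard constants
(a₁…e₂ from n); S = 0 yields a missing D.

**Significance.** p-values use the beta-distribution approximation of D's
null: D is rescaled between its attainable extremes Dmin = (2/n −
1/a₁)/√e₂ and Dmax = ((n+1)/2n − 1/a₁)/√e₂, compared against the beta law
with mean 0 and variance 1, two-tailed (p = 2·min(F, 1−F)). Calibration is
verified behaviorally: under a neutral coalescent null (msprime, n = 20,
E[S] = 10, 2000 non-recombining loci) the nominal 5% level rejects ≈ 3.5–4.5%
(`popgen.neutral_type_one_error`). The approximation is mildly
conservative, as expected.

**Empirical background interval.** The 95% interval of D over neutral
intergenic background loci uses linearly interpolated percentiles (2.5th /
97.5th); whether the original interval used linear or nearest-rank
percentiles is not recorded. Classification: p ≥ 0.05 →
purifying_or_neutral; p < 0.05 with D below / inside / above the interval →
positive / significant_within_ci / balancing.

## Synthetic data: what it emulates and what it does not

The generator (`linckit.simulate`) emulates the study conditions at desk
scale: 7 chromosomes (60 kb each — toy size), ten tissues, 102 accessions,
500 neutral intergenic background loci standing in for a genome-wide
background set, and a transcript population with one planted truth class
per pipeline step (30 clean lincRNAs, 10 each of coding-like,
repeat-overlap, flank-overlap, short, long-ORF, housekeeping-like, and 8
redundant copies). Counts are negative binomial (gamma–Poisson, dispersion
0.3) with baseline medians ~1.5 (lincRNA) vs ~25 (mRNA) counts so the
planted condition "lincRNAs express lower than mRNAs" is robust; planted
tissue-restricted genes are exactly single-tissue; planted correlated
pairs/modules share a per-tissue log-normal factor (σ = 1.2) with Poisson
noise at high counts, giving true |r| ≈ 0.99. All randomness derives from
one seed through named sub-streams; outputs are byte-identical across runs.

Not emulated: read-level noise, mapping ambiguity, assembly artifacts,
isoforms, genome-scale feature density, and — importantly — genealogical
correlation between segregating sites. Neutral loci draw each site's
derived-allele count independently with P(i) ∝ 1/i (the standard-coalescent
*expectation*), which reproduces the expected SFS shape but understates the
variance of D; the generator's neutral loci therefore have a narrower D
distribution than a true coalescent (the background interval above is
correspondingly narrower than a field value would be). That is why the
type-I calibration of `d_pvalue` is checked against a real coalescent
simulation rather than against the generator. Passing tests demonstrate
algorithmic correctness and planted-truth recovery, not performance on
real sequencing data.

## Problem sizes

Default test/acceptance scale: 98 transcripts on a 420 kb genome, 80 genes
in the expression matrix over 10 tissues, 102 accessions over ~530 loci,
2000 coalescent loci for calibration, 200-seed Monte-Carlo runs for the
network and SFS-sign checks. The full test suite runs in ~20 s and the
acceptance script in ~15 s on one CPU.
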