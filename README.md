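# linckit

A toolkit for discovering and analyzing **long intergenic noncoding RNAs
(lincRNAs)** — intergenic transcripts of at least 200 nt without
protein-coding potential — in a plant genome, written for researchers who
want a tested, reusable implementation of a complete lincRNA study:
identification from mapped transcript evidence, descriptive
characterization, expression and tissue-specificity analysis, miRNA
target/target-mimic scoring, co-expression-based function annotation, and a
population-genetic selection scan. A built-in synthetic-data generator with
planted ground truth makes every stage testable end-to-end without any
external downloads or binaries.

## What it computes

**Identification** (`linckit.identify`). Transcript units (TUs) pass an
ordered filter chain: perfect full-length genome mapping → removal of TUs
overlapping annotated genes or natural antisense transcripts → repeats →
500 bp gene flanks → six-frame ORF scan (remove if any stop-free codon run
reaches 300 nt) → length ≥ 200 nt → four pluggable homology/coding screens
(protein, coding-potential/nr-like, nt-like, structural/housekeeping RNA;
built-in exact k-mer screen or verbatim external hit tables) → greedy
redundancy clustering at 95% identity, keeping the longest sequence per
cluster. Every step is accounted in a `FilterReport` whose counts chain
exactly.

**Tissue specificity** (`linckit.expression`). RPKM = count·10⁹ /
(library size × length); the specificity index

&nbsp;&nbsp;&nbsp;&nbsp;τ = Σᵢ (1 − expᵢ/exp_max) / (n − 1)

is 0 for uniformly expressed genes and 1 for single-tissue genes; τ > 0.9
is called tissue-specific. Expression classes by peak RPKM: low ≤ 5 <
moderate ≤ 10 < high ≤ 20 < very high. LincRNA-vs-mRNA abundance is
compared per tissue with a two-sample Kolmogorov–Smirnov test.

**miRNA targets** (`linckit.mirna_target`). A miRNA is aligned antisense
against every lincRNA window; per-position penalties — mismatch 1.0, G:U
wobble 0.5, gap 1.0 inside the essential region (miRNA positions 2–17),
down-weighted to 0.5/0.3/0.5 outside; at most one gap, only 3′ of position
17 — are summed, and alignments with total penalty ≤ 2.5 are hits. The
ledger is frozen by calibration against 18 published cucumber
miRNA–lincRNA alignments with printed scores (`linckit.calibration`
reproduces 17/18 exactly; see `docs/methods.md`).

**Co-expression annotation** (`linckit.coexpression`). After keeping the
top 75% most variable genes, all pairs are tested (Pearson r, Fisher z
p-value, Bonferroni over tested pairs); edges require adjusted p < 0.05
*and* a correlation in the top or bottom 5% of all tested pairs. LincRNAs
are annotated hub-based (≥ 10 mRNA partners) and module-based (Markov
clustering; modules with ≥ 10 coding genes and ≥ 1 lincRNA), inheriting
hypergeometric GO enrichment of their partners at Benjamini–Hochberg FDR
0.05.

**Selection scan** (`linckit.popgen`). Accession SNPs applied to each locus
give a haplotype alignment; from it S (segregating sites, gaps/N excluded),
π (pairwise-deletion nucleotide diversity) and Tajima's

&nbsp;&nbsp;&nbsp;&nbsp;D = (k̂ − S/a₁) / √(e₁S + e₂S(S−1))

are computed; significance uses the beta-distribution approximation of D's
null, and each locus is classified against the empirical 95% interval of D
over neutral intergenic background loci: significant D below the interval →
positive selection, above → balancing selection.

## Worked example

```bash
python examples/01_identify_lincRNAs.py
```

```
step              in  removed   out
map               98        0    98
gene_nat          98        0    98
repeat            98       10    88
flank500          88       10    78
orf               78       10    68
length            68       10    58
protein           58       10    48
nr_like           48        0    48
nt_like           48        0    48
housekeeping      48       10    38
cluster           38        8    30

identified 30 lincRNAs; planted 30; recovered exactly: True
```

Each `removed` count equals the number of planted contaminants of the class
that step targets (10 repeat-overlappers at `repeat`, 10 long-ORF
transcripts at `orf`, 8 redundant copies at `cluster`, …), and the 30
survivors are exactly the planted lincRNAs — precision = recall = 1 on the
synthetic truth. The other examples print the expression/τ tables, rendered
miRNA alignments such as

```
mir-02-wobble x tx0024  penalty = 0.5
miRNA: 1     CATTTGGTTTGTGGATTTAAC 21
             ||||:||||||||||||||||
lincRNA: 155 GTAAGCCAAACACCTAAATTG 135
```

(a single essential-region G:U wobble, penalty 0.5), the co-expression
annotation of the planted module's lincRNA, and the selection scan, which
recovers the three planted rare-variant-excess loci as `positive`
(D ≈ −2.2) and the three intermediate-frequency loci as `balancing`
(D ≈ +3.9) against the 500-locus background interval (−1.49, 1.88).

A thin CLI mirrors the stages: `linckit simulate|identify|characterize|
express|targets|network|popgen --help`.

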