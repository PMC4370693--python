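"""Synthetic genomes, transcripts, expression, miRNAs and accession SNPs.

Every downstream stage of the pipeline is exercised on data generated here,
with planted ground truth: each generated transcript carries exactly one
truth label naming the pipeline step that should (or should not) remove it;
expression matrices carry planted tissue-restricted genes, correlated
lincRNA-mRNA pairs and co-expressed modules; miRNA libraries carry planted
target sites of designed penalty composition; and per-locus accession SNPs
carry a controlled site-frequency spectrum (rare-excess, intermediate-excess
or standard-coalescent neutral).

All randomness flows from ``SimulationConfig.seed`` through named
sub-streams, so a fixed seed reproduces every output byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, compute_rpkm
from .identify import STOP_CODONS, _translate, orf_scan, pair_identity, revcomp
from .io_formats import (
    AnnotationRecord,
    GenomeSequence,
    SnpRecord,
    TranscriptAlignment,
    write_alignments,
    write_expression_table,
    write_fasta,
    write_gff3,
    write_go_annotation,
    write_snp_table,
)

BASES = np.array(list("ACGT"))

TRUTH_CLASSES = [
    "lincRNA", "coding", "repeat_overlap", "flank_overlap",
    "short", "long_orf", "housekeeping_like", "redundant_copy",
]

SFS_SKEWS = ("rare-excess", "intermediate-excess", "neutral")

_NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


class SizingError(ValueError):
    """Requested features exceed chromosome capacity."""


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults mirror the study design being emulated where one is stated
    (seven chromosomes, ten tissues, 102 accessions, 500 neutral intergenic
    background loci); toy genome sizes keep everything desk-scale.
    """

    seed: int = 0
    n_chroms: int = 7
    chrom_length: int = 60_000
    n_genes: int = 50
    n_nats: int = 4
    n_repeats: int = 21
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "lincRNA": 30,
            "coding": 10,
            "repeat_overlap": 10,
            "flank_overlap": 10,
            "short": 10,
            "long_orf": 10,
            "housekeeping_like": 10,
            "redundant_copy": 8,
        }
    )
    flank: int = 500
    multi_exon_fraction: float = 0.12
    # expression
    n_tissues: int = 10
    nb_dispersion: float = 0.3
    library_background: float = 2_000_000.0
    n_specific: int = 6
    n_pos_pairs: int = 4
    n_neg_pairs: int = 2
    n_modules: int = 1
    module_size: int = 10
    # population genetics
    n_accessions: int = 102
    n_background_loci: int = 500
    neutral_snps_mean: float = 4.0
    skew_snps: int = 8
    n_rare_loci: int = 3
    n_intermediate_loci: int = 3
    # miRNAs
    mirna_length: int = 21

    def __post_init__(self) -> None:
        counts = [
            self.n_chroms, self.n_genes, self.n_nats, self.n_repeats,
            self.n_tissues, self.n_accessions, self.n_background_loci,
            *self.class_counts.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be nonnegative")
        unknown = set(self.class_counts) - set(TRUTH_CLASSES)
        if unknown:
            raise ValueError(f"unknown truth classes {sorted(unknown)}")


@dataclass
class Locus:
    """A reference locus (by id) on which accession SNPs are planted."""

    locus_id: str
    ref_seq: str
    skew: str = "neutral"  # rare-excess | intermediate-excess | neutral

    def __post_init__(self) -> None:
        if self.skew not in SFS_SKEWS:
            raise ValueError(f"unknown sfs skew {self.skew!r}")


@dataclass
class TranscriptSet:
    sequences: dict[str, str]
    alignments: list[TranscriptAlignment]
    truth_labels: dict[str, str]
    #: screen libraries: name -> [(subject_id, sequence)]
    libraries: dict[str, list[tuple[str, str]]]
    #: redundant-copy id -> source lincRNA id
    copy_sources: dict[str, str]
    #: transcript id -> evidence source tag (EST / hiseq / p454)
    tu_source: dict[str, str] = field(default_factory=dict)


@dataclass
class ExpressionBundle:
    counts: pd.DataFrame
    matrix: ExpressionMatrix
    gene_lengths: pd.Series
    planted_specific: list[str]
    planted_pairs: list[tuple[str, str, int]]  # (gene_a, gene_b, sign)
    planted_modules: list[dict]  # {"mrnas": [...], "linc": id, "go_term": str}
    go_annotation: dict[str, set[str]]


@dataclass
class MirnaSet:
    mirnas: list[GenomeSequence]
    sites: pd.DataFrame  # mirna_id, linc_id, kind, expected_score, start, end


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: list[GenomeSequence]
    annotation: list[AnnotationRecord]
    transcripts: TranscriptSet
    expression: ExpressionBundle
    mirnas: MirnaSet
    loci: list[Locus]
    snps: list[SnpRecord]
    accessions: list[str]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


# ---------------------------------------------------------------------------
# Genome


def generate_genome(
    config: SimulationConfig,
) -> tuple[list[GenomeSequence], list[AnnotationRecord]]:
    """Random chromosomes with non-overlapping gene/NAT/repeat features.

    Features are separated by gaps of at least 1,600 nt (> 2x the 500 nt
    flank width), guaranteeing plantable intergenic space.
    """
    rng = _rng(config, 1)
    specs: list[tuple[str, str]] = (
        [("gene", f"gene{i:04d}") for i in range(1, config.n_genes + 1)]
        + [("NAT", f"nat{i:03d}") for i in range(1, config.n_nats + 1)]
        + [("repeat", f"rep{i:03d}") for i in range(1, config.n_repeats + 1)]
    )
    order = rng.permutation(len(specs))
    per_chrom: list[list[tuple[str, str]]] = [[] for _ in range(config.n_chroms)]
    for k, idx in enumerate(order):
        per_chrom[k % config.n_chroms].append(specs[idx])

    length_ranges = {"gene": (600, 1500), "NAT": (400, 800), "repeat": (250, 600)}
    genomes: list[GenomeSequence] = []
    annotation: list[AnnotationRecord] = []
    for c in range(config.n_chroms):
        chrom_id = f"chr{c + 1}"
        seq = _random_seq(rng, config.chrom_length)
        pos = int(rng.integers(800, 1400))
        for feature_class, record_id in per_chrom[c]:
            lo, hi = length_ranges[feature_class]
            flen = int(rng.integers(lo, hi + 1))
            if pos + flen > config.chrom_length - 800:
                raise SizingError(
                    f"features exceed capacity of {chrom_id} "
                    f"(length {config.chrom_length})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            annotation.append(
                AnnotationRecord(chrom_id, pos, pos + flen, strand, feature_class, record_id)
            )
            pos += flen + int(rng.integers(1600, 2400))
        genomes.append(GenomeSequence(chrom_id, seq))
    return genomes, annotation


def _free_slots(
    genome: list[GenomeSequence],
    annotation: list[AnnotationRecord],
    config: SimulationConfig,
) -> dict[str, list[list[int]]]:
    """Intergenic intervals clear of gene flanks and repeat margins."""
    margin = {"gene": config.flank + 60, "NAT": config.flank + 60, "repeat": 160}
    slots: dict[str, list[list[int]]] = {}
    for g in genome:
        feats = sorted(
            (f for f in annotation if f.chrom_id == g.chrom_id),
            key=lambda f: f.start,
        )
        free: list[list[int]] = []
        cursor = 50
        for f in feats:
            left_end = f.start - margin[f.feature_class]
            if left_end - cursor >= 260:
                free.append([cursor, left_end])
            cursor = max(cursor, f.end + margin[f.feature_class])
        if len(g) - 50 - cursor >= 260:
            free.append([cursor, len(g) - 50])
        slots[g.chrom_id] = free
    return slots


class _SlotAllocator:
    """Round-robin first-fit allocator over per-chromosome free intervals."""

    def __init__(self, slots: dict[str, list[list[int]]]) -> None:
        self.chroms = sorted(slots)
        self.slots = slots
        self._next = 0

    def allocate(self, length: int) -> tuple[str, int]:
        for _ in range(len(self.chroms)):
            chrom = self.chroms[self._next % len(self.chroms)]
            self._next += 1
            for slot in self.slots[chrom]:
                if slot[1] - slot[0] >= length + 30:
                    start = slot[0]
                    slot[0] += length + 30
                    return chrom, start
        raise SizingError(f"no intergenic slot of length {length} left")


def _linc_like_seq(rng: np.random.Generator, lo: int = 220, hi: int = 650) -> str:
    """Random sequence with no >=300 nt stop-free stretch in any frame."""
    while True:
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if orf_scan(seq, 300)[1]:
            return seq


def _with_insert(rng: np.random.Generator, donor: str, k: int = 51) -> str:
    """Linc-like sequence carrying an exact k-mer copied from ``donor``."""
    while True:
        seq = _linc_like_seq(rng, lo=max(260, k + 60))
        off = int(rng.integers(0, len(donor) - k + 1))
        pos = int(rng.integers(20, len(seq) - k - 20))
        cand = seq[:pos] + donor[off : off + k] + seq[pos + k :]
        if orf_scan(cand, 300)[1]:
            return cand


# ---------------------------------------------------------------------------
# Transcripts


def generate_transcripts(
    genome: list[GenomeSequence],
    annotation: list[AnnotationRecord],
    config: SimulationConfig,
) -> TranscriptSet:
    """Plant one transcript population covering every truth class.

    The planted sequences are written into the chromosome sequences (the
    ``genome`` records are updated in place) so that every alignment is a
    perfect full-length placement.
    """
    rng = _rng(config, 2)
    chrom_seq = {g.chrom_id: bytearray(g.seq, "ascii") for g in genome}
    slots = _free_slots(genome, annotation, config)
    alloc = _SlotAllocator(slots)
    genes = [f for f in annotation if f.feature_class == "gene"]
    repeats = [f for f in annotation if f.feature_class == "repeat"]

    # screen libraries
    cds_library = [
        (f"cds{i:02d}", "".join(rng.choice(_NONSTOP_CODONS, size=180)))
        for i in range(1, 7)
    ]
    protein_library = [(cid, _translate(seq)) for cid, seq in cds_library]
    hk_library = [
        (f"rrna{i:02d}", _random_seq(rng, int(rng.integers(400, 1200))))
        for i in range(1, 5)
    ]
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    nr_library = [
        (f"nr{i:02d}", "".join(rng.choice(aa, size=200))) for i in range(1, 4)
    ]
    nt_library = [
        (f"organelle{i:02d}", _random_seq(rng, 500)) for i in range(1, 4)
    ]
    libraries = {
        "protein": protein_library,
        "nr_like": nr_library,
        "nt_like": nt_library,
        "housekeeping": hk_library,
    }

    sequences: dict[str, str] = {}
    alignments: list[TranscriptAlignment] = []
    truth_labels: dict[str, str] = {}
    copy_sources: dict[str, str] = {}
    sources = ("hiseq", "EST", "p454")

    def paste(tu_id: str, seq: str, chrom: str, start: int, blocks=None) -> None:
        if blocks is None:
            blocks = [(start, start + len(seq))]
            chrom_seq[chrom][start : start + len(seq)] = seq.encode()
        else:
            off = 0
            for bs, be in blocks:
                chrom_seq[chrom][bs:be] = seq[off : off + be - bs].encode()
                off += be - bs
        alignments.append(
            TranscriptAlignment(
                tu_id=tu_id,
                chrom_id=chrom,
                strand="+",
                blocks=blocks,
                matched=len(seq),
                mismatches=0,
            )
        )
        sequences[tu_id] = seq

    serial = 0

    def next_id(prefix: str) -> str:
        nonlocal serial
        serial += 1
        return f"{prefix}{serial:04d}"

    counts = config.class_counts
    linc_ids: list[str] = []

    # clean intergenic noncoding transcripts (some with two exons)
    for _ in range(counts.get("lincRNA", 0)):
        seq = _linc_like_seq(rng, lo=250)
        tu_id = next_id("tx")
        if rng.random() < config.multi_exon_fraction:
            intron = int(rng.integers(60, 200))
            cut = len(seq) // 2
            chrom, start = alloc.allocate(len(seq) + intron)
            blocks = [(start, start + cut), (start + cut + intron, start + intron + len(seq))]
            paste(tu_id, seq, chrom, start, blocks)
        else:
            chrom, start = alloc.allocate(len(seq))
            paste(tu_id, seq, chrom, start)
        truth_labels[tu_id] = "lincRNA"
        linc_ids.append(tu_id)

    # coding-like: shares an exact 51-mer with a planted reference CDS
    for _ in range(counts.get("coding", 0)):
        donor = cds_library[int(rng.integers(len(cds_library)))][1]
        seq = _with_insert(rng, donor)
        tu_id = next_id("tx")
        chrom, start = alloc.allocate(len(seq))
        paste(tu_id, seq, chrom, start)
        truth_labels[tu_id] = "coding"

    # housekeeping-like: shares a 51-mer with the housekeeping library
    for _ in range(counts.get("housekeeping_like", 0)):
        donor = hk_library[int(rng.integers(len(hk_library)))][1]
        seq = _with_insert(rng, donor)
        tu_id = next_id("tx")
        chrom, start = alloc.allocate(len(seq))
        paste(tu_id, seq, chrom, start)
        truth_labels[tu_id] = "housekeeping_like"

    # short transcripts (< 200 nt)
    for _ in range(counts.get("short", 0)):
        seq = _random_seq(rng, int(rng.integers(90, 200)))
        tu_id = next_id("tx")
        chrom, start = alloc.allocate(len(seq))
        paste(tu_id, seq, chrom, start)
        truth_labels[tu_id] = "short"

    # long-ORF transcripts (>= 300 nt stop-free stretch)
    for _ in range(counts.get("long_orf", 0)):
        head = _random_seq(rng, int(rng.integers(30, 90)))
        stretch = "".join(rng.choice(_NONSTOP_CODONS, size=int(rng.integers(110, 150))))
        tail = _random_seq(rng, int(rng.integers(30, 90)))
        seq = head + stretch + tail
        assert not orf_scan(seq, 300)[1]
        tu_id = next_id("tx")
        chrom, start = alloc.allocate(len(seq))
        paste(tu_id, seq, chrom, start)
        truth_labels[tu_id] = "long_orf"

    # gene-flank overlappers: entirely inside the 500 bp flank band
    flank_genes = list(rng.permutation(len(genes)))
    for j in range(counts.get("flank_overlap", 0)):
        gene = genes[flank_genes[j % len(genes)]]
        length = int(rng.integers(220, 380))
        start = gene.end + 60
        seq = _linc_like_seq(rng, lo=length, hi=length)
        tu_id = next_id("tx")
        paste(tu_id, seq, gene.chrom_id, start)
        truth_labels[tu_id] = "flank_overlap"

    # repeat overlappers: straddle a repeat's upstream edge
    rep_order = list(rng.permutation(len(repeats)))
    for j in range(counts.get("repeat_overlap", 0)):
        rep = repeats[rep_order[j % len(repeats)]]
        length = int(rng.integers(230, 320))
        start = rep.start - 120
        seq = _linc_like_seq(rng, lo=length, hi=length)
        tu_id = next_id("tx")
        paste(tu_id, seq, rep.chrom_id, start)
        truth_labels[tu_id] = "repeat_overlap"

    # redundant copies (>= 95% identical, shorter than their source)
    sources_pool = [t for t in linc_ids if len(sequences[t]) >= 280]
    for j in range(counts.get("redundant_copy", 0)):
        src_id = sources_pool[j % len(sources_pool)]
        src = sequences[src_id]
        while True:
            copy = list(src[: int(round(len(src) * 0.97))])
            n_mut = max(1, int(round(len(copy) * 0.01)))
            for p in rng.choice(len(copy), size=n_mut, replace=False):
                copy[p] = str(rng.choice([b for b in "ACGT" if b != copy[p]]))
            copy_seq = "".join(copy)
            if orf_scan(copy_seq, 300)[1] and pair_identity(copy_seq, src) >= 0.96:
                break
        tu_id = next_id("tx")
        chrom, start = alloc.allocate(len(copy_seq))
        paste(tu_id, copy_seq, chrom, start)
        truth_labels[tu_id] = "redundant_copy"
        copy_sources[tu_id] = src_id

    for g in genome:
        g.seq = chrom_seq[g.chrom_id].decode()

    # tag transcript provenance (EST / hiseq / 454) for realism
    tu_source = {
        tu_id: sources[int(rng.integers(len(sources)))] for tu_id in sorted(sequences)
    }
    return TranscriptSet(
        sequences, alignments, truth_labels, libraries, copy_sources, tu_source
    )


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    linc_lengths: pd.Series,
    mrna_lengths: pd.Series,
    config: SimulationConfig,
) -> ExpressionBundle:
    """Negative-binomial counts converted to RPKM, with planted structure.

    Plants ``n_specific`` lincRNAs expressed in exactly one tissue,
    ``n_pos_pairs``/``n_neg_pairs`` lincRNA-mRNA pairs tied to a shared
    per-tissue factor (high positive / negative correlation), and
    ``n_modules`` co-expressed blocks of mRNAs plus one lincRNA each whose
    mRNAs share a GO term.
    """
    if config.n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = _rng(config, 3)
    tissues = [f"tissue{t + 1:02d}" for t in range(config.n_tissues)]
    linc_ids = list(linc_lengths.index)
    mrna_ids = list(mrna_lengths.index)
    genes = linc_ids + mrna_ids
    lengths = pd.concat([linc_lengths, mrna_lengths]).astype(float)
    n_t = config.n_tissues

    # baseline: flat per-gene mean with NB overdispersion
    base_mean = pd.Series(
        np.concatenate(
            [
                rng.lognormal(np.log(1.5), 1.0, size=len(linc_ids)),
                rng.lognormal(np.log(25.0), 1.0, size=len(mrna_ids)),
            ]
        ),
        index=genes,
    )
    disp = config.nb_dispersion
    mu = np.tile(base_mean.to_numpy()[:, None], (1, n_t))

    def nb_draw(mean: np.ndarray) -> np.ndarray:
        # NB with Var = mu + disp * mu^2, via gamma-Poisson mixture
        shape = 1.0 / disp
        lam = rng.gamma(shape, mean * disp)
        return rng.poisson(lam)

    counts = pd.DataFrame(nb_draw(mu), index=genes, columns=tissues, dtype=float)

    # planted tissue-restricted lincRNAs: one tissue only, zero elsewhere
    pool = [g for g in linc_ids]
    rng.shuffle(pool)
    planted_specific = pool[: config.n_specific]
    for j, g in enumerate(planted_specific):
        counts.loc[g] = 0.0
        counts.loc[g, tissues[j % n_t]] = float(rng.poisson(40) + 5)
    pool = pool[config.n_specific :]

    # planted correlated pairs (lincRNA vs mRNA) via a shared tissue factor
    mpool = list(mrna_ids)
    rng.shuffle(mpool)
    planted_pairs: list[tuple[str, str, int]] = []
    n_pairs = config.n_pos_pairs + config.n_neg_pairs
    for j in range(n_pairs):
        linc, mrna = pool[j], mpool[j]
        sign = 1 if j < config.n_pos_pairs else -1
        f = rng.lognormal(0.0, 1.2, size=n_t)
        counts.loc[linc] = rng.poisson(300.0 * f)
        if sign == 1:
            counts.loc[mrna] = rng.poisson(400.0 * f)
        else:
            g = (f.max() * 1.05 - f) / f.mean()
            counts.loc[mrna] = rng.poisson(400.0 * g)
        planted_pairs.append((linc, mrna, sign))
    pool = pool[n_pairs:]
    mpool = mpool[n_pairs:]

    # planted co-expressed modules with a shared GO term
    planted_modules: list[dict] = []
    go_annotation: dict[str, set[str]] = {}
    for j in range(config.n_modules):
        if len(mpool) < config.module_size or not pool:
            break
        members = mpool[: config.module_size]
        mpool = mpool[config.module_size :]
        linc = pool.pop(0)
        f = rng.lognormal(0.0, 1.2, size=n_t)
        counts.loc[linc] = rng.poisson(300.0 * f)
        term = f"GO:{7000000 + j}"
        for m in members:
            counts.loc[m] = rng.poisson(rng.uniform(200, 500) * f)
            go_annotation.setdefault(m, set()).add(term)
        planted_modules.append({"mrnas": members, "linc": linc, "go_term": term})

    # background GO annotation so enrichment has a background universe
    bg_terms = [f"GO:{6000000 + j}" for j in range(12)]
    for g in genes:
        for term in rng.choice(bg_terms, size=2, replace=False):
            go_annotation.setdefault(g, set()).add(str(term))

    library_sizes = counts.sum(axis=0) + config.library_background
    rpkm = compute_rpkm(counts, lengths, library_sizes)
    gene_types = pd.Series(
        ["lincRNA"] * len(linc_ids) + ["mRNA"] * len(mrna_ids), index=genes
    )
    matrix = ExpressionMatrix(rpkm, gene_types, library_sizes)
    return ExpressionBundle(
        counts=counts,
        matrix=matrix,
        gene_lengths=lengths,
        planted_specific=planted_specific,
        planted_pairs=planted_pairs,
        planted_modules=planted_modules,
        go_annotation=go_annotation,
    )


# ---------------------------------------------------------------------------
# Accession SNPs


def _sample_derived_count(rng: np.random.Generator, n: int, skew: str) -> int:
    if skew == "rare-excess":
        return 1 if rng.random() < 0.9 else 2
    if skew == "intermediate-excess":
        return n // 2
    # neutral: standard-coalescent expectation, P(i) proportional to 1/i
    i = np.arange(1, n)
    p = (1.0 / i) / np.sum(1.0 / i)
    return int(rng.choice(i, p=p))


def generate_accession_snps(
    loci: list[Locus],
    config: SimulationConfig,
    n_snps: dict[str, int] | None = None,
) -> tuple[list[SnpRecord], list[str]]:
    """Plant per-locus SNPs with a controlled site-frequency spectrum.

    Neutral loci receive a Poisson-distributed number of segregating sites
    (mean ``neutral_snps_mean``); skewed loci receive exactly ``skew_snps``.
    Each site's derived-allele count follows the locus skew and the carriers
    are a uniform accession subset.  Returns the SNPs (chrom = locus id,
    1-based position) and the accession panel.
    """
    rng = _rng(config, 4)
    n = config.n_accessions
    accessions = [f"acc{i + 1:03d}" for i in range(n)]
    records: list[SnpRecord] = []
    for locus in loci:
        L = len(locus.ref_seq)
        if n_snps and locus.locus_id in n_snps:
            s = n_snps[locus.locus_id]
        elif locus.skew == "neutral":
            s = int(rng.poisson(config.neutral_snps_mean))
        else:
            s = config.skew_snps
        s = min(s, L)
        positions = sorted(rng.choice(L, size=s, replace=False))
        for pos0 in positions:
            ref = locus.ref_seq[pos0]
            if ref not in "ACGT":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            count = _sample_derived_count(rng, n, locus.skew)
            carriers = rng.choice(n, size=count, replace=False)
            for ci in sorted(carriers):
                records.append(
                    SnpRecord(
                        chrom_id=locus.locus_id,
                        pos=int(pos0) + 1,
                        ref_base=ref,
                        alt_base=alt,
                        accession_id=accessions[int(ci)],
                    )
                )
    return records, accessions


# ---------------------------------------------------------------------------
# miRNAs


def _wobble_partner(base: str) -> str | None:
    # G:T(U) pairs in either orientation are wobbles
    return {"T": "G", "G": "T"}.get(base)


_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def generate_mirnas(
    linc_seqs: dict[str, str],
    config: SimulationConfig,
    essential: tuple[int, int] = (2, 17),
) -> MirnaSet:
    """Plant miRNAs with target sites of designed penalty composition.

    Four kinds are planted on distinct lincRNAs: a perfect complement
    (expected penalty 0), a single essential-region G:U wobble (0.5), an
    essential mismatch plus wobble (1.5), and a 5-mismatch decoy that must
    fail the 2.5 threshold.
    """
    if not linc_seqs:
        raise ValueError("need at least one lincRNA to plant miRNA sites")
    rng = _rng(config, 5)
    m = config.mirna_length
    hosts = [t for t in sorted(linc_seqs) if len(linc_seqs[t]) >= m + 40]
    rng.shuffle(hosts)
    kinds = ["perfect", "wobble", "mismatch_wobble", "decoy"]
    expected = {"perfect": 0.0, "wobble": 0.5, "mismatch_wobble": 1.5, "decoy": None}
    mirnas: list[GenomeSequence] = []
    rows = []
    for j, kind in enumerate(kinds):
        linc_id = hosts[j % len(hosts)]
        seq = linc_seqs[linc_id]
        e_lo, e_hi = essential
        while True:
            w = int(rng.integers(10, len(seq) - m - 10))
            window = seq[w : w + m]
            mir = list(revcomp(window))  # perfect complement
            # miRNA position p (1-based) pairs forward position w + m - p
            ess_positions = [
                p for p in range(e_lo, e_hi + 1)
                if _wobble_partner(window[m - p]) is not None
            ]
            if kind in ("wobble", "mismatch_wobble") and not ess_positions:
                continue
            break
        if kind == "wobble":
            p = int(rng.choice(ess_positions))
            mir[p - 1] = _wobble_partner(window[m - p])
        elif kind == "mismatch_wobble":
            p = int(rng.choice(ess_positions))
            mir[p - 1] = _wobble_partner(window[m - p])
            others = [q for q in range(e_lo, e_hi + 1) if q != p]
            q = int(rng.choice(others))
            mir[q - 1] = _mismatch_base(rng, window[m - q])
        elif kind == "decoy":
            ps = rng.choice(np.arange(e_lo, e_hi + 1), size=5, replace=False)
            for q in ps:
                mir[int(q) - 1] = _mismatch_base(rng, window[m - int(q)])
        mirna_id = f"mir-{j + 1:02d}-{kind}"
        mirnas.append(GenomeSequence(mirna_id, "".join(mir)))
        rows.append(
            (mirna_id, linc_id, kind, expected[kind], w + 1, w + m)
        )
    sites = pd.DataFrame(
        rows,
        columns=["mirna_id", "linc_id", "kind", "expected_score", "start", "end"],
    )
    return MirnaSet(mirnas, sites)


def _mismatch_base(rng: np.random.Generator, target_base: str) -> str:
    """A miRNA base that neither WC-pairs nor wobbles with ``target_base``."""
    banned = {_WC[target_base]}
    wob = _wobble_partner(target_base)
    if wob:
        banned.add(wob)
    return str(rng.choice(sorted(set("ACGT") - banned)))


# ---------------------------------------------------------------------------
# Orchestration


def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic study: genome to SNPs, one seed, all stages."""
    config = config or SimulationConfig()
    genome, annotation = generate_genome(config)
    transcripts = generate_transcripts(genome, annotation, config)

    linc_ids = sorted(
        t for t, label in transcripts.truth_labels.items() if label == "lincRNA"
    )
    linc_lengths = pd.Series(
        {t: len(transcripts.sequences[t]) for t in linc_ids}, dtype=float
    )
    genes = [f for f in annotation if f.feature_class == "gene"]
    mrna_lengths = pd.Series(
        {g.record_id: float(g.end - g.start) for g in genes}
    ).sort_index()
    expression = generate_expression(linc_lengths, mrna_lengths, config)

    mirnas = generate_mirnas(
        {t: transcripts.sequences[t] for t in linc_ids}, config
    )

    rng = _rng(config, 6)
    skews = (
        ["rare-excess"] * config.n_rare_loci
        + ["intermediate-excess"] * config.n_intermediate_loci
    )
    loci = []
    for j, t in enumerate(linc_ids):
        skew = skews[j] if j < len(skews) else "neutral"
        loci.append(Locus(t, transcripts.sequences[t], skew))
    for j in range(config.n_background_loci):
        L = int(rng.integers(250, 800))
        loci.append(Locus(f"bg{j + 1:04d}", _random_seq(rng, L), "neutral"))
    snps, accessions = generate_accession_snps(loci, config)

    return SyntheticDataset(
        config=config,
        genome=genome,
        annotation=annotation,
        transcripts=transcripts,
        expression=expression,
        mirnas=mirnas,
        loci=loci,
        snps=snps,
        accessions=accessions,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write every generated artifact as plain-text files (stable order)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fa", dataset.genome)
    write_gff3(out / "annotation.gff3", dataset.annotation)
    write_fasta(
        out / "transcripts.fa",
        [
            GenomeSequence(t, s)
            for t, s in sorted(dataset.transcripts.sequences.items())
        ],
    )
    write_alignments(out / "transcripts.bed", dataset.transcripts.alignments)
    pd.DataFrame(
        sorted(dataset.transcripts.truth_labels.items()),
        columns=["transcript_id", "class"],
    ).to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    for name, library in dataset.transcripts.libraries.items():
        write_fasta(
            out / f"library_{name}.fa",
            [GenomeSequence(i, s) for i, s in library],
        )
    write_expression_table(out / "counts.tsv", dataset.expression.counts)
    write_expression_table(out / "rpkm.tsv", dataset.expression.matrix.values)
    dataset.expression.gene_lengths.rename("length").to_frame().to_csv(
        out / "gene_lengths.tsv", sep="\t"
    )
    dataset.expression.matrix.gene_types.rename("gene_type").to_frame().to_csv(
        out / "gene_types.tsv", sep="\t"
    )
    write_go_annotation(out / "go_annotation.tsv", dataset.expression.go_annotation)
    write_fasta(out / "mirnas.fa", dataset.mirnas.mirnas)
    dataset.mirnas.sites.to_csv(out / "mirna_sites.tsv", sep="\t", index=False)
    write_fasta(
        out / "loci.fa",
        [GenomeSequence(l.locus_id, l.ref_seq) for l in dataset.loci],
    )
    pd.DataFrame(
        [(l.locus_id, l.skew) for l in dataset.loci], columns=["locus_id", "sfs_skew"]
    ).to_csv(out / "locus_skew.tsv", sep="\t", index=False)
    write_snp_table(out / "snps.tsv", dataset.snps)
    pd.Series(dataset.accessions, name="accession").to_frame().to_csv(
        out / "accessions.tsv", sep="\t", index=False
    )
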