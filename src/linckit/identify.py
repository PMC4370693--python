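"""The lincRNA identification pipeline over transcript units (TUs).

A mapped transcript enters as a :class:`TranscriptUnit` and is passed through
an ordered chain of filters: perfect-mapping, overlap with annotated
genes/antisense transcripts, overlap with repeats, proximity to gene flanks,
long open reading frames, minimum length, four pluggable homology/coding
screens, and finally redundancy clustering.  Every step is accounted for in a
:class:`FilterReport` whose counts chain exactly.

The homology screens abstract external database searches (protein databases,
coding-potential classifiers, nucleotide databases, structural-RNA
catalogues) behind one interface: the built-in screen flags a TU when it
shares an exact k-mer (nucleotide k=30, or peptide k=10 on six-frame
translations for protein screens) with any library sequence; alternatively a
precomputed external hit table is honored verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import AnnotationRecord, TranscriptAlignment

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: canonical order of the pipeline steps
PIPELINE_STEPS = [
    "map", "gene_nat", "repeat", "flank500", "orf", "length",
    "protein", "nr_like", "nt_like", "housekeeping", "cluster",
]

#: screens whose libraries are protein sequences (six-frame comparison)
PROTEIN_SCREENS = {"protein", "nr_like"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptUnit:
    """A genome-mapped transcript; may occupy several perfect placements."""

    tu_id: str
    seq: str
    source: str = "hiseq"  # EST | hiseq | p454
    loci: list[TranscriptAlignment] = field(default_factory=list)
    status: str = "active"

    @property
    def chrom_id(self) -> str:
        return self.loci[0].chrom_id

    @property
    def blocks(self) -> list[tuple[int, int]]:
        return self.loci[0].blocks

    @property
    def strand(self) -> str:
        return self.loci[0].strand

    @property
    def removed(self) -> bool:
        return self.status != "active"

    def remove(self, step_tag: str) -> "TranscriptUnit":
        return replace(self, status=f"removed({step_tag})")


@dataclass
class FilterStep:
    step_tag: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class FilterReport:
    """Per-step accounting; consecutive steps chain (n_out -> next n_in)."""

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, step_tag: str, n_in: int, n_removed: int) -> None:
        if self.steps and self.steps[-1].n_out != n_in:
            raise ValueError(
                f"report chain broken at {step_tag}: previous n_out "
                f"{self.steps[-1].n_out} != n_in {n_in}"
            )
        self.steps.append(FilterStep(step_tag, n_in, n_removed))

    def validate_chain(self) -> bool:
        return all(
            a.n_out == b.n_in for a, b in zip(self.steps, self.steps[1:])
        )

    def to_rows(self) -> list[tuple[str, int, int, int]]:
        return [(s.step_tag, s.n_in, s.n_removed, s.n_out) for s in self.steps]


@dataclass
class ScreenHit:
    tu_id: str
    subject_id: str
    screen_name: str
    significant: bool = True


@dataclass
class IdentifyConfig:
    """Knobs of the identification pipeline (defaults follow the method)."""

    flank: int = 500
    min_length: int = 200
    orf_min_length: int = 300
    orf_require_init: bool = False
    kmer: int = 30
    peptide_kmer: int = 10
    cluster_identity: float = 0.95
    screens: tuple[str, ...] = ("protein", "nr_like", "nt_like", "housekeeping")


# ---------------------------------------------------------------------------
# Step 1: perfect-mapping filter


def map_filter(
    alignments: Iterable[TranscriptAlignment],
    sequences: Mapping[str, str],
    chrom_ids: Iterable[str],
    sources: Mapping[str, str] | None = None,
) -> list[TranscriptUnit]:
    """Retain transcripts whose every nucleotide maps with 100% identity.

    A transcript with several perfect placements becomes one TU carrying all
    of its loci.  Alignments referencing unknown chromosomes are an error.
    """
    known = set(chrom_ids)
    perfect: dict[str, list[TranscriptAlignment]] = {}
    for aln in alignments:
        if aln.chrom_id not in known:
            raise ValueError(
                f"alignment of {aln.tu_id} references unknown chromosome {aln.chrom_id!r}"
            )
        seq = sequences.get(aln.tu_id)
        if seq is None:
            raise ValueError(f"no sequence supplied for aligned transcript {aln.tu_id}")
        if aln.mismatches == 0 and aln.matched == len(seq):
            perfect.setdefault(aln.tu_id, []).append(aln)
    tus = []
    for tu_id in sorted(perfect):
        source = (sources or {}).get(tu_id, "hiseq")
        tus.append(
            TranscriptUnit(tu_id=tu_id, seq=sequences[tu_id], source=source, loci=perfect[tu_id])
        )
    return tus


# ---------------------------------------------------------------------------
# Steps 2-4: interval overlap filters

OVERLAP_MODES = {
    "gene_nat": ({"gene", "NAT"}, 0),
    "repeat": ({"repeat"}, 0),
    "flank500": ({"gene"}, 500),
}


def interval_overlap_filter(
    tus: Sequence[TranscriptUnit],
    features: Sequence[AnnotationRecord],
    mode: str,
    flank: int = 500,
) -> list[TranscriptUnit]:
    """Drop TUs any of whose blocks (at any locus) touch the given features.

    ``gene_nat``/``repeat`` remove on any 1-bp overlap, strand-agnostic;
    ``flank500`` extends each gene by ``flank`` bp on both sides first.
    """
    if mode not in OVERLAP_MODES:
        raise ValueError(f"unknown overlap mode {mode!r}")
    classes, pad = OVERLAP_MODES[mode]
    if mode == "flank500":
        pad = flank
    trees: dict[str, IntervalTree] = {}
    for f in features:
        if f.feature_class in classes:
            start = max(0, f.start - pad)
            trees.setdefault(f.chrom_id, IntervalTree()).addi(start, f.end + pad)
    kept = []
    for tu in tus:
        hit = any(
            trees.get(locus.chrom_id) is not None
            and any(trees[locus.chrom_id].overlap(s, e) for s, e in locus.blocks)
            for locus in tu.loci
        )
        if not hit:
            kept.append(tu)
    return kept


# ---------------------------------------------------------------------------
# Step 5: ORF scan


def orf_scan(
    seq: str, min_len: int = 300, require_init: bool = False
) -> tuple[int, bool]:
    """Six-frame ORF scan; returns (longest ORF length in nt, passes).

    An ORF is a maximal run of codons free of stop codons (TAA/TAG/TGA) —
    no start codon required unless ``require_init``.  Codons containing N
    never count as stops and count toward the length.  A TU *fails* (is
    coding-suspect) iff some ORF reaches ``min_len`` nucleotides.
    """
    longest = 0
    for strand_seq in (seq, revcomp(seq)):
        for offset in range(3):
            codons = [
                strand_seq[i : i + 3]
                for i in range(offset, len(strand_seq) - 2, 3)
            ]
            run = 0
            run_has_init = not require_init
            best_here = 0
            for codon in codons:
                if codon in STOP_CODONS:
                    run = 0
                    run_has_init = not require_init
                    continue
                if require_init and not run_has_init:
                    if codon == "ATG":
                        run_has_init = True
                    else:
                        continue
                run += 1
                best_here = max(best_here, run)
            longest = max(longest, best_here * 3)
    return longest, longest < min_len


# ---------------------------------------------------------------------------
# Step 6: length filter


def length_filter(
    tus: Sequence[TranscriptUnit], min_len: int = 200
) -> list[TranscriptUnit]:
    """Keep TUs of length >= min_len (strictly shorter ones are discarded)."""
    return [tu for tu in tus if len(tu.seq) >= min_len]


# ---------------------------------------------------------------------------
# Steps 7-11: pluggable homology / coding screens


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


_CODON_TABLE: dict[str, str] = {}


def _translate(seq: str) -> str:
    """Translate a nucleotide string; codons with N become 'X', stops '*'."""
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)


def six_frame_translations(seq: str) -> list[str]:
    return [
        _translate(strand_seq[offset:])
        for strand_seq in (seq, revcomp(seq))
        for offset in range(3)
    ]


def homology_screen(
    tus: Sequence[TranscriptUnit],
    reference_library: Sequence[tuple[str, str]],
    screen_name: str,
    k: int = 30,
    peptide_k: int = 10,
    hit_table: Sequence[ScreenHit] | None = None,
) -> tuple[list[ScreenHit], list[TranscriptUnit]]:
    """Flag and drop TUs with detectable similarity to a reference library.

    ``reference_library`` is (subject_id, sequence) pairs: nucleotide
    sequences for ``nt_like``/``housekeeping`` screens, protein sequences for
    ``protein``/``nr_like``.  The built-in screen uses exact shared k-mers
    (forward or reverse complement; peptide k-mers on six-frame translations
    for protein screens).  If ``hit_table`` is given it replaces the built-in
    screen and is honored verbatim.
    """
    if hit_table is not None:
        flagged = {h.tu_id for h in hit_table if h.significant}
        hits = list(hit_table)
        kept = [tu for tu in tus if tu.tu_id not in flagged]
        return hits, kept

    if not reference_library:
        logger.warning("empty library for screen %r: all TUs pass", screen_name)
        return [], list(tus)

    protein_mode = screen_name in PROTEIN_SCREENS
    kk = peptide_k if protein_mode else k
    library_kmers: dict[str, str] = {}
    for subject_id, subject_seq in reference_library:
        for kmer in _kmer_set(subject_seq, kk):
            library_kmers.setdefault(kmer, subject_id)

    hits: list[ScreenHit] = []
    kept: list[TranscriptUnit] = []
    for tu in tus:
        if protein_mode:
            queries = six_frame_translations(tu.seq)
        else:
            queries = [tu.seq, revcomp(tu.seq)]
        subject = None
        for q in queries:
            for i in range(len(q) - kk + 1):
                kmer = q[i : i + kk]
                if "*" in kmer or "X" in kmer:
                    continue
                if kmer in library_kmers:
                    subject = library_kmers[kmer]
                    break
            if subject:
                break
        if subject is None:
            kept.append(tu)
        else:
            hits.append(ScreenHit(tu.tu_id, subject, screen_name, True))
    return hits, kept


# ---------------------------------------------------------------------------
# Step 12: redundancy clustering


def pair_identity(a: str, b: str) -> float:
    """Identity of the end-gap-free alignment of the shorter inside the longer.

    Computed over both strands; identity = 1 - edits / len(shorter).
    """
    if len(a) > len(b):
        a, b = b, a
    best = 0.0
    for query in (a, revcomp(a)):
        dist = edlib.align(query, b, mode="HW", task="distance")["editDistance"]
        best = max(best, 1.0 - dist / len(query))
    return best


def cluster_redundant(
    tus: Sequence[TranscriptUnit], identity: float = 0.95
) -> list[TranscriptUnit]:
    """Greedy longest-first clustering; representatives are cluster heads.

    TUs are sorted by length descending (ties by tu_id); each joins the first
    representative with pairwise identity >= the threshold, else founds its
    own cluster.
    """
    ordered = sorted(tus, key=lambda t: (-len(t.seq), t.tu_id))
    reps: list[TranscriptUnit] = []
    for tu in ordered:
        if not any(pair_identity(tu.seq, rep.seq) >= identity for rep in reps):
            reps.append(tu)
    reps.sort(key=lambda t: t.tu_id)
    return reps


# ---------------------------------------------------------------------------
# Orchestration


def run_identification(
    alignments: Iterable[TranscriptAlignment],
    sequences: Mapping[str, str],
    annotation: Sequence[AnnotationRecord],
    chrom_ids: Iterable[str],
    libraries: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    hit_tables: Mapping[str, Sequence[ScreenHit]] | None = None,
    config: IdentifyConfig | None = None,
    sources: Mapping[str, str] | None = None,
) -> tuple[list[TranscriptUnit], FilterReport, list[ScreenHit]]:
    """Run the full pipeline in its canonical order and account every step."""
    cfg = config or IdentifyConfig()
    libraries = libraries or {}
    hit_tables = hit_tables or {}
    report = FilterReport()

    n_candidates = len(set(a.tu_id for a in alignments)) if not isinstance(
        alignments, (list, tuple)
    ) else len({a.tu_id for a in alignments})
    tus = map_filter(alignments, sequences, chrom_ids, sources)
    report.add("map", n_candidates, n_candidates - len(tus))

    for mode in ("gene_nat", "repeat", "flank500"):
        n_in = len(tus)
        tus = interval_overlap_filter(tus, annotation, mode, flank=cfg.flank)
        report.add(mode, n_in, n_in - len(tus))

    n_in = len(tus)
    tus = [
        tu
        for tu in tus
        if orf_scan(tu.seq, cfg.orf_min_length, cfg.orf_require_init)[1]
    ]
    report.add("orf", n_in, n_in - len(tus))

    n_in = len(tus)
    tus = length_filter(tus, cfg.min_length)
    report.add("length", n_in, n_in - len(tus))

    all_hits: list[ScreenHit] = []
    for screen_name in cfg.screens:
        n_in = len(tus)
        hits, tus = homology_screen(
            tus,
            libraries.get(screen_name, ()),
            screen_name,
            k=cfg.kmer,
            peptide_k=cfg.peptide_kmer,
            hit_table=hit_tables.get(screen_name),
        )
        all_hits.extend(hits)
        report.add(screen_name, n_in, n_in - len(tus))

    n_in = len(tus)
    tus = cluster_redundant(tus, cfg.cluster_identity)
    report.add("cluster", n_in, n_in - len(tus))

    return tus, report, all_hits


# ---------------------------------------------------------------------------
# Chromosome distribution


def chromosome_distribution_test(
    counts: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
    expectation: str = "length_proportional",
) -> tuple[float, float]:
    """Chi-square goodness of fit of per-chromosome lincRNA counts.

    ``expectation`` is ``equal`` (uniform across chromosomes) or
    ``length_proportional`` (proportional to chromosome length).  Returns
    (statistic, p) with k-1 degrees of freedom.
    """
    chroms = sorted(chrom_lengths)
    if len(chroms) < 2:
        raise ValueError("need at least 2 chromosomes")
    observed = np.array([counts.get(c, 0) for c in chroms], dtype=float)
    total = observed.sum()
    if expectation == "equal":
        props = np.full(len(chroms), 1.0 / len(chroms))
    elif expectation == "length_proportional":
        lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
        props = lengths / lengths.sum()
    else:
        raise ValueError(f"unknown expectation {expectation!r}")
    expected = props * total
    if np.any(expected == 0):
        raise ValueError("expected count of zero on some chromosome")
    stat, p = stats.chisquare(observed, expected)
    return float(stat), float(p)
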