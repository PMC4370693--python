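"""Readers and writers for the on-disk formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open ``[start, end)``.  GFF3 files
use 1-based inclusive coordinates and are converted at the boundary; SNP
tables carry 1-based positions that are kept 1-based on the record (the
position of a base, not an interval).  All writers emit records in a stable,
deterministic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
SNP_BASES = set("ACGT")

#: default mapping from GFF3 column-3 feature types to internal classes
DEFAULT_FEATURE_MAP: dict[str, str] = {
    "gene": "gene",
    "mRNA": "gene",
    "protein_coding_gene": "gene",
    "antisense_RNA": "NAT",
    "antisense_lncRNA": "NAT",
    "NAT": "NAT",
    "repeat_region": "repeat",
    "transposable_element": "repeat",
    "dispersed_repeat": "repeat",
    "repeat": "repeat",
}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass
class GenomeSequence:
    """A chromosome (or contig) of the reference genome."""

    chrom_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for {self.chrom_id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AnnotationRecord:
    """A genome annotation feature with internal 0-based half-open coords."""

    chrom_id: str
    start: int
    end: int
    strand: str
    feature_class: str  # gene | NAT | repeat | other
    record_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.record_id}: invalid interval [{self.start}, {self.end})"
            )


@dataclass
class SnpRecord:
    """One biallelic substitution observed in one accession (1-based pos)."""

    chrom_id: str
    pos: int
    ref_base: str
    alt_base: str
    accession_id: str

    def __post_init__(self) -> None:
        if self.ref_base not in SNP_BASES or self.alt_base not in SNP_BASES:
            raise ValueError(
                f"SNP at {self.chrom_id}:{self.pos} has non-ACGT allele "
                f"{self.ref_base}>{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError(
                f"SNP at {self.chrom_id}:{self.pos} has ref == alt ({self.ref_base})"
            )


@dataclass
class TranscriptAlignment:
    """A transcript-to-genome placement with exon blocks (BED-like).

    ``matched`` is the number of transcript nucleotides aligned and
    ``mismatches`` the number of substitutions inside the aligned part, as a
    spliced aligner would report them.
    """

    tu_id: str
    chrom_id: str
    strand: str
    blocks: list[tuple[int, int]] = field(default_factory=list)
    matched: int = 0
    mismatches: int = 0

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def span_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read FASTA records; sequences are uppercased and U is mapped to T."""
    records: list[GenomeSequence] = []
    with open(path) as handle:
        try:
            parsed = list(SeqIO.parse(handle, "fasta"))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        for rec in parsed:
            seq = str(rec.seq).upper().replace("U", "T")
            if not rec.id:
                raise ParseError(f"{path}: FASTA record with empty header")
            if not seq:
                raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
            records.append(GenomeSequence(chrom_id=rec.id, seq=seq))
    if not records:
        # distinguish an empty file from a parse failure
        text = Path(path).read_text()
        if text.strip():
            raise ParseError(f"{path}: no FASTA records parsed (missing '>' header?)")
    return records


def write_fasta(path: str | Path, records: Iterable[GenomeSequence], width: int = 70) -> None:
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.chrom_id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path: str | Path,
    feature_map: Mapping[str, str] | None = None,
) -> list[AnnotationRecord]:
    """Read a GFF3 file, converting to 0-based half-open coordinates.

    ``feature_map`` maps GFF3 column-3 types to the internal classes
    ``gene|NAT|repeat``; unmapped types become ``other`` with a logged
    warning.
    """
    fmap = DEFAULT_FEATURE_MAP if feature_map is None else dict(feature_map)
    records: list[AnnotationRecord] = []
    warned: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end {end1} < start {start1}")
            feature_class = fmap.get(ftype)
            if feature_class is None:
                feature_class = "other"
                if ftype not in warned:
                    warned.add(ftype)
                    logger.warning("unmapped GFF3 feature type %r -> 'other'", ftype)
            record_id = _gff3_id(attrs) or f"{ftype}:{chrom}:{start1}-{end1}"
            records.append(
                AnnotationRecord(
                    chrom_id=chrom,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in "+-" else ".",
                    feature_class=feature_class,
                    record_id=record_id,
                )
            )
    return records


def _gff3_id(attrs: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:]
    return None


def write_gff3(
    path: str | Path,
    records: Sequence[AnnotationRecord],
    source: str = "linckit",
    type_of: Mapping[str, str] | None = None,
) -> None:
    """Write records back to GFF3 (1-based inclusive), stable order."""
    inv = {"gene": "gene", "NAT": "antisense_RNA", "repeat": "repeat_region", "other": "region"}
    if type_of:
        inv.update(type_of)
    ordered = sorted(records, key=lambda r: (r.chrom_id, r.start, r.end, r.record_id))
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for r in ordered:
            handle.write(
                "\t".join(
                    [
                        r.chrom_id,
                        source,
                        inv.get(r.feature_class, "region"),
                        str(r.start + 1),
                        str(r.end),
                        ".",
                        r.strand,
                        ".",
                        f"ID={r.record_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SNP table (long format: one accession per row)

SNP_COLUMNS = ["chrom", "pos", "ref", "alt", "accession"]


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read the long-format SNP TSV (chrom, pos, ref, alt, accession)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing SNP columns {missing}")
    records: list[SnpRecord] = []
    seen: set[tuple[str, int, str]] = set()
    for row in df.itertuples(index=False):
        rec = SnpRecord(
            chrom_id=str(row.chrom),
            pos=int(row.pos),
            ref_base=str(row.ref),
            alt_base=str(row.alt),
            accession_id=str(row.accession),
        )
        key = (rec.chrom_id, rec.pos, rec.accession_id)
        if key in seen:
            raise ParseError(
                f"{path}: duplicate SNP row for (chrom={key[0]}, pos={key[1]}, "
                f"accession={key[2]})"
            )
        seen.add(key)
        records.append(rec)
    return records


def write_snp_table(path: str | Path, records: Sequence[SnpRecord]) -> None:
    ordered = sorted(records, key=lambda r: (r.chrom_id, r.pos, r.accession_id))
    df = pd.DataFrame(
        [(r.chrom_id, r.pos, r.ref_base, r.alt_base, r.accession_id) for r in ordered],
        columns=SNP_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcript alignments (BED6 + blocks + mismatch count)

ALN_COLUMNS = [
    "chrom", "start", "end", "name", "matched", "strand",
    "block_sizes", "block_starts", "mismatches",
]


def read_alignments(path: str | Path) -> list[TranscriptAlignment]:
    """Read BED6+blocks transcript alignments (0-based half-open on disk)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ALN_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing alignment columns {missing}")
    out: list[TranscriptAlignment] = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        if len(sizes) != len(offsets):
            raise ParseError(f"{path}: block_sizes/block_starts mismatch for {row.name}")
        blocks = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        aln = TranscriptAlignment(
            tu_id=str(row.name),
            chrom_id=str(row.chrom),
            strand=str(row.strand),
            blocks=blocks,
            matched=int(row.matched),
            mismatches=int(row.mismatches),
        )
        if aln.end != int(row.end):
            raise ParseError(f"{path}: blocks of {aln.tu_id} do not reach end coordinate")
        out.append(aln)
    return out


def write_alignments(path: str | Path, alignments: Sequence[TranscriptAlignment]) -> None:
    rows = []
    for a in sorted(alignments, key=lambda x: (x.chrom_id, x.start, x.tu_id)):
        sizes = ",".join(str(e - s) for s, e in a.blocks)
        offsets = ",".join(str(s - a.start) for s, _e in a.blocks)
        rows.append(
            (a.chrom_id, a.start, a.end, a.tu_id, a.matched, a.strand, sizes, offsets, a.mismatches)
        )
    pd.DataFrame(rows, columns=ALN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Simple TSV tables


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Gene-by-tissue numeric table, first column = gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative expression values")
    return df


def write_expression_table(path: str | Path, df: pd.DataFrame) -> None:
    df.sort_index().to_csv(path, sep="\t")


def read_go_annotation(path: str | Path) -> dict[str, set[str]]:
    """Two-column gene -> GO-term TSV; returns gene -> set of terms."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: GO annotation needs two columns (gene, term)")
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(str(gene), set()).add(str(term))
    return mapping


def write_go_annotation(path: str | Path, mapping: Mapping[str, Iterable[str]]) -> None:
    rows = [(g, t) for g in sorted(mapping) for t in sorted(mapping[g])]
    pd.DataFrame(rows, columns=["gene", "go_term"]).to_csv(path, sep="\t", index=False)
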