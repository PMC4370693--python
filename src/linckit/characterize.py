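"""Descriptive characterization of identified lincRNAs.

Length and exon-count summaries, nearest protein-coding-gene distances
(binned into the 0.5-1 kb flank band, 1-5 kb, and >5 kb), and sequence
conservation calls from precomputed similarity-search hit tables (a lincRNA
counts as conserved in a subject genome when more than 20% of its sequence
is covered by matched regions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .identify import TranscriptUnit
from .io_formats import AnnotationRecord

DISTANCE_BINS = ("flank_0.5_1k", "1k_5k", "gt_5k")

CONSERVED_FRACTION = 0.20


@dataclass
class NeighborDistance:
    linc_id: str
    nearest_gene_id: str | None
    distance: int | None  # nt gap; None when no gene shares a chromosome
    bin: str | None

    @staticmethod
    def bin_of(distance: int) -> str:
        if distance < 1000:
            return "flank_0.5_1k"
        if distance < 5000:
            return "1k_5k"
        return "gt_5k"


@dataclass
class ConservationCall:
    linc_id: str
    subject_genome: str
    covered_fraction: float
    conserved: bool


def length_and_exon_stats(lincs: Sequence[TranscriptUnit]) -> dict:
    """Min/max/mean length, exon-count histogram, single-exon fraction.

    Exon count is the number of alignment blocks at the primary locus.
    """
    if not lincs:
        raise ValueError("empty lincRNA set")
    lengths = np.array([len(t.seq) for t in lincs])
    exon_counts = [len(t.blocks) for t in lincs]
    hist: dict[int, int] = {}
    for c in exon_counts:
        hist[c] = hist.get(c, 0) + 1
    return {
        "n": len(lincs),
        "min_length": int(lengths.min()),
        "max_length": int(lengths.max()),
        "mean_length": float(lengths.mean()),
        "exon_count_histogram": dict(sorted(hist.items())),
        "single_exon_fraction": hist.get(1, 0) / len(lincs),
    }


def _interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in nt between half-open intervals; 0 if they overlap or touch."""
    if a[0] >= b[1]:
        return a[0] - b[1]
    if b[0] >= a[1]:
        return b[0] - a[1]
    return 0


def nearest_gene_distance(
    lincs: Sequence[TranscriptUnit],
    genes: Sequence[AnnotationRecord],
) -> list[NeighborDistance]:
    """Nearest-gene gap per lincRNA, over all of its loci and blocks.

    Strand-agnostic, same chromosome only; a lincRNA on a chromosome without
    genes is recorded with a missing distance.
    """
    by_chrom: dict[str, list[AnnotationRecord]] = {}
    for g in genes:
        if g.feature_class == "gene":
            by_chrom.setdefault(g.chrom_id, []).append(g)
    out: list[NeighborDistance] = []
    for linc in lincs:
        best: tuple[int, str] | None = None
        for locus in linc.loci:
            for gene in by_chrom.get(locus.chrom_id, ()):
                gap = min(
                    _interval_gap(block, (gene.start, gene.end))
                    for block in locus.blocks
                )
                if best is None or (gap, gene.record_id) < best:
                    best = (gap, gene.record_id)
        if best is None:
            out.append(NeighborDistance(linc.tu_id, None, None, None))
        else:
            out.append(
                NeighborDistance(
                    linc.tu_id, best[1], best[0], NeighborDistance.bin_of(best[0])
                )
            )
    return out


def distance_bin_fractions(distances: Sequence[NeighborDistance]) -> dict[str, float]:
    """Fraction of lincRNAs (with a recorded distance) per bin; sums to 1."""
    recorded = [d for d in distances if d.bin is not None]
    if not recorded:
        return {b: 0.0 for b in DISTANCE_BINS}
    return {
        b: sum(1 for d in recorded if d.bin == b) / len(recorded)
        for b in DISTANCE_BINS
    }


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length covered by the union of half-open intervals."""
    merged = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s > last_end:
            merged += e - s
            last_end = e
        elif e > last_end:
            merged += e - last_end
            last_end = e
    return merged


def conservation_call(
    linc_id: str,
    linc_length: int,
    subject_genome: str,
    hit_intervals: Sequence[tuple[int, int]],
) -> ConservationCall:
    """Conservation from matched spans on the lincRNA (0-based half-open).

    covered_fraction = |union of hits| / length; conserved iff strictly
    greater than 20%.
    """
    for s, e in hit_intervals:
        if not 0 <= s < e <= linc_length:
            raise ValueError(
                f"{linc_id}: hit interval [{s}, {e}) out of bounds (length {linc_length})"
            )
    fraction = union_length(hit_intervals) / linc_length
    return ConservationCall(
        linc_id, subject_genome, fraction, fraction > CONSERVED_FRACTION
    )
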