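"""Plant miRNA target / target-mimic detection with a penalty score.

A miRNA is aligned antisense against every window of a lincRNA; each miRNA
position contributes a penalty depending on its pair state — Watson-Crick
pair 0, G:U wobble, mismatch, or gap — weighted down outside the essential
region (miRNA positions 2-17 by default).  At most one single-base gap is
permitted, and only 3' of a configurable miRNA position.  An alignment whose
total penalty does not exceed the threshold (default 2.5) is a target hit;
per (miRNA, lincRNA) pair the minimum-penalty alignment is reported.

The default penalty ledger is frozen by calibration against a published set
of cucumber miRNA-lincRNA alignments with printed total scores (see
:mod:`linckit.calibration`): mismatch 1.0 / 0.5 (essential / outside),
wobble 0.5 / 0.3, gap 1.0 / 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .identify import revcomp

logger = logging.getLogger(__name__)

WC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}  # G:U in DNA representation

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PenaltyLedger:
    """Per-pair-state penalties, inside and outside the essential region."""

    mismatch_in: float = 1.0
    mismatch_out: float = 0.5
    wobble_in: float = 0.5
    wobble_out: float = 0.3
    gap_in: float = 1.0
    gap_out: float = 0.5

    def penalty(self, state: str, inside: bool) -> float:
        if state == "WC":
            return 0.0
        if state == "wobble":
            return self.wobble_in if inside else self.wobble_out
        if state == "mismatch":
            return self.mismatch_in if inside else self.mismatch_out
        if state in ("gap_m", "gap_t"):
            return self.gap_in if inside else self.gap_out
        raise ValueError(f"unknown pair state {state!r}")


DEFAULT_LEDGER = PenaltyLedger()


@dataclass
class TargetParams:
    """Scan parameters (the method's 'moderate' settings by default)."""

    threshold: float = 2.5
    essential_start: int = 2
    essential_end: int = 17
    max_gaps: int = 1
    gap_after: int = 17
    ledger: PenaltyLedger = field(default_factory=PenaltyLedger)
    min_mirna_len: int = 18
    max_mirna_len: int = 26


@dataclass
class AlignmentColumn:
    """One column of a miRNA-target alignment.

    ``mir_pos`` is the 1-based miRNA position (None in a miRNA-gap column);
    ``target_pos`` the 1-based forward-strand lincRNA position (None in a
    target-gap column).  ``state`` is WC | wobble | mismatch | gap_m | gap_t.
    """

    mir_pos: int | None
    target_pos: int | None
    mir_base: str
    target_base: str
    state: str


@dataclass
class TargetHit:
    mirna_id: str
    linc_id: str
    score: float
    mirna_span: tuple[int, int]
    #: forward-strand 1-based coordinates, descending (antisense pairing)
    target_span: tuple[int, int]
    columns: list[AlignmentColumn]


def pair_state(mir_base: str, target_base: str) -> str:
    pair = (mir_base, target_base)
    if pair in WC_PAIRS:
        return "WC"
    if pair in WOBBLE_PAIRS:
        return "wobble"
    return "mismatch"


def score_columns(columns: Iterable[AlignmentColumn], params: TargetParams) -> float:
    """Total penalty of an alignment from its per-column pair states.

    A gap column inherits the essential/outside weighting from the miRNA
    position it interrupts (the preceding position for a miRNA gap).
    """
    total = 0.0
    last_mir_pos = 0
    for col in columns:
        if col.state == "gap_m":  # miRNA gap: sits between positions last, last+1
            inside = last_mir_pos < params.essential_end
        else:
            p = col.mir_pos
            inside = params.essential_start <= p <= params.essential_end
            last_mir_pos = p
        total += params.ledger.penalty(col.state, inside)
    return round(total, 10)


# ---------------------------------------------------------------------------
# Window scan


def _penalty_rows(mir: str, linc: str, params: TargetParams) -> np.ndarray:
    """P[p-1, j] = penalty of miRNA position p paired with linc position j."""
    led = params.ledger
    pen_in = np.full((5, 5), led.mismatch_in)
    pen_out = np.full((5, 5), led.mismatch_out)
    for (a, b) in WC_PAIRS:
        pen_in[_BASE_CODE[a], _BASE_CODE[b]] = 0.0
        pen_out[_BASE_CODE[a], _BASE_CODE[b]] = 0.0
    for (a, b) in WOBBLE_PAIRS:
        pen_in[_BASE_CODE[a], _BASE_CODE[b]] = led.wobble_in
        pen_out[_BASE_CODE[a], _BASE_CODE[b]] = led.wobble_out
    mir_code = np.array([_BASE_CODE.get(b, 4) for b in mir])
    linc_code = np.array([_BASE_CODE.get(b, 4) for b in linc])
    m = len(mir)
    P = np.empty((m, len(linc)))
    for p in range(1, m + 1):
        inside = params.essential_start <= p <= params.essential_end
        table = pen_in if inside else pen_out
        P[p - 1] = table[mir_code[p - 1], linc_code]
    return P


def _variant_scores(
    P: np.ndarray, m: int, L: int, params: TargetParams
) -> list[tuple[str, int | None, np.ndarray]]:
    """Score every alignment variant at every window start.

    Variants: ("ungapped", None), ("gap_t", g) — miRNA position g unpaired,
    ("gap_m", g) — an extra target base after miRNA position g.  Returns
    (variant, g, scores-by-window-start) triples.
    """
    led = params.ledger
    out: list[tuple[str, int | None, np.ndarray]] = []

    def seg(p: int, shift: int, width: int) -> np.ndarray:
        return P[p - 1, shift : shift + width]

    if L >= m:
        width = L - m + 1
        s = np.zeros(width)
        for p in range(1, m + 1):
            s += seg(p, m - p, width)
        out.append(("ungapped", None, s))

    if params.max_gaps >= 1:
        # miRNA position g unpaired (gap in target), window length m-1
        if L >= m - 1:
            width = L - (m - 1) + 1
            for g in range(params.gap_after + 1, m + 1):
                gap_pen = (
                    led.gap_in
                    if params.essential_start <= g <= params.essential_end
                    else led.gap_out
                )
                s = np.full(width, gap_pen)
                for p in range(1, m + 1):
                    if p == g:
                        continue
                    shift = (m - 1 - p) if p < g else (m - p)
                    s += seg(p, shift, width)
                out.append(("gap_t", g, s))
        # extra target base after miRNA position g (gap in miRNA), len m+1
        if L >= m + 1:
            width = L - (m + 1) + 1
            for g in range(params.gap_after, m):
                gap_pen = led.gap_in if g < params.essential_end else led.gap_out
                s = np.full(width, gap_pen)
                for p in range(1, m + 1):
                    shift = (m - p + 1) if p <= g else (m - p)
                    s += seg(p, shift, width)
                out.append(("gap_m", g, s))
    return out


def _build_columns(
    mir: str, linc: str, i: int, variant: str, g: int | None
) -> list[AlignmentColumn]:
    """Materialize the alignment columns of one scored variant."""
    m = len(mir)
    cols: list[AlignmentColumn] = []
    if variant == "ungapped":
        top = i + m - 1  # 0-based highest target index
        for p in range(1, m + 1):
            t = top - (p - 1)
            cols.append(
                AlignmentColumn(p, t + 1, mir[p - 1], linc[t], pair_state(mir[p - 1], linc[t]))
            )
    elif variant == "gap_t":
        top = i + m - 2
        for p in range(1, m + 1):
            if p == g:
                cols.append(AlignmentColumn(p, None, mir[p - 1], "-", "gap_t"))
                continue
            t = top - (p - 1) if p < g else top - (p - 2)
            cols.append(
                AlignmentColumn(p, t + 1, mir[p - 1], linc[t], pair_state(mir[p - 1], linc[t]))
            )
    elif variant == "gap_m":
        top = i + m
        for p in range(1, m + 1):
            t = top - (p - 1) if p <= g else top - p
            cols.append(
                AlignmentColumn(p, t + 1, mir[p - 1], linc[t], pair_state(mir[p - 1], linc[t]))
            )
            if p == g:
                tg = top - g
                cols.append(AlignmentColumn(None, tg + 1, "-", linc[tg], "gap_m"))
    else:
        raise ValueError(variant)
    return cols


def _scan_oriented(
    mir: str, linc: str, params: TargetParams
) -> tuple[float, int, str, int | None] | None:
    m, L = len(mir), len(linc)
    if L < m - 1:
        return None
    P = _penalty_rows(mir, linc, params)
    best: tuple[float, int, str, int | None] | None = None
    for variant, g, scores in _variant_scores(P, m, L, params):
        if scores.size == 0:
            continue
        i = int(np.argmin(scores))
        s = float(scores[i])
        # prefer lower score, then leftmost window, then ungapped
        key = (round(s, 9), i, variant != "ungapped")
        if best is None or key < (round(best[0], 9), best[1], best[2] != "ungapped"):
            best = (s, i, variant, g)
    return best


def scan_pair(
    mirna_id: str,
    mir: str,
    linc_id: str,
    linc: str,
    params: TargetParams,
) -> TargetHit | None:
    """Best (minimum-penalty) alignment of one miRNA on one lincRNA.

    Both representations of the lincRNA are scanned so the result is
    invariant under strand representation; coordinates are always reported
    on the given (forward) sequence, descending for an antisense site and
    ascending for a site found on the reverse-complement representation.
    """
    L = len(linc)
    rc = revcomp(linc)
    best = None
    for strand, seq in (("+", linc), ("-", rc)):
        cand = _scan_oriented(mir, seq, params)
        if cand is None:
            continue
        key = (round(cand[0], 9), strand != "+", cand[1])
        if best is None or key < best[0]:
            best = (key, strand, cand)
    if best is None:
        return None
    (_, strand, (s, i, variant, g)) = best
    if s > params.threshold + 1e-9:
        return None
    seq = linc if strand == "+" else rc
    cols = _build_columns(mir, seq, i, variant, g)
    if strand == "-":
        for c in cols:
            if c.target_pos is not None:
                c.target_pos = L + 1 - c.target_pos
    score = score_columns(cols, params)
    tpos = [c.target_pos for c in cols if c.target_pos is not None]
    span = (max(tpos), min(tpos)) if strand == "+" else (min(tpos), max(tpos))
    return TargetHit(
        mirna_id=mirna_id,
        linc_id=linc_id,
        score=score,
        mirna_span=(1, len(mir)),
        target_span=span,
        columns=cols,
    )


def scan_targets(
    mirnas: Mapping[str, str],
    lincs: Mapping[str, str],
    params: TargetParams | None = None,
) -> list[TargetHit]:
    """Exhaustive antisense window scan of every miRNA against every lincRNA.

    Input sequences may use U; they are uppercased and mapped to DNA.
    miRNAs outside the 18-26 nt length bounds are skipped with a warning.
    """
    params = params or TargetParams()
    hits: list[TargetHit] = []
    for mirna_id in sorted(mirnas):
        mir = mirnas[mirna_id].upper().replace("U", "T")
        if not params.min_mirna_len <= len(mir) <= params.max_mirna_len:
            logger.warning(
                "skipping %s: length %d outside [%d, %d]",
                mirna_id, len(mir), params.min_mirna_len, params.max_mirna_len,
            )
            continue
        for linc_id in sorted(lincs):
            linc = lincs[linc_id].upper().replace("U", "T")
            hit = scan_pair(mirna_id, mir, linc_id, linc, params)
            if hit is not None:
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Rendering

_MATCH_CHAR = {"WC": "|", "wobble": ":", "mismatch": " ", "gap_m": " ", "gap_t": " "}


def render_alignment(hit: TargetHit) -> str:
    """Three-line text block: miRNA 5'->3', match string, target 3'->5'.

    Target coordinates are forward-strand and descend left to right, as the
    pairing is antisense.
    """
    mir_line = "".join(c.mir_base for c in hit.columns)
    match_line = "".join(_MATCH_CHAR[c.state] for c in hit.columns)
    tgt_line = "".join(c.target_base for c in hit.columns)
    left1 = f"miRNA: {hit.mirna_span[0]} "
    left3 = f"lincRNA: {hit.target_span[0]} "
    pad = max(len(left1), len(left3))
    return "\n".join(
        [
            f"{left1:<{pad}}{mir_line} {hit.mirna_span[1]}",
            " " * pad + match_line,
            f"{left3:<{pad}}{tgt_line} {hit.target_span[1]}",
        ]
    )
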