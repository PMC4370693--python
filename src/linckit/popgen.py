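"""Per-locus polymorphism and neutrality analysis across accession panels.

Accession SNPs are applied to a reference locus to form a haplotype
alignment; from it the number of segregating sites S, the nucleotide
diversity pi (per site) and the mean number of pairwise differences k_hat
are computed, and Tajima's D contrasts the pairwise estimator with the
Watterson estimator S/a1.  Significance of D uses the beta-distribution
approximation of its null (D rescaled between its attainable extremes),
and each locus is classified against an empirical 95% confidence interval
of D built from neutral intergenic background loci: significantly negative
D outside the interval indicates recent positive selection, significantly
positive D outside the interval balancing selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SnpRecord
from .simulate import Locus

logger = logging.getLogger(__name__)

SELECTION_CLASSES = (
    "purifying_or_neutral", "positive", "balancing", "significant_within_ci",
)

_VALID = frozenset(b"ACGT")


@dataclass
class LocusAlignment:
    """n accession haplotypes of equal length for one locus."""

    locus_id: str
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.seqs) < 2:
            raise ValueError("alignment needs n >= 2 sequences")
        L = len(self.seqs[0])
        if any(len(s) != L for s in self.seqs):
            raise ValueError("sequences differ in length")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def as_array(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype="S1"
        ).reshape(self.n, self.length)


@dataclass(frozen=True)
class NeutralityConstants:
    """Sample-size-dependent constants of Tajima's test statistic."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "NeutralityConstants":
        if n < 2:
            raise ValueError("need n >= 2")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class LocusPolymorphism:
    locus_id: str
    length: int
    S: int
    pi: float
    k_hat: float
    snps_per_100nt: float
    D: float | None
    p: float | None
    in_background_ci: bool | None
    selection_class: str | None


def apply_snps(
    ref_seq: str,
    snps: Sequence[SnpRecord],
    accessions: Sequence[str],
    locus_id: str = "",
) -> LocusAlignment:
    """One haplotype per accession: the reference with its alt substitutions.

    SNP positions are 1-based within the locus and every SNP's ref allele
    must match the reference sequence.
    """
    by_acc: dict[str, list[SnpRecord]] = {}
    for snp in snps:
        if not 1 <= snp.pos <= len(ref_seq):
            raise ValueError(
                f"{locus_id}: SNP position {snp.pos} outside locus (length {len(ref_seq)})"
            )
        if ref_seq[snp.pos - 1] != snp.ref_base:
            raise ValueError(
                f"{locus_id}: ref mismatch at position {snp.pos}: locus has "
                f"{ref_seq[snp.pos - 1]}, SNP claims {snp.ref_base}"
            )
        by_acc.setdefault(snp.accession_id, []).append(snp)
    seqs = []
    for acc in accessions:
        if acc in by_acc:
            s = list(ref_seq)
            for snp in by_acc[acc]:
                s[snp.pos - 1] = snp.alt_base
            seqs.append("".join(s))
        else:
            seqs.append(ref_seq)
    return LocusAlignment(locus_id, seqs)


def segregating_sites(alignment: LocusAlignment) -> int:
    """Columns with >= 2 distinct bases among A/C/G/T (gaps and N excluded)."""
    arr = alignment.as_array()
    S = 0
    for col in arr.T:
        observed = {b for b in col.tobytes() if b in _VALID}
        if len(observed) >= 2:
            S += 1
    return S


def nucleotide_diversity(alignment: LocusAlignment) -> tuple[float, float]:
    """(pi per site, k_hat total mean pairwise differences).

    Pairwise deletion: sites with a gap or N in either member of a pair are
    excluded for that pair.  pi is the mean over pairs of the per-pair
    proportion of differing sites; k_hat the mean count of differences.
    With complete data pi = k_hat / L, computed via the per-column fast path.
    """
    arr = alignment.as_array()
    n, L = arr.shape
    n_pairs = n * (n - 1) // 2
    valid_mask = np.isin(arr, [b"A", b"C", b"G", b"T"])
    if valid_mask.all():
        # column decomposition: diffs at a column = C(n,2) - sum_b C(c_b,2)
        diff_pairs = 0
        for base in (b"A", b"C", b"G", b"T"):
            c = (arr == base).sum(axis=0)
            diff_pairs -= (c * (c - 1) // 2).sum()
        diff_pairs += L * n_pairs
        k_hat = diff_pairs / n_pairs
        return k_hat / L, k_hat
    total_diffs = 0.0
    total_ratio = 0.0
    used_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid_mask[i] & valid_mask[j]
            comparable = int(both.sum())
            if comparable == 0:
                logger.info(
                    "%s: pair (%d, %d) has no comparable sites, skipped",
                    alignment.locus_id, i, j,
                )
                continue
            diffs = int((arr[i][both] != arr[j][both]).sum())
            total_diffs += diffs
            total_ratio += diffs / comparable
            used_pairs += 1
    if used_pairs == 0:
        return 0.0, 0.0
    return total_ratio / used_pairs, total_diffs / used_pairs


def tajimas_d(
    S: int, k_hat: float, n: int
) -> tuple[float | None, NeutralityConstants]:
    """D = (k_hat - S/a1) / sqrt(e1*S + e2*S*(S-1)); missing when S = 0."""
    const = NeutralityConstants.from_n(n)
    if S == 0:
        return None, const
    var = const.e1 * S + const.e2 * S * (S - 1)
    return float((k_hat - S / const.a1) / math.sqrt(var)), const


def d_extremes(n: int) -> tuple[float, float]:
    """Attainable extremes of D for a sample of n sequences.

    The lower bound is reached when every variant is a singleton, the upper
    when every variant is at 50% frequency (many sites, S -> infinity).
    """
    const = NeutralityConstants.from_n(n)
    d_min = (2.0 / n - 1.0 / const.a1) / math.sqrt(const.e2)
    d_max = ((n + 1) / (2.0 * n) - 1.0 / const.a1) / math.sqrt(const.e2)
    return d_min, d_max


def d_pvalue(D: float, n: int) -> float:
    """Two-tailed significance of D under its beta-distribution null.

    D is rescaled to [0, 1] between its attainable minimum and maximum and
    compared against a beta law whose shape parameters give the null mean 0
    and variance 1; p = 2 * min(F(D), 1 - F(D)).
    """
    a, b = d_extremes(n)
    ab = a * b
    alpha_shape = -(1.0 + ab) * b / (b - a)
    beta_shape = (1.0 + ab) * a / (b - a)
    if alpha_shape <= 0 or beta_shape <= 0:
        raise ValueError(f"beta approximation unavailable for n={n}")
    x = (min(max(D, a), b) - a) / (b - a)
    # density proportional to (b - D)^(alpha-1) (D - a)^(beta-1)
    cdf = float(stats.beta.cdf(x, beta_shape, alpha_shape))
    return min(1.0, 2.0 * min(cdf, 1.0 - cdf))


def empirical_ci(
    background_d: Iterable[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Percentile interval (linear interpolation) and mean of background D."""
    values = np.array([d for d in background_d if d is not None], dtype=float)
    if len(values) < 40:
        raise ValueError(f"need >= 40 background D values, got {len(values)}")
    tail = 100.0 * (1.0 - level) / 2.0
    lower, upper = np.percentile(values, [tail, 100.0 - tail])
    return float(lower), float(upper), float(values.mean())


def classify_selection(
    D: float | None, p: float | None, ci: tuple[float, float]
) -> str | None:
    """Selection class from D's significance and its position vs the CI."""
    if D is None or p is None:
        return None
    if p >= 0.05:
        return "purifying_or_neutral"
    lower, upper = ci[0], ci[1]
    if D < lower:
        return "positive"
    if D > upper:
        return "balancing"
    return "significant_within_ci"


def neutral_type_one_error(
    n: int = 20,
    expected_s: float = 10.0,
    n_loci: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of :func:`d_pvalue` under a neutral coalescent null.

    Simulates ``n_loci`` non-recombining neutral loci (standard coalescent,
    infinite sites, theta chosen so E[S] = ``expected_s``) and returns the
    fraction rejected at level ``alpha``.  The genealogical correlation of
    sites is what gives D its unit-variance null; a check against
    independent-site frequency draws would be far too conservative.
    """
    import msprime

    const = NeutralityConstants.from_n(n)
    theta = expected_s / const.a1
    rejected = 0
    total = 0
    replicates = msprime.sim_ancestry(
        samples=n, ploidy=1, sequence_length=1000,
        num_replicates=n_loci, random_seed=seed % (2**31 - 1) + 1,
    )
    for k, ts in enumerate(replicates, start=1):
        mts = msprime.sim_mutations(
            ts,
            rate=theta / (2 * 1000),
            random_seed=(seed * 1_000_003 + k) % (2**31 - 1) + 1,
            discrete_genome=False,
        )
        S = mts.num_sites
        if S == 0:
            continue
        k_hat = float(mts.diversity(span_normalise=False, mode="site"))
        D, _ = tajimas_d(S, k_hat, n)
        total += 1
        if d_pvalue(D, n) < alpha:
            rejected += 1
    return rejected / total


# ---------------------------------------------------------------------------
# Locus-set drivers


def analyze_locus(
    locus: Locus,
    snps: Sequence[SnpRecord],
    accessions: Sequence[str],
    ci: tuple[float, float] | None = None,
) -> LocusPolymorphism:
    aln = apply_snps(locus.ref_seq, snps, accessions, locus.locus_id)
    S = segregating_sites(aln)
    pi, k_hat = nucleotide_diversity(aln)
    D, _ = tajimas_d(S, k_hat, aln.n)
    p = d_pvalue(D, aln.n) if D is not None else None
    in_ci = None
    sel = None
    if ci is not None and D is not None:
        in_ci = ci[0] <= D <= ci[1]
        sel = classify_selection(D, p, ci)
    return LocusPolymorphism(
        locus_id=locus.locus_id,
        length=aln.length,
        S=S,
        pi=pi,
        k_hat=k_hat,
        snps_per_100nt=100.0 * S / aln.length,
        D=D,
        p=p,
        in_background_ci=in_ci,
        selection_class=sel,
    )


def selection_scan(
    loci: Sequence[Locus],
    background_loci: Sequence[Locus],
    snps: Sequence[SnpRecord],
    accessions: Sequence[str],
) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """Classify loci against the empirical D interval of background loci.

    Returns (per-locus table in the published-table column layout, the
    (lower, upper, mean) of the background distribution).
    """
    by_locus: dict[str, list[SnpRecord]] = {}
    for snp in snps:
        by_locus.setdefault(snp.chrom_id, []).append(snp)
    background_d = []
    for locus in background_loci:
        res = analyze_locus(locus, by_locus.get(locus.locus_id, ()), accessions)
        if res.D is not None:
            background_d.append(res.D)
    ci = empirical_ci(background_d)
    rows = []
    for locus in loci:
        res = analyze_locus(
            locus, by_locus.get(locus.locus_id, ()), accessions, ci=(ci[0], ci[1])
        )
        rows.append(
            (
                res.locus_id, res.length, res.S, res.pi, res.D, res.p,
                res.in_background_ci, res.selection_class, res.snps_per_100nt,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "locus_id", "length", "S", "pi", "tajimas_d", "p_value",
            "within_ci", "selection_class", "snps_per_100nt",
        ],
    )
    return table, ci
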