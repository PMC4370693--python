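"""Expression quantification and tissue-specificity analysis.

Abundance is expressed as RPKM (reads per kilobase of transcript per million
mapped reads).  Genes are classed by their maximum expression across tissues,
scored with the tissue-specificity index tau = sum_i(1 - exp_i/exp_max)/(n-1)
(0 for uniformly expressed genes, 1 for single-tissue genes), and the
lincRNA-vs-mRNA abundance distributions are compared per tissue with a
two-sample Kolmogorov-Smirnov test plus kernel-density curves for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TAU_SPECIFIC_CUTOFF = 0.9

EXPRESSION_CLASSES = ["low", "moderate", "high", "very_high"]


@dataclass
class ExpressionMatrix:
    """Genes x tissues RPKM values with per-gene type labels."""

    values: pd.DataFrame  # genes x tissues, RPKM
    gene_types: pd.Series  # gene -> {"lincRNA", "mRNA"}
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("RPKM values must be nonnegative")
        self.gene_types = self.gene_types.reindex(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TissueSpecificity:
    gene_id: str
    tau: float | None
    peak_tissue: str | None
    specific: bool


def compute_rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM = count * 1e9 / (library_size * length_nt).

    ``library_sizes`` defaults to the per-tissue column sums of ``counts``.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:3]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return (
        counts.astype(float) * 1e9
    ).div(library_sizes, axis=1).div(lengths.astype(float), axis=0)


def classify_expression(exp_max: float, convention: str = "results") -> str:
    """Class of a gene from its maximum RPKM across tissues.

    ``results`` convention: low <=5 < moderate <=10 < high <=20 < very_high.
    ``methods`` convention shifts the boundaries to half-open-from-below
    intervals (low <5, moderate [5,10), high [10,20), very_high >=20).
    """
    if exp_max < 0:
        raise ValueError("exp_max must be nonnegative")
    if convention == "results":
        if exp_max <= 5:
            return "low"
        if exp_max <= 10:
            return "moderate"
        if exp_max <= 20:
            return "high"
        return "very_high"
    if convention == "methods":
        if exp_max < 5:
            return "low"
        if exp_max < 10:
            return "moderate"
        if exp_max < 20:
            return "high"
        return "very_high"
    raise ValueError(f"unknown convention {convention!r}")


def tissue_specificity_index(
    profile: pd.Series | np.ndarray,
    gene_id: str = "",
) -> TissueSpecificity:
    """tau = sum_i (1 - exp_i / exp_max) / (n - 1); peak tissue = argmax.

    tau is 0 for a flat profile and 1 for expression confined to a single
    tissue.  An all-zero profile has no defined tau (returned as None).
    """
    if isinstance(profile, pd.Series):
        values = profile.to_numpy(dtype=float)
        names = list(profile.index)
    else:
        values = np.asarray(profile, dtype=float)
        names = [str(i) for i in range(len(values))]
    if len(values) < 2:
        raise ValueError("tau needs at least 2 tissues")
    if (values < 0).any():
        raise ValueError("expression values must be nonnegative")
    exp_max = values.max()
    if exp_max == 0:
        return TissueSpecificity(gene_id, None, None, False)
    tau = float(np.sum(1.0 - values / exp_max) / (len(values) - 1))
    peak = names[int(np.argmax(values))]  # first index on ties
    return TissueSpecificity(gene_id, tau, peak, tau > TAU_SPECIFIC_CUTOFF)


def tissue_specificity_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene tau/peak/specific table over the whole matrix."""
    rows = []
    for gene_id, profile in matrix.values.iterrows():
        ts = tissue_specificity_index(profile, gene_id)
        rows.append((gene_id, ts.tau, ts.peak_tissue, ts.specific))
    return pd.DataFrame(
        rows, columns=["gene_id", "tau", "peak_tissue", "specific"]
    ).set_index("gene_id")


@dataclass
class KsComparison:
    tissue: str
    statistic: float
    p_value: float
    #: evaluation grid and the two Gaussian-KDE curves, for plotting
    grid: np.ndarray = field(repr=False, default=None)
    linc_density: np.ndarray = field(repr=False, default=None)
    mrna_density: np.ndarray = field(repr=False, default=None)


def compare_linc_mrna_expression(
    matrix: ExpressionMatrix, tissue: str, n_grid: int = 256
) -> KsComparison:
    """Two-sample KS test of lincRNA vs mRNA expression in one tissue."""
    col = matrix.values[tissue]
    linc = col[matrix.gene_types == "lincRNA"].to_numpy(dtype=float)
    mrna = col[matrix.gene_types == "mRNA"].to_numpy(dtype=float)
    for name, vals in (("lincRNA", linc), ("mRNA", mrna)):
        if len(vals) < 2:
            raise ValueError(f"fewer than 2 {name} values in tissue {tissue!r}")
        if np.ptp(vals) == 0:
            raise ValueError(f"degenerate (constant) {name} sample in {tissue!r}")
    stat, p = stats.ks_2samp(linc, mrna, method="asymp")
    grid = np.linspace(
        min(linc.min(), mrna.min()), max(linc.max(), mrna.max()), n_grid
    )
    return KsComparison(
        tissue=tissue,
        statistic=float(stat),
        p_value=float(p),
        grid=grid,
        linc_density=stats.gaussian_kde(linc)(grid),
        mrna_density=stats.gaussian_kde(mrna)(grid),
    )
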