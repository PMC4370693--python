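"""Expression classes, tissue specificity and lincRNA-vs-mRNA comparison.

Quantifies the synthetic ten-tissue expression matrix as RPKM, classes each
gene by its peak expression, computes the tissue-specificity index tau
(0 = uniform, 1 = single-tissue; > 0.9 called tissue-specific), and compares
the lincRNA and mRNA abundance distributions with a Kolmogorov-Smirnov test.
"""

from collections import Counter

from linckit.expression import (
    classify_expression,
    compare_linc_mrna_expression,
    tissue_specificity_table,
)
from linckit.simulate import SimulationConfig, generate_dataset

ds = generate_dataset(SimulationConfig(seed=1))
matrix = ds.expression.matrix

exp_max = matrix.values.max(axis=1)
classes = Counter(classify_expression(v) for v in exp_max)
print("expression classes (by peak RPKM):", dict(classes))

tau = tissue_specificity_table(matrix)
specific = tau[tau["specific"].fillna(False)]
print(f"tissue-specific genes (tau > 0.9): {len(specific)}"
      f" (planted single-tissue: {len(ds.expression.planted_specific)})")
print(specific[["tau", "peak_tissue"]].head(6).to_string())

ks = compare_linc_mrna_expression(matrix, matrix.tissue_ids[0])
print(f"\nKS lincRNA vs mRNA in {ks.tissue}: D = {ks.statistic:.3f}, "
      f"p = {ks.p_value:.2e}")
# A small p confirms the planted condition that lincRNAs sit lower in the
# abundance distribution than mRNAs.
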