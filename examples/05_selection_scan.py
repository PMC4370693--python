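"""Tajima's-D selection scan against an empirical intergenic background.

Applies the 102-accession SNPs to every lincRNA locus and to 500 neutral
intergenic background loci, computes S, pi and Tajima's D per locus, builds
the background's empirical 95% interval of D, and classifies each lincRNA:
significantly negative D outside the interval = positive selection,
significantly positive D outside = balancing selection.
"""

from linckit.popgen import selection_scan
from linckit.simulate import SimulationConfig, generate_dataset

ds = generate_dataset(SimulationConfig(seed=1))
linc_loci = [l for l in ds.loci if not l.locus_id.startswith("bg")]
background = [l for l in ds.loci if l.locus_id.startswith("bg")]

table, (lower, upper, mean) = selection_scan(
    linc_loci, background, ds.snps, ds.accessions
)
print(f"background (n={len(background)} loci): mean D = {mean:.3f}, "
      f"95% interval ({lower:.3f}, {upper:.3f})")

selected = table[table["selection_class"].isin(["positive", "balancing"])]
print(f"\nloci outside the interval with p < 0.05: {len(selected)}")
print(
    selected[["locus_id", "length", "S", "pi", "tajimas_d", "selection_class"]]
    .to_string(index=False)
)
# The generator plants three rare-variant-excess loci (recovered as
# 'positive', D << 0) and three intermediate-frequency loci ('balancing',
# D >> 0); the remaining loci carry neutral variation.
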