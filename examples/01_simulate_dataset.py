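"""Simulate one genotype/phenotype dataset and inspect its structure.

One SNP at allele-A frequency 0.3 under Hardy-Weinberg equilibrium, ten
traits with pairwise correlation 0.5, and a multiplicative genotype effect
delta=1.2 on every trait mean (BB/AB/AA group means 1, 1.2, 1.44).
"""

import numpy as np

import multiphen as mp

config = mp.SimulationConfig(
    allele_freq=0.3, n_samples=300, n_phenotypes=10,
    effect_size=1.2, correlation=0.5, seed=42,
)
genotypes, phenotypes = mp.simulate_dataset(config)

freqs = np.bincount(genotypes.counts, minlength=3) / config.n_samples
print("genotype frequencies (BB, AB, AA):", np.round(freqs[::-1], 3))
print("expected under HWE:              ", mp.hwe_genotype_probs(0.3))

for count, label in ((0, "BB"), (1, "AB"), (2, "AA")):
    group = phenotypes.values[genotypes.counts == count]
    print(f"mean trait value in {label}: {group.mean():.3f} "
          f"(model: {mp.genotype_mean(count, config.effect_size):.2f})")

corr = np.corrcoef(phenotypes.values, rowvar=False)
off = corr[np.triu_indices(10, k=1)]
print(f"mean pairwise trait correlation: {off.mean():.3f} (model: 0.5)")
# The genotype groups differ in mean by the multiplicative delta model and
# the traits share a common equicorrelation, the two ingredients every
# association strategy below has to contend with.
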