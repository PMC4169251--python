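"""Test whether QTLs for a second phenotype are also meQTLs.

A set of SNPs known to drive a linked quantitative trait is tested for
association with methylation at probes within 3 kb, and the observed
proportion significant is compared with a matched-permutation null
(random SNP sets of the same size drawn from all testable SNPs).
"""

from methqtl.overlap import enrichment_analysis
from methqtl.preprocess import quantile_normalize
from methqtl.simulate import (
    SimConfig,
    simulate_genotypes,
    simulate_linked_phenotype,
    simulate_methylation,
)

cfg = SimConfig(
    n_samples=64, n_probes=500, n_snps=600, region_length=500_000,
    causal_fraction=0.06, effect_size=1.5, regional_effect_span=0, seed=3,
)
geno = simulate_genotypes(cfg)
beta, manifest, truth = simulate_methylation(geno, cfg)
norm = quantile_normalize(beta)

pheno = simulate_linked_phenotype(geno, truth, effect=1.0, noise_sd=0.5, seed=4)
fg = sorted({pheno.snp_of_trait[t] for t in pheno.values})

res = enrichment_analysis(
    fg, norm, geno, manifest, window=3000, fdr=0.10, B=999, seed=5,
    label="linked-trait QTLs",
)
print(f"foreground SNPs tested:      {res.n_tested}")
print(f"proportion significant:      {res.prop_significant:.1%}")
print(f"mean proportion, null draws: {res.null_mean:.1%}")
print(f"empirical P (B={res.B}):      {res.empirical_p:.4g}")
print(f"directions (+/-):            {res.n_positive}/{res.n_negative}")
print()
print("Shared-QTL SNPs hit methylation far more often than matched random")
print("SNPs; the empirical P uses the add-one (b+1)/(B+1) rule.")
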