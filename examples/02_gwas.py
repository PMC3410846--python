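"""Breed-average GWAS: linear scan for discovery, mixed model for
relatedness control.

Each dog carries its breed-sex average shape phenotype; the linear scan
is powerful but inflated by breed structure, the kinship-corrected mixed
model is calibrated.
"""

import numpy as np

from cranioscan.association import (assign_phenotypes, bonferroni_threshold,
                                    kinship, linear_assoc, lmm_assoc, snp_qc)
from cranioscan.simulate import SimConfig, simulate_genotypes_and_trait

cfg = SimConfig(seed=1)
study = simulate_genotypes_and_trait(cfg)

G = snp_qc(study.genotypes)                    # missingness < 0.10, MAF > 0.01
Gp, y, size = assign_phenotypes(G, study.phenotypes)
print(f"{Gp.n_individuals} dogs x {Gp.n_markers} SNPs after QC")

lin = linear_assoc(Gp, y, covariates=size.reshape(-1, 1))
mix = lmm_assoc(Gp, y, kinship(Gp), covariates=size.reshape(-1, 1))
thr = bonferroni_threshold(0.05, Gp.n_markers)
print(f"Bonferroni cutoff: -log10(p) >= {thr:.2f}")
print(f"inflation lambda_GC: linear {lin.genomic_inflation():.2f}, "
      f"mixed {mix.genomic_inflation():.2f}")

qtls = study.genotypes.markers.iloc[study.qtl_indices]
print("planted QTLs:", [f"{r.chrom}:{r.pos}" for r in qtls.itertuples()])
top = lin.markers.nlargest(5, "neg_log10_p")[["chrom", "pos", "neg_log10_p"]]
print("top linear-scan markers:")
print(top.to_string(index=False))
n_hit = (lin.markers.merge(qtls[["chrom", "pos"]])["neg_log10_p"] >= thr).sum()
print(f"planted QTLs surpassing Bonferroni in the linear scan: {n_hit}/5")
# the linear scan recovers most planted QTLs; the mixed model's lambda ~1
# shows breed relatedness is absorbed by the kinship random effect.
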