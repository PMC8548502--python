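"""Population-genomic divergence contrasts between plasticity classes.

Filters SNPs (quality >= 20, MAF >= 5%, missingness < 20%), estimates
per-SNP Weir-Cockerham FST between forest and urban habitats, and
contrasts the adaptive / maladaptive candidate SNP sets against the
transcriptome background: outlier enrichment beyond the empirical 95th
percentile, mean-FST Welch test, windowed LD decay, Hardy-Weinberg
deviations, and annotation-class enrichment.
"""

import pandas as pd

from plastisel.popgen import (annotation_class_enrichment, filter_variants,
                              fst_outlier_enrichment, hwe_scan,
                              ld_set_comparison, mean_fst_contrast,
                              multilocus_theta, pairwise_ld,
                              weir_cockerham_fst)
from plastisel.simulate import (GeneratorConfig, generate_expression_dataset,
                                generate_variant_dataset)

config = GeneratorConfig(n_genes=600, n_candidates=150, n_snps=6000, seed=17)
samples, _, truth = generate_expression_dataset(config)
variants = generate_variant_dataset(config, truth, samples)
variants, report = filter_variants(variants)
print(f"SNP filter: {report['n_retained']}/{report['n_input']} retained")

forest = list(samples.index[samples.habitat == "forest"])
urban = list(samples.index[samples.habitat == "urban"])
scan = weir_cockerham_fst(variants, forest, urban, sigma_bp=50_000)
theta = scan.theta
snps = variants.snps
sets = {label: snps.index[snps.set_label == label]
        for label in ("background", "candidate_adaptive",
                      "candidate_maladaptive")}

fi = variants.sample_indices(forest)
ui = variants.sample_indices(urban)
for label, idx in sets.items():
    multi = multilocus_theta(variants.genotypes, fi, ui,
                             snp_mask=snps.set_label.eq(label).to_numpy())
    print(f"{label}: per-SNP mean theta = {theta.loc[idx].mean():.4f}, "
          f"multi-locus = {multi:.4f} "
          f"(planted {truth.planted_fst[label]:.2f})")

for label in ("candidate_adaptive", "candidate_maladaptive"):
    enr = fst_outlier_enrichment(theta, sets[label], sets["background"])
    print(f"{label}: {100 * enr['outlier_proportion']:.1f}% beyond the "
          f"background 95th percentile (expected 5%), p = {enr['p']:.2e}")

welch = mean_fst_contrast(theta, sets["candidate_maladaptive"],
                          sets["candidate_adaptive"])
print(f"maladaptive vs adaptive mean FST: {welch['mean_x']:.4f} vs "
      f"{welch['mean_y']:.4f}, Welch p = {welch['p']:.2e}")

pairs = pairwise_ld(variants.subset_samples(forest), window_bp=10_000)
ld = ld_set_comparison(pairs, n_perm=300, seed=17)
print(f"forest LD: candidate mean r2 = {ld['mean_r2_candidate']:.3f} vs "
      f"background {ld['mean_r2_background']:.3f}, "
      f"gene-permutation p = {ld['empirical_p']:.4f}")

pops = {m: list(samples.index[samples.municipality == m])
        for m in sorted(samples.municipality.unique())}
_, hwe = hwe_scan(variants, pops)
for pop, rep in hwe.items():
    print(f"HWE deviants in {pop}: candidate "
          f"{100 * rep['prop_deviant_candidate']:.1f}% vs background "
          f"{100 * rep['prop_deviant_background']:.1f}%, p = {rep['p']:.3f}")

for label, klass in (("candidate_adaptive", "nonsynonymous"),
                     ("candidate_maladaptive", "noncoding")):
    enr = annotation_class_enrichment(variants, label, klass)
    print(f"{klass} in {label}: {100 * enr['prop_focal']:.1f}% vs background "
          f"{100 * enr['prop_background']:.1f}%, p = {enr['p']:.2e}")
# Elevated divergence, LD and HWE deviation at maladaptive-plasticity
# genes, with noncoding enrichment, is the cis-regulatory-selection
# signature; nonsynonymous enrichment at adaptive genes points to coding
# targets.
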