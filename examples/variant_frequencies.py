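"""Population-stratified variant-allele frequencies and functional classes.

Simulates a cohort, extracts genotypes at the pharmacogenomic variants, and
computes: per-population variant-allele frequencies (MAF), the max-minus-min
frequency spread across ancestral groups (a differentiation measure), the
"extreme" variants that are common (>=0.1) in one population yet rare
(<=0.005) in another, and SIFT/PolyPhen functional classes.
"""

import tempfile

from popgx import (classify_variants, compute_maf, default_config, delta_maf,
                   extract_genotypes, filter_extreme_variants,
                   load_population_map, load_variant_annotations,
                   simulate_cohort)

with tempfile.TemporaryDirectory() as workdir:
    cfg = default_config(seed=1, n_per_pop=300)
    out = simulate_cohort(cfg, workdir)
    popmap = load_population_map(out.panel_path)
    defs = load_variant_annotations(out.annotation_path)
    gm = extract_genotypes(out.vcf_path, defs, popmap)

    maf_pop = compute_maf(gm, "population")
    maf_grp = compute_maf(gm, "group")
    print("variant-allele frequency by population (first 5 variants):")
    print(maf_pop.values.head().round(3).to_string())

    spread = delta_maf(maf_grp).sort_values(ascending=False)
    print("\nmost population-differentiated variants "
          "(max - min group frequency):")
    print(spread.head(3).round(3).to_string())

    extreme = filter_extreme_variants(maf_pop)
    print(f"\nvariants common (>=0.1) in one population and rare (<=0.005) "
          f"in another: {sorted(extreme)}")

    classes = classify_variants(gm.variants)
    print("\nfunctional class tally (from SIFT/PolyPhen scores):")
    print(classes.value_counts().to_string())
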