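"""Generate a synthetic phased cohort and inspect its ground truth.

Builds the reference scenario — 5 populations (YRI, LWK, CEU, TSI, CHB) in 3
ancestral groups, 3 genes — writes the VCF/panel/annotation/translation-table
bundle, and prints the generating haplotype frequencies for one gene.  These
are the values the downstream analyses are expected to recover.
"""

import tempfile

from popgx import default_config, simulate_cohort

with tempfile.TemporaryDirectory() as workdir:
    cfg = default_config(seed=1, n_per_pop=100)
    out = simulate_cohort(cfg, workdir)
    print(f"VCF:        {out.vcf_path}")
    print(f"panel:      {out.panel_path}")
    print(f"annotation: {out.annotation_path}")
    print(f"tables:     {sorted(out.table_paths)}")

    gene = cfg.genes[0].table.gene
    print(f"\ngenerating haplotype frequencies for {gene} "
          f"(what HAF estimation should recover):")
    for pop, freqs in out.truth.hap_freqs[gene].items():
        pretty = ", ".join(f"{h}={f:.3f}" for h, f in freqs.items())
        print(f"  {pop}: {pretty}")
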