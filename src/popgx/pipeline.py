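"""End-to-end orchestration: variant -> haplotype -> phenotype stages.

The pipeline reads a phased VCF, a sample panel, a variant annotation table
and a directory of translation tables, and writes population-stratified
frequency tables, diplotype calls, phenotype distributions and (optionally)
the standard report figures, each with a TSV twin holding the plotted
numbers.  All tabular outputs are deterministic functions of the inputs.
"""

from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import haplotypes as hap
from . import phenotypes as phe
from . import variants as var
from .errors import PipelineError
from .genotype import extract_genotypes, load_population_map, load_variant_annotations
from .translation import TranslationTable, parse_translation_table, restrict_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, output directory and analysis thresholds for one run."""

    vcf: str
    panel: str
    annotation: str
    tables_dir: str
    out_dir: str
    level: str = "population"
    common_thr: float = 0.1          # "common" frequency cutoff
    rare_thr: float = 0.005          # "rare" frequency cutoff
    rare_class_thr: float = 0.05     # summary cutoff for calling a variant rare
    sift_thr: float = 0.05
    polyphen_thr: float = 0.2
    coverage_thr: float = 0.9        # phenotype assignment coverage gate
    hi: float = 0.8                  # high-difference phenotype frequency
    lo: float = 0.2
    top_k: int = 10                  # variants shown in the spread chart
    figures: bool = True

    def validate(self) -> None:
        for name in ("common_thr", "rare_thr", "rare_class_thr", "sift_thr",
                     "polyphen_thr", "coverage_thr", "hi", "lo"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.hi <= self.lo:
            raise ValueError("hi threshold must exceed lo threshold")
        if self.level not in ("population", "group", "global"):
            raise ValueError(f"unknown level {self.level!r}")


@dataclass
class ReportBundle:
    """Paths of everything a run wrote, keyed by artifact name."""

    out_dir: str
    tables: dict[str, str] = field(default_factory=dict)
    figures: dict[str, str] = field(default_factory=dict)
    log_path: str = ""


def load_tables(tables_dir: str) -> dict[str, TranslationTable]:
    paths = sorted(glob.glob(os.path.join(tables_dir, "*.tsv")))
    if not paths:
        raise FileNotFoundError(f"no translation tables (*.tsv) in {tables_dir}")
    return {t.gene: t for t in (parse_translation_table(p) for p in paths)}


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Run all three analysis stages and write the report bundle."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    bundle = ReportBundle(out_dir=cfg.out_dir)
    log_lines: list[str] = []

    def out(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    def save(df: pd.DataFrame | pd.Series, name: str, **kwargs) -> str:
        path = out(name)
        df.to_csv(path, sep="\t", float_format="%.6g", **kwargs)
        bundle.tables[name] = path
        return path

    # ---- load stage ----------------------------------------------------
    try:
        popmap = load_population_map(cfg.panel)
        defs = load_variant_annotations(cfg.annotation)
        tables = load_tables(cfg.tables_dir)
        gm = extract_genotypes(cfg.vcf, defs, popmap)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    rep = gm.report
    log_lines += [
        f"samples: {len(gm.samples)} ({len(rep.dropped_samples)} dropped, "
        f"not in panel)",
        f"variants requested: {len(defs)}; resolved: {len(rep.resolved)}; "
        f"flipped orientation: {len(rep.flipped)}; "
        f"allele mismatch (excluded): {len(rep.allele_mismatch)}; "
        f"not found: {len(rep.not_found)}",
    ]

    # ---- variant stage -------------------------------------------------
    try:
        maf_pop = var.compute_maf(gm, "population")
        maf_grp = var.compute_maf(gm, "group")
        maf_all = var.compute_maf(gm, "global")
        classes = var.classify_variants(
            gm.variants, sift_thr=cfg.sift_thr, polyphen_thr=cfg.polyphen_thr)
        dmaf = var.delta_maf(maf_grp)
        extreme_v = var.filter_extreme_variants(
            maf_pop, common_thr=cfg.common_thr, rare_thr=cfg.rare_thr)
        profile = var.common_damaging_profile(maf_pop, classes,
                                              thr=cfg.common_thr)
        rare_frac = var.fraction_rare(maf_all, thr=cfg.rare_class_thr)
    except Exception as exc:
        raise PipelineError("variant", str(exc)) from exc

    save(maf_pop.values, "maf_population.tsv")
    save(maf_pop.denominators, "maf_population_denominators.tsv")
    save(maf_grp.values, "maf_group.tsv")
    save(maf_all.values, "maf_global.tsv")
    cls_frame = pd.DataFrame({
        "sift": {d.rsid: "" if d.sift is None else d.sift for d in gm.variants},
        "polyphen": {d.rsid: "" if d.polyphen is None else d.polyphen
                     for d in gm.variants},
        "class": classes})
    cls_frame.index.name = "rsid"
    save(cls_frame, "classification.tsv")
    save(dmaf, "delta_maf.tsv", header=True)
    save(pd.Series(sorted(extreme_v), name="rsid"), "extreme_variants.tsv",
         index=False)
    save(profile, "common_damaging.tsv")
    log_lines.append(
        f"variant stage: {len(extreme_v)} extreme variants "
        f"(common>={cfg.common_thr}, rare<={cfg.rare_thr}); global fraction "
        f"rare (MAF<={cfg.rare_class_thr}): {float(rare_frac.iloc[0]):.3f}")

    # ---- haplotype stage -------------------------------------------------
    try:
        available = set(gm.rsids)
        calls = []
        restricted: dict[str, TranslationTable] = {}
        for gene, table in tables.items():
            try:
                rt = restrict_table(table, available)
            except Exception as exc:
                log_lines.append(f"haplotype stage: {gene} skipped ({exc})")
                continue
            dropped = set(table.haplotype_names) - {
                n for name in rt.haplotype_names for n in name.split("|")}
            if dropped:
                log_lines.append(
                    f"haplotype stage: {gene}: dropped at restriction: "
                    f"{sorted(dropped)}")
            restricted[gene] = rt
            calls.extend(hap.call_diplotypes(gm, rt, restrict=False))
        if not calls:
            raise ValueError("no gene produced diplotype calls")
        unm = hap.unmatched_rate(calls, popmap, level="population")
        haf_pop = hap.haplotype_frequency(calls, popmap, "population",
                                          tables=restricted)
        haf_grp = hap.haplotype_frequency(calls, popmap, "group",
                                          tables=restricted)
        extreme_h = hap.filter_extreme_haplotypes(
            haf_pop, common_thr=cfg.common_thr, rare_thr=cfg.rare_thr)
        span = hap.population_span(haf_pop)
        hist = hap.span_histogram(span, n_populations=len(popmap.populations))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("haplotype", str(exc)) from exc

    save(unm, "unmatched_rate.tsv")
    save(haf_pop.values, "haf_population.tsv")
    save(haf_pop.denominators, "haf_population_denominators.tsv")
    save(haf_grp.values, "haf_group.tsv")
    save(pd.Series(sorted(extreme_h), name="haplotype"),
         "extreme_haplotypes.tsv", index=False)
    save(span, "population_span.tsv", header=True)
    log_lines.append(
        f"haplotype stage: {len(extreme_h)} extreme haplotypes; "
        f"{hist['matched_all']:.0%} of observed haplotypes present in all "
        f"populations, {hist['matched_one']:.0%} in exactly one")

    # ---- phenotype stage -------------------------------------------------
    try:
        phe.assign_phenotypes(calls, restricted)
        dist = phe.phenotype_distribution(calls, popmap)
        hi_genes = phe.high_difference_genes(
            dist, coverage_thr=cfg.coverage_thr, hi=cfg.hi, lo=cfg.lo)
    except Exception as exc:
        raise PipelineError("phenotype", str(exc)) from exc

    diplo_path = out("diplotypes.tsv")
    hap.write_diplotype_calls(calls, diplo_path)
    bundle.tables["diplotypes.tsv"] = diplo_path
    pheno_path = out("phenotype_distribution.tsv")
    phe.write_phenotype_distribution(dist, pheno_path)
    bundle.tables["phenotype_distribution.tsv"] = pheno_path
    save(pd.Series(sorted(hi_genes), name="gene"),
         "high_difference_genes.tsv", index=False)
    log_lines.append(
        f"phenotype stage: {len(hi_genes)} genes pass the coverage "
        f">={cfg.coverage_thr} and {cfg.hi:.0%}/{cfg.lo:.0%} difference gates")

    # ---- figures ---------------------------------------------------------
    if cfg.figures:
        try:
            from . import plots

            extreme_rows = [r for r in maf_pop.items if r in extreme_v]
            if extreme_rows:
                path = out("fig_maf_heatmap.png")
                plots.frequency_heatmap(
                    maf_pop.values.loc[extreme_rows], path,
                    "extreme variants: frequency by population")
                bundle.figures["fig_maf_heatmap.png"] = path
            path = out("fig_delta_maf.png")
            plots.delta_maf_chart(maf_grp.values, dmaf, path, top_k=cfg.top_k)
            bundle.figures["fig_delta_maf.png"] = path

            chrom_counts = (
                pd.DataFrame({"chrom": [d.chrom for d in gm.variants],
                              "class": [classes[d.rsid] for d in gm.variants]})
                .value_counts().unstack(fill_value=0).sort_index())
            save(chrom_counts, "class_by_chromosome.tsv")
            path = out("fig_class_by_chromosome.png")
            plots.class_by_chromosome(chrom_counts, path)
            bundle.figures["fig_class_by_chromosome.png"] = path

            path = out("fig_unmatched_rate.png")
            plots.unmatched_rate_chart(unm, path)
            bundle.figures["fig_unmatched_rate.png"] = path

            extreme_hrows = [r for r in haf_pop.items if r in extreme_h]
            if extreme_hrows:
                path = out("fig_haf_heatmap.png")
                plots.frequency_heatmap(
                    haf_pop.values.loc[extreme_hrows], path,
                    "extreme haplotypes: frequency by population")
                bundle.figures["fig_haf_heatmap.png"] = path

            for gene in restricted:
                path = out(f"fig_phenotypes_{gene}.png")
                plots.phenotype_bars(dist.freqs, gene, path)
                bundle.figures[os.path.basename(path)] = path
                path = out(f"fig_track_{gene}.png")
                plots.gene_track(gm.variants, classes, maf_pop.values,
                                 gene, path)
                bundle.figures[os.path.basename(path)] = path
        except Exception as exc:
            raise PipelineError("figures", str(exc)) from exc

    log_path = out("run_log.txt")
    with open(log_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")
    bundle.log_path = log_path
    for line in log_lines:
        logger.info(line)
    return bundle
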