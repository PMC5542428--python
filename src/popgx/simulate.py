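"""Synthetic phased cohorts for pharmacogenomic analyses.

The generator produces everything the pipeline consumes — translation tables,
a phased multi-sample VCF, a sample panel, a variant annotation table — plus
the ground truth that produced them, so every analysis stage can be tested
without external downloads.

Population model: random mating.  Each sample's two strands at a gene are
drawn independently from that population's haplotype-frequency vector.  Any
residual mass (1 - sum of the vector) becomes a "novel haplotype" strand: a
random allele combination rejection-sampled to match no table row, emulating
real cohorts in which translation tables are incomplete.  Missingness and
unphasing noise are applied per genotype after strand assignment.

Reproducibility: every gene draws from its own random substream derived from
(seed, gene index), so adding a gene leaves earlier genes' cohorts untouched,
and the same seed and config yield byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SimulationError
from .genotype import VariantDef
from .translation import TranslationTable, write_translation_table

NOVEL = "NOVEL"
_BASES = "ACGT"


@dataclass(frozen=True)
class PopulationSpec:
    code: str
    group: str
    n_samples: int

    def __post_init__(self):
        if self.n_samples < 1:
            raise SimulationError(f"{self.code}: n_samples must be >= 1")


@dataclass
class SimGene:
    """One simulated gene: its table, variant definitions and frequencies.

    ``hap_freqs`` maps population code -> vector over the table's haplotypes
    (definition order).  Vectors are non-negative and sum to at most 1; the
    residual is the novel-haplotype contamination mass for that population.
    """

    table: TranslationTable
    defs: list[VariantDef]
    hap_freqs: dict[str, np.ndarray]

    def validate(self, populations: list[PopulationSpec]) -> None:
        nh = self.table.n_haplotypes
        if len(self.defs) != len(self.table.variants):
            raise SimulationError(
                f"{self.table.gene}: {len(self.defs)} variant defs for "
                f"{len(self.table.variants)} table columns")
        for d, rsid in zip(self.defs, self.table.variants):
            if d.rsid != rsid:
                raise SimulationError(
                    f"{self.table.gene}: def order mismatch at {d.rsid}")
            if d.ref_allele != self.table.wild_type_allele(rsid):
                raise SimulationError(
                    f"{self.table.gene}:{rsid}: def ref allele differs from "
                    f"the table's wild-type allele")
            alt = self.table.alt_allele(rsid)
            if alt is not None and d.variant_allele != alt:
                raise SimulationError(
                    f"{self.table.gene}:{rsid}: def variant allele differs "
                    f"from the table's alternative allele")
        for pop in populations:
            if pop.code not in self.hap_freqs:
                raise SimulationError(
                    f"{self.table.gene}: no frequency vector for population "
                    f"{pop.code}")
            vec = np.asarray(self.hap_freqs[pop.code], dtype=float)
            if vec.shape != (nh,):
                raise SimulationError(
                    f"{self.table.gene}: frequency vector for {pop.code} has "
                    f"{vec.shape} entries, table has {nh} haplotypes")
            if (vec < 0).any():
                raise SimulationError(
                    f"{self.table.gene}/{pop.code}: negative frequency")
            if vec.sum() > 1 + 1e-9:
                raise SimulationError(
                    f"{self.table.gene}/{pop.code}: frequencies sum to "
                    f"{vec.sum():.4f} > 1")


@dataclass
class SimConfig:
    seed: int
    populations: list[PopulationSpec]
    genes: list[SimGene]
    missing_rate: float = 0.0
    unphase_rate: float = 0.0

    def validate(self) -> None:
        if not self.populations or not self.genes:
            raise SimulationError("need at least one population and one gene")
        for rate, name in ((self.missing_rate, "missing_rate"),
                           (self.unphase_rate, "unphase_rate")):
            if not (0.0 <= rate <= 1.0):
                raise SimulationError(f"{name} must be in [0,1]")
        codes = [p.code for p in self.populations]
        if len(set(codes)) != len(codes):
            raise SimulationError("duplicate population codes")
        for g in self.genes:
            g.validate(self.populations)

    @property
    def sample_names(self) -> list[str]:
        names = []
        for p in self.populations:
            names.extend(f"{p.code}{i:04d}" for i in range(p.n_samples))
        return names


@dataclass
class GroundTruth:
    """What the generator actually drew, keyed for direct comparison."""

    #: (sample, gene) -> pair of haplotype names (or NOVEL), strand order
    strand_haplotypes: dict[tuple[str, str], tuple[str, str]]
    #: gene -> population -> {haplotype: generating frequency}
    hap_freqs: dict[str, dict[str, dict[str, float]]]

    def to_json(self, path: str) -> None:
        payload = {
            "strand_haplotypes": {f"{s}\t{g}": list(v)
                                  for (s, g), v in self.strand_haplotypes.items()},
            "hap_freqs": self.hap_freqs,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SimOutput:
    vcf_path: str
    panel_path: str
    annotation_path: str
    table_paths: dict[str, str]
    truth: GroundTruth


def _gene_rng(seed: int, gene_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, gene_index, stream])


def _novel_vector(rng: np.random.Generator, states: np.ndarray) -> np.ndarray:
    """Random 0/1 strand vector guaranteed to match no table row."""
    nv = states.shape[1]
    if nv == 0:
        raise SimulationError("cannot draw novel strand over zero variants")
    while True:
        vec = rng.integers(0, 2, size=nv, dtype=np.int8)
        if not (states == vec).all(axis=1).any():
            return vec


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def simulate_cohort(cfg: SimConfig, out_dir: str) -> SimOutput:
    """Generate a phased cohort and write all pipeline input files.

    Writes ``cohort.vcf``, ``panel.tsv``, ``annotation.tsv``, one translation
    table per gene under ``tables/`` and ``truth.json`` into ``out_dir``;
    returns the paths and the in-memory ground truth.
    """
    cfg.validate()
    os.makedirs(out_dir, exist_ok=True)
    tables_dir = os.path.join(out_dir, "tables")
    os.makedirs(tables_dir, exist_ok=True)

    samples = cfg.sample_names
    sample_pop = {}
    for p in cfg.populations:
        for i in range(p.n_samples):
            sample_pop[f"{p.code}{i:04d}"] = p.code

    truth_strands: dict[tuple[str, str], tuple[str, str]] = {}
    truth_freqs: dict[str, dict[str, dict[str, float]]] = {}
    # per gene: (S, V, 2) strand states and (S, V) phased flags after noise
    gene_states: list[np.ndarray] = []
    gene_missing: list[np.ndarray] = []
    gene_unphased: list[np.ndarray] = []

    for gi, gene in enumerate(cfg.genes):
        table = gene.table
        nv = len(table.variants)
        states = np.array([table.state_row(h) for h in table.haplotype_names],
                          dtype=np.int8)
        rng = _gene_rng(cfg.seed, gi, 0)
        noise_rng = _gene_rng(cfg.seed, gi, 1)
        S = len(samples)
        calls = np.zeros((S, nv, 2), dtype=np.int8)
        row = 0
        truth_freqs[table.gene] = {}
        for p in cfg.populations:
            vec = np.asarray(gene.hap_freqs[p.code], dtype=float)
            residual = max(0.0, 1.0 - vec.sum())
            probs = np.append(vec, residual)
            probs = probs / probs.sum()
            truth_freqs[table.gene][p.code] = {
                h: float(f) for h, f in zip(table.haplotype_names, vec)}
            draws = rng.choice(len(probs), size=(p.n_samples, 2), p=probs)
            for si in range(p.n_samples):
                names = []
                for strand in range(2):
                    k = draws[si, strand]
                    if k == len(vec):  # novel contamination
                        calls[row, :, strand] = _novel_vector(rng, states)
                        names.append(NOVEL)
                    else:
                        calls[row, :, strand] = states[k]
                        names.append(table.haplotype_names[k])
                truth_strands[(samples[row], table.gene)] = tuple(names)
                row += 1
        missing = noise_rng.random((S, nv)) < cfg.missing_rate
        unphase = noise_rng.random((S, nv)) < cfg.unphase_rate
        gene_states.append(calls)
        gene_missing.append(missing)
        gene_unphased.append(unphase)

    # ---- write panel --------------------------------------------------
    panel_path = os.path.join(out_dir, "panel.tsv")
    with open(panel_path, "w", encoding="utf-8") as fh:
        fh.write("sample\tpopulation\tgroup\n")
        group = {p.code: p.group for p in cfg.populations}
        for s in samples:
            pop = sample_pop[s]
            fh.write(f"{s}\t{pop}\t{group[pop]}\n")

    # ---- write tables and annotation ----------------------------------
    table_paths = {}
    for gene in cfg.genes:
        path = os.path.join(tables_dir, f"{gene.table.gene}.tsv")
        write_translation_table(gene.table, path)
        table_paths[gene.table.gene] = path
    annotation_path = os.path.join(out_dir, "annotation.tsv")
    with open(annotation_path, "w", encoding="utf-8") as fh:
        fh.write("rsid\tgene\tchrom\tpos\tref\tvariant\tsift\tpolyphen\n")
        for gene in cfg.genes:
            for d in gene.defs:
                sift = "" if d.sift is None else f"{d.sift:.4g}"
                poly = "" if d.polyphen is None else f"{d.polyphen:.4g}"
                fh.write(f"{d.rsid}\t{d.gene}\t{d.chrom}\t{d.pos}\t"
                         f"{d.ref_allele}\t{d.variant_allele}\t{sift}\t{poly}\n")

    # ---- write VCF -----------------------------------------------------
    records = []  # (chrom_key, pos, line)
    for gi, gene in enumerate(cfg.genes):
        calls = gene_states[gi]
        missing = gene_missing[gi]
        unphase = gene_unphased[gi]
        for vi, d in enumerate(gene.defs):
            gts = []
            for si in range(len(samples)):
                if missing[si, vi]:
                    gts.append("./.")
                    continue
                a, b = int(calls[si, vi, 0]), int(calls[si, vi, 1])
                sep = "/" if (a != b and unphase[si, vi]) else "|"
                gts.append(f"{a}{sep}{b}")
            line = (f"{d.chrom}\t{d.pos}\t{d.rsid}\t{d.ref_allele}\t"
                    f"{d.variant_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
            records.append((_chrom_key(d.chrom), d.pos, line))
    records.sort(key=lambda r: (r[0], r[1]))
    vcf_path = os.path.join(out_dir, "cohort.vcf")
    chroms = sorted({d.chrom for g in cfg.genes for d in g.defs},
                    key=_chrom_key)
    with open(vcf_path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popgx-simulate\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for _, _, line in records:
            fh.write(line + "\n")

    truth = GroundTruth(strand_haplotypes=truth_strands, hap_freqs=truth_freqs)
    truth.to_json(os.path.join(out_dir, "truth.json"))
    return SimOutput(vcf_path=vcf_path, panel_path=panel_path,
                     annotation_path=annotation_path, table_paths=table_paths,
                     truth=truth)


def implied_variant_freqs(cfg: SimConfig) -> pd.DataFrame:
    """Expected variant-allele frequency per variant per population.

    Each variant's expected frequency is the sum of the haplotype frequencies
    over the haplotypes carrying its alternative allele.  Only defined when
    every frequency vector sums to 1 (no novel-haplotype mass, whose allele
    content is random).
    """
    cfg.validate()
    rows = {}
    pops = [p.code for p in cfg.populations]
    for gene in cfg.genes:
        table = gene.table
        states = np.array([table.state_row(h) for h in table.haplotype_names],
                          dtype=float)
        for pop in pops:
            vec = np.asarray(gene.hap_freqs[pop], dtype=float)
            if vec.sum() < 1 - 1e-9:
                raise SimulationError(
                    f"{table.gene}/{pop}: implied frequencies are undefined "
                    f"with novel-haplotype mass > 0")
        for vi, rsid in enumerate(table.variants):
            rows[rsid] = {
                pop: float(np.asarray(gene.hap_freqs[pop], dtype=float)
                           @ states[:, vi])
                for pop in pops}
    frame = pd.DataFrame.from_dict(rows, orient="index")[pops]
    frame.index.name = "item"
    return frame


def implied_phenotype_freqs(cfg: SimConfig) -> pd.DataFrame:
    """Expected phenotype-label frequencies among assignable samples.

    Under random mating the two strands are independent draws, so with
    wild-type mass p and total on-table mass s per population the assigned
    fractions are (p/s)^2 for WT/WT, 2(p/s)(1-p/s) for WT/V and the square of
    the rest for V/V.  Indexed by (gene, population).
    """
    cfg.validate()
    rows = []
    for gene in cfg.genes:
        for p in cfg.populations:
            vec = np.asarray(gene.hap_freqs[p.code], dtype=float)
            s = vec.sum()
            if s <= 0:
                continue
            pw = vec[0] / s
            rows.append({"gene": gene.table.gene, "population": p.code,
                         "WT/WT": pw ** 2, "WT/V": 2 * pw * (1 - pw),
                         "V/V": (1 - pw) ** 2})
    return pd.DataFrame(rows).set_index(["gene", "population"])


# ---------------------------------------------------------------------------
# table/gene builders and the reference scenario
# ---------------------------------------------------------------------------

def random_gene(rng: np.random.Generator, gene: str, chrom: str,
                start_pos: int, n_variants: int, n_haplotypes: int,
                rsid_offset: int = 0) -> tuple[TranslationTable, list[VariantDef]]:
    """Random biallelic translation table plus matching variant definitions.

    The wild type is all-reference; every other haplotype is a distinct
    non-empty subset of alternative alleles.  SIFT/PolyPhen scores are drawn
    to cover all four functional classes (benign, damaging, ambiguous and
    missing-score variants all occur with positive probability).
    """
    if n_haplotypes < 2 or n_haplotypes > 2 ** n_variants:
        raise SimulationError(
            f"{gene}: cannot place {n_haplotypes} distinct haplotypes over "
            f"{n_variants} biallelic variants")
    patterns = {tuple([0] * n_variants)}
    while len(patterns) < n_haplotypes:
        vec = tuple(int(x) for x in rng.integers(0, 2, size=n_variants))
        if any(vec):
            patterns.add(vec)
    ordered = [tuple([0] * n_variants)] + sorted(patterns - {tuple([0] * n_variants)})

    refs, alts = [], []
    for _ in range(n_variants):
        i = rng.integers(0, 4)
        j = (i + 1 + rng.integers(0, 3)) % 4
        refs.append(_BASES[i])
        alts.append(_BASES[j])

    names = ["*1"] + [f"*{k + 2}" for k in range(len(ordered) - 1)]
    rows = [[alts[v] if pat[v] else refs[v] for v in range(n_variants)]
            for pat in ordered]
    frame = pd.DataFrame(rows, index=pd.Index(names, name="haplotype"),
                         columns=[f"rs{rsid_offset + k}" for k in range(n_variants)])
    table = TranslationTable(gene=gene, alleles=frame, provenance="synthetic")

    defs = []
    for k in range(n_variants):
        kind = rng.integers(0, 4)
        if kind == 0:    # benign
            sift, poly = float(rng.uniform(0.05, 1.0)), float(rng.uniform(0.0, 0.2))
        elif kind == 1:  # damaging
            sift, poly = float(rng.uniform(0.0, 0.05)), float(rng.uniform(0.2001, 1.0))
        elif kind == 2:  # ambiguous
            sift, poly = float(rng.uniform(0.0, 0.05)), float(rng.uniform(0.0, 0.2))
        else:            # unknown
            sift, poly = None, None
        defs.append(VariantDef(
            rsid=f"rs{rsid_offset + k}", gene=gene, chrom=chrom,
            pos=start_pos + 100 * k, ref_allele=refs[k],
            variant_allele=alts[k], sift=sift, polyphen=poly))
    return table, defs


def default_config(seed: int, n_per_pop: int = 500,
                   missing_rate: float = 0.0, unphase_rate: float = 0.0,
                   novel_mass: float = 0.0) -> SimConfig:
    """The reference synthetic scenario: 5 populations in 3 ancestral groups,
    3 genes.

    Gene CYPA is built with a strong wild-type frequency cline across
    populations (0.95 down to 0.10) so population-differentiated phenotypes
    occur; the other two genes draw their per-population haplotype frequency
    vectors from a flat Dirichlet.  ``novel_mass`` rescales every vector to
    leave that much off-table contamination.
    """
    pops = [PopulationSpec("YRI", "AFR", n_per_pop),
            PopulationSpec("LWK", "AFR", n_per_pop),
            PopulationSpec("CEU", "EUR", n_per_pop),
            PopulationSpec("TSI", "EUR", n_per_pop),
            PopulationSpec("CHB", "EAS", n_per_pop)]
    rng = np.random.default_rng([seed, 9000])
    genes = []
    specs = [("CYPA", "10", 10_000, 6, 5),
             ("CYPB", "16", 50_000, 4, 4),
             ("UGTC", "2", 90_000, 8, 6)]
    rsid_offset = 1000
    for k, (name, chrom, start, nv, nh) in enumerate(specs):
        table, defs = random_gene(rng, name, chrom, start, nv, nh,
                                  rsid_offset=rsid_offset)
        rsid_offset += nv
        freqs = {}
        if k == 0:
            wt_cline = [0.95, 0.90, 0.50, 0.45, 0.10]
            for p, wt in zip(pops, wt_cline):
                rest = rng.dirichlet(np.ones(nh - 1)) * (1 - wt)
                freqs[p.code] = np.concatenate([[wt], rest])
        else:
            for p in pops:
                freqs[p.code] = rng.dirichlet(np.ones(nh))
        if novel_mass > 0:
            for code in freqs:
                freqs[code] = freqs[code] * (1 - novel_mass)
        genes.append(SimGene(table=table, defs=defs, hap_freqs=freqs))
    return SimConfig(seed=seed, populations=pops, genes=genes,
                     missing_rate=missing_rate, unphase_rate=unphase_rate)


def config_from_yaml(path: str) -> SimConfig:
    """Build a SimConfig from a YAML file.

    Schema::

        seed: 1
        missing_rate: 0.0      # optional
        unphase_rate: 0.0      # optional
        populations:
          - {code: YRI, group: AFR, n: 200}
        genes:
          - gene: CYPA         # generated table
            chrom: "10"
            start_pos: 10000
            n_variants: 6
            n_haplotypes: 5
            novel_mass: 0.0    # optional off-table contamination
            hap_freqs:         # optional explicit vectors (else Dirichlet)
              YRI: [0.9, 0.05, 0.05, 0.0, 0.0]

    Omitted ``hap_freqs`` entries are drawn from a flat Dirichlet using the
    config seed, so a YAML file fully determines the cohort.
    """
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        seed = int(raw["seed"])
        pops = [PopulationSpec(str(p["code"]), str(p["group"]), int(p["n"]))
                for p in raw["populations"]]
        genes = []
        rsid_offset = 1000
        rng = np.random.default_rng([seed, 9000])
        for g in raw["genes"]:
            nv, nh = int(g["n_variants"]), int(g["n_haplotypes"])
            table, defs = random_gene(rng, str(g["gene"]), str(g["chrom"]),
                                      int(g["start_pos"]), nv, nh,
                                      rsid_offset=rsid_offset)
            rsid_offset += nv
            novel = float(g.get("novel_mass", 0.0))
            explicit = g.get("hap_freqs") or {}
            freqs = {}
            for p in pops:
                if p.code in explicit:
                    freqs[p.code] = np.asarray(explicit[p.code], dtype=float)
                else:
                    freqs[p.code] = rng.dirichlet(np.ones(nh)) * (1 - novel)
            genes.append(SimGene(table=table, defs=defs, hap_freqs=freqs))
    except (KeyError, TypeError) as exc:
        raise SimulationError(f"{path}: malformed simulation config: {exc}") from exc
    cfg = SimConfig(seed=seed, populations=pops, genes=genes,
                    missing_rate=float(raw.get("missing_rate", 0.0)),
                    unphase_rate=float(raw.get("unphase_rate", 0.0)))
    cfg.validate()
    return cfg
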