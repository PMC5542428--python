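"""Phased genotype extraction at pharmacogenomic variants.

The pipeline works on a compact allele-state alphabet per strand:

* ``REF`` — the allele the translation table treats as wild type at that site
* ``VAR`` — the allele designated as carrying the pharmacogenomic effect
* ``OTHER`` — an observed allele that is neither (multi-allelic ALTs)
* ``MISSING`` — no call

Orientation between the VCF's REF/ALT and the table's ref/variant alleles is
resolved per record: a record whose REF equals the table's variant allele is
simply flipped.  Records whose alleles match neither orientation are excluded
and logged — allele-identity agreement is the only assembly check performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenotypeError, PanelError

logger = logging.getLogger(__name__)

# allele-state codes (int8)
REF = 0
VAR = 1
OTHER = 2
MISSING = -1

STATE_NAMES = {REF: "REF", VAR: "VAR", OTHER: "OTHER", MISSING: "MISSING"}


@dataclass(frozen=True)
class VariantDef:
    """One pharmacogenomic variant: location, allele pair and predictor scores.

    ``variant_allele`` is the allele associated with the pharmacogenomic
    effect (the translation table's alternative allele); ``ref_allele`` is the
    wild-type allele.  SIFT/PolyPhen scores are in [0, 1] or None.
    """

    rsid: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    variant_allele: str
    sift: float | None = None
    polyphen: float | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        if self.ref_allele == self.variant_allele:
            raise ValueError(f"{self.rsid}: ref and variant alleles are equal")
        for label, score in (("sift", self.sift), ("polyphen", self.polyphen)):
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(f"{self.rsid}: {label} score {score} not in [0,1]")


@dataclass(frozen=True)
class PopulationMap:
    """Sample -> population -> ancestral group assignment."""

    sample_population: dict[str, str]
    population_group: dict[str, str]

    def __post_init__(self):
        for pop in self.sample_population.values():
            if pop not in self.population_group:
                raise PanelError(f"population {pop!r} has no ancestral group")

    def __contains__(self, sample: str) -> bool:
        return sample in self.sample_population

    def __len__(self) -> int:
        return len(self.sample_population)

    def population_of(self, sample: str) -> str:
        return self.sample_population[sample]

    def group_of(self, sample: str) -> str:
        return self.population_group[self.sample_population[sample]]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_population.values():
            seen.setdefault(pop, None)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.populations:
            seen.setdefault(self.population_group[pop], None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.sample_population.items() if p == population]


def load_population_map(path: str) -> PopulationMap:
    """Load a sample panel TSV with columns sample, population, group."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population", "group"}
    if not required.issubset(frame.columns):
        raise PanelError(
            f"{path}: panel needs columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    sample_pop: dict[str, str] = {}
    pop_group: dict[str, str] = {}
    for _, row in frame.iterrows():
        s, p, g = row["sample"], row["population"], row["group"]
        if s in sample_pop and sample_pop[s] != p:
            raise PanelError(
                f"{path}: sample {s!r} listed with conflicting populations "
                f"{sample_pop[s]!r} and {p!r}"
            )
        if p in pop_group and pop_group[p] != g:
            raise PanelError(
                f"{path}: population {p!r} listed with conflicting groups "
                f"{pop_group[p]!r} and {g!r}"
            )
        sample_pop[s] = p
        pop_group[p] = g
    return PopulationMap(sample_population=sample_pop, population_group=pop_group)


def load_variant_annotations(path: str) -> list[VariantDef]:
    """Load the variant annotation TSV.

    Columns: rsid, gene, chrom, pos, ref, variant, sift, polyphen; empty
    sift/polyphen cells mean "no prediction available".
    """
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    defs = []
    for _, row in frame.iterrows():
        defs.append(VariantDef(
            rsid=str(row["rsid"]), gene=str(row["gene"]),
            chrom=str(row["chrom"]), pos=int(row["pos"]),
            ref_allele=str(row["ref"]), variant_allele=str(row["variant"]),
            sift=None if pd.isna(row["sift"]) else float(row["sift"]),
            polyphen=None if pd.isna(row["polyphen"]) else float(row["polyphen"]),
        ))
    return defs


@dataclass
class ExtractionReport:
    """Bookkeeping from a VCF extraction run (for the pipeline log)."""

    resolved: list[str] = field(default_factory=list)
    flipped: list[str] = field(default_factory=list)
    not_found: list[str] = field(default_factory=list)
    allele_mismatch: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)


@dataclass
class GenotypeMatrix:
    """Per-sample phased allele-state pairs at resolvable PGx variants.

    ``calls`` has shape (n_samples, n_variants, 2) with int8 state codes;
    ``phased`` is False only for heterozygous pairs written unphased.
    """

    samples: list[str]
    variants: list[VariantDef]
    calls: np.ndarray
    phased: np.ndarray
    popmap: PopulationMap
    report: ExtractionReport | None = None

    def __post_init__(self):
        assert self.calls.shape == (len(self.samples), len(self.variants), 2)
        assert self.phased.shape == (len(self.samples), len(self.variants))

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def variant_index(self, rsid: str) -> int:
        for i, v in enumerate(self.variants):
            if v.rsid == rsid:
                return i
        raise KeyError(rsid)

    def gene_columns(self, gene: str) -> list[int]:
        return [i for i, v in enumerate(self.variants) if v.gene == gene]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.gene, None)
        return list(seen)

    def sample_indices_by(self, level: str) -> dict[str, np.ndarray]:
        """Column label -> sample row indices, for a stratification level."""
        if level == "global":
            return {"ALL": np.arange(len(self.samples))}
        labels: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            if level == "population":
                key = self.popmap.population_of(s)
            elif level == "group":
                key = self.popmap.group_of(s)
            else:
                raise ValueError(f"unknown level {level!r}")
            labels.setdefault(key, []).append(i)
        return {k: np.asarray(v) for k, v in labels.items()}


def _orient(record, vdef: VariantDef):
    """Return (code -> state map, flipped) for a VCF record, or None."""
    alts = list(record.ALT)
    if record.REF == vdef.ref_allele and vdef.variant_allele in alts:
        j = alts.index(vdef.variant_allele) + 1
        mapping = {0: REF, j: VAR}
        return mapping, False
    if record.REF == vdef.variant_allele and vdef.ref_allele in alts:
        j = alts.index(vdef.ref_allele) + 1
        mapping = {0: VAR, j: REF}
        return mapping, True
    return None


def extract_genotypes(vcf_path: str, defs: list[VariantDef],
                      popmap: PopulationMap) -> GenotypeMatrix:
    """Extract phased allele states at the given variants from a VCF.

    Records are located by rsID first, with chrom+pos as fallback.  Variants
    whose alleles match the definition in neither orientation are excluded
    and logged; samples absent from the panel are dropped with a warning.
    """
    from cyvcf2 import VCF

    if not defs:
        raise GenotypeError("no variant definitions supplied")
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise GenotypeError(f"cannot read VCF {vcf_path}: {exc}") from exc

    report = ExtractionReport()
    vcf_samples = list(vcf.samples)
    keep_mask = [s in popmap for s in vcf_samples]
    samples = [s for s, k in zip(vcf_samples, keep_mask) if k]
    report.dropped_samples = [s for s, k in zip(vcf_samples, keep_mask) if not k]
    if report.dropped_samples:
        logger.warning("dropping %d samples absent from the panel",
                       len(report.dropped_samples))
    keep_idx = np.flatnonzero(keep_mask)

    by_id = {d.rsid: d for d in defs}
    by_pos = {(d.chrom, d.pos): d for d in defs}

    resolved: dict[str, tuple[VariantDef, np.ndarray, np.ndarray, bool]] = {}
    for record in vcf:
        vdef = by_id.get(record.ID) or by_pos.get((record.CHROM, record.POS))
        if vdef is None:
            continue
        if vdef.rsid in resolved:
            logger.warning("%s: multiple VCF records match; keeping the first",
                           vdef.rsid)
            continue
        oriented = _orient(record, vdef)
        if oriented is None:
            report.allele_mismatch.append(vdef.rsid)
            logger.info("%s: VCF alleles %s/%s do not match definition %s/%s; "
                        "excluded", vdef.rsid, record.REF, record.ALT,
                        vdef.ref_allele, vdef.variant_allele)
            continue
        mapping, flipped = oriented
        geno = record.genotypes  # [allele_a, allele_b, phased] per sample
        col = np.full((len(samples), 2), MISSING, dtype=np.int8)
        ph = np.ones(len(samples), dtype=bool)
        for out_i, vcf_i in enumerate(keep_idx):
            entry = geno[vcf_i]
            if len(entry) < 3:  # haploid call: treat second allele as missing
                a, b, is_phased = entry[0], -1, True
            else:
                a, b, is_phased = entry[0], entry[1], entry[2]
            sa = MISSING if a < 0 else mapping.get(int(a), OTHER)
            sb = MISSING if b < 0 else mapping.get(int(b), OTHER)
            col[out_i] = (sa, sb)
            # unphased flag is only meaningful for full heterozygous calls
            het = sa != sb and sa != MISSING and sb != MISSING
            ph[out_i] = bool(is_phased) or not het
        resolved[vdef.rsid] = (vdef, col, ph, flipped)
        report.resolved.append(vdef.rsid)
        if flipped:
            report.flipped.append(vdef.rsid)

    report.not_found = [d.rsid for d in defs
                        if d.rsid not in resolved
                        and d.rsid not in report.allele_mismatch]
    kept_defs = [d for d in defs if d.rsid in resolved]
    if not kept_defs:
        raise GenotypeError("no variant definitions were resolvable in the VCF")

    calls = np.stack([resolved[d.rsid][1] for d in kept_defs], axis=1)
    phased = np.stack([resolved[d.rsid][2] for d in kept_defs], axis=1)
    return GenotypeMatrix(samples=samples, variants=kept_defs, calls=calls,
                          phased=phased, popmap=popmap, report=report)
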