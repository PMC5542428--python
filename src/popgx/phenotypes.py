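"""Three-level drug-metabolizing phenotype inference.

A diplotype is collapsed to one of three phenotype labels: WT/WT when both
strands match the wild-type haplotype, WT/V when exactly one does, and V/V
when both strands match non-wild-type haplotypes.  These are conventionally
read as normal, intermediate and abnormal metabolizer status.  Calls with an
unmatched strand, or whose phase enumeration was ambiguous, get no phenotype
(UNASSIGNED); per-population label frequencies are computed among assigned
samples only, so the three labels sum to one, with a separate per-gene
coverage figure saying how many samples were assignable at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import PopulationMap
from .haplotypes import DiplotypeCall
from .translation import TranslationTable, UNMATCHED

WT_WT = "WT/WT"
WT_V = "WT/V"
V_V = "V/V"
UNASSIGNED = "UNASSIGNED"
LABELS = (WT_WT, WT_V, V_V)
PHENOTYPE_COLORS = {WT_WT: "green", WT_V: "orange", V_V: "darkred",
                    UNASSIGNED: "lightgrey"}
#: Conventional metabolizer reading of each label.
METABOLIZER_STATUS = {WT_WT: "normal", WT_V: "intermediate", V_V: "abnormal"}


def assign_phenotype(call: DiplotypeCall, table: TranslationTable) -> str:
    """Phenotype label for one diplotype call (strand order irrelevant)."""
    if call.gene != table.gene:
        raise ValueError(f"call is for gene {call.gene!r}, table for {table.gene!r}")
    if call.ambiguous or UNMATCHED in call.allele_matches:
        return UNASSIGNED
    wt = table.wild_type
    n_wt = sum(h == wt for h in call.allele_matches)
    return {2: WT_WT, 1: WT_V, 0: V_V}[n_wt]


def assign_phenotypes(calls: list[DiplotypeCall],
                      tables: dict[str, TranslationTable]) -> list[DiplotypeCall]:
    """Fill the phenotype field of every call in place; returns the list."""
    for call in calls:
        call.phenotype = assign_phenotype(call, tables[call.gene])
    return calls


@dataclass(frozen=True)
class PhenotypeDistribution:
    """Per (gene, population) label frequencies plus per-gene coverage.

    ``freqs`` is indexed by (gene, population) with columns WT/WT, WT/V, V/V
    (frequencies among assigned samples; NaN if none assigned), n_assigned
    and n_total.  ``coverage`` is the per-gene assigned fraction over the
    whole cohort.
    """

    freqs: pd.DataFrame
    coverage: pd.Series


def phenotype_distribution(calls: list[DiplotypeCall],
                           popmap: PopulationMap) -> PhenotypeDistribution:
    """Tabulate phenotype-label frequencies per gene and population."""
    if any(c.phenotype is None for c in calls):
        raise ValueError("calls have no phenotype; run assign_phenotypes first")
    rows = []
    genes = sorted({c.gene for c in calls})
    pops = sorted({popmap.population_of(c.sample) for c in calls})
    by_key: dict[tuple[str, str], list[str]] = {}
    for c in calls:
        by_key.setdefault((c.gene, popmap.population_of(c.sample)), []).append(
            c.phenotype)
    for gene in genes:
        for pop in pops:
            labels = by_key.get((gene, pop), [])
            if not labels:
                continue
            assigned = [l for l in labels if l != UNASSIGNED]
            n_a, n_t = len(assigned), len(labels)
            row = {"gene": gene, "population": pop,
                   "n_assigned": n_a, "n_total": n_t}
            for lab in LABELS:
                row[lab] = assigned.count(lab) / n_a if n_a else np.nan
            rows.append(row)
    freqs = pd.DataFrame(rows).set_index(["gene", "population"])
    cov = {}
    for gene in genes:
        sub = freqs.loc[gene]
        cov[gene] = sub["n_assigned"].sum() / sub["n_total"].sum()
    return PhenotypeDistribution(freqs=freqs,
                                 coverage=pd.Series(cov, name="coverage"))


def high_difference_genes(dist: PhenotypeDistribution,
                          coverage_thr: float = 0.9, hi: float = 0.8,
                          lo: float = 0.2) -> set[str]:
    """Genes with well-covered, strongly population-differentiated phenotypes.

    A gene qualifies when its cohort-wide assignment coverage is at least
    ``coverage_thr`` and some label reaches frequency >= ``hi`` in one
    population while staying <= ``lo`` in another.
    """
    out = set()
    for gene, cov in dist.coverage.items():
        if cov < coverage_thr:
            continue
        sub = dist.freqs.loc[gene]
        for lab in LABELS:
            col = sub[lab].dropna()
            if len(col) >= 2 and col.max() >= hi and col.min() <= lo:
                out.add(gene)
                break
    return out


def write_phenotype_distribution(dist: PhenotypeDistribution, path: str) -> None:
    """TSV: gene, population, wtwt, wtv, vv, coverage (per-gene, repeated)."""
    frame = dist.freqs.reset_index()
    frame["coverage"] = frame["gene"].map(dist.coverage)
    frame = frame.rename(columns={WT_WT: "wtwt", WT_V: "wtv", V_V: "vv"})
    frame[["gene", "population", "wtwt", "wtv", "vv", "coverage"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g")
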