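"""Haplotype matching, diplotype calling and haplotype frequencies.

Matching is exact: a strand's allele vector must agree with a translation
table row at *every* table column to be called that haplotype.  A strand with
any OTHER or MISSING state, or whose allele combination appears in no row, is
UNMATCHED — partial or best-effort matching is deliberately not offered,
because an "unmatched" tally is itself one of the quantities of interest.

Haplotype frequencies (HAF) use all 2N strands of a column as denominator, so
matched mass, unmatched mass and (for unphased data) ambiguous mass together
account for every strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, MISSING, OTHER, PopulationMap, REF, VAR
from .translation import TranslationTable, UNMATCHED, restrict_table

#: Hard cap on unphased heterozygous sites per call (2^16 enumerations).
MAX_UNPHASED_SITES = 16


@dataclass
class DiplotypeCall:
    """The matched haplotype pair for one sample at one gene.

    ``allele_matches`` holds two haplotype names (or UNMATCHED).  For unphased
    input whose phase enumeration is consistent with several distinct
    diplotypes, ``ambiguous`` is set and ``consistent`` lists them all.
    """

    sample: str
    gene: str
    allele_matches: tuple[str, str]
    ambiguous: bool = False
    consistent: tuple[tuple[str, str], ...] = ()
    phenotype: str | None = None

    def __post_init__(self):
        assert len(self.allele_matches) == 2
        if self.ambiguous:
            assert len(self.consistent) >= 2


def _table_state_matrix(table: TranslationTable) -> np.ndarray:
    return np.array([table.state_row(n) for n in table.haplotype_names],
                    dtype=np.int8)


def match_allele(allele_vector, table: TranslationTable) -> str:
    """Match one strand's allele states against the table's haplotype rows.

    ``allele_vector`` gives one state code per table variant (REF/VAR/OTHER/
    MISSING, in table column order).  REF translates to the wild-type allele
    at that column and VAR to the column's alternative allele; the first row
    equal to the translated vector at every column is returned, else
    UNMATCHED.  OTHER or MISSING anywhere makes the strand unmatchable.
    """
    vec = np.asarray(allele_vector, dtype=np.int8)
    if vec.shape != (len(table.variants),):
        raise ValueError(
            f"allele vector has {vec.shape[0] if vec.ndim == 1 else 'bad'} "
            f"entries for a table with {len(table.variants)} variants"
        )
    if np.any((vec != REF) & (vec != VAR)):
        return UNMATCHED
    states = _table_state_matrix(table)
    hits = np.flatnonzero((states == vec).all(axis=1))
    if hits.size == 0:
        return UNMATCHED
    return table.haplotype_names[hits[0]]


def call_diplotype(pair_codes, phased, table: TranslationTable,
                   sample: str = "", ) -> DiplotypeCall:
    """Call a sample's diplotype at one gene from per-variant allele pairs.

    ``pair_codes`` is (n_variants, 2) state codes in table column order;
    ``phased`` is a boolean per variant (False only at heterozygous sites
    whose phase is unknown).  Fully phased input matches the two strand
    vectors independently.  Unphased heterozygous sites are resolved by
    enumerating every phase assignment and collecting the distinct unordered
    diplotypes where both strands match a table row: exactly one consistent
    diplotype is returned as such, several set ``ambiguous``, none yields
    UNMATCHED/UNMATCHED.
    """
    codes = np.asarray(pair_codes, dtype=np.int8)
    ph = np.asarray(phased, dtype=bool)
    nv = len(table.variants)
    if codes.shape != (nv, 2) or ph.shape != (nv,):
        raise ValueError("genotypes do not cover the table's variants")

    het = codes[:, 0] != codes[:, 1]
    unphased_sites = np.flatnonzero(het & ~ph)
    if unphased_sites.size == 0:
        a = match_allele(codes[:, 0], table)
        b = match_allele(codes[:, 1], table)
        return DiplotypeCall(sample=sample, gene=table.gene,
                             allele_matches=(a, b))

    if unphased_sites.size > MAX_UNPHASED_SITES:
        raise ValueError(
            f"{sample}/{table.gene}: {unphased_sites.size} unphased "
            f"heterozygous sites exceeds the enumeration cap "
            f"({MAX_UNPHASED_SITES})"
        )
    consistent: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    base = codes.copy()
    for flips in itertools.product((False, True), repeat=unphased_sites.size):
        work = base.copy()
        for site, flip in zip(unphased_sites, flips):
            if flip:
                work[site, 0], work[site, 1] = base[site, 1], base[site, 0]
        a = match_allele(work[:, 0], table)
        b = match_allele(work[:, 1], table)
        if a == UNMATCHED or b == UNMATCHED:
            continue
        key = tuple(sorted((a, b)))
        if key not in seen:
            seen.add(key)
            consistent.append(key)
    if not consistent:
        return DiplotypeCall(sample=sample, gene=table.gene,
                             allele_matches=(UNMATCHED, UNMATCHED))
    if len(consistent) == 1:
        return DiplotypeCall(sample=sample, gene=table.gene,
                             allele_matches=consistent[0])
    return DiplotypeCall(sample=sample, gene=table.gene,
                         allele_matches=consistent[0], ambiguous=True,
                         consistent=tuple(consistent))


def call_diplotypes(gm: GenotypeMatrix, table: TranslationTable,
                    restrict: bool = True) -> list[DiplotypeCall]:
    """Call every sample's diplotype for one gene.

    When ``restrict`` is set the table is first restricted to the rsIDs the
    genotype matrix actually resolved, so tables defined over more variants
    than the dataset carries remain callable.
    """
    if restrict:
        table = restrict_table(table, set(gm.rsids))
    cols = [gm.variant_index(rsid) for rsid in table.variants]
    calls = []
    for i, sample in enumerate(gm.samples):
        calls.append(call_diplotype(gm.calls[i][cols], gm.phased[i][cols],
                                    table, sample=sample))
    return calls


def _column_samples(calls: list[DiplotypeCall], popmap: PopulationMap,
                    level: str) -> dict[str, list[DiplotypeCall]]:
    out: dict[str, list[DiplotypeCall]] = {}
    for call in calls:
        if level == "population":
            key = popmap.population_of(call.sample)
        elif level == "group":
            key = popmap.group_of(call.sample)
        elif level == "global":
            key = "ALL"
        else:
            raise ValueError(f"unknown level {level!r}")
        out.setdefault(key, []).append(call)
    return out


def unmatched_rate(calls: list[DiplotypeCall], popmap: PopulationMap,
                   level: str = "population") -> pd.DataFrame:
    """Proportion of UNMATCHED strands per gene per column.

    Each sample contributes two strands.  Strands of ambiguous calls count in
    the denominator but in neither the matched nor the unmatched numerator
    (they are tallied by :func:`ambiguous_mass`).
    """
    genes = sorted({c.gene for c in calls})
    strata = _column_samples(calls, popmap, level)
    out = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"),
                       columns=sorted(strata))
    for col, members in strata.items():
        for gene in genes:
            sub = [c for c in members if c.gene == gene]
            if not sub:
                continue
            total = 2 * len(sub)
            unm = sum((not c.ambiguous) * c.allele_matches.count(UNMATCHED)
                      for c in sub)
            out.loc[gene, col] = unm / total
    return out


def ambiguous_mass(calls: list[DiplotypeCall], popmap: PopulationMap,
                   level: str = "population") -> pd.DataFrame:
    """Proportion of strands belonging to ambiguous (unresolvable) calls."""
    genes = sorted({c.gene for c in calls})
    strata = _column_samples(calls, popmap, level)
    out = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"),
                       columns=sorted(strata))
    for col, members in strata.items():
        for gene in genes:
            sub = [c for c in members if c.gene == gene]
            if not sub:
                continue
            out.loc[gene, col] = sum(2 * c.ambiguous for c in sub) / (2 * len(sub))
    return out


def haplotype_frequency(calls: list[DiplotypeCall], popmap: PopulationMap,
                        level: str = "population",
                        tables: dict[str, TranslationTable] | None = None):
    """Haplotype frequencies (HAF) per column.

    HAF(h, col) = matched strands of h / (2 x samples in col).  Unmatched and
    ambiguous strands stay in the denominator, so for every gene and column
    the haplotype frequencies plus the unmatched and ambiguous masses sum to
    one.  Items are named ``gene:haplotype``; supplying ``tables`` adds
    zero-frequency rows for haplotypes never observed.
    """
    from .variants import FrequencyTable

    strata = _column_samples(calls, popmap, level)
    columns = sorted(strata)
    item_names: list[str] = []
    if tables:
        for gene, table in tables.items():
            item_names.extend(f"{gene}:{h}" for h in table.haplotype_names)
    observed = sorted({f"{c.gene}:{h}" for c in calls if not c.ambiguous
                       for h in c.allele_matches if h != UNMATCHED})
    for name in observed:
        if name not in item_names:
            item_names.append(name)

    values = pd.DataFrame(np.nan, index=pd.Index(item_names, name="item"),
                          columns=columns)
    denoms = pd.DataFrame(0, index=values.index, columns=columns, dtype=int)
    for col, members in strata.items():
        per_gene_n: dict[str, int] = {}
        counts: dict[str, int] = {}
        for c in members:
            per_gene_n[c.gene] = per_gene_n.get(c.gene, 0) + 1
            if c.ambiguous:
                continue
            for h in c.allele_matches:
                if h != UNMATCHED:
                    counts[f"{c.gene}:{h}"] = counts.get(f"{c.gene}:{h}", 0) + 1
        for item in item_names:
            gene = item.split(":", 1)[0]
            n = per_gene_n.get(gene, 0)
            if n == 0:
                continue
            denoms.loc[item, col] = 2 * n
            values.loc[item, col] = counts.get(item, 0) / (2 * n)
    return FrequencyTable(values=values, denominators=denoms, level=level)


def filter_extreme_haplotypes(ft, common_thr: float = 0.1,
                              rare_thr: float = 0.005) -> set[str]:
    """Haplotypes common (>= common_thr) in at least one population and rare
    (<= rare_thr) in at least one other; same rule as for variants."""
    from .variants import filter_extreme_variants

    return filter_extreme_variants(ft, common_thr=common_thr, rare_thr=rare_thr)


def population_span(ft) -> pd.Series:
    """Number of columns (populations) where each haplotype has HAF > 0."""
    arr = ft.values.to_numpy(dtype=float)
    span = ((~np.isnan(arr)) & (arr > 0)).sum(axis=1)
    return pd.Series(span, index=ft.values.index, name="span")


def span_histogram(span: pd.Series, n_populations: int) -> dict[str, float]:
    """Fractions of haplotypes observed in all vs exactly one population,
    among haplotypes observed anywhere."""
    present = span[span > 0]
    if present.empty:
        return {"matched_all": 0.0, "matched_one": 0.0, "n_present": 0}
    return {
        "matched_all": float((present == n_populations).mean()),
        "matched_one": float((present == 1).mean()),
        "n_present": int(len(present)),
    }


def write_diplotype_calls(calls: list[DiplotypeCall], path: str) -> None:
    """Write calls as TSV: sample, gene, hap1, hap2, ambiguous, phenotype."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tgene\thap1\thap2\tambiguous\tphenotype\n")
        for c in calls:
            fh.write(f"{c.sample}\t{c.gene}\t{c.allele_matches[0]}\t"
                     f"{c.allele_matches[1]}\t{int(c.ambiguous)}\t"
                     f"{c.phenotype or ''}\n")
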