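"""Shared fixtures and independent oracles for the popgx test suite.

The oracles here deliberately re-derive results by brute force (row-by-row
string comparison, full phase enumeration, per-sample recounting) so they
share no code path with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from popgx import (GenotypeMatrix, PopulationMap, TranslationTable,
                   UNMATCHED, VariantDef)
from popgx.genotype import MISSING, OTHER, REF, VAR


# ---------------------------------------------------------------------------
# toy translation table (3 haplotypes x 2 variants)
# ---------------------------------------------------------------------------

TOY_TSV = (
    "haplotype\trsA\trsB\n"
    "*1\tC\tG\n"
    "*2\tT\tG\n"
    "*3\tT\tA\n"
)


@pytest.fixture
def toy_table() -> TranslationTable:
    frame = pd.DataFrame([["C", "G"], ["T", "G"], ["T", "A"]],
                         index=pd.Index(["*1", "*2", "*3"], name="haplotype"),
                         columns=["rsA", "rsB"])
    return TranslationTable(gene="TOY", alleles=frame)


@pytest.fixture
def toy_table_file(tmp_path):
    path = tmp_path / "TOY.tsv"
    path.write_text(TOY_TSV)
    return str(path)


# ---------------------------------------------------------------------------
# genotype-matrix builder
# ---------------------------------------------------------------------------

def make_defs(n: int, gene: str = "G1", chrom: str = "1",
              prefix: str = "rs") -> list[VariantDef]:
    return [VariantDef(rsid=f"{prefix}{i}", gene=gene, chrom=chrom,
                       pos=100 + 10 * i, ref_allele="C", variant_allele="T")
            for i in range(n)]


def make_gm(calls, sample_pops: list[str],
            pop_groups: dict[str, str] | None = None,
            defs: list[VariantDef] | None = None,
            phased=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix directly from a (S, V, 2) state array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_v, _ = calls.shape
    assert len(sample_pops) == n_s
    if pop_groups is None:
        pop_groups = {p: "GRP" for p in set(sample_pops)}
    samples = [f"S{i:03d}" for i in range(n_s)]
    popmap = PopulationMap(
        sample_population=dict(zip(samples, sample_pops)),
        population_group=pop_groups)
    if defs is None:
        defs = make_defs(n_v)
    if phased is None:
        phased = np.ones((n_s, n_v), dtype=bool)
    return GenotypeMatrix(samples=samples, variants=defs, calls=calls,
                          phased=np.asarray(phased, dtype=bool), popmap=popmap)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_match(vec, table: TranslationTable) -> str:
    """Row-by-row string comparison after literal state->allele translation."""
    wt = list(table.alleles.iloc[0])
    translated = []
    for j, s in enumerate(vec):
        if s == REF:
            translated.append(wt[j])
        elif s == VAR:
            alts = set(table.alleles.iloc[:, j]) - {wt[j]}
            translated.append(alts.pop() if alts else None)
        else:
            return UNMATCHED
    for name in table.haplotype_names:
        if list(table.alleles.loc[name]) == translated:
            return name
    return UNMATCHED


def oracle_diplotypes(codes, phased, table: TranslationTable):
    """All unordered diplotypes consistent with a genotype, by enumerating
    every phase assignment of unphased heterozygous sites."""
    codes = [list(p) for p in codes]
    sites = [i for i, (p, ph) in enumerate(zip(codes, phased))
             if p[0] != p[1] and not ph]
    found = set()
    for flips in itertools.product((0, 1), repeat=len(sites)):
        work = [list(p) for p in codes]
        for s, f in zip(sites, flips):
            if f:
                work[s] = [work[s][1], work[s][0]]
        a = oracle_match([p[0] for p in work], table)
        b = oracle_match([p[1] for p in work], table)
        if a != UNMATCHED and b != UNMATCHED:
            found.add(tuple(sorted((a, b))))
    return found


def random_fixture(rng: np.random.Generator, max_variants: int = 12,
                   max_haplotypes: int = 30) -> TranslationTable:
    """Random biallelic table for oracle-equivalence checks."""
    from popgx import random_gene

    nv = int(rng.integers(1, max_variants + 1))
    nh = int(rng.integers(2, min(max_haplotypes, 2 ** nv) + 1))
    table, _ = random_gene(rng, "RND", "1", 1000, nv, nh)
    return table


def random_state_vector(rng: np.random.Generator, nv: int,
                        p_other: float = 0.05,
                        p_missing: float = 0.05) -> np.ndarray:
    states = rng.integers(0, 2, size=nv).astype(np.int8)
    u = rng.random(nv)
    states[u < p_other] = OTHER
    states[(u >= p_other) & (u < p_other + p_missing)] = MISSING
    return states
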