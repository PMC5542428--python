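"""Haplotype translation tables.

A translation table defines, for one pharmacogene, each named (star-allele)
haplotype by the allele it carries at every member variant.  The first
haplotype listed is the reference ("wild-type") haplotype: it carries zero
alternative alleles by definition, and every other haplotype is described by
where it departs from it.

Tables are TSV files::

    haplotype<TAB>rsID1<TAB>rsID2 ...
    *1<TAB>C<TAB>G          <- first data row is the wild type
    *2<TAB>T<TAB>G
    # comment lines start with '#'

Allele cells are nucleotide strings (possibly multi-base, for insertions the
anchor base plus the inserted sequence) or the deletion token ``del``.  IUPAC
ambiguity codes are rejected: a haplotype definition is a concrete sequence
claim, not a degenerate one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable

import pandas as pd

from .errors import TableError

DELETION_TOKEN = "del"
_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: Sentinel returned by haplotype matching when no table row fits.
UNMATCHED = "UNMATCHED"


@dataclass(frozen=True)
class TranslationTable:
    """Per-gene haplotype definitions over an ordered variant list.

    Attributes
    ----------
    gene:
        Gene symbol.
    alleles:
        DataFrame indexed by haplotype name, one column per variant rsID,
        values are allele strings.  Row order is definition order; the first
        row is the wild type.
    provenance:
        Free-form origin string (source path + parse timestamp), or None for
        tables built in memory.
    """

    gene: str
    alleles: pd.DataFrame
    provenance: str | None = None

    def __post_init__(self):
        _validate_alleles(self.gene, self.alleles)

    @property
    def variants(self) -> tuple[str, ...]:
        return tuple(self.alleles.columns)

    @property
    def haplotype_names(self) -> tuple[str, ...]:
        return tuple(self.alleles.index)

    @property
    def wild_type(self) -> str:
        return self.alleles.index[0]

    @property
    def n_haplotypes(self) -> int:
        return len(self.alleles)

    def wild_type_allele(self, rsid: str) -> str:
        return self.alleles.iloc[0][rsid]

    def alt_allele(self, rsid: str) -> str | None:
        """The unique non-wild-type allele at a column, or None if the column
        is invariant across all haplotypes."""
        wt = self.wild_type_allele(rsid)
        alts = set(self.alleles[rsid]) - {wt}
        if not alts:
            return None
        # uniqueness enforced at construction
        return next(iter(alts))

    def state_row(self, name: str) -> tuple[int, ...]:
        """Haplotype as 0/1 states (0 = wild-type allele, 1 = alternative)."""
        if name not in self.alleles.index:
            raise KeyError(f"unknown haplotype {name!r} in gene {self.gene}")
        wt = self.alleles.iloc[0]
        row = self.alleles.loc[name]
        return tuple(int(a != b) for a, b in zip(row, wt))


def _normalise_allele(cell: str) -> str:
    cell = cell.strip()
    if cell.lower() == DELETION_TOKEN:
        return DELETION_TOKEN
    return cell.upper()


def _validate_alleles(gene: str, alleles: pd.DataFrame) -> None:
    if alleles.shape[0] < 1:
        raise TableError(f"{gene}: a translation table needs at least 1 haplotype")
    if alleles.shape[1] < 1:
        raise TableError(f"{gene}: a translation table needs at least 1 variant")
    if alleles.index.duplicated().any():
        dup = alleles.index[alleles.index.duplicated()][0]
        raise TableError(f"{gene}: duplicate haplotype {dup!r}")
    if alleles.columns.duplicated().any():
        dup = alleles.columns[alleles.columns.duplicated()][0]
        raise TableError(f"{gene}: duplicate variant column {dup!r}")
    for hap, row in alleles.iterrows():
        for rsid, cell in row.items():
            if not isinstance(cell, str) or not cell:
                raise TableError(
                    f"{gene}: empty allele cell at haplotype {hap!r}, variant {rsid!r}"
                )
            if cell != DELETION_TOKEN and not _ALLELE_RE.match(cell):
                raise TableError(
                    f"{gene}: invalid allele {cell!r} at haplotype {hap!r}, "
                    f"variant {rsid!r} (IUPAC ambiguity codes are not allowed)"
                )
    # Each column must be biallelic relative to the wild type: one wild-type
    # allele plus at most one alternative.  Two distinct alternatives cannot
    # be represented by a single variant-allele definition downstream.
    wt = alleles.iloc[0]
    for rsid in alleles.columns:
        alts = set(alleles[rsid]) - {wt[rsid]}
        if len(alts) > 1:
            raise TableError(
                f"{gene}: variant {rsid!r} carries more than one alternative "
                f"allele ({sorted(alts)}); tables must be biallelic per column"
            )


def parse_translation_table(path: str, gene: str | None = None) -> TranslationTable:
    """Parse and validate a translation-table TSV.

    The gene symbol defaults to the file's stem.  The first data row becomes
    the wild-type haplotype.
    """
    import os

    if gene is None:
        gene = os.path.splitext(os.path.basename(str(path)))[0]
    rows: list[tuple[str, list[str]]] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                if cells[0].lower() != "haplotype":
                    raise TableError(
                        f"{path}:{lineno}: header must start with 'haplotype'"
                    )
                header = cells[1:]
                if not header:
                    raise TableError(f"{path}:{lineno}: no variant columns")
                continue
            if len(cells) != len(header) + 1:
                raise TableError(
                    f"{path}:{lineno}: expected {len(header) + 1} columns, "
                    f"got {len(cells)}"
                )
            name = cells[0].strip()
            if not name:
                raise TableError(f"{path}:{lineno}: empty haplotype name")
            rows.append((name, [_normalise_allele(c) for c in cells[1:]]))
    if header is None:
        raise TableError(f"{path}: no header line")
    if len(rows) < 2:
        raise TableError(f"{path}: need at least 2 haplotype rows")
    names = [n for n, _ in rows]
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dup = next(n for n in names if n in seen or seen.add(n))
        raise TableError(f"{path}: duplicate haplotype {dup!r}")
    frame = pd.DataFrame(
        [vals for _, vals in rows], index=pd.Index(names, name="haplotype"),
        columns=header,
    )
    stamp = datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
    return TranslationTable(gene=gene, alleles=frame,
                            provenance=f"{path} parsed {stamp}")


def write_translation_table(table: TranslationTable, path: str) -> None:
    """Write a table in the canonical TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("haplotype\t" + "\t".join(table.variants) + "\n")
        for name in table.haplotype_names:
            fh.write(name + "\t" + "\t".join(table.alleles.loc[name]) + "\n")


def restrict_table(table: TranslationTable,
                   available_rsids: Iterable[str]) -> TranslationTable:
    """Restrict a table to the variants observable in a dataset.

    Variant columns not in ``available_rsids`` are dropped.  A non-wild-type
    haplotype whose definition required an alternative allele at a dropped
    column can no longer be distinguished from table rows that agree with it
    elsewhere, so it is dropped.  Retained haplotypes that become identical
    over the remaining columns are merged under a composite ``A|B`` name
    (members sorted lexicographically).  The wild type is never dropped.
    """
    available = set(available_rsids)
    if not available:
        raise TableError(f"{table.gene}: available_rsids is empty")
    keep = [v for v in table.variants if v in available]
    if not keep:
        raise TableError(f"{table.gene}: gene has no observable variants")
    wt = table.wild_type
    wt_row = table.alleles.iloc[0]
    dropped_cols = [v for v in table.variants if v not in available]

    kept_names: list[str] = []
    for name in table.haplotype_names:
        if name == wt:
            kept_names.append(name)
            continue
        row = table.alleles.loc[name]
        if any(row[c] != wt_row[c] for c in dropped_cols):
            continue  # its distinguishing allele is unobservable
        kept_names.append(name)

    sub = table.alleles.loc[kept_names, keep]
    # merge rows identical over remaining columns
    groups: dict[tuple[str, ...], list[str]] = {}
    order: list[tuple[str, ...]] = []
    for name in kept_names:
        key = tuple(sub.loc[name])
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(name)
    merged_names = []
    merged_rows = []
    for key in order:
        members = groups[key]
        if wt in members:
            # wild type cannot coincide with a retained non-wild-type row:
            # such a row would have been dropped above; keep its own name.
            merged_names.append(wt)
        else:
            merged_names.append("|".join(sorted(members)))
        merged_rows.append(list(key))
    frame = pd.DataFrame(merged_rows,
                         index=pd.Index(merged_names, name="haplotype"),
                         columns=keep)
    return TranslationTable(gene=table.gene, alleles=frame,
                            provenance=table.provenance)


def haplotype_variability(table: TranslationTable, name: str) -> int:
    """Number of variants a haplotype carries in their alternative form.

    The wild type has variability 0 by definition.
    """
    return sum(table.state_row(name))
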