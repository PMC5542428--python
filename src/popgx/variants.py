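"""Population-stratified variant-allele frequencies and functional classes.

Throughout this package "MAF" denotes the frequency of the *variant allele* —
the allele the translation tables associate with the pharmacogenomic effect —
within a population, ancestral group, or the whole cohort.  Because the
designation is pharmacological rather than statistical, the value may exceed
0.5 (a "minor" allele can be the majority allele in some populations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, MISSING, VAR, VariantDef

#: Variants with MAF at or below this value everywhere are reported as "rare"
#: in cohort summaries.
RARE_MAF = 0.05

#: Functional-class labels and the plotting colours attached to them.
BENIGN = "benign"
DAMAGING = "damaging"
UNKNOWN = "unknown"
AMBIGUOUS = "ambiguous"
CLASS_COLORS = {BENIGN: "green", DAMAGING: "darkred",
                UNKNOWN: "grey", AMBIGUOUS: "orange"}

#: Default predictor thresholds: SIFT < 0.05 is deleterious, PolyPhen > 0.2
#: is damaging; the benign call requires both predictors to agree.
SIFT_THRESHOLD = 0.05
POLYPHEN_THRESHOLD = 0.2


@dataclass(frozen=True)
class FrequencyTable:
    """Item x column frequency matrix with its allele-count denominators.

    ``values`` holds frequencies in [0, 1] (NaN where the denominator is 0);
    ``denominators`` holds the number of allele calls each cell is based on.
    Items are variant rsIDs or ``gene:haplotype`` names; columns are
    populations, ancestral groups, or the single column ``ALL``.
    """

    values: pd.DataFrame
    denominators: pd.DataFrame
    level: str

    def __post_init__(self):
        v, d = self.values, self.denominators
        assert v.shape == d.shape and list(v.index) == list(d.index)
        arr = v.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("frequencies outside [0, 1]")
        if ((d.to_numpy() == 0) & ~np.isnan(arr)).any():
            raise ValueError("defined frequency with zero denominator")

    @property
    def items(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


def compute_maf(gm: GenotypeMatrix, level: str = "population") -> FrequencyTable:
    """Variant-allele frequency per variant per column at the given level.

    The denominator is the number of non-missing allele calls (REF, VAR and
    OTHER all count); the numerator counts VAR states.  Columns pool allele
    counts over their samples, so group-level values are allele-count-weighted
    means of the member populations, not plain averages.
    """
    if not gm.samples or not gm.variants:
        raise ValueError("empty genotype matrix")
    strata = gm.sample_indices_by(level)
    rsids = gm.rsids
    values = {}
    denoms = {}
    for label, idx in strata.items():
        block = gm.calls[idx]                      # (n, V, 2)
        var_count = (block == VAR).sum(axis=(0, 2))
        called = (block != MISSING).sum(axis=(0, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(called > 0, var_count / np.maximum(called, 1), np.nan)
        values[label] = freq
        denoms[label] = called
    return FrequencyTable(
        values=pd.DataFrame(values, index=pd.Index(rsids, name="item")),
        denominators=pd.DataFrame(denoms, index=pd.Index(rsids, name="item")),
        level=level,
    )


def classify_variant(sift: float | None, polyphen: float | None,
                     sift_thr: float = SIFT_THRESHOLD,
                     polyphen_thr: float = POLYPHEN_THRESHOLD) -> str:
    """Classify a variant from its SIFT and PolyPhen scores.

    * ``benign``   — SIFT >= sift_thr and PolyPhen <= polyphen_thr
    * ``damaging`` — SIFT <  sift_thr and PolyPhen >  polyphen_thr
    * ``unknown``  — either score unavailable
    * ``ambiguous``— the two predictors disagree
    """
    for label, score in (("sift", sift), ("polyphen", polyphen)):
        if score is not None and not (0.0 <= score <= 1.0):
            raise ValueError(f"{label} score {score} not in [0,1]")
    if sift is None or polyphen is None:
        return UNKNOWN
    if sift >= sift_thr and polyphen <= polyphen_thr:
        return BENIGN
    if sift < sift_thr and polyphen > polyphen_thr:
        return DAMAGING
    return AMBIGUOUS


def classify_variants(defs: list[VariantDef], **kwargs) -> pd.Series:
    """Per-variant functional class, indexed by rsID."""
    return pd.Series({d.rsid: classify_variant(d.sift, d.polyphen, **kwargs)
                      for d in defs}, name="class")


def delta_maf(ft: FrequencyTable) -> pd.Series:
    """Per-item spread of frequencies: max minus min over defined columns.

    Intended for a table over ancestral groups; items with fewer than two
    defined columns get NaN.
    """
    arr = ft.values.to_numpy(dtype=float)
    defined = (~np.isnan(arr)).sum(axis=1)
    safe = np.where(np.isnan(arr), 0.0, arr)
    hi = np.max(np.where(np.isnan(arr), -np.inf, safe), axis=1)
    lo = np.min(np.where(np.isnan(arr), np.inf, safe), axis=1)
    spread = np.where(defined >= 2, hi - lo, np.nan)
    return pd.Series(spread, index=ft.values.index, name="delta_maf")


def filter_extreme_variants(ft: FrequencyTable, common_thr: float = 0.1,
                            rare_thr: float = 0.005) -> set[str]:
    """Items common (>= common_thr) in at least one column and rare
    (<= rare_thr) in at least one other."""
    arr = ft.values.to_numpy(dtype=float)
    common = np.max(np.where(np.isnan(arr), -np.inf, arr), axis=1) >= common_thr
    rare = np.min(np.where(np.isnan(arr), np.inf, arr), axis=1) <= rare_thr
    keep = common & rare
    return {item for item, k in zip(ft.values.index, keep) if k}


def common_damaging_profile(ft: FrequencyTable, classes: pd.Series,
                            thr: float = 0.1) -> pd.DataFrame:
    """Per-column counts of common damaging and common benign variants.

    Returns a DataFrame indexed by column (population) with integer columns
    ``damaging`` and ``benign``.
    """
    out = pd.DataFrame(0, index=pd.Index(ft.columns, name="population"),
                       columns=[DAMAGING, BENIGN], dtype=int)
    for rsid in ft.items:
        cls = classes.get(rsid)
        if cls not in (DAMAGING, BENIGN):
            continue
        row = ft.values.loc[rsid]
        for col in ft.columns:
            val = row[col]
            if not np.isnan(val) and val >= thr:
                out.loc[col, cls] += 1
    return out


def fraction_rare(ft: FrequencyTable, thr: float = RARE_MAF) -> pd.Series:
    """Per-column fraction of variants with frequency <= thr (cohort summary)."""
    arr = ft.values
    return (arr <= thr).sum() / arr.notna().sum()


def write_frequency_table(ft: FrequencyTable, path: str,
                          denominators_path: str | None = None) -> None:
    ft.values.to_csv(path, sep="\t", float_format="%.6g")
    if denominators_path:
        ft.denominators.to_csv(denominators_path, sep="\t")
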