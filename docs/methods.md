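# Methods

This note documents the models, rules and numerical choices behind `popgx`,
and what the synthetic cohorts used for validation do and do not emulate.

## Translation tables and the wild type

A translation table is a haplotype × variant matrix of allele strings for one
gene. The first row is the reference ("wild-type") haplotype; every other
haplotype is characterized by the columns where it departs from that row, and
its *variability* is the count of such columns (the wild type has variability
0 by definition). Allele cells are concrete nucleotide strings (`[ACGT]+`),
insertions written as the anchor base plus the inserted sequence, deletions
as the token `del`; IUPAC ambiguity codes are rejected because a haplotype
definition is a concrete sequence claim. Mixed case is normalized to upper
case.

Each column must be biallelic relative to the wild type: one wild-type allele
plus at most one alternative across all rows. This is stricter than the bare
matrix format requires, but the whole downstream model — a single designated
variant allele per rsID, REF/VAR strand states — cannot represent two
distinct alternatives at one position, so tables that need them are rejected
at parse time with an explicit error rather than silently mis-matched.

### Restriction to observable variants

Real cohorts rarely carry every variant a table mentions.
`restrict_table(table, available_rsids)`:

1. drops the unobservable columns;
2. drops every non-wild-type haplotype that required an alternative allele at
   a dropped column (it is no longer distinguishable from rows agreeing with
   it elsewhere);
3. merges retained haplotypes that have become identical over the remaining
   columns under a composite `A|B` name (members sorted lexicographically) —
   this also collapses genuinely duplicated definitions;
4. never drops the wild type.

The operation is idempotent and leaves all retained rows pairwise distinct,
so exact matching stays well defined. Merging (rather than silently dropping
duplicates) was chosen so haplotype-frequency mass remains attributable; the
run log reports which haplotypes each restriction dropped.

## Genotype extraction

Strand states at each variant are coded REF (wild-type allele), VAR (the
designated variant allele), OTHER (an observed allele that is neither, e.g. a
third allele at a multi-allelic site) or MISSING. VCF records are located by
rsID first, chrom+pos as fallback; REF/ALT orientation is resolved per record
by allele identity, flipping when the VCF's REF is the table's variant
allele, and excluding (with a log entry) records matching neither orientation
— allele-identity agreement is also the only assembly-consistency check
performed, so annotations must be on the VCF's assembly. Multi-allelic ALT
alleles other than the designated one become OTHER rather than MISSING: they
are real observations that should fail haplotype matching and surface in the
unmatched tally, not vanish from denominators. The unphased flag is only kept
for heterozygous calls, where phase is informative.

## Frequencies

*Variant level.* MAF(v, column) = VAR strand count / non-missing strand
count, pooled over the column's samples. Group-level values therefore equal
allele-count-weighted means of member populations, not plain averages — with
unbalanced population sizes the two differ. A zero denominator leaves the
cell undefined (NaN) with its denominator recorded in a sidecar table.

ΔMAF is max − min frequency over ancestral groups; it needs at least two
defined group values, else NaN. The extreme-item filter keeps items with
frequency ≥ 0.1 (common) in at least one population *and* ≤ 0.005 (rare) in
at least one other; both conditions can never hold in the same population, so
no explicit "other" check is needed. A separate reporting constant (0.05)
summarizes what fraction of variants are rare everywhere. All thresholds are
parameters of `RunConfig`.

*Functional classes.* benign = SIFT ≥ 0.05 ∧ PolyPhen ≤ 0.2; damaging =
SIFT < 0.05 ∧ PolyPhen > 0.2; unknown = either score missing; ambiguous =
the predictors disagree. The four labels partition the variant set. The
thresholds are configurable; 0.05/0.2 are the defaults because they make the
benign and damaging cells exact complements over the two scores.

*Haplotype level.* HAF(h, column) = strands matched to h / (2 × samples in
the column). Unmatched strands stay in the denominator, and strands belonging
to ambiguous calls (see below) form a third, separately reported mass, giving
the exact conservation identity ΣHAF + unmatched + ambiguous = 1 per gene and
column — the invariant the tests check to 1e-12.

## Diplotype calling

Matching is exact: a strand matches haplotype h iff its translated allele
equals h's allele at every table column; OTHER or MISSING anywhere makes the
strand UNMATCHED. Partial or best-overlap matching is deliberately not
offered — the unmatched rate is itself one of the quantities of interest, and
exact semantics keep it interpretable. If a raw table contains duplicate
rows, the first in definition order wins (restriction merges them anyway).

Phased genotypes are matched strand by strand. For unphased heterozygous
sites every phase assignment is enumerated (capped at 16 unphased sites,
2^16 assignments — far above anything a per-gene table produces) and the
distinct unordered diplotypes where *both* strands match are collected:
exactly one → a normal call; several → an ambiguous call carrying the full
consistent set; none → UNMATCHED/UNMATCHED. Ambiguous calls are excluded from
HAF numerators and phenotype assignment and reported as their own mass;
phased cohorts never produce them.

## Phenotypes

WT/WT, WT/V, V/V according to how many strands match the wild-type
haplotype; any unmatched strand or ambiguous call is UNASSIGNED. Label
frequencies are computed among assigned samples only, so the three labels sum
to 1 per (gene, population); assignment *coverage* (assigned/total) is
tracked per gene over the whole cohort. The high-difference screen selects
genes with coverage ≥ 0.9 where some label reaches ≥ 0.8 in one population
and ≤ 0.2 in another. Coverage is evaluated globally per gene (not per
population): the gate expresses "the gene is callable in this cohort", and a
global denominator keeps it monotone in data quality. The
normal/intermediate/abnormal metabolizer reading of the three labels is an
annotation (`METABOLIZER_STATUS` map), not a separate computation.

## Synthetic cohorts

`SimConfig` specifies populations (code, ancestral group, size), per-gene
translation tables with aligned variant definitions, per-population haplotype
frequency vectors (sum ≤ 1), and missingness/unphasing rates. Sampling is
random mating: each sample's two strands are independent draws from its
population's vector. Residual mass (1 − Σ frequencies) yields a "novel"
strand — a random allele combination rejection-sampled against the table
rows, so it is guaranteed unmatched and the expected unmatched rate equals
the configured mass exactly. Missingness then unphasing noise are applied per
genotype. Every gene draws from substreams seeded by (seed, gene index), so
the output is byte-identical for a fixed seed and unchanged by appending
genes.

Closed-form expectations used in validation: the implied variant-allele
frequency is the sum of haplotype frequencies carrying that variant's
alternative allele (defined only with zero novel mass); implied phenotype
frequencies among assigned samples follow Hardy–Weinberg pairing of the
renormalized on-table vector (WT/WT = (p_wt/s)², etc.).

The reference scenario (`default_config`) is 5 populations (YRI, LWK → AFR;
CEU, TSI → EUR; CHB → EAS) of 500 samples each and 3 genes of 4–8 variants
and 4–6 haplotypes: one gene with a strong wild-type frequency cline
(0.95 → 0.10) so phenotype differentiation occurs, two with flat-Dirichlet
frequency vectors. These sizes keep every binomial standard error near 1%,
tight enough that parameter-recovery checks are meaningful, while the full
validation suite runs in seconds.

What the simulation does *not* emulate: linkage disequilibrium beyond
haplotype co-inheritance, demographic history (drift, admixture, selection),
genotyping error that mimics real allele-frequency spectra, copy-number
variation (whole-gene deletions/duplications such as CYP2D6's), or
multi-allelic sites. Passing recovery tests therefore demonstrates the
*estimators and rules* are correct under the stated sampling model, not that
the pipeline is robust to every artifact of real sequencing data.

## Numerical and degenerate-input choices

* Frequencies are plain double-precision ratios; conservation identities hold
  to machine epsilon and are asserted at 1e-12.
* Zero denominators (no samples or all-missing cells) give NaN values with a
  zero recorded denominator, never 0/0 silently.
* Ties in duplicate-row matching resolve to definition order; composite merge
  names sort members lexicographically.
* Heatmap and table ordering is input order; hierarchical clustering of
  heatmap axes is cosmetic and intentionally omitted.
* Chromosome ideograms would need cytoband files; the per-gene track plot
  shows the position axis, functional classes and the frequency heatmap
  without the ideogram band.

## Known limitations

* Biallelic-per-column tables only (rejected otherwise, see above).
* No copy-number or hybrid-allele calling; no activity-score metabolizer
  categories (poor/intermediate/normal/ultrarapid) — only the three-level
  scheme.
* No liftover: annotation coordinates must match the VCF assembly.
* Sub-allele naming semantics (e.g. *2A vs *2B relationships) are not
  interpreted; names are opaque labels.
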