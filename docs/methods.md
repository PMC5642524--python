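# Methods

`gastrosubtype` re-implements, as tested library code, the downstream
analysis of a 107-patient gastric-cancer cohort profiled with a 43-gene
tumor/normal sequencing panel, a five-marker MSI PCR assay, EBV qPCR, and
orthogonal copy-number evidence. This note documents the models and
procedures, the parameters that matter, what the synthetic cohort
generator does and does not emulate, and the numerical choices made where
the upstream description was silent.

## Variant post-filtering

The package consumes annotated variant tables (TSV, or a minimal VCF with
`DP`/`AF` INFO keys); alignment, calling and annotation are out of scope.
Two cascades are applied per case:

* **Somatic**: tumor VAF > 5 %, total depth > 50×, exonic (splice-site
  calls are admitted), population frequency < 0.005, no support in the
  matched normal, and present in at most 2 non-tumor samples cohort-wide
  (panel of normals, counting distinct cases rather than reads).
* **Germline**: present in both tumor and matched normal with both VAFs
  > 30 %, both depths > 50×, population frequency < 0.01.

Three interpretation decisions were open and are fixed as follows:

1. *Boundary semantics*: all comparisons are strict, so a depth of exactly
   50 is rejected. The thresholds were stated as strict inequalities and
   are implemented verbatim.
2. *Population frequency*: the maximum across the three databases (1000
   Genomes, ESP6500, ExAC) is compared against the cutoff; an absent value
   counts as 0. This is the conservative reading of "below the cutoff in
   each database".
3. *Matched-normal evidence*: a somatic call survives if the site-allele
   is absent from the normal table or present at VAF < 2 % — the
   behavior of tumor/normal callers in the Varscan family, which the
   upstream pipeline delegated to without stating a cutoff
   (`FilterThresholds.normal_max_vaf`, configurable).

Consequence classes are derived from HGVS p. strings: `Ter`/`*` and
frameshifts → `trunc`; frame-preserving `del`/`dup`/`ins` → `in_frame`;
single-residue substitutions → `missense`; splice annotation terms →
`splicing`; anything unparseable → `other` (logged, never dropped).

Recurrence tallies group variants by gene and normalized protein change;
`del` and `dup` at the same residue range are pooled into one `del/dup`
event (replication slippage at the same repeat), with a configurable
pooling map for other equivalences. A variant is recurrent at ≥ 2 distinct
cases.

## MSI calling

Instability is assessed per marker (BAT-25, BAT-26, NR-21, NR-24, NR-27)
by comparing tumor and matched-normal allele-length histograms. The
published assay judged electropherograms by eye; the numeric rule here is
this package's own construction:

* **novel-allele mass**: total tumor support at lengths farther than
  `tolerance_bp` (default 1 bp) from every allele in the normal profile;
  unstable when ≥ `min_novel_fraction` (default 0.20);
* **modal shift**: unstable when the modal length moves by more than
  `max_shift_bp` (default 1 bp).

Either condition suffices. Status aggregation follows the standard
pentaplex rule — 0 unstable markers: MSS; exactly 1: MSI-L; ≥ 2: MSI-H —
verified against brute-force enumeration of all 32 flag vectors
(1 / 5 / 26).

## Copy-number calling

Per-target log2 ratios are computed as
`log2((tumor/median_tumor) / (normal/median_normal))`; zero-depth targets
are masked. A three-state HMM (deletion, copy-neutral, duplication) with
Gaussian emissions is decoded by Viterbi, restarting at chromosome
boundaries. Defaults:

| parameter | default | rationale |
|---|---|---|
| state means | −1, 0, +0.58 | single-copy loss / neutral / single-copy gain (log2 3/2) in a diploid; amplification beyond one copy is not distinguished |
| emission SD | 0.2 (or IQR/1.349 of the ratios, floored at 0.05, when unset) | the robust mid-50 % estimate ignores CNA-driven tails |
| stay probability | 0.98 | merges multi-exon events without freezing the chain |
| prior | (0.01, 0.98, 0.01) | strong copy-neutral prior |
| min. supporting targets | 2 | suppresses single-exon artifacts |

A gene is called non-neutral when its most frequent non-neutral decoded
state has at least `min_targets` supporting targets. Viterbi optimality is
property-tested against exhaustive path enumeration (≤ 3⁸ paths).
Concordance against an orthogonal reference (e.g. Her2 IHC) reports
sensitivity and specificity with exact Clopper–Pearson intervals;
undefined quantities (no positives) are `None`, never 0.

## Serial subtype classification

Strict precedence: EBV-positive → **EBV**; else any marker instability
(MSI-L *or* MSI-H) → **MSI**; else any gene-level CNA → **CIN**; else
**GS**. Two deliberate conventions:

* MSI-L joins the MSI arm. TCGA proper restricts the subtype to MSI-H;
  the cohort this package models counts 19 MSI-subtype cases = 15 MSI-H +
  4 MSI-L, which forces the inclusive rule.
* EBV positivity is a threshold on the qPCR copy number
  (`ebv_min_copies`, default 100 — a detection-limit convention; the
  synthetic generator emits positives ≥ 10³ copies so the margin is wide).
* An externally supplied CNA status (e.g. from a SNP array) overrides the
  panel caller when present; otherwise CIN requires ≥ 1 gene-level call
  from coverage.

## Cohort statistics

Gene-by-subtype tables count each case once per gene. Mutation rate per
subtype is the column sum divided by the subtype size. Percentages are
rounded half-away-from-zero to one decimal throughout, matching the
conventions of the published tables.

The per-gene association test is the Fisher–Freeman–Halton exact test on
the 2×K (mutated / not-mutated × subtype) table: with margins fixed, the
top row is multivariate hypergeometric, and the p-value sums the
probabilities of all tables at most as probable as the observed one.
Numerical choices:

* tie comparison uses a *relative* tolerance of 1e-12
  (`p_table ≤ p_obs·(1+1e-12)`); an absolute tolerance would misrank
  tables when `p_obs` is itself below 1e-12;
* enumeration is exact up to a 5×10⁶-table budget; beyond it, a seeded
  Monte Carlo estimate over 10⁵ multivariate-hypergeometric draws is used
  (with the +1 correction including the observed table);
* the Pearson chi-square p-value is reported alongside; the exact test is
  primary because most table rows have small expected cells;
* no multiple-testing correction is applied — p-values are reported raw,
  as in the source tables.

The test is verified against an independent enumeration built on scipy's
`multivariate_hypergeom.pmf` and calibrated under the null (empirical size
≤ 0.06 at α = 0.05 over 2,000 simulated tables).

Pathway summaries count a case as altered in a gene set when it carries a
retained somatic variant or a non-neutral CNA in any member gene (RTK set:
ERBB2, EGFR, FGFR2, KDR; RAS/PI3K set: KRAS, BRAF, PIK3CA, PTEN, MTOR); a
case altered in both sets counts once in the combined figure. The
mutual-exclusivity report lists cases carrying both a substitution and a
copy-number event in the same gene.

Clopper–Pearson intervals come from beta quantiles, with the conventional
closed ends (lower = 0 at x = 0, upper = 1 at x = n).

## Survival analysis

Relapse-free survival events are loco-regional recurrence, distant
metastasis, or death from any cause; cancer-specific survival events are
GC-related deaths (a GCSS event therefore implies an RFS event, and the
record type enforces it). Times are days from surgery; months appear only
in display.

Kaplan–Meier estimation and the log-rank test are delegated to lifelines.
Cox proportional-hazards models use the **Breslow** tie approximation
(statsmodels `PHReg`) — the commonest default, and the one under which the
two-group log-rank statistic exactly equals the Cox score test, a property
the suite checks to 1e-6 on tie-free data. Wald confidence intervals;
zero-variance covariates are reported as HR 1 with NA inference;
coefficients exceeding |5| on standardized inputs are flagged as potential
separation. Convergence is verified by the post-fit gradient norm.

The published multivariate hazard ratios (MTOR 9.26, CCND1 5.71, stage III
1.9, stage IV 2.15) cannot be reproduced without the per-case follow-up
data, which was never deposited; the Cox implementation is instead
validated by parameter recovery — a 95 % Wald CI covering the true hazard
ratio of 3 in ≥ 90 % of 100 simulated replicates (n = 500, ~20 %
censoring).

## Synthetic cohort generator

The generator emits, per case, exactly the post-assay summaries the
pipeline consumes: tumor/normal variant tables, EBV qPCR copies, MSI
marker histograms, per-target coverage, clinical covariates and follow-up.
Each case carries a hidden true subtype; assay outputs are drawn
consistently with that truth, so pipeline accuracy against the withheld
manifest is measurable.

**Modes.** `exact` deterministically reproduces the published marginal
structure — 7/19/46/35 subtype counts, the published per-gene mutated-case
counts within each subtype, the 15 MSI-H + 4 MSI-L split — for table
reproduction. `sampling` draws i.i.d. from the same profiles for
statistical property tests. Subtype prevalences, per-gene probabilities
(count/size) and the CNA gene weights all come from the published tables.

**Distributional choices** (the source reports thresholds, not
distributions):

* somatic VAF ~ Beta(2, 4) truncated to [0.05, 1] (mean ≈ 0.33, the bulk
  between 10 % and 60 %, consistent with the 5–33 % range quoted for
  recurrent indels and higher clonal substitutions);
* per-variant depth ~ negative binomial (mean 700, dispersion 3), floored
  at 60× — matching the spread of the published germline table
  (147–1,498×) under a panel with very high average coverage;
* germline VAF ~ Normal(0.5, 0.05), clipped;
* germline variants come from the 18 distinct published germline
  site-alleles, carried with their observed cohort frequencies and
  synthetic rare population frequencies (< 0.01);
* MSI: stable markers mirror the quasi-monomorphic normal profile
  (80/10/10 % at mode ± 1 bp); unstable markers carry 35 % novel mass
  4 bp below the mode — beyond the ± 1 bp tolerance and above the 20 %
  novel-fraction cutoff;
* coverage: 8 targets per gene; tumor depth is the normal depth times
  2^shift (+0.58 gain, −1 loss over planted CNA genes) times lognormal
  noise (σ = 0.05);
* per-marker instability probability 0.5 within the MSI subtype (MSI-H :
  MSI-L ≈ 0.81 : 0.16, close to the observed 15 : 4), 0 elsewhere; in
  sampling mode an MSI-truth case redraws until at least one marker is
  unstable so the hidden truth stays consistent with its assays;
* every CIN-truth case receives one panel-visible CNA. In the source
  cohort CIN status came from SNP arrays and the panel caller detected
  CNVs in only 14/46 CIN cases; planting panel-visible events in all CIN
  cases is a deliberate simplification that lets the panel caller alone
  support classification (an externally supplied CNA flag is the
  alternative input path);
* clinical covariates are multinomial draws from the published
  subtype-conditional cross-tabs; TNM categories are drawn compatible
  with the sampled AJCC (7th edition, gastric) stage group, so stage and
  TNM are always consistent (per-category pT/pN marginals are therefore
  approximate);
* follow-up: exponential relapse times with stage-multiplied hazards
  (baseline median 1,500 days; multipliers 1 / 1.5 / 2.5 / 4 for stages
  I–IV), uniform censoring on [100, 1800] days, follow-up available for
  72/107 of cases, GC-specific death in 12/19 of relapses — the
  availability, relapse and death fractions observed in the study.

**Noise.** Two sub-threshold artifact variants per case (low VAF, low
depth, or high population frequency — all rejected by construction) and a
recurrent off-panel artifact site present in ~30 % of normals exercise the
filters and the panel-of-normals exclusion without perturbing any
cohort-level count.

**Determinism.** One integer seed; all streams derive from it by
`SeedSequence.spawn`. Identical specs serialize to byte-identical cohort
directories (tested).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: FFPE artifacts and strand bias, subclonal
architecture and purity variation, gene–gene mutation correlation (gene
indicators are independent given the subtype; the published data only
constrain the marginals), realistic electropherogram stutter, GC-content
coverage waves, and informative censoring. Round-trip accuracy of 1.0 on
the exact cohort demonstrates the pipeline's internal consistency, not
clinical performance.

## Test scale and statistical test design

Problem sizes in the default suite are chosen to make every check sharp at
desk scale: the cohort fixtures use the study's n = 107; frequency
recovery uses n = 2,000 (binomial SDs small enough to detect a misencoded
probability); null calibration uses 2,000 simulated tables; Cox coverage
uses 100 replicates of n = 500. The frequency-recovery check is
family-wise rather than per-cell: with ~156 simultaneous gene-by-subtype
cells, a hard 3-SD bound per cell would fail for roughly a third of seeds
by chance alone, so the suite instead bounds the maximum deviation at
4.5 SD and the number of > 3 SD exceedances at 2 (expected ≈ 0.4 under the
null). Zero-probability cells must be exactly zero.

## Known limitations

* The MSI instability metric is a construction over summary histograms;
  it is not a fragment-trace signal processor and has no validated
  clinical operating point.
* The CNV caller does not model purity, ploidy, or allele-specific copy
  number; gain vs high-level amplification is not distinguished.
* The FFH Monte Carlo fallback has sampling error ~1/√draws; at the
  default 10⁵ draws, p-values near a decision threshold should be
  re-run with a larger budget.
* Printed p-values in the source tables come from SPSS and may mix exact
  and chi-square methods; agreement beyond 3 decimals is not expected and
  not asserted.
* The published Her2 IHC validation counts are internally inconsistent
  (4 positives + 39 negatives stated out of 54 cases), and the printed
  specificity CI is not reproducible from n = 39; the concordance metrics
  here are generic and verified against their own closed forms instead.
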