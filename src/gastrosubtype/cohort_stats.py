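"""Cohort-level statistics: gene-by-subtype tables, mutation rates, exact
r x c association tests, pathway alteration summaries, exact binomial CIs.

The Fisher-Freeman-Halton (FFH) test generalizes Fisher's exact test to
2 x K tables: with both margins fixed, the cell counts follow a
multivariate hypergeometric distribution, and the p-value sums the
probabilities of all tables no more probable than the observed one. The
enumeration is exact up to a table budget, beyond which a seeded Monte
Carlo estimate over multivariate-hypergeometric draws is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import chi2_contingency

from .subtype_classifier import SUBTYPES, CaseAssay

#: Exact-enumeration budget; larger tables fall back to Monte Carlo.
ENUMERATION_BUDGET = 5_000_000
MONTE_CARLO_DRAWS = 100_000
#: Relative tolerance when comparing table probabilities for ties.
TIE_RTOL = 1e-12


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (matches the published tables' rounding)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class GeneSubtypeTable:
    genes: tuple[str, ...]
    subtypes: tuple[str, ...]
    mutated_counts: np.ndarray  # genes x subtypes, case counts
    subtype_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.mutated_counts)
        sizes = np.asarray(self.subtype_sizes)
        if (counts < 0).any() or (counts > sizes[None, :]).any():
            raise ValueError("cell count outside [0, subtype size]")

    def percentages(self) -> np.ndarray:
        sizes = np.asarray(self.subtype_sizes, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * self.mutated_counts / sizes[None, :]
        return np.vectorize(lambda v: round_half_up(v, 1))(np.nan_to_num(pct))

    def row(self, gene: str) -> np.ndarray:
        return self.mutated_counts[self.genes.index(gene)]


@dataclass(frozen=True)
class ExactTestResult:
    p_value: float
    method: str  # ffh_enumeration | ffh_montecarlo | chi_square
    n_tables_enumerated: Optional[int] = None
    n_draws: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class PathwayGeneSets:
    rtk: frozenset[str]
    ras_pi3k: frozenset[str]

    @classmethod
    def default(cls) -> "PathwayGeneSets":
        from .tables import RAS_PI3K_GENES, RTK_GENES

        return cls(rtk=RTK_GENES, ras_pi3k=RAS_PI3K_GENES)


# ---------------------------------------------------------------------------
# Gene x subtype table


def gene_subtype_table(
    cases: Sequence[CaseAssay],
    labels: Mapping[str, str],
    gene_list: Sequence[str],
    subtypes: Sequence[str] = SUBTYPES,
) -> GeneSubtypeTable:
    """Count, per gene and subtype, cases with >=1 retained somatic variant.

    A case counts once per gene regardless of variant multiplicity.
    """
    for c in cases:
        if c.case_id not in labels:
            raise ValueError(f"unlabeled case {c.case_id!r}")
    sizes = tuple(
        sum(1 for c in cases if labels[c.case_id] == s) for s in subtypes
    )
    counts = np.zeros((len(gene_list), len(subtypes)), dtype=int)
    sub_index = {s: j for j, s in enumerate(subtypes)}
    gene_index = {g: i for i, g in enumerate(gene_list)}
    for c in cases:
        j = sub_index[labels[c.case_id]]
        for g in c.mutated_genes:
            i = gene_index.get(g)
            if i is not None:
                counts[i, j] += 1
    return GeneSubtypeTable(
        genes=tuple(gene_list),
        subtypes=tuple(subtypes),
        mutated_counts=counts,
        subtype_sizes=sizes,
    )


def mutation_rate_per_subtype(table: GeneSubtypeTable) -> dict[str, Optional[float]]:
    """Mean mutated-gene count per case, by subtype (1-decimal, half-up).

    rate = (sum over genes of mutated-case counts) / subtype size; a
    zero-size subtype yields None (NA).
    """
    rates: dict[str, Optional[float]] = {}
    col_sums = table.mutated_counts.sum(axis=0)
    for j, s in enumerate(table.subtypes):
        n = table.subtype_sizes[j]
        rates[s] = round_half_up(col_sums[j] / n, 1) if n > 0 else None
    return rates


# ---------------------------------------------------------------------------
# Exact tests


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def ffh_exact_test(
    counts: Sequence[Sequence[int]] | np.ndarray,
    *,
    budget: int = ENUMERATION_BUDGET,
    n_draws: int = MONTE_CARLO_DRAWS,
    seed: int = 20170722,
) -> ExactTestResult:
    """Fisher-Freeman-Halton exact test for a 2 x K table.

    Enumerates all tables with the observed margins; the p-value is the
    total multivariate-hypergeometric probability of tables at most as
    probable as the observed one (relative tie tolerance 1e-12). Above
    ``budget`` candidate tables, falls back to seeded Monte Carlo.
    """
    table = np.asarray(counts, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x K table")
    if (table < 0).any():
        raise ValueError("negative cell count")
    col = table.sum(axis=0)
    m1 = int(table[0].sum())
    N = int(table.sum())
    K = table.shape[1]
    if N == 0 or m1 == 0 or m1 == N or (col == 0).all():
        return ExactTestResult(p_value=1.0, method="ffh_enumeration", n_tables_enumerated=1)

    log_denom = float(_log_binom(N, m1))

    def log_prob(top: np.ndarray) -> float:
        return float(_log_binom(col, top).sum() - log_denom)

    lp_obs = log_prob(table[0])
    p_obs = math.exp(lp_obs)
    threshold = p_obs * (1.0 + TIE_RTOL)

    # upper bound on the number of candidate tables
    bound = 1
    for c in col:
        bound *= min(int(c), m1) + 1
        if bound > budget:
            break
    if bound > budget:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_hypergeometric(col, m1, size=n_draws)
        lps = _log_binom(col[None, :], draws).sum(axis=1) - log_denom
        hits = int((np.exp(lps) <= threshold).sum())
        # add-one to include the observed table itself
        return ExactTestResult(
            p_value=(hits + 1) / (n_draws + 1),
            method="ffh_montecarlo",
            n_draws=n_draws,
        )

    total = 0.0
    n_tables = 0
    suffix_cap = np.concatenate([np.cumsum(col[::-1])[::-1][1:], [0]])
    top = np.zeros(K, dtype=np.int64)

    def recurse(k: int, remaining: int, acc: float) -> None:
        nonlocal total, n_tables
        if k == K - 1:
            if 0 <= remaining <= col[k]:
                lp = acc + float(_log_binom(int(col[k]), remaining)) - log_denom
                n_tables += 1
                if math.exp(lp) <= threshold:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(suffix_cap[k]))
        hi = min(int(col[k]), remaining)
        for x in range(lo, hi + 1):
            recurse(k + 1, remaining - x, acc + float(_log_binom(int(col[k]), x)))

    recurse(0, m1, 0.0)
    return ExactTestResult(
        p_value=min(total, 1.0),
        method="ffh_enumeration",
        n_tables_enumerated=n_tables,
    )


def chi_square_test(counts: Sequence[Sequence[int]] | np.ndarray) -> ExactTestResult:
    """Pearson chi-square test on an r x c table (no continuity correction)."""
    res = chi2_contingency(np.asarray(counts), correction=False)
    return ExactTestResult(p_value=float(res.pvalue), method="chi_square")


def gene_association_tests(
    table: GeneSubtypeTable, **kwargs
) -> dict[str, ExactTestResult]:
    """FFH exact test per gene row: mutated vs non-mutated across subtypes."""
    results = {}
    for i, gene in enumerate(table.genes):
        mutated = table.mutated_counts[i]
        not_mutated = np.asarray(table.subtype_sizes) - mutated
        results[gene] = ffh_exact_test(np.vstack([mutated, not_mutated]), **kwargs)
    return results


# ---------------------------------------------------------------------------
# Pathway summary


@dataclass(frozen=True)
class PathwaySummary:
    n_cases: int
    rtk_altered: int
    ras_pi3k_altered: int
    combined_altered: int
    combined_fraction_pct: float
    per_gene_altered: dict[str, int]
    #: gene -> case ids carrying both a substitution and an amplification
    exclusivity_violations: dict[str, list[str]]


def pathway_alteration_summary(
    cases: Sequence[CaseAssay],
    genesets: PathwayGeneSets | None = None,
) -> PathwaySummary:
    """Count cases altered (somatic variant OR non-normal CNA) per pathway.

    A case altered in both gene sets counts once in the combined figure.
    The mutual-exclusivity report lists, per gene, cases carrying both a
    substitution and a copy-number event in that gene.
    """
    gs = genesets or PathwayGeneSets.default()
    all_genes = gs.rtk | gs.ras_pi3k
    rtk = ras = combined = 0
    per_gene: dict[str, set[str]] = {g: set() for g in sorted(all_genes)}
    violations: dict[str, list[str]] = {}
    for case in cases:
        mut = case.mutated_genes
        cna = set(case.cna_genes)
        altered = (mut | cna) & all_genes
        if altered & gs.rtk:
            rtk += 1
        if altered & gs.ras_pi3k:
            ras += 1
        if altered:
            combined += 1
        for g in altered:
            per_gene[g].add(case.case_id)
        for g in sorted(mut & cna & all_genes):
            violations.setdefault(g, []).append(case.case_id)
    n = len(cases)
    return PathwaySummary(
        n_cases=n,
        rtk_altered=rtk,
        ras_pi3k_altered=ras,
        combined_altered=combined,
        combined_fraction_pct=round_half_up(100.0 * combined / n, 1) if n else 0.0,
        per_gene_altered={g: len(v) for g, v in per_gene.items()},
        exclusivity_violations=violations,
    )


# ---------------------------------------------------------------------------
# Exact binomial CI


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via beta quantiles.

    Lower bound is 0 when successes = 0; upper bound is 1 when
    successes = trials.
    """
    if trials < 1 or not (0 <= successes <= trials):
        raise ValueError(f"invalid counts: {successes}/{trials}")
    alpha = 1.0 - level
    lower = (
        0.0
        if successes == 0
        else float(beta_dist.ppf(alpha / 2, successes, trials - successes + 1))
    )
    upper = (
        1.0
        if successes == trials
        else float(beta_dist.ppf(1 - alpha / 2, successes + 1, trials - successes))
    )
    return lower, upper


# ---------------------------------------------------------------------------
# Report assembly


def gene_table_frame(
    table: GeneSubtypeTable,
    tests: Optional[Mapping[str, ExactTestResult]] = None,
) -> pd.DataFrame:
    """Table-4-style report: per-gene counts, percentages and p-values."""
    pct = table.percentages()
    rows = []
    for i, gene in enumerate(table.genes):
        row: dict = {"gene": gene}
        for j, s in enumerate(table.subtypes):
            row[f"{s}_n"] = int(table.mutated_counts[i, j])
            row[f"{s}_pct"] = pct[i, j]
        if tests is not None and gene in tests:
            row["p_value"] = tests[gene].p_value
            row["method"] = tests[gene].method
        rows.append(row)
    return pd.DataFrame(rows)
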