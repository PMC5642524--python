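"""Gene-level copy-number calling from tumor/normal panel coverage.

Per-target coverage ratios are normalized (each sample scaled by its median
target depth), log2-transformed, and decoded with a three-state hidden
Markov model (deletion / copy-neutral / duplication) under Gaussian
emissions, with a prior strongly favoring the copy-neutral state and a
sticky transition matrix that merges multi-exon calls. Gene-level calls
require a minimum number of supporting targets, suppressing single-exon
artifacts. Concordance of calls against an orthogonal reference (e.g. Her2
immunohistochemistry) is scored with exact binomial confidence intervals.

Default state means are -1 (single-copy loss) and +0.58 (single-copy gain,
log2(3/2)) on the log2-ratio scale; amplification beyond one copy is not
distinguished from gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CNV_STATES = ("deletion", "normal", "duplication")


@dataclass(frozen=True)
class HmmParams:
    state_means: tuple[float, float, float] = (-1.0, 0.0, 0.58)
    #: Shared emission SD; None = estimate from the middle 50% of ratios.
    emission_sd: Optional[float] = 0.2
    transition_stay_prob: float = 0.98
    prior: tuple[float, float, float] = (0.01, 0.98, 0.01)
    min_targets: int = 2

    def __post_init__(self) -> None:
        if self.emission_sd is not None and self.emission_sd <= 0:
            raise ValueError("emission_sd must be positive")
        if not (0 < self.transition_stay_prob < 1):
            raise ValueError("transition_stay_prob must be in (0,1)")
        if abs(sum(self.prior) - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")

    def transition_matrix(self) -> np.ndarray:
        stay = self.transition_stay_prob
        off = (1.0 - stay) / 2.0
        return np.full((3, 3), off) + np.eye(3) * (stay - off)


@dataclass
class CoverageBin:
    """One capture target with tumor/normal depths and its log2 ratio."""

    target_id: str
    gene_symbol: str
    chrom: str
    start: int  # 1-based, closed
    end: int
    tumor_depth: float
    normal_depth: float
    log2_ratio: Optional[float] = None
    masked: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end in target {self.target_id}")
        if self.tumor_depth < 0 or self.normal_depth < 0:
            raise ValueError("depths must be >= 0")


@dataclass(frozen=True)
class GeneCNA:
    gene_symbol: str
    state: str
    n_targets_supporting: int
    mean_log2_ratio: float

    def __post_init__(self) -> None:
        if self.state not in CNV_STATES:
            raise ValueError(f"invalid state {self.state!r}")


@dataclass(frozen=True)
class ConcordanceResult:
    sensitivity: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity: Optional[float]
    specificity_ci: Optional[tuple[float, float]]
    tp: int
    fp: int
    tn: int
    fn: int


def normalize_coverage(
    bins: Sequence[CoverageBin],
    normal_bins: Optional[Sequence[CoverageBin]] = None,
) -> list[CoverageBin]:
    """Compute per-target log2 coverage ratios.

    log2_ratio = log2((tumor/median_tumor) / (normal/median_normal)).
    Accepts either bins carrying both depths, or separate tumor/normal bin
    lists matched by target_id. Zero-depth targets are masked and excluded
    from decoding; all-zero coverage raises.
    """
    if normal_bins is not None:
        norm_by_id = {b.target_id: b for b in normal_bins}
        if set(norm_by_id) != {b.target_id for b in bins}:
            raise ValueError("tumor and normal target lists do not match")
        bins = [
            replace(b, normal_depth=norm_by_id[b.target_id].tumor_depth)
            for b in bins
        ]
    else:
        bins = [replace(b) for b in bins]
    t = np.array([b.tumor_depth for b in bins], dtype=float)
    n = np.array([b.normal_depth for b in bins], dtype=float)
    ok = (t > 0) & (n > 0)
    if not ok.any():
        raise ValueError("all targets have zero coverage")
    med_t = float(np.median(t[ok]))
    med_n = float(np.median(n[ok]))
    for b, good in zip(bins, ok):
        if good:
            b.log2_ratio = math.log2((b.tumor_depth / med_t) / (b.normal_depth / med_n))
            b.masked = False
        else:
            b.log2_ratio = None
            b.masked = True
    return list(bins)


def _estimate_sd(ratios: np.ndarray) -> float:
    """Robust shared emission SD from the middle 50% of ratios (IQR/1.349)."""
    q1, q3 = np.percentile(ratios, [25, 75])
    return max((q3 - q1) / 1.349, 0.05)


def _log_gauss(x: float, mean: float, sd: float) -> float:
    return -0.5 * ((x - mean) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


def hmm_segment(
    bins: Sequence[CoverageBin], params: HmmParams = HmmParams()
) -> list[Optional[str]]:
    """Viterbi-decode per-target copy-number states.

    Bins must be ordered by (chrom, start); the chain restarts from the
    prior at each chromosome boundary. Masked bins get None. Returns one
    state per input bin.
    """
    states: list[Optional[str]] = [None] * len(bins)
    usable = [(i, b) for i, b in enumerate(bins) if not b.masked and b.log2_ratio is not None]
    if not usable:
        return states
    sd = params.emission_sd
    if sd is None:
        sd = _estimate_sd(np.array([b.log2_ratio for _, b in usable]))
    log_prior = np.log(np.asarray(params.prior))
    log_trans = np.log(params.transition_matrix())
    means = params.state_means

    # split runs by chromosome
    run: list[tuple[int, CoverageBin]] = []
    runs: list[list[tuple[int, CoverageBin]]] = []
    for item in usable:
        if run and item[1].chrom != run[-1][1].chrom:
            runs.append(run)
            run = []
        run.append(item)
    runs.append(run)

    for run in runs:
        obs = [b.log2_ratio for _, b in run]
        T = len(obs)
        delta = np.empty((T, 3))
        psi = np.zeros((T, 3), dtype=int)
        for s in range(3):
            delta[0, s] = log_prior[s] + _log_gauss(obs[0], means[s], sd)
        for t_idx in range(1, T):
            for s in range(3):
                cand = delta[t_idx - 1] + log_trans[:, s]
                psi[t_idx, s] = int(np.argmax(cand))
                delta[t_idx, s] = cand[psi[t_idx, s]] + _log_gauss(obs[t_idx], means[s], sd)
        path = np.empty(T, dtype=int)
        path[-1] = int(np.argmax(delta[-1]))
        for t_idx in range(T - 2, -1, -1):
            path[t_idx] = psi[t_idx + 1, path[t_idx + 1]]
        for (i, _), s in zip(run, path):
            states[i] = CNV_STATES[s]
    return states


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    state: str
    n_targets: int
    mean_log2_ratio: float


def merge_segments(
    states: Sequence[Optional[str]], bins: Sequence[CoverageBin]
) -> list[Segment]:
    """Merge contiguous equal-state runs (per chromosome) into segments."""
    segments: list[Segment] = []
    cur: list[tuple[str, CoverageBin]] = []
    for state, b in zip(states, bins):
        if state is None:
            continue
        if cur and (state != cur[-1][0] or b.chrom != cur[-1][1].chrom):
            segments.append(_close_segment(cur))
            cur = []
        cur.append((state, b))
    if cur:
        segments.append(_close_segment(cur))
    return segments


def _close_segment(items: list[tuple[str, CoverageBin]]) -> Segment:
    bs = [b for _, b in items]
    return Segment(
        chrom=bs[0].chrom,
        start=min(b.start for b in bs),
        end=max(b.end for b in bs),
        state=items[0][0],
        n_targets=len(bs),
        mean_log2_ratio=float(np.mean([b.log2_ratio for b in bs])),
    )


def gene_cna_calls(
    states: Sequence[Optional[str]],
    bins: Sequence[CoverageBin],
    params: HmmParams = HmmParams(),
) -> list[GeneCNA]:
    """Collapse the decoded state path to per-gene copy-number calls.

    A gene is called non-normal when its most frequent non-normal state is
    supported by at least ``min_targets`` targets; otherwise it is normal.
    """
    by_gene: dict[str, list[tuple[str, CoverageBin]]] = {}
    for state, b in zip(states, bins):
        if state is None:
            continue
        by_gene.setdefault(b.gene_symbol, []).append((state, b))
    calls = []
    for gene in sorted(by_gene):
        items = by_gene[gene]
        support = {
            s: [b for st, b in items if st == s]
            for s in ("deletion", "duplication")
        }
        best = max(
            ("deletion", "duplication"),
            key=lambda s: (len(support[s]), s == "duplication"),
        )
        if len(support[best]) >= params.min_targets:
            sup = support[best]
            calls.append(
                GeneCNA(
                    gene_symbol=gene,
                    state=best,
                    n_targets_supporting=len(sup),
                    mean_log2_ratio=float(np.mean([b.log2_ratio for b in sup])),
                )
            )
        else:
            calls.append(
                GeneCNA(
                    gene_symbol=gene,
                    state="normal",
                    n_targets_supporting=len(items),
                    mean_log2_ratio=float(np.mean([b.log2_ratio for _, b in items])),
                )
            )
    return calls


def call_case_cnas(
    bins: Sequence[CoverageBin], params: HmmParams = HmmParams()
) -> list[GeneCNA]:
    """normalize -> segment -> gene calls for one case's coverage table."""
    ordered = sorted(bins, key=lambda b: (b.chrom, b.start))
    normalized = normalize_coverage(ordered)
    states = hmm_segment(normalized, params)
    return gene_cna_calls(states, normalized, params)


def concordance_metrics(
    calls: Sequence[bool], reference_labels: Sequence[bool], level: float = 0.95
) -> ConcordanceResult:
    """Sensitivity/specificity of binary calls vs reference, with exact CIs.

    Undefined quantities (zero positives or zero negatives in the
    reference) are reported as None.
    """
    from .cohort_stats import clopper_pearson

    if len(calls) != len(reference_labels):
        raise ValueError("calls and reference labels differ in length")
    tp = sum(1 for c, r in zip(calls, reference_labels) if c and r)
    fn = sum(1 for c, r in zip(calls, reference_labels) if not c and r)
    tn = sum(1 for c, r in zip(calls, reference_labels) if not c and not r)
    fp = sum(1 for c, r in zip(calls, reference_labels) if c and not r)
    sens = sens_ci = spec = spec_ci = None
    if tp + fn > 0:
        sens = tp / (tp + fn)
        sens_ci = clopper_pearson(tp, tp + fn, level)
    if tn + fp > 0:
        spec = tn / (tn + fp)
        spec_ci = clopper_pearson(tn, tn + fp, level)
    return ConcordanceResult(sens, sens_ci, spec, spec_ci, tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# I/O: BED-like TSV


_COVERAGE_COLUMNS = (
    "target_id", "gene_symbol", "chrom", "start", "end",
    "tumor_depth", "normal_depth",
)


def write_coverage_table(bins: Sequence[CoverageBin], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(b, c) for c in _COVERAGE_COLUMNS} for b in bins]
    ).to_csv(path, sep="\t", index=False)


def read_coverage_table(path: str | Path) -> list[CoverageBin]:
    df = pd.read_csv(path, sep="\t")
    for col in _COVERAGE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"coverage table missing column {col!r}")
    return [
        CoverageBin(
            target_id=str(r.target_id),
            gene_symbol=str(r.gene_symbol),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            tumor_depth=float(r.tumor_depth),
            normal_depth=float(r.normal_depth),
        )
        for r in df.itertuples(index=False)
    ]
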