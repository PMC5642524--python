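"""Serial TCGA-style molecular subtype assignment (EBV -> MSI -> CIN -> GS).

A case is classified in strict precedence order: EBV-positive tumors are
the EBV subtype; of the rest, any tumor with microsatellite instability
(MSI-L or MSI-H — instability at one or more of the five markers) is the
MSI subtype; of the rest, any tumor carrying a somatic copy-number
aberration is CIN; the remainder is genomically stable (GS).

Note the divergence from TCGA proper, which restricts the MSI subtype to
MSI-H: here MSI-L joins the MSI arm, matching the source study's
arithmetic (19 MSI-subtype cases = 15 MSI-H + 4 MSI-L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .cnv_caller import GeneCNA
from .msi_caller import MSI_STATUSES, MSIResult
from .variant_filtering import VariantCall

SUBTYPES = ("EBV", "MSI", "CIN", "GS")


class MissingAssayError(ValueError):
    """A required assay result is unresolved for a case."""


@dataclass
class ClinicalCovariates:
    """Clinicopathological covariates for one patient."""

    age: Optional[int] = None
    sex: Optional[str] = None
    lauren_class: Optional[str] = None
    who_class: Optional[str] = None
    pT: Optional[str] = None
    pN: Optional[str] = None
    M: Optional[str] = None
    ajcc_stage: Optional[str] = None
    anatomical_region: Optional[str] = None
    h_pylori: Optional[bool] = None
    lymphatic_invasion: Optional[str] = None
    venous_invasion: Optional[str] = None
    perineural_invasion: Optional[str] = None
    followup_days: Optional[float] = None
    relapse_event: Optional[bool] = None
    gc_death_event: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.followup_days is not None and self.followup_days < 0:
            raise ValueError("followup_days must be >= 0")


@dataclass
class CaseAssay:
    """One patient's resolved assay bundle, input to classification."""

    case_id: str
    ebv_positive: Optional[bool] = None
    msi: Optional[MSIResult] = None
    cna_positive: Optional[bool] = None
    somatic_calls: list[VariantCall] = field(default_factory=list)
    germline_calls: list[VariantCall] = field(default_factory=list)
    gene_cnas: list[GeneCNA] = field(default_factory=list)
    clinical: Optional[ClinicalCovariates] = None

    @property
    def mutated_genes(self) -> set[str]:
        return {c.gene_symbol for c in self.somatic_calls}

    @property
    def cna_genes(self) -> dict[str, str]:
        return {
            c.gene_symbol: c.state for c in self.gene_cnas if c.state != "normal"
        }


@dataclass(frozen=True)
class SubtypeDistribution:
    counts: dict[str, int]
    percentages: dict[str, float]
    n: int


def classify_case(
    ebv_positive: Optional[bool],
    msi_status: Optional[str],
    cna_positive: Optional[bool],
) -> str:
    """Serial classification of one case; precedence is strict and total."""
    if ebv_positive is None:
        raise MissingAssayError("EBV status unresolved")
    if ebv_positive:
        return "EBV"
    if msi_status is None:
        raise MissingAssayError("MSI status unresolved")
    if msi_status not in MSI_STATUSES:
        raise ValueError(f"invalid MSI status {msi_status!r}")
    if msi_status in ("MSI-L", "MSI-H"):
        return "MSI"
    if cna_positive is None:
        raise MissingAssayError("CNA status unresolved")
    return "CIN" if cna_positive else "GS"


def classify_assay(case: CaseAssay) -> str:
    msi_status = case.msi.status if case.msi is not None else None
    return classify_case(case.ebv_positive, msi_status, case.cna_positive)


def classify_cohort(
    cases: Sequence[CaseAssay],
) -> tuple[dict[str, str], SubtypeDistribution]:
    """Classify every case; return per-case labels and the distribution."""
    from .cohort_stats import round_half_up

    if not cases:
        raise ValueError("empty cohort")
    labels = {c.case_id: classify_assay(c) for c in cases}
    n = len(cases)
    counts = {s: sum(1 for v in labels.values() if v == s) for s in SUBTYPES}
    pcts = {s: round_half_up(100.0 * counts[s] / n, 1) for s in SUBTYPES}
    return labels, SubtypeDistribution(counts=counts, percentages=pcts, n=n)


def mutation_matrix(
    cases: Sequence[CaseAssay],
    labels: dict[str, str],
    gene_list: Sequence[str],
) -> pd.DataFrame:
    """Oncoprint-style gene x case 0/1 mutation matrix, columns ordered by
    subtype (EBV, MSI, CIN, GS) then case id."""
    order = sorted(
        (c.case_id for c in cases),
        key=lambda cid: (SUBTYPES.index(labels[cid]), cid),
    )
    mutated = {c.case_id: c.mutated_genes for c in cases}
    data = {
        cid: [int(g in mutated[cid]) for g in gene_list] for cid in order
    }
    return pd.DataFrame(data, index=list(gene_list))


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(labels.items()), columns=["case_id", "subtype"]
    ).to_csv(path, sep="\t", index=False)
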