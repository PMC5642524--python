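"""Synthetic cohort generator emulating the study's per-case assay bundles.

Each generated case carries a hidden true molecular subtype (EBV, MSI,
CIN, GS) and emits the post-assay summaries the pipeline consumes:

* tumor and matched non-tumor variant tables (somatic variants for the
  case's mutated genes, shared germline variants, plus sub-threshold
  artifacts that exercise the filters),
* an EBV qPCR copy number,
* tumor/normal allele-length histograms for the five MSI markers,
* per-target tumor/normal coverage with multiplicative shifts over genes
  carrying a planted copy-number event, and
* clinical covariates and follow-up drawn from the published
  subtype-conditional cross-tabs.

Two generation modes: ``exact`` deterministically hits the published
marginal counts (7/19/46/35 subtypes; per-gene mutated-case counts; the
15 MSI-H + 4 MSI-L split) for table reproduction, while ``sampling``
draws cases i.i.d. from the subtype profiles for statistical property
tests. A single integer seed drives everything through stable
sub-seeding; identical specs produce byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from . import tables
from .msi_caller import MSI_MARKERS, MarkerProfile
from .cnv_caller import CoverageBin, write_coverage_table
from .msi_caller import write_marker_profiles
from .subtype_classifier import SUBTYPES, ClinicalCovariates
from .variant_filtering import (
    VariantCall,
    classify_consequence,
    write_variant_table,
)


class ParameterError(ValueError):
    """Invalid generator parameter (e.g. probability outside [0, 1])."""


# ---------------------------------------------------------------------------
# Specification types


@dataclass(frozen=True)
class SubtypeProfile:
    """Generative profile of one molecular subtype."""

    subtype_label: str
    prevalence: float
    per_gene_mutation_prob: dict[str, float]
    cna_prob: float
    msi_marker_instab_probs: dict[str, float]
    ebv_positive: bool
    expected_mutation_rate: float

    def __post_init__(self) -> None:
        probs = [self.prevalence, self.cna_prob, *self.per_gene_mutation_prob.values(),
                 *self.msi_marker_instab_probs.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ParameterError(
                f"{self.subtype_label}: probability outside [0, 1]"
            )


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial per-variant total depth (reads)."""

    mean: float = 700.0
    dispersion: float = 3.0
    floor: int = 60

    def draw(self, rng: np.random.Generator) -> int:
        p = self.dispersion / (self.dispersion + self.mean)
        return max(self.floor, int(rng.negative_binomial(self.dispersion, p)))


@dataclass(frozen=True)
class VafModel:
    """Somatic VAF ~ Beta(alpha, beta) truncated to [minimum, 1]."""

    alpha: float = 2.0
    beta: float = 4.0
    minimum: float = 0.05

    def draw(self, rng: np.random.Generator) -> float:
        lo = beta_dist.cdf(self.minimum, self.alpha, self.beta)
        u = rng.uniform(lo, 1.0)
        return float(beta_dist.ppf(u, self.alpha, self.beta))


@dataclass(frozen=True)
class FollowupModel:
    """Exponential relapse times with stage-dependent hazards.

    Hazard multipliers escalate with AJCC stage; censoring is uniform.
    The fraction of cases with follow-up mirrors the study (72/107).
    """

    baseline_median_days: float = 1500.0
    stage_multipliers: dict[str, float] = field(
        default_factory=lambda: {"I": 1.0, "II": 1.5, "III": 2.5, "IV": 4.0}
    )
    censor_low_days: float = 100.0
    censor_high_days: float = 1800.0
    availability: float = 72 / 107
    gc_death_given_relapse: float = 12 / 19


@dataclass(frozen=True)
class NoiseModel:
    """Filter-exercising noise; everything here is rejected downstream."""

    artifacts_per_case: int = 2
    pon_artifact: bool = True
    coverage_noise_sd: float = 0.05


@dataclass(frozen=True)
class GermlinePoolVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str
    transcript_id: str
    protein_change: str
    significance: str
    popfreq: float
    carrier_prob: float


def default_germline_pool() -> list[GermlinePoolVariant]:
    """Germline pool from the published 30-record germline table.

    Carrier probabilities are the observed carrier counts over the cohort
    size; population frequencies are synthetic rare values below the 0.01
    germline cutoff (the study did not print per-variant frequencies).
    """
    df = tables.germline_table()
    pool = []
    grouped = df.groupby(
        ["chrom", "pos", "ref", "alt", "gene_symbol", "transcript_id",
         "protein_change", "significance"],
        sort=True,
    )
    for i, (key, grp) in enumerate(grouped):
        chrom, pos, ref, alt, gene, tx, pc, sig = key
        pool.append(
            GermlinePoolVariant(
                chrom=str(chrom), pos=int(pos), ref=str(ref), alt=str(alt),
                gene_symbol=str(gene), transcript_id=str(tx),
                protein_change=str(pc), significance=str(sig),
                popfreq=round(0.0005 + 0.0004 * (i % 20), 4),
                carrier_prob=len(grp) / tables.COHORT_N,
            )
        )
    return pool


@dataclass(frozen=True)
class CohortSpec:
    n_cases: int = tables.COHORT_N
    profiles: tuple[SubtypeProfile, ...] = ()
    seed: int = 0
    mode: str = "exact"  # "exact" (marginal reproduction) | "sampling"
    depth_model: DepthModel = DepthModel()
    vaf_model: VafModel = VafModel()
    followup_model: FollowupModel = FollowupModel()
    noise: NoiseModel = NoiseModel()
    germline_pool: tuple[GermlinePoolVariant, ...] = ()
    targets_per_gene: int = 8
    ebv_positive_min_copies: float = 1e3
    normal_coverage_mean: float = 500.0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ParameterError("n_cases must be >= 0")
        if self.mode not in ("exact", "sampling"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        profiles = self.profiles or tuple(default_subtype_profiles())
        object.__setattr__(self, "profiles", profiles)
        if [p.subtype_label for p in profiles] != list(SUBTYPES):
            raise ParameterError("profiles must cover EBV, MSI, CIN, GS in order")
        if abs(sum(p.prevalence for p in profiles) - 1.0) > 1e-9:
            raise ParameterError("prevalences must sum to 1")
        if any(p.ebv_positive and p.subtype_label != "EBV" for p in profiles):
            raise ParameterError("ebv_positive allowed only for the EBV profile")
        pool = self.germline_pool or tuple(default_germline_pool())
        object.__setattr__(self, "germline_pool", pool)


@dataclass(frozen=True)
class CaseTruth:
    """Hidden ground truth for one generated case (the withheld manifest)."""

    case_id: str
    subtype: str
    mutated_genes: frozenset[str]
    unstable_markers: frozenset[str]
    msi_status: str
    ebv_positive: bool
    cna_events: dict[str, str]  # gene -> deletion|duplication
    germline_indices: tuple[int, ...]


@dataclass
class CaseBundle:
    """Raw per-case assay outputs, as the pipeline would read them."""

    case_id: str
    ebv_copies: float
    tumor_variants: list[VariantCall]
    normal_variants: list[VariantCall]
    tumor_msi: dict[str, MarkerProfile]
    normal_msi: dict[str, MarkerProfile]
    coverage: list[CoverageBin]
    clinical: ClinicalCovariates
    followup_available: bool


# ---------------------------------------------------------------------------
# Default profiles from the published tables


def default_subtype_profiles() -> list[SubtypeProfile]:
    """Subtype profiles parameterized by the published gene-by-subtype
    counts (per-gene probability = mutated cases / subtype size) and the
    subtype prevalences (7/107, 19/107, 46/107, 35/107)."""
    sizes = tables.SUBTYPE_SIZES
    profiles = []
    for j, label in enumerate(SUBTYPES):
        n = sizes[label]
        gene_probs = {
            g: counts[j] / n for g, counts in tables.GENE_SUBTYPE_COUNTS.items()
        }
        # Per-marker instability only in the MSI arm; 0.5 per marker gives
        # an MSI-H : MSI-L split close to the observed 15 : 4.
        marker_probs = {
            m: (0.5 if label == "MSI" else 0.0) for m in MSI_MARKERS
        }
        profiles.append(
            SubtypeProfile(
                subtype_label=label,
                prevalence=n / tables.COHORT_N,
                per_gene_mutation_prob=gene_probs,
                cna_prob=1.0 if label == "CIN" else 0.0,
                msi_marker_instab_probs=marker_probs,
                ebv_positive=label == "EBV",
                expected_mutation_rate=sum(gene_probs.values()),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Truth assignment


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    raw = [w * total for w in weights]
    base = [int(math.floor(x)) for x in raw]
    short = total - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def _assign_truths(spec: CohortSpec, rng: np.random.Generator) -> list[CaseTruth]:
    n = spec.n_cases
    case_ids = [f"SYN{i + 1:04d}" for i in range(n)]
    profiles = {p.subtype_label: p for p in spec.profiles}
    genes = sorted(spec.profiles[0].per_gene_mutation_prob)

    if spec.mode == "exact":
        counts = _largest_remainder([p.prevalence for p in spec.profiles], n)
        subtype_of = []
        for label, k in zip(SUBTYPES, counts):
            subtype_of.extend([label] * k)
        # interleave deterministically so case order is not informative
        perm = rng.permutation(n)
        subtypes = [subtype_of[i] for i in perm]
    else:
        prev = [p.prevalence for p in spec.profiles]
        subtypes = [SUBTYPES[i] for i in rng.choice(4, size=n, p=prev)]

    members: dict[str, list[int]] = {s: [] for s in SUBTYPES}
    for i, s in enumerate(subtypes):
        members[s].append(i)

    mutated: list[set[str]] = [set() for _ in range(n)]
    if spec.mode == "exact":
        for label in SUBTYPES:
            idx = members[label]
            prof = profiles[label]
            for g in genes:
                k = int(round(prof.per_gene_mutation_prob[g] * len(idx)))
                if k > 0:
                    chosen = rng.choice(len(idx), size=k, replace=False)
                    for c in chosen:
                        mutated[idx[c]].add(g)
    else:
        for i, s in enumerate(subtypes):
            prof = profiles[s]
            for g in genes:
                if rng.random() < prof.per_gene_mutation_prob[g]:
                    mutated[i].add(g)

    # MSI marker truth
    unstable: list[frozenset[str]] = [frozenset()] * n
    msi_status = ["MSS"] * n
    msi_idx = members["MSI"]
    if spec.mode == "exact":
        n_h = int(round(len(msi_idx) * tables.MSI_STATUS_COUNTS["MSI-H"]
                        / (tables.MSI_STATUS_COUNTS["MSI-H"]
                           + tables.MSI_STATUS_COUNTS["MSI-L"])))
        shuffled = list(rng.permutation(msi_idx)) if msi_idx else []
        for rank, i in enumerate(shuffled):
            k = 3 if rank < n_h else 1
            marks = rng.choice(len(MSI_MARKERS), size=k, replace=False)
            unstable[i] = frozenset(MSI_MARKERS[m] for m in marks)
    else:
        for i in msi_idx:
            probs = profiles["MSI"].msi_marker_instab_probs
            while True:
                flags = {m for m in MSI_MARKERS if rng.random() < probs[m]}
                if flags:
                    break
            unstable[i] = frozenset(flags)
    for i in range(n):
        k = len(unstable[i])
        msi_status[i] = "MSS" if k == 0 else ("MSI-L" if k == 1 else "MSI-H")

    # CNA truth: CIN cases carry at least one event; gene weighted by the
    # published per-gene CNV event counts
    cna_genes = sorted(tables.CNA_EVENT_COUNTS)
    cna_weights = np.array(
        [tables.CNA_EVENT_COUNTS[g][1] for g in cna_genes], dtype=float
    )
    cna_weights /= cna_weights.sum()
    cna_events: list[dict[str, str]] = [dict() for _ in range(n)]
    for i, s in enumerate(subtypes):
        prof = profiles[s]
        has_cna = (s == "CIN") if spec.mode == "exact" else (
            rng.random() < prof.cna_prob
        )
        if has_cna:
            g = cna_genes[int(rng.choice(len(cna_genes), p=cna_weights))]
            cna_events[i][g] = tables.CNA_EVENT_COUNTS[g][0]

    # germline carriers
    germline: list[tuple[int, ...]] = []
    for i in range(n):
        carried = tuple(
            j for j, v in enumerate(spec.germline_pool)
            if rng.random() < v.carrier_prob
        )
        germline.append(carried)

    return [
        CaseTruth(
            case_id=case_ids[i],
            subtype=subtypes[i],
            mutated_genes=frozenset(mutated[i]),
            unstable_markers=unstable[i],
            msi_status=msi_status[i],
            ebv_positive=profiles[subtypes[i]].ebv_positive,
            cna_events=cna_events[i],
            germline_indices=germline[i],
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Per-case assay emission


def _stable_msi_histogram(marker: str) -> dict[int, float]:
    mode = tables.MSI_MARKER_MODAL_LENGTHS[marker]
    return {mode - 1: 0.1, mode: 0.8, mode + 1: 0.1}


def _unstable_msi_histogram(marker: str) -> dict[int, float]:
    # 35% novel-allele mass 4 bp below the germline mode: outside the
    # +/-1 bp tolerance and above the 0.2 novel-fraction cutoff
    mode = tables.MSI_MARKER_MODAL_LENGTHS[marker]
    return {mode - 4: 0.35, mode - 1: 0.065, mode: 0.52, mode + 1: 0.065}


def generate_case_assays(
    truth: CaseTruth, spec: CohortSpec, seed: np.random.SeedSequence | int
) -> CaseBundle:
    """Emit one case's assay bundle consistent with its hidden truth."""
    rng = np.random.default_rng(seed)
    catalog = tables.GENE_CATALOG

    # --- tumor variant table: somatic variants for mutated genes
    tumor: list[VariantCall] = []
    for g in sorted(truth.mutated_genes):
        chrom, base, pchange = catalog[g]
        tumor.append(
            VariantCall(
                case_id=truth.case_id,
                chrom=chrom,
                pos=base,
                ref_allele="C",
                alt_allele="T",
                gene_symbol=g,
                transcript_id="",
                protein_change=pchange,
                consequence_class=classify_consequence(pchange),
                total_depth=spec.depth_model.draw(rng),
                vaf_tumor=spec.vaf_model.draw(rng),
                origin="tumor_table",
            )
        )

    # --- sub-threshold artifacts (always rejected by the somatic filter)
    panel = list(catalog)
    for a in range(spec.noise.artifacts_per_case):
        g = panel[int(rng.integers(len(panel)))]
        chrom, base, _ = catalog[g]
        mode = a % 3
        tumor.append(
            VariantCall(
                case_id=truth.case_id,
                chrom=chrom,
                pos=base + 17 + a,
                ref_allele="G",
                alt_allele="A",
                gene_symbol=g,
                protein_change="p.Ala999Val",
                consequence_class="missense",
                total_depth=(
                    int(rng.integers(10, 50)) if mode == 1
                    else spec.depth_model.draw(rng)
                ),
                vaf_tumor=(
                    float(rng.uniform(0.005, 0.045)) if mode == 0
                    else float(rng.uniform(0.06, 0.3))
                ),
                popfreq_exac=(
                    float(rng.uniform(0.02, 0.2)) if mode == 2 else None
                ),
                origin="tumor_table",
            )
        )

    # --- germline variants present in both tables
    normal: list[VariantCall] = []
    for j in truth.germline_indices:
        v = spec.germline_pool[j]
        depth_t = spec.depth_model.draw(rng)
        depth_n = spec.depth_model.draw(rng)
        vaf_t = float(np.clip(rng.normal(0.5, 0.05), 0.32, 0.95))
        vaf_n = float(np.clip(rng.normal(0.5, 0.05), 0.32, 0.95))
        common = dict(
            case_id=truth.case_id, chrom=v.chrom, pos=v.pos,
            ref_allele=v.ref, alt_allele=v.alt, gene_symbol=v.gene_symbol,
            transcript_id=v.transcript_id, protein_change=v.protein_change,
            consequence_class=classify_consequence(v.protein_change),
            popfreq_1kg=v.popfreq, significance=v.significance,
        )
        tumor.append(VariantCall(
            total_depth=depth_t, vaf_tumor=vaf_t, origin="tumor_table", **common
        ))
        normal.append(VariantCall(
            total_depth=depth_n, vaf_tumor=vaf_n, origin="normal_table", **common
        ))

    # --- recurrent panel-of-normals artifact at a fixed off-panel locus
    if spec.noise.pon_artifact:
        case_no = int(truth.case_id[3:])
        if case_no % 10 in (0, 1, 2):  # ~30% of normals
            normal.append(VariantCall(
                case_id=truth.case_id, chrom="2", pos=179400000,
                ref_allele="A", alt_allele="G", gene_symbol="TTN",
                protein_change="p.Ser100Gly", consequence_class="missense",
                total_depth=spec.depth_model.draw(rng),
                vaf_tumor=float(rng.uniform(0.03, 0.1)),
                origin="normal_table",
            ))
        if case_no % 7 == 0:
            tumor.append(VariantCall(
                case_id=truth.case_id, chrom="2", pos=179400000,
                ref_allele="A", alt_allele="G", gene_symbol="TTN",
                protein_change="p.Ser100Gly", consequence_class="missense",
                total_depth=spec.depth_model.draw(rng),
                vaf_tumor=float(rng.uniform(0.06, 0.15)),
                origin="tumor_table",
            ))

    # --- MSI marker histograms
    tumor_msi, normal_msi = {}, {}
    for m in MSI_MARKERS:
        normal_msi[m] = MarkerProfile(m, _stable_msi_histogram(m))
        hist = (
            _unstable_msi_histogram(m)
            if m in truth.unstable_markers
            else _stable_msi_histogram(m)
        )
        tumor_msi[m] = MarkerProfile(m, hist)

    # --- coverage bins with multiplicative shifts over CNA genes
    coverage: list[CoverageBin] = []
    sd = spec.noise.coverage_noise_sd
    for g in sorted(tables.GENE_PANEL):
        chrom, base, _ = catalog[g]
        state = truth.cna_events.get(g)
        shift = {"duplication": 0.58, "deletion": -1.0}.get(state, 0.0)
        for k in range(spec.targets_per_gene):
            nd = float(rng.lognormal(math.log(spec.normal_coverage_mean), 0.1))
            noise = float(rng.lognormal(0.0, sd)) if sd > 0 else 1.0
            td = nd * (2.0 ** shift) * noise
            coverage.append(CoverageBin(
                target_id=f"{g}_t{k + 1}",
                gene_symbol=g,
                chrom=chrom,
                start=base + 150 * k,
                end=base + 150 * k + 119,
                tumor_depth=round(td, 2),
                normal_depth=round(nd, 2),
            ))

    # --- EBV qPCR
    ebv_copies = float(10 ** rng.uniform(3.2, 5.0)) if truth.ebv_positive else 0.0

    # --- clinical covariates and follow-up
    clinical, available = _draw_clinical(truth.subtype, spec, rng)

    return CaseBundle(
        case_id=truth.case_id,
        ebv_copies=ebv_copies,
        tumor_variants=tumor,
        normal_variants=normal,
        tumor_msi=tumor_msi,
        normal_msi=normal_msi,
        coverage=coverage,
        clinical=clinical,
        followup_available=available,
    )


_AGE_BANDS = {
    "<=50": (32, 50), "51-60": (51, 60), "61-70": (61, 70),
    "71-80": (71, 80), ">80": (81, 90),
}


def _draw_categorical(
    counts_by_subtype: dict[str, tuple[int, ...]],
    subtype: str,
    rng: np.random.Generator,
) -> str:
    j = SUBTYPES.index(subtype)
    cats = list(counts_by_subtype)
    weights = np.array([counts_by_subtype[c][j] for c in cats], dtype=float)
    if weights.sum() == 0:
        weights[:] = 1.0
    return cats[int(rng.choice(len(cats), p=weights / weights.sum()))]


def _draw_clinical(
    subtype: str, spec: CohortSpec, rng: np.random.Generator
) -> tuple[ClinicalCovariates, bool]:
    cc = tables.CLINICAL_SUBTYPE_COUNTS
    band = _draw_categorical(cc["age_band"], subtype, rng)
    lo, hi = _AGE_BANDS[band]
    stage_group = _draw_categorical(cc["ajcc_stage_group"], subtype, rng)
    combos = tables.AJCC_STAGE_COMBOS[stage_group]
    pT, pN, M = combos[int(rng.integers(len(combos)))]

    fm = spec.followup_model
    available = bool(rng.random() < fm.availability)
    hazard = math.log(2) / (
        fm.baseline_median_days / fm.stage_multipliers[stage_group]
    )
    t_event = float(rng.exponential(1.0 / hazard))
    t_censor = float(rng.uniform(fm.censor_low_days, fm.censor_high_days))
    relapse = t_event <= t_censor
    gc_death = bool(relapse and rng.random() < fm.gc_death_given_relapse)

    clin = ClinicalCovariates(
        age=int(rng.integers(lo, hi + 1)),
        sex=_draw_categorical(cc["sex"], subtype, rng),
        lauren_class=_draw_categorical(cc["lauren_class"], subtype, rng),
        who_class=_draw_categorical(cc["who_class"], subtype, rng),
        pT=pT, pN=pN, M=M, ajcc_stage=stage_group,
        anatomical_region=_draw_categorical(cc["anatomical_region"], subtype, rng),
        h_pylori=_draw_categorical(cc["h_pylori"], subtype, rng) == "Positive",
        lymphatic_invasion=_draw_categorical(cc["lymphatic_invasion"], subtype, rng),
        venous_invasion=_draw_categorical(cc["venous_invasion"], subtype, rng),
        perineural_invasion=_draw_categorical(cc["perineural_invasion"], subtype, rng),
        followup_days=round(min(t_event, t_censor), 1),
        relapse_event=relapse,
        gc_death_event=gc_death,
    )
    return clin, available


# ---------------------------------------------------------------------------
# Cohort-level generation and serialization


def generate_cohort(spec: CohortSpec) -> tuple[list[CaseBundle], list[CaseTruth]]:
    """Generate the full cohort; identical specs give identical cohorts."""
    if spec.n_cases == 0:
        return [], []
    root = np.random.SeedSequence(spec.seed)
    truth_seed, *case_seeds = root.spawn(spec.n_cases + 1)
    truths = _assign_truths(spec, np.random.default_rng(truth_seed))
    bundles = [
        generate_case_assays(truth, spec, seed)
        for truth, seed in zip(truths, case_seeds)
    ]
    return bundles, truths


def write_cohort(
    bundles: Sequence[CaseBundle],
    truths: Sequence[CaseTruth],
    outdir: str | Path,
    include_manifest: bool = True,
) -> None:
    """Serialize a cohort as a directory of per-case TSVs plus cohort-level
    clinical/follow-up/EBV tables; the truth manifest is written separately
    and is withheld from the pipeline under test."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ebv_rows, clin_rows, fu_rows = [], [], []
    for b in bundles:
        write_variant_table(b.tumor_variants, outdir / f"{b.case_id}.tumor.tsv")
        write_variant_table(b.normal_variants, outdir / f"{b.case_id}.normal.tsv")
        write_marker_profiles(
            outdir / f"{b.case_id}.msi.tsv", b.case_id, b.tumor_msi, b.normal_msi
        )
        write_coverage_table(b.coverage, outdir / f"{b.case_id}.coverage.tsv")
        ebv_rows.append({"case_id": b.case_id, "ebv_copies": b.ebv_copies})
        c = b.clinical
        clin_rows.append({
            "case_id": b.case_id, "age": c.age, "sex": c.sex,
            "lauren_class": c.lauren_class, "who_class": c.who_class,
            "pT": c.pT, "pN": c.pN, "M": c.M, "ajcc_stage": c.ajcc_stage,
            "anatomical_region": c.anatomical_region,
            "h_pylori": c.h_pylori,
            "lymphatic_invasion": c.lymphatic_invasion,
            "venous_invasion": c.venous_invasion,
            "perineural_invasion": c.perineural_invasion,
        })
        if b.followup_available:
            fu_rows.append({
                "case_id": b.case_id,
                "time_days": c.followup_days,
                "rfs_event": int(bool(c.relapse_event or c.gc_death_event)),
                "gcss_event": int(bool(c.gc_death_event)),
                "ajcc_stage": c.ajcc_stage,
            })
    pd.DataFrame(ebv_rows).to_csv(outdir / "ebv.tsv", sep="\t", index=False)
    pd.DataFrame(clin_rows).to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    pd.DataFrame(fu_rows).to_csv(outdir / "followup.tsv", sep="\t", index=False)
    if include_manifest:
        pd.DataFrame([
            {
                "case_id": t.case_id,
                "subtype": t.subtype,
                "msi_status": t.msi_status,
                "ebv_positive": t.ebv_positive,
                "mutated_genes": ";".join(sorted(t.mutated_genes)),
                "cna_genes": ";".join(
                    f"{g}:{s}" for g, s in sorted(t.cna_events.items())
                ),
            }
            for t in truths
        ]).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
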