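"""End-to-end cohort pipeline: read a cohort directory, run filtering ->
MSI -> CNV -> serial classification -> cohort statistics -> survival, and
emit report tables.

The input directory layout matches what the synthetic generator writes
(and what a real cohort would be exported as): per-case
``<case>.tumor.tsv`` / ``<case>.normal.tsv`` variant tables,
``<case>.msi.tsv`` marker profiles, ``<case>.coverage.tsv`` target
coverage, plus cohort-level ``ebv.tsv``, ``clinical.tsv`` and
``followup.tsv``. A ``manifest.tsv`` (ground truth), if present, is
ignored by the pipeline.

Reports are deterministic functions of the inputs and configuration: the
run manifest records a configuration hash and seed but no timestamps, so
two runs on the same inputs produce byte-identical report files. Stage
timings go to the logger only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import tables
from .cnv_caller import HmmParams, call_case_cnas, read_coverage_table
from .cohort_stats import (
    PathwayGeneSets,
    chi_square_test,
    gene_association_tests,
    gene_subtype_table,
    gene_table_frame,
    mutation_rate_per_subtype,
    pathway_alteration_summary,
)
from .msi_caller import MsiParams, call_case, read_marker_profiles
from .subtype_classifier import (
    SUBTYPES,
    CaseAssay,
    ClinicalCovariates,
    classify_cohort,
    mutation_matrix,
    write_labels,
)
from .survival_analysis import (
    SurvivalRecord,
    cox_ph,
    km_curve,
    logrank_test,
    survival_frame,
)
from .variant_filtering import (
    FilterThresholds,
    VariantCall,
    build_panel_of_normals,
    filter_germline,
    filter_somatic,
    read_variant_table,
    summarize_germline,
    tally_recurrence,
)

log = logging.getLogger(__name__)

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class DataError(ValueError):
    """Malformed or missing input data."""


@dataclass
class PipelineConfig:
    input_dir: Path
    output_dir: Path
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    msi_params: MsiParams = field(default_factory=MsiParams)
    hmm_params: HmmParams = field(default_factory=HmmParams)
    ebv_min_copies: float = 100.0
    gene_panel: tuple[str, ...] = tables.GENE_PANEL
    pathway_sets: PathwayGeneSets = field(default_factory=PathwayGeneSets.default)
    seed: int = 0
    run_stats: bool = True
    run_survival: bool = True
    strict: bool = False

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if not self.gene_panel:
            raise ConfigError("gene_panel must be nonempty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            kwargs = dict(raw)
            for key, klass in (
                ("thresholds", FilterThresholds),
                ("msi_params", MsiParams),
                ("hmm_params", HmmParams),
            ):
                if key in kwargs and isinstance(kwargs[key], dict):
                    sub = dict(kwargs[key])
                    for tuple_field in ("state_means", "prior"):
                        if tuple_field in sub:
                            sub[tuple_field] = tuple(sub[tuple_field])
                    kwargs[key] = klass(**sub)
            if "gene_panel" in kwargs:
                kwargs["gene_panel"] = tuple(kwargs["gene_panel"])
            if "pathway_sets" in kwargs and isinstance(kwargs["pathway_sets"], dict):
                kwargs["pathway_sets"] = PathwayGeneSets(
                    rtk=frozenset(kwargs["pathway_sets"].get("rtk", [])),
                    ras_pi3k=frozenset(kwargs["pathway_sets"].get("ras_pi3k", [])),
                )
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        """Hash of the analytical configuration (thresholds, model
        parameters, panel, seed) — filesystem locations are excluded so
        identical analyses hash identically wherever they run."""

        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, (tuple, list)):
                return [encode(x) for x in obj]
            if isinstance(obj, Path):
                return str(obj)
            return obj

        payload = {
            f.name: encode(getattr(self, f.name))
            for f in dataclasses.fields(self)
            if f.name not in ("input_dir", "output_dir")
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CaseAttrition:
    """Per-case variant accounting: input = somatic + germline + rejected."""

    case_id: str
    n_input: int
    n_somatic: int
    n_germline: int
    rejected_by_reason: dict[str, int]

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected_by_reason.values())


@dataclass
class CohortSummary:
    cases: list[CaseAssay]
    labels: dict[str, str]
    distribution: "object"
    gene_table: Optional[object] = None
    gene_table_frame: Optional[pd.DataFrame] = None
    mutation_rates: Optional[dict] = None
    pathway: Optional[object] = None
    recurrence: Optional[list] = None
    germline_summary: Optional[dict] = None
    survival: Optional[dict] = None
    attrition: list[CaseAttrition] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Input reading


def discover_cases(input_dir: Path) -> list[str]:
    ids = sorted(p.name[: -len(".tumor.tsv")] for p in input_dir.glob("*.tumor.tsv"))
    if not ids:
        raise DataError(f"no case files (*.tumor.tsv) found in {input_dir}")
    return ids


def _rejection_reason(
    call: VariantCall,
    normal_by_site: dict,
    pon: dict,
    t: FilterThresholds,
) -> str:
    """First somatic-filter rule the call fails (for attrition reports)."""
    if call.vaf_tumor <= t.somatic_min_vaf:
        return "low_vaf"
    if call.total_depth <= t.min_depth:
        return "low_depth"
    if not (call.exonic or call.consequence_class == "splicing"):
        return "non_exonic"
    if call.max_popfreq() >= t.somatic_max_popfreq:
        return "population_frequency"
    nv = normal_by_site.get(call.site_allele)
    if nv is not None and nv >= t.normal_max_vaf:
        return "present_in_matched_normal"
    if pon.get(call.site_allele, 0) > t.pon_max_normals:
        return "panel_of_normals"
    return "other"


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: PipelineConfig) -> CohortSummary:
    """Run all enabled stages over the cohort directory; write reports."""
    t0 = time.perf_counter()
    input_dir = config.input_dir
    if not input_dir.is_dir():
        raise DataError(f"input directory not found: {input_dir}")
    case_ids = discover_cases(input_dir)

    ebv_path = input_dir / "ebv.tsv"
    ebv_copies: dict[str, float] = {}
    if ebv_path.exists():
        df = pd.read_csv(ebv_path, sep="\t")
        ebv_copies = dict(zip(df.case_id.astype(str), df.ebv_copies.astype(float)))

    clinical: dict[str, ClinicalCovariates] = {}
    clin_path = input_dir / "clinical.tsv"
    if clin_path.exists():
        df = pd.read_csv(clin_path, sep="\t")
        for r in df.itertuples(index=False):
            d = r._asdict()
            cid = str(d.pop("case_id"))
            clinical[cid] = ClinicalCovariates(
                **{k: (None if pd.isna(v) else v) for k, v in d.items()}
            )

    # panel of normals over every non-tumor table in the cohort
    normal_tables: dict[str, list[VariantCall]] = {}
    for cid in case_ids:
        p = input_dir / f"{cid}.normal.tsv"
        normal_tables[cid] = (
            read_variant_table(p, origin="normal_table") if p.exists() else []
        )
    pon = build_panel_of_normals(normal_tables.values())
    log.info("panel of normals: %d site-alleles from %d cases", len(pon), len(case_ids))

    cases: list[CaseAssay] = []
    attrition: list[CaseAttrition] = []
    errors: list[str] = []
    for cid in case_ids:
        try:
            case, attr = _process_case(
                cid, input_dir, normal_tables.get(cid, []), pon,
                ebv_copies, clinical, config,
            )
        except Exception as exc:
            msg = f"{cid}: {exc}"
            if config.strict:
                raise DataError(msg) from exc
            log.error("skipping case %s", msg)
            errors.append(msg)
            continue
        cases.append(case)
        attrition.append(attr)
    if not cases:
        raise DataError("no cases could be processed")
    log.info("processed %d cases in %.2fs", len(cases), time.perf_counter() - t0)

    labels, distribution = classify_cohort(cases)
    summary = CohortSummary(
        cases=cases, labels=labels, distribution=distribution,
        attrition=attrition, errors=errors,
    )

    if config.run_stats:
        table = gene_subtype_table(cases, labels, config.gene_panel)
        tests = gene_association_tests(table, seed=config.seed)
        summary.gene_table = table
        frame = gene_table_frame(table, tests)
        # chi-square reported alongside the exact test (exact is primary)
        sizes = pd.Series(table.subtype_sizes, index=list(table.subtypes))
        frame["p_chi2"] = [
            chi_square_test(
                [table.row(g).tolist(), (sizes - table.row(g)).tolist()]
            ).p_value
            if table.row(g).sum() > 0 else float("nan")
            for g in frame["gene"]
        ]
        summary.gene_table_frame = frame
        summary.mutation_rates = mutation_rate_per_subtype(table)
        summary.pathway = pathway_alteration_summary(cases, config.pathway_sets)
        all_somatic = [c for case in cases for c in case.somatic_calls]
        summary.recurrence = tally_recurrence(all_somatic, len(cases))
        all_germline = [c for case in cases for c in case.germline_calls]
        summary.germline_summary = summarize_germline(all_germline)

    if config.run_survival:
        summary.survival = _survival_stage(input_dir, cases, labels)

    _write_reports(summary, config)
    log.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return summary


def _process_case(
    cid: str,
    input_dir: Path,
    normal_calls: list[VariantCall],
    pon: dict,
    ebv_copies: dict[str, float],
    clinical: dict[str, ClinicalCovariates],
    config: PipelineConfig,
) -> tuple[CaseAssay, CaseAttrition]:
    tumor_calls = read_variant_table(input_dir / f"{cid}.tumor.tsv")
    somatic = filter_somatic(tumor_calls, normal_calls, pon, config.thresholds)
    germline = filter_germline(tumor_calls, normal_calls, config.thresholds)

    somatic_keys = {c.site_allele for c in somatic}
    germline_keys = {c.site_allele for c in germline}
    normal_by_site = {c.site_allele: c.vaf_tumor for c in normal_calls}
    reasons: dict[str, int] = {}
    for call in tumor_calls:
        if call.site_allele in somatic_keys or call.site_allele in germline_keys:
            continue
        reason = _rejection_reason(call, normal_by_site, pon, config.thresholds)
        reasons[reason] = reasons.get(reason, 0) + 1
    attr = CaseAttrition(
        case_id=cid,
        n_input=len(tumor_calls),
        n_somatic=len(somatic),
        n_germline=len(germline),
        rejected_by_reason=reasons,
    )

    msi_path = input_dir / f"{cid}.msi.tsv"
    msi = None
    if msi_path.exists():
        tumor_msi, normal_msi = read_marker_profiles(msi_path)
        msi = call_case(tumor_msi, normal_msi, config.msi_params)

    cov_path = input_dir / f"{cid}.coverage.tsv"
    gene_cnas = []
    cna_positive = None
    if cov_path.exists():
        bins = read_coverage_table(cov_path)
        gene_cnas = call_case_cnas(bins, config.hmm_params)
        cna_positive = any(g.state != "normal" for g in gene_cnas)

    ebv = None
    if cid in ebv_copies:
        ebv = ebv_copies[cid] >= config.ebv_min_copies

    case = CaseAssay(
        case_id=cid,
        ebv_positive=ebv,
        msi=msi,
        cna_positive=cna_positive,
        somatic_calls=somatic,
        germline_calls=germline,
        gene_cnas=gene_cnas,
        clinical=clinical.get(cid),
    )
    return case, attr


def _survival_stage(
    input_dir: Path, cases: Sequence[CaseAssay], labels: dict[str, str]
) -> Optional[dict]:
    fu_path = input_dir / "followup.tsv"
    if not fu_path.exists():
        return None
    df = pd.read_csv(fu_path, sep="\t")
    if df.empty:
        return None
    mutated = {c.case_id: c.mutated_genes for c in cases}
    records = []
    for r in df.itertuples(index=False):
        cid = str(r.case_id)
        if cid not in labels:
            continue
        stage = str(getattr(r, "ajcc_stage", "I"))
        gcss = bool(r.gcss_event)
        records.append(SurvivalRecord(
            case_id=cid,
            time=float(r.time_days),
            rfs_event=bool(r.rfs_event) or gcss,
            gcss_event=gcss,
            covariates={
                "stage_iii": float(stage == "III"),
                "stage_iv": float(stage == "IV"),
                "mtor_mut": float("MTOR" in mutated.get(cid, set())),
                "ccnd1_mut": float("CCND1" in mutated.get(cid, set())),
            },
        ))
    if not records:
        return None
    out: dict = {"records": records}
    # KM + log-rank by molecular subtype, for both endpoints
    groups: dict[str, list[SurvivalRecord]] = {}
    for rec in records:
        groups.setdefault(labels[rec.case_id], []).append(rec)
    nonempty = [g for g in SUBTYPES if g in groups]
    for endpoint, tag in (("rfs_event", "rfs"), ("gcss_event", "gcss")):
        km = {}
        for subtype, recs in sorted(groups.items()):
            km[subtype] = km_curve(
                [r.time for r in recs], [getattr(r, endpoint) for r in recs]
            )
        out[f"km_by_subtype_{tag}"] = km
        if len(nonempty) >= 2 and any(getattr(r, endpoint) for r in records):
            chi2, df_, p = logrank_test(
                [([r.time for r in groups[g]],
                  [getattr(r, endpoint) for r in groups[g]])
                 for g in nonempty]
            )
            out[f"logrank_{tag}"] = {"chi2": chi2, "df": df_, "p": p}
    n_events = sum(r.rfs_event for r in records)
    if n_events >= 5:
        try:
            out["cox_rfs"] = cox_ph(
                records, ["stage_iii", "stage_iv", "mtor_mut", "ccnd1_mut"]
            )
        except Exception as exc:
            log.warning("Cox stage skipped: %s", exc)
    return out


# ---------------------------------------------------------------------------
# Reports


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_reports(summary: CohortSummary, config: PipelineConfig) -> None:
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    write_labels(summary.labels, out / "subtype_labels.tsv")
    msi_rows = []
    for case in summary.cases:
        if case.msi is None:
            continue
        row = {"case_id": case.case_id}
        row.update({m: int(v) for m, v in sorted(case.msi.per_marker_unstable.items())})
        row["n_unstable"] = case.msi.n_unstable
        row["status"] = case.msi.status
        msi_rows.append(row)
    if msi_rows:
        pd.DataFrame(msi_rows).to_csv(out / "msi_results.tsv", sep="\t", index=False)
    dist = summary.distribution
    _json_dump(
        {"n": dist.n, "counts": dist.counts, "percentages": dist.percentages},
        out / "subtype_distribution.json",
    )
    if summary.gene_table_frame is not None:
        summary.gene_table_frame.to_csv(
            out / "gene_subtype_table.tsv", sep="\t", index=False
        )
        _json_dump(summary.mutation_rates, out / "mutation_rates.json")
        pw = summary.pathway
        _json_dump(
            {
                "n_cases": pw.n_cases,
                "rtk_altered": pw.rtk_altered,
                "ras_pi3k_altered": pw.ras_pi3k_altered,
                "combined_altered": pw.combined_altered,
                "combined_fraction_pct": pw.combined_fraction_pct,
                "per_gene_altered": pw.per_gene_altered,
                "exclusivity_violations": pw.exclusivity_violations,
            },
            out / "pathway_summary.json",
        )
        pd.DataFrame(
            [dataclasses.asdict(r) for r in summary.recurrence]
        ).to_csv(out / "recurrence.tsv", sep="\t", index=False)
        _json_dump(summary.germline_summary, out / "germline_summary.json")
        mm = mutation_matrix(
            summary.cases, summary.labels, config.gene_panel
        )
        mm.to_csv(out / "mutation_matrix.tsv", sep="\t")
    if summary.survival is not None:
        surv = summary.survival
        for tag in ("rfs", "gcss"):
            km_frames = []
            for subtype, frame in surv[f"km_by_subtype_{tag}"].items():
                f = frame.copy()
                f.insert(0, "subtype", subtype)
                km_frames.append(f)
            pd.concat(km_frames).to_csv(
                out / f"km_{tag}_by_subtype.tsv", sep="\t", index=False
            )
            if f"logrank_{tag}" in surv:
                _json_dump(surv[f"logrank_{tag}"], out / f"logrank_{tag}.json")
        if "cox_rfs" in surv:
            surv["cox_rfs"].summary.to_csv(out / "cox_rfs.tsv", sep="\t")
        survival_frame(surv["records"]).to_csv(
            out / "survival_records.tsv", sep="\t", index=False
        )
    rows = []
    for a in summary.attrition:
        row = {
            "case_id": a.case_id, "n_input": a.n_input,
            "n_somatic": a.n_somatic, "n_germline": a.n_germline,
            "n_rejected": a.n_rejected,
        }
        row.update({f"rejected_{k}": v for k, v in sorted(a.rejected_by_reason.items())})
        rows.append(row)
    pd.DataFrame(rows).fillna(0).to_csv(out / "attrition.tsv", sep="\t", index=False)
    _json_dump(
        {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "n_cases": len(summary.cases),
            "errors": summary.errors,
        },
        out / "run_manifest.json",
    )
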