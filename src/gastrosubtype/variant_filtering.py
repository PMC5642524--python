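"""Tumor/normal variant-table I/O and post-filter cascades.

The upstream caller (alignment + somatic/germline calling + annotation) is
out of scope: this module consumes annotated variant tables and applies the
study's downstream post-filters:

* somatic: tumor VAF > 5%, depth > 50x, exonic, population frequency
  < 0.005 in each of 1000 Genomes / ESP6500 / ExAC, not supported by the
  matched normal, and seen in at most 2 non-tumor samples cohort-wide
  (panel-of-normals exclusion);
* germline: present in both tumor and matched non-tumor with VAF > 30%,
  depth > 50x, population frequency < 0.01.

All threshold comparisons are strict inequalities, exactly as stated (a
depth of exactly 50 is rejected). Population frequencies are compared via
the maximum over the databases present; absent values count as 0.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

CONSEQUENCE_CLASSES = ("missense", "trunc", "in_frame", "splicing", "other")

#: Splice-region annotation terms recognized by classify_consequence.
_SPLICE_TERMS = {
    "splicing", "splice", "splice_acceptor_variant", "splice_donor_variant",
    "splice_region_variant", "splice_site",
}

_THREE_TO_ONE = (
    "Ala|Arg|Asn|Asp|Cys|Gln|Glu|Gly|His|Ile|Leu|Lys|Met|Phe|Pro|Ser|Thr"
    "|Trp|Tyr|Val|Ter|Sec"
)
_AA1 = "ACDEFGHIKLMNPQRSTVWYX*"
# p.Arg2194Ter / p.R2194* / p.His1047Arg / p.V832M, with optional trailing
# del/dup/ins/fs qualifiers
_RE_MISSENSE3 = re.compile(
    rf"^p\.\(?({_THREE_TO_ONE})(\d+)({_THREE_TO_ONE})\)?$"
)
_RE_MISSENSE1 = re.compile(rf"^p\.\(?([{_AA1}])(\d+)([{_AA1}])\)?$")
_RE_FRAMESHIFT = re.compile(r"fs", re.IGNORECASE)
_RE_INFRAME = re.compile(r"(del|dup|ins)(?!\w*fs)", re.IGNORECASE)


class VariantTableError(ValueError):
    """Malformed variant table (missing column, bad row)."""


class MissingNormalError(ValueError):
    """A matched non-tumor table is required but was not provided."""


@dataclass(frozen=True)
class FilterThresholds:
    """Post-filter cutoffs; defaults are the study's stated values."""

    somatic_min_vaf: float = 0.05
    min_depth: int = 50
    somatic_max_popfreq: float = 0.005
    germline_min_vaf: float = 0.30
    germline_max_popfreq: float = 0.01
    pon_max_normals: int = 2
    #: Max VAF in the matched normal for a call to still count as somatic
    #: (Varscan-style "absent or low in normal" evidence).
    normal_max_vaf: float = 0.02

    def __post_init__(self) -> None:
        for name in (
            "somatic_min_vaf", "min_depth", "somatic_max_popfreq",
            "germline_min_vaf", "germline_max_popfreq",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.somatic_min_vaf >= self.germline_min_vaf:
            raise ValueError("somatic_min_vaf must be below germline_min_vaf")


@dataclass(frozen=True)
class VariantCall:
    """One annotated variant call from a tumor or non-tumor table."""

    case_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    gene_symbol: str
    transcript_id: str = ""
    protein_change: str = ""
    consequence_class: str = "other"
    total_depth: int = 0
    vaf_tumor: float = 0.0
    vaf_normal: Optional[float] = None
    popfreq_1kg: Optional[float] = None
    popfreq_esp6500: Optional[float] = None
    popfreq_exac: Optional[float] = None
    origin: str = "tumor_table"
    exonic: bool = True
    significance: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.total_depth < 0:
            raise ValueError("total_depth must be >= 0")
        for v in (self.vaf_tumor, self.vaf_normal):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"VAF out of [0,1]: {v}")

    @property
    def site_allele(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) key uniquely identifying a site-allele."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def max_popfreq(self) -> float:
        """Max population frequency across databases; absent counts as 0."""
        freqs = [
            f for f in (self.popfreq_1kg, self.popfreq_esp6500, self.popfreq_exac)
            if f is not None and not pd.isna(f)
        ]
        return max(freqs) if freqs else 0.0


@dataclass(frozen=True)
class RecurrenceRecord:
    """A protein change recurrently observed across cases."""

    gene_symbol: str
    protein_change: str
    n_mutated_samples: int
    pct_of_cohort: float
    cosmic_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_mutated_samples < 1:
            raise ValueError("n_mutated_samples must be >= 1")


# ---------------------------------------------------------------------------
# I/O


_REQUIRED_COLUMNS = (
    "case_id", "chrom", "pos", "ref", "alt", "gene_symbol",
    "total_depth", "vaf_tumor",
)

#: accepted alias -> canonical column name
_COLUMN_ALIASES = {
    "ref": "ref_allele",
    "alt": "alt_allele",
    "start": "pos",
    "gene": "gene_symbol",
    "sample": "case_id",
}


def _parse_fraction(value) -> Optional[float]:
    """Parse '48.51%' or '0.4851' (or blank) into a fraction."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"na", "nan", ".", ""}:
        return None
    if s.endswith("%"):
        return float(s[:-1]) / 100.0
    x = float(s)
    # Percent-valued columns without a % sign (e.g. "48.51") are converted.
    return x / 100.0 if x > 1.0 else x


def _str_or_empty(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value)


def read_variant_table(path: str | Path, origin: str = "tumor_table") -> list[VariantCall]:
    """Read a TSV variant table into VariantCall records.

    Percent-formatted VAF columns are converted to fractions. Raises
    VariantTableError naming the missing column or the bad row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {
        alias: canonical
        for alias, canonical in _COLUMN_ALIASES.items()
        if alias in df.columns and canonical not in df.columns
    }
    df = df.rename(columns=rename)
    needed = [_COLUMN_ALIASES.get(c, c) for c in _REQUIRED_COLUMNS]
    for col in needed:
        if col not in df.columns:
            raise VariantTableError(f"missing required column: {col!r}")
    calls: list[VariantCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            popfreqs = {
                k: _parse_fraction(d.get(k))
                for k in ("popfreq_1kg", "popfreq_esp6500", "popfreq_exac")
            }
            call = VariantCall(
                case_id=str(d["case_id"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref_allele=str(d["ref_allele"]),
                alt_allele=str(d["alt_allele"]),
                gene_symbol=str(d["gene_symbol"]),
                transcript_id=_str_or_empty(d.get("transcript_id")),
                protein_change=_str_or_empty(d.get("protein_change")),
                consequence_class=(
                    _str_or_empty(d.get("consequence_class"))
                    or classify_consequence(_str_or_empty(d.get("protein_change")))
                ),
                total_depth=int(float(d["total_depth"])),
                vaf_tumor=_parse_fraction(d["vaf_tumor"]) or 0.0,
                vaf_normal=_parse_fraction(d.get("vaf_normal")),
                origin=origin,
                exonic=str(d.get("exonic", "True")).strip().lower()
                not in {"false", "0", "no"},
                significance=_str_or_empty(d.get("significance")) or None,
                **popfreqs,
            )
        except (TypeError, ValueError) as exc:
            raise VariantTableError(f"line {i}: {exc}") from exc
        calls.append(call)
    return calls


_WRITE_COLUMNS = (
    "case_id", "chrom", "pos", "ref", "alt", "gene_symbol", "transcript_id",
    "protein_change", "consequence_class", "total_depth", "vaf_tumor",
    "vaf_normal", "popfreq_1kg", "popfreq_esp6500", "popfreq_exac",
    "exonic", "significance",
)


def read_vcf(path: str | Path, origin: str = "tumor_table") -> list[VariantCall]:
    """Read a minimal VCF 4.x variant table via pysam.

    Required INFO keys: DP (total depth) and AF (alternate allele
    fraction); GENE, PC (HGVS protein change), EXONIC and the population
    frequency keys PF1KG / PFESP / PFEXAC are honored when present. The
    case id is the single sample name, or the file stem for sample-less
    VCFs.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        case_id = samples[0] if samples else Path(path).stem
        for rec in vcf:
            info = rec.info
            if "DP" not in info or "AF" not in info:
                raise VariantTableError(
                    f"{path}: VCF record at {rec.chrom}:{rec.pos} lacks DP/AF"
                )
            af = info["AF"]
            af = float(af[0] if isinstance(af, tuple) else af)
            pc = str(_info_get(info, "PC") or "")
            for alt in rec.alts or ():
                calls.append(VariantCall(
                    case_id=case_id,
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref_allele=str(rec.ref),
                    alt_allele=str(alt),
                    gene_symbol=str(_info_get(info, "GENE") or ""),
                    protein_change=pc,
                    consequence_class=classify_consequence(pc),
                    total_depth=int(info["DP"]),
                    vaf_tumor=af,
                    popfreq_1kg=_info_float(info, "PF1KG"),
                    popfreq_esp6500=_info_float(info, "PFESP"),
                    popfreq_exac=_info_float(info, "PFEXAC"),
                    origin=origin,
                    exonic=bool(_info_get(info, "EXONIC", True)),
                ))
    return calls


def _info_get(info, key, default=None):
    # pysam raises on INFO keys absent from the header; treat as missing
    try:
        return info.get(key, default)
    except (KeyError, ValueError):
        return default


def _info_float(info, key) -> Optional[float]:
    v = _info_get(info, key)
    if v is None:
        return None
    return float(v[0] if isinstance(v, tuple) else v)


def read_calls(path: str | Path, origin: str = "tumor_table") -> list[VariantCall]:
    """Dispatch on extension: .vcf/.vcf.gz via read_vcf, else TSV."""
    name = str(path)
    if name.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path, origin)
    return read_variant_table(path, origin)


def write_variant_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as a TSV readable by read_variant_table (round-trips)."""
    rows = []
    for c in calls:
        rows.append({
            "case_id": c.case_id,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref_allele,
            "alt": c.alt_allele,
            "gene_symbol": c.gene_symbol,
            "transcript_id": c.transcript_id,
            "protein_change": c.protein_change,
            "consequence_class": c.consequence_class,
            "total_depth": c.total_depth,
            "vaf_tumor": c.vaf_tumor,
            "vaf_normal": "" if c.vaf_normal is None else c.vaf_normal,
            "popfreq_1kg": "" if c.popfreq_1kg is None else c.popfreq_1kg,
            "popfreq_esp6500": "" if c.popfreq_esp6500 is None else c.popfreq_esp6500,
            "popfreq_exac": "" if c.popfreq_exac is None else c.popfreq_exac,
            "exonic": c.exonic,
            "significance": c.significance or "",
        })
    pd.DataFrame(rows, columns=list(_WRITE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Consequence classification


def classify_consequence(
    protein_change: str, annotation_terms: Iterable[str] = ()
) -> str:
    """Classify an HGVS p. string into missense/trunc/in_frame/splicing/other.

    Nonsense (Ter/*) and frameshift changes are 'trunc'; frame-preserving
    del/dup/ins are 'in_frame'; single amino-acid substitutions are
    'missense'; splice annotation terms take precedence over the protein
    change. Unparseable strings fall through to 'other'.
    """
    terms = {str(t).lower() for t in annotation_terms}
    if terms & _SPLICE_TERMS:
        return "splicing"
    pc = (protein_change or "").strip().replace(" ", "")
    if not pc:
        return "other"
    if _RE_FRAMESHIFT.search(pc):
        return "trunc"
    m = _RE_MISSENSE3.match(pc) or _RE_MISSENSE1.match(pc)
    if m:
        ref_aa, alt_aa = m.group(1), m.group(3)
        if alt_aa in ("Ter", "*", "X"):
            return "trunc"
        if ref_aa == alt_aa:
            return "other"  # synonymous
        return "missense"
    if pc.endswith(("Ter", "*")) and not _RE_INFRAME.search(pc):
        return "trunc"
    if _RE_INFRAME.search(pc):
        return "in_frame"
    log.debug("unparseable protein change %r -> other", protein_change)
    return "other"


# ---------------------------------------------------------------------------
# Filters


def build_panel_of_normals(
    normal_tables: Iterable[Sequence[VariantCall]],
) -> dict[tuple[str, int, str, str], int]:
    """Count, per site-allele, the number of distinct non-tumor samples.

    Counts distinct cases, not read support: a variant appearing twice in
    one normal table still counts once for that case.
    """
    carriers: dict[tuple, set[str]] = defaultdict(set)
    for table in normal_tables:
        for call in table:
            carriers[call.site_allele].add(call.case_id)
    return {site: len(cases) for site, cases in carriers.items()}


def _is_exonic(call: VariantCall) -> bool:
    # Splice-site calls are admitted alongside exonic ones.
    return call.exonic or call.consequence_class == "splicing"


def filter_somatic(
    tumor_calls: Sequence[VariantCall],
    normal_calls: Optional[Sequence[VariantCall]],
    pon: Mapping[tuple, int],
    thresholds: FilterThresholds = FilterThresholds(),
    *,
    allow_missing_normal: bool = False,
) -> list[VariantCall]:
    """Apply the somatic post-filter cascade for one case.

    Retains calls with tumor VAF > somatic_min_vaf, depth > min_depth,
    exonic (or splice-site) consequence, max population frequency <
    somatic_max_popfreq, no supporting evidence in the matched normal
    (absent, or VAF < normal_max_vaf), and present in at most
    pon_max_normals non-tumor samples cohort-wide. Output sorted by
    (chrom, pos).
    """
    if normal_calls is None:
        if not allow_missing_normal:
            raise MissingNormalError(
                "matched non-tumor table required (pass allow_missing_normal"
                "=True to proceed tumor-only)"
            )
        log.warning("no matched normal: somatic filtering is tumor-only")
        normal_vaf: dict[tuple, float] = {}
    else:
        normal_vaf = {c.site_allele: c.vaf_tumor for c in normal_calls}
    t = thresholds
    kept = []
    for call in tumor_calls:
        if call.vaf_tumor <= t.somatic_min_vaf:
            continue
        if call.total_depth <= t.min_depth:
            continue
        if not _is_exonic(call):
            continue
        if call.max_popfreq() >= t.somatic_max_popfreq:
            continue
        nv = normal_vaf.get(call.site_allele)
        if nv is not None and nv >= t.normal_max_vaf:
            continue
        if pon.get(call.site_allele, 0) > t.pon_max_normals:
            continue
        kept.append(call)
    return sorted(kept, key=lambda c: (c.chrom, c.pos, c.alt_allele))


def filter_germline(
    tumor_calls: Sequence[VariantCall],
    normal_calls: Optional[Sequence[VariantCall]],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[VariantCall]:
    """Apply the germline post-filter cascade for one case.

    Retains site-alleles present in BOTH tables with both VAFs >
    germline_min_vaf, both depths > min_depth, and max population frequency
    < germline_max_popfreq. Returned records are the tumor-side calls with
    vaf_normal filled from the matched normal.
    """
    if normal_calls is None:
        raise MissingNormalError("germline filtering requires the matched normal")
    t = thresholds
    normal_by_site = {c.site_allele: c for c in normal_calls}
    kept = []
    for call in tumor_calls:
        mate = normal_by_site.get(call.site_allele)
        if mate is None:
            continue
        if call.vaf_tumor <= t.germline_min_vaf or mate.vaf_tumor <= t.germline_min_vaf:
            continue
        if call.total_depth <= t.min_depth or mate.total_depth <= t.min_depth:
            continue
        if call.max_popfreq() >= t.germline_max_popfreq:
            continue
        kept.append(replace(call, vaf_normal=mate.vaf_tumor))
    return sorted(kept, key=lambda c: (c.chrom, c.pos, c.alt_allele))


# ---------------------------------------------------------------------------
# Summaries


#: Canonical clinical-significance buckets (labels are pass-through inputs).
_SIGNIFICANCE_CANON = {
    "benign": "Benign or Likely Benign",
    "likely benign": "Benign or Likely Benign",
    "benign or likely benign": "Benign or Likely Benign",
    "vus": "VUS",
    "uncertain significance": "VUS",
    "likely pathogenic": "Likely pathogenic",
    "pathogenic": "Pathogenic",
}


def summarize_germline(calls: Sequence[VariantCall]) -> dict[str, int]:
    """Tally germline calls by externally supplied significance label.

    Returns {"total": n, <canonical label>: count, ...}; unknown labels are
    counted under "other" and logged. No classification logic is applied.
    """
    counts: dict[str, int] = {"total": len(calls)}
    for call in calls:
        raw = (call.significance or "").strip().lower()
        label = _SIGNIFICANCE_CANON.get(raw)
        if label is None:
            log.warning("unknown clinical-significance label %r", call.significance)
            label = "other"
        counts[label] = counts.get(label, 0) + 1
    return counts


_RE_SUFFIX = re.compile(r"(del|dup)$")


def normalize_protein_change(
    protein_change: str, pooling_map: Optional[Mapping[str, str]] = None
) -> str:
    """Normalize a protein change for recurrence grouping.

    By default, del and dup events at the same residue range are pooled
    under a single 'del/dup' key (frame-preserving indel slippage at the
    same repeat is one recurrent event). A pooling_map can add or override
    groupings.
    """
    pc = (protein_change or "").strip().replace(" ", "")
    if pooling_map and pc in pooling_map:
        return pooling_map[pc]
    if _RE_SUFFIX.search(pc) and "fs" not in pc:
        return _RE_SUFFIX.sub("del/dup", pc)
    return pc


def tally_recurrence(
    somatic_calls: Sequence[VariantCall],
    cohort_n: int,
    pooling_map: Optional[Mapping[str, str]] = None,
) -> list[RecurrenceRecord]:
    """Tally recurrent somatic variants cohort-wide.

    Groups by (gene, normalized protein change); a variant is recurrent
    when seen in >= 2 distinct cases. Percentages are over cohort_n.
    Sorted by gene then descending count.
    """
    from .cohort_stats import round_half_up

    carriers: dict[tuple[str, str], set[str]] = defaultdict(set)
    display: dict[tuple[str, str], str] = {}
    for call in somatic_calls:
        key = (call.gene_symbol, normalize_protein_change(call.protein_change, pooling_map))
        carriers[key].add(call.case_id)
        display.setdefault(key, key[1])
    records = []
    for (gene, pc), cases in carriers.items():
        n = len(cases)
        if n < 2:
            continue
        # a pooled label only shows 'del/dup' when both forms were seen
        label = pc
        if pc.endswith("del/dup"):
            seen = {
                c.protein_change.strip()
                for c in somatic_calls
                if c.gene_symbol == gene
                and normalize_protein_change(c.protein_change, pooling_map) == pc
            }
            if len(seen) == 1:
                label = next(iter(seen))
        records.append(
            RecurrenceRecord(
                gene_symbol=gene,
                protein_change=label,
                n_mutated_samples=n,
                pct_of_cohort=round_half_up(100.0 * n / cohort_n, 1),
            )
        )
    return sorted(records, key=lambda r: (r.gene_symbol, -r.n_mutated_samples, r.protein_change))
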