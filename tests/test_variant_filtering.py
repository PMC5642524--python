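"""Variant-table I/O, consequence classification, and the somatic/germline
post-filter cascades."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gastrosubtype import (
    FilterThresholds,
    VariantCall,
    build_panel_of_normals,
    classify_consequence,
    filter_germline,
    filter_somatic,
    read_variant_table,
    summarize_germline,
    tally_recurrence,
    write_variant_table,
)
from gastrosubtype.tables import GERMLINE_TABLE_TSV
from gastrosubtype.variant_filtering import (
    MissingNormalError,
    VariantTableError,
    normalize_protein_change,
)


@pytest.fixture()
def germline_fixture_path(tmp_path):
    p = tmp_path / "germline.tsv"
    p.write_text(GERMLINE_TABLE_TSV)
    return p


def make_call(**kwargs) -> VariantCall:
    defaults = dict(
        case_id="C1", chrom="1", pos=100, ref_allele="A", alt_allele="T",
        gene_symbol="TP53", protein_change="p.Arg248Trp",
        consequence_class="missense", total_depth=500, vaf_tumor=0.3,
    )
    defaults.update(kwargs)
    return VariantCall(**defaults)


class TestIO:
    def test_published_germline_table_parses(self, germline_fixture_path):
        calls = read_variant_table(germline_fixture_path)
        assert len(calls) == 30
        alk = next(c for c in calls if c.case_id == "YMC 54")
        assert alk.gene_symbol == "ALK"
        assert alk.total_depth == 637
        assert alk.vaf_tumor == pytest.approx(0.4851)
        assert alk.vaf_normal == pytest.approx(0.6036)

    def test_write_read_round_trip(self, tmp_path):
        calls = [
            make_call(),
            make_call(pos=200, vaf_normal=0.5, popfreq_exac=0.001,
                      significance="VUS", exonic=False),
        ]
        p = tmp_path / "t.tsv"
        write_variant_table(calls, p)
        back = read_variant_table(p)
        assert back == calls

    def test_missing_column_is_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("case_id\tchrom\tpos\tref\talt\tgene_symbol\tvaf_tumor\nX\t1\t5\tA\tT\tTP53\t0.2\n")
        with pytest.raises(VariantTableError, match="total_depth"):
            read_variant_table(p)

    def test_minimal_vcf_input(self, tmp_path):
        from gastrosubtype.variant_filtering import read_calls

        p = tmp_path / "case7.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n'
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Allele fraction">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n'
            '##INFO=<ID=PC,Number=1,Type=String,Description="Protein change">\n'
            '##INFO=<ID=PFEXAC,Number=1,Type=Float,Description="ExAC freq">\n'
            "##contig=<ID=17>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "17\t7578000\t.\tC\tT\t.\t.\tDP=637;AF=0.4851;GENE=TP53;"
            "PC=p.Arg248Trp;PFEXAC=0.0001\n"
        )
        calls = read_calls(p)
        assert len(calls) == 1
        c = calls[0]
        assert c.case_id == "case7"
        assert c.gene_symbol == "TP53"
        assert c.total_depth == 637
        assert c.vaf_tumor == pytest.approx(0.4851)
        assert c.popfreq_exac == pytest.approx(0.0001)
        assert c.consequence_class == "missense"

    def test_bad_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "case_id\tchrom\tpos\tref\talt\tgene_symbol\ttotal_depth\tvaf_tumor\n"
            "X\t1\t5\tA\tT\tTP53\tdeep\t0.2\n"
        )
        with pytest.raises(VariantTableError, match="line 2"):
            read_variant_table(p)


@pytest.mark.parametrize(
    "protein_change, terms, expected",
    [
        ("p.Arg2194Ter", (), "trunc"),
        ("p.Pro619LeufsTer43", (), "trunc"),
        ("p.Asp1850ThrfsTer33", (), "trunc"),
        ("p.His1047Arg", (), "missense"),
        ("p.V832M", (), "missense"),
        ("p.Glu280del", (), "in_frame"),
        ("p.Gln1334dup", (), "in_frame"),
        ("p.Leu15del", (), "in_frame"),
        ("", (), "other"),
        ("nonsense-string", (), "other"),
        ("p.His1047Arg", ("splice_donor_variant",), "splicing"),
    ],
)
def test_classify_consequence(protein_change, terms, expected):
    assert classify_consequence(protein_change, terms) == expected


class TestPanelOfNormals:
    def test_counts_distinct_cases_not_reads(self):
        tables = [
            [make_call(case_id=f"N{i}", origin="normal_table"),
             make_call(case_id=f"N{i}", origin="normal_table")]  # duplicate row
            for i in range(3)
        ]
        pon = build_panel_of_normals(tables)
        assert pon[("1", 100, "A", "T")] == 3

    def test_empty_input(self):
        assert build_panel_of_normals([]) == {}


class TestSomaticFilter:
    def test_threshold_rejections(self):
        pon = {}
        cases = {
            "low_depth": make_call(total_depth=40, vaf_tumor=0.20),
            "boundary_depth": make_call(total_depth=50),
            "low_vaf": make_call(total_depth=600, vaf_tumor=0.04),
            "popfreq": make_call(popfreq_exac=0.02),
            "non_exonic": make_call(exonic=False),
        }
        for name, call in cases.items():
            assert filter_somatic([call], [], pon) == [], name
        good = make_call(total_depth=600, vaf_tumor=0.2)
        assert filter_somatic([good], [], pon) == [good]

    def test_matched_normal_and_pon(self):
        call = make_call()
        in_normal = make_call(case_id="C1", vaf_tumor=0.3, origin="normal_table")
        assert filter_somatic([call], [in_normal], {}) == []
        assert filter_somatic([call], [], {call.site_allele: 3}) == []
        assert filter_somatic([call], [], {call.site_allele: 2}) == [call]

    def test_missing_normal_requires_opt_in(self):
        with pytest.raises(MissingNormalError):
            filter_somatic([make_call()], None, {})
        assert filter_somatic([make_call()], None, {}, allow_missing_normal=True)

    def test_idempotence(self):
        rng = np.random.default_rng(7)
        calls = _random_calls(rng, 300)
        once = filter_somatic(calls, [], {})
        twice = filter_somatic(once, [], {})
        assert twice == once

    def test_monotonic_in_vaf_threshold(self):
        rng = np.random.default_rng(8)
        calls = _random_calls(rng, 300)
        lo = {c.site_allele for c in filter_somatic(calls, [], {})}
        strict = FilterThresholds(somatic_min_vaf=0.15)
        hi = {c.site_allele for c in filter_somatic(calls, [], {}, strict)}
        assert hi <= lo

    def test_matches_independent_predicate_on_random_records(self):
        """Filter decisions agree with a direct row-by-row re-evaluation."""
        rng = np.random.default_rng(20170722)
        calls = _random_calls(rng, 1000)
        normals = [c for c in calls if rng.random() < 0.2]
        pon = {c.site_allele: int(rng.integers(0, 5)) for c in calls}
        normal_vaf = {c.site_allele: c.vaf_tumor for c in normals}

        def oracle(c: VariantCall) -> bool:
            ok = c.vaf_tumor > 0.05
            ok = ok and c.total_depth > 50
            ok = ok and (c.exonic or c.consequence_class == "splicing")
            freqs = [f for f in (c.popfreq_1kg, c.popfreq_esp6500, c.popfreq_exac)
                     if f is not None]
            ok = ok and (max(freqs) if freqs else 0.0) < 0.005
            nv = normal_vaf.get(c.site_allele)
            ok = ok and (nv is None or nv < 0.02)
            ok = ok and pon.get(c.site_allele, 0) <= 2
            return ok

        kept = {id(c) for c in filter_somatic(calls, normals, pon)}
        for c in calls:
            assert (id(c) in kept) == oracle(c)


class TestGermlineFilter:
    def test_shared_high_vaf_variant_retained(self):
        tumor = make_call(protein_change="p.V832M", gene_symbol="CDH1",
                          total_depth=1337, vaf_tumor=0.5221)
        normal = make_call(protein_change="p.V832M", gene_symbol="CDH1",
                           total_depth=1100, vaf_tumor=0.4975,
                           origin="normal_table")
        kept = filter_germline([tumor], [normal])
        assert len(kept) == 1
        assert kept[0].vaf_normal == pytest.approx(0.4975)

    def test_low_vaf_rejected(self):
        tumor = make_call(vaf_tumor=0.25)
        normal = make_call(vaf_tumor=0.5, origin="normal_table")
        assert filter_germline([tumor], [normal]) == []

    def test_tumor_only_rejected(self):
        assert filter_germline([make_call(vaf_tumor=0.5)], []) == []

    def test_partition_with_somatic(self):
        """Disjoint planted germline/somatic truth is recovered exactly."""
        somatic_truth = [make_call(pos=1000 + i, vaf_tumor=0.2) for i in range(5)]
        germ_truth = [make_call(pos=2000 + i, vaf_tumor=0.5) for i in range(5)]
        normal = [make_call(pos=2000 + i, vaf_tumor=0.48, origin="normal_table")
                  for i in range(5)]
        tumor = somatic_truth + germ_truth
        som = filter_somatic(tumor, normal, {})
        germ = filter_germline(tumor, normal)
        som_keys = {c.site_allele for c in som}
        germ_keys = {c.site_allele for c in germ}
        assert som_keys == {c.site_allele for c in somatic_truth}
        assert germ_keys == {c.site_allele for c in germ_truth}
        assert not (som_keys & germ_keys)


class TestSummaries:
    def test_germline_significance_counts(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(GERMLINE_TABLE_TSV)
        counts = summarize_germline(read_variant_table(p))
        assert counts["total"] == 30
        assert counts["Benign or Likely Benign"] == 16
        assert counts["VUS"] == 12
        assert counts["Likely pathogenic"] == 2

    def test_empty_summary(self):
        assert summarize_germline([]) == {"total": 0}

    def test_unknown_label_goes_to_other(self):
        counts = summarize_germline([make_call(significance="odd label")])
        assert counts["other"] == 1

    def test_recurrence_pct_and_threshold(self):
        calls = [
            make_call(case_id=f"C{i}", gene_symbol="ARID1A",
                      protein_change="p.Gln1334dup" if i % 2 else "p.Gln1334del")
            for i in range(23)
        ]
        calls.append(make_call(case_id="Z1", gene_symbol="KRAS",
                               protein_change="p.Gly13Asp"))
        recs = tally_recurrence(calls, cohort_n=107)
        assert len(recs) == 1  # the singleton KRAS variant is not recurrent
        rec = recs[0]
        assert rec.protein_change == "p.Gln1334del/dup"
        assert rec.n_mutated_samples == 23
        assert rec.pct_of_cohort == 21.5

    def test_single_suffix_not_relabelled(self):
        calls = [make_call(case_id=f"C{i}", gene_symbol="CCND1",
                           protein_change="p.Glu280del") for i in range(7)]
        recs = tally_recurrence(calls, cohort_n=107)
        assert recs[0].protein_change == "p.Glu280del"
        assert recs[0].pct_of_cohort == 6.5

    def test_pooling_map_override(self):
        assert normalize_protein_change(
            "p.Arg5Gln", {"p.Arg5Gln": "p.Arg5Gln/Trp"}
        ) == "p.Arg5Gln/Trp"
        assert normalize_protein_change("p.Asp1850ThrfsTer33") == "p.Asp1850ThrfsTer33"


@settings(derandomize=True, max_examples=50)
@given(
    vaf=st.floats(0.0, 1.0),
    depth=st.integers(0, 2000),
    pop=st.one_of(st.none(), st.floats(0, 0.5)),
)
def test_somatic_filter_never_keeps_below_threshold(vaf, depth, pop):
    call = make_call(vaf_tumor=vaf, total_depth=depth, popfreq_1kg=pop)
    kept = filter_somatic([call], [], {})
    if kept:
        assert vaf > 0.05 and depth > 50 and (pop or 0.0) < 0.005


def _random_calls(rng: np.random.Generator, n: int) -> list[VariantCall]:
    calls = []
    for i in range(n):
        calls.append(make_call(
            case_id=f"R{i}",
            pos=int(rng.integers(1, 500)),
            vaf_tumor=float(rng.uniform(0, 0.8)),
            total_depth=int(rng.integers(0, 800)),
            popfreq_exac=(float(rng.uniform(0, 0.02))
                          if rng.random() < 0.5 else None),
            exonic=bool(rng.random() < 0.9),
        ))
    return calls
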