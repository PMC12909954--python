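"""SV matching, VCF I/O, callerset validation, blacklist and collapse."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svsieve import sv_core as core
from svsieve.config import ABSENT, HET, HOM
from svsieve.sv_core import MatchParams, SVRecord, sv_match

from conftest import brute_force_partition, make_random_records


def rec(sv_id="a", chrom="chr1", start=1000, svtype="INS", svlen=300, seq=None, **kw):
    end = start if svtype == "INS" else start + svlen
    return SVRecord(sv_id=sv_id, chrom=chrom, start=start, end=end, svtype=svtype,
                    svlen=svlen, seq=seq, **kw)


class TestSvMatch:
    def test_identical_insertions_match_with_unit_similarity(self, default_params):
        a = rec(seq="ACGT" * 75)
        d = sv_match(a, rec(sv_id="b", seq="ACGT" * 75), default_params)
        assert d.matched and d.size_similarity == 1.0 and d.seq_similarity == 1.0

    def test_type_mismatch_never_matches(self, default_params):
        assert not sv_match(rec(svtype="INS"), rec(sv_id="b", svtype="DEL"), default_params).matched

    def test_size_ratio_below_pctsize_fails(self, default_params):
        # 260/300 = 0.867 < 0.9, within refdist
        a = rec(svlen=260)
        b = rec(sv_id="b", start=1100, svlen=300)
        d = sv_match(a, b, default_params)
        assert not d.matched
        assert d.size_similarity == pytest.approx(260 / 300)

    def test_chrom_mismatch_is_a_nonmatch_not_an_error(self, default_params):
        assert not sv_match(rec(), rec(sv_id="b", chrom="chr2"), default_params).matched

    def test_sequenceless_records_fall_back_to_size_matching(self, default_params):
        d = sv_match(rec(seq=None), rec(sv_id="b", seq=None), default_params)
        assert d.matched and d.seq_fallback and d.seq_similarity is None

    def test_reciprocal_overlap_gates_deletions(self):
        p = MatchParams(pctseq=0.0, pctsize=0.5, pctovl=0.5, refdist=500)
        a = rec(svtype="DEL", start=0, svlen=400)
        b = rec(sv_id="b", svtype="DEL", start=300, svlen=400)  # overlap 100/400 = 0.25
        assert not sv_match(a, b, p).matched
        c = rec(sv_id="c", svtype="DEL", start=100, svlen=400)  # overlap 300/400 = 0.75
        assert sv_match(a, c, p).matched

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_symmetry_and_refdist_monotonicity(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        (a, _), (b, _) = make_random_records(rng, 2, span=1500)
        p_small = MatchParams(refdist=data.draw(st.integers(0, 500)))
        p_big = MatchParams(refdist=p_small.refdist + data.draw(st.integers(0, 1000)))
        fwd, rev = sv_match(a, b, p_small), sv_match(b, a, p_small)
        assert fwd.matched == rev.matched
        assert fwd.size_similarity == rev.size_similarity
        if fwd.matched:  # match set grows with refdist
            assert sv_match(a, b, p_big).matched


class TestVcfIO:
    def test_coordinate_convention_for_insertion(self, tmp_path):
        """A 300 bp INS at 1-based position 1000 reads back as 0-based start 999."""
        seq = "A" * 300
        path = tmp_path / "one.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr1,length=100000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            f"chr1\t1000\tins1\tN\tN{seq}\t.\t.\tSVTYPE=INS;SVLEN=300\tGT\t0/1\n"
        )
        t = core.read_sv_vcf(str(path))
        (r,) = t.rows
        assert (r.start, r.end, r.svlen, r.svtype, r.seq) == (999, 999, 300, "INS", seq)
        assert t.genotypes[0, 0] == HET

    def test_multiallelic_line_splits_into_biallelic_records(self, tmp_path):
        path = tmp_path / "ma.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr1,length=100000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            f"chr1\t500\tm1\tN\tN{'A' * 60},N{'C' * 90}\t.\t.\t.\tGT\t1/2\n"
        )
        t = core.read_sv_vcf(str(path))
        assert t.n_rows == 2
        assert sorted(r.svlen for r in t.rows) == [60, 90]
        assert list(t.genotypes[:, 0]) == [HET, HET]

    def test_records_without_length_are_skipped_not_fatal(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr1,length=100000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t500\tbad1\tN\t<INS>\t.\t.\tSVTYPE=INS\tGT\t0/1\n"
            f"chr1\t900\tok1\tN\tN{'G' * 70}\t.\t.\tSVTYPE=INS\tGT\t1/1\n"
        )
        t = core.read_sv_vcf(str(path))
        assert [r.sv_id for r in t.rows] == ["ok1"]
        assert t.genotypes[0, 0] == HOM

    def test_write_then_read_is_identity(self, tmp_path):
        rng = np.random.default_rng(5)
        entries = make_random_records(rng, 100, n_samples=3)
        table = core.collapse_cohort(_group(entries), MatchParams())
        path = str(tmp_path / "t.vcf")
        core.write_sv_vcf(table, path)
        back = core.read_sv_vcf(path)
        assert back.samples == table.samples
        assert [r.key() for r in back.rows] == [r.key() for r in table.rows]
        assert (back.genotypes == table.genotypes).all()


def _group(entries):
    callsets = {}
    for r, s in entries:
        callsets.setdefault(s, []).append(r)
    return callsets


class TestValidateAndBlacklist:
    def test_supporting_equals_primary_validates_all(self, default_params):
        rng = np.random.default_rng(0)
        prim = [r for r, _ in make_random_records(rng, 50)]
        out = core.validate_callersets(prim, [list(prim)], default_params)
        assert len(out) == len(prim)
        assert all(r.support for r in out)

    def test_empty_supporting_callsets_validate_nothing(self, default_params):
        rng = np.random.default_rng(0)
        prim = [r for r, _ in make_random_records(rng, 20)]
        assert core.validate_callersets(prim, [[], []], default_params) == []
        with pytest.raises(ValueError):
            core.validate_callersets(prim, [], default_params)

    def test_blacklist_exclusion_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        svs = [r for r, _ in make_random_records(rng, 1000, span=100_000)]
        bl = [
            ("chr1" if rng.random() < 0.5 else "chr2", int(s), int(s) + int(rng.integers(100, 5000)))
            for s in rng.integers(0, 100_000, 40)
        ]
        kept = core.exclude_blacklist(svs, bl)
        oracle = [
            sv
            for sv in svs
            if not any(
                c == sv.chrom and s < sv.span[1] and sv.span[0] < e for c, s, e in bl
            )
        ]
        assert [r.sv_id for r in kept] == [r.sv_id for r in oracle]
        assert core.exclude_blacklist(svs, []) == svs


class TestCollapse:
    def test_single_nonredundant_sample_is_identity(self, default_params):
        recs = [rec(sv_id=f"x{i}", start=i * 10_000, seq="ACGT" * 100) for i in range(5)]
        t = core.collapse_cohort({"s1": recs}, default_params)
        assert t.n_rows == 5
        assert [r.sv_id for r in t.rows] == [r.sv_id for r in recs]

    def test_shared_insertion_collapses_to_one_row(self, default_params):
        seq = "ACGT" * 75
        callsets = {
            f"s{i}": [rec(sv_id=f"v{i}", start=1000 + i * 10, seq=seq)] for i in range(5)
        }
        t = core.collapse_cohort(callsets, default_params)
        assert t.n_rows == 1
        assert (t.genotypes[0] != ABSENT).sum() == 5

    @pytest.mark.parametrize("trial", range(10))
    def test_partition_equals_brute_force_union_find(self, trial, default_params):
        rng = np.random.default_rng(100 + trial)
        entries = make_random_records(rng, 100)
        table = core.collapse_cohort(_group(entries), default_params)
        oracle = brute_force_partition(entries, default_params)
        # compare partitions via per-entry labels
        labels = core.cluster_records(entries, default_params)
        got = frozenset(
            frozenset(i for i, lab in enumerate(labels) if lab == root)
            for root in set(labels)
        )
        assert got == oracle
        assert table.n_rows == len(oracle)

    def test_collapse_is_idempotent_and_nonredundant(self, default_params):
        rng = np.random.default_rng(9)
        entries = make_random_records(rng, 300, span=20_000)
        t1 = core.collapse_cohort(_group(entries), default_params)
        t2 = core.collapse_cohort(t1.to_callsets(), default_params, samples=t1.samples)
        assert [r.key() for r in t2.rows] == [r.key() for r in t1.rows]
        assert (t2.genotypes == t1.genotypes).all()
        # nonredundancy, allowing only the intra-sample het/het exception
        for a, b in core.redundant_pairs(t1, default_params):
            ia, ib = t1.rows.index(a), t1.rows.index(b)
            both_het_same_sample = (
                (t1.genotypes[ia] == HET) & (t1.genotypes[ib] == HET)
            ).any()
            assert both_het_same_sample

    def test_keep_policies_select_documented_representative(self, default_params):
        seq = "A" * 100
        shared = [rec(sv_id=f"c{i}", start=1000, svlen=100, seq=seq, qual=10.0) for i in range(3)]
        odd = rec(sv_id="q", start=1050, svlen=100, seq=seq, qual=99.0)
        callsets = {f"s{i}": [shared[i]] for i in range(3)}
        callsets["s3"] = [odd]
        common = core.collapse_cohort(callsets, default_params, keep="common")
        assert common.rows[0].sv_id == "c0"  # allele seen in 3 samples, leftmost id
        maxq = core.collapse_cohort(callsets, default_params, keep="maxqual")
        assert maxq.rows[0].sv_id == "q"
        first = core.collapse_cohort(callsets, default_params, keep="first")
        assert first.rows[0].start == 1000
        with pytest.raises(ValueError):
            core.collapse_cohort(callsets, default_params, keep="nope")

    def test_unknown_sample_in_callset_is_an_input_error(self, default_params):
        with pytest.raises(ValueError):
            core.collapse_cohort({"s1": [rec()]}, default_params, samples=["other"])
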