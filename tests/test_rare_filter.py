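"""Control filtering, zygosity categories, Mendelian confidence, origin
classes, MAF and panel analyses."""

import numpy as np
import pandas as pd
import pytest

from svsieve import cohort_sim as cs
from svsieve import rare_filter as rf
from svsieve import sv_core as core
from svsieve.config import ABSENT, CARRIER_CODES, HEMI, HET, HOM, MISSING
from svsieve.sv_core import CohortSVTable, MatchParams, SVRecord

from conftest import make_random_records


def mini_table(rows, samples, gt):
    return CohortSVTable(rows=rows, samples=samples, genotypes=np.array(gt, np.int8))


def sv(sv_id, chrom="chr1", start=1000, svtype="INS", svlen=100):
    end = start if svtype == "INS" else start + svlen
    return SVRecord(sv_id, chrom, start, end, svtype, svlen)


def quad(fid="f1", proband_sex="F", sibling_sex="M", pop="nonAFR"):
    return (
        fid,
        [
            cs.Individual(f"{fid}_fa", fid, "father", "M", pop),
            cs.Individual(f"{fid}_mo", fid, "mother", "F", pop),
            cs.Individual(f"{fid}_p1", fid, "proband", proband_sex, pop),
            cs.Individual(f"{fid}_s1", fid, "sibling", sibling_sex, pop),
        ],
    )


class TestPangenomeFilter:
    def test_child_only_sv_retained_control_hit_removed(self):
        rows = [sv("a"), sv("b", start=5000)]
        samples = ["child1", "ctrl1"]
        gt = [[HET, ABSENT], [HET, HET]]
        rare = rf.pangenome_filter(
            mini_table(rows, samples, gt), ["child1"], ["ctrl1"], {"child1": "F", "ctrl1": "F"}
        )
        assert list(rare.entries["sv_id"]) == ["a"]

    def test_sex_matched_rule_on_chromosome_x(self):
        """A female child's non-PAR X SV carried only by male controls is kept."""
        rows = [sv("x1", chrom="chrX", start=20_000_000)]
        samples = ["girl", "ctrlM", "ctrlF"]
        sexes = {"girl": "F", "ctrlM": "M", "ctrlF": "F"}
        kept = rf.pangenome_filter(
            mini_table(rows, samples, [[HET, HEMI, ABSENT]]), ["girl"], ["ctrlM", "ctrlF"], sexes
        )
        assert len(kept) == 1
        removed = rf.pangenome_filter(
            mini_table(rows, samples, [[HET, ABSENT, HET]]), ["girl"], ["ctrlM", "ctrlF"], sexes
        )
        assert len(removed) == 0

    def test_unknown_child_is_an_input_error(self):
        t = mini_table([sv("a")], ["s1"], [[HET]])
        with pytest.raises(ValueError):
            rf.pangenome_filter(t, ["ghost"], [], {})

    def test_missing_control_genotypes_do_not_count_as_carriers(self):
        t = mini_table([sv("a")], ["c1", "k1"], [[HET, MISSING]])
        rare = rf.pangenome_filter(t, ["c1"], ["k1"], {"c1": "F", "k1": "F"})
        assert len(rare) == 1


class TestZygosityCategories:
    @pytest.mark.parametrize(
        "cc,sex,gt,expected",
        [
            ("AUTO", "F", HET, "AUTO_HET"),
            ("AUTO", "M", HOM, "AUTO_HOM"),
            ("X", "F", HET, "X_HET"),
            ("X", "F", HOM, "X_HOM"),
            ("X", "M", HEMI, "X_HEMI"),
            ("Y", "M", HEMI, "Y_HEMI"),
        ],
    )
    def test_category_assignment(self, cc, sex, gt, expected):
        cat, flag = rf.zygosity_category(cc, sex, gt)
        assert cat == expected and flag is None

    def test_male_diploid_x_genotype_is_flagged_not_fatal(self):
        cat, flag = rf.zygosity_category("X", "M", HOM)
        assert cat == "X_HEMI" and flag == "male_x_diploid_genotype"

    def test_simulated_counts_match_truth_and_partition(self, small_cohort):
        _, ped, sim, _ = small_cohort
        table = cs.cohort_table(sim)
        rare = rf.pangenome_filter(table, ped.children, ped.control_ids, ped.sexes)
        res = rf.classify_zygosity_categories(rare, ped.sexes)
        assert sum(res["pair_counts"].values()) == len(rare)
        # truth recomputation from the genotype matrix
        expected = dict.fromkeys(rf.CATEGORIES, 0)
        for e in rare.entries.itertuples():
            cat, _ = rf.zygosity_category(e.chrom_class, ped.sexes[e.child], e.genotype)
            expected[cat] += 1
        assert res["pair_counts"] == expected


class TestMendelian:
    def test_het_child_with_het_father_is_high_confidence(self):
        assert rf.mendelian_classify(HET, HET, ABSENT) == "HC"

    def test_hom_child_with_absent_parents_is_low_confidence(self):
        assert rf.mendelian_classify(HOM, ABSENT, ABSENT) == "LC"

    def test_missing_parent_is_low_confidence(self):
        assert rf.mendelian_classify(HET, MISSING, HET) == "LC"

    def test_sex_chromosome_rules(self):
        # sons take X from the mother only; the father's X is irrelevant
        assert rf.mendelian_classify(HEMI, ABSENT, HET, cc="X", child_sex="M") == "HC"
        assert rf.mendelian_classify(HEMI, HEMI, ABSENT, cc="X", child_sex="M") == "LC"
        # Y: father only; mother structurally missing
        assert rf.mendelian_classify(HEMI, HEMI, MISSING, cc="Y", child_sex="M") == "HC"
        assert rf.mendelian_classify(HEMI, ABSENT, MISSING, cc="Y", child_sex="M") == "LC"

    def test_error_free_cohort_without_denovo_is_fully_concordant(self):
        pool = cs.simulate_sv_pool(1500, seed=21, with_sequences=False)
        ped = cs.PedigreeSpec.standard(n_quads=3, n_controls=30, seed=21)
        sim, _ = cs.simulate_cohort(pool, ped, denovo_rate=0.0, error_rate=0.0, seed=21)
        rare = rf.pangenome_filter(cs.cohort_table(sim), ped.children, ped.control_ids, ped.sexes)
        rf.classify_zygosity_categories(rare, ped.sexes)
        assert rf.mendelian_classify_table(rare, ped) == 1.0


class TestVariantOrigin:
    def build(self, child_gt, fa_gt, mo_gt, other_fa=ABSENT, other_mo=ABSENT):
        ped = cs.PedigreeSpec(
            families=[quad("f1"), quad("f2")],
            controls=[cs.Individual("k1", "", "control", "F", "nonAFR")],
        )
        rows = [sv("v1")]
        samples = ped.samples
        gt = {s: ABSENT for s in samples}
        gt.update({"f1_p1": child_gt, "f1_fa": fa_gt, "f1_mo": mo_gt,
                   "f2_fa": other_fa, "f2_mo": other_mo})
        table = mini_table(rows, samples, [[gt[s] for s in samples]])
        rare = rf.pangenome_filter(table, ped.children, ["k1"], ped.sexes)
        rf.classify_zygosity_categories(rare, ped.sexes)
        rf.mendelian_classify_table(rare, ped)
        rf.classify_variant_origin(rare, ped)
        return rare.entries.set_index("child").loc["f1_p1", "origin"]

    def test_child_het_parents_absent_is_denovo(self):
        assert self.build(HET, ABSENT, ABSENT) == "DENOVO"

    def test_hom_child_of_two_family_unique_hets_is_private_biallelic(self):
        assert self.build(HOM, HET, HET) == "PRIVATE_BIALLELIC_HOM"

    def test_allele_seen_in_one_parent_cohortwide_is_private_inherited(self):
        assert self.build(HET, HET, ABSENT) == "PRIVATE_INHERITED"

    def test_allele_in_two_parents_is_inherited_other(self):
        assert self.build(HET, HET, ABSENT, other_fa=HET) == "INHERITED_OTHER"

    def test_denovo_recovery_is_exact_on_error_free_simulation(self, small_cohort):
        _, ped, sim, truth = small_cohort
        rare = rf.pangenome_filter(cs.cohort_table(sim), ped.children, ped.control_ids, ped.sexes)
        rf.classify_zygosity_categories(rare, ped.sexes)
        rf.mendelian_classify_table(rare, ped)
        rf.classify_variant_origin(rare, ped)
        rec = rf.denovo_recovery(rare, truth)
        assert rec["sensitivity"] == 1.0 and rec["false_positives"] == 0
        # origin exclusivity: exactly one label per entry
        assert rare.entries["origin"].isin(rf.ORIGINS).all()


class TestMAF:
    def test_single_het_among_fifty_diploids(self):
        t = mini_table([sv("a")], [f"s{i}" for i in range(50)],
                       [[HET] + [ABSENT] * 49])
        maf = rf.compute_maf(t, {f"s{i}": "F" for i in range(50)})
        assert maf.loc[0, "maf"] == pytest.approx(1 / 100)
        assert maf.loc[0, "allele_number"] == 100

    def test_all_hom_folds_to_zero(self):
        t = mini_table([sv("a")], ["s1", "s2"], [[HOM, HOM]])
        maf = rf.compute_maf(t, {"s1": "F", "s2": "F"})
        assert maf.loc[0, "maf"] == 0.0

    def test_hemizygous_males_contribute_one_allele(self):
        t = mini_table([sv("y", chrom="chrY", start=5_000_000)], ["m1", "m2", "f1"],
                       [[HEMI, ABSENT, MISSING]])
        maf = rf.compute_maf(t, {"m1": "M", "m2": "M", "f1": "F"})
        assert maf.loc[0, "allele_number"] == 2
        assert maf.loc[0, "maf"] == pytest.approx(0.5)

    def test_random_matrix_matches_per_allele_tally(self):
        rng = np.random.default_rng(8)
        n, m = 40, 12
        rows = [sv(f"v{i}", start=1000 + 10_000 * i) for i in range(n)]
        gt = rng.choice([MISSING, ABSENT, HET, HOM], size=(n, m), p=[0.05, 0.5, 0.3, 0.15])
        t = mini_table(rows, [f"s{j}" for j in range(m)], gt)
        maf = rf.compute_maf(t, {f"s{j}": "F" for j in range(m)})
        for i in range(n):
            an = 2 * (gt[i] != MISSING).sum()
            ac = ((gt[i] == HET) * 1 + (gt[i] == HOM) * 2).sum()
            f = ac / an
            assert maf.loc[i, "maf"] == pytest.approx(min(f, 1 - f))


class TestPanels:
    def test_identical_callsets_give_flat_curve(self, default_params):
        recs = [sv(f"v{i}", start=1000 + 10_000 * i) for i in range(7)]
        callsets = {f"s{j}": list(recs) for j in range(4)}
        out = rf.discovery_curve(callsets, {f"s{j}": "AFR" for j in range(4)}, 3, default_params, seed=0)
        assert (out["AFR"]["mean"] == 7).all()

    def test_disjoint_callsets_accumulate_set_sizes(self, default_params):
        callsets = {
            f"s{j}": [sv(f"v{j}_{i}", start=1000 + 100_000 * (5 * j + i)) for i in range(j + 1)]
            for j in range(3)
        }
        out = rf.discovery_curve(callsets, {f"s{j}": "AFR" for j in range(3)}, 5, default_params, seed=1)
        df = out["AFR"]
        assert df["mean"].iloc[-1] == 1 + 2 + 3
        assert (df["mean"].diff().dropna() > 0).all()  # strictly increasing here

    def test_equal_panels_capture_everything(self, default_params):
        rng = np.random.default_rng(2)
        entries = make_random_records(rng, 60, span=500_000)
        callsets = {}
        for r, s in entries:
            callsets.setdefault(s, []).append(r)
        table = core.collapse_cohort(callsets, default_params)
        capt = rf.maf_capture(table, table, [0, 0.1, 0.5], default_params)
        assert (capt["fraction"].dropna() == 1.0).all()

    def test_empty_small_panel_captures_nothing(self, default_params):
        rng = np.random.default_rng(2)
        entries = make_random_records(rng, 30, span=500_000)
        callsets = {}
        for r, s in entries:
            callsets.setdefault(s, []).append(r)
        table = core.collapse_cohort(callsets, default_params)
        empty = CohortSVTable(rows=[], samples=["x"], genotypes=np.zeros((0, 1), np.int8))
        capt = rf.maf_capture(empty, table, [0, 0.1, 0.5], default_params)
        assert (capt["fraction"].fillna(0) == 0.0).all()

    def test_twenty_percent_subpanel_captures_singletons_at_subset_rate(self, default_params):
        pool = cs.simulate_sv_pool(4000, seed=31, with_sequences=False)
        controls = [cs.Individual(f"c{i}", "", "control", "F", "nonAFR") for i in range(30)]
        ped = cs.PedigreeSpec(families=[], controls=controls)
        sim, _ = cs.simulate_cohort(pool, ped, denovo_rate=0, seed=31)
        table = cs.cohort_table(sim)
        callsets = table.to_callsets()
        small_ids = [c.sample_id for c in controls[::5]]  # 6 of 30 = 20%
        small = core.collapse_cohort({s: callsets[s] for s in small_ids}, default_params)
        maf = rf.compute_maf(table, {s: "F" for s in table.samples})
        window = core._Window(small.rows)
        singleton = maf["allele_count"].to_numpy() == 1
        caught = []
        for i, r in enumerate(table.rows):
            if not singleton[i]:
                continue
            caught.append(
                any(core.sv_match(r, c, default_params).matched for c in window.near(r, 500))
            )
        frac = np.mean(caught)
        n = len(caught)
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / n)

    def test_nested_panels_never_increase_per_child_counts(self):
        pool = cs.simulate_sv_pool(1500, seed=41, with_sequences=False)
        ped = cs.PedigreeSpec.standard(n_quads=2, n_controls=40, seed=41)
        sim, _ = cs.simulate_cohort(pool, ped, denovo_rate=0.3, seed=41)
        table = cs.cohort_table(sim)
        prev = None
        for k in (5, 15, 40):
            rare = rf.pangenome_filter(table, ped.children, ped.control_ids[:k], ped.sexes)
            counts = rare.per_child_counts().reindex(ped.children, fill_value=0)
            if prev is not None:
                assert (counts <= prev).all()
            prev = counts
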