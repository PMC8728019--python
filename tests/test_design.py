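import numpy as np
import pandas as pd
import pytest

from _oracles import greedy_trace_oracle, wc_theta_oracle
from conftest import random_ld_instance
from tagarray import design, ldtag
from tagarray.design import (
    DesignSelection, SelectionConfig, classify_content, coverage_fill,
    fst_weir_cockerham, gap_fill, relaxed_rescue, sample_size_compensation,
    select_dgenome_content, select_tsnps, subgroup_mafs, tagged_at,
)
from tagarray.genodata import GenotypeMatrix, SNPRecord, SubgroupSpec
from tagarray.ldtag import LDTable, build_tag_sets, order_tag_sets


def chain_order(q=0.9, m=2):
    """The 3-SNP chain: T(A)={A,B,C}, T(B)={A,B}, T(C)={A,C}."""
    table = LDTable(["A", "A", "B"], ["B", "C", "C"], np.array([0.95, 0.92, 0.85]))
    records = [SNPRecord(snp_id=s, chromosome="chr1", position=p)
               for s, p in (("A", 100), ("B", 200), ("C", 300))]
    sets = build_tag_sets(table, "ABC", q, records)
    return order_tag_sets(sets, records), table, records


def run_select(order, F, m=2, **kwargs):
    config = SelectionConfig(m=m, **kwargs)
    return select_tsnps(order, F, config)


class TestGreedySelection:
    def test_chain_selects_only_a(self):
        order, _, _ = chain_order()
        selection, _ = run_select(order, {"A", "B", "C"}, m=2)
        assert selection.snp_ids == ["A"]  # A's set intersects both others

    def test_all_sets_below_m_gives_empty_selection(self):
        order, _, _ = chain_order()
        selection, _ = run_select(order, {"A", "B", "C"}, m=4)
        assert len(selection) == 0

    def test_empty_F_gives_empty_selection(self):
        order, _, _ = chain_order()
        selection, _ = run_select(order, set(), m=2)
        assert len(selection) == 0

    def test_ineligible_focal_falls_through_to_next_head(self):
        order, _, _ = chain_order()
        selection, _ = run_select(order, {"B", "C"}, m=2)
        # B's set {A,B} is selected first (tie rule), killing C's set {A,C}
        assert selection.snp_ids == ["B"]

    @pytest.mark.parametrize("size,expected_tags", [(55, 3), (25, 2), (12, 1)])
    def test_redundancy_tiers(self, size, expected_tags):
        members = [f"x{k}" for k in range(size - 1)]
        table = LDTable(["f"] * (size - 1), members,
                        np.linspace(0.99, 0.9, size - 1))
        records = [SNPRecord(snp_id="f", chromosome="chr1", position=50)] + [
            SNPRecord(snp_id=x, chromosome="chr1", position=100 + k)
            for k, x in enumerate(members)]
        sets = build_tag_sets(table, ["f"] + members, 0.9, records)
        order = order_tag_sets(sets, records)
        F = {"f"} | set(members)
        selection, _ = select_tsnps(order, F, SelectionConfig(),
                                    ld=table, records=records)
        primary = selection.by_category("tag_strict")
        redundant = selection.by_category("tag_redundant")
        assert len(primary) == 1 and primary[0].snp_id == "f"
        assert 1 + len(redundant) == expected_tags
        # redundant tags are the highest-r² members
        if redundant:
            assert [e.snp_id for e in redundant] == members[: len(redundant)]

    def test_matches_bruteforce_trace_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for trial in range(60):
            records, table, F, m, tiers = random_ld_instance(rng)
            ids = [r.snp_id for r in records]
            sets = build_tag_sets(table, ids, 0.9, records)
            order = order_tag_sets(sets, records)
            config = SelectionConfig(m=m, redundancy_tiers=tiers)
            selection, _ = select_tsnps(order, F, config, ld=table,
                                        records=records)
            locus = {r.snp_id: (r.chromosome, r.position) for r in records}
            r2_lookup = {frozenset((a, b)): v for a, b, v in table.iter_pairs()
                         if v >= 0.9}
            expected = greedy_trace_oracle(
                {t.focal_snp: t.members for t in sets}, F, m, tiers,
                r2_lookup, locus)
            got = [(e.snp_id, e.category, e.tag_set_id) for e in selection.entries]
            assert got == expected, f"trial {trial} diverged"

    def test_no_double_tagging_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            records, table, F, m, _ = random_ld_instance(rng)
            ids = [r.snp_id for r in records]
            sets = build_tag_sets(table, ids, 0.9, records)
            order = order_tag_sets(sets, records)
            selection, _ = run_select(order, F, m=m)
            by_focal = {t.focal_snp: t.members for t in sets}
            seen = set()
            for e in selection.by_category("tag_strict"):
                members = by_focal[e.snp_id]
                assert not (members & seen)
                seen |= members

    def test_determinism(self):
        rng = np.random.default_rng(99)
        records, table, F, m, tiers = random_ld_instance(rng)
        ids = [r.snp_id for r in records]
        sets = build_tag_sets(table, ids, 0.9, records)

        def run():
            order = order_tag_sets(sets, records)
            sel, _ = select_tsnps(order, F, SelectionConfig(m=m, redundancy_tiers=tiers),
                                  ld=table, records=records)
            return [(e.snp_id, e.category) for e in sel.entries]

        assert run() == run()

    def test_target_count_caps_primary_selections(self):
        rng = np.random.default_rng(5)
        records, table, F, _, _ = random_ld_instance(rng, n_snps=30)
        ids = [r.snp_id for r in records]
        sets = build_tag_sets(table, ids, 0.9, records)
        order = order_tag_sets(sets, records)
        sel, _ = select_tsnps(order, set(ids), SelectionConfig(m=2, target_count=1))
        assert len(sel.by_category("tag_strict")) <= 1


class TestRelaxedRescue:
    def test_rescues_set_whose_members_fail_strict(self):
        members = [f"x{k}" for k in range(11)]
        table = LDTable(["f"] * 11, members, np.full(11, 0.95))
        records = [SNPRecord(snp_id="f", chromosome="chr1", position=50)] + [
            SNPRecord(snp_id=x, chromosome="chr1", position=100 + k)
            for k, x in enumerate(members)]
        sets = build_tag_sets(table, ["f"] + members, 0.9, records)
        order = order_tag_sets(sets, records)
        selection, state = select_tsnps(order, set(), SelectionConfig())
        assert len(selection) == 0
        added = relaxed_rescue(state, {"f"}, selection, SelectionConfig())
        assert [e.snp_id for e in added] == ["f"]
        assert added[0].category == "tag_relaxed"

    def test_set_touched_by_strict_pass_never_rescued(self):
        order, table, records = chain_order()
        selection, state = run_select(order, {"A"}, m=2)
        assert selection.snp_ids == ["A"]
        added = relaxed_rescue(state, {"B", "C"}, selection, SelectionConfig(m=2))
        assert added == []

    def test_no_remaining_sets_no_additions(self):
        order, _, _ = chain_order()
        selection, state = run_select(order, {"A", "B", "C"}, m=2)
        assert relaxed_rescue(state, {"A", "B", "C"}, selection,
                              SelectionConfig(m=2)) == []


class TestGapFill:
    def make_instance(self, span):
        members = ["g0", "g1", "g2", "g3"]
        positions = [100, span // 3, 2 * span // 3, span + 100]
        table = LDTable(["g0"] * 3, members[1:], np.full(3, 0.95))
        records = [SNPRecord(snp_id=s, chromosome="chr1", position=p)
                   for s, p in zip(members, positions)]
        sets = build_tag_sets(table, members, 0.9, records)
        order = order_tag_sets(sets, records)
        return order, records

    def test_wide_small_set_selected(self):
        order, records = self.make_instance(800_000)
        selection, state = select_tsnps(order, set(), SelectionConfig())
        added = gap_fill(state, {"g0", "g1", "g2", "g3"}, selection, records,
                         SelectionConfig(span_min_bp=500_000))
        assert [e.snp_id for e in added] == ["g0"]
        assert added[0].category == "gap_fill"

    def test_narrow_set_not_selected(self):
        order, records = self.make_instance(100_000)
        selection, state = select_tsnps(order, set(), SelectionConfig())
        assert gap_fill(state, {"g0", "g1", "g2", "g3"}, selection, records,
                        SelectionConfig(span_min_bp=500_000)) == []

    def test_singleton_set_never_selected(self):
        records = [SNPRecord(snp_id="solo", chromosome="chr1", position=100)]
        table = LDTable([], [], np.array([]))
        sets = build_tag_sets(table, ["solo"], 0.9, records)
        order = order_tag_sets(sets, records)
        selection, state = select_tsnps(order, set(), SelectionConfig())
        assert gap_fill(state, {"solo"}, selection, records,
                        SelectionConfig(span_min_bp=0)) == []


class TestCoverageFill:
    def make_records(self, mafs, positions, chrom="chr1"):
        return [SNPRecord(snp_id=f"c{i}", chromosome=chrom, position=p, maf=m,
                          call_rate=1.0)
                for i, (m, p) in enumerate(zip(mafs, positions))]

    def test_highest_maf_snp_added_in_empty_window(self):
        records = self.make_records([0.1, 0.4, 0.2], [1_000, 2_000, 3_000])
        selection = DesignSelection()
        added = coverage_fill(records, {r.snp_id for r in records}, selection)
        assert [e.snp_id for e in added] == ["c1"]
        assert added[0].category == "coverage_fill"

    def test_window_with_selected_snp_skipped(self):
        records = self.make_records([0.1, 0.4], [1_000, 2_000])
        selection = DesignSelection()
        selection.add("c0", "tag_strict")
        assert coverage_fill(records, {"c0", "c1"}, selection) == []

    def test_window_without_eligible_snps_skipped(self):
        records = self.make_records([0.1, 0.4], [1_000, 2_000])
        assert coverage_fill(records, set(), DesignSelection()) == []

    def test_separate_windows_filled_independently(self):
        records = self.make_records([0.1, 0.4], [1_000, 15_000_000])
        added = coverage_fill(records, {"c0", "c1"}, DesignSelection(),
                              SelectionConfig(coverage_window_bp=10_000_000))
        assert sorted(e.snp_id for e in added) == ["c0", "c1"]


class TestTaggedAt:
    def test_thresholding_by_hand(self):
        table = LDTable(["A", "A", "A"], ["B", "C", "D"],
                        np.array([0.95, 0.6, 0.4]))
        sel = DesignSelection()
        sel.add("A", "tag_strict")
        assert tagged_at(sel, table, 0.9) == {"A", "B"}
        assert tagged_at(sel, table, 0.5) == {"A", "B", "C"}

    def test_empty_selection(self):
        table = LDTable([], [], np.array([]))
        assert tagged_at(DesignSelection(), table, 0.9) == set()

    def test_nesting(self, sim_design):
        _, _, selection, ld, _ = sim_design
        t9 = tagged_at(selection, ld, 0.9)
        t7 = tagged_at(selection, ld, 0.7)
        t5 = tagged_at(selection, ld, 0.5)
        assert t9 <= t7 <= t5


class TestFst:
    def make_two_group_panel(self, col1, col2):
        """One SNP; col1/col2 are genotype lists for groups g1/g2."""
        calls = np.array(col1 + col2, dtype=np.int8).reshape(-1, 1)
        samples = [f"a{i}" for i in range(len(col1))] + \
                  [f"b{i}" for i in range(len(col2))]
        panel = GenotypeMatrix(samples, ["snp"], calls)
        groups = ([s for s in samples if s.startswith("a")],
                  [s for s in samples if s.startswith("b")])
        return panel, groups

    def test_fixed_difference_theta_one(self):
        panel, groups = self.make_two_group_panel([2] * 20, [0] * 20)
        res = fst_weir_cockerham(panel, groups)
        assert res.theta[0] == pytest.approx(1.0)

    def test_identical_columns_theta_nonpositive(self):
        col = [0, 1, 2, 1, 0, 2, 1, 0, 1, 2]
        panel, groups = self.make_two_group_panel(col, col)
        res = fst_weir_cockerham(panel, groups)
        assert res.theta[0] <= 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            col1 = rng.integers(0, 3, size=20).tolist()
            col2 = rng.integers(0, 3, size=20).tolist()
            panel, groups = self.make_two_group_panel(col1, col2)
            res = fst_weir_cockerham(panel, groups)
            expect = wc_theta_oracle(col1, col2)
            if expect is None:
                assert not np.isfinite(res.theta[0])
            else:
                assert res.theta[0] == pytest.approx(expect, abs=1e-10)

    def test_unbalanced_allele_counts_vs_oracle(self):
        # 15/40 vs 5/40 ALT alleles in 20 diploids each, minimal hets
        col1 = [2] * 7 + [1] + [0] * 12
        col2 = [2] * 2 + [1] + [0] * 17
        panel, groups = self.make_two_group_panel(col1, col2)
        res = fst_weir_cockerham(panel, groups)
        assert res.theta[0] == pytest.approx(wc_theta_oracle(col1, col2),
                                             abs=1e-12)

    def test_three_subgroups_is_error(self):
        panel, _ = self.make_two_group_panel([0, 1], [2, 1])
        spec = SubgroupSpec({s: f"g{i % 3}" for i, s in enumerate(panel.sample_ids)})
        with pytest.raises(ValueError, match="exactly 2"):
            fst_weir_cockerham(panel, spec)

    def test_undercalled_group_gives_nan(self):
        calls = np.array([[0], [-1], [2], [2]], dtype=np.int8)
        panel = GenotypeMatrix(["a0", "a1", "b0", "b1"], ["snp"], calls)
        res = fst_weir_cockerham(panel, (["a0", "a1"], ["b0", "b1"]))
        assert not np.isfinite(res.theta[0])


class TestContentClasses:
    def test_private_class(self):
        maf = pd.DataFrame({"g1": [0.2], "g2": [0.02], "g3": [0.0], "g4": [0.04]},
                           index=["snp"])
        assert classify_content(maf)["snp"] == "content_private"

    def test_neutral_class(self):
        maf = pd.DataFrame({"g1": [0.05], "g2": [0.06], "g3": [0.07], "g4": [0.08]},
                           index=["snp"])
        out = classify_content(maf, overall_maf=pd.Series({"snp": 0.45}))
        assert out["snp"] == "content_neutral"

    def test_differentiating_overrides_everything(self):
        maf = pd.DataFrame({"g1": [0.2], "g2": [0.0]}, index=["snp"])
        out = classify_content(maf, fst_top={"snp"})
        assert out["snp"] == "content_differentiating"

    def test_high_maf_class(self):
        maf = pd.DataFrame({"g1": [0.35], "g2": [0.2]}, index=["snp"])
        assert classify_content(maf)["snp"] == "content_high_maf"

    def test_no_class(self):
        maf = pd.DataFrame({"g1": [0.06], "g2": [0.06]}, index=["snp"])
        out = classify_content(maf, overall_maf=pd.Series({"snp": 0.06}))
        assert out["snp"] is None

    def test_classes_are_exclusive(self):
        rng = np.random.default_rng(3)
        maf = pd.DataFrame(rng.uniform(0, 0.5, size=(50, 4)),
                           columns=list("abcd"),
                           index=[f"s{i}" for i in range(50)])
        out = classify_content(maf, fst_top={"s0", "s1"})
        assert out.map(lambda v: v is None or isinstance(v, str)).all()

    def test_fst_top_fraction_ties_toward_inclusion(self):
        theta = np.array([0.1] * 98 + [0.9, 0.9])
        res = design.FstResult([f"s{i}" for i in range(100)], theta, (10, 10))
        top = res.top_fraction(2.0)
        assert top == {"s98", "s99"}


class TestDGenomeRule:
    @pytest.mark.parametrize("a,b,expect", [
        (0.25, 0.05, True),
        (0.25, 0.2, False),
        (0.05, 0.05, False),
        (0.1, 0.05, False),   # strict > on the derived side
    ])
    def test_rule(self, a, b, expect):
        got = select_dgenome_content({"snp": a}, {"snp": b})
        assert ("snp" in got) is expect


def test_sample_size_compensation_at_design_threshold():
    assert sample_size_compensation(0.9) == pytest.approx(100 * (1 / 0.9 - 1))
    assert round(sample_size_compensation(0.9)) == 11


def test_subgroup_mafs_shape(sim_panel):
    panel, _, _ = sim_panel
    half = panel.n_samples // 2
    spec = SubgroupSpec({s: ("g1" if i < half else "g2")
                         for i, s in enumerate(panel.sample_ids)})
    table = subgroup_mafs(panel, spec)
    assert table.shape == (panel.n_snps, 2)
    assert ((table >= 0) & (table <= 0.5)).all().all()
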