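"""Per-ancestor and micro/macro-averaged impact metrics against brute force."""

import math

import pytest

from hierimpact import (
    DefectRelation,
    batch_assess,
    build_index,
    per_query_precision,
    per_query_recall,
    precision_impact,
    recall_impact,
)
from hierimpact.errors import PreconditionError
from hierimpact.impact import is_na, results_to_frame

from _oracles import brute_impact
from conftest import make_graph


class TestPerQueryRatios:
    def test_published_recall_example(self):
        # 47 552 patients retrieved vs 660 907 expected once the relation is added
        assert round(per_query_recall(47_552, 660_907), 4) == 0.0719

    def test_published_precision_example(self):
        # 153 319 of 192 904 retrieved patients remain once the bad edge is gone
        assert round(per_query_precision(153_319, 192_904), 4) == 0.7948

    def test_zero_denominator_is_na(self):
        assert is_na(per_query_recall(0, 0))
        assert is_na(per_query_precision(0, 0))


class TestRecallImpact:
    def test_empty_subconcept_cohort_gives_all_ones(self):
        g = make_graph([("c2", "top")], extra_concepts=["c1"])
        idx = build_index([("P1", "c2"), ("P2", "top")])
        r = recall_impact(idx, g, DefectRelation("c1", "c2", "missing"))
        assert r.micro == 1.0 and r.macro == 1.0
        assert all(row.metric == 1.0 for row in r.rows)

    def test_all_empty_cohorts_give_na(self):
        g = make_graph([("c2", "top")], extra_concepts=["c1"])
        r = recall_impact(build_index([]), g, DefectRelation("c1", "c2", "missing"))
        assert is_na(r.micro) and is_na(r.macro)
        assert all(is_na(row.metric) for row in r.rows)

    def test_existing_path_violates_precondition(self, chain):
        idx = build_index([])
        with pytest.raises(PreconditionError, match="has_path"):
            recall_impact(idx, chain, DefectRelation("a", "c", "missing"))

    def test_simple_two_level_example(self):
        # c1's patients {P1,P2} missing from c2's cohort {P2,P3}:
        # recall at c2 = |{P2,P3}| / |{P1,P2,P3}| = 2/3
        g = make_graph([("x", "c2")], extra_concepts=["c1"])
        idx = build_index([("P1", "c1"), ("P2", "c1"), ("P2", "x"), ("P3", "c2")])
        r = recall_impact(idx, g, DefectRelation("c1", "c2", "missing"))
        assert r.n_ancestors == 1 and r.n_c1 == 2
        assert r.micro == pytest.approx(2 / 3) and r.macro == pytest.approx(2 / 3)

    def test_union_bound_on_per_ancestor_recall(self, synth_world):
        _, _, g_def, defects, _, idx, _ = synth_world
        for d in defects:
            if d.defect_type != "missing":
                continue
            r = recall_impact(idx, g_def, d)
            for row in r.rows:
                if is_na(row.metric):
                    continue
                assert row.metric >= row.n_p / (row.n_p + r.n_c1) - 1e-12

    def test_metrics_match_brute_force(self, synth_world):
        _, _, g_def, defects, _, idx, pairs = synth_world
        edges = [(e.child, e.parent) for e in g_def.edges()]
        concepts = set(g_def.concept_ids)
        for d in defects:
            if d.defect_type != "missing":
                continue
            r = recall_impact(idx, g_def, d)
            micro, macro = brute_impact(
                edges, concepts, pairs, d.subconcept, d.superconcept, "missing"
            )
            assert r.micro == pytest.approx(micro, abs=1e-12)
            assert r.macro == pytest.approx(macro, abs=1e-12)


class TestPrecisionImpact:
    def test_missing_direct_edge_violates_precondition(self, chain):
        with pytest.raises(PreconditionError, match="direct edge"):
            precision_impact(build_index([]), chain, DefectRelation("a", "c", "inaccurate"))

    def test_empty_subconcept_cohort_gives_ones(self, chain):
        # nothing is diagnosed under the subconcept, so nothing is subtracted
        idx = build_index([("P1", "b")])
        r = precision_impact(idx, chain, DefectRelation("a", "b", "inaccurate"))
        assert r.n_c1 == 0
        assert r.micro == 1.0 and r.macro == 1.0
        assert all(row.metric == 1.0 for row in r.rows)

    def test_all_empty_gives_na(self, chain):
        r = precision_impact(build_index([]), chain, DefectRelation("a", "b", "inaccurate"))
        assert is_na(r.micro) and is_na(r.macro)

    def test_full_subtraction_even_with_alternate_paths(self):
        # P1 reaches top both through the inaccurate edge and a legitimate one,
        # yet is still subtracted — the formula subtracts all of N_c1
        g = make_graph([("c1", "c2"), ("c1", "alt"), ("alt", "c2")])
        idx = build_index([("P1", "c1"), ("P2", "c2")])
        r = precision_impact(idx, g, DefectRelation("c1", "c2", "inaccurate"))
        row_c2 = next(row for row in r.rows if row.ancestor == "c2")
        assert row_c2.n_reference == 1 and row_c2.metric == pytest.approx(0.5)

    def test_metrics_match_brute_force(self, synth_world):
        _, _, g_def, defects, _, idx, pairs = synth_world
        edges = [(e.child, e.parent) for e in g_def.edges()]
        concepts = set(g_def.concept_ids)
        for d in defects:
            if d.defect_type != "inaccurate":
                continue
            r = precision_impact(idx, g_def, d)
            micro, macro = brute_impact(
                edges, concepts, pairs, d.subconcept, d.superconcept, "inaccurate"
            )
            assert r.micro == pytest.approx(micro, abs=1e-12)
            assert r.macro == pytest.approx(macro, abs=1e-12)


class TestAggregationProperties:
    def test_micro_equals_macro_for_single_ancestor(self):
        g = make_graph([("x", "c2")], extra_concepts=["c1"])
        idx = build_index([("P1", "c1"), ("P2", "x")])
        r = recall_impact(idx, g, DefectRelation("c1", "c2", "missing"))
        assert r.n_ancestors == 1 and r.micro == r.macro

    def test_shrinking_subconcept_cohort_never_lowers_metrics(self, synth_world):
        _, _, g_def, defects, _, idx, pairs = synth_world
        d = next(x for x in defects if x.defect_type == "missing")
        full = recall_impact(idx, g_def, d)
        # drop the patients directly diagnosed under c1
        sub = g_def.descendants_inclusive(d.subconcept)
        reduced_pairs = [(p, c) for p, c in pairs if c not in sub]
        idx2 = build_index(reduced_pairs)
        shrunk = recall_impact(idx2, g_def, d)
        if not is_na(full.micro) and not is_na(shrunk.micro):
            assert shrunk.micro >= full.micro - 1e-12
            assert shrunk.macro >= full.macro - 1e-12

    def test_superconcept_closure_unchanged_by_the_defect_edge(self, synth_world):
        # c2's ancestor set is the same whether or not the edge c1 -> c2 exists:
        # adding the edge changes c1's ancestors, never c2's (a change would
        # require c2 to reach c1, i.e. a cycle)
        _, _, g_def, defects, _, _, _ = synth_world
        for d in defects:
            if d.defect_type != "missing":
                continue
            with_edge = g_def.add_edge(d.subconcept, d.superconcept)
            assert with_edge.ancestors_inclusive(d.superconcept) == g_def.ancestors_inclusive(
                d.superconcept
            )

    def test_all_metrics_in_unit_interval_or_na(self, synth_world):
        _, _, g_def, defects, _, idx, _ = synth_world
        for r in batch_assess(idx, g_def, defects):
            assert r.ok
            for v in (r.micro, r.macro, *(row.metric for row in r.rows)):
                assert is_na(v) or 0.0 <= v <= 1.0


class TestBatchAssess:
    def test_empty_list(self, synth_world):
        _, _, g_def, _, _, idx, _ = synth_world
        assert batch_assess(idx, g_def, []) == []

    def test_precondition_failure_captured_not_raised(self, chain):
        idx = build_index([("P1", "a")])
        defects = [
            DefectRelation("a", "c", "missing"),  # path exists -> violation
            DefectRelation("a", "b", "inaccurate"),  # fine
        ]
        results = batch_assess(idx, chain, defects)
        assert len(results) == 2
        assert not results[0].ok and "has_path" in results[0].error
        assert results[1].ok

    def test_batch_equals_single_calls(self, synth_world):
        _, _, g_def, defects, _, idx, _ = synth_world
        batch = batch_assess(idx, g_def, defects)
        for d, r in zip(defects, batch):
            single = (
                recall_impact(idx, g_def, d)
                if d.defect_type == "missing"
                else precision_impact(idx, g_def, d)
            )
            assert r.defect == d
            assert (is_na(r.micro) and is_na(single.micro)) or r.micro == single.micro
            assert (is_na(r.macro) and is_na(single.macro)) or r.macro == single.macro


class TestSerialization:
    def test_frame_rounds_to_4_decimals_and_writes_na(self, tmp_path, synth_world):
        _, _, g_def, defects, _, idx, _ = synth_world
        results = batch_assess(idx, g_def, defects)
        df = results_to_frame(results, g_def)
        assert len(df) == len(defects)
        defined = df["micro"].dropna()
        assert all(abs(v * 10_000 - round(v * 10_000)) < 1e-9 for v in defined)
        out = tmp_path / "metrics.csv"
        from hierimpact.impact import write_metrics_csv

        write_metrics_csv(results, out, g_def)
        text = out.read_text()
        assert "subconcept_id" in text
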