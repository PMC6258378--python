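import pytest

from svjunction.core import (
    BreakpointSide,
    CopyNumberSegment,
    DerivativeStructure,
    JunctionRecord,
    SegmentUse,
    DUPLICATE_COPY,
    RETAINED,
)
from svjunction.descriptors import descriptor_span, structure_to_pattern
from svjunction.reconstruct import (
    GraphError,
    InfeasibleWalkError,
    build_fragment_graph,
    classify_duplications,
    enumerate_structures,
    has_nested_deletion,
    junction_equivalence,
    normalize_structure,
    structure_cn,
    structure_implied_junctions,
    structure_to_bed,
)
from svjunction.simulate import BLUNT, PlantSpec, plant_rearrangement, random_reference


def graph_for_case(bundle, case, pad=5000):
    from svjunction.descriptors import descriptor_to_structure
    row = bundle.case_row(case)
    ops = bundle.descriptor_ops(case)
    lo, hi = descriptor_span(ops)
    span = (max(1, lo - pad), hi + pad)
    structure = descriptor_to_structure(ops, span, contig=row.chromosome)
    junctions = structure_implied_junctions(structure, case)
    cn = structure_cn(structure, span)
    return build_fragment_graph(junctions, cn, span), structure, span


class TestBuildGraph:
    def test_single_deletion_two_interior_nodes(self):
        j = JunctionRecord("x", 1, BreakpointSide("c", 100, "+"),
                           BreakpointSide("c", 201, "+"))
        cn = [CopyNumberSegment("c", 101, 200, 1)]
        g = build_fragment_graph([j], cn, (1, 300))
        assert len(g.nodes) == 3
        assert [n.count for n in g.nodes] == [1, 0, 1]
        assert len(g.edges) == 1

    def test_p2109_123_graph(self, bundle, case_structures):
        g, structure, span = graph_for_case(bundle, "P2109_123")
        assert len(g.edges) == 2
        non_diploid = [n for n in g.nodes if n.count != 1]
        assert len(non_diploid) == 2  # the two deleted fragments

    def test_out_of_span_coordinates_error(self):
        j = JunctionRecord("x", 1, BreakpointSide("c", 100, "+"),
                           BreakpointSide("c", 900, "+"))
        with pytest.raises(GraphError):
            build_fragment_graph([j], [], (1, 500))

    def test_half_edges_retained(self):
        j = JunctionRecord("x", 1, BreakpointSide("c", 100, "+"), None)
        g = build_fragment_graph([j], [], (1, 300))
        assert len(g.half_edges) == 1 and not g.edges
        assert "half" in g.to_tsv()
        assert "dashed" in g.to_dot()

    def test_simulator_plant_graph_matches_truth(self):
        genome = random_reference(9000, 0.45, seed=70)
        spec = PlantSpec("sim1",
                         [(1, 2000, "+"), (4000, 5000, "-"), (7000, 9000, "+")],
                         [BLUNT, BLUNT], seed=70)
        truth = plant_rearrangement(genome, spec)
        span = (1, 9000)
        graph = build_fragment_graph(truth.junctions, truth.cn, span)
        structures = enumerate_structures(graph)
        assert normalize_structure(truth.structure) in {
            normalize_structure(s) for s in structures}


class TestEnumerate:
    def test_p2109_123_unique_structure(self, bundle, case_structures):
        g, structure, span = graph_for_case(bundle, "P2109_123")
        structures = enumerate_structures(g)
        assert len(structures) == 1
        assert str(structure_to_pattern(structures[0], span=span)) == "DEL-INV-DEL"

    def test_p5513_206_multiple_structures_contain_descriptor(self, bundle,
                                                              case_structures):
        g, structure, span = graph_for_case(bundle, "P5513_206")
        structures = enumerate_structures(g)
        assert len(structures) >= 3
        forms = {normalize_structure(s) for s in structures}
        assert normalize_structure(structure) in forms
        patterns = {str(structure_to_pattern(s, span=span)) for s in structures}
        assert "DUPinv-N-DUP-N-DUP-N-DUPinv-N-DUP" in patterns

    def test_no_junction_graph_gives_reference(self):
        g = build_fragment_graph([], [], (1, 500), contig="c")
        structures = enumerate_structures(g)
        assert len(structures) == 1
        assert normalize_structure(structures[0]) == (("c", 1, 500, "+"),) or \
            len(structures[0].segments) == 1

    def test_infeasible_graph_reports(self):
        j = JunctionRecord("x", 1, BreakpointSide("c", 100, "+"),
                           BreakpointSide("c", 201, "+"))
        cn = [CopyNumberSegment("c", 1, 100, 1), CopyNumberSegment("c", 101, 500, 1)]
        # left terminus has one copy but the junction forces re-entry
        j2 = JunctionRecord("x", 2, BreakpointSide("c", 300, "+"),
                            BreakpointSide("c", 50, "+"))
        with pytest.raises(InfeasibleWalkError):
            enumerate_structures(build_fragment_graph([j, j2], cn, (1, 500)))


class TestClassifyDuplications:
    def test_definition_tandem(self):
        st = DerivativeStructure("d", [
            SegmentUse("c", 1, 100, "+", RETAINED),
            SegmentUse("c", 50, 100, "+", RETAINED),
            SegmentUse("c", 50, 100, "+", DUPLICATE_COPY),
            SegmentUse("c", 101, 200, "+", RETAINED),
        ])
        calls = classify_duplications(st)
        assert len(calls) == 1
        assert calls[0].architecture == "tandem" and calls[0].orientation == "+"

    def test_p4855_512_one_tandem_one_interspersed_inverted(self, bundle,
                                                            case_structures):
        st, _ = case_structures["P4855_512"]
        calls = classify_duplications(st)
        assert len(calls) == 2
        by_arch = {c.architecture: c for c in calls}
        assert by_arch["tandem"].orientation == "+"
        assert by_arch["interspersed"].orientation == "-"

    def test_cohort_totals_3_tandem_33_interspersed(self, bundle, case_structures):
        calls = [c for case in bundle.cases
                 for c in classify_duplications(case_structures[case][0])]
        assert len(calls) == 36
        assert sum(1 for c in calls if c.architecture == "tandem") == 3
        assert sum(1 for c in calls if c.architecture == "interspersed") == 33

    def test_no_duplicates_empty(self, case_structures):
        st, _ = case_structures["P2109_190"]
        assert classify_duplications(st) == []

    def test_translation_and_renaming_invariance(self, case_structures):
        st, _ = case_structures["P4855_512"]
        moved = st.translate(12345)
        calls_a = classify_duplications(st)
        calls_b = classify_duplications(moved)
        assert [(c.architecture, c.orientation) for c in calls_a] == \
            [(c.architecture, c.orientation) for c in calls_b]
        assert [c.start + 12345 for c in calls_a] == [c.start for c in calls_b]


class TestNestedDeletion:
    def test_four_dup_n_dup_cases(self, case_structures):
        for case in ("P06", "P4855_511", "P74", "P2109_150"):
            assert has_nested_deletion(case_structures[case][0]), case

    def test_del_inv_del_cases_negative(self, case_structures):
        for case in ("P2109_190", "P2109_123", "P2109_302", "P72"):
            assert not has_nested_deletion(case_structures[case][0]), case


class TestJunctionEquivalence:
    def fixture_record(self, bundle, case, jid):
        row = next(r for r in bundle.junctions_for(case) if r.junction == jid)
        return JunctionRecord(case, jid,
                              BreakpointSide(row.chromosome, row.side1, "+"),
                              BreakpointSide(row.chromosome, row.side2, "+"),
                              microhomology_len=row.mh,
                              insertion_len=row.ins)

    def test_shared_2p_junction_identical(self, bundle):
        a = self.fixture_record(bundle, "P4855_511", 2)
        b = self.fixture_record(bundle, "P06", 2)
        assert junction_equivalence(a, b) == "identical"

    def test_opposite_orientation_distinct(self):
        a = JunctionRecord("x", 1, BreakpointSide("c", 100, "+"),
                           BreakpointSide("c", 200, "+"))
        b = JunctionRecord("y", 1, BreakpointSide("c", 100, "+"),
                           BreakpointSide("c", 200, "-"))
        assert junction_equivalence(a, b) == "distinct"

    def test_within_tolerance_compatible(self):
        a = JunctionRecord("x", 1, BreakpointSide("c", 100, "+"),
                           BreakpointSide("c", 200, "+"))
        b = JunctionRecord("y", 1, BreakpointSide("c", 103, "+"),
                           BreakpointSide("c", 197, "+"))
        assert junction_equivalence(a, b, tolerance=5) == "compatible"
        assert junction_equivalence(a, b, tolerance=2) == "distinct"


class TestExports:
    def test_bed_export(self, case_structures):
        st, _ = case_structures["P2109_123"]
        bed = structure_to_bed(st)
        lines = bed.splitlines()
        assert len(lines) == len(st.segments)
        assert all(len(line.split("\t")) == 6 for line in lines)
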