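import numpy as np
import pytest

from svjunction.core import BreakpointSide, GenomeModel, reverse_complement
from svjunction.characterize import (
    ConfigurationError,
    GenomeIndex,
    MultiJunctionError,
    SplitReadGroup,
    annotate_repeats,
    build_consensus,
    collect_split_reads,
    compute_microhomology,
    decompose_insertion,
    find_novel_snvs,
    resolve_junction,
)
from svjunction.simulate import (
    BLUNT,
    BlockSpec,
    Chemistry,
    LibraryConfig,
    PlantSpec,
    generate_reads,
    plant_rearrangement,
    random_reference,
    single_deletion_plan,
)


def characterize_first(truth, lib_seed=1, coverage=30, error_rate=0.0, **kwargs):
    _, sam = generate_reads(truth, LibraryConfig(seed=lib_seed, coverage=coverage,
                                                 error_rate=error_rate))
    groups = collect_split_reads(sam, **kwargs)
    assert groups, "no split-read group found"
    consensus = build_consensus(groups[0])
    return resolve_junction(consensus, truth.genome, support=groups[0].support), groups


class TestCollectSplitReads:
    def test_single_deletion_one_group(self):
        g = random_reference(6000, 0.45, seed=20)
        truth = plant_rearrangement(g, single_deletion_plan(6000, seed=20))
        _, sam = generate_reads(truth, LibraryConfig(seed=21, coverage=30))
        groups = collect_split_reads(sam)
        assert len(groups) == 1
        assert groups[0].support >= 5

    def test_no_split_reads_empty(self):
        g = random_reference(6000, 0.45, seed=22)
        spec = PlantSpec("sim1", [(1, 6000, "+")], [], seed=22)
        truth = plant_rearrangement(g, spec)
        _, sam = generate_reads(truth, LibraryConfig(seed=23, coverage=10))
        assert collect_split_reads(sam) == []

    def test_two_close_junctions_distinct_groups(self):
        # junctions 150 bp apart on the derivative; clustering tolerance 50
        g = random_reference(9000, 0.45, seed=24)
        spec = PlantSpec("sim1",
                         [(1, 2000, "+"), (3000, 3149, "+"), (5000, 9000, "+")],
                         [BLUNT, BLUNT], seed=24)
        truth = plant_rearrangement(g, spec)
        _, sam = generate_reads(truth, LibraryConfig(seed=25, coverage=40))
        groups = collect_split_reads(sam, tol=50)
        assert len(groups) == 2

    def test_candidate_filter(self):
        g = random_reference(6000, 0.45, seed=26)
        truth = plant_rearrangement(g, single_deletion_plan(6000, seed=26))
        _, sam = generate_reads(truth, LibraryConfig(seed=27, coverage=30))
        near = collect_split_reads(sam, candidates=[("sim1", 1900, 2100)])
        far = collect_split_reads(sam, candidates=[("sim1", 5500, 5600)],
                                  candidate_pad=100)
        assert len(near) == 1 and far == []

    def test_records_without_sequence_skipped(self):
        g = random_reference(6000, 0.45, seed=28)
        truth = plant_rearrangement(g, single_deletion_plan(6000, seed=28))
        _, sam = generate_reads(truth, LibraryConfig(seed=29, coverage=30))
        for rec in sam:
            rec.seq = "*"
        assert collect_split_reads(sam) == []
        assert collect_split_reads.last_skipped > 0


class TestConsensus:
    def test_identical_reads(self):
        read = "ACGTACGTACGTACGTACGTACGTA"
        group = SplitReadGroup(BreakpointSide("c", 1, "+"),
                               BreakpointSide("c", 2, "+"), [read] * 10)
        cons = build_consensus(group)
        assert cons.sequence == read
        assert cons.contributing == 10
        assert not cons.low_confidence

    def test_single_read(self):
        read = "ACGTACGTACGTACGTACGTACGTA"
        group = SplitReadGroup(BreakpointSide("c", 1, "+"),
                               BreakpointSide("c", 2, "+"), [read])
        cons = build_consensus(group)
        assert cons.sequence == read and cons.contributing == 1

    def test_tiled_reads_with_errors_recover_window(self):
        rng = np.random.default_rng(1)
        window = "".join(rng.choice(list("ACGT"), size=300))
        reads = []
        for start in range(0, 150, 10):
            chunk = list(window[start : start + 150])
            if rng.random() < 0.5:  # ~0.1% error scale on a few reads
                pos = int(rng.integers(len(chunk)))
                chunk[pos] = "ACGT"[(("ACGT").index(chunk[pos]) + 1) % 4]
            reads.append("".join(chunk))
        reads = reads * 2  # coverage so that majority voting wins
        group = SplitReadGroup(BreakpointSide("c", 1, "+"),
                               BreakpointSide("c", 2, "+"), reads)
        cons = build_consensus(group)
        assert cons.sequence in window

    def test_irreconcilable_reads_low_confidence(self):
        a = "A" * 30 + "CGTGACTGAC" * 2
        b = "TTGCAATTGCAATTGCAA" * 2
        group = SplitReadGroup(BreakpointSide("c", 1, "+"),
                               BreakpointSide("c", 2, "+"), [a, a, b])
        cons = build_consensus(group)
        assert cons.low_confidence
        assert cons.contributing >= 1

    def test_support_length_matches(self):
        group = SplitReadGroup(BreakpointSide("c", 1, "+"),
                               BreakpointSide("c", 2, "+"),
                               ["ACGTACGTACGTACGTACGTACGTA"] * 3)
        cons = build_consensus(group)
        assert len(cons.support) == len(cons.sequence)


class TestResolve:
    def test_blunt_deletion_exact(self):
        g = random_reference(6000, 0.45, seed=30)
        truth = plant_rearrangement(g, single_deletion_plan(6000, seed=30))
        rec, _ = characterize_first(truth)
        t = truth.junctions[0]
        assert (rec.side1, rec.side2) == (t.side1, t.side2)
        assert rec.microhomology_len == 0 and rec.insertion_len == 0

    def test_seven_bp_homology_left_aligned(self):
        g = random_reference(6000, 0.45, seed=31)
        truth = plant_rearrangement(
            g, single_deletion_plan(6000, chemistry=Chemistry("microhomology", mh=7),
                                    seed=31))
        rec, _ = characterize_first(truth)
        t = truth.junctions[0]
        assert rec.microhomology_len == 7
        assert (rec.side1, rec.side2) == (t.side1, t.side2)
        assert rec.microhomology_seq == t.microhomology_seq

    def test_inversion_side_orientation(self):
        g = random_reference(8000, 0.45, seed=32)
        spec = PlantSpec("sim1", [(1, 2500, "+"), (4000, 6000, "-")],
                         [BLUNT], seed=32)
        truth = plant_rearrangement(g, spec)
        rec, _ = characterize_first(truth)
        assert rec.side2.orientation == "-"
        assert (rec.side1, rec.side2) == (truth.junctions[0].side1,
                                          truth.junctions[0].side2)

    def test_unresolved_when_one_anchor(self):
        g = random_reference(3000, 0.5, seed=33)
        seq = g.contigs["sim1"][100:300]
        from svjunction.characterize import ConsensusSequence
        cons = ConsensusSequence(seq, [5] * len(seq), 5)
        rec = resolve_junction(cons, g)
        assert rec.side1 is None and rec.microhomology_len is None

    def test_multi_junction_error(self):
        g = random_reference(9000, 0.5, seed=34)
        ref = g.contigs["sim1"]
        # three long segments stitched together -> two junctions in one window
        seq = ref[1000:1100] + ref[4000:4080] + ref[7000:7100]
        from svjunction.characterize import ConsensusSequence
        cons = ConsensusSequence(seq, [5] * len(seq), 5)
        with pytest.raises(MultiJunctionError):
            resolve_junction(cons, g)


def _shift_side(side, j, role):
    sign = (1 if side.orientation == "+" else -1)
    if role == "right":
        return BreakpointSide(side.contig, side.position + sign * j, side.orientation)
    return BreakpointSide(side.contig, side.position + sign * j, side.orientation)


def oracle_microhomology(genome, side1, side2, max_k=60, window=80):
    """Brute force: count breakpoint shifts that leave the junction sequence
    unchanged (pure string comparison, independent of compute_microhomology)."""
    seq = genome.contigs[side1.contig]

    def left_flank(side, k):
        if side.orientation == "+":
            lo = side.position - k
            if lo < 0:
                return None
            return seq[lo : side.position]
        hi = side.position - 1 + k
        if hi > len(seq):
            return None
        return reverse_complement(seq[side.position - 1 : hi])

    def right_flank(side, k):
        if side.orientation == "+":
            hi = side.position - 1 + k
            if hi > len(seq):
                return None
            return seq[side.position - 1 : hi]
        lo = side.position - k
        if lo < 0:
            return None
        return reverse_complement(seq[lo : side.position])

    def window_at(j):
        # flank lengths complement each other so every placement spells the
        # same fixed stretch of the derivative
        lf = left_flank(_shift_side(side1, j, "left"), window + max_k + j)
        rf = right_flank(_shift_side(side2, j, "right"), window + max_k - j)
        if lf is None or rf is None:
            return None
        return lf + rf

    base = window_at(0)
    assert base is not None
    count = 0
    for j in range(-max_k, max_k + 1):
        if j == 0:
            continue
        if window_at(j) == base:
            count += 1
    return count


class TestMicrohomology:
    def test_no_shared_sequence_zero(self):
        g = GenomeModel({"c": "A" * 50 + "C" * 50 + "G" * 50 + "T" * 50})
        mh, seq, *_ = compute_microhomology(g, BreakpointSide("c", 50, "+"),
                                            BreakpointSide("c", 101, "+"))
        assert (mh, seq) == (0, "")

    def test_engineered_tgc(self):
        # side1's reference continuation and side2's retained flank share
        # exactly TGC, so the breakpoint slides across a 3-bp tract
        left = "CATCATCATCATCATCATCA"
        g = GenomeModel({"c": left + "TGCA" + "G" * 10 + "TGC"
                              + "GAAGAAGAAGAAGAAGAAGA"})
        side1 = BreakpointSide("c", len(left), "+")
        side2 = BreakpointSide("c", len(left) + 4 + 10 + 1, "+")
        mh, seq, canon1, canon2 = compute_microhomology(g, side1, side2)
        assert (mh, seq) == (3, "TGC")
        assert (canon1, canon2) == (side1, side2)  # already left-aligned

    def test_matches_bruteforce_oracle_on_random_junctions(self):
        rng = np.random.default_rng(99)
        g = random_reference(4000, 0.45, seed=99)
        for _ in range(300):
            p1 = int(rng.integers(200, 1800))
            p2 = int(rng.integers(2200, 3800))
            o1, o2 = rng.choice(["+", "-"], size=2)
            side1 = BreakpointSide("sim1", p1, o1)
            side2 = BreakpointSide("sim1", p2, o2)
            mh, _, _, _ = compute_microhomology(g, side1, side2)
            assert mh == oracle_microhomology(g, side1, side2)

    def test_left_alignment_shift_invariance(self):
        # shifting a planted breakpoint within its homology tract yields the
        # identical canonical placement
        g = random_reference(6000, 0.45, seed=35)
        truth = plant_rearrangement(
            g, single_deletion_plan(6000, chemistry=Chemistry("microhomology", mh=9),
                                    seed=35))
        t = truth.junctions[0]
        canon = compute_microhomology(truth.genome, t.side1, t.side2)
        for j in range(1, 10):
            s1 = _shift_side(t.side1, j, "left")
            s2 = _shift_side(t.side2, j, "right")
            assert compute_microhomology(truth.genome, s1, s2) == canon

    def test_n_bases_never_match(self):
        g = GenomeModel({"c": "ACGTACGTAC" + "N" * 10 + "ACGTACGTAC" * 3})
        side1 = BreakpointSide("c", 10, "+")
        side2 = BreakpointSide("c", 21, "+")
        mh, *_ = compute_microhomology(g, side1, side2)
        assert mh == 0


class TestDecomposeInsertion:
    genome = random_reference(2000, 0.45, seed=40)
    side1 = BreakpointSide("sim1", 600, "+")
    side2 = BreakpointSide("sim1", 1400, "+")

    def test_empty_insert(self):
        assert decompose_insertion(self.genome, "", self.side1, self.side2) == []

    def test_p2109_188_architecture(self):
        g = random_reference(8000, 0.41, seed=41)
        chem = Chemistry("insertion", blocks=(
            BlockSpec("non_templated", 14),
            BlockSpec("templated", 26, strand="-", side=2, offset=30),
            BlockSpec("non_templated", 12)))
        truth = plant_rearrangement(g, single_deletion_plan(8000, chemistry=chem,
                                                            seed=41))
        t = truth.junctions[0]
        insert = "".join(b.sequence for b in t.insertion_blocks)
        blocks = decompose_insertion(truth.genome, insert, t.side1, t.side2)
        assert [(b.kind, len(b.sequence)) for b in blocks] == [
            ("non_templated", 14), ("templated", 26), ("non_templated", 12)]
        assert blocks[1].source_strand == "-"
        assert blocks[1].check_source(truth.genome)

    def test_random_20mer_single_nontemplated_block(self):
        rng = np.random.default_rng(42)
        windows = []
        seq = self.genome.contigs["sim1"]
        for side in (self.side1, self.side2):
            w = seq[side.position - 101 : side.position + 100]
            windows.extend([w, reverse_complement(w)])

        def in_windows(s):  # exhaustive oracle scan
            return any(s[i : i + 10] in w for w in windows
                       for i in range(len(s) - 9))

        while True:
            insert = "".join(rng.choice(list("ACGT"), size=20))
            if not in_windows(insert):
                break
        blocks = decompose_insertion(self.genome, insert, self.side1, self.side2)
        assert [(b.kind, len(b.sequence)) for b in blocks] == [("non_templated", 20)]

    def test_window_config_error(self):
        with pytest.raises(ConfigurationError):
            decompose_insertion(self.genome, "ACGT", self.side1, self.side2,
                                window=5, min_templated=10)


class TestAnnotateRepeats:
    def make_junction(self, pos1, pos2):
        from svjunction.core import JunctionRecord
        return JunctionRecord("x", 1, BreakpointSide("c", pos1, "+"),
                              BreakpointSide("c", pos2, "+"),
                              microhomology_len=0, microhomology_seq="",
                              insertion_len=0, insertion_blocks=[])

    def test_alu_pair(self):
        track = {"c": [(90, 120, "AluSx"), (480, 520, "AluSx1")]}
        rec = annotate_repeats(self.make_junction(100, 500), track)
        assert (rec.repeat1, rec.repeat2) == ("AluSx", "AluSx1")
        from svjunction.mechanisms import same_repeat_family
        assert same_repeat_family(rec.repeat1, rec.repeat2)

    def test_empty_track(self):
        rec = annotate_repeats(self.make_junction(100, 500), {})
        assert rec.repeat1 is None and rec.repeat2 is None

    def test_boundary_containment_inclusive(self):
        track = {"c": [(100, 200, "L1MA7")]}
        for pos, expected in ((99, None), (100, "L1MA7"), (200, "L1MA7"), (201, None)):
            rec = annotate_repeats(self.make_junction(pos, 500), track)
            assert rec.repeat1 == expected, pos


class TestNovelSnvs:
    def plant_with_snv(self, seed=50):
        g = random_reference(6000, 0.5, seed=seed)
        base_spec = single_deletion_plan(6000, seed=seed)
        pos = 1800  # 200 bp left of the junction at 2000
        ref_base = g.contigs["sim1"][pos - 1]
        alt = "A" if ref_base != "A" else "G"
        spec = PlantSpec(base_spec.contig, base_spec.segments,
                         base_spec.chemistries, snvs=[(pos, alt)], seed=seed)
        truth = plant_rearrangement(g, spec)
        _, sam = generate_reads(truth, LibraryConfig(seed=seed + 1, coverage=30))
        return truth, sam, pos, ref_base, alt

    def test_planted_snv_reported_novel(self):
        truth, sam, pos, ref_base, alt = self.plant_with_snv()
        out = find_novel_snvs(sam, truth.genome, truth.junctions, freq_table={})
        hits = [s for s in out if s.position == pos]
        assert len(hits) == 1
        s = hits[0]
        assert (s.ref, s.alt, s.novel) == (ref_base, alt, True)
        assert s.distance == 200

    def test_known_snv_filtered(self):
        truth, sam, pos, ref_base, alt = self.plant_with_snv()
        table = {("sim1", pos, ref_base, alt): 0.01}
        out = find_novel_snvs(sam, truth.genome, truth.junctions, freq_table=table)
        hits = [s for s in out if s.position == pos]
        assert hits and hits[0].novel is False

    def test_missing_table_flags_unfiltered(self):
        truth, sam, pos, *_ = self.plant_with_snv()
        out = find_novel_snvs(sam, truth.genome, truth.junctions, freq_table=None)
        hits = [s for s in out if s.position == pos]
        assert hits and hits[0].unfiltered and hits[0].novel is None

    def test_no_mismatches_empty(self):
        g = random_reference(6000, 0.5, seed=52)
        truth = plant_rearrangement(g, single_deletion_plan(6000, seed=52))
        _, sam = generate_reads(truth, LibraryConfig(seed=53, coverage=20))
        assert find_novel_snvs(sam, truth.genome, truth.junctions, freq_table={}) == []


class TestInvariants:
    def test_mh_and_insertion_exclusive_on_emitted_records(self):
        for seed in range(5):
            g = random_reference(6000, 0.45, seed=60 + seed)
            chem = (Chemistry("microhomology", mh=4) if seed % 2
                    else Chemistry("insertion",
                                   blocks=(BlockSpec("non_templated", 9),)))
            truth = plant_rearrangement(g, single_deletion_plan(6000, chemistry=chem,
                                                                seed=60 + seed))
            rec, _ = characterize_first(truth, lib_seed=seed)
            assert not ((rec.microhomology_len or 0) > 0
                        and (rec.insertion_len or 0) > 0)
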