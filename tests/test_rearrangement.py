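"""Derivative-path assembly, inversion classification and their inverses."""

import pytest

from junctura import (
    Breakend,
    ChromosomeModel,
    Junction,
    NonLinearArchitectureError,
    Orientation,
    Segment,
    Side,
    ValidationError,
    assemble_path,
    canonicalize_path,
    classify_inversions,
    junctions_from_path,
    segments_from_cuts,
)
from junctura.models import DerivativePath
from junctura.rearrangement import (
    cluster_cut_sites,
    is_reference_adjacency,
    merged_cut_position,
    segment_label,
)
from junctura.synthetic import generate_case

L, R = Side.LEFT_OF_CUT, Side.RIGHT_OF_CUT


def be(pos, side, chrom="toy"):
    return Breakend(chrom, pos, side)


class TestSegmentsFromCuts:
    def test_no_cuts_single_segment(self):
        model = ChromosomeModel("toy", 100)
        segs = segments_from_cuts([], model)
        assert [(s.start, s.end) for s in segs] == [(1, 100)]

    def test_single_cut_convention(self):
        """Cut at x severs between x and x+1."""
        model = ChromosomeModel("toy", 100)
        segs = segments_from_cuts([40], model)
        assert [(s.start, s.end) for s in segs] == [(1, 40), (41, 100)]
        assert [s.id for s in segs] == ["A", "B"]

    def test_seven_segments_conserve_chromosome(self, chr6):
        cuts = [16_030_695, 111_030_695, 157_240_701, 158_240_695,
                159_240_695, 160_240_695]
        segs = segments_from_cuts(cuts, chr6)
        assert len(segs) == 7
        assert sum(s.length for s in segs) == chr6.length

    @pytest.mark.parametrize("cuts", [[10, 10], [30, 20], [0], [100]])
    def test_bad_cuts_rejected(self, cuts):
        model = ChromosomeModel("toy", 100)
        with pytest.raises(ValidationError):
            segments_from_cuts(cuts, model)

    def test_labels_extend_past_alphabet(self):
        assert segment_label(0) == "A"
        assert segment_label(25) == "Z"
        assert segment_label(26) == "AA"
        assert segment_label(27) == "AB"


class TestBreakendMerging:
    def test_nearby_sites_cluster_to_floored_midpoint(self):
        clusters = cluster_cut_sites([100, 113, 500], tolerance=100)
        assert clusters == [[100, 113], [500]]
        assert merged_cut_position([100, 113]) == 106

    def test_exact_tolerance_edge(self):
        assert cluster_cut_sites([100, 200, 301], tolerance=100) == [[100, 200], [301]]


class TestAssemblePath:
    def test_reference_adjacency_junctions_give_identity(self):
        model = ChromosomeModel("toy", 100)
        junctions = [
            Junction("r1", be(40, L), be(41, R)),
            Junction("r2", be(70, L), be(71, R)),
        ]
        path = assemble_path(junctions, model, merge_tolerance=0)
        assert path.describe() == "A+ B+ C+"
        assert classify_inversions(path).n_inversions == 0
        assert classify_inversions(path).n_junctions == 0

    def test_no_junctions_identity(self):
        model = ChromosomeModel("toy", 100)
        assert assemble_path([], model).describe() == "A+"

    def test_patient_architecture(self, chr6, patient_junctions):
        """The six-junction table yields the walk A B- C- D- F+ E- G."""
        path = assemble_path(patient_junctions, chr6)
        assert path.describe() == "A+ B- C- D- F+ E- G+"
        assert sum(s.length for s in path) == chr6.length

    def test_patient_arid1b_breakends_merge_to_one_cut(self, chr6, patient_junctions):
        path = assemble_path(patient_junctions, chr6)
        # 157,240,695 and the 13 bp resected mate unify at the floored midpoint
        assert 157_240_701 in path.cut_sites

    def test_duplicate_breakend_rejected(self):
        model = ChromosomeModel("toy", 100)
        junctions = [
            Junction("x", be(40, L), be(41, R)),
            Junction("y", be(40, L), be(70, L)),
        ]
        with pytest.raises(NonLinearArchitectureError) as err:
            assemble_path(junctions, model, merge_tolerance=0)
        assert "x" in err.value.junction_ids or "y" in err.value.junction_ids

    def test_dangling_end_rejected(self):
        model = ChromosomeModel("toy", 100)
        # cut at 40 has only its left side used
        junctions = [Junction("x", be(40, L), be(70, L))]
        with pytest.raises(NonLinearArchitectureError, match="dangling"):
            assemble_path(junctions, model, merge_tolerance=0)

    def test_cycle_rejected(self):
        model = ChromosomeModel("toy", 100)
        # A joins straight to D while B and C close a loop on the side
        junctions = [
            Junction("j1", be(20, L), be(81, R)),
            Junction("j2", be(50, L), be(51, R)),
            Junction("j3", be(80, L), be(21, R)),
        ]
        with pytest.raises(NonLinearArchitectureError) as err:
            assemble_path(junctions, model, merge_tolerance=0)
        assert set(err.value.junction_ids) == {"j2", "j3"}

    @pytest.mark.parametrize("seed", range(40))
    def test_round_trip_generated_cases(self, seed):
        """Reassembling a generated case's junction list reproduces its truth."""
        model = ChromosomeModel("toy", 100_000)
        case = generate_case(model, n_segments=7, inversion_prob=0.5, seed=seed)
        path = assemble_path(list(case.junctions), model, merge_tolerance=0)
        assert path == case.truth_path


class TestJunctionsFromPath:
    def test_identity_path_emits_nothing(self):
        model = ChromosomeModel("toy", 100)
        path = DerivativePath(segments_from_cuts([40], model), model)
        assert junctions_from_path(path) == []

    def test_patient_path_emits_six(self, chr6, patient_junctions):
        path = assemble_path(patient_junctions, chr6)
        assert len(junctions_from_path(path)) == 6

    @pytest.mark.parametrize("seed", range(25))
    def test_novel_junctions_round_trip_to_canonical_path(self, seed):
        model = ChromosomeModel("toy", 50_000)
        case = generate_case(model, n_segments=6, inversion_prob=0.5, seed=seed)
        novel = junctions_from_path(case.truth_path)
        rebuilt = assemble_path(novel, model, merge_tolerance=0)
        assert rebuilt == canonicalize_path(case.truth_path)


class TestClassifyInversions:
    def _path(self, model, spec):
        """spec: list of (start, end, inverted)."""
        segs = [
            Segment(chr(ord("A") + i), s, e,
                    Orientation.INVERTED if inv else Orientation.DIRECT)
            for i, (s, e, inv) in enumerate(spec)
        ]
        return DerivativePath(segs, model)

    def test_identity(self, toy_model):
        path = self._path(toy_model, [(1, 1000, False)])
        summary = classify_inversions(path)
        assert (summary.n_inversions, summary.n_pericentric,
                summary.n_paracentric, summary.n_junctions) == (0, 0, 0, 0)

    def test_patient_counts(self, chr6, patient_junctions):
        """Four events: one pericentric, three paracentric, six junctions."""
        summary = classify_inversions(assemble_path(patient_junctions, chr6))
        assert summary.n_inversions == 4
        assert summary.n_pericentric == 1
        assert summary.n_paracentric == 3
        assert summary.n_junctions == 6
        assert ("B", "pericentric") in summary.per_segment

    def test_minimal_paracentric(self, toy_model):
        # single inverted middle segment away from the centromere midpoint
        path = self._path(toy_model, [(1, 600, False), (601, 800, True),
                                      (801, 1000, False)])
        summary = classify_inversions(path)
        assert (summary.n_inversions, summary.n_pericentric,
                summary.n_paracentric, summary.n_junctions) == (1, 0, 1, 2)

    def test_pericentric_uses_centromere_midpoint(self, toy_model):
        path = self._path(toy_model, [(1, 400, False), (401, 700, True),
                                      (701, 1000, False)])
        summary = classify_inversions(path)  # midpoint 500 inside [401, 700]
        assert summary.n_pericentric == 1

    def test_missing_centromere_only_fails_with_inversions(self):
        model = ChromosomeModel("toy", 1000)  # no centromere
        flat = self._path(model, [(1, 1000, False)])
        assert classify_inversions(flat).n_inversions == 0
        inv = self._path(model, [(1, 400, False), (401, 700, True),
                                 (701, 1000, False)])
        with pytest.raises(ValidationError):
            classify_inversions(inv)

    def test_invariant_under_segment_relabeling(self, toy_model):
        spec = [(1, 300, False), (601, 800, True), (301, 600, True),
                (801, 1000, False)]
        base = self._path(toy_model, spec)
        relabelled = DerivativePath(
            [Segment(f"S{i}", s.start, s.end, s.orientation)
             for i, s in enumerate(base)],
            toy_model,
        )
        a, b = classify_inversions(base), classify_inversions(relabelled)
        assert (a.n_inversions, a.n_pericentric, a.n_junctions) == (
            b.n_inversions, b.n_pericentric, b.n_junctions)


class TestPathInvariants:
    def test_adjacent_inverted_reference_neighbours_are_reference_like(self):
        a = Segment("A", 101, 200, Orientation.INVERTED)
        b = Segment("B", 1, 100, Orientation.INVERTED)
        assert is_reference_adjacency(a, b)
        assert not is_reference_adjacency(b, a)

    def test_partition_violations_rejected(self, toy_model):
        with pytest.raises(ValidationError):
            DerivativePath([Segment("A", 1, 400), Segment("B", 500, 1000)], toy_model)
        with pytest.raises(ValidationError):
            DerivativePath([Segment("A", 1, 600), Segment("B", 500, 1000)], toy_model)
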