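"""Junction-signature calling against spec'd strings and a brute-force oracle."""

import numpy as np
import pytest

from junctura import (
    AlignmentError,
    JunctionSequenceBundle,
    SignatureCall,
    TemplateHit,
    ValidationError,
    call_insertion,
    call_microhomology,
    classify_junction,
    generate_junction_bundle,
    infer_mechanism,
    revcomp,
    search_template,
)

BASES = "ACGT"


def make_bundle(p_ret, p_cont, d_cont, d_ret, obs):
    """Build a bundle from explicit flank quarters (pads to equal flank_len)."""
    F = max(len(p_ret) - 1, len(p_cont), len(d_cont), len(d_ret) - 1)
    # pad outward with a neutral base that cannot extend any of the matches
    p = ("T" * (F + 1 - len(p_ret)) + p_ret + p_cont + "T" * (F - len(p_cont)))
    d = ("T" * (F - len(d_cont)) + d_cont + d_ret + "T" * (F + 1 - len(d_ret)))
    return JunctionSequenceBundle(p, d, obs, F)


def brute_force_call(bundle):
    """Independent oracle for generator bundles: the junction read is anchored
    at the start of the proximal flank and the end of the distal flank, so the
    maximal matches are plain longest common prefix/suffix."""
    obs, prox, dist = bundle.junction_obs, bundle.proximal_ref, bundle.distal_ref
    a = 0
    while a < min(len(obs), len(prox)) and obs[a] == prox[a]:
        a += 1
    b = 0
    while b < min(len(obs), len(dist)) and obs[-1 - b] == dist[-1 - b]:
        b += 1
    overlap = a + b - len(obs)
    if overlap > 0:
        return ("microhomology", overlap, obs[len(obs) - b : a], "")
    if overlap == 0:
        return ("blunt", 0, "", "")
    return ("insertion", 0, "", obs[a : len(obs) - b])


def brute_force_template(ins, bundle, window=50):
    hits = []
    for srank, (source, flank) in enumerate(
        (("proximal", bundle.proximal_ref), ("distal", bundle.distal_ref))
    ):
        for qrank, query in enumerate((ins, revcomp(ins))):
            for s in range(len(flank) - len(query) + 1):
                offset = s - bundle.flank_len
                if flank[s : s + len(query)] == query and abs(offset) <= window \
                        and s + len(query) <= bundle.flank_len + window + 1:
                    hits.append((abs(offset), srank, qrank, source, offset,
                                 "forward" if qrank == 0 else "reverse_complement"))
    if not hits:
        return None
    best = min(hits)
    return TemplateHit(best[3], best[4], best[5])


class TestOverlapScan:
    def test_blunt_construction(self):
        # proximal ...AAAC| continues T..., distal |GTTT..., read AAACGTTT
        bundle = make_bundle("AAAC", "TAAA", "CCCG", "GTTT", "AAACGTTT")
        assert call_microhomology(bundle) == (0, "")
        assert call_insertion(bundle) == ""
        assert classify_junction(bundle).klass == "blunt"

    def test_two_bp_overlap(self):
        # prox ...AAAATG| continuing CACA, dist |TGGGGG: the TG is claimed by
        # both flanks, so the junction carries 2 bp of microhomology
        bundle = make_bundle("AAAATG", "CACA", "CCCC", "TGGGGG", "AAAATGGGGG")
        assert call_microhomology(bundle) == (2, "TG")
        assert call_insertion(bundle) == ""

    def test_symmetric_scan_reports_total_ambiguous_overlap(self):
        # 1 bp shared at the join and 1 bp of ambiguity beyond it: overlap 2
        bundle = make_bundle("AAAG", "TCCC", "GGGC", "GTAA", "AAAGTAA")
        mh_len, mh_seq = call_microhomology(bundle)
        assert (mh_len, mh_seq) == (2, "GT")

    def test_planted_single_g_microhomology(self):
        spec = SignatureCall("j", "microhomology", mh_len=1, mh_seq="G")
        bundle = generate_junction_bundle(spec, flank_len=30, seed=11)
        assert call_microhomology(bundle) == (1, "G")
        call = classify_junction(bundle)
        assert (call.klass, call.mh_len, call.mh_seq) == ("microhomology", 1, "G")

    def test_planted_single_g_insertion(self):
        spec = SignatureCall("j", "insertion", ins_seq="G")
        bundle = generate_junction_bundle(spec, flank_len=30, seed=5)
        assert call_insertion(bundle) == "G"
        assert classify_junction(bundle).klass == "insertion"

    def test_planted_templated_insertion(self):
        spec = SignatureCall(
            "j", "insertion", ins_seq="TTTGAAG",
            template_hit=TemplateHit("proximal", -9, "forward"),
        )
        bundle = generate_junction_bundle(spec, flank_len=60, seed=3)
        assert call_insertion(bundle) == "TTTGAAG"
        call = classify_junction(bundle)
        assert call.template_hit == TemplateHit("proximal", -9, "forward")

    def test_inconsistent_read_raises(self):
        bundle = JunctionSequenceBundle("ACGTA", "ACGTA", "TTTTT", 2)
        with pytest.raises(AlignmentError):
            call_microhomology(bundle)

    def test_exclusivity_never_both(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            spec = _random_spec(rng)
            bundle = generate_junction_bundle(spec, flank_len=60,
                                              seed=int(rng.integers(1 << 30)))
            call = classify_junction(bundle)
            assert not (call.mh_len > 0 and call.ins_seq)

    def test_strand_symmetry(self):
        """Reverse-complementing the bundle (and swapping flank roles) leaves
        the microhomology and insertion lengths unchanged."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            spec = _random_spec(rng, allow_template=False)
            bundle = generate_junction_bundle(spec, flank_len=60,
                                              seed=int(rng.integers(1 << 30)))
            flipped = JunctionSequenceBundle(
                proximal_ref=revcomp(bundle.distal_ref),
                distal_ref=revcomp(bundle.proximal_ref),
                junction_obs=revcomp(bundle.junction_obs),
                flank_len=bundle.flank_len,
            )
            assert call_microhomology(flipped)[0] == call_microhomology(bundle)[0]
            assert len(call_insertion(flipped)) == len(call_insertion(bundle))


class TestTemplateSearch:
    def test_short_insertions_not_traced(self):
        spec = SignatureCall("j", "insertion", ins_seq="G")
        bundle = generate_junction_bundle(spec, flank_len=30, seed=5)
        assert search_template("G", bundle) is None
        assert search_template("GG", bundle) is None

    def test_absent_template_returns_none(self):
        spec = SignatureCall("j", "insertion", ins_seq="TTTGAAG")
        bundle = generate_junction_bundle(spec, flank_len=60, seed=9)
        assert search_template("TTTGAAG", bundle) is None
        assert brute_force_template("TTTGAAG", bundle) is None

    @pytest.mark.parametrize("source,offset,strand", [
        ("proximal", -9, "forward"),
        ("proximal", 12, "forward"),
        ("distal", -20, "forward"),
        ("distal", 7, "reverse_complement"),
        ("proximal", -30, "reverse_complement"),
    ])
    def test_planted_origin_recovered(self, source, offset, strand):
        spec = SignatureCall(
            "j", "insertion", ins_seq="TTCGAAG",
            template_hit=TemplateHit(source, offset, strand),
        )
        bundle = generate_junction_bundle(spec, flank_len=60, seed=21)
        hit = search_template("TTCGAAG", bundle)
        assert hit == TemplateHit(source, offset, strand)
        assert hit == brute_force_template("TTCGAAG", bundle)

    def test_empty_insertion_rejected(self):
        spec = SignatureCall("j", "blunt")
        bundle = generate_junction_bundle(spec, flank_len=20, seed=1)
        with pytest.raises(ValidationError):
            search_template("", bundle)


def _random_spec(rng, allow_template=True):
    roll = rng.random()
    if roll < 0.3:
        return SignatureCall("r", "blunt")
    if roll < 0.6:
        k = int(rng.integers(1, 9))
        return SignatureCall("r", "microhomology", mh_len=k,
                             mh_seq="".join(rng.choice(list(BASES), k)))
    # insertions of 3-5 nt are skipped: a trigram-to-pentamer cannot plausibly
    # be kept absent from (or unique within) +-50 bp of random flank sequence
    n = int(rng.choice([1, 2, 6, 7, 8, 9, 10]))
    ins = "".join(rng.choice(list(BASES), n))
    hit = None
    if allow_template and n >= 6 and rng.random() < 0.5:
        # keep the planted span clear of the junction boundary bases, whose
        # values are constrained by the planted insertion itself
        if rng.random() < 0.5:
            offset = int(rng.integers(-25, -n - 1))
        else:
            offset = int(rng.integers(2, 20))
        hit = TemplateHit(
            "proximal" if rng.random() < 0.5 else "distal",
            offset,
            "forward" if rng.random() < 0.5 else "reverse_complement",
        )
    return SignatureCall("r", "insertion", ins_seq=ins, template_hit=hit)


class TestCallerAgainstOracle:
    def test_matches_brute_force_on_random_fixtures(self):
        """The caller agrees with exhaustive prefix/suffix enumeration."""
        rng = np.random.default_rng(99)
        for i in range(300):
            spec = _random_spec(rng)
            bundle = generate_junction_bundle(spec, flank_len=60,
                                              seed=int(rng.integers(1 << 30)))
            call = classify_junction(bundle)
            klass, mh_len, mh_seq, ins = brute_force_call(bundle)
            assert (call.klass, call.mh_len, call.mh_seq, call.ins_seq) == (
                klass, mh_len, mh_seq, ins), f"fixture {i}: {spec}"


class TestMechanismInference:
    def _patient_calls(self):
        return [
            SignatureCall("J1", "insertion", ins_seq="G"),
            SignatureCall("J2", "blunt"),
            SignatureCall("J3", "insertion", ins_seq="TTTGAAG",
                          template_hit=TemplateHit("proximal", -9, "forward")),
            SignatureCall("J4", "blunt"),
            SignatureCall("J5", "microhomology", mh_len=1, mh_seq="G"),
            SignatureCall("J6", "blunt"),
        ]

    def test_patient_signatures_are_nhej_compatible(self):
        """Three blunt joins, 1 bp of homology and short insertions in a
        copy-number-neutral event point to canonical end joining."""
        call = infer_mechanism(self._patient_calls(), copy_number_neutral=True)
        assert call.label == "NHEJ_compatible"

    def test_long_microhomology_is_mmej(self):
        calls = [SignatureCall("x", "microhomology", mh_len=8, mh_seq="A" * 8)]
        assert infer_mechanism(calls).label == "MMEJ_compatible"

    def test_copy_number_change_is_replicative(self):
        calls = [SignatureCall("x", "blunt")]
        assert infer_mechanism(calls, copy_number_neutral=False).label == \
            "replicative_suspect"

    def test_long_templated_insertion_is_replicative(self):
        calls = [SignatureCall(
            "x", "insertion", ins_seq="A" * 12,
            template_hit=TemplateHit("distal", 5, "forward"))]
        assert infer_mechanism(calls).label == "replicative_suspect"

    def test_order_invariance(self):
        calls = self._patient_calls()
        assert infer_mechanism(calls) == infer_mechanism(calls[::-1])

    def test_empty_calls_rejected(self):
        with pytest.raises(ValidationError):
            infer_mechanism([])


class TestSignatureCallInvariants:
    @pytest.mark.parametrize("kwargs", [
        dict(klass="blunt", mh_len=1, mh_seq="G"),
        dict(klass="microhomology"),
        dict(klass="insertion"),
        dict(klass="microhomology", mh_len=2, mh_seq="AG", ins_seq="T"),
    ])
    def test_inconsistent_calls_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SignatureCall("x", **kwargs)
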