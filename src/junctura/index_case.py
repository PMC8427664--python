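"""The worked chromosome 6 index case: a de novo chromoanagenesis event with
four copy-number-neutral inversions (one pericentric, three paracentric) and
six breakpoint junctions, one of which disrupts ARID1B.

Reference segments A..G of hg19 chromosome 6 read, in the derivative, as

    A  B-  C-  D-  F+  E-  G

(B inverted across the centromere; C, D and E inverted on the q arm; F moved
in direct orientation).

Provenance of the numbers — PARTIALLY SYNTHETIC RECONSTRUCTION:

* exact published breakpoints: the two ARID1B disruption coordinates
  chr6:157,240,695 (junction 3) and chr6:157,240,708 (junction 5), in cis, and
  the chromosome span chr6:1-171,115,067 (hg19);
* reconstructed: the remaining cut positions, fixed arithmetically from the
  published segment sizes (pericentric inversion ~95 Mb, the 46.21-Mb q-arm
  inversion, and the three ~1-Mb fragments). They are faithful to the
  published architecture but not base-accurate.
* synthetic: the junction sequence context. Published Sanger reads are not
  redistributed here; :func:`index_bundles` regenerates random-flank bundles
  carrying the published per-junction signatures (junctions 2/4/6 blunt,
  junction 5 one base of microhomology "G", junction 1 a 1-nt insertion "G",
  junction 3 a 7-nt insertion "TTTGAAG" templated 9 bp upstream on the
  proximal strand).

The ARID1B transcript model below is likewise a synthetic approximation: only
the intron containing the breakpoints is coordinate-faithful by construction
(its flanking exons bracket the published positions); the remaining exons are
plausible placeholders for structure-level queries only.
"""

from __future__ import annotations

from .models import Breakend, ChromosomeModel, Junction, Side
from .nullmodel import ObservedCase
from .signature import SignatureCall, TemplateHit
from .synthetic import JunctionSequenceBundle, chr6_model, generate_junction_bundle
from .transcripts import TranscriptModel

#: Published ARID1B disruption coordinates (hg19), junctions 3 and 5 in cis.
ARID1B_BREAK_J3 = 157_240_695
ARID1B_BREAK_J5 = 157_240_708

#: Published/derived segment sizes (bp): the ~95-Mb pericentric inversion (B),
#: the 46.21-Mb q-arm inversion (C), and ~1-Mb segments D, E, F.
SIZE_B = 95_000_000
SIZE_C = 46_210_000
SIZE_D = 1_000_000
SIZE_E = 1_000_000
SIZE_F = 1_000_000

#: Reconstructed reference cut sites c1..c6 between segments A|B|C|D|E|F|G.
CUT_C3 = ARID1B_BREAK_J3
CUT_C2 = CUT_C3 - SIZE_C
CUT_C1 = CUT_C2 - SIZE_B
CUT_C4 = CUT_C3 + SIZE_D
CUT_C5 = CUT_C4 + SIZE_E
CUT_C6 = CUT_C5 + SIZE_F

#: The D-side breakend of the ARID1B disruption (13 bp of resection away from
#: the C-side breakend; unified by breakend merging during assembly).
CUT_C3_PRIME = ARID1B_BREAK_J5 - 1

#: Observed count of breakpoints inside protein-coding genes (published: four
#: of the six breakpoints occur within genes — ARID1B, ATXN1, CDK19, SYNJ2).
BREAKPOINTS_IN_GENES = 4

N_SEGMENTS = 7


def index_chromosome() -> ChromosomeModel:
    """hg19 chromosome 6 with an example centromere interval."""
    return chr6_model()


def index_junctions() -> list[Junction]:
    """The six breakpoint junctions of the derivative path A B- C- D- F+ E- G.

    Ids follow the published numbering where it is anchored (junction 3 ends
    at chr6:157,240,695, junction 5 at chr6:157,240,708); the remaining ids
    are assigned along the derivative walk.
    """
    chrom = "chr6"
    L, R = Side.LEFT_OF_CUT, Side.RIGHT_OF_CUT

    def be(pos: int, side: Side) -> Breakend:
        return Breakend(chrom, pos, side)

    return [
        # A+ -> B-: end of A joins the (inverted) right end of B
        Junction("J1", be(CUT_C1, L), be(CUT_C2, L), inserted_seq="G"),
        # B- -> C-: left end of B joins the right end of C (ARID1B side)
        Junction("J3", be(CUT_C1 + 1, R), be(ARID1B_BREAK_J3, L), inserted_seq="TTTGAAG"),
        # C- -> D-: left end of C joins the right end of D
        Junction("J2", be(CUT_C2 + 1, R), be(CUT_C4, L)),
        # D- -> F+: left end of D (ARID1B side, 13 bp resected) joins start of F
        Junction("J5", be(ARID1B_BREAK_J5, R), be(CUT_C5 + 1, R)),
        # F+ -> E-: end of F joins the right end of E
        Junction("J4", be(CUT_C6, L), be(CUT_C5, L)),
        # E- -> G+: left end of E joins the start of G
        Junction("J6", be(CUT_C4 + 1, R), be(CUT_C6 + 1, R)),
    ]


def index_observed_case(merge_tolerance: int = 100) -> ObservedCase:
    """Observed cut sites and breakend pairs for the null-model tests."""
    return ObservedCase.from_junctions(
        index_junctions(),
        n_segments=N_SEGMENTS,
        merge_tolerance=merge_tolerance,
        fusion_count_override=BREAKPOINTS_IN_GENES,
    )


def index_signature_truth() -> dict[str, SignatureCall]:
    """Published per-junction signatures keyed by junction id."""
    return {
        "J1": SignatureCall("J1", "insertion", ins_seq="G"),
        "J2": SignatureCall("J2", "blunt"),
        "J3": SignatureCall(
            "J3",
            "insertion",
            ins_seq="TTTGAAG",
            template_hit=TemplateHit("proximal", -9, "forward"),
        ),
        "J4": SignatureCall("J4", "blunt"),
        "J5": SignatureCall("J5", "microhomology", mh_len=1, mh_seq="G"),
        "J6": SignatureCall("J6", "blunt"),
    }


def index_bundles(seed: int = 0, flank_len: int = 60) -> dict[str, JunctionSequenceBundle]:
    """Synthetic junction sequence bundles carrying the published signatures."""
    out: dict[str, JunctionSequenceBundle] = {}
    for i, (jid, truth) in enumerate(sorted(index_signature_truth().items())):
        out[jid] = generate_junction_bundle(truth, flank_len=flank_len, seed=seed * 1000 + i)
    return out


#: SYNTHETIC approximation of the ARID1B canonical transcript (NM_001374820.1,
#: hg19, + strand, 20 exons). Only the boundaries of intron 4 are meaningful:
#: exon 4 ends well before and exon 5 starts well after the published
#: breakpoints at 157,240,695/157,240,708, so both fall in intron 4 (between
#: the fourth and fifth exons). Other exon coordinates are plausible
#: placeholders, not reference-accurate.
ARID1B_TRANSCRIPT_SYNTHETIC = TranscriptModel(
    name="NM_001374820.1-synthetic",
    chrom="chr6",
    strand="+",
    exons=(
        (157_099_063, 157_100_814),
        (157_150_400, 157_150_652),
        (157_191_230, 157_191_349),
        (157_198_914, 157_199_062),   # exon 4: ends upstream of the break
        (157_256_024, 157_256_126),   # exon 5: starts downstream of the break
        (157_431_576, 157_431_782),
        (157_454_248, 157_454_406),
        (157_461_049, 157_461_197),
        (157_462_189, 157_462_322),
        (157_469_676, 157_469_819),
        (157_470_648, 157_470_822),
        (157_488_926, 157_489_106),
        (157_502_079, 157_502_228),
        (157_505_521, 157_505_658),
        (157_510_590, 157_510_713),
        (157_521_858, 157_521_952),
        (157_522_077, 157_522_201),
        (157_523_760, 157_523_913),
        (157_526_617, 157_526_786),
        (157_530_316, 157_531_913),
    ),
)
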