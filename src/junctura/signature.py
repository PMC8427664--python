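"""Nucleotide-level breakpoint-junction signatures and mechanism inference.

A junction is summarised by aligning the observed read across the join against
the two reference flanks. Let ``a`` be the longest prefix of the junction read
that follows the proximal reference through its breakend, and ``b`` the longest
suffix that follows the distal reference back through its breakend. With read
length ``n``:

* ``a + b > n``  — the two alignments overlap: microhomology of ``a + b - n``
  bases (the exact break position is ambiguous within that window);
* ``a + b == n`` — blunt fusion;
* ``a + b < n``  — the unexplained middle is an insertion, optionally traced
  to a nearby templated origin on either flank and strand.

The scan is exact-match only: the features reported for germline junctions of
this kind are 0-1 bp of homology and short insertions, where a single mismatch
already breaks the signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, TYPE_CHECKING

from .errors import AlignmentError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import JunctionSequenceBundle

COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_TEMPLATE_WINDOW = 50
MIN_TEMPLATE_LEN = 3


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TemplateHit:
    """An exact local origin for inserted bases.

    ``offset`` is the signed start of the hit relative to the breakend base of
    the flank it lies on (negative = 5' of the breakend as the flank is
    written, i.e. "upstream").
    """

    source: Literal["proximal", "distal"]
    offset: int
    strand: Literal["forward", "reverse_complement"]


@dataclass(frozen=True)
class SignatureCall:
    """Per-junction classification: blunt, microhomology, or insertion."""

    junction_id: str
    klass: Literal["blunt", "microhomology", "insertion"]
    mh_len: int = 0
    mh_seq: str = ""
    ins_seq: str = ""
    template_hit: Optional[TemplateHit] = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if len(self.mh_seq) != self.mh_len:
            raise ValidationError("mh_seq length must equal mh_len")
        if self.mh_len > 0 and self.ins_seq:
            raise ValidationError("a call cannot report both microhomology and insertion")
        expected = (
            "insertion" if self.ins_seq else "microhomology" if self.mh_len else "blunt"
        )
        if self.klass != expected:
            raise ValidationError(
                f"klass {self.klass!r} inconsistent with mh_len={self.mh_len}, "
                f"ins_seq={self.ins_seq!r}"
            )


@dataclass(frozen=True)
class MechanismCall:
    label: Literal[
        "NHEJ_compatible", "MMEJ_compatible", "replicative_suspect", "indeterminate"
    ]
    rationale: str
    thresholds: dict = field(default_factory=dict, compare=False)


def _longest_common_prefix(x: str, y: str) -> int:
    n = 0
    for cx, cy in zip(x, y):
        if cx != cy:
            break
        n += 1
    return n


def _align(bundle: "JunctionSequenceBundle") -> tuple[int, int]:
    """Return (a, b): maximal proximal-prefix and distal-suffix match lengths.

    The prefix alignment is anchored on the proximal retained flank (the read
    must begin inside it) and extended through the breakend into the proximal
    continuation; symmetrically for the suffix on the distal side.
    """
    obs = bundle.junction_obs
    p_ret, p_cont = bundle.proximal_retained, bundle.proximal_continuation
    d_cont, d_ret = bundle.distal_continuation, bundle.distal_retained

    # The proximal part of the read is suffix-anchored: obs[:m] must equal the
    # last m retained bases (ending at the breakend). Take the maximal m, then
    # extend the match through the breakend into the continuation.
    m1 = 0
    for m in range(min(len(obs), len(p_ret)), 0, -1):
        if obs[:m] == p_ret[-m:]:
            m1 = m
            break
    if m1 == 0:
        raise AlignmentError(
            f"junction read does not begin in the proximal retained flank "
            f"(read {obs[:20]!r}...)"
        )
    a = m1 + _longest_common_prefix(obs[m1:], p_cont)

    m2 = 0
    for m in range(min(len(obs), len(d_ret)), 0, -1):
        if obs[-m:] == d_ret[:m]:
            m2 = m
            break
    if m2 == 0:
        raise AlignmentError(
            f"junction read does not end in the distal retained flank "
            f"(read ...{obs[-20:]!r})"
        )
    b = m2 + _longest_common_prefix(
        obs[: len(obs) - m2][::-1], d_cont[::-1]
    )
    return a, b


def call_microhomology(bundle: "JunctionSequenceBundle") -> tuple[int, str]:
    """Maximal shared overlap between the two flank alignments at the join.

    Returns ``(mh_len, mh_seq)``; ``(0, "")`` for blunt or insertion junctions.
    The overlap includes ambiguity on both sides of the nominal transition
    (bases 5' of the join matching the distal start and bases 3' matching the
    proximal continuation).
    """
    a, b = _align(bundle)
    n = len(bundle.junction_obs)
    overlap = a + b - n
    if overlap <= 0:
        return 0, ""
    return overlap, bundle.junction_obs[n - b : a]


def call_insertion(bundle: "JunctionSequenceBundle") -> str:
    """Bases of the junction read explained by neither flank (else '')."""
    a, b = _align(bundle)
    n = len(bundle.junction_obs)
    if a + b >= n:
        return ""
    return bundle.junction_obs[a : n - b]


def search_template(
    ins_seq: str,
    bundle: "JunctionSequenceBundle",
    window: int = DEFAULT_TEMPLATE_WINDOW,
    min_template_len: int = MIN_TEMPLATE_LEN,
) -> Optional[TemplateHit]:
    """Exhaustive exact scan for a local origin of the inserted bases.

    Both flanks and both strands are searched within ``window`` bp of each
    breakend. The hit with the smallest ``|offset|`` wins; ties break proximal
    before distal, then forward before reverse-complement. Insertions shorter
    than ``min_template_len`` are never traced (a 1-2 nt match is
    uninformative). ``None`` is a valid outcome.
    """
    if not ins_seq:
        raise ValidationError("search_template requires a non-empty insertion")
    if len(ins_seq) < min_template_len:
        return None
    candidates: list[tuple[int, int, int, TemplateHit]] = []
    flanks = (
        ("proximal", bundle.proximal_ref, bundle.flank_len),
        ("distal", bundle.distal_ref, bundle.flank_len),
    )
    for source_rank, (source, flank, bp_index) in enumerate(flanks):
        lo = max(0, bp_index - window)
        hi = min(len(flank), bp_index + window + 1)
        region = flank[lo:hi]
        for strand_rank, query in enumerate((ins_seq, revcomp(ins_seq))):
            start = region.find(query)
            while start != -1:
                offset = lo + start - bp_index
                hit = TemplateHit(
                    source=source,  # type: ignore[arg-type]
                    offset=offset,
                    strand="forward" if strand_rank == 0 else "reverse_complement",
                )
                candidates.append((abs(offset), source_rank, strand_rank, hit))
                start = region.find(query, start + 1)
    if not candidates:
        return None
    return min(candidates, key=lambda t: t[:3])[3]


def classify_junction(
    bundle: "JunctionSequenceBundle",
    junction_id: str = "",
    window: int = DEFAULT_TEMPLATE_WINDOW,
    min_template_len: int = MIN_TEMPLATE_LEN,
) -> SignatureCall:
    """Compose the overlap scan and template search into one call.

    Single-base features can be formally ambiguous between the insertion and
    microhomology readings under alternative breakend calls; such calls carry
    ``ambiguous=True`` rather than being silently resolved.
    """
    mh_len, mh_seq = call_microhomology(bundle)
    if mh_len > 0:
        ambiguous = mh_len == 1 and _one_bp_mh_could_be_insertion(bundle, mh_seq)
        return SignatureCall(
            junction_id, "microhomology", mh_len=mh_len, mh_seq=mh_seq, ambiguous=ambiguous
        )
    ins = call_insertion(bundle)
    if ins:
        hit = search_template(ins, bundle, window=window, min_template_len=min_template_len)
        ambiguous = len(ins) == 1 and _one_bp_ins_could_be_mh(bundle, ins)
        return SignatureCall(
            junction_id, "insertion", ins_seq=ins, template_hit=hit, ambiguous=ambiguous
        )
    return SignatureCall(junction_id, "blunt")


def _one_bp_ins_could_be_mh(bundle: "JunctionSequenceBundle", ins: str) -> bool:
    # A 1-nt insertion reads as 1-bp microhomology if shifting either breakend
    # call by one base would place the inserted base on the reference: i.e. it
    # duplicates the base just inside either retained flank.
    return ins == bundle.proximal_retained[-1] or ins == bundle.distal_retained[0]


def _one_bp_mh_could_be_insertion(bundle: "JunctionSequenceBundle", mh: str) -> bool:
    # Symmetric reading: 1 bp of homology is indistinguishable from a 1-nt
    # insertion templated immediately at the break when the shared base also
    # tandemly repeats at the junction in either flank.
    return (
        len(bundle.proximal_retained) >= 2 and mh == bundle.proximal_retained[-2]
    ) or (len(bundle.distal_retained) >= 2 and mh == bundle.distal_retained[1])


def infer_mechanism(
    calls: Sequence[SignatureCall],
    copy_number_neutral: bool = True,
    mh_max: int = 1,
    ins_max: int = 10,
    mmej_band: tuple[int, int] = (2, 25),
    template_suspect_len: int = 10,
) -> MechanismCall:
    """Label the likely repair mechanism from the junction signatures.

    Qualitative, literature-conventional rules:

    * ``replicative_suspect`` — copy-number change, or a templated insertion of
      ``template_suspect_len`` bases or more (template switching);
    * ``NHEJ_compatible`` — copy-number neutral, all microhomologies at most
      ``mh_max`` bp and all insertions at most ``ins_max`` nt;
    * ``MMEJ_compatible`` — copy-number neutral, some microhomology inside
      ``mmej_band`` and no insertion longer than ``ins_max``;
    * ``indeterminate`` otherwise.

    The result is a pure, order-invariant function of the call list.
    """
    if not calls:
        raise ValidationError("infer_mechanism requires at least one signature call")
    thresholds = {
        "mh_max": mh_max,
        "ins_max": ins_max,
        "mmej_band": mmej_band,
        "template_suspect_len": template_suspect_len,
    }
    long_templated = [
        c.junction_id
        for c in calls
        if c.template_hit is not None and len(c.ins_seq) >= template_suspect_len
    ]
    if not copy_number_neutral or long_templated:
        why = (
            "rearrangement is not copy-number neutral"
            if not copy_number_neutral
            else f"templated insertion >= {template_suspect_len} nt at "
            f"{sorted(long_templated)}"
        )
        return MechanismCall("replicative_suspect", why, thresholds)
    mh_lens = sorted(c.mh_len for c in calls)
    ins_lens = sorted(len(c.ins_seq) for c in calls)
    if max(mh_lens) <= mh_max and max(ins_lens) <= ins_max:
        return MechanismCall(
            "NHEJ_compatible",
            f"copy-number neutral; all microhomologies <= {mh_max} bp and all "
            f"insertions <= {ins_max} nt",
            thresholds,
        )
    lo, hi = mmej_band
    if any(lo <= m <= hi for m in mh_lens) and max(ins_lens) <= ins_max:
        return MechanismCall(
            "MMEJ_compatible",
            f"copy-number neutral; microhomology in [{lo}, {hi}] bp present",
            thresholds,
        )
    return MechanismCall(
        "indeterminate",
        "signatures fit neither the end-joining nor the microhomology-mediated rules",
        thresholds,
    )
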