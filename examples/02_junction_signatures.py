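"""Call nucleotide-level signatures at the six index-case junctions.

Regenerates synthetic sequence bundles carrying the published signatures
(blunt joins at junctions 2/4/6, 1 bp of microhomology at 5, a 1-nt G
insertion at 1, and the 7-nt templated TTTGAAG insertion at 3), classifies
each junction, and infers the compatible repair mechanism.
"""

from junctura import classify_junction, infer_mechanism
from junctura.index_case import index_bundles

bundles = index_bundles(seed=0)
calls = []
print("junction  class          mh  ins      template origin")
for jid, bundle in sorted(bundles.items()):
    call = classify_junction(bundle, junction_id=jid)
    calls.append(call)
    hit = ("-" if call.template_hit is None else
           f"{call.template_hit.source} {call.template_hit.offset:+d} bp "
           f"({call.template_hit.strand})")
    print(f"{jid:>8}  {call.klass:<13}  {call.mh_len:>2}  {call.ins_seq:<7}  {hit}")

mechanism = infer_mechanism(calls, copy_number_neutral=True)
print(f"\nmechanism: {mechanism.label}")
print(f"rationale: {mechanism.rationale}")
# Blunt joins and 0-1 bp features with no copy-number change are the
# signature of non-homologous end joining; long microhomologies would point
# to MMEJ, and long templated insertions or dosage changes to replicative
# repair (MMBIR-like).
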