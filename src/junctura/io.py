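"""Readers and writers for the formats the pipeline touches.

* junction tables — a TSV dialect with header
  ``junction_id chrom_a pos_a side_a chrom_b pos_b side_b inserted_seq``;
* gene annotations — BED (0-based half-open on disk, converted to the 1-based
  closed convention in memory; an optional 5th column carries the biotype);
* junction sequence bundles — FASTA with three records per junction named
  ``<id>__proximal`` / ``<id>__distal`` / ``<id>__observed``;
* breakend VCFs — BND records with bracket notation (MATEID pairs resolved);
  symbolic ``<INV>`` records are expanded to their two breakend pairs;
* JSON reports — analysis outputs wrapped with a provenance block.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import ParseError, ValidationError
from .models import Breakend, GeneAnnotation, GeneRecord, Junction, Side
from .synthetic import JunctionSequenceBundle

logger = logging.getLogger("junctura")

JUNCTION_COLUMNS = [
    "junction_id",
    "chrom_a",
    "pos_a",
    "side_a",
    "chrom_b",
    "pos_b",
    "side_b",
    "inserted_seq",
]

_SIDE_ALIASES = {
    "left_of_cut": Side.LEFT_OF_CUT,
    "right_of_cut": Side.RIGHT_OF_CUT,
    "left": Side.LEFT_OF_CUT,
    "right": Side.RIGHT_OF_CUT,
}


def provenance(params: Mapping | None = None) -> dict:
    """Tool version, timestamp and full parameter echo for output embedding."""
    return {
        "tool": "junctura",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": dict(params or {}),
    }


def write_json_report(path: str | Path, payload: Mapping, params: Mapping | None = None) -> None:
    doc = {"provenance": provenance(params), **payload}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")


# ---------------------------------------------------------------------------
# junction tables


def read_junction_table(path: str | Path) -> list[Junction]:
    """Parse the junction TSV dialect; errors name the offending line."""
    junctions: list[Junction] = []
    seen_ids: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = [c for c in JUNCTION_COLUMNS if c not in header]
                if missing:
                    raise ParseError(f"missing required columns {missing}", line=lineno)
                continue
            if len(row) < len(header):
                raise ParseError(
                    f"expected {len(header)} fields, found {len(row)}", line=lineno
                )
            rec = dict(zip(header, (c.strip() for c in row)))
            jid = rec["junction_id"]
            if jid in seen_ids:
                raise ParseError(
                    f"duplicate junction id {jid!r} (first seen on line "
                    f"{seen_ids[jid]})",
                    line=lineno,
                )
            seen_ids[jid] = lineno
            breakends = []
            for suffix in ("a", "b"):
                pos_raw = rec[f"pos_{suffix}"]
                if not pos_raw.isdigit():
                    raise ParseError(
                        f"non-numeric position pos_{suffix}={pos_raw!r}", line=lineno
                    )
                side_raw = rec[f"side_{suffix}"].lower()
                if side_raw not in _SIDE_ALIASES:
                    raise ParseError(
                        f"unknown side_{suffix}={side_raw!r} "
                        f"(expected one of {sorted(_SIDE_ALIASES)})",
                        line=lineno,
                    )
                breakends.append(
                    Breakend(rec[f"chrom_{suffix}"], int(pos_raw), _SIDE_ALIASES[side_raw])
                )
            ins = rec["inserted_seq"].upper()
            if ins in (".", "-"):
                ins = ""
            if set(ins) - set("ACGTN"):
                raise ParseError(f"invalid inserted_seq {ins!r}", line=lineno)
            try:
                junctions.append(Junction(jid, breakends[0], breakends[1], ins))
            except ValidationError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    if header is None:
        raise ParseError("empty junction table (no header)", line=1)
    return junctions


def write_junction_table(
    junctions: Sequence[Junction], path: str | Path, comments: Sequence[str] = ()
) -> None:
    with open(path, "w", newline="") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(JUNCTION_COLUMNS)
        for j in junctions:
            writer.writerow(
                [
                    j.id,
                    j.a.chrom,
                    j.a.pos,
                    j.a.side.value,
                    j.b.chrom,
                    j.b.pos,
                    j.b.side.value,
                    j.inserted_seq,
                ]
            )


# ---------------------------------------------------------------------------
# gene annotations (BED)


def read_genes_bed(path: str | Path, biotype_filter: str = "protein_coding") -> GeneAnnotation:
    """Read BED3+ gene intervals (0-based half-open) into 1-based closed records.

    When a 5th column is present it is interpreted as the biotype and records
    are filtered to ``biotype_filter``; otherwise all records are kept and a
    note is logged.
    """
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        logger.warning("gene BED %s is empty; returning an empty annotation", path)
        return GeneAnnotation([])
    if frame.shape[1] < 3:
        raise ParseError(f"{path}: BED needs at least 3 columns, found {frame.shape[1]}")
    has_biotype = frame.shape[1] >= 5
    if not has_biotype:
        logger.info(
            "gene BED %s has no biotype column; keeping all %d records",
            path,
            len(frame),
        )
    records: list[GeneRecord] = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=1):
        fields = list(row)
        try:
            start0, end0 = int(fields[1]), int(fields[2])
        except (TypeError, ValueError):
            raise ParseError(f"non-numeric BED coordinates {fields[1]!r}/{fields[2]!r}",
                             line=lineno) from None
        if start0 < 0 or end0 <= start0:
            raise ParseError(f"invalid BED interval [{start0}, {end0})", line=lineno)
        gene_id = (fields[3] if len(fields) > 3 and pd.notna(fields[3]) else f"row{lineno}")
        biotype = fields[4] if has_biotype and pd.notna(fields[4]) else "protein_coding"
        if has_biotype and biotype != biotype_filter:
            continue
        records.append(GeneRecord(str(gene_id), start0 + 1, end0, str(biotype)))
    return GeneAnnotation(records)


def write_genes_bed(genes: GeneAnnotation, path: str | Path, chrom: str = "chr6") -> None:
    """Write the annotation as BED5 (0-based half-open, biotype in column 5)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t{g.biotype}\n")


# ---------------------------------------------------------------------------
# junction sequence bundles (FASTA)

_BUNDLE_ROLES = ("proximal", "distal", "observed")


def write_bundle_fasta(bundles: Mapping[str, JunctionSequenceBundle], path: str | Path) -> None:
    records = []
    for jid, bundle in bundles.items():
        for role, seq in (
            ("proximal", bundle.proximal_ref),
            ("distal", bundle.distal_ref),
            ("observed", bundle.junction_obs),
        ):
            records.append(
                SeqRecord(Seq(seq), id=f"{jid}__{role}",
                          description=f"flank_len={bundle.flank_len}")
            )
    SeqIO.write(records, str(path), "fasta")


def read_bundle_fasta(path: str | Path) -> dict[str, JunctionSequenceBundle]:
    """Read ``<id>__proximal/__distal/__observed`` triplets into bundles."""
    sequences: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "__" not in rec.id:
            raise ParseError(
                f"record {rec.id!r} does not follow the <id>__role naming convention"
            )
        jid, _, role = rec.id.rpartition("__")
        if role not in _BUNDLE_ROLES:
            raise ParseError(f"record {rec.id!r}: unknown role {role!r}")
        sequences.setdefault(jid, {})[role] = str(rec.seq).upper()
    bundles: dict[str, JunctionSequenceBundle] = {}
    for jid, parts in sorted(sequences.items()):
        missing = [r for r in _BUNDLE_ROLES if r not in parts]
        if missing:
            raise ParseError(f"junction {jid!r}: missing records {missing}")
        span = len(parts["proximal"])
        if span != len(parts["distal"]) or span % 2 == 0:
            raise ParseError(
                f"junction {jid!r}: flanks must share an odd length, got "
                f"{span} and {len(parts['distal'])}"
            )
        bundles[jid] = JunctionSequenceBundle(
            proximal_ref=parts["proximal"],
            distal_ref=parts["distal"],
            junction_obs=parts["observed"],
            flank_len=(span - 1) // 2,
        )
    return bundles


# ---------------------------------------------------------------------------
# VCF breakends

_BND_RE = re.compile(
    r"^(?P<leading>[ACGTNacgtn]*)"
    r"(?P<open>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<close>[\[\]])"
    r"(?P<trailing>[ACGTNacgtn]*)$"
)


def read_breakend_vcf(path: str | Path) -> list[Junction]:
    """Extract junctions from the BND subset of a VCF (plus symbolic <INV>).

    Bracket notation determines the retained flanks: ``t[p[`` joins the
    sequence left of the record to the sequence right of the mate, ``t]p]``
    left to left, ``]p]t`` right to left and ``[p[t`` right to right. Mate
    pairs (MATEID) are emitted once; non-BND, non-INV records are skipped with
    a logged note. Inserted bases are the ALT bases beyond the anchor base.
    """
    import pysam

    junctions: list[Junction] = []
    emitted: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else None
            if alt == "<INV>":
                end = rec.stop
                junctions.extend(_inv_to_junctions(rec.id or f"inv{rec.pos}",
                                                   rec.chrom, rec.pos, end))
                continue
            if rec.info.get("SVTYPE") != "BND" or alt is None:
                logger.warning("skipping non-breakend record %s at %s:%d",
                               rec.id, rec.chrom, rec.pos)
                continue
            if rec.id in emitted:
                continue
            m = _BND_RE.match(alt)
            if m is None:
                raise ParseError(f"record {rec.id}: malformed breakend ALT {alt!r}")
            mate_id = rec.info.get("MATEID")
            if isinstance(mate_id, tuple):
                mate_id = mate_id[0]
            if mate_id:
                emitted.add(str(mate_id))
            leading, trailing = m["leading"].upper(), m["trailing"].upper()
            if leading:
                side_a = Side.LEFT_OF_CUT
                inserted = leading[1:]
            else:
                side_a = Side.RIGHT_OF_CUT
                inserted = trailing[:-1]
            side_b = (
                Side.RIGHT_OF_CUT if (m["open"], m["close"]) == ("[", "[")
                else Side.LEFT_OF_CUT
            )
            a = Breakend(rec.chrom, rec.pos, side_a)
            b = Breakend(m["chrom"], int(m["pos"]), side_b)
            junctions.append(Junction(rec.id or f"bnd{rec.pos}", a, b, inserted))
    return junctions


def _inv_to_junctions(vid: str, chrom: str, start: int, end: int) -> list[Junction]:
    """Expand a symbolic inversion over [start+1, end] into its breakend pairs."""
    return [
        Junction(
            f"{vid}_5p",
            Breakend(chrom, start, Side.LEFT_OF_CUT),
            Breakend(chrom, end, Side.LEFT_OF_CUT),
        ),
        Junction(
            f"{vid}_3p",
            Breakend(chrom, start + 1, Side.RIGHT_OF_CUT),
            Breakend(chrom, end + 1, Side.RIGHT_OF_CUT),
        ),
    ]
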