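"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based, half-open for intervals, throughout the
package. The one single-base coordinate type, :class:`PtCall.pos`, is the
0-based position (on the + strand reference) of the base physically
carrying the modified guanine: for a + strand call that base is the G
opening the GATC motif; for a − strand call it is the + strand C closing
the motif (the modified G of the bottom strand sits opposite that C).
Storing both strands in one coordinate system makes duplex pairing pure
integer arithmetic (+ call at p partners − call at p + 3).

GFF3 feature tables use 1-based inclusive coordinates on disk and are
converted on read; the package's own 6-column TSV dialect is already
0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from skbio import TreeNode

VALID_NUCLEOTIDES = frozenset("ACGTN")
FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "pseudogene", "other")
GENE_SYMBOLS = (
    "dndA", "dndB", "dndC", "dndD", "dndE",
    "pbeA", "pbeB", "pbeC", "pbeD",
    "dndF", "dndG", "dndH",
    "mtase", "other",
)

HOMOLOGY_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


class FormatError(ValueError):
    """Raised when an input file violates its dialect or an invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence (chromosome, plasmid or contig)."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("genome record id must be non-empty")
        bad = set(self.seq) - VALID_NUCLEOTIDES
        if bad:
            raise FormatError(
                f"genome {self.id!r}: invalid characters {sorted(bad)} "
                "(sequences must be upper-case over A,C,G,T,N)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureRecord:
    """An annotated genomic interval (0-based, half-open)."""

    contig: str
    start: int
    end: int
    strand: str
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.label!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"feature strand must be + or -, got {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True, order=True)
class PtCall:
    """A strand-resolved phosphorothioate call at one GATC motif.

    ``pos`` is the + strand coordinate of the base carrying the modified
    G: the motif's G for a + call, the motif's closing C for a − call.
    """

    contig: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"PT call strand must be + or -, got {self.strand!r}")
        if self.pos < 0:
            raise FormatError("PT call position must be non-negative")

    @property
    def locus_start(self) -> int:
        """Start of the GATC duplex locus this call belongs to."""
        return self.pos if self.strand == "+" else self.pos - 3


@dataclass(frozen=True)
class HomologyHit:
    """One row of a tabular protein homology search, plus subject context."""

    query_id: str
    query_len: int
    subject_genome: str
    subject_prot: str
    pct_identity: float
    aln_len: int
    evalue: float
    subject_contig: str
    subject_start: int
    subject_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise FormatError("alignment length must be >= 1")
        if self.evalue < 0:
            raise FormatError("e-value must be non-negative")
        if self.query_len <= 0:
            raise FormatError("query length must be positive")


@dataclass(frozen=True)
class GeneAnnotation:
    """A named defence-gene interval in a specific genome."""

    genome_id: str
    symbol: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.symbol not in GENE_SYMBOLS:
            raise FormatError(f"unknown gene symbol {self.symbol!r}")
        if self.start >= self.end:
            raise FormatError("annotation requires start < end")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a nucleotide FASTA into :class:`GenomeRecord` objects.

    Sequences are upper-cased; RNA (U) and other non-ACGTN characters are
    rejected. Duplicate ids and empty files are errors.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise FormatError(f"record {rec.id!r}: RNA (U) not accepted")
        records.append(GenomeRecord(id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def parse_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA as an ordered id → sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"no FASTA records found in {path}")
    return out


def write_protein_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PT-call TSV
# ---------------------------------------------------------------------------

def _motif_context_ok(seq: str, call: PtCall) -> bool:
    s = call.locus_start
    return 0 <= s and s + 4 <= len(seq) and seq[s:s + 4] == "GATC"


def parse_pt_calls(path: str | Path, genomes: Sequence[GenomeRecord]) -> list[PtCall]:
    """Read a PT-call TSV (contig, pos, strand; '#' comments) and validate.

    Every call must sit in a GATC context on the referenced genome:
    a + call's base is the motif G, a − call's base is the + strand C at
    motif offset +3. Violations raise with the offending line number.
    """
    by_id = {g.id: g for g in genomes}
    calls: list[PtCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            contig, pos_s, strand = parts
            if contig not in by_id:
                raise FormatError(f"{path}:{lineno}: unknown contig {contig!r}")
            call = PtCall(contig=contig, pos=int(pos_s), strand=strand)
            if not _motif_context_ok(by_id[contig].seq, call):
                raise FormatError(
                    f"{path}:{lineno}: call at {contig}:{call.pos}({strand}) "
                    "is not in a GATC context"
                )
            calls.append(call)
    calls.sort(key=lambda c: (c.contig, c.pos, c.strand))
    return calls


def write_pt_calls(calls: Iterable[PtCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# contig\tpos\tstrand\n")
        for c in calls:
            fh.write(f"{c.contig}\t{c.pos}\t{c.strand}\n")


# ---------------------------------------------------------------------------
# Feature tables (GFF3 or 6-column TSV)
# ---------------------------------------------------------------------------

_GFF_KIND_MAP = {
    "CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "pseudogene": "pseudogene",
}


def parse_feature_table(path: str | Path, dialect: str = "auto") -> list[FeatureRecord]:
    """Read genome features from GFF3 (1-based inclusive, converted on
    read) or the package's 0-based 6-column TSV.

    ``dialect`` is ``gff3``, ``tsv`` or ``auto`` (sniffed from the
    ``##gff-version`` pragma / column count).
    """
    with open(path) as fh:
        lines = fh.readlines()
    if dialect == "auto":
        dialect = "gff3" if any(l.startswith("##gff-version") for l in lines) else "tsv"
    feats: list[FeatureRecord] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if dialect == "gff3":
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            contig, _src, gff_type, start1, end1, _score, strand, _phase, attrs = parts
            kind = _GFF_KIND_MAP.get(gff_type, "other")
            label = ""
            for item in attrs.split(";"):
                if item.startswith(("ID=", "Name=")):
                    label = item.split("=", 1)[1]
                    break
            feats.append(FeatureRecord(contig, int(start1) - 1, int(end1), strand, kind, label))
        else:
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: feature TSV needs 6 columns")
            contig, start, end, strand, kind, label = parts
            feats.append(FeatureRecord(contig, int(start), int(end), strand, kind, label))
    return feats


def write_feature_table(features: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write features in the 0-based 6-column TSV dialect."""
    with open(path, "w") as fh:
        fh.write("# contig\tstart\tend\tstrand\tkind\tlabel\n")
        for f in features:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\t{f.strand}\t{f.kind}\t{f.label}\n")


# ---------------------------------------------------------------------------
# Gene annotation tables
# ---------------------------------------------------------------------------

def parse_annotation_table(path: str | Path) -> list[GeneAnnotation]:
    """Read a defence-gene annotation TSV:
    genome_id, symbol, contig, start, end, strand (0-based half-open)."""
    out: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: annotation TSV needs 6 columns")
            genome_id, symbol, contig, start, end, strand = parts
            out.append(GeneAnnotation(genome_id, symbol, contig, int(start), int(end), strand))
    return out


def write_annotation_table(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# genome_id\tsymbol\tcontig\tstart\tend\tstrand\n")
        for a in annotations:
            fh.write(f"{a.genome_id}\t{a.symbol}\t{a.contig}\t{a.start}\t{a.end}\t{a.strand}\n")


# ---------------------------------------------------------------------------
# Homology-hit tables (12-column tabular + query-length side table)
# ---------------------------------------------------------------------------

def parse_query_lengths(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV of query_id → protein length (aa)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            qid, qlen = line.split("\t")
            out[qid] = int(qlen)
    return out


def parse_homology_table(
    path: str | Path, query_lengths: Mapping[str, int]
) -> list[HomologyHit]:
    """Read 12-column tabular homology hits (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    The subject id encodes its provenance as ``genome~contig~protein``;
    sstart > send marks a minus-strand subject (coordinates are swapped to
    the forward orientation on read, 1-based inclusive converted to
    0-based half-open). Rows are returned in input order.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            qseqid, sseqid = parts[0], parts[1]
            if qseqid not in query_lengths:
                raise FormatError(f"{path}:{lineno}: no query length for {qseqid!r}")
            try:
                evalue = float(parts[10])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric e-value {parts[10]!r}") from exc
            sub = sseqid.split("~")
            if len(sub) != 3:
                raise FormatError(
                    f"{path}:{lineno}: subject id must read genome~contig~protein, got {sseqid!r}"
                )
            sstart, send = int(parts[8]), int(parts[9])
            strand = "+" if sstart <= send else "-"
            lo, hi = min(sstart, send), max(sstart, send)
            hits.append(HomologyHit(
                query_id=qseqid,
                query_len=int(query_lengths[qseqid]),
                subject_genome=sub[0],
                subject_prot=sub[2],
                pct_identity=float(parts[2]),
                aln_len=int(parts[3]),
                evalue=evalue,
                subject_contig=sub[1],
                subject_start=lo - 1,
                subject_end=hi,
                strand=strand,
            ))
    return hits


def write_homology_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits back in the 12-column dialect (mismatch/gapopen/qstart/
    qend are not modelled and are written as zeros / full-query spans)."""
    with open(path, "w") as fh:
        for h in hits:
            sseqid = f"{h.subject_genome}~{h.subject_contig}~{h.subject_prot}"
            sstart1, send1 = h.subject_start + 1, h.subject_end
            if h.strand == "-":
                sstart1, send1 = send1, sstart1
            fh.write("\t".join(map(str, (
                h.query_id, sseqid, f"{h.pct_identity:.2f}", h.aln_len, 0, 0,
                1, h.query_len, sstart1, send1, f"{h.evalue:.3g}", 0.0,
            ))) + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as Newick with branch lengths, ';'-terminated.

    The tree must have at least two leaves with unique labels.
    """
    leaves = [t.name for t in tree.tips()]
    if len(leaves) < 2:
        raise FormatError("tree must have at least 2 leaves")
    if len(set(leaves)) != len(leaves):
        raise FormatError("duplicate leaf labels in tree")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def write_json_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
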