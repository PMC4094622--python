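"""Readers and writers for the external formats the pipeline touches.

FASTA/FASTQ go through Biopython; BED, RepeatMasker .out and the alignment
table are small line formats handled here.  All writers are deterministic
byte-for-byte for identical inputs, and all genomic coordinates are converted
to 0-based half-open at this boundary.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, GenomicInterval, MEAnnotation, WeightedAlignment

ALIGNMENT_COLUMNS = [
    "read_id",
    "chrom",
    "start",
    "end",
    "strand",
    "mismatches",
    "n_positions",
    "weight",
    "first_base",
    "sequence",
]


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read a FASTQ file into a list of (read_id, sequence)."""
    return [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    """Write reads with a constant Sanger Q40 quality string."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)     ID\n"
    "\n"
)


def read_repeatmasker_out(path) -> list[MEAnnotation]:
    """Parse a RepeatMasker .out file (3 header lines, whitespace columns).

    Genomic coordinates (1-based inclusive) are converted to 0-based
    half-open; orientation 'C' becomes strand '-'; the ID column becomes
    ``repeat_id``.  The parenthesized token among the three repeat-position
    columns is the 'left' count and is ignored when deriving the consensus
    span, which makes the parser orientation-agnostic.
    """
    annotations: list[MEAnnotation] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 15:
            raise ValueError(
                f"{path}:{lineno}: expected >=15 columns, got {len(fields)}"
            )
        chrom = fields[4]
        begin, end = int(fields[5]), int(fields[6])
        orient = fields[8]
        strand = "-" if orient == "C" else "+"
        subfamily = fields[9]
        me_class = fields[10]
        rep_pos = [f for f in fields[11:14] if not f.startswith("(")]
        rep_pos = sorted(int(p) for p in rep_pos)
        repeat_id = int(fields[14])
        annotations.append(
            MEAnnotation(
                interval=GenomicInterval(chrom, begin - 1, end, strand),
                subfamily=subfamily,
                me_class=me_class,
                repeat_id=repeat_id,
                consensus_span=(rep_pos[0] - 1, rep_pos[1]),
            )
        )
    return annotations


def write_repeatmasker_out(annotations: list[MEAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for ann in annotations:
            iv = ann.interval
            orient = "C" if iv.strand == "-" else "+"
            cb, ce = ann.consensus_span
            fh.write(
                f"  500  5.0  0.0  0.0  {iv.chrom}  {iv.start + 1}  {iv.end}"
                f"  (0)  {orient}  {ann.subfamily}  {ann.me_class}"
                f"  {cb + 1}  {ce}  (0)  {ann.repeat_id}\n"
            )


# ---------------------------------------------------------------------------
# BED12 gene / lncRNA models
# ---------------------------------------------------------------------------

def _blocks(fields: list[str]) -> list[tuple[int, int]]:
    chrom_start = int(fields[1])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    return [(chrom_start + s, chrom_start + s + sz) for s, sz in zip(starts, sizes)]


def read_gene_models(path) -> list[GeneModel]:
    """Read BED12 transcripts into :class:`GeneModel` objects.

    thickStart/thickEnd delimit the CDS.  Exon blocks are intersected with
    [chromStart, thickStart), [thickStart, thickEnd) and [thickEnd, chromEnd);
    on '+' the left flank is the 5'UTR, on '-' it is the 3'UTR.  The BED name
    column is ``gene_id|transcript_id`` (a bare name serves as both).
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            if not (start <= thick_start <= thick_end <= end):
                raise ValueError(
                    f"{path}:{lineno}: thick bounds [{thick_start}, {thick_end})"
                    f" outside transcript [{start}, {end})"
                )
            gene_id, _, transcript_id = name.partition("|")
            transcript_id = transcript_id or gene_id
            left: list[GenomicInterval] = []
            cds: list[GenomicInterval] = []
            right: list[GenomicInterval] = []
            for bs, be in _blocks(f):
                for lo, hi, dest in (
                    (bs, min(be, thick_start), left),
                    (max(bs, thick_start), min(be, thick_end), cds),
                    (max(bs, thick_end), be, right),
                ):
                    if lo < hi:
                        dest.append(GenomicInterval(chrom, lo, hi, strand))
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    strand=strand,
                    utr5=utr5,
                    cds=cds,
                    utr3=utr3,
                )
            )
    return models


def write_gene_models_bed12(models: list[GeneModel], path) -> None:
    lines = []
    for m in models:
        exons = m.exons
        start, end = exons[0].start, exons[-1].end
        cds = sorted(m.cds, key=lambda iv: iv.start)
        thick_start = cds[0].start if cds else start
        thick_end = cds[-1].end if cds else start
        sizes = ",".join(str(len(iv)) for iv in exons)
        starts = ",".join(str(iv.start - start) for iv in exons)
        lines.append(
            "\t".join(
                [
                    exons[0].chrom,
                    str(start),
                    str(end),
                    f"{m.gene_id}|{m.transcript_id}",
                    "0",
                    m.strand,
                    str(thick_start),
                    str(thick_end),
                    "0",
                    str(len(exons)),
                    sizes,
                    starts,
                ]
            )
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# Generic interval / cluster output
# ---------------------------------------------------------------------------

def write_intervals(records, path, format: str = "BED6") -> None:
    """Write intervals (or objects carrying ``.interval``) as BED6 or TSV.

    BED6 is 0-based half-open and sorted by (chrom, start, end, strand); the
    score column carries ``rpkm`` rounded to 4 decimals when present.
    """
    if format not in ("BED6", "TSV"):
        raise ValueError(f"unknown format {format!r}")
    rows = []
    for i, rec in enumerate(records):
        iv = rec if isinstance(rec, GenomicInterval) else rec.interval
        name = getattr(rec, "name", None) or f"feature_{i + 1}"
        rpkm = getattr(rec, "rpkm", None)
        score = f"{rpkm:.4f}" if rpkm is not None else "0"
        rows.append((iv.chrom, iv.start, iv.end, name, score, iv.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[5]))
    buf = _io.StringIO()
    if format == "TSV":
        buf.write("chrom\tstart\tend\tname\tscore\tstrand\n")
    for row in rows:
        buf.write("\t".join(str(x) for x in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_intervals(path) -> list[GenomicInterval]:
    """Read a BED6 (or the TSV dialect above) back into intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not line.strip() or f[0] == "chrom":
                continue
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]))
    return out


# ---------------------------------------------------------------------------
# Alignment table
# ---------------------------------------------------------------------------

def write_alignments(alignments: list[WeightedAlignment], path) -> None:
    rows = [
        (
            a.read_id,
            a.interval.chrom,
            a.interval.start,
            a.interval.end,
            a.interval.strand,
            a.mismatches,
            a.n_positions,
            a.weight,
            a.first_base,
            a.sequence,
        )
        for a in alignments
    ]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_alignments(path) -> list[WeightedAlignment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        WeightedAlignment(
            read_id=str(r.read_id),
            interval=GenomicInterval(
                str(r.chrom), int(r.start), int(r.end), str(r.strand)
            ),
            mismatches=int(r.mismatches),
            n_positions=int(r.n_positions),
            first_base=str(r.first_base),
            sequence=str(r.sequence),
        )
        for r in df.itertuples()
    ]
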