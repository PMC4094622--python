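"""Small-RNA read preprocessing.

The four-step funnel from raw reads to putative piRNAs:

1. strip the 3' adapter (longest read suffix equal to an adapter prefix,
   minimum 3 nt, exact match) and keep reads of 5-45 nt;
2. remove reads matching any known small-RNA sequence (either strand,
   <= 1 mismatch);
3. map the remainder to the genome, reporting all best-stratum positions
   with <= 1 mismatch;
4. keep mapped reads of 26-31 nt as putative piRNAs, each position weighted
   1/n over its n reported positions.

Per-step tallies are conserved: input = survivors + removed, at every step.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._match import Hit, MismatchIndex
from .core import GenomicInterval, WeightedAlignment


@dataclass
class ReadRecord:
    """A read with its survival flag through the processing funnel."""

    read_id: str
    sequence: str
    kept: bool = True
    removal_reason: str | None = None

    def remove(self, reason: str) -> None:
        self.kept = False
        self.removal_reason = reason


def _as_records(reads) -> list[ReadRecord]:
    return [
        r if isinstance(r, ReadRecord) else ReadRecord(r[0], r[1])
        for r in reads
    ]


def trim_adapter(sequence: str, adapter: str, min_overlap: int = 3) -> str:
    """Remove the longest read suffix equal to a prefix of *adapter*.

    Exact matching only; reads without a >= min_overlap match are returned
    untrimmed.
    """
    max_l = min(len(sequence), len(adapter))
    for l in range(max_l, min_overlap - 1, -1):
        if sequence.endswith(adapter[:l]):
            return sequence[:-l]
    return sequence


def trim_and_window(
    reads, adapter: str, min_len: int = 5, max_len: int = 45
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Step 1: adapter stripping and the 5-45 nt size window."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    records = _as_records(reads)
    survivors = []
    tally = {"input": len(records), "kept": 0, "adapter_short": 0, "size": 0}
    for rec in records:
        trimmed = trim_adapter(rec.sequence, adapter)
        was_trimmed = len(trimmed) < len(rec.sequence)
        rec.sequence = trimmed
        if min_len <= len(trimmed) <= max_len:
            survivors.append(rec)
            tally["kept"] += 1
        elif was_trimmed and len(trimmed) < min_len:
            rec.remove("adapter_short")
            tally["adapter_short"] += 1
        else:
            rec.remove("size")
            tally["size"] += 1
    return survivors, tally


def remove_known_rna(
    reads: list[ReadRecord],
    known_rna: dict[str, str],
    max_mismatch: int = 1,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Step 2: subtract reads matching known small-RNA sequences.

    A read is removed iff it aligns within any known-RNA sequence, on either
    strand, with at most *max_mismatch* substitutions.
    """
    if not known_rna:
        raise ValueError("known-RNA set must be non-empty")
    index = MismatchIndex(known_rna, k=8)
    survivors = []
    tally = {"input": len(reads), "kept": 0, "known_rna": 0}
    for rec in reads:
        if index.find(rec.sequence, max_mismatch, best_stratum=False):
            rec.remove("known_rna")
            tally["known_rna"] += 1
        else:
            survivors.append(rec)
            tally["kept"] += 1
    return survivors, tally


def align_reads(
    reads: list[ReadRecord],
    reference: dict[str, str],
    max_mismatch: int = 1,
    index: MismatchIndex | None = None,
) -> tuple[dict[str, list[Hit]], list[ReadRecord], dict[str, int]]:
    """Step 3: exhaustive genome mapping, best stratum only.

    Every position on both strands where a read matches with
    <= *max_mismatch* is found; if any 0-mismatch hit exists, higher-stratum
    hits are suppressed.  Reads with no hit are marked unmapped.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    if index is None:
        index = MismatchIndex(reference, k=12)
    hits_by_read: dict[str, list[Hit]] = {}
    survivors = []
    tally = {"input": len(reads), "kept": 0, "unmapped": 0}
    # identical sequences share their hit list
    cache: dict[str, list[Hit]] = {}
    for rec in reads:
        hits = cache.get(rec.sequence)
        if hits is None:
            hits = index.find(rec.sequence, max_mismatch, best_stratum=True)
            cache[rec.sequence] = hits
        if hits:
            hits_by_read[rec.read_id] = hits
            survivors.append(rec)
            tally["kept"] += 1
        else:
            rec.remove("unmapped")
            tally["unmapped"] += 1
    return hits_by_read, survivors, tally


def size_select(
    reads: list[ReadRecord], min_len: int = 26, max_len: int = 31
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Step 4: keep putative piRNAs of 26-31 nt (inclusive bounds)."""
    survivors = []
    tally = {"input": len(reads), "kept": 0, "size": 0}
    for rec in reads:
        if min_len <= len(rec.sequence) <= max_len:
            survivors.append(rec)
            tally["kept"] += 1
        else:
            rec.remove("size")
            tally["size"] += 1
    return survivors, tally


def assign_multimap_weights(
    hits_by_read: dict[str, list[Hit]], reads: list[ReadRecord]
) -> list[WeightedAlignment]:
    """Fractional 1/n weighting over each read's n best-stratum positions.

    A read mapped to 10 positions is counted as 0.1 reads at each; the summed
    weight per read is exactly 1.
    """
    alignments: list[WeightedAlignment] = []
    for rec in reads:
        hits = hits_by_read.get(rec.read_id)
        if not hits:
            continue
        n = len(hits)
        for h in hits:
            alignments.append(
                WeightedAlignment(
                    read_id=rec.read_id,
                    interval=GenomicInterval(
                        h.ref, h.start, h.start + len(rec.sequence), h.strand
                    ),
                    mismatches=h.mismatches,
                    n_positions=n,
                    first_base=rec.sequence[0],
                    sequence=rec.sequence,
                )
            )
    return alignments


@dataclass
class PreprocessResult:
    """Alignments plus the per-step bookkeeping table."""

    alignments: list[WeightedAlignment]
    survivors: list[ReadRecord]
    tallies: list[tuple[str, dict[str, int]]]

    @property
    def total_weight(self) -> float:
        return sum(a.weight for a in self.alignments)


def run_preprocess(
    reads,
    genome: dict[str, str],
    known_rna: dict[str, str],
    adapter: str,
    min_pirna: int = 26,
    max_pirna: int = 31,
    genome_index: MismatchIndex | None = None,
) -> PreprocessResult:
    """Run steps 1-4 in order and assign multi-mapping weights."""
    records = _as_records(reads)
    s1, t1 = trim_and_window(records, adapter)
    s2, t2 = remove_known_rna(s1, known_rna)
    hits, s3, t3 = align_reads(s2, genome, index=genome_index)
    s4, t4 = size_select(s3, min_pirna, max_pirna)
    alignments = assign_multimap_weights(hits, s4)
    return PreprocessResult(
        alignments=alignments,
        survivors=s4,
        tallies=[
            ("adapter_and_window", t1),
            ("known_rna_removal", t2),
            ("genome_mapping", t3),
            ("pirna_size_selection", t4),
        ],
    )
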