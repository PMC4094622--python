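"""Core genomic data model shared by the whole pipeline.

All coordinates are 0-based half-open ([start, end)) on the forward strand of
the reference; 1-based formats (RepeatMasker .out) are converted at the I/O
boundary only.  Strand is '+', '-' or '.' (strandless).
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


ME_CLASSES = frozenset({"DNA", "LINE", "SINE", "LTR", "SVA"})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Reference sequence name (non-empty).
    start, end : int
        0-based half-open bounds, ``0 <= start < end``.
    strand : str
        '+', '-' or '.' for strandless features.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class WeightedAlignment:
    """One mapping of a read carrying a fractional multi-mapping weight.

    A read reported at ``n_positions`` best-stratum positions contributes
    weight ``1/n_positions`` at each of them, so its total mass over the
    genome is exactly 1.
    """

    read_id: str
    interval: GenomicInterval
    mismatches: int
    n_positions: int
    first_base: str
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")

    @property
    def weight(self) -> float:
        return 1.0 / self.n_positions

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def five_prime(self) -> int:
        """Genomic position of the read's 5' end (0-based)."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass
class GeneModel:
    """A transcript with its 5'UTR / CDS / 3'UTR interval partition.

    Region intervals are non-overlapping and all carry the transcript strand;
    the exon union is their merged span projection.
    """

    gene_id: str
    transcript_id: str
    strand: str
    utr5: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        for ivs in (self.utr5, self.cds, self.utr3):
            if ivs:
                return ivs[0].chrom
        raise ValueError(f"empty gene model {self.transcript_id}")

    @property
    def exons(self) -> list[GenomicInterval]:
        """Merged exon union of all three regions (strandless merge)."""
        ivs = sorted(
            self.utr5 + self.cds + self.utr3, key=lambda iv: (iv.start, iv.end)
        )
        merged: list[GenomicInterval] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1].end:
                if iv.end > merged[-1].end:
                    merged[-1] = GenomicInterval(
                        iv.chrom, merged[-1].start, iv.end, self.strand
                    )
            else:
                merged.append(
                    GenomicInterval(iv.chrom, iv.start, iv.end, self.strand)
                )
        return merged

    def region_length(self, region: str) -> int:
        return sum(len(iv) for iv in getattr(self, region))


@dataclass
class MEAnnotation:
    """One RepeatMasker fragment of a mobile-element copy.

    ``repeat_id`` links fragments of a single interrupted copy (the .out ID
    column); ``consensus_span`` is the [begin, end) span covered on the
    subfamily consensus.
    """

    interval: GenomicInterval
    subfamily: str
    me_class: str
    repeat_id: int
    consensus_span: tuple[int, int] = (0, 0)

    @property
    def is_mobile_element(self) -> bool:
        """False for Low_complexity / Satellite / Simple_repeat / ncRNA rows."""
        return self.me_class.split("/")[0] in ME_CLASSES


def merge_intervals(
    intervals: list[tuple[int, int]], gap: int = 0
) -> list[tuple[int, int]]:
    """Merge (start, end) half-open intervals closer than *gap* apart."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def union_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
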