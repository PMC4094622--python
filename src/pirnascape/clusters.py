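"""piRNA cluster calling by sliding-window genomic-length RPKM.

A 5 kb window slides in 1 kb steps along each chromosome; each window's
weighted piRNA count (reads assigned by 5' end) is normalised to RPKM on the
*genomic* window length — reads per kb of DNA per million mapped piRNAs, not
per transcript kb.  Windows at or above the cutoff are merged when they
overlap or touch, the merged extent is trimmed to the span of its member
reads, and per-cluster 1U / strand statistics are weight-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenomicInterval, WeightedAlignment


@dataclass
class WindowScore:
    interval: GenomicInterval
    weighted_count: float
    rpkm: float


@dataclass
class PiRNACluster:
    """A merged, read-trimmed genomic interval of concentrated piRNA output."""

    interval: GenomicInterval
    rpkm: float
    weighted_count: float
    u1_fraction: float = 0.0
    plus_fraction: float = 0.0
    name: str = ""
    members: list[WeightedAlignment] = field(default_factory=list, repr=False)

    @property
    def majority_strand_fraction(self) -> float:
        return max(self.plus_fraction, 1.0 - self.plus_fraction)

    @property
    def is_directional(self) -> bool:
        return self.majority_strand_fraction > 0.75

    @property
    def is_u1_biased(self) -> bool:
        return self.u1_fraction >= 0.75


def _rpkm(count: float, length_bp: int, total_weighted: float) -> float:
    return count / (length_bp / 1000.0) / (total_weighted / 1e6)


def window_scan(
    alignments: list[WeightedAlignment],
    chrom_lengths: dict[str, int],
    window: int = 5000,
    step: int = 1000,
    total_weighted: float | None = None,
) -> list[WindowScore]:
    """Score sliding windows on every chromosome.

    A read contributes its weight to a window iff its 5' end lies in the
    window.  The final partial window is normalised by its actual length.
    """
    if total_weighted is None:
        total_weighted = sum(a.weight for a in alignments)
    if total_weighted <= 0:
        raise ValueError("total_weighted must be > 0 (RPKM undefined)")
    by_chrom: dict[str, list[WeightedAlignment]] = {}
    for a in alignments:
        by_chrom.setdefault(a.interval.chrom, []).append(a)
    scores: list[WindowScore] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        members = by_chrom.get(chrom, [])
        pos = np.array([a.five_prime for a in members], dtype=np.int64)
        w = np.array([a.weight for a in members], dtype=np.float64)
        order = np.argsort(pos, kind="stable")
        pos, w = pos[order], w[order]
        cumw = np.concatenate([[0.0], np.cumsum(w)])
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        counts = cumw[hi] - cumw[lo]
        for s, e, c in zip(starts, ends, counts):
            scores.append(
                WindowScore(
                    interval=GenomicInterval(chrom, int(s), int(e), "."),
                    weighted_count=float(c),
                    rpkm=_rpkm(float(c), int(e - s), total_weighted),
                )
            )
    return scores


def call_clusters(
    windows: list[WindowScore],
    alignments: list[WeightedAlignment],
    cutoff_rpkm: float,
    total_weighted: float | None = None,
    min_length: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[PiRNACluster]:
    """Merge qualifying windows into clusters and annotate them.

    A window qualifies iff ``rpkm >= cutoff`` (closed).  Maximal runs of
    overlapping/adjacent qualifying windows are merged; the merged extent is
    trimmed to the span of its member reads (first read start to last read
    end); cluster RPKM is recomputed over the trimmed extent; clusters
    shorter than *min_length* are padded to it, centred on the read span.
    """
    if cutoff_rpkm <= 0:
        raise ValueError("cutoff_rpkm must be > 0")
    if total_weighted is None:
        total_weighted = sum(a.weight for a in alignments)
    qualifying = [ws for ws in windows if ws.rpkm >= cutoff_rpkm]
    by_chrom: dict[str, list[WindowScore]] = {}
    for ws in qualifying:
        by_chrom.setdefault(ws.interval.chrom, []).append(ws)
    aln_by_chrom: dict[str, list[WeightedAlignment]] = {}
    for a in alignments:
        aln_by_chrom.setdefault(a.interval.chrom, []).append(a)

    clusters: list[PiRNACluster] = []
    for chrom in sorted(by_chrom):
        wss = sorted(by_chrom[chrom], key=lambda ws: ws.interval.start)
        merged: list[list[int]] = []
        for ws in wss:
            if merged and ws.interval.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], ws.interval.end)
            else:
                merged.append([ws.interval.start, ws.interval.end])
        chrom_alns = aln_by_chrom.get(chrom, [])
        for lo, hi in merged:
            members = [a for a in chrom_alns if lo <= a.five_prime < hi]
            if not members:
                continue
            start = min(a.interval.start for a in members)
            end = max(a.interval.end for a in members)
            if end - start < min_length:
                centre = (start + end) // 2
                start = max(0, centre - min_length // 2)
                end = start + min_length
                if chrom_lengths and end > chrom_lengths[chrom]:
                    end = chrom_lengths[chrom]
                    start = max(0, end - min_length)
            count = sum(a.weight for a in members)
            clusters.append(
                cluster_stats(
                    PiRNACluster(
                        interval=GenomicInterval(chrom, start, end, "."),
                        rpkm=_rpkm(count, end - start, total_weighted),
                        weighted_count=count,
                        members=members,
                    ),
                    members,
                )
            )
    for i, cl in enumerate(clusters, start=1):
        cl.name = f"cluster_{i}"
    return clusters


def cluster_stats(
    cluster: PiRNACluster, members: list[WeightedAlignment]
) -> PiRNACluster:
    """Weight-weighted 1U and strand fractions of a cluster's members."""
    if not members:
        raise ValueError("a cluster must have member alignments")
    total = sum(a.weight for a in members)
    cluster.u1_fraction = (
        sum(a.weight for a in members if a.first_base in "TU") / total
    )
    cluster.plus_fraction = (
        sum(a.weight for a in members if a.interval.strand == "+") / total
    )
    cluster.weighted_count = total
    return cluster


def capture_fraction(
    clusters: list[PiRNACluster], alignments: list[WeightedAlignment]
) -> float:
    """Fraction of total alignment weight falling inside called clusters."""
    total = sum(a.weight for a in alignments)
    if total == 0:
        return 0.0
    spans: dict[str, list[tuple[int, int]]] = {}
    for cl in clusters:
        spans.setdefault(cl.interval.chrom, []).append(
            (cl.interval.start, cl.interval.end)
        )
    inside = 0.0
    for a in alignments:
        p = a.five_prime
        for s, e in spans.get(a.interval.chrom, ()):
            if s <= p < e:
                inside += a.weight
                break
    return inside / total
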