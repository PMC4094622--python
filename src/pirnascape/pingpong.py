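"""Ping-pong signature analysis on mobile-element consensus sequences.

Reads are matched directly to repeat consensus sequences with a mismatch
budget (default 3, ~10% of a 28-nt piRNA).  A candidate ping-pong pair is a
(sense, antisense) alignment pair whose 5' ends overlap by exactly 10 nt:
in consensus coordinates, sense 5' + 9 = antisense 5'.  Within a qualifying
pair each read is classified by its own 5'->3' sequence:

    SPS  (sense ping-pong signature):     1U on sense  or 10A on antisense
    ASPS (antisense ping-pong signature): 10A on sense or 1U on antisense

Per-position densities of all, SPS- and ASPS-classified reads support peak
calling, and antisense peak reads can be traced back to genomic source
clusters by perfect-match unique-position re-mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._match import MismatchIndex
from .clusters import PiRNACluster
from .core import merge_intervals


@dataclass
class ConsensusAlignment:
    """One mapping of a read on a consensus sequence."""

    read_id: str
    consensus_id: str
    start: int
    end: int
    strand: str  # '+' = sense to the consensus, '-' = antisense
    mismatches: int
    n_positions: int
    sequence: str  # the read's own 5'->3' sequence
    is_sps: bool = False
    is_asps: bool = False

    @property
    def weight(self) -> float:
        return 1.0 / self.n_positions

    @property
    def five_prime(self) -> int:
        return self.end - 1 if self.strand == "-" else self.start

    @property
    def signature(self) -> str:
        if self.is_sps and self.is_asps:
            return "both"
        if self.is_sps:
            return "SPS"
        if self.is_asps:
            return "ASPS"
        return "none"


@dataclass
class PingPongPair:
    sense: ConsensusAlignment
    antisense: ConsensusAlignment


@dataclass
class SignaturePeak:
    consensus_id: str
    strand: str
    start: int
    end: int  # half-open consensus interval
    signature: str  # 'SPS' or 'ASPS'
    total_weight: float


@dataclass
class ConsensusProfile:
    """Per-position weighted 5'-start densities on one consensus."""

    consensus_id: str
    length: int
    sense: np.ndarray
    antisense: np.ndarray
    sps_sense: np.ndarray
    sps_antisense: np.ndarray
    asps_sense: np.ndarray
    asps_antisense: np.ndarray


# ---------------------------------------------------------------------------
# Composite consensus construction
# ---------------------------------------------------------------------------

@dataclass
class CompositeConsensus:
    include_all_insertion: str
    include_all_deletion: str
    # index in insertion coordinates for every deletion-consensus position
    deletion_to_insertion: list[int] = field(default_factory=list)

    def lift_deletion_to_insertion(self, pos: int) -> int:
        return self.deletion_to_insertion[pos]

    def lift_insertion_to_deletion(self, pos: int) -> int | None:
        """Inverse lift; None for insertion-only columns."""
        try:
            return self.deletion_to_insertion.index(pos)
        except ValueError:
            return None


def build_composite_consensus(aligned: list[str]) -> CompositeConsensus:
    """Build the two composite consensuses from one gapped alignment.

    include-all-insertion keeps every column with at least one non-gap base;
    include-all-deletion keeps only gap-free columns.  The column base is the
    majority among non-gap residues, ties broken in A < C < G < T order.
    """
    if not aligned:
        raise ValueError("empty alignment")
    length = len(aligned[0])
    if any(len(row) != length for row in aligned):
        raise ValueError("alignment rows must have equal length")
    rows = [row.upper() for row in aligned]
    ins_chars: list[str] = []
    del_chars: list[str] = []
    del_to_ins: list[int] = []
    for col in range(length):
        column = [row[col] for row in rows]
        bases = [b for b in column if b not in "-."]
        if not bases:
            continue  # all-gap column appears in neither consensus
        counts = {b: bases.count(b) for b in sorted(set(bases))}
        best = max(counts.values())
        base = sorted(b for b, c in counts.items() if c == best)[0]
        ins_idx = len(ins_chars)
        ins_chars.append(base)
        if len(bases) == len(column):  # gap-free column
            del_to_ins.append(ins_idx)
            del_chars.append(base)
    return CompositeConsensus(
        include_all_insertion="".join(ins_chars),
        include_all_deletion="".join(del_chars),
        deletion_to_insertion=del_to_ins,
    )


# ---------------------------------------------------------------------------
# Consensus mapping and signature classification
# ---------------------------------------------------------------------------

def map_to_consensus(
    reads: list[tuple[str, str]],
    consensus: dict[str, str],
    max_mismatch: int = 3,
) -> list[ConsensusAlignment]:
    """All best-stratum positions of each read on each strand of each
    consensus, with <= *max_mismatch* substitutions."""
    if not consensus:
        raise ValueError("consensus set must be non-empty")
    index = MismatchIndex(consensus, k=6)
    out: list[ConsensusAlignment] = []
    cache: dict[str, list] = {}
    for read_id, seq in reads:
        hits = cache.get(seq)
        if hits is None:
            hits = index.find(seq, max_mismatch, best_stratum=True)
            cache[seq] = hits
        n = len(hits)
        for h in hits:
            out.append(
                ConsensusAlignment(
                    read_id=read_id,
                    consensus_id=h.ref,
                    start=h.start,
                    end=h.start + len(seq),
                    strand=h.strand,
                    mismatches=h.mismatches,
                    n_positions=n,
                    sequence=seq,
                )
            )
    return out


def classify_pingpong(
    alignments: list[ConsensusAlignment],
) -> list[PingPongPair]:
    """Find 10-nt 5'-overlap pairs and label each member read.

    Pairing is symmetric in the two roles; a read in no qualifying pair
    keeps signature 'none'.
    """
    pairs: list[PingPongPair] = []
    by_consensus: dict[str, list[ConsensusAlignment]] = {}
    for a in alignments:
        by_consensus.setdefault(a.consensus_id, []).append(a)
    for alns in by_consensus.values():
        sense = [a for a in alns if a.strand == "+"]
        anti = [a for a in alns if a.strand == "-"]
        anti_by_5p: dict[int, list[ConsensusAlignment]] = {}
        for a in anti:
            anti_by_5p.setdefault(a.five_prime, []).append(a)
        for s in sense:
            for a in anti_by_5p.get(s.five_prime + 9, ()):
                pairs.append(PingPongPair(sense=s, antisense=a))
                # sense read: 1U -> SPS, 10A -> ASPS
                if s.sequence[0] in "TU":
                    s.is_sps = True
                if len(s.sequence) >= 10 and s.sequence[9] == "A":
                    s.is_asps = True
                # antisense read: 10A -> SPS, 1U -> ASPS
                if len(a.sequence) >= 10 and a.sequence[9] == "A":
                    a.is_sps = True
                if a.sequence[0] in "TU":
                    a.is_asps = True
    return pairs


def build_profiles(
    alignments: list[ConsensusAlignment], consensus: dict[str, str]
) -> dict[str, ConsensusProfile]:
    """Per-consensus weighted 5'-start density tracks (run after
    :func:`classify_pingpong` so signature tracks are populated)."""
    profiles = {
        cid: ConsensusProfile(
            consensus_id=cid,
            length=len(seq),
            sense=np.zeros(len(seq)),
            antisense=np.zeros(len(seq)),
            sps_sense=np.zeros(len(seq)),
            sps_antisense=np.zeros(len(seq)),
            asps_sense=np.zeros(len(seq)),
            asps_antisense=np.zeros(len(seq)),
        )
        for cid, seq in consensus.items()
    }
    for a in alignments:
        prof = profiles[a.consensus_id]
        side = "sense" if a.strand == "+" else "antisense"
        p = a.five_prime
        getattr(prof, side)[p] += a.weight
        if a.is_sps:
            getattr(prof, f"sps_{side}")[p] += a.weight
        if a.is_asps:
            getattr(prof, f"asps_{side}")[p] += a.weight
    return profiles


def find_signature_peaks(
    profile: ConsensusProfile,
    min_reads: float,
    gap_tolerance: int = 5,
) -> list[SignaturePeak]:
    """Maximal runs of nonzero signature density with total >= *min_reads*.

    Runs separated by more than *gap_tolerance* zero positions are distinct
    peaks.
    """
    if min_reads <= 0:
        raise ValueError("min_reads must be > 0")
    peaks: list[SignaturePeak] = []
    tracks = [
        ("SPS", "+", profile.sps_sense),
        ("SPS", "-", profile.sps_antisense),
        ("ASPS", "+", profile.asps_sense),
        ("ASPS", "-", profile.asps_antisense),
    ]
    for signature, strand, dens in tracks:
        nz = np.nonzero(dens)[0]
        if len(nz) == 0:
            continue
        runs = []
        run_start = prev = nz[0]
        for p in nz[1:]:
            if p - prev > gap_tolerance + 1:
                runs.append((run_start, prev))
                run_start = p
            prev = p
        runs.append((run_start, prev))
        for lo, hi in runs:
            total = float(dens[lo : hi + 1].sum())
            if total >= min_reads:
                peaks.append(
                    SignaturePeak(
                        consensus_id=profile.consensus_id,
                        strand=strand,
                        start=int(lo),
                        end=int(hi) + 1,
                        signature=signature,
                        total_weight=total,
                    )
                )
    peaks.sort(key=lambda p: (p.strand, p.signature, p.start))
    return peaks


def peak_members(
    peak: SignaturePeak, alignments: list[ConsensusAlignment]
) -> list[ConsensusAlignment]:
    """Alignments whose 5' end and signature fall inside a peak."""
    want = {"SPS": "is_sps", "ASPS": "is_asps"}[peak.signature]
    return [
        a
        for a in alignments
        if a.consensus_id == peak.consensus_id
        and a.strand == peak.strand
        and getattr(a, want)
        and peak.start <= a.five_prime < peak.end
    ]


def trace_antisense_source(
    peak_alignments: list[ConsensusAlignment],
    genome: dict[str, str],
    clusters: list[PiRNACluster],
    genome_index: MismatchIndex | None = None,
    merge_gap: int = 1000,
) -> dict:
    """Trace peak reads to their genomic source loci.

    Each peak read is re-matched to the genome with zero mismatches; reads
    with exactly one genomic position are assigned, their positions merged
    into source intervals, and the weighted fraction of the peak explained
    by each overlapping cluster is reported.
    """
    if genome_index is None:
        genome_index = MismatchIndex(genome, k=12)
    total_w = sum(a.weight for a in peak_alignments)
    seen_reads: dict[str, tuple] = {}
    for a in peak_alignments:
        if a.read_id in seen_reads:
            continue
        hits = genome_index.find(a.sequence, max_mismatch=0)
        seen_reads[a.read_id] = (a, hits)

    assigned: dict[str, list[tuple[int, int]]] = {}
    unique_w = 0.0
    cluster_w: dict[str, float] = {}
    for a, hits in seen_reads.values():
        w = sum(x.weight for x in peak_alignments if x.read_id == a.read_id)
        if len(hits) != 1:
            continue  # multi-mapping or unmatched reads are excluded
        h = hits[0]
        unique_w += w
        assigned.setdefault(h.ref, []).append((h.start, h.start + len(a.sequence)))
        for cl in clusters:
            civ = cl.interval
            if (
                civ.chrom == h.ref
                and civ.start <= h.start
                and h.start + len(a.sequence) <= civ.end
            ):
                cluster_w[cl.name] = cluster_w.get(cl.name, 0.0) + w
    if unique_w == 0.0:
        return {
            "status": "no_uniquely_mapping_reads",
            "source_intervals": {},
            "explained_fraction": 0.0,
            "cluster_fractions": {},
        }
    return {
        "status": "ok",
        "source_intervals": {
            chrom: merge_intervals(ivs, gap=merge_gap)
            for chrom, ivs in assigned.items()
        },
        "explained_fraction": unique_w / total_w if total_w else 0.0,
        "cluster_fractions": {
            name: w / total_w for name, w in sorted(cluster_w.items())
        },
    }


def consensus_discriminating_positions(
    seq_a: str, seq_b: str, start: int, end: int
) -> list[int]:
    """Positions in [start, end) where two consensuses differ (e.g. to ask
    whether a peak's reads are specific to one of two related elements)."""
    end = min(end, len(seq_a), len(seq_b))
    return [i for i in range(start, end) if seq_a[i] != seq_b[i]]
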