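"""Synthetic small-RNA study generator with a machine-readable truth ledger.

Generates a toy genome carrying planted piRNA clusters (with configurable
strand and 1U bias), genes with 3'UTR piRNA excess, piRNA-producing lncRNAs,
mobile-element copies mutated from consensus sequences, ping-pong read pairs
with exact 10-nt 5' overlaps, exact multi-mapper duplications and known
small-RNA contaminants — then emits adapter-ligated reads and a ledger
attributing every read to exactly one planted category (or background).

All randomness flows from a single integer seed; identical (config, seed)
gives byte-identical outputs.  Reads are emitted in DNA alphabet, so the
"1U" property is a leading T on the read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .core import GeneModel, GenomicInterval, MEAnnotation, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class ClusterSpec:
    length: int
    target_rpkm: float
    strand_bias: float = 0.85  # majority-strand fraction, in [0.5, 1]
    u1_bias: float = 0.8  # fraction of reads starting with U/T


@dataclass
class GeneSpec:
    utr5_len: int
    cds_len: int
    utr3_len: int
    utr3_read_count: int  # excess reads planted in the 3'UTR
    expression_level: float = 1.0
    uniform_reads_per_100bp: int = 2  # exact proportional floor
    strand: str = "+"


@dataclass
class LncRNASpec:
    exon_lengths: list[int]
    intron_lengths: list[int]
    exonic_read_count: int
    sense_fraction: float = 0.95
    strand: str = "+"


@dataclass
class MECopySpec:
    consensus_id: str
    me_class: str
    divergence: float
    strand: str = "+"
    n_fragments: int = 1  # >1 plants an interrupted copy sharing one ID


@dataclass
class PingPongSpec:
    consensus_id: str
    sense_5p_position: int
    pair_count: int
    signature: str  # 'SPS' or 'ASPS'


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 2
    library_size: int = 30_000
    clusters: list[ClusterSpec] = field(default_factory=list)
    genes: list[GeneSpec] = field(default_factory=list)
    lncrnas: list[LncRNASpec] = field(default_factory=list)
    consensus_lengths: dict[str, int] = field(default_factory=dict)
    consensus_classes: dict[str, str] = field(default_factory=dict)
    me_copies: list[MECopySpec] = field(default_factory=list)
    me_read_counts: dict[str, int] = field(default_factory=dict)
    age_ranks: dict[str, int] = field(default_factory=dict)
    pingpong_pairs: list[PingPongSpec] = field(default_factory=list)
    multimapper_copies: int = 0
    multimapper_reads: int = 0
    contaminant_count: int = 0
    n_known_rna: int = 12
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length_range: tuple[int, int] = (26, 31)

    def validate(self) -> None:
        for c in self.clusters:
            if c.length <= 0:
                raise ValueError("cluster length must be > 0")
            if not (0.5 <= c.strand_bias <= 1.0):
                raise ValueError("strand_bias must be in [0.5, 1]")
            if not (0.0 <= c.u1_bias <= 1.0):
                raise ValueError("u1_bias must be in [0, 1]")
        if self.read_length_range[0] > self.read_length_range[1]:
            raise ValueError("read_length_range must be (min, max)")


@dataclass
class GenomeBundle:
    genome: dict[str, str]
    chrom_lengths: dict[str, int]
    gene_models: list[GeneModel]
    lncrna_models: list[GeneModel]
    me_annotations: list[MEAnnotation]
    known_rna: dict[str, str]
    consensus: dict[str, str]
    expression: dict[str, float]
    age_ranks: dict[str, int]
    cluster_intervals: list[GenomicInterval]
    multimapper_segments: list[GenomicInterval]
    me_copy_map: dict[str, list[tuple[GenomicInterval, float]]]
    lncrna_specs: dict[str, LncRNASpec]
    gene_specs: dict[str, GeneSpec]


@dataclass
class SyntheticTruth:
    """Ledger of every planted feature, keyed to emitted read ids."""

    planted_clusters: list[dict]
    enriched_genes: dict[str, int]
    uniform_genes: list[str]
    pi_lncrnas: list[str]
    pingpong_pairs: list[dict]
    multimapper_reads: dict[str, int]
    contaminant_reads: list[str]
    read_category: dict[str, str]
    category_counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tcategory\n")
            for rid in sorted(self.read_category):
                fh.write(f"{rid}\t{self.read_category[rid]}\n")


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    if divergence <= 0:
        return seq
    arr = np.array(list(seq))
    n_mut = int(round(divergence * len(seq)))
    pos = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


class _Layout:
    """Sequential feature placement across chromosomes with per-feature gaps.

    Piles features onto the first chromosome with room.  The gap around a
    feature keeps sliding windows anchored on one feature from bridging to
    the next (a 5 kb window reaches at most 5 kb beyond a read's 5' end).
    """

    def __init__(self, chrom_lengths: dict[str, int], gap: int = 3000):
        self.chrom_lengths = chrom_lengths
        self.gap = gap
        self.cursors = {c: gap for c in chrom_lengths}

    def place(self, length: int, name: str, gap: int | None = None):
        gap = self.gap if gap is None else gap
        for chrom, cur in self.cursors.items():
            start = max(cur, gap)
            if start + length + gap <= self.chrom_lengths[chrom]:
                self.cursors[chrom] = start + length + gap
                return chrom, start
        raise ValueError(
            f"feature {name!r} of length {length} does not fit in the genome"
        )


def make_genome(config: SimConfig) -> GenomeBundle:
    """Build the toy genome and all annotations for *config*."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # chromosomes: n roughly equal pieces of genome_length
    per = config.genome_length // config.n_chromosomes
    chrom_lengths = {
        f"chr{i + 1}": per
        + (config.genome_length - per * config.n_chromosomes if i == 0 else 0)
        for i in range(config.n_chromosomes)
    }
    genome_arr = {
        c: np.array(list(_random_seq(rng, n)))
        for c, n in chrom_lengths.items()
    }
    layout = _Layout(chrom_lengths)

    # consensus sequences, with ping-pong diagnostic bases fixed before any
    # copy is planted so that copies inherit them
    consensus = {
        cid: list(_random_seq(rng, n))
        for cid, n in config.consensus_lengths.items()
    }
    for pp in config.pingpong_pairs:
        seq = consensus[pp.consensus_id]
        s = pp.sense_5p_position
        if pp.signature == "SPS":
            seq[s] = "T"  # sense 1U == antisense 10A (same consensus base)
            seq[s + 9] = "C"  # suppress the ASPS diagnostic
        elif pp.signature == "ASPS":
            seq[s + 9] = "A"  # sense 10A == antisense 1U
            seq[s] = "G"  # suppress the SPS diagnostic
        else:
            raise ValueError(f"unknown signature {pp.signature!r}")
    consensus = {cid: "".join(seq) for cid, seq in consensus.items()}

    cluster_intervals = []
    for i, spec in enumerate(config.clusters):
        # wide berth so each planted cluster is resolvable by 5 kb windows
        chrom, start = layout.place(spec.length, f"cluster_{i + 1}", gap=12000)
        cluster_intervals.append(
            GenomicInterval(chrom, start, start + spec.length, ".")
        )

    gene_models, gene_specs, expression = [], {}, {}
    for i, g in enumerate(config.genes):
        total = g.utr5_len + g.cds_len + g.utr3_len
        gid = f"gene_{i + 1}"
        chrom, start = layout.place(total, gid)
        iv = lambda a, b: GenomicInterval(chrom, a, b, g.strand)  # noqa: E731
        if g.strand == "+":
            utr5 = [iv(start, start + g.utr5_len)]
            cds = [iv(start + g.utr5_len, start + g.utr5_len + g.cds_len)]
            utr3 = [iv(start + g.utr5_len + g.cds_len, start + total)]
        else:
            utr3 = [iv(start, start + g.utr3_len)]
            cds = [iv(start + g.utr3_len, start + g.utr3_len + g.cds_len)]
            utr5 = [iv(start + g.utr3_len + g.cds_len, start + total)]
        gene_models.append(
            GeneModel(gid, f"{gid}.t1", g.strand, utr5, cds, utr3)
        )
        gene_specs[gid] = g
        expression[gid] = g.expression_level

    lncrna_models, lncrna_specs = [], {}
    for i, l in enumerate(config.lncrnas):
        lid = f"lnc_{i + 1}"
        total = sum(l.exon_lengths) + sum(l.intron_lengths)
        chrom, start = layout.place(total, lid)
        exons, pos = [], start
        for j, elen in enumerate(l.exon_lengths):
            exons.append(GenomicInterval(chrom, pos, pos + elen, l.strand))
            pos += elen
            if j < len(l.intron_lengths):
                pos += l.intron_lengths[j]
        # non-coding: whole exon set modelled as 'cds-free' 3'UTR-less model
        lncrna_models.append(
            GeneModel(lid, f"{lid}.t1", l.strand, utr5=exons, cds=[], utr3=[])
        )
        lncrna_specs[lid] = l

    me_annotations, me_copy_map = [], {}
    next_repeat_id = 1
    for spec in config.me_copies:
        cons = consensus[spec.consensus_id]
        copy_seq = _mutate(rng, cons, spec.divergence)
        placed = copy_seq if spec.strand == "+" else revcomp(copy_seq)
        repeat_id = next_repeat_id
        next_repeat_id += 1
        n_frag = max(1, spec.n_fragments)
        frag_bounds = np.linspace(0, len(cons), n_frag + 1).astype(int)
        for f in range(n_frag):
            lo, hi = int(frag_bounds[f]), int(frag_bounds[f + 1])
            frag = placed[lo:hi]
            chrom, start = layout.place(
                len(frag), f"{spec.consensus_id}_copy{repeat_id}"
            )
            genome_arr[chrom][start : start + len(frag)] = list(frag)
            iv = GenomicInterval(chrom, start, start + len(frag), spec.strand)
            me_annotations.append(
                MEAnnotation(
                    interval=iv,
                    subfamily=spec.consensus_id,
                    me_class=config.consensus_classes.get(
                        spec.consensus_id, "LTR"
                    ),
                    repeat_id=repeat_id,
                    consensus_span=(lo, hi),
                )
            )
            me_copy_map.setdefault(spec.consensus_id, []).append(
                (iv, spec.divergence)
            )

    multimapper_segments = []
    if config.multimapper_copies > 1:
        seg = _random_seq(rng, 80)
        for i in range(config.multimapper_copies):
            chrom, start = layout.place(len(seg), f"multimap_copy_{i + 1}")
            genome_arr[chrom][start : start + len(seg)] = list(seg)
            multimapper_segments.append(
                GenomicInterval(chrom, start, start + len(seg), "+")
            )

    known_rna = {
        f"known_rna_{i + 1}": _random_seq(rng, int(rng.integers(28, 80)))
        for i in range(config.n_known_rna)
    }
    return GenomeBundle(
        genome={c: "".join(a) for c, a in genome_arr.items()},
        chrom_lengths=chrom_lengths,
        gene_models=gene_models,
        lncrna_models=lncrna_models,
        me_annotations=me_annotations,
        known_rna=known_rna,
        consensus=consensus,
        expression=expression,
        age_ranks=dict(config.age_ranks),
        cluster_intervals=cluster_intervals,
        multimapper_segments=multimapper_segments,
        me_copy_map=me_copy_map,
        lncrna_specs=lncrna_specs,
        gene_specs=gene_specs,
    )


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

def _read_from_genome(
    genome: dict[str, str], chrom: str, five_prime: int, length: int,
    strand: str,
) -> str:
    if strand == "+":
        return genome[chrom][five_prime : five_prime + length]
    return revcomp(genome[chrom][five_prime - length + 1 : five_prime + 1])


def _cluster_reads(
    rng, genome, iv: GenomicInterval, spec: ClusterSpec, count: int,
    lmin: int, lmax: int, warnings: list[str],
) -> list[str]:
    """Cluster reads with the configured strand and 1U bias.

    1U is imposed by drawing 5' positions whose genomic base is T on the
    read strand; if an interval has no such base the draw falls back to any
    position and a warning is recorded.
    """
    chrom = iv.chrom
    seq = genome[chrom]
    margin = lmax
    lo, hi = iv.start + margin, iv.end - margin
    positions = np.arange(lo, hi)
    plus_u = positions[np.frombuffer(
        seq[lo:hi].encode(), dtype=np.uint8) == ord("T")]
    minus_u = positions[np.frombuffer(
        seq[lo:hi].encode(), dtype=np.uint8) == ord("A")]
    plus_not = np.setdiff1d(positions, plus_u)
    minus_not = np.setdiff1d(positions, minus_u)
    reads = []
    for _ in range(count):
        strand = "+" if rng.random() < spec.strand_bias else "-"
        want_u = rng.random() < spec.u1_bias
        if strand == "+":
            pool = plus_u if want_u else plus_not
        else:
            pool = minus_u if want_u else minus_not
        if len(pool) == 0:
            warnings.append(
                f"cluster at {chrom}:{iv.start}: no "
                f"{'1U' if want_u else 'non-1U'} start on {strand}; "
                "best-effort placement"
            )
            pool = positions
        p5 = int(pool[rng.integers(0, len(pool))])
        length = int(rng.integers(lmin, lmax + 1))
        reads.append(_read_from_genome(genome, chrom, p5, length, strand))
    return reads


def make_reads(
    config: SimConfig, bundle: GenomeBundle
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Emit adapter-ligated reads and the complete truth ledger."""
    rng = np.random.default_rng(config.seed + 1)
    lmin, lmax = config.read_length_range
    genome = bundle.genome
    warnings: list[str] = []

    # (sequence, category, meta) triples; ids assigned after shuffling
    pending: list[tuple[str, str, dict]] = []

    planted_clusters = []
    for iv, spec in zip(bundle.cluster_intervals, config.clusters):
        count = int(round(
            spec.target_rpkm * (spec.length / 1000.0)
            * (config.library_size / 1e6)
        ))
        for seq in _cluster_reads(
            rng, genome, iv, spec, count, lmin, lmax, warnings
        ):
            pending.append((seq, "cluster", {}))
        planted_clusters.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "read_count": count,
                "target_rpkm": spec.target_rpkm,
                "strand_bias": spec.strand_bias,
                "u1_bias": spec.u1_bias,
            }
        )

    enriched_genes, uniform_genes = {}, []
    for model in bundle.gene_models:
        g = bundle.gene_specs[model.gene_id]
        # exact proportional floor: reads per region = len/100 * density
        for region in ("utr5", "cds", "utr3"):
            riv = getattr(model, region)[0]
            c = (len(riv) // 100) * g.uniform_reads_per_100bp
            if c == 0:
                continue
            span = len(riv) - lmax
            for j in range(c):
                start = riv.start + (j * span) // max(c, 1)
                length = int(rng.integers(lmin, lmax + 1))
                p5 = start if g.strand == "+" else start + length - 1
                pending.append(
                    (
                        _read_from_genome(
                            genome, riv.chrom, p5, length, g.strand
                        ),
                        "genic",
                        {},
                    )
                )
        if g.utr3_read_count > 0:
            riv = model.utr3[0]
            for _ in range(g.utr3_read_count):
                length = int(rng.integers(lmin, lmax + 1))
                start = int(rng.integers(riv.start, riv.end - length + 1))
                p5 = start if g.strand == "+" else start + length - 1
                pending.append(
                    (
                        _read_from_genome(
                            genome, riv.chrom, p5, length, g.strand
                        ),
                        "genic",
                        {},
                    )
                )
            enriched_genes[model.gene_id] = g.utr3_read_count
        else:
            uniform_genes.append(model.gene_id)

    pi_lncrnas = []
    for model in bundle.lncrna_models:
        spec = bundle.lncrna_specs[model.gene_id]
        exons = model.exons
        for _ in range(spec.exonic_read_count):
            sense = rng.random() < spec.sense_fraction
            ex = exons[int(rng.integers(0, len(exons)))]
            length = int(rng.integers(lmin, lmax + 1))
            start = int(rng.integers(ex.start, ex.end - length + 1))
            strand = spec.strand if sense else ("-" if spec.strand == "+" else "+")
            p5 = start if strand == "+" else start + length - 1
            pending.append(
                (
                    _read_from_genome(genome, ex.chrom, p5, length, strand),
                    "lncrna",
                    {},
                )
            )
        if spec.exonic_read_count >= 10 and spec.sense_fraction >= 0.5:
            pi_lncrnas.append(model.gene_id)

    # antisense ME-derived piRNAs per subfamily (age-density structure)
    for subfamily, count in config.me_read_counts.items():
        copies = [
            (iv, d) for iv, d in bundle.me_copy_map.get(subfamily, [])
            if d == 0.0
        ]
        if not copies:
            raise ValueError(
                f"me_read_counts for {subfamily!r} requires a divergence-0 copy"
            )
        for _ in range(count):
            iv, _d = copies[int(rng.integers(0, len(copies)))]
            length = int(rng.integers(lmin, lmax + 1))
            start = int(rng.integers(iv.start, iv.end - length + 1))
            strand = "-" if iv.strand == "+" else "+"  # antisense to the ME
            p5 = start if strand == "+" else start + length - 1
            pending.append(
                (
                    _read_from_genome(genome, iv.chrom, p5, length, strand),
                    "me",
                    {},
                )
            )

    # ping-pong pairs on consensus coordinates, realised on the genome via a
    # divergence-0 '+'-strand copy so the reads survive genome mapping
    pingpong_truth = []
    for pp in config.pingpong_pairs:
        copies = [
            (iv, d)
            for iv, d in bundle.me_copy_map.get(pp.consensus_id, [])
            if d == 0.0 and iv.strand == "+"
        ]
        if not copies:
            raise ValueError(
                f"ping-pong pairs on {pp.consensus_id!r} require a "
                "divergence-0 '+' strand copy"
            )
        copy_iv = copies[0][0]
        s = pp.sense_5p_position
        for _ in range(pp.pair_count):
            l1 = int(rng.integers(lmin, lmax + 1))
            l2 = int(rng.integers(lmin, lmax + 1))
            g5_sense = copy_iv.start + s
            g5_anti = copy_iv.start + s + 9
            sense_seq = _read_from_genome(
                genome, copy_iv.chrom, g5_sense, l1, "+"
            )
            anti_seq = _read_from_genome(
                genome, copy_iv.chrom, g5_anti, l2, "-"
            )
            pending.append((sense_seq, "pingpong", {"role": "sense", "pp": pp}))
            pending.append((anti_seq, "pingpong", {"role": "antisense", "pp": pp}))
        pingpong_truth.append(
            {
                "consensus_id": pp.consensus_id,
                "sense_5p": s,
                "antisense_5p": s + 9,
                "signature": pp.signature,
                "pair_count": pp.pair_count,
            }
        )

    multimapper_meta = []
    if config.multimapper_reads > 0 and bundle.multimapper_segments:
        seg = bundle.multimapper_segments[0]
        for _ in range(config.multimapper_reads):
            length = int(rng.integers(lmin, lmax + 1))
            start = int(rng.integers(seg.start, seg.end - length + 1))
            seq = genome[seg.chrom][start : start + length]
            pending.append((seq, "multimapper", {}))
            multimapper_meta.append(len(bundle.multimapper_segments))

    for _ in range(config.contaminant_count):
        entry = list(bundle.known_rna.values())[
            int(rng.integers(0, len(bundle.known_rna)))
        ]
        length = min(len(entry), int(rng.integers(lmin, lmax + 1)))
        start = int(rng.integers(0, len(entry) - length + 1))
        seq = list(entry[start : start + length])
        if rng.random() < 0.5:  # +- 1 mutation
            p = int(rng.integers(0, len(seq)))
            seq[p] = "ACGT"[(("ACGT".index(seq[p]) + 1) % 4)]
        pending.append(("".join(seq), "contaminant", {}))

    n_background = config.library_size - len(pending)
    if n_background < 0:
        raise ValueError(
            f"planted reads ({len(pending)}) exceed library_size "
            f"({config.library_size})"
        )
    chroms = list(bundle.chrom_lengths)
    for _ in range(n_background):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(lmin, lmax + 1))
        start = int(rng.integers(0, bundle.chrom_lengths[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        p5 = start if strand == "+" else start + length - 1
        pending.append(
            (_read_from_genome(genome, chrom, p5, length, strand),
             "background", {})
        )

    order = rng.permutation(len(pending))
    reads: list[tuple[str, str]] = []
    read_category: dict[str, str] = {}
    multimapper_reads: dict[str, int] = {}
    contaminant_reads: list[str] = []
    mm_copies = len(bundle.multimapper_segments)
    pp_read_ids: dict[int, list[str]] = {}
    for out_idx, idx in enumerate(order):
        seq, category, meta = pending[idx]
        rid = f"read_{out_idx + 1:06d}"
        reads.append((rid, seq + config.adapter))
        read_category[rid] = category
        if category == "multimapper":
            multimapper_reads[rid] = mm_copies
        elif category == "contaminant":
            contaminant_reads.append(rid)
        elif category == "pingpong":
            pp_read_ids.setdefault(
                id(meta["pp"]), []
            ).append(rid)
    for rec, pp in zip(pingpong_truth, config.pingpong_pairs):
        rec["read_ids"] = pp_read_ids.get(id(pp), [])

    counts: dict[str, int] = {}
    for cat in read_category.values():
        counts[cat] = counts.get(cat, 0) + 1
    truth = SyntheticTruth(
        planted_clusters=planted_clusters,
        enriched_genes=enriched_genes,
        uniform_genes=uniform_genes,
        pi_lncrnas=pi_lncrnas,
        pingpong_pairs=pingpong_truth,
        multimapper_reads=multimapper_reads,
        contaminant_reads=contaminant_reads,
        read_category=read_category,
        category_counts=counts,
        warnings=warnings,
    )
    return reads, truth


# ---------------------------------------------------------------------------
# default study configuration and file emission
# ---------------------------------------------------------------------------

def default_config(seed: int = 0) -> SimConfig:
    """The default synthetic study: a 1 Mb two-chromosome genome, a 30k-read
    library, ten strong clusters absorbing ~86% of reads, 3'UTR-enriched and
    uniform genes, pi-lncRNAs, six LTR subfamilies with density increasing
    toward young ranks, ping-pong peaks on two consensuses, one exact
    8-copy multi-mapper segment and ~5% uniform background."""
    cluster_lengths = [8000, 10000, 12000, 6000, 9000, 11000, 7000, 10000,
                       8000, 9000]
    strand_biases = [0.80, 0.85, 0.90, 0.95, 1.00, 0.82, 0.88, 0.92, 0.86,
                     0.84]
    u1_biases = [0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.78, 0.82, 0.88, 0.92]
    ltr_subfamilies = [f"LTR_SIM{i}" for i in range(1, 7)]
    consensus_lengths = {
        "LTR1_SIM": 1400,
        "HERVK_SIM": 1200,
        "ALU_SIM": 300,
        "L1_SIM": 1500,
        "MER_SIM": 800,
        **{sf: 500 for sf in ltr_subfamilies},
    }
    consensus_classes = {
        "LTR1_SIM": "LTR",
        "HERVK_SIM": "LTR",
        "ALU_SIM": "SINE",
        "L1_SIM": "LINE",
        "MER_SIM": "DNA",
        **{sf: "LTR" for sf in ltr_subfamilies},
    }
    me_copies = [
        MECopySpec("LTR1_SIM", "LTR", 0.0, "+"),
        MECopySpec("LTR1_SIM", "LTR", 0.15, "-"),
        MECopySpec("HERVK_SIM", "LTR", 0.0, "+"),
        MECopySpec("ALU_SIM", "SINE", 0.08, "+"),
        MECopySpec("ALU_SIM", "SINE", 0.10, "-"),
        MECopySpec("ALU_SIM", "SINE", 0.12, "+"),
        MECopySpec("L1_SIM", "LINE", 0.05, "+"),
        MECopySpec("L1_SIM", "LINE", 0.06, "+", n_fragments=2),
        MECopySpec("MER_SIM", "DNA", 0.15, "+"),
        *[MECopySpec(sf, "LTR", 0.0, "+") for sf in ltr_subfamilies],
    ]
    genes = [
        *[
            GeneSpec(300, 900, 600, utr3_read_count=60,
                     expression_level=float(5 + i),
                     strand="+" if i % 2 == 0 else "-")
            for i in range(12)
        ],
        *[
            GeneSpec(300, 900, 600, utr3_read_count=0,
                     expression_level=float(3 + i),
                     strand="+" if i % 2 == 0 else "-")
            for i in range(8)
        ],
    ]
    lncrnas = [
        *[
            LncRNASpec([600, 500], [400], exonic_read_count=90,
                       sense_fraction=0.95,
                       strand="+" if i % 2 == 0 else "-")
            for i in range(6)
        ],
        *[
            LncRNASpec([600, 500], [400], exonic_read_count=3,
                       sense_fraction=0.95, strand="+")
            for i in range(4)
        ],
    ]
    return SimConfig(
        seed=seed,
        genome_length=1_000_000,
        n_chromosomes=2,
        library_size=30_000,
        clusters=[
            ClusterSpec(l, 9600.0, sb, ub)
            for l, sb, ub in zip(cluster_lengths, strand_biases, u1_biases)
        ],
        genes=genes,
        lncrnas=lncrnas,
        consensus_lengths=consensus_lengths,
        consensus_classes=consensus_classes,
        me_copies=me_copies,
        me_read_counts={
            sf: c for sf, c in zip(ltr_subfamilies, [5, 10, 15, 20, 30, 50])
        },
        age_ranks={sf: i + 1 for i, sf in enumerate(ltr_subfamilies)},
        pingpong_pairs=[
            PingPongSpec("LTR1_SIM", 400, 40, "SPS"),
            PingPongSpec("LTR1_SIM", 440, 35, "SPS"),
            PingPongSpec("LTR1_SIM", 470, 30, "ASPS"),
            PingPongSpec("HERVK_SIM", 200, 25, "SPS"),
        ],
        multimapper_copies=8,
        multimapper_reads=60,
        contaminant_count=100,
    )


def write_bundle(bundle: GenomeBundle, outdir) -> dict[str, Path]:
    """Write the genome bundle in its external dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.bed12",
        "lncrna": outdir / "lncrna.bed12",
        "rmsk": outdir / "repeats.out",
        "known_rna": outdir / "known_rna.fa",
        "consensus": outdir / "consensus.fa",
        "expression": outdir / "expression.tsv",
        "ages": outdir / "age_ranks.tsv",
    }
    pio.write_fasta(bundle.genome, paths["genome"])
    pio.write_gene_models_bed12(bundle.gene_models, paths["genes"])
    pio.write_gene_models_bed12(bundle.lncrna_models, paths["lncrna"])
    pio.write_repeatmasker_out(bundle.me_annotations, paths["rmsk"])
    pio.write_fasta(bundle.known_rna, paths["known_rna"])
    pio.write_fasta(bundle.consensus, paths["consensus"])
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\texpression\n")
        for gid in sorted(bundle.expression):
            fh.write(f"{gid}\t{bundle.expression[gid]}\n")
    with open(paths["ages"], "w") as fh:
        fh.write("subfamily\tage_rank\n")
        for sf in sorted(bundle.age_ranks):
            fh.write(f"{sf}\t{bundle.age_ranks[sf]}\n")
    return paths
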