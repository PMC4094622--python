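"""Genome-wide mobile-element piRNA accounting.

Counts weighted piRNAs per ME subfamily (a read counts iff its mapping
position lies entirely within one annotated fragment), computes per-kb
densities and the age-rank vs density Spearman correlation per class, and
measures ME enrichment within lncRNA exons against genome-wide abundance
with binomial / hypergeometric / Poisson tail tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, MEAnnotation, WeightedAlignment, merge_intervals

MIN_OVERLAP = 10  # bp of exon-ME intersection required to keep a fragment


@dataclass
class SubfamilyDensity:
    subfamily: str
    me_class: str
    sense_count: float
    antisense_count: float
    genomic_bp: int
    age_rank: int | None = None

    @property
    def weighted_count(self) -> float:
        return self.sense_count + self.antisense_count

    @property
    def density(self) -> float:
        """Weighted piRNAs per kb of subfamily genomic sequence."""
        if self.genomic_bp == 0:
            return 0.0
        return self.weighted_count / (self.genomic_bp / 1000.0)


@dataclass
class MEEnrichmentRow:
    subfamily: str
    me_class: str
    in_set_count: int
    in_set_bp: int
    in_genome_count: int
    in_genome_bp: int
    ratio: float
    p_binomial: float
    p_hypergeometric: float
    p_poisson: float
    q_binomial: float | None = None


def count_me_pirnas(
    alignments: list[WeightedAlignment],
    annotations: list[MEAnnotation],
    age_ranks: dict[str, int] | None = None,
) -> list[SubfamilyDensity]:
    """Per-subfamily weighted piRNA counts and densities.

    A read contributes its weight to a subfamily iff its interval is
    entirely within one annotated fragment; a multi-mapper contributes each
    of its positions independently.  Sense/antisense is relative to the ME
    strand.
    """
    trees: dict[str, IntervalTree] = {}
    for ann in annotations:
        iv = ann.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, ann)

    acc: dict[str, SubfamilyDensity] = {}
    for ann in annotations:
        sd = acc.get(ann.subfamily)
        if sd is None:
            acc[ann.subfamily] = sd = SubfamilyDensity(
                ann.subfamily, ann.me_class, 0.0, 0.0, 0
            )
        sd.genomic_bp += len(ann.interval)

    for a in alignments:
        tree = trees.get(a.interval.chrom)
        if tree is None:
            continue
        hit_subfamilies: set[str] = set()
        for node in tree.overlap(a.interval.start, a.interval.end):
            ann: MEAnnotation = node.data
            if ann.interval.contains(a.interval):
                # a position inside overlapping copies of the same subfamily
                # counts once; different subfamilies each get the weight
                if ann.subfamily in hit_subfamilies:
                    continue
                hit_subfamilies.add(ann.subfamily)
                sd = acc[ann.subfamily]
                if a.interval.strand == ann.interval.strand:
                    sd.sense_count += a.weight
                else:
                    sd.antisense_count += a.weight
    out = sorted(acc.values(), key=lambda sd: sd.subfamily)
    if age_ranks:
        for sd in out:
            sd.age_rank = age_ranks.get(sd.subfamily)
    return out


def age_density_correlation(
    densities: list[SubfamilyDensity], min_subfamilies: int = 5
) -> dict[str, dict]:
    """Spearman correlation of age rank (1 = oldest) vs piRNA density.

    Computed per ME class over subfamilies carrying an age rank; ties get
    average ranks; constant vectors give an undefined correlation.
    """
    by_class: dict[str, list[SubfamilyDensity]] = {}
    for sd in densities:
        if sd.age_rank is not None:
            by_class.setdefault(sd.me_class, []).append(sd)
    out: dict[str, dict] = {}
    for me_class, sds in sorted(by_class.items()):
        if len(sds) < min_subfamilies:
            out[me_class] = {"status": "too_few_subfamilies", "n": len(sds)}
            continue
        ranks = [sd.age_rank for sd in sds]
        dens = [sd.density for sd in sds]
        if len(set(dens)) == 1 or len(set(ranks)) == 1:
            out[me_class] = {"status": "undefined_constant", "n": len(sds)}
            continue
        rho, p = stats.spearmanr(ranks, dens)
        out[me_class] = {
            "status": "ok", "n": len(sds), "rho": float(rho), "p": float(p)
        }
    return out


def lncrna_me_enrichment(
    lncrna_models: list[GeneModel],
    annotations: list[MEAnnotation],
    genome_size: int,
    bh_correction: bool = False,
) -> list[MEEnrichmentRow]:
    """ME subfamily enrichment within lncRNA exons vs genome-wide abundance.

    Exon-ME intersections shorter than 10 bp are discarded; fragments
    sharing a repeat ID count once (in the set and in the genome); bp are
    corrected for overlaps between MEs of a subfamily; non-ME repeat classes
    are excluded.  The ratio is (in-set count proportion)/(in-genome count
    proportion); enrichment p-values are upper tails on counts.
    """
    exon_ivs: dict[str, list[tuple[int, int]]] = {}
    for model in lncrna_models:
        for ex in model.exons:
            exon_ivs.setdefault(ex.chrom, []).append((ex.start, ex.end))
    exon_ivs = {c: merge_intervals(v) for c, v in exon_ivs.items()}

    me_anns = [a for a in annotations if a.is_mobile_element]

    genome_ids: dict[str, set[int]] = {}
    genome_bp_ivs: dict[str, dict[str, list[tuple[int, int]]]] = {}
    set_ids: dict[str, set[int]] = {}
    set_bp_ivs: dict[str, dict[str, list[tuple[int, int]]]] = {}
    classes: dict[str, str] = {}

    for ann in me_anns:
        sf = ann.subfamily
        classes[sf] = ann.me_class
        genome_ids.setdefault(sf, set()).add(ann.repeat_id)
        genome_bp_ivs.setdefault(sf, {}).setdefault(
            ann.interval.chrom, []
        ).append((ann.interval.start, ann.interval.end))
        for es, ee in exon_ivs.get(ann.interval.chrom, ()):
            lo = max(es, ann.interval.start)
            hi = min(ee, ann.interval.end)
            if hi - lo >= MIN_OVERLAP:
                set_ids.setdefault(sf, set()).add(ann.repeat_id)
                set_bp_ivs.setdefault(sf, {}).setdefault(
                    ann.interval.chrom, []
                ).append((lo, hi))

    def union_bp(ivs_by_chrom) -> int:
        return sum(
            e - s
            for ivs in ivs_by_chrom.values()
            for s, e in merge_intervals(ivs)
        )

    total_set = sum(len(ids) for ids in set_ids.values())
    total_genome = sum(len(ids) for ids in genome_ids.values())
    rows: list[MEEnrichmentRow] = []
    for sf in sorted(genome_ids):
        k_set = len(set_ids.get(sf, ()))
        k_gen = len(genome_ids[sf])
        p_gen = k_gen / total_genome if total_genome else 0.0
        prop_set = k_set / total_set if total_set else 0.0
        ratio = prop_set / p_gen if p_gen > 0 else 0.0
        if total_set > 0 and p_gen > 0:
            p_bin = float(stats.binom.sf(k_set - 1, total_set, p_gen))
            p_hyp = float(
                stats.hypergeom.sf(k_set - 1, total_genome, k_gen, total_set)
            )
            p_poi = float(stats.poisson.sf(k_set - 1, total_set * p_gen))
        else:
            p_bin = p_hyp = p_poi = 1.0
        rows.append(
            MEEnrichmentRow(
                subfamily=sf,
                me_class=classes[sf],
                in_set_count=k_set,
                in_set_bp=union_bp(set_bp_ivs.get(sf, {})),
                in_genome_count=k_gen,
                in_genome_bp=union_bp(genome_bp_ivs[sf]),
                ratio=ratio,
                p_binomial=p_bin,
                p_hypergeometric=p_hyp,
                p_poisson=p_poi,
            )
        )
    if bh_correction and rows:
        from statsmodels.stats.multitest import multipletests

        q = multipletests([r.p_binomial for r in rows], method="fdr_bh")[1]
        for r, qv in zip(rows, q):
            r.q_binomial = float(qv)
    return rows


def class_proportions(
    densities: list[SubfamilyDensity],
) -> dict[str, dict[str, float]]:
    """Per-class shares of genomic ME bp and of ME-derived piRNA weight.

    Both vectors sum to 1 over classes (given any ME bp / ME piRNAs exist).
    """
    bp_total = sum(sd.genomic_bp for sd in densities)
    w_total = sum(sd.weighted_count for sd in densities)
    out: dict[str, dict[str, float]] = {}
    for sd in densities:
        d = out.setdefault(
            sd.me_class, {"genome_fraction": 0.0, "pirna_fraction": 0.0}
        )
        if bp_total:
            d["genome_fraction"] += sd.genomic_bp / bp_total
        if w_total:
            d["pirna_fraction"] += sd.weighted_count / w_total
    return out
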