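"""lncRNA piRNA-precursor candidate scoring.

Only sense-strand piRNAs fully contained in a lncRNA's exon union count.
Per lncRNA we report the exonic RPKM (weighted count per kb of exon per
million mapped piRNAs), the non-exonic RPKM over the gene span minus exons,
and exonic base coverage.  Candidates are selected on a grid of
(RPKM cutoff, coverage cutoff) pairs: RPKM closed (>=), coverage strict (>).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import GeneModel, WeightedAlignment, merge_intervals, union_length


@dataclass
class LncRNAScore:
    lncrna_id: str
    exonic_rpkm: float
    nonexonic_rpkm: float
    coverage: float
    weighted_count: float
    u1_fraction: float


def _rpkm(count: float, length_bp: int, total_weighted: float) -> float:
    if length_bp == 0:
        return 0.0
    return count / (length_bp / 1000.0) / (total_weighted / 1e6)


def score_lncrnas(
    alignments: list[WeightedAlignment],
    lncrna_models: list[GeneModel],
    total_weighted: float | None = None,
) -> list[LncRNAScore]:
    """Score every lncRNA model; zero-exon models are skipped."""
    if total_weighted is None:
        total_weighted = sum(a.weight for a in alignments)
    if total_weighted <= 0:
        raise ValueError("total_weighted must be > 0")
    by_chrom: dict[str, list[WeightedAlignment]] = {}
    for a in alignments:
        by_chrom.setdefault(a.interval.chrom, []).append(a)

    scores: list[LncRNAScore] = []
    for model in lncrna_models:
        exons = model.exons  # already merged
        if not exons:
            continue
        exon_len = sum(len(iv) for iv in exons)
        if exon_len == 0:
            continue
        chrom = model.chrom
        span_lo, span_hi = exons[0].start, exons[-1].end
        introns = []
        for prev, nxt in zip(exons, exons[1:]):
            if prev.end < nxt.start:
                introns.append((prev.end, nxt.start))
        intron_len = sum(e - s for s, e in introns)

        exonic_w = 0.0
        u1_w = 0.0
        intronic_w = 0.0
        covered: list[tuple[int, int]] = []
        for a in by_chrom.get(chrom, ()):
            iv = a.interval
            if iv.end <= span_lo or iv.start >= span_hi:
                continue
            if iv.strand != model.strand:
                continue
            if any(ex.contains(iv) for ex in exons):
                exonic_w += a.weight
                covered.append((iv.start, iv.end))
                if a.first_base in "TU":
                    u1_w += a.weight
            elif any(s <= iv.start and iv.end <= e for s, e in introns):
                intronic_w += a.weight
        covered_bp = union_length(covered)
        scores.append(
            LncRNAScore(
                lncrna_id=model.gene_id,
                exonic_rpkm=_rpkm(exonic_w, exon_len, total_weighted),
                nonexonic_rpkm=_rpkm(intronic_w, intron_len, total_weighted),
                coverage=covered_bp / exon_len,
                weighted_count=exonic_w,
                u1_fraction=u1_w / exonic_w if exonic_w > 0 else 0.0,
            )
        )
    return scores


def select_pi_lncrnas(
    scores: list[LncRNAScore],
    rpkm_cutoff: float,
    coverage_cutoff: float,
    total_weighted: float | None = None,
) -> tuple[list[LncRNAScore], dict]:
    """Apply one (RPKM, coverage) threshold pair and summarise the selection.

    Selected iff ``exonic_rpkm >= rpkm_cutoff`` and
    ``coverage > coverage_cutoff``.
    """
    selected = [
        s for s in scores
        if s.exonic_rpkm >= rpkm_cutoff and s.coverage > coverage_cutoff
    ]
    count = sum(s.weighted_count for s in selected)
    u1 = sum(s.u1_fraction * s.weighted_count for s in selected)
    summary = {
        "rpkm_cutoff": rpkm_cutoff,
        "coverage_cutoff": coverage_cutoff,
        "n_selected": len(selected),
        "weighted_pirnas_captured": count,
        "pct_of_total_pirnas": 100.0 * count / total_weighted
        if total_weighted else None,
        "pooled_u1_fraction": u1 / count if count > 0 else None,
    }
    return selected, summary


def threshold_grid(
    scores: list[LncRNAScore],
    rpkm_cutoffs=(1.0, 3.0, 10.0),
    coverage_cutoffs=(0.5, 0.7),
    total_weighted: float | None = None,
) -> list[dict]:
    """The candidate-count summary over the full threshold grid."""
    return [
        select_pi_lncrnas(scores, r, c, total_weighted)[1]
        for r in rpkm_cutoffs
        for c in coverage_cutoffs
    ]
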