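"""Genic piRNA accounting and the 3'UTR enrichment statistic.

A read is genic iff it lies entirely within the exon union of a transcript
on the transcript's strand; per gene the isoform with the largest weighted
count is kept.  The normalised enrichment of a region is

    e_region = (n_region / n_gene) / (l_region / l_gene)

so counts proportional to lengths give e = 1 everywhere, and the
length-weighted average of e over regions is identically 1.  A gene is
3'UTR-enriched when e_utr3 exceeds both e_cds and e_utr5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GeneModel, WeightedAlignment


@dataclass
class GenicCounts:
    """Weighted piRNA counts and lengths per region of a chosen isoform."""

    gene_id: str
    transcript_id: str
    n_utr5: float
    n_cds: float
    n_utr3: float
    l_utr5: int
    l_cds: int
    l_utr3: int

    @property
    def n_gene(self) -> float:
        return self.n_utr5 + self.n_cds + self.n_utr3

    @property
    def l_gene(self) -> int:
        return self.l_utr5 + self.l_cds + self.l_utr3


@dataclass
class RegionEnrichment:
    e_utr5: float | None
    e_cds: float | None
    e_utr3: float | None
    is_3utr_enriched: bool


def _contained_region(aln: WeightedAlignment, model: GeneModel) -> str | None:
    """Region name if *aln* is genic for this transcript, else None.

    Genic means: same strand, read entirely inside the exon union.  The
    region is taken at the read's 5' end when the read straddles a region
    junction within one exon.
    """
    iv = aln.interval
    if iv.strand != model.strand:
        return None
    if not any(ex.contains(iv) for ex in model.exons):
        return None
    p5 = aln.five_prime
    for region in ("utr5", "cds", "utr3"):
        for riv in getattr(model, region):
            if riv.start <= p5 < riv.end:
                return region
    return None


def assign_genic(
    alignments: list[WeightedAlignment], gene_models: list[GeneModel]
) -> tuple[dict[str, GenicCounts], float]:
    """Per-gene weighted region counts, choosing the best isoform.

    Returns ``(counts by gene_id, antisense_exonic_weight)`` — the second
    term tallies reads inside exon unions but on the opposite strand, which
    are not genic.
    """
    by_chrom: dict[str, list[WeightedAlignment]] = {}
    for a in alignments:
        by_chrom.setdefault(a.interval.chrom, []).append(a)

    per_transcript: dict[str, GenicCounts] = {}
    antisense = 0.0
    seen_antisense: set[tuple[str, str]] = set()
    for model in gene_models:
        exons = model.exons
        if not exons:
            continue
        chrom = model.chrom
        lo, hi = exons[0].start, exons[-1].end
        n = {"utr5": 0.0, "cds": 0.0, "utr3": 0.0}
        for a in by_chrom.get(chrom, ()):
            iv = a.interval
            if iv.end <= lo or iv.start >= hi:
                continue
            region = _contained_region(a, model)
            if region is not None:
                n[region] += a.weight
            elif iv.strand != model.strand and any(
                ex.contains(iv) for ex in exons
            ):
                key = (a.read_id, f"{iv.chrom}:{iv.start}:{iv.strand}")
                if key not in seen_antisense:
                    seen_antisense.add(key)
                    antisense += a.weight
        per_transcript[model.transcript_id] = GenicCounts(
            gene_id=model.gene_id,
            transcript_id=model.transcript_id,
            n_utr5=n["utr5"],
            n_cds=n["cds"],
            n_utr3=n["utr3"],
            l_utr5=model.region_length("utr5"),
            l_cds=model.region_length("cds"),
            l_utr3=model.region_length("utr3"),
        )

    best: dict[str, GenicCounts] = {}
    for gc in per_transcript.values():
        cur = best.get(gc.gene_id)
        if cur is None or gc.n_gene > cur.n_gene:
            best[gc.gene_id] = gc
    return best, antisense


def region_enrichment(counts: GenicCounts) -> RegionEnrichment:
    """The normalised per-region enrichment statistic for one gene."""
    if counts.n_gene <= 0:
        raise ValueError(f"gene {counts.gene_id} has no piRNAs (n_gene = 0)")
    e = {}
    for region in ("utr5", "cds", "utr3"):
        l_region = getattr(counts, f"l_{region}")
        if l_region == 0:
            e[region] = None  # undefined; excluded from the comparison
            continue
        n_region = getattr(counts, f"n_{region}")
        e[region] = (n_region / counts.n_gene) / (l_region / counts.l_gene)
    e3 = e["utr3"]
    enriched = e3 is not None and all(
        e3 > e[r] for r in ("cds", "utr5") if e[r] is not None
    )
    return RegionEnrichment(
        e_utr5=e["utr5"], e_cds=e["cds"], e_utr3=e["utr3"],
        is_3utr_enriched=enriched,
    )


def _mannwhitney(x, y) -> float:
    """Two-sided Mann-Whitney U p-value; exact only for small samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    method = "exact" if (len(x) <= 20 and len(y) <= 20) else "asymptotic"
    try:
        return float(stats.mannwhitneyu(x, y, method=method).pvalue)
    except ValueError:
        return float("nan")


def gene_set_statistics(
    counts: dict[str, GenicCounts],
    expression: dict[str, float],
    min_count: float = 300.0,
) -> dict:
    """Cross-gene summaries of the 3'UTR enrichment signal.

    Mann-Whitney comparisons of e_utr3 vs e_cds and e_utr5 over genes with
    at least *min_count* piRNAs, plus Pearson correlations of n_utr3 with
    expression and with 3'UTR length.
    """
    qualified = [
        gc for gc in counts.values()
        if gc.n_gene >= min_count and gc.l_utr5 > 0 and gc.l_cds > 0
        and gc.l_utr3 > 0
    ]
    if len(qualified) < 3:
        return {"status": "withheld", "reason": "fewer than 3 qualifying genes"}
    enr = [region_enrichment(gc) for gc in qualified]
    e3 = [r.e_utr3 for r in enr]
    ecds = [r.e_cds for r in enr]
    e5 = [r.e_utr5 for r in enr]
    n3 = np.array([gc.n_utr3 for gc in qualified])
    l3 = np.array([gc.l_utr3 for gc in qualified], float)
    out = {
        "status": "ok",
        "n_genes": len(qualified),
        "n_3utr_enriched": sum(r.is_3utr_enriched for r in enr),
        "p_utr3_vs_cds": _mannwhitney(e3, ecds),
        "p_utr3_vs_utr5": _mannwhitney(e3, e5),
        "pearson_n3_vs_utr3_length": float(stats.pearsonr(n3, l3)[0])
        if np.std(n3) > 0 and np.std(l3) > 0 else float("nan"),
    }
    expr = np.array([expression.get(gc.gene_id, np.nan) for gc in qualified])
    ok = ~np.isnan(expr)
    if ok.sum() >= 3 and np.std(n3[ok]) > 0 and np.std(expr[ok]) > 0:
        out["pearson_n3_vs_expression"] = float(
            stats.pearsonr(n3[ok], expr[ok])[0]
        )
    # are highly expressed genes the 3'UTR piRNA producers? compare median
    # 3'UTR counts in the top expression decile vs the enriched set
    if ok.sum() >= 10:
        cut = np.quantile(expr[ok], 0.9)
        top = n3[ok][expr[ok] >= cut]
        enriched = [
            gc.n_utr3 for gc, r in zip(qualified, enr) if r.is_3utr_enriched
        ]
        if len(top) and len(enriched):
            out["median_n_utr3_top_decile_expression"] = float(np.median(top))
            out["median_n_utr3_enriched_genes"] = float(np.median(enriched))
    return out


def homolog_overlap_test(
    set_a: set[str], set_b: set[str], universe_size: int
) -> float:
    """Upper-tail hypergeometric P(X >= overlap of A and B).

    Population = universe, successes = |A|, draws = |B|.
    """
    overlap = len(set_a & set_b)
    if overlap > min(len(set_a), len(set_b)):
        raise ValueError("overlap exceeds the smaller set")
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("set larger than universe")
    return float(
        stats.hypergeom.sf(overlap - 1, universe_size, len(set_a), len(set_b))
    )


def conservation_metrics(
    counts: dict[str, GenicCounts],
    homolog_genes: set[str],
    expression: dict[str, float] | None = None,
) -> dict:
    """Four per-gene 3'UTR piRNA metrics compared across homolog status.

    Metrics: raw n_utr3; n_utr3 per 3'UTR bp; normalised enrichment e_utr3;
    n_utr3 per unit expression (genes with zero/missing expression excluded
    from that metric).  Each is compared homolog-of-enriched vs all others
    with a two-sided Mann-Whitney U test.
    """
    expression = expression or {}

    def metrics(gc: GenicCounts) -> dict[str, float | None]:
        e3 = None
        if gc.n_gene > 0 and gc.l_utr3 > 0:
            e3 = (gc.n_utr3 / gc.n_gene) / (gc.l_utr3 / gc.l_gene)
        expr = expression.get(gc.gene_id, 0.0)
        return {
            "n_utr3": gc.n_utr3,
            "n_utr3_per_bp": gc.n_utr3 / gc.l_utr3 if gc.l_utr3 else None,
            "e_utr3": e3,
            "n_utr3_per_expression": gc.n_utr3 / expr if expr > 0 else None,
        }

    groups: dict[str, dict[str, list[float]]] = {
        m: {"homolog": [], "other": []}
        for m in ("n_utr3", "n_utr3_per_bp", "e_utr3", "n_utr3_per_expression")
    }
    for gid, gc in counts.items():
        side = "homolog" if gid in homolog_genes else "other"
        for m, v in metrics(gc).items():
            if v is not None and math.isfinite(v):
                groups[m][side].append(v)
    out = {}
    for m, g in groups.items():
        if len(g["homolog"]) < 2 or len(g["other"]) < 2:
            out[m] = {"status": "withheld"}
        else:
            out[m] = {
                "status": "ok",
                "p_value": _mannwhitney(g["homolog"], g["other"]),
                "median_homolog": float(np.median(g["homolog"])),
                "median_other": float(np.median(g["other"])),
            }
    return out
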