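"""End-to-end orchestration: synthetic study -> preprocessing -> clusters ->
genic / lncRNA / ME / ping-pong analyses, with a summary dictionary.

Desk-scale note: on a small genome the genomic-length RPKM axis is inflated
relative to a mammalian genome (a window's background RPKM is
``background_fraction * 1e6 / genome_kb`` independent of library size), so
the default cluster-calling cutoff (500) is placed between the analytic
background band (~50 for the default study) and the planted-cluster scale
(~1e4); the conventional low cutoffs {1, 3, 10} are still swept to produce
the cutoff/cluster-count table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from ._match import MismatchIndex
from .clusters import PiRNACluster, call_clusters, capture_fraction, window_scan
from .core import WeightedAlignment
from .genic import (
    GenicCounts,
    assign_genic,
    conservation_metrics,
    gene_set_statistics,
    region_enrichment,
)
from .lncrna import score_lncrnas, threshold_grid
from .me import (
    age_density_correlation,
    class_proportions,
    count_me_pirnas,
    lncrna_me_enrichment,
)
from .pingpong import (
    build_profiles,
    classify_pingpong,
    find_signature_peaks,
    map_to_consensus,
    peak_members,
    trace_antisense_source,
)
from .preprocess import PreprocessResult, run_preprocess
from .synthetic import GenomeBundle, SimConfig, SyntheticTruth, default_config, make_genome, make_reads


@dataclass
class PipelineResult:
    config: SimConfig
    bundle: GenomeBundle
    truth: SyntheticTruth
    preprocess: PreprocessResult
    clusters: list[PiRNACluster]
    cluster_sweep: dict[float, int]
    capture: float
    genic_counts: dict[str, GenicCounts]
    antisense_exonic_weight: float
    genic_stats: dict
    conservation: dict
    lncrna_scores: list
    lncrna_grid: list[dict]
    me_densities: list
    me_class_proportions: dict
    age_correlation: dict
    me_enrichment: list
    pingpong_pairs: list
    profiles: dict
    peaks: list
    trace: dict | None
    summary: dict = field(default_factory=dict)

    @property
    def alignments(self) -> list[WeightedAlignment]:
        return self.preprocess.alignments


def run_pipeline(
    config: SimConfig | None = None,
    seed: int = 0,
    cluster_cutoff: float = 500.0,
    sweep_cutoffs: tuple[float, ...] = (1.0, 3.0, 10.0),
    min_count_genes: float = 50.0,
    min_peak_reads: float = 20.0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole analysis on a synthetic study."""
    if config is None:
        config = default_config(seed)
    bundle = make_genome(config)
    reads, truth = make_reads(config, bundle)

    genome_index = MismatchIndex(bundle.genome, k=12)
    pre = run_preprocess(
        reads,
        bundle.genome,
        bundle.known_rna,
        config.adapter,
        genome_index=genome_index,
    )
    alignments = pre.alignments
    total_weighted = pre.total_weight

    windows = window_scan(
        alignments, bundle.chrom_lengths, total_weighted=total_weighted
    )
    clusters = call_clusters(
        windows,
        alignments,
        cluster_cutoff,
        total_weighted=total_weighted,
        chrom_lengths=bundle.chrom_lengths,
    )
    sweep = {
        c: len(
            call_clusters(
                windows, alignments, c, total_weighted=total_weighted,
                chrom_lengths=bundle.chrom_lengths,
            )
        )
        for c in sweep_cutoffs
    }
    capture = capture_fraction(clusters, alignments)

    genic_counts, antisense_w = assign_genic(alignments, bundle.gene_models)
    genic_stats = gene_set_statistics(
        genic_counts, bundle.expression, min_count=min_count_genes
    )
    conservation = conservation_metrics(
        genic_counts,
        homolog_genes=set(truth.enriched_genes),
        expression=bundle.expression,
    )

    lnc_scores = score_lncrnas(
        alignments, bundle.lncrna_models, total_weighted=total_weighted
    )
    lnc_grid = threshold_grid(lnc_scores, total_weighted=total_weighted)

    me_dens = count_me_pirnas(
        alignments, bundle.me_annotations, age_ranks=bundle.age_ranks
    )
    age_corr = age_density_correlation(me_dens)
    me_enr = lncrna_me_enrichment(
        bundle.lncrna_models, bundle.me_annotations, config.genome_length
    )

    pirna_reads = [(r.read_id, r.sequence) for r in pre.survivors]
    cons_alns = map_to_consensus(pirna_reads, bundle.consensus)
    pairs = classify_pingpong(cons_alns)
    profiles = build_profiles(cons_alns, bundle.consensus)
    peaks = [
        p
        for prof in profiles.values()
        for p in find_signature_peaks(prof, min_reads=min_peak_reads)
    ]
    trace = None
    antisense_peaks = [p for p in peaks if p.strand == "-"]
    if antisense_peaks:
        top = max(antisense_peaks, key=lambda p: p.total_weight)
        trace = trace_antisense_source(
            peak_members(top, cons_alns),
            bundle.genome,
            clusters,
            genome_index=genome_index,
        )

    result = PipelineResult(
        config=config,
        bundle=bundle,
        truth=truth,
        preprocess=pre,
        clusters=clusters,
        cluster_sweep=sweep,
        capture=capture,
        genic_counts=genic_counts,
        antisense_exonic_weight=antisense_w,
        genic_stats=genic_stats,
        conservation=conservation,
        lncrna_scores=lnc_scores,
        lncrna_grid=lnc_grid,
        me_densities=me_dens,
        me_class_proportions=class_proportions(me_dens),
        age_correlation=age_corr,
        me_enrichment=me_enr,
        pingpong_pairs=pairs,
        profiles=profiles,
        peaks=peaks,
        trace=trace,
    )
    result.summary = summarize(result)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def summarize(result: PipelineResult) -> dict:
    """Headline numbers of one pipeline run."""
    alns = result.alignments
    total_w = result.preprocess.total_weight
    mapped_reads = {a.read_id for a in alns}
    u1_w = sum(a.weight for a in alns if a.first_base in "TU")
    enr = {
        gid: region_enrichment(gc)
        for gid, gc in result.genic_counts.items()
        if gc.n_gene > 0
    }
    clusters = result.clusters
    return {
        "reads_in": result.preprocess.tallies[0][1]["input"],
        "putative_pirnas": len(result.preprocess.survivors),
        "mapped_reads": len(mapped_reads),
        "total_weight": total_w,
        "pct_reads_1U": 100.0 * u1_w / total_w if total_w else 0.0,
        "n_clusters": len(clusters),
        "cluster_sweep": result.cluster_sweep,
        "capture_fraction": result.capture,
        "pct_clusters_u1_ge_75": 100.0
        * sum(c.is_u1_biased for c in clusters) / len(clusters)
        if clusters else 0.0,
        "pct_clusters_directional": 100.0
        * sum(c.is_directional for c in clusters) / len(clusters)
        if clusters else 0.0,
        "n_3utr_enriched_genes": sum(
            e.is_3utr_enriched for e in enr.values()
        ),
        "antisense_exonic_weight": result.antisense_exonic_weight,
        "n_pingpong_pairs": len(result.pingpong_pairs),
        "n_signature_peaks": len(result.peaks),
        "trace_explained_fraction": result.trace["explained_fraction"]
        if result.trace else None,
    }


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write the main result tables (BED/TSV) under *outdir*."""
    import json

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_alignments(result.alignments, outdir / "alignments.tsv")
    pio.write_intervals(result.clusters, outdir / "clusters.bed", "BED6")
    pd.DataFrame(
        [
            {
                "name": c.name,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "rpkm": c.rpkm,
                "weighted_count": c.weighted_count,
                "u1_fraction": c.u1_fraction,
                "plus_fraction": c.plus_fraction,
            }
            for c in result.clusters
        ]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_id": gc.gene_id,
                "transcript_id": gc.transcript_id,
                "n_utr5": gc.n_utr5,
                "n_cds": gc.n_cds,
                "n_utr3": gc.n_utr3,
                "n_gene": gc.n_gene,
                "l_utr5": gc.l_utr5,
                "l_cds": gc.l_cds,
                "l_utr3": gc.l_utr3,
            }
            for gc in result.genic_counts.values()
        ]
    ).to_csv(outdir / "genic_counts.tsv", sep="\t", index=False)
    pd.DataFrame([s.__dict__ for s in result.lncrna_scores]).to_csv(
        outdir / "lncrna_scores.tsv", sep="\t", index=False
    )
    pd.DataFrame(result.lncrna_grid).to_csv(
        outdir / "lncrna_grid.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "subfamily": d.subfamily,
                "class": d.me_class,
                "sense": d.sense_count,
                "antisense": d.antisense_count,
                "genomic_bp": d.genomic_bp,
                "density_per_kb": d.density,
                "age_rank": d.age_rank,
            }
            for d in result.me_densities
        ]
    ).to_csv(outdir / "me_densities.tsv", sep="\t", index=False)
    pd.DataFrame([r.__dict__ for r in result.me_enrichment]).to_csv(
        outdir / "me_enrichment.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "consensus": p.consensus_id,
                "strand": p.strand,
                "start": p.start,
                "end": p.end,
                "signature": p.signature,
                "total_weight": p.total_weight,
            }
            for p in result.peaks
        ]
    ).to_csv(outdir / "signature_peaks.tsv", sep="\t", index=False)
    for cid, prof in result.profiles.items():
        pd.DataFrame(
            {
                "position": range(prof.length),
                "sense": prof.sense,
                "antisense": prof.antisense,
                "sps_sense": prof.sps_sense,
                "sps_antisense": prof.sps_antisense,
                "asps_sense": prof.asps_sense,
                "asps_antisense": prof.asps_antisense,
            }
        ).to_csv(outdir / f"profile_{cid}.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(result.summary, indent=1, default=str)
    )
    result.truth.to_json(outdir / "truth.json")
    result.truth.write_tsv(outdir / "truth.tsv")
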