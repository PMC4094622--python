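"""Genic assignment, the enrichment statistic and the cross-gene tests."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from pirnascape.core import GeneModel, GenomicInterval, WeightedAlignment
from pirnascape.genic import (
    GenicCounts,
    assign_genic,
    conservation_metrics,
    gene_set_statistics,
    homolog_overlap_test,
    region_enrichment,
)
from pirnascape.preprocess import run_preprocess
from pirnascape.synthetic import GeneSpec, SimConfig, make_genome, make_reads


def gene(strand="+", chrom="chr1"):
    iv = lambda a, b: GenomicInterval(chrom, a, b, strand)  # noqa: E731
    if strand == "+":
        return GeneModel("g1", "g1.t1", strand,
                         utr5=[iv(0, 100)], cds=[iv(100, 800)],
                         utr3=[iv(800, 1000)])
    return GeneModel("g1", "g1.t1", strand,
                     utr3=[iv(0, 200)], cds=[iv(200, 900)],
                     utr5=[iv(900, 1000)])


def aln(start, length=28, strand="+", n=1, chrom="chr1", rid=None):
    return WeightedAlignment(
        rid or f"r{start}{strand}",
        GenomicInterval(chrom, start, start + length, strand), 0, n, "T",
    )


class TestAssignGenic:
    def test_sense_read_in_utr3_counted(self):
        counts, antisense = assign_genic([aln(850)], [gene()])
        assert counts["g1"].n_utr3 == 1.0
        assert counts["g1"].n_gene == 1.0
        assert antisense == 0.0

    def test_antisense_read_tallied_separately(self):
        counts, antisense = assign_genic([aln(850, strand="-")], [gene()])
        assert counts["g1"].n_gene == 0.0
        assert antisense == 1.0

    def test_read_straddling_exon_boundary_not_genic(self):
        # exon union is [0, 1000): a read crossing the gene end is excluded
        counts, _ = assign_genic([aln(990)], [gene()])
        assert counts["g1"].n_gene == 0.0

    def test_intron_containment_rule(self):
        iv = lambda a, b: GenomicInterval("chr1", a, b, "+")  # noqa: E731
        spliced = GeneModel(
            "g2", "g2.t1", "+",
            utr5=[iv(0, 100)], cds=[iv(100, 300), iv(700, 900)],
            utr3=[iv(900, 1000)],
        )
        # read inside the intron gap, same strand: not genic
        counts, _ = assign_genic([aln(400)], [spliced])
        assert counts["g2"].n_gene == 0.0
        # read crossing the splice gap on the genome: not genic either
        counts, _ = assign_genic([aln(290)], [spliced])
        assert counts["g2"].n_gene == 0.0

    def test_best_isoform_chosen(self):
        iv = lambda a, b: GenomicInterval("chr1", a, b, "+")  # noqa: E731
        short = GeneModel("g1", "t_short", "+", utr5=[iv(0, 100)],
                          cds=[iv(100, 400)], utr3=[iv(400, 500)])
        long = GeneModel("g1", "t_long", "+", utr5=[iv(0, 100)],
                         cds=[iv(100, 800)], utr3=[iv(800, 1000)])
        counts, _ = assign_genic([aln(600), aln(850)], [short, long])
        assert counts["g1"].transcript_id == "t_long"
        assert counts["g1"].n_gene == 2.0


class TestRegionEnrichment:
    def test_worked_example(self):
        """All 20 reads in a 100 bp 3'UTR of a 1 kb gene:
        e_utr3 = (20/20)/(100/1000) = 10."""
        gc = GenicCounts("g", "t", 0, 0, 20, 400, 500, 100)
        e = region_enrichment(gc)
        assert math.isclose(e.e_utr3, 10.0)
        assert e.is_3utr_enriched

    def test_counts_proportional_to_lengths_give_unity(self):
        gc = GenicCounts("g", "t", 4.0, 5.0, 1.0, 400, 500, 100)
        e = region_enrichment(gc)
        for v in (e.e_utr5, e.e_cds, e.e_utr3):
            assert math.isclose(v, 1.0, abs_tol=1e-12)
        assert not e.is_3utr_enriched

    def test_weighted_average_identity(self, rng):
        """sum over regions of e * l/l_gene is identically 1."""
        for _ in range(50):
            n = rng.random(3) * 40
            l = rng.integers(50, 2000, size=3)
            if n.sum() == 0:
                continue
            gc = GenicCounts("g", "t", n[0], n[1], n[2],
                             int(l[0]), int(l[1]), int(l[2]))
            e = region_enrichment(gc)
            s = (
                e.e_utr5 * gc.l_utr5 + e.e_cds * gc.l_cds
                + e.e_utr3 * gc.l_utr3
            ) / gc.l_gene
            assert math.isclose(s, 1.0, rel_tol=1e-9)

    def test_zero_length_region_excluded(self):
        gc = GenicCounts("g", "t", 0, 10, 10, 0, 500, 100)
        e = region_enrichment(gc)
        assert e.e_utr5 is None
        assert e.is_3utr_enriched  # compared against CDS only

    def test_matches_independent_recomputation_from_reads(self, rng):
        """e values agree with a direct recomputation from raw read lists."""
        model = gene()
        reads = []
        for i in range(200):
            start = int(rng.integers(0, 972))
            reads.append(aln(start, rid=f"r{i}"))
        counts, _ = assign_genic(reads, [model])
        gc = counts["g1"]
        # oracle: region by 5' position, containment in [0, 1000)
        def n_in(lo, hi):
            return sum(
                1 for a in reads
                if lo <= a.interval.start < hi and a.interval.end <= 1000
            )

        assert gc.n_utr5 == n_in(0, 100)
        assert gc.n_cds == n_in(100, 800)
        assert gc.n_utr3 == n_in(800, 1000)
        e = region_enrichment(gc)
        assert math.isclose(
            e.e_utr3, (gc.n_utr3 / gc.n_gene) / (200 / 1000)
        )


class TestHypergeometricOverlap:
    def test_total_overlap_5_5_10_is_1_over_252(self):
        """Exhaustive enumeration: drawing 5 of 10 with all 5 'successes'
        has probability 1/C(10,5) = 1/252."""
        a = set("abcde")
        p = homolog_overlap_test(a, a, 10)
        assert math.isclose(p, 1 / 252, rel_tol=1e-12)

    def test_matches_enumeration_for_small_universes(self):
        """P(X >= k) equals brute-force enumeration over all draws for
        universes up to 15."""
        for m, na, nb in [(8, 3, 4), (10, 5, 5), (12, 6, 3), (15, 7, 5)]:
            universe = list(range(m))
            set_a = set(universe[:na])
            for k in range(min(na, nb) + 1):
                total = hits = 0
                for draw in combinations(universe, nb):
                    total += 1
                    if len(set_a & set(draw)) >= k:
                        hits += 1
                want = hits / total
                got = float(
                    stats.hypergeom.sf(k - 1, m, na, nb)
                )
                assert math.isclose(got, want, rel_tol=1e-9)

    def test_zero_overlap_in_large_universe(self):
        p = homolog_overlap_test({"a"}, {"b"}, 10_000)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_full_universe(self):
        u = {str(i) for i in range(8)}
        assert homolog_overlap_test(u, u, 8) == pytest.approx(1.0)

    def test_impossible_overlap_rejected(self):
        with pytest.raises(ValueError):
            homolog_overlap_test({"a"}, {"a"}, 0)


class TestGeneSetStatistics:
    def _counts(self, rng, n=60, utr3_boost=1.0):
        out = {}
        for i in range(n):
            base = rng.random(3) * 100 + 100
            base[2] *= utr3_boost
            out[f"g{i}"] = GenicCounts(
                f"g{i}", f"g{i}.t", float(base[0]), float(base[1]),
                float(base[2]), 300, 900, 600,
            )
        return out

    def test_null_distributions_give_large_p(self, rng):
        counts = self._counts(rng)
        res = gene_set_statistics(counts, {}, min_count=0)
        assert res["status"] == "ok"
        # identical distributions in the two groups: two-sided p near 1
        from pirnascape.genic import _mannwhitney

        assert _mannwhitney(np.arange(50.0), np.arange(50.0)) > 0.9

    def test_perfect_proportionality_pearson_one(self):
        counts = {
            f"g{i}": GenicCounts(f"g{i}", "t", 10, 10, float(2 * l), 300,
                                 900, l)
            for i, l in enumerate(range(100, 1100, 100))
        }
        res = gene_set_statistics(counts, {}, min_count=0)
        assert res["pearson_n3_vs_utr3_length"] == pytest.approx(1.0)

    def test_simulated_correlation_recovered(self):
        """A planted n_utr3 ~ expression correlation of 0.2 at n = 2000 is
        estimated within +-0.06 (Monte-Carlo oracle at fixed seed)."""
        r_target = 0.2
        gen = np.random.default_rng(42)
        z = gen.standard_normal(2000)
        x = r_target * z + math.sqrt(1 - r_target**2) * gen.standard_normal(
            2000
        )
        counts = {
            f"g{i}": GenicCounts(
                f"g{i}", "t", 10.0, 10.0, float(100 + 10 * z[i]), 300, 900,
                600,
            )
            for i in range(2000)
        }
        expr = {f"g{i}": float(100 + 10 * x[i]) for i in range(2000)}
        res = gene_set_statistics(counts, expr, min_count=0)
        assert abs(res["pearson_n3_vs_expression"] - r_target) <= 0.06

    def test_top_decile_vs_enriched_medians_reported(self, rng):
        counts = self._counts(rng, n=60, utr3_boost=4.0)
        expr = {f"g{i}": float(i) for i in range(60)}
        res = gene_set_statistics(counts, expr, min_count=0)
        assert "median_n_utr3_top_decile_expression" in res
        assert res["median_n_utr3_enriched_genes"] > 0

    def test_too_few_genes_withheld(self):
        res = gene_set_statistics({}, {}, min_count=300)
        assert res["status"] == "withheld"


class TestConservationMetrics:
    def test_shifted_homolog_group_significant_on_all_four(self):
        """Homolog genes with uniformly 10x more 3'UTR piRNAs are detected
        by all four controlled metrics at n = 200 per group."""
        gen = np.random.default_rng(7)
        counts, expr = {}, {}
        homologs = set()
        for i in range(400):
            boost = 10.0 if i < 200 else 1.0
            if i < 200:
                homologs.add(f"g{i}")
            n3 = float(boost * (20 + 10 * gen.random()))
            counts[f"g{i}"] = GenicCounts(
                f"g{i}", "t", 10.0, 30.0, n3, 300, 900,
                int(gen.integers(300, 900)),
            )
            expr[f"g{i}"] = float(5 + gen.random() * 10)
        res = conservation_metrics(counts, homologs, expr)
        for metric, r in res.items():
            assert r["status"] == "ok"
            assert r["p_value"] < 0.01

    def test_type_i_error_control(self):
        """Identical group distributions reject at about the nominal 5%
        level over repeated simulation."""
        gen = np.random.default_rng(11)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            x = gen.random(40) * 100
            p = stats.mannwhitneyu(x[:20], x[20:],
                                   method="asymptotic").pvalue
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_single_gene_groups_withheld(self):
        counts = {
            "a": GenicCounts("a", "t", 1, 1, 5.0, 300, 900, 600),
            "b": GenicCounts("b", "t", 1, 1, 5.0, 300, 900, 600),
        }
        res = conservation_metrics(counts, {"a"})
        assert all(r["status"] == "withheld" for r in res.values())


class TestClassificationRecovery:
    def test_planted_enriched_genes_recovered_with_perfect_specificity(self):
        """Planted 3'UTR-excess genes are classified enriched with high
        sensitivity and no uniform gene is called enriched, across seeds."""
        sens_num = sens_den = 0
        for seed in range(20):
            cfg = SimConfig(
                seed=seed,
                genome_length=150_000,
                n_chromosomes=1,
                library_size=840,  # exactly the planted read count
                clusters=[],
                genes=[
                    *[GeneSpec(300, 900, 600, utr3_read_count=48)
                      for _ in range(7)],
                    *[GeneSpec(300, 900, 600, utr3_read_count=0)
                      for _ in range(7)],
                ],
            )
            bundle = make_genome(cfg)
            reads, truth = make_reads(cfg, bundle)
            assert truth.category_counts.get("background", 0) == 0
            res = run_preprocess(
                reads, bundle.genome, {"k": "A" * 24}, cfg.adapter
            )
            counts, _ = assign_genic(res.alignments, bundle.gene_models)
            for gid, gc in counts.items():
                e = region_enrichment(gc)
                if gid in truth.enriched_genes:
                    sens_den += 1
                    sens_num += e.is_3utr_enriched
                else:
                    # uniform genes: exact proportionality, e == 1
                    for v in (e.e_utr5, e.e_cds, e.e_utr3):
                        assert math.isclose(v, 1.0, abs_tol=1e-9)
                    assert not e.is_3utr_enriched
        assert sens_den == 140
        assert sens_num / sens_den >= 0.95
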