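"""Consensus mapping, ping-pong pair classification, peaks and source trace."""

import math

import numpy as np
import pytest

from conftest import brute_force_matches, random_seq
from pirnascape.core import revcomp
from pirnascape.pingpong import (
    ConsensusAlignment,
    build_composite_consensus,
    build_profiles,
    classify_pingpong,
    consensus_discriminating_positions,
    find_signature_peaks,
    map_to_consensus,
    peak_members,
    trace_antisense_source,
)
from pirnascape.pipeline import run_pipeline
from pirnascape.preprocess import run_preprocess
from pirnascape.synthetic import (
    MECopySpec,
    PingPongSpec,
    SimConfig,
    make_genome,
    make_reads,
)


class TestCompositeConsensus:
    def test_identical_ungapped_rows_identity(self):
        rows = ["ACGTACGT"] * 3
        cc = build_composite_consensus(rows)
        assert cc.include_all_insertion == "ACGTACGT"
        assert cc.include_all_deletion == "ACGTACGT"

    def test_insertion_present_only_in_insertion_consensus(self):
        rows = ["ACG---TACGT", "ACGGGGTACGT", "ACG---TACGT"]
        cc = build_composite_consensus(rows)
        assert cc.include_all_insertion == "ACGGGGTACGT"
        assert cc.include_all_deletion == "ACGTACGT"
        assert len(cc.include_all_insertion) - len(cc.include_all_deletion) == 3

    def test_majority_with_tie_break(self):
        """Per-column majority among non-gaps; ties resolved A<C<G<T
        (oracle: direct per-column tally)."""
        rows = ["AAGT", "AAGT", "GAGT"]
        cc = build_composite_consensus(rows)
        assert cc.include_all_insertion[0] == "A"
        tie = build_composite_consensus(["ATTT", "GTTT"])
        assert tie.include_all_insertion[0] == "A"  # tie A vs G -> A

    def test_unequal_rows_error(self):
        with pytest.raises(ValueError):
            build_composite_consensus(["ACGT", "ACG"])

    def test_coordinate_map_round_trip(self):
        rows = ["AC--GTAC", "ACGGGTAC", "AC--GTAC"]
        cc = build_composite_consensus(rows)
        for dpos in range(len(cc.include_all_deletion)):
            ipos = cc.lift_deletion_to_insertion(dpos)
            assert cc.lift_insertion_to_deletion(ipos) == dpos
            assert (
                cc.include_all_deletion[dpos] == cc.include_all_insertion[ipos]
            )


class TestMapToConsensus:
    def test_sense_exact_hit(self, rng):
        cons = {"C": random_seq(rng, 600)}
        read = cons["C"][100:128]
        (hit,) = map_to_consensus([("r", read)], cons)
        assert (hit.start, hit.strand, hit.mismatches) == (100, "+", 0)
        assert hit.five_prime == 100

    def test_antisense_hit_five_prime_at_right_edge(self, rng):
        cons = {"C": random_seq(rng, 600)}
        read = revcomp(cons["C"][400:430])
        (hit,) = map_to_consensus([("r", read)], cons)
        assert (hit.start, hit.strand) == (400, "-")
        assert hit.five_prime == 429

    def test_two_mismatch_read_found_only_as_best_stratum(self, rng):
        cons = {"C": random_seq(rng, 600)}
        base = cons["C"][200:228]
        mutated = list(base)
        for p in (3, 17):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        read = "".join(mutated)
        hits = map_to_consensus([("r", read)], cons, max_mismatch=3)
        want = brute_force_matches(read, cons, 3)
        best = min(h[3] for h in want)
        assert {(h.start, h.strand, h.mismatches) for h in hits} == {
            (s, st, mm) for _, s, st, mm in want if mm == best
        }

    def test_density_equals_brute_force_tally(self, rng):
        """Per-position 5'-start densities match a direct per-position count
        over all best-stratum matches."""
        cons = {"C": random_seq(rng, 400)}
        reads = []
        for i in range(30):
            s = int(rng.integers(0, 360))
            seq = cons["C"][s : s + 28]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append((f"r{i}", seq))
        alns = map_to_consensus(reads, cons, max_mismatch=1)
        profiles = build_profiles(alns, cons)
        prof = profiles["C"]
        sense = np.zeros(400)
        anti = np.zeros(400)
        for a in alns:
            (sense if a.strand == "+" else anti)[a.five_prime] += a.weight
        assert np.allclose(prof.sense, sense)
        assert np.allclose(prof.antisense, anti)


def mk_aln(start, length, strand, seq, cid="C", rid=None):
    end = start + length
    return ConsensusAlignment(
        rid or f"{cid}:{start}:{strand}", cid, start, end, strand, 0, 1, seq
    )


class TestClassifyPingPong:
    def test_sps_pair_labels(self):
        """Sense 5' at 100 with 1U, antisense 5' at 109 with 10A: both reads
        carry the sense ping-pong signature."""
        sense = mk_aln(100, 28, "+", "T" + "G" * 27)
        anti = mk_aln(82, 28, "-", "G" * 9 + "A" + "G" * 18)  # 5' at 109
        pairs = classify_pingpong([sense, anti])
        assert len(pairs) == 1
        assert sense.signature == "SPS"
        assert anti.signature == "SPS"

    def test_asps_pair_labels(self):
        sense = mk_aln(100, 28, "+", "G" * 9 + "A" + "G" * 18)  # 10A
        anti = mk_aln(82, 28, "-", "T" + "G" * 27)  # 1U
        classify_pingpong([sense, anti])
        assert sense.signature == "ASPS"
        assert anti.signature == "ASPS"

    def test_offset_eight_not_paired(self):
        sense = mk_aln(100, 28, "+", "T" + "G" * 27)
        anti = mk_aln(81, 28, "-", "G" * 9 + "A" + "G" * 18)  # 5' at 108
        assert classify_pingpong([sense, anti]) == []
        assert sense.signature == "none"

    @pytest.mark.parametrize("offset", [0, 5, 8, 10, 11, 20])
    def test_no_pairs_at_any_other_offset(self, offset):
        sense = mk_aln(100, 28, "+", "T" + "G" * 27)
        anti_start = 100 + offset - 27  # antisense 5' = 100 + offset
        anti = mk_aln(anti_start, 28, "-", "T" + "G" * 27)
        assert classify_pingpong([sense, anti]) == []

    def test_pair_symmetry_role_swap(self):
        """The 10-nt overlap test is symmetric: the same pair is found
        regardless of which alignment is examined first."""
        sense = mk_aln(100, 28, "+", "T" + "G" * 27)
        anti = mk_aln(82, 28, "-", "G" * 9 + "A" + "G" * 18)
        p1 = classify_pingpong([sense, anti])
        s2 = mk_aln(100, 28, "+", "T" + "G" * 27)
        a2 = mk_aln(82, 28, "-", "G" * 9 + "A" + "G" * 18)
        p2 = classify_pingpong([a2, s2])
        key = lambda p: (p.sense.five_prime, p.antisense.five_prime)  # noqa
        assert [key(p) for p in p1] == [key(p) for p in p2]

    def test_unqualified_read_labelled_none(self):
        sense = mk_aln(100, 28, "+", "G" * 28)  # neither 1U nor partner 10A
        anti = mk_aln(82, 28, "-", "G" * 28)
        pairs = classify_pingpong([sense, anti])
        assert len(pairs) == 1  # geometry qualifies ...
        assert sense.signature == "none"  # ... but no diagnostic base


class TestSignaturePeaks:
    def _profile(self, sps_anti):
        import numpy as np

        from pirnascape.pingpong import ConsensusProfile

        n = len(sps_anti)
        z = np.zeros(n)
        return ConsensusProfile(
            "C", n, z.copy(), np.array(sps_anti, float), z.copy(),
            np.array(sps_anti, float), z.copy(), z.copy(),
        )

    def test_single_block_single_peak(self):
        dens = [0] * 50 + [5] * 20 + [0] * 50
        peaks = find_signature_peaks(self._profile(dens), min_reads=50)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (50, 70)
        assert peaks[0].total_weight == 100

    def test_all_zero_no_peaks(self):
        assert find_signature_peaks(self._profile([0] * 100), 1) == []

    def test_blocks_split_beyond_gap_tolerance(self):
        """Two nonzero runs separated by 10 zeros are distinct peaks
        (run-length oracle with gap tolerance 5)."""
        dens = [0] * 10 + [8] * 5 + [0] * 10 + [8] * 5 + [0] * 10
        peaks = find_signature_peaks(self._profile(dens), min_reads=10)
        assert len(peaks) == 2
        dens2 = [0] * 10 + [8] * 5 + [0] * 4 + [8] * 5 + [0] * 10
        peaks2 = find_signature_peaks(self._profile(dens2), min_reads=10)
        assert len(peaks2) == 1

    def test_threshold_filters_small_runs(self):
        dens = [0] * 10 + [3] * 5 + [0] * 20 + [100] * 5 + [0] * 10
        peaks = find_signature_peaks(self._profile(dens), min_reads=100)
        assert len(peaks) == 1 and peaks[0].start == 35


class TestPlantedRecovery:
    def _study(self, seed=0):
        cfg = SimConfig(
            seed=seed,
            genome_length=120_000,
            n_chromosomes=1,
            library_size=120,
            clusters=[],
            consensus_lengths={"CONS": 900},
            consensus_classes={"CONS": "LTR"},
            me_copies=[MECopySpec("CONS", "LTR", 0.0, "+")],
            pingpong_pairs=[
                PingPongSpec("CONS", 150, 20, "SPS"),
                PingPongSpec("CONS", 400, 25, "ASPS"),
                PingPongSpec("CONS", 700, 15, "SPS"),
            ],
        )
        bundle = make_genome(cfg)
        reads, truth = make_reads(cfg, bundle)
        res = run_preprocess(reads, bundle.genome, {"k": "A" * 24},
                             cfg.adapter)
        alns = map_to_consensus(
            [(r.read_id, r.sequence) for r in res.survivors],
            bundle.consensus,
        )
        pairs = classify_pingpong(alns)
        return cfg, bundle, truth, res, alns, pairs

    def test_all_planted_pairs_recovered_with_correct_labels(self):
        """Every planted ping-pong read participates in a qualifying pair
        and carries the planted signature label."""
        _, _, truth, _, alns, pairs = self._study()
        paired_reads = {p.sense.read_id for p in pairs} | {
            p.antisense.read_id for p in pairs
        }
        by_read = {}
        for a in alns:
            by_read.setdefault(a.read_id, []).append(a)
        for rec in truth.pingpong_pairs:
            for rid in rec["read_ids"]:
                assert rid in paired_reads
                labels = {a.signature for a in by_read[rid]}
                assert rec["signature"] in labels

    def test_pair_positions_match_truth(self):
        _, _, truth, _, _, pairs = self._study()
        planted = {(r["sense_5p"], r["antisense_5p"])
                   for r in truth.pingpong_pairs}
        found = {(p.sense.five_prime, p.antisense.five_prime) for p in pairs}
        assert planted <= found

    def test_profiles_and_peaks_locate_planted_positions(self):
        cfg, bundle, truth, _, alns, _ = self._study()
        profiles = build_profiles(alns, bundle.consensus)
        peaks = find_signature_peaks(profiles["CONS"], min_reads=10)
        starts = {p.start for p in peaks}
        # sense 5' positions and antisense 5' positions both carry peaks
        for rec in truth.pingpong_pairs:
            assert rec["sense_5p"] in starts
            assert rec["antisense_5p"] in starts


class TestTrace:
    def test_single_locus_fully_explained(self, rng):
        genome = {"chr1": random_seq(rng, 4000)}
        locus = genome["chr1"][1000:1200]
        alns = [
            mk_aln(10, 28, "-", revcomp(locus[i : i + 28]), rid=f"r{i}")
            for i in range(0, 60, 10)
        ]
        for a in alns:
            a.is_asps = True
        res = trace_antisense_source(alns, genome, clusters=[])
        assert res["status"] == "ok"
        assert res["explained_fraction"] == pytest.approx(1.0)
        (ivs,) = res["source_intervals"].values()
        lo, hi = ivs[0]
        assert lo >= 1000 and hi <= 1200 + 28

    def test_multi_mapping_reads_excluded(self, rng):
        core = random_seq(rng, 200)
        genome = {"chr1": random_seq(rng, 500) + core + random_seq(rng, 500)
                  + core + random_seq(rng, 100)}
        unique = random_seq(rng, 1000)
        genome["chr2"] = unique
        alns = [
            mk_aln(0, 28, "-", revcomp(core[0:28]), rid="multi"),
            *[
                mk_aln(0, 28, "-", revcomp(unique[i : i + 28]),
                       rid=f"u{i}")
                for i in range(0, 120, 30)
            ],
        ]
        res = trace_antisense_source(alns, genome, clusters=[])
        # 4 of 5 reads are uniquely placed -> 0.8 explained
        assert res["explained_fraction"] == pytest.approx(0.8)
        assert "chr1" not in res["source_intervals"]

    def test_no_unique_reads_diagnostic(self, rng):
        seg = random_seq(rng, 100)
        genome = {"chr1": seg + random_seq(rng, 50) + seg}
        res = trace_antisense_source(
            [mk_aln(0, 28, "-", revcomp(seg[0:28]))], genome, clusters=[]
        )
        assert res["status"] == "no_uniquely_mapping_reads"

    def test_default_study_trace_hits_called_cluster(self, default_run):
        trace = default_run.trace
        assert trace is not None and trace["status"] == "ok"
        assert trace["explained_fraction"] > 0.5
        assert trace["cluster_fractions"]


def test_discriminating_positions():
    a = "ACGTACGTAC"
    b = "ACGAACGTCC"
    assert consensus_discriminating_positions(a, b, 0, 10) == [3, 8]
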