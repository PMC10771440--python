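"""Peak windows, PWMs, ZOOPS discovery, composite motifs, exact-p scanning."""

import itertools

import numpy as np
import pytest

from sigrekin import motif_tools as mt
from sigrekin import synthetic_data as sd
from sigrekin.errors import ParameterError, StructuralError


def random_seqs(rng, n, length, gc=0.5, prefix="s"):
    chars = np.array(list(mt.ALPHABET))
    bg = mt.gc_background(gc)
    return {
        f"{prefix}{i}": "".join(chars[rng.choice(4, size=length, p=bg)])
        for i in range(n)
    }


class TestPeakWindows:
    def test_summit_centered_interval(self):
        genome = {"chr": "A" * 450 + "CGT" * 40 + "A" * 430}
        peak = mt.PeakRegion("chr", 400, 600, 500, "p1")
        windows = mt.extract_peak_windows([peak], genome, width=100)
        assert windows["p1"] == genome["chr"][450:550]
        assert len(windows["p1"]) == 100

    def test_edge_peak_skipped_with_warning(self):
        genome = {"chr": "ACGT" * 25}
        peak = mt.PeakRegion("chr", 0, 40, 10, "edge")
        with pytest.warns(UserWarning):
            windows = mt.extract_peak_windows([peak], genome, width=100, policy="skip")
        assert windows == {}

    def test_edge_peak_clipped(self):
        genome = {"chr": "ACGT" * 25}
        peak = mt.PeakRegion("chr", 0, 40, 10, "edge")
        windows = mt.extract_peak_windows([peak], genome, width=100, policy="clip")
        assert windows["edge"] == genome["chr"][0:60]

    def test_strand_symmetry_of_extraction(self, rng):
        genome = {"chr": "".join(np.array(list(mt.ALPHABET))[rng.choice(4, 300)])}
        L = 300
        peak = mt.PeakRegion("chr", 100, 200, 150, "p")
        fwd = mt.extract_peak_windows([peak], genome, width=50)["p"]
        rc_genome = {"chr": mt.revcomp(genome["chr"])}
        # the summit mirror: position x maps to L - 1 - x
        mirrored = mt.PeakRegion("chr", L - 200, L - 100, L - 150, "p")
        rev = mt.extract_peak_windows([mirrored], rc_genome, width=50)["p"]
        assert rev == mt.revcomp(fwd)

    def test_unknown_contig_rejected(self):
        with pytest.raises(StructuralError):
            mt.extract_peak_windows(
                [mt.PeakRegion("nope", 0, 10, 5)], {"chr": "ACGTACGTAC"}
            )

    def test_summit_outside_interval_rejected(self):
        with pytest.raises(StructuralError):
            mt.PeakRegion("chr", 10, 20, 25)


class TestBuildPwm:
    def test_unanimous_sites_without_pseudocount(self):
        pwm = mt.build_pwm(["TA", "TA", "TA"], pseudocount=0.0)
        np.testing.assert_allclose(pwm.probs[0], [0, 0, 0, 1])
        np.testing.assert_allclose(pwm.probs[1], [1, 0, 0, 0])

    def test_pseudocount_gives_strictly_positive_matrix(self):
        pwm = mt.build_pwm(["TA", "TA"], pseudocount=0.5)
        assert np.all(pwm.probs > 0)

    def test_uniform_random_sites_approach_background(self, rng):
        sites = ["".join(np.array(list(mt.ALPHABET))[rng.integers(0, 4, 8)])
                 for _ in range(4000)]
        pwm = mt.build_pwm(sites, pseudocount=0.0)
        assert np.all(np.abs(pwm.probs - 0.25) < 0.05)

    def test_ragged_and_non_acgt_rejected(self):
        with pytest.raises(StructuralError):
            mt.build_pwm(["AC", "ACG"])
        with pytest.raises(StructuralError):
            mt.build_pwm(["AN", "AC"])


class TestZoopsDiscovery:
    def test_planted_motif_recovered(self, rng):
        planted = "TTGACAT"
        seqs = {}
        chars = np.array(list(mt.ALPHABET))
        for i in range(100):
            s = chars[rng.integers(0, 4, 60)]
            if rng.random() < 0.9:
                pos = rng.integers(0, 60 - len(planted))
                for c, b in enumerate(planted):
                    s[pos + c] = b
            seqs[f"s{i}"] = "".join(s)
        res = mt.discover_motif_zoops(seqs, len(planted), seed=1)
        assert res.pwm.consensus in (planted, mt.revcomp(planted))
        assert res.gamma > 0.7

    def test_likelihood_non_decreasing(self, rng):
        seqs = random_seqs(rng, 30, 40)
        res = mt.discover_motif_zoops(seqs, 5, n_starts=1, seed=3)
        assert np.all(np.diff(res.ll_trace) >= -1e-8)

    def test_reproducible_given_seed(self, rng):
        seqs = random_seqs(rng, 20, 30)
        a = mt.discover_motif_zoops(seqs, 6, n_starts=1, seed=5)
        b = mt.discover_motif_zoops(seqs, 6, n_starts=1, seed=5)
        np.testing.assert_array_equal(a.pwm.probs, b.pwm.probs)
        assert a.sites == b.sites

    def test_width_out_of_range_rejected(self, rng):
        with pytest.raises(ParameterError):
            mt.discover_motif_zoops(random_seqs(rng, 5, 10), 11)


class TestUpstreamSegments:
    def test_plus_strand_coordinates(self):
        seq = "".join(mt.ALPHABET[i % 4] for i in range(60))
        segs = mt.extract_upstream_segments(
            {"s": seq}, {"s": (40, "+")}, site_width=6, offset=23, length=10
        )
        assert segs["s"] == seq[17:27]

    def test_out_of_range_site_skipped(self):
        seq = "ACGT" * 15
        with pytest.warns(UserWarning):
            segs = mt.extract_upstream_segments(
                {"s": seq}, {"s": (5, "+")}, site_width=6
            )
        assert segs == {}

    def test_minus_strand_mirrors_reverse_complement(self, rng):
        # oracle: brute-force string reversal
        seq = "".join(np.array(list(mt.ALPHABET))[rng.integers(0, 4, 80)])
        w, pos = 6, 30
        rc = mt.revcomp(seq)
        pos_rc = len(seq) - w - pos
        oracle = mt.extract_upstream_segments(
            {"s": rc}, {"s": (pos_rc, "+")}, site_width=w
        )
        out = mt.extract_upstream_segments(
            {"s": seq}, {"s": (pos, "-")}, site_width=w
        )
        assert out == oracle


class TestCompositeMotif:
    @pytest.fixture(scope="class")
    def halves(self):
        bg = mt.gc_background(0.6)
        return (mt.consensus_pwm("GGAACTT", 0.8, bg), mt.consensus_pwm("GTCTAAT", 0.8, bg))

    def test_total_width(self, halves):
        comp = mt.build_composite_motif(*halves, spacer=18)
        assert comp.width == 7 + 18 + 7

    def test_spacer_columns_score_zero(self, halves):
        comp = mt.build_composite_motif(*halves, spacer=17)
        bg = mt.gc_background(0.6)
        S = mt._int_score_matrix(comp, bg, 0.01)
        spacer_rows = np.setdiff1d(np.arange(comp.width), comp.informative_columns)
        assert np.all(S[spacer_rows] == 0)

    def test_flank_columns_shared_across_spacers(self, halves):
        bg = mt.gc_background(0.6)
        comps = [mt.build_composite_motif(*halves, spacer=s) for s in (16, 17, 18, 19)]
        for comp in comps[1:]:
            np.testing.assert_array_equal(
                comp.probs(bg)[:7], comps[0].probs(bg)[:7]
            )
            np.testing.assert_array_equal(
                comp.probs(bg)[-7:], comps[0].probs(bg)[-7:]
            )

    def test_spacer_out_of_range_rejected(self, halves):
        with pytest.raises(ParameterError):
            mt.build_composite_motif(*halves, spacer=25)


class TestScorePValueTable:
    @pytest.mark.parametrize("width", [3, 5, 6])
    def test_dp_equals_brute_force_enumeration(self, width):
        rng = np.random.default_rng(width)
        bg = mt.gc_background(0.62)
        pwm = mt.PWM(rng.dirichlet(np.ones(4), size=width), 0.0, bg)
        table = mt.score_pvalue_table(pwm, bg, granularity=0.01)
        S = mt._int_score_matrix(pwm, bg, 0.01)[:, :4]
        scores, weights = [], []
        for word in itertools.product(range(4), repeat=width):
            scores.append(sum(S[c, b] for c, b in enumerate(word)))
            weights.append(np.prod([bg[b] for b in word]))
        scores, weights = np.array(scores), np.array(weights)
        for s in np.unique(scores):
            brute = weights[scores >= s].sum()
            assert table.pvalue_int(s) == pytest.approx(brute, abs=1e-12)

    def test_background_motif_scores_zero_with_p_one(self):
        bg = mt.gc_background(0.5)
        pwm = mt.PWM(np.tile(bg, (6, 1)), 0.0, bg)
        table = mt.score_pvalue_table(pwm, bg)
        assert table.min_score == 0
        assert table.pvalue_int(0) == 1.0

    def test_tail_monotone_and_starts_at_one(self):
        rng = np.random.default_rng(9)
        bg = mt.gc_background(0.7)
        pwm = mt.PWM(rng.dirichlet(np.ones(4), size=8), 0.0, bg)
        table = mt.score_pvalue_table(pwm, bg)
        assert table.tail[0] == pytest.approx(1.0)
        assert np.all(np.diff(table.tail) <= 1e-15)

    def test_granularity_refinement_stable(self):
        rng = np.random.default_rng(4)
        bg = mt.gc_background(0.6)
        pwm = mt.PWM(rng.dirichlet(np.ones(4), size=6), 0.0, bg)
        coarse = mt.score_pvalue_table(pwm, bg, granularity=0.02)
        fine = mt.score_pvalue_table(pwm, bg, granularity=0.01)
        # p at the same bit-score may move by at most the discretization bound
        lo = pwm.log_odds(bg)
        for word in [(0, 1, 2, 3, 0, 1), (3, 3, 3, 3, 3, 3), (2, 2, 1, 0, 2, 1)]:
            bits = sum(lo[c, b] for c, b in enumerate(word))
            pc, pf = coarse.pvalue_bits(bits), fine.pvalue_bits(bits)
            # both are exact tails of slightly different lattices; they must
            # bracket each other within the mass near the score boundary
            assert pc == pytest.approx(pf, abs=0.05)

    def test_non_positive_granularity_rejected(self):
        pwm = mt.consensus_pwm("ACGT", 0.7)
        with pytest.raises(ParameterError):
            mt.score_pvalue_table(pwm, granularity=0.0)


class TestScanning:
    def test_planted_consensus_sites_recovered_exactly(self):
        config = sd.SimulationConfig(n_sequences=200, planting_rate=1.0)
        motifs = sd.default_composite_motifs(config.gc_content)
        seqs, truth = sd.generate_promoter_set(config, motifs, seed=7,
                                               consensus_sites=True)
        hits = mt.scan_sequences(list(motifs.values()), seqs, p_threshold=0.05)
        best = {}
        for h in hits:
            if h.seq_id not in best or mt._hit_rank(h) < mt._hit_rank(best[h.seq_id]):
                best[h.seq_id] = h
        exact = sum(
            1 for sid, site in truth.sites.items()
            if sid in best and (best[sid].offset, best[sid].strand, best[sid].spacer)
            == (site.position, site.strand, site.spacer)
        )
        assert exact / len(truth.sites) >= 0.99

    def test_reverse_complement_involution(self, rng):
        seqs = random_seqs(rng, 30, 80, gc=0.6)
        motifs = list(sd.default_composite_motifs(0.6).values())
        bg = mt.gc_background(0.6)  # strand-symmetric background
        fwd = mt.scan_sequences(motifs, seqs, p_threshold=0.3, background=bg,
                                dedupe=False)
        rc_seqs = {sid: mt.revcomp(s) for sid, s in seqs.items()}
        rev = mt.scan_sequences(motifs, rc_seqs, p_threshold=0.3, background=bg,
                                dedupe=False)
        def key(h, L):
            return (h.seq_id, L - h.width - h.offset, "+-"[h.strand == "+"],
                    h.spacer, round(h.score, 6))
        mapped = sorted(key(h, 80) for h in rev)
        original = sorted((h.seq_id, h.offset, h.strand, h.spacer, round(h.score, 6))
                          for h in fwd)
        assert mapped == original

    def test_null_calibration_at_threshold(self):
        from sigrekin import validation

        rate, n = validation.scanner_false_positive_rate(0.05, n_windows=8000, seed=2)
        band = 1.96 * np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= band

    def test_non_acgt_bases_warn(self):
        motif = sd.default_composite_motifs(0.5)[16]
        seq = "ACGT" * 10 + "N" + "ACGT" * 10
        with pytest.warns(UserWarning):
            mt.scan_sequences([motif], {"s": seq}, p_threshold=1.0, dedupe=False)

    def test_invalid_threshold_rejected(self):
        motif = sd.default_composite_motifs(0.5)[16]
        with pytest.raises(ParameterError):
            mt.scan_sequences([motif], {"s": "ACGT" * 20}, p_threshold=0.0)


class TestHitFiltering:
    @staticmethod
    def hit(seq_id="s1", offset=0, strand="+", p=0.01, matched="GCTAGGGTAC", spacer=18):
        return mt.MotifHit(seq_id, offset, strand, 10.0, p, spacer, matched)

    def test_wildcard_pattern_matching(self):
        assert mt.matches_pattern("GCTAGGGTAC", "--TA---T--")
        assert not mt.matches_pattern("GCAAGGGTAC", "--TA---T--")

    def test_single_hit_per_sequence_is_identity(self):
        hits = [self.hit("s1", 5, matched="GCTAGGGGGC"),
                self.hit("s2", 9, matched="GCAAGGGGGC")]
        assert mt.filter_best_and_pattern(hits) == sorted(
            hits, key=lambda h: (h.seq_id, h.offset, h.strand))

    def test_union_of_best_and_pattern_matches(self):
        best = self.hit("s1", 3, p=0.001, matched="GGGGGGGGGG")
        pattern_hit = self.hit("s1", 20, p=0.04, matched="GCTAGGGTAC")
        loser = self.hit("s1", 40, p=0.02, matched="CCCCCCCCCC")
        out = mt.filter_best_and_pattern([loser, pattern_hit, best])
        assert {h.offset for h in out} == {3, 20}

    def test_tie_break_and_order_invariance(self):
        a = self.hit("s1", 10, "+", p=0.01, matched="GGGGGGGGGG")
        b = self.hit("s1", 30, "+", p=0.01, matched="CCCCCCCCCC")
        c = self.hit("s1", 10, "-", p=0.01, matched="AAAAAAAAAA")
        import itertools as it
        results = {
            tuple((h.offset, h.strand) for h in mt.filter_best_and_pattern(list(perm)))
            for perm in it.permutations([a, b, c])
        }
        assert results == {((10, "+"),)}  # leftmost, then + strand

    def test_pattern_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            mt.filter_best_and_pattern([self.hit(matched="ACGT")])


class TestSpacerTally:
    def test_counts(self):
        hits = [mt.MotifHit("a", 0, "+", 1.0, 0.01, s, "X") for s in (18, 18, 17)]
        assert mt.tally_spacers(hits) == {16: 0, 17: 1, 18: 2, 19: 0}

    def test_empty_input_gives_zeros(self):
        assert mt.tally_spacers([]) == {16: 0, 17: 0, 18: 0, 19: 0}


class TestFileFormats:
    def test_fasta_round_trip(self, tmp_path, rng):
        seqs = random_seqs(rng, 5, 30)
        path = tmp_path / "x.fasta"
        mt.write_fasta(seqs, path)
        assert mt.read_fasta(path) == seqs

    def test_narrowpeak_summit_offset(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text(
            "chr1\t100\t300\tpeak_a\t50\t.\t5.0\t4.0\t3.0\t25\n"
            "chr1\t400\t500\tpeak_b\t50\t.\t5.0\t4.0\t3.0\t-1\n"
        )
        peaks = mt.read_narrowpeak(path)
        assert peaks[0].summit == 125          # start + offset
        assert peaks[1].summit == 450          # midpoint fallback

    def test_bed_midpoint_summit(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t10\t50\n")
        assert mt.read_narrowpeak(path)[0].summit == 30

    def test_meme_round_trip(self, tmp_path):
        bg = mt.gc_background(0.72)
        pwms = [mt.consensus_pwm("GGAACTT", 0.8, bg, name="m35"),
                mt.consensus_pwm("GTCTAA", 0.9, bg, name="m10")]
        path = tmp_path / "m.meme"
        mt.write_meme(pwms, path)
        back = mt.read_meme(path)
        assert [p.name for p in back] == ["m35", "m10"]
        np.testing.assert_allclose(back[0].probs, pwms[0].probs, atol=1e-5)
        np.testing.assert_allclose(back[0].background, bg, atol=1e-4)

    def test_hits_tsv_columns(self, tmp_path):
        import pandas as pd

        hits = [mt.MotifHit("s1", 4, "-", 8.2, 0.003, 18, "GGAACTT")]
        path = tmp_path / "hits.tsv"
        mt.write_hits_tsv(hits, path)
        df = pd.read_csv(path, sep="\t")
        assert df.loc[0, "end"] == 4 + 7
        assert df.loc[0, "strand"] == "-"
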