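"""PWM construction, the exact score-distribution DP, scanning and enrichment."""

import itertools
import math

import numpy as np
import pytest

from enhancerlink.motifs import (
    PositionFrequencyMatrix,
    enrichment_table,
    pfm_to_pwm,
    read_jaspar,
    read_meme,
    scan_regions,
    score_distribution,
    score_threshold,
)

RC = str.maketrans("ACGT", "TGCA")


class TestPfmToPwm:
    def test_uniform_pfm_scores_zero_everywhere(self):
        pfm = PositionFrequencyMatrix("u", np.full((4, 5), 10.0))
        pwm = pfm_to_pwm(pfm)
        assert np.allclose(pwm.scores, 0.0)

    def test_deterministic_column_favours_its_base(self):
        counts = np.zeros((4, 1))
        counts[0, 0] = 100  # all A
        counts[1:, 0] = 1e-9
        pwm = pfm_to_pwm(PositionFrequencyMatrix("a", counts + 1e-9))
        assert pwm.scores[0, 0] > 1.5
        assert np.all(pwm.scores[1:, 0] < 0)

    def test_matches_hand_computed_two_column_example(self):
        counts = np.array([[8.0, 2.0], [1.0, 3.0], [1.0, 4.0], [0.0, 1.0]])
        pwm = pfm_to_pwm(
            PositionFrequencyMatrix("toy", counts), background=[0.25] * 4, pseudocount=0.1
        )
        # column 0, base A: (8 + 0.1*0.25) / (10 + 0.1) / 0.25
        expected = math.log2((8 + 0.025) / 10.1 / 0.25)
        assert pwm.scores[0, 0] == pytest.approx(expected)
        # column 0, base T with zero count relies on the pseudocount
        expected_t = math.log2((0 + 0.025) / 10.1 / 0.25)
        assert pwm.scores[3, 0] == pytest.approx(expected_t)
        # column 1, base G
        expected_g = math.log2((4 + 0.025) / 10.1 / 0.25)
        assert pwm.scores[2, 1] == pytest.approx(expected_g)

    def test_invalid_background_rejected(self):
        pfm = PositionFrequencyMatrix("u", np.full((4, 2), 5.0))
        with pytest.raises(ValueError):
            pfm_to_pwm(pfm, background=[0.5, 0.5, 0.0, 0.0])


def _brute_force_tails(pwm):
    """Exact tail probabilities by enumerating every k-mer (width <= 6)."""
    scores = {}
    for kmer in itertools.product(range(4), repeat=pwm.width):
        s = sum(pwm.scores[b, j] for j, b in enumerate(kmer))
        p = np.prod([pwm.background[b] for b in kmer])
        scores[s] = scores.get(s, 0.0) + p
    return scores


class TestScoreDistribution:
    def test_mass_sums_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            pfm = PositionFrequencyMatrix("r", rng.integers(1, 40, size=(4, 8)).astype(float))
            dist = score_distribution(pfm_to_pwm(pfm))
            assert dist.mass.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("width", [1, 3, 5])
    def test_tail_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        pfm = PositionFrequencyMatrix(
            "r", rng.integers(1, 30, size=(4, width)).astype(float)
        )
        pwm = pfm_to_pwm(pfm)
        dist = score_distribution(pwm, epsilon=0.01)
        brute = _brute_force_tails(pwm)
        slack = 0.01 * (width + 1)
        for s in sorted(brute):
            exact_tail = sum(p for s2, p in brute.items() if s2 >= s - 1e-12)
            assert dist.tail(s - slack) >= exact_tail - 1e-9
            assert dist.tail(s + slack) <= exact_tail + 1e-9

    def test_threshold_monotone_in_p(self):
        pfm = PositionFrequencyMatrix.from_consensus("TGACGTCA")
        pwm = pfm_to_pwm(pfm)
        thresholds = [score_threshold(pwm, p) for p in (1e-2, 1e-3, 1e-4)]
        assert thresholds == sorted(thresholds)

    def test_width_one_threshold_equals_direct_enumeration(self):
        counts = np.array([[50.0], [30.0], [15.0], [5.0]])
        pwm = pfm_to_pwm(PositionFrequencyMatrix("w1", counts))
        # p = 0.3: only scores with tail <= 0.3 qualify; enumerate 4 bases
        base_scores = sorted(pwm.scores[:, 0], reverse=True)
        # tail of the top base alone is 0.25 <= 0.3
        thr = score_threshold(pwm, p=0.3)
        assert thr <= base_scores[0] + 1e-9
        assert thr > base_scores[1]

    def test_unreachable_p_warns_and_returns_max(self):
        pwm = pfm_to_pwm(PositionFrequencyMatrix.from_consensus("ACG"))
        with pytest.warns(UserWarning, match="tail"):
            thr = score_threshold(pwm, p=1e-6)
        assert thr <= pwm.max_score
        assert thr >= pwm.max_score - 0.05

    def test_agrees_with_biopython_fpr_threshold(self):
        # independent route: Biopython's score distribution on the same PFM
        from Bio.motifs import matrix as bio_matrix

        rng = np.random.default_rng(3)
        counts = rng.integers(1, 30, size=(4, 6)).astype(float)
        fpm = bio_matrix.FrequencyPositionMatrix(
            "ACGT", {b: list(counts[i]) for i, b in enumerate("ACGT")}
        )
        pssm = fpm.normalize(pseudocounts=0.5).log_odds()
        dist = pssm.distribution(precision=10**4)
        pwm = pfm_to_pwm(PositionFrequencyMatrix("r", counts), pseudocount=2.0)
        for p in (1e-2, 1e-3):
            assert score_threshold(pwm, p=p) == pytest.approx(
                float(dist.threshold_fpr(p)), abs=0.1
            )


class TestScanRegions:
    @pytest.fixture()
    def consensus_pwm(self):
        pwm = pfm_to_pwm(PositionFrequencyMatrix.from_consensus("TGACTCA"))
        return pwm, score_threshold(pwm, 1e-4)

    def test_consensus_and_reverse_complement_hit(self, consensus_pwm):
        pwm, thr = consensus_pwm
        rc = "TGACTCA".translate(RC)[::-1]
        hits, hit_list = scan_regions(
            {"fwd": "AAAA" + "TGACTCA" + "GGGG", "rev": "CCCC" + rc + "TTTT"},
            pwm,
            thr,
        )
        assert hits == {"fwd": True, "rev": True}
        strands = {h.region: h.strand for h in hit_list}
        assert strands == {"fwd": "+", "rev": "-"}

    def test_background_sequence_misses(self, consensus_pwm):
        pwm, thr = consensus_pwm
        hits, _ = scan_regions({"bg": "ACGT" * 10}, pwm, thr)
        assert hits == {"bg": False}

    def test_windows_with_n_are_skipped_but_others_scanned(self, consensus_pwm):
        pwm, thr = consensus_pwm
        hits, _ = scan_regions(
            {"broken": "TGANTCA" + "A" * 10, "later": "N" * 5 + "TGACTCA"}, pwm, thr
        )
        assert hits == {"broken": False, "later": True}

    def test_short_region_warns_and_is_unhit(self, consensus_pwm):
        pwm, thr = consensus_pwm
        with pytest.warns(UserWarning, match="shorter"):
            hits, _ = scan_regions({"tiny": "TGA"}, pwm, thr)
        assert hits == {"tiny": False}

    def test_matches_naive_rescan_oracle(self, consensus_pwm):
        pwm, thr = consensus_pwm
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        seqs = {
            f"r{i}": "".join(bases[rng.integers(0, 4, size=80)]) for i in range(100)
        }
        hits, _ = scan_regions(seqs, pwm, thr)
        for name, seq in seqs.items():
            naive = False
            for strand_seq in (seq, seq.translate(RC)[::-1]):
                for i in range(len(strand_seq) - pwm.width + 1):
                    window = strand_seq[i : i + pwm.width]
                    score = sum(
                        pwm.scores["ACGT".index(b), j] for j, b in enumerate(window)
                    )
                    naive = naive or score >= thr
            assert hits[name] == naive


class TestEnrichmentTable:
    def test_published_count_pair_reproduces_p_value(self):
        table = enrichment_table({"FOS": (398, 650)}, total_a=1004, total_b=1047)
        assert len(table) == 1
        assert table.p_value.iloc[0] == pytest.approx(2.90e-24, rel=0.01)

    def test_equal_proportions_filtered_out(self):
        table = enrichment_table({"flat": (50, 50)}, total_a=200, total_b=200)
        assert table.empty

    def test_rows_sorted_by_ascending_p(self):
        table = enrichment_table(
            {"weak": (60, 40), "strong": (90, 10)}, total_a=200, total_b=200
        )
        assert table.motif.tolist() == ["strong", "weak"]
        assert table.p_value.is_monotonic_increasing

    def test_hit_count_above_total_rejected(self):
        with pytest.raises(ValueError):
            enrichment_table({"m": (11, 0)}, total_a=10, total_b=10)

    def test_planted_motif_ranks_first_on_synthetic_sets(self, small_world):
        pwm = pfm_to_pwm(
            PositionFrequencyMatrix.from_consensus(small_world.config.motif_consensus)
        )
        thr = score_threshold(pwm, 1e-4)
        decoys = {
            name: (pfm_to_pwm(PositionFrequencyMatrix.from_consensus(name)),)
            for name in ("GATTACA", "CACGTGA")
        }
        counts = {}
        for name, p in [("planted", pwm)] + [(n, d[0]) for n, d in decoys.items()]:
            t = thr if p is pwm else score_threshold(p, 1e-4)
            hits_a, _ = scan_regions(small_world.sequences["a"], p, t)
            hits_b, _ = scan_regions(small_world.sequences["b"], p, t)
            counts[name] = (sum(hits_a.values()), sum(hits_b.values()))
        table = enrichment_table(
            counts,
            total_a=len(small_world.sequences["a"]),
            total_b=len(small_world.sequences["b"]),
        )
        assert table.motif.iloc[0] == "planted"
        assert table.p_value.iloc[0] < 1e-6


class TestReaders:
    def test_jaspar_round_trip(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0000.1 TOY\n"
            "A [ 10  2  0 ]\n"
            "C [  0  3  1 ]\n"
            "G [  0  4  1 ]\n"
            "T [  2  3 10 ]\n"
        )
        (pfm,) = read_jaspar(path)
        assert pfm.width == 3
        assert pfm.counts[0, 0] == 10
        assert pfm.database == "JASPAR"

    def test_minimal_meme_reader(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGT\n\n"
            "MOTIF TOY1\n"
            "letter-probability matrix: alength= 4 w= 2 nsites= 10\n"
            "0.7 0.1 0.1 0.1\n"
            "0.1 0.1 0.1 0.7\n"
        )
        (pfm,) = read_meme(path)
        assert pfm.width == 2
        assert pfm.counts[0, 0] == pytest.approx(7.0)
        assert pfm.counts[3, 1] == pytest.approx(7.0)
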