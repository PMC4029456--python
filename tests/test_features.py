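"""TRAP motif affinities and chromatin-mark aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhancerclass.features import (
    TrapParams,
    build_feature_matrix,
    default_r0,
    epi_feature,
    mismatch_energy,
    pwm_probabilities,
    trap_affinity,
)
from enhancerclass.io import Genome, GenomicRegion, PWM, SignalTrack, reverse_complement

from trap_oracle import trap_oracle

UNIFORM4 = PWM(id="uniform", matrix=np.full((4, 4), 0.25))


class TestPwmProbabilities:
    def test_pseudocount_arithmetic(self):
        pwm = PWM(id="x", matrix=[[10, 0, 0, 0]])
        np.testing.assert_allclose(
            pwm_probabilities(pwm, 1.0), [[11 / 14, 1 / 14, 1 / 14, 1 / 14]]
        )

    def test_probability_input_unchanged(self):
        pwm = PWM(id="x", matrix=[[0.7, 0.1, 0.1, 0.1]])
        np.testing.assert_allclose(pwm_probabilities(pwm, 0.0), pwm.matrix)

    def test_all_zero_position_rejected(self):
        pwm = PWM(id="x", matrix=[[0, 0, 0, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            pwm_probabilities(pwm, 0.0)


class TestMismatchEnergy:
    def test_consensus_is_zero(self):
        probs = pwm_probabilities(PWM(id="x", matrix=[[8, 1, 1, 0], [0, 9, 1, 0]]), 1.0)
        assert mismatch_energy(probs, "AC", 0.7) == 0.0

    def test_single_position_hand_value(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1]])
        assert mismatch_energy(probs, "C", 0.7) == pytest.approx(math.log(7) / 0.7)

    def test_additive_over_positions(self):
        probs = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.6, 0.2, 0.1]])
        e_xy = mismatch_energy(probs, "CG", 0.7)
        e_x = mismatch_energy(probs[:1], "C", 0.7)
        e_y = mismatch_energy(probs[1:], "G", 0.7)
        assert e_xy == pytest.approx(e_x + e_y)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mismatch_energy(np.array([[0.25] * 4]), "AC", 0.7)


class TestR0:
    def test_printed_formula_at_length_10(self):
        assert default_r0(10) == pytest.approx(math.exp(0.18))

    def test_crosses_one_between_9_and_10(self):
        assert default_r0(9) < 1 < default_r0(10)

    def test_override_wins(self):
        assert default_r0(10, TrapParams(r0_override=2.5)) == 2.5


class TestTrapAffinity:
    def test_uniform_pwm_closed_form(self):
        L, m = 48, 4
        seq = "ACGT" * (L // 4)
        r0 = default_r0(m)
        expected = 2 * (L - m + 1) * r0 / (1 + r0)
        assert trap_affinity(UNIFORM4, seq) == pytest.approx(expected, rel=1e-12)

    def test_sequence_shorter_than_motif(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert trap_affinity(UNIFORM4, "AC") == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            trap_affinity(UNIFORM4, "")

    def test_n_windows_contribute_zero(self):
        # all-N sequence has no valid window on either strand
        assert trap_affinity(UNIFORM4, "N" * 30) == 0.0
        # interior N knocks out exactly the windows covering it
        pwm = PWM(id="x", matrix=np.array([[5, 1, 1, 1], [1, 5, 1, 1]]))
        seq_plain = "AACGTACG"
        seq_n = "AACGNACG"
        assert trap_affinity(pwm, seq_n) < trap_affinity(pwm, seq_plain)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            m = int(rng.integers(1, 16))
            L = int(rng.integers(m, 200))
            counts = rng.integers(0, 25, size=(m, 4))
            pwm = PWM(id="x", matrix=counts)
            seq = "".join(rng.choice(list("ACGTN"), size=L, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            got = trap_affinity(pwm, seq)
            want = trap_oracle(counts.tolist(), seq)
            assert got == pytest.approx(want, abs=1e-9)

    def test_bounded_and_monotone_in_r0(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        pwm = PWM(id="x", matrix=rng.integers(0, 20, size=(8, 4)))
        L, m = 120, 8
        small = trap_affinity(pwm, seq, TrapParams(r0_override=0.1))
        large = trap_affinity(pwm, seq, TrapParams(r0_override=10.0))
        assert 0 <= small < large <= 2 * (L - m + 1)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGT", min_size=8, max_size=60), st.integers(0, 10_000))
def test_affinity_strand_symmetric(seq, pwm_seed):
    rng = np.random.default_rng(pwm_seed)
    pwm = PWM(id="x", matrix=rng.integers(0, 12, size=(5, 4)) + 1)
    fwd = trap_affinity(pwm, seq)
    rev = trap_affinity(pwm, reverse_complement(seq))
    assert fwd == pytest.approx(rev, rel=1e-12, abs=1e-12)


class TestEpiFeature:
    TRACK = SignalTrack("m", 50, {"chr1": np.array([1.0, 3.0])})

    def test_unweighted_two_window_mean(self):
        assert epi_feature(self.TRACK, GenomicRegion("chr1", 40, 60)) == 2.0

    def test_single_window(self):
        assert epi_feature(self.TRACK, GenomicRegion("chr1", 50, 100)) == 3.0

    def test_constant_track(self):
        track = SignalTrack("m", 50, {"chr1": np.full(100, 2.5)})
        assert epi_feature(track, GenomicRegion("chr1", 123, 4321)) == pytest.approx(2.5)

    def test_overhang_windows_imputed_zero(self):
        # region extends past the recorded vector: missing windows count as 0
        assert epi_feature(self.TRACK, GenomicRegion("chr1", 50, 200)) == pytest.approx(1.0)

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            epi_feature(self.TRACK, GenomicRegion("chrX", 0, 10))

    def test_split_at_window_boundary_consistent(self, rng):
        vec = rng.normal(size=40)
        track = SignalTrack("m", 50, {"chr1": vec})
        region = GenomicRegion("chr1", 130, 1730)
        left = GenomicRegion("chr1", 130, 1000)  # boundary at window 20
        right = GenomicRegion("chr1", 1000, 1730)
        n_l = (999 // 50) - (130 // 50) + 1
        n_r = (1729 // 50) - (1000 // 50) + 1
        weighted = (epi_feature(track, left) * n_l + epi_feature(track, right) * n_r) / (n_l + n_r)
        assert epi_feature(track, region) == pytest.approx(weighted)


class TestFeatureMatrix:
    @pytest.fixture()
    def inputs(self, rng):
        genome = Genome({"chr1": "".join(rng.choice(list("ACGT"), size=2000))})
        tracks = [
            SignalTrack(m, 50, {"chr1": rng.normal(size=40)})
            for m in ("H3K4me1", "H3K4me3", "Mef2")
        ]
        pwms = [PWM(id=f"TF{i}", matrix=rng.integers(1, 10, size=(6, 4))) for i in range(4)]
        regions = [
            GenomicRegion("chr1", 100, 400, label="positive", id="p1"),
            GenomicRegion("chr1", 600, 800, label="negative", id="n1"),
            GenomicRegion("chr1", 900, 1300, label="negative", id="n2"),
        ]
        return genome, tracks, pwms, regions

    def test_column_layout_per_feature_set(self, inputs):
        genome, tracks, pwms, regions = inputs
        epi = build_feature_matrix(genome, tracks, pwms, regions, "EPI")
        mot = build_feature_matrix(genome, tracks, pwms, regions, "MOT")
        both = build_feature_matrix(genome, tracks, pwms, regions, "ALL")
        assert epi.feature_names == ["EPI:H3K4me1", "EPI:H3K4me3", "EPI:Mef2"]
        assert mot.feature_names == ["MOT:TF0", "MOT:TF1", "MOT:TF2", "MOT:TF3"]
        assert both.feature_names == epi.feature_names + mot.feature_names
        np.testing.assert_array_equal(both.labels, [1, 0, 0])
        np.testing.assert_allclose(
            both.features.to_numpy()[:, :3], epi.features.to_numpy()
        )

    def test_unlabeled_region_rejected(self, inputs):
        genome, tracks, pwms, _ = inputs
        with pytest.raises(ValueError, match="unlabeled"):
            build_feature_matrix(genome, tracks, pwms, [GenomicRegion("chr1", 0, 50)], "EPI")

    def test_region_past_chromosome_end_rejected(self, inputs):
        genome, tracks, pwms, _ = inputs
        bad = [GenomicRegion("chr1", 1990, 2050, label="positive")]
        with pytest.raises(ValueError, match="exceeds"):
            build_feature_matrix(genome, tracks, pwms, bad, "MOT")
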