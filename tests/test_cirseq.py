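import numpy as np
import pytest

from tmseq import (
    ReferenceSet,
    Rejected,
    cirseq_error_rate,
    detect_period,
    fold_consensus,
    fold_fastq,
    RepeatConsensus,
)

from oracles import fold_oracle, period_oracle


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestDetectPeriod:
    def test_exact_triple_repeat(self, rng):
        s = _random_seq(rng, 50)
        assert detect_period(s * 3, 20, 80) == 50

    def test_two_repeats_fail_the_repeat_gate(self, rng):
        s = _random_seq(rng, 50)
        arr = list(s)
        arr[3] = "A" if arr[3] != "A" else "C"
        arr[17] = "G" if arr[17] != "G" else "T"
        read = s + "".join(arr)
        # mismatch fraction 0.04 <= 0.1 but only 2 repeats under default
        assert detect_period(read, 30, 60) is None
        assert detect_period(read, 30, 60, min_repeats=2) == 50

    def test_trailing_partial_repeat_is_harmless(self, rng):
        s = _random_seq(rng, 40)
        full = detect_period(s * 3, 10, 60)
        with_tail = detect_period(s * 3 + s[:17], 10, 60)
        assert full == with_tail == 40

    def test_matches_exhaustive_scan_on_noisy_rolling_reads(self, rng):
        agree = 0
        correct = 0
        n = 200
        for _ in range(n):
            p = int(rng.integers(20, 41))
            reps = int(rng.integers(3, 6))
            unit = _random_seq(rng, p)
            read = list(unit * reps)
            for j in range(len(read)):
                if rng.random() < 0.005:
                    read[j] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            got = detect_period(read, 15, 50)
            assert got == period_oracle(read, 15, 50)
            agree += 1
            correct += got == p
        assert agree == n
        assert correct / n >= 0.99

    def test_rejects_too_short_reads(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_period("ACGT", 10, 20)


class TestFoldConsensus:
    def test_exact_repeats_full_support(self, rng):
        s = _random_seq(rng, 30)
        cons = fold_consensus(s * 3, "I" * 90, 30)
        assert isinstance(cons, RepeatConsensus)
        assert cons.consensus_sequence == s
        assert cons.n_repeats == 3
        assert (cons.per_base_support == [3, 3]).all()

    def test_single_error_outvoted_at_equal_quality(self, rng):
        s = _random_seq(rng, 30)
        bad = list(s)
        bad[7] = "A" if bad[7] != "A" else "G"
        read = s + "".join(bad) + s
        cons = fold_consensus(read, "I" * 90, 30)
        assert cons.consensus_sequence == s
        assert tuple(cons.per_base_support[7]) == (2, 3)

    def test_quality_weighting_can_overrule_the_majority(self, rng):
        # one high-quality copy beats two low-quality copies only when its
        # summed quality reaches twice theirs; otherwise the column masks
        s = "A" * 10
        bad = "C" + "A" * 9
        quals = chr(40 + 33) + "!" * 9 + "!" * 10 + "!" * 10  # q40 vs q0+q0
        cons = fold_consensus(bad + s + s, quals, 10)
        assert cons.consensus_sequence[0] == "C"

    def test_three_way_tie_masked(self):
        read = "A" + "C" + "G"  # period 1, three discordant copies
        cons = fold_consensus(read, "III", 1, max_masked_frac=1.0)
        assert cons.consensus_sequence == "N"

    def test_too_masked_rejected(self):
        read = "ACG" * 1  # period 1 over 3 discordant copies
        res = fold_consensus(read, "III", 1, max_masked_frac=0.2)
        assert isinstance(res, Rejected) and res.reason == "too_masked"

    def test_nonpositive_period_is_hard_error(self):
        with pytest.raises(ValueError, match="period"):
            fold_consensus("ACGT", "IIII", 0)

    def test_matches_column_vote_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            p = int(rng.integers(5, 15))
            reps = int(rng.integers(3, 5))
            tail = int(rng.integers(0, p))
            L = p * reps + tail
            seq = _random_seq(rng, L)
            quals = "".join(
                chr(int(q) + 33) for q in rng.integers(2, 41, L)
            )
            cons = fold_consensus(seq, quals, p, max_masked_frac=1.0)
            expect_seq, expect_support = fold_oracle(seq, quals, p)
            assert cons.consensus_sequence == expect_seq
            assert [tuple(s) for s in cons.per_base_support] == expect_support


class TestCirseqErrorRate:
    def _cons(self, seq, tx, start, rid="r"):
        support = np.tile([3, 3], (len(seq), 1))
        return RepeatConsensus(rid, len(seq), 3, seq, support, tx, start)

    def test_no_mismatches_zero_rate(self, small_reference):
        tx = small_reference.ids[0]
        cons = [self._cons(small_reference[tx][:40], tx, 0)]
        spec = cirseq_error_rate(cons, small_reference)
        assert spec.overall_rate == 0.0
        assert spec.total_surveyed == 40

    def test_recurrent_site_excluded_as_mutation(self, small_reference):
        tx = small_reference.ids[0]
        ref = small_reference[tx]
        alt = "A" if ref[5] != "A" else "C"
        mutant = ref[:5] + alt + ref[6:40]
        cons = [self._cons(mutant, tx, 0, rid=f"r{i}") for i in range(12)]
        spec = cirseq_error_rate(cons, small_reference)
        assert spec.total_errors == 0
        assert spec.total_surveyed == 12 * 40 - 12

    def test_zero_surveyed_warns_undefined(self, small_reference):
        spec = cirseq_error_rate([], small_reference)
        with pytest.warns(UserWarning):
            assert np.isnan(spec.overall_rate)


def test_fold_fastq_end_to_end(small_reference, tmp_path):
    from tmseq import SimulationConfig, simulate_cirseq

    cfg = SimulationConfig(
        n_cells=2,
        molecules_per_cell_per_transcript=3.0,
        cirseq_fragments=60,
        background_tx_error_rate=5e-3,
        seq_error_rate=1e-3,
        seed=4,
    )
    fq, _ = simulate_cirseq(cfg, small_reference, 3, 50, tmp_path / "c.fastq")
    consensi, tally = fold_fastq(fq, 30, 70)
    assert len(consensi) + sum(tally.values()) == 60
    assert len(consensi) >= 55
    spec = cirseq_error_rate(consensi, small_reference)
    assert spec.total_surveyed > 0
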