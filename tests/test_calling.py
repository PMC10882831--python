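import warnings

import numpy as np
import pytest

from tmseq import (
    CANDIDATE_DNA_MUTATION,
    TRANSCRIPTION_ERROR,
    DiscrepancyCall,
    ErrorSpectrum,
    ReferenceSet,
    call_discrepancies,
    classify_calls,
    classify_site,
    error_spectrum,
)
from tmseq.calling import read_calls_tsv, write_calls_tsv

from conftest import make_molecule
from oracles import tally_calls_oracle


@pytest.fixture
def ref_c100():
    return ReferenceSet([("tx000", "C" * 100)])


class TestCallDiscrepancies:
    def test_matching_molecules_yield_no_calls(self, small_reference):
        tx = small_reference.ids[0]
        mols = [make_molecule(small_reference[tx][:50], tx=tx) for _ in range(3)]
        assert call_discrepancies(mols, small_reference) == []

    def test_hand_counted_site(self, ref_c100):
        mols = [
            make_molecule("C" * 100, umi=f"U{i}") for i in range(2)
        ] + [make_molecule("C" * 20 + "T" + "C" * 79, umi="U2")]
        calls = call_discrepancies(mols, ref_c100)
        assert len(calls) == 1
        c = calls[0]
        assert (c.position, c.ref_base, c.alt_base) == (20, "C", "T")
        assert (c.n_mut, c.n_wt) == (1, 2)

    def test_masked_positions_are_skipped(self, ref_c100):
        mols = [
            make_molecule("C" * 100, umi="U0"),
            make_molecule("N" * 100, umi="U1"),
        ]
        assert call_discrepancies(mols, ref_c100) == []

    def test_cells_never_merged(self, ref_c100):
        mols = [
            make_molecule("T" + "C" * 99, cb="cellA", umi="U0"),
            make_molecule("C" * 100, cb="cellB", umi="U1"),
        ]
        calls = call_discrepancies(mols, ref_c100)
        assert len(calls) == 1
        assert calls[0].cell_barcode == "cellA"
        assert calls[0].n_wt == 0  # cellB's coverage does not count

    def test_out_of_bounds_molecule_is_a_hard_error(self, ref_c100):
        mols = [make_molecule("C" * 50, start=60)]
        with pytest.raises(ValueError, match="past end"):
            call_discrepancies(mols, ref_c100)

    def test_matches_exhaustive_tally_oracle(self, rng):
        ref = ReferenceSet.random(2, 60, seed=8)
        for _ in range(100):
            mols, simple = [], []
            for i in range(20):
                cell = f"c{int(rng.integers(0, 3))}"
                tx = ref.ids[int(rng.integers(0, 2))]
                start = int(rng.integers(0, 30))
                L = int(rng.integers(10, 30))
                seq = list(ref[tx][start : start + L])
                for j in range(len(seq)):
                    u = rng.random()
                    if u < 0.03:
                        seq[j] = "ACGT"[int(rng.integers(0, 4))]
                    elif u < 0.05:
                        seq[j] = "N"
                seq = "".join(seq)
                mols.append(make_molecule(seq, cb=cell, umi=f"U{i}", tx=tx, start=start))
                simple.append((cell, tx, start, seq))
            got = {
                (c.cell_barcode, c.transcript_id, c.position, c.alt_base): (
                    c.n_mut,
                    c.n_wt,
                )
                for c in call_discrepancies(mols, ref)
            }
            assert got == tally_calls_oracle(simple, ref)


class TestClassifySite:
    def _call(self, n_mut, n_wt, cell="c0"):
        return DiscrepancyCall(cell, "tx000", 5, "C", "T", n_mut, n_wt)

    def test_fully_mutant_high_coverage_is_candidate_mutation(self):
        assert classify_site([self._call(12, 0)]) == CANDIDATE_DNA_MUTATION

    def test_fifty_fifty_pseudo_allele_stays_transcription_error(self):
        assert classify_site([self._call(6, 6)]) == TRANSCRIPTION_ERROR

    def test_low_coverage_fully_mutant_is_not_enough_evidence(self):
        assert classify_site([self._call(3, 0)]) == TRANSCRIPTION_ERROR

    def test_pools_across_cells(self):
        calls = [self._call(5, 0, "c0"), self._call(6, 0, "c1")]
        assert classify_site(calls) == CANDIDATE_DNA_MUTATION
        classify_calls(calls)
        assert all(c.classification == CANDIDATE_DNA_MUTATION for c in calls)


class TestErrorSpectrum:
    def test_single_error_rate_arithmetic(self, ref_c100):
        # 1 mutant molecule base over 10,000 surveyed C bases -> 1e-4
        mols = [make_molecule("C" * 100, umi=f"U{i}") for i in range(99)]
        mols.append(make_molecule("C" * 50 + "T" + "C" * 49, umi="U99"))
        calls = classify_calls(call_discrepancies(mols, ref_c100))
        spec = error_spectrum(calls, mols, ref_c100)
        assert spec.surveyed["C"] == 10_000
        assert spec.errors[("C", "T")] == 1
        assert spec.rate("C", "T") == pytest.approx(1.0e-4)
        assert spec.overall_rate == pytest.approx(1.0e-4)

    def test_candidate_mutation_removed_from_both_sides(self, ref_c100):
        mols = [
            make_molecule("C" * 20 + "T" + "C" * 79, umi=f"U{i}") for i in range(12)
        ]
        calls = classify_calls(call_discrepancies(mols, ref_c100))
        assert calls[0].classification == CANDIDATE_DNA_MUTATION
        spec = error_spectrum(calls, mols, ref_c100)
        assert spec.errors[("C", "T")] == 0
        # the excluded site's 12 covering bases leave the denominator
        assert spec.surveyed["C"] == 12 * 100 - 12

    def test_unit_site_counts_distinct_sites(self, ref_c100):
        mols = [
            make_molecule("C" * 20 + "T" + "C" * 79, umi="U0"),
            make_molecule("C" * 20 + "T" + "C" * 79, umi="U1"),
        ] + [make_molecule("C" * 100, umi=f"U{i}") for i in range(2, 6)]
        calls = classify_calls(call_discrepancies(mols, ref_c100))
        assert error_spectrum(calls, mols, ref_c100, unit="molecule").errors[
            ("C", "T")
        ] == 2
        assert error_spectrum(calls, mols, ref_c100, unit="site").errors[
            ("C", "T")
        ] == 1

    def test_transcript_space_types_never_folded(self):
        # a C->T error must never increment G->A: transcripts are
        # single-stranded, the asymmetry is the DNA-mutation control
        ref = ReferenceSet([("t", "GCGCGCGCGC")])
        mols = [make_molecule("GCGCGCGCGC", tx="t", umi=f"U{i}") for i in range(4)]
        mols.append(make_molecule("GTGCGCGCGC", tx="t", umi="U9"))
        calls = classify_calls(call_discrepancies(mols, ref))
        spec = error_spectrum(calls, mols, ref)
        assert spec.errors[("C", "T")] == 1
        assert spec.errors[("G", "A")] == 0

    def test_zero_denominator_is_undefined_not_zero(self):
        ref = ReferenceSet([("t", "GGGG")])
        mols = [make_molecule("GGGG", tx="t")]
        spec = error_spectrum([], mols, ref)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(spec.rate("C", "T"))
        assert spec.rate("G", "A") == 0.0

    def test_multiple_alts_share_wt_coverage(self, ref_c100):
        mols = [
            make_molecule("C" * 100, umi=f"U{i}") for i in range(8)
        ] + [
            make_molecule("T" + "C" * 99, umi="U8"),
            make_molecule("A" + "C" * 99, umi="U9"),
        ]
        calls = classify_calls(call_discrepancies(mols, ref_c100))
        by_alt = {c.alt_base: c for c in calls}
        assert by_alt["T"].n_mut == 1 and by_alt["A"].n_mut == 1
        assert by_alt["T"].n_wt == by_alt["A"].n_wt == 8

    def test_blacklisted_site_excluded(self, ref_c100, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("tx000\t20\t21\n")
        from tmseq.calling import load_blacklist

        mols = [make_molecule("C" * 100, umi=f"U{i}") for i in range(4)]
        mols.append(make_molecule("C" * 20 + "T" + "C" * 79, umi="U4"))
        calls = classify_calls(call_discrepancies(mols, ref_c100))
        spec = error_spectrum(
            calls, mols, ref_c100, blacklist=load_blacklist(bed)
        )
        assert spec.errors[("C", "T")] == 0
        assert spec.surveyed["C"] == 5 * 100 - 5

    def test_spectrum_invariants_and_tsv_round_trip(self, tmp_path):
        spec = ErrorSpectrum(
            "s1", {("C", "T"): 5, ("G", "A"): 2}, {"A": 10, "C": 1000, "G": 500, "T": 10}
        )
        assert spec.total_errors == 7
        path = tmp_path / "spec.tsv"
        spec.to_tsv(path)
        back = ErrorSpectrum.from_tsv(path)
        assert back.errors == spec.errors and back.surveyed == spec.surveyed
        with pytest.raises(ValueError, match="more C errors"):
            ErrorSpectrum("bad", {("C", "T"): 11}, {"C": 10})


def test_calls_tsv_round_trip(tmp_path):
    calls = [
        DiscrepancyCall("c0", "t", 3, "C", "T", 2, 5, TRANSCRIPTION_ERROR),
        DiscrepancyCall("c1", "t", 9, "G", "A", 11, 0, CANDIDATE_DNA_MUTATION),
    ]
    path = tmp_path / "calls.tsv"
    write_calls_tsv(calls, path)
    back = read_calls_tsv(path)
    assert len(back) == 2
    assert back[0].__dict__ == calls[0].__dict__
    assert back[1].__dict__ == calls[1].__dict__


def test_vcf_like_export_is_one_based(tmp_path):
    from tmseq.calling import export_vcf_like

    calls = [DiscrepancyCall("c0", "t", 3, "C", "T", 2, 5, TRANSCRIPTION_ERROR)]
    path = tmp_path / "calls.vcf-like.tsv"
    export_vcf_like(calls, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("##") and "1-based" in lines[0]
    fields = lines[-1].split("\t")
    assert fields[0] == "t" and fields[1] == "4"  # 0-based 3 -> 1-based 4
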