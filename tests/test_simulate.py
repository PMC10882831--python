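import numpy as np
import pytest

from tmseq import (
    ReferenceSet,
    SimulatedCells,
    SimulatedCirseq,
    SimulationConfig,
    read_fastq,
    simulate_cells,
    simulate_cirseq,
)

from oracles import cirseq_column_distribution


def _clean_config(**kw):
    base = dict(
        n_cells=3,
        molecules_per_cell_per_transcript=4.0,
        reads_per_molecule=2.0,
        min_reads_per_molecule=2,
        seed=123,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestValidation:
    def test_rejects_zero_cells(self, small_reference):
        with pytest.raises(ValueError, match="n_cells"):
            SimulatedCells.generate(_clean_config(n_cells=0), small_reference)

    @pytest.mark.parametrize(
        "kw",
        [
            {"lesion_site_rate": 1.5},
            {"seq_error_rate": -0.1},
            {"reads_per_molecule": 1.0, "min_reads_per_molecule": 2},
            {"lesion_ref_base": "Q"},
            {"lesion_ref_base": "C", "lesion_alt_base": "C"},
            {"fragment_length": 10**6},
        ],
    )
    def test_rejects_invalid_parameters(self, small_reference, kw):
        with pytest.raises(ValueError):
            SimulatedCells.generate(_clean_config(**kw), small_reference)

    def test_rejects_mutation_at_matching_base(self, small_reference):
        tx = small_reference.ids[0]
        same = small_reference[tx][10]
        cfg = _clean_config(dna_mutation_sites=((0, tx, 10, same),))
        with pytest.raises(ValueError, match="alt equals reference"):
            SimulatedCells.generate(cfg, small_reference)


class TestSimulateCells:
    def test_zero_rates_reads_match_reference_exactly(self, small_reference, tmp_path):
        fq, truth = simulate_cells(
            _clean_config(), small_reference, tmp_path / "r.fastq"
        )
        assert len(truth) == 0
        n = 0
        for read in read_fastq(fq):
            expect = small_reference[read.transcript_id][
                read.start : read.start + len(read.sequence)
            ]
            assert read.sequence == expect
            n += 1
        assert n > 0

    def test_dna_mutation_fully_penetrant(self, small_reference):
        tx = small_reference.ids[1]
        alt = "A" if small_reference[tx][10] != "A" else "G"
        cfg = _clean_config(dna_mutation_sites=((0, tx, 10, alt),))
        sim = SimulatedCells.generate(cfg, small_reference)
        t = list(small_reference.ids).index(tx)
        lo, hi = sim.molecule_range(0, t)
        covering = [
            m
            for m in range(lo, hi)
            if sim.mol_start[m] <= 10 < sim.mol_start[m] + sim.mol_len[m]
        ]
        assert covering, "fixture needs molecules covering the site"
        for m in covering:
            seq = sim.molecule_sequence(m)
            assert seq[10 - sim.mol_start[m]] == "ACGT".index(alt)
        # other cells untouched
        lo1, hi1 = sim.molecule_range(1, t)
        for m in range(lo1, hi1):
            assert sim.molecule_sequence(m)[10] == small_reference.codes(tx)[10]
        assert (sim.truth.frame["kind"] == "dna_mutation").all()
        assert (sim.truth.frame["expected_mutant_fraction"] == 1.0).all()

    def test_lesion_site_fifty_fifty_ratio(self):
        # one C in the transcript; a fully miscoding single-allele lesion
        # should yield mutant transcripts at ~50% of the site's molecules
        ref = ReferenceSet([("t", "A" * 50 + "C" + "G" * 49)])
        cfg = _clean_config(
            n_cells=1,
            molecules_per_cell_per_transcript=250.0,
            lesion_site_rate=1.0,
            lesion_miscoding_prob=1.0,
            lesioned_allele_fraction=0.5,
            seed=77,
        )
        sim = SimulatedCells.generate(cfg, ref)
        assert len(sim.truth) == 1
        assert sim.truth.frame.loc[0, "expected_mutant_fraction"] == 0.5
        n = sim.n_molecules
        assert n >= 200
        mutant = sum(sim.molecule_sequence(m)[50] == 3 for m in range(n))  # T
        half_width = 2.576 * np.sqrt(0.25 / n)  # binomial 99% CI
        assert abs(mutant / n - 0.5) <= half_width

    def test_truth_consistency_at_depth(self):
        # law of large numbers: empirical mutant fraction within 3 sigma
        ref = ReferenceSet([("t", ("AGTC" * 25))])  # 25 C sites
        cfg = _clean_config(
            n_cells=1,
            molecules_per_cell_per_transcript=400.0,
            lesion_site_rate=0.3,
            lesion_miscoding_prob=0.8,
            lesioned_allele_fraction=0.5,
            seed=5,
        )
        sim = SimulatedCells.generate(cfg, ref)
        assert len(sim.truth) >= 3
        n = sim.n_molecules
        assert n >= 200
        seqs = [sim.molecule_sequence(m) for m in range(n)]
        for row in sim.truth.frame.itertuples():
            expected = row.expected_mutant_fraction
            mutant = sum(s[row.position] == 3 for s in seqs)
            sigma = np.sqrt(expected * (1 - expected) / n)
            assert abs(mutant / n - expected) <= 3 * sigma

    def test_byte_identical_for_fixed_seed(self, small_reference, tmp_path):
        cfg = _clean_config(
            background_tx_error_rate=1e-3,
            seq_error_rate=5e-3,
            pcr_error_rate=1e-4,
            lesion_site_rate=1e-2,
        )
        fq1, truth1 = simulate_cells(cfg, small_reference, tmp_path / "a.fastq")
        fq2, truth2 = simulate_cells(cfg, small_reference, tmp_path / "b.fastq")
        assert fq1.read_bytes() == fq2.read_bytes()
        assert truth1.frame.equals(truth2.frame)
        fq3, _ = simulate_cells(
            cfg.evolve(seed=999), small_reference, tmp_path / "c.fastq"
        )
        assert fq1.read_bytes() != fq3.read_bytes()

    def test_read_count_conservation(self, small_reference, tmp_path):
        cfg = _clean_config(reads_per_molecule=3.0)
        sim = SimulatedCells.generate(cfg, small_reference)
        fq = sim.write_fastq(tmp_path / "r.fastq")
        n_lines = sum(1 for _ in open(fq))
        assert n_lines == 4 * int(sim.mol_reads.sum())
        assert sim.n_reads == int(sim.mol_reads.sum())
        assert (sim.mol_reads >= cfg.min_reads_per_molecule).all()

    def test_config_file_round_trip(self, tmp_path):
        yaml_path = tmp_path / "cfg.yaml"
        yaml_path.write_text(
            "n_cells: 7\nseq_error_rate: 0.001\n"
            "dna_mutation_sites: [[0, tx000, 5, A]]\nseed: 3\n"
        )
        cfg = SimulationConfig.from_file(yaml_path)
        assert cfg.n_cells == 7
        assert cfg.dna_mutation_sites == ((0, "tx000", 5, "A"),)
        flat = tmp_path / "cfg.txt"
        flat.write_text("n_cells=7\nseq_error_rate=0.001\nseed=3\n")
        cfg2 = SimulationConfig.from_file(flat)
        assert cfg2.n_cells == 7 and cfg2.seq_error_rate == 0.001


class TestSimulateCirseq:
    def test_exact_triple_tandem_repeats(self, small_reference, tmp_path):
        fq, truth = simulate_cirseq(
            _clean_config(), small_reference, 3, 40, tmp_path / "c.fastq"
        )
        assert len(truth) == 0
        n = 0
        with open(fq) as fh:
            lines = fh.read().splitlines()
        for i in range(0, len(lines), 4):
            name, seq = lines[i], lines[i + 1]
            assert len(seq) == 120
            unit = seq[:40]
            assert seq == unit * 3
            tx = name.split("|TX:")[1].split("|")[0]
            pos = int(name.split("|POS:")[1])
            assert unit == small_reference[tx][pos : pos + 40]
            n += 1
        assert n > 0

    def test_transcription_errors_shared_by_all_repeats(self, small_reference):
        cfg = _clean_config(background_tx_error_rate=0.02, seq_error_rate=0.0)
        sim = SimulatedCirseq.generate(cfg, small_reference, 3, 50)
        any_mismatch = False
        for i in range(sim.n_fragments):
            read = sim.read_sequence(i)
            copies = read.reshape(3, 50)
            assert (copies == copies[0]).all()
            tx = small_reference.ids[sim.frag_tx[i]]
            refslice = small_reference.codes(tx)[
                sim.frag_start[i] : sim.frag_start[i] + 50
            ]
            any_mismatch = any_mismatch or (copies[0] != refslice).any()
        assert any_mismatch, "expected at least one transcription error"

    def test_sequencing_discordance_matches_enumeration(self):
        # independent per-copy errors: fraction of repeat-discordant
        # columns should match the closed form from exhaustive enumeration
        e = 0.01
        ref = ReferenceSet.random(2, 300, seed=9)
        cfg = _clean_config(
            seq_error_rate=e, cirseq_fragments=1000, seed=21
        )
        sim = SimulatedCirseq.generate(cfg, ref, 3, 60)
        discordant = total = 0
        for i in range(sim.n_fragments):
            copies = sim.read_sequence(i).reshape(3, 60)
            same = (copies == copies[0]).all(axis=0)
            discordant += int((~same).sum())
            total += 60
        p_all_same = (1 - e) ** 3 + 3 * (e / 3) ** 3
        expect = 1 - p_all_same
        sigma = np.sqrt(expect * (1 - expect) / total)
        assert abs(discordant / total - expect) <= 4 * sigma

    def test_rejects_bad_geometry(self, small_reference, tmp_path):
        with pytest.raises(ValueError, match="repeat_count"):
            simulate_cirseq(_clean_config(), small_reference, 1, 40, tmp_path / "x")
        with pytest.raises(ValueError, match="fragment_length"):
            simulate_cirseq(_clean_config(), small_reference, 3, 0, tmp_path / "x")
        with pytest.raises(ValueError, match="shortest"):
            simulate_cirseq(_clean_config(), small_reference, 3, 10**5, tmp_path / "x")
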