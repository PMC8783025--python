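"""Read simulator: isoform mixture, error model, truncation, pooling."""

import numpy as np
import pytest

import valveseq as vs
from valveseq import io as vio


class TestTranscripts:
    def test_te_one_always_ends_at_the_drawn_position(self, one_design):
        model = vs.default_truth_model(one_design, 1.0, polyA_length=0)
        (pos,) = model.termination_weights
        rng = np.random.default_rng(0)
        for _ in range(50):
            read = vs.simulate_transcript(one_design, model, rng)
            assert read.is_terminated
            assert read.termination_position == pos
            assert read.sequence == one_design.reference_sequence[:pos]

    def test_te_zero_always_full_length(self, one_design):
        model = vs.default_truth_model(one_design, 0.0, polyA_length=5)
        rng = np.random.default_rng(0)
        for _ in range(50):
            read = vs.simulate_transcript(one_design, model, rng)
            assert not read.is_terminated
            assert read.sequence == one_design.reference_sequence + "AAAAA"

    def test_terminated_count_near_binomial_mean(self, one_design):
        model = vs.default_truth_model(one_design, 0.8)
        rng = np.random.default_rng(123)
        n = 1000
        k = sum(vs.simulate_transcript(one_design, model, rng).is_terminated for _ in range(n))
        sd = np.sqrt(n * 0.8 * 0.2)
        assert abs(k - n * 0.8) <= 3 * sd

    def test_position_outside_terminator_rejected(self, one_design):
        model = vs.TruthModel(one_design.id, 0.5, {one_design.x_s: 1.0})
        with pytest.raises(ValueError, match="outside terminator"):
            vs.simulate_transcript(one_design, model, np.random.default_rng(0))


class TestSubstitutions:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(1)
        assert vs.apply_substitutions("ACGTACGT", 0.0, rng) == "ACGTACGT"

    def test_rate_one_changes_every_base(self):
        rng = np.random.default_rng(1)
        seq = "ACGT" * 25
        out = vs.apply_substitutions(seq, 1.0, rng)
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_hamming_distance_near_binomial_mean(self):
        rng = np.random.default_rng(7)
        n = 10_000
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), n))
        out = vs.apply_substitutions(seq, 0.15, rng)
        dist = sum(a != b for a, b in zip(seq, out))
        sd = np.sqrt(n * 0.15 * 0.85)
        assert abs(dist - n * 0.15) <= 3 * sd


class TestIndels:
    def test_rate_zero_is_identity(self):
        assert vs.apply_indels("ACGTACGT", 0.0, np.random.default_rng(0)) == "ACGTACGT"

    def test_length_drift_is_symmetric(self):
        rng = np.random.default_rng(5)
        seq = "".join(np.random.default_rng(6).choice(list("ACGT"), 2000))
        lengths = [len(vs.apply_indels(seq, 0.05, rng)) for _ in range(50)]
        # insertions and deletions are equally likely: mean length preserved
        assert abs(np.mean(lengths) - 2000) < 15

    def test_demux_survives_moderate_indels(self, small_designs):
        from valveseq.demux import DesignLibrary

        designs = small_designs[:6]
        lib = DesignLibrary(designs)
        rng = np.random.default_rng(9)
        correct = 0
        for d in designs:
            seq = vs.apply_indels(d.reference_sequence, 0.05, rng)
            a = vs.assign_read("r", seq, lib)
            correct += a.design_id == d.id
        assert correct == len(designs)


class TestTruncation:
    def test_prob_zero_is_identity(self, one_design):
        read = vs.SimulatedRead("r", "A" * 100, one_design.id, False)
        out = vs.apply_truncation(read, 0.0, np.random.default_rng(0))
        assert out.sequence == read.sequence and out.truncation_position is None

    def test_no_legal_cut_is_identity(self):
        read = vs.SimulatedRead("r", "ACGT" * 25, "d", False)
        out = vs.apply_truncation(read, 1.0, np.random.default_rng(0), min_keep=100)
        assert out.sequence == read.sequence and out.truncation_position is None

    def test_truncated_fraction_near_binomial_mean(self):
        rng = np.random.default_rng(11)
        n = 10_000
        read = vs.SimulatedRead("r", "ACGT" * 50, "d", False)
        k = sum(
            vs.apply_truncation(read, 0.5, rng).truncation_position is not None
            for _ in range(n)
        )
        assert abs(k - n * 0.5) <= 3 * np.sqrt(n * 0.25)

    def test_cut_removes_prefix_only(self):
        rng = np.random.default_rng(3)
        seq = "".join(np.random.default_rng(4).choice(list("ACGT"), 200))
        read = vs.SimulatedRead("r", seq, "d", False)
        for _ in range(20):
            out = vs.apply_truncation(read, 1.0, rng, min_keep=50)
            cut = out.truncation_position
            assert 1 <= cut <= 150
            assert out.sequence == seq[cut:]


class TestPool:
    def test_counts_and_truth_table(self, small_designs):
        designs = small_designs[:2]
        models = {d.id: vs.default_truth_model(d, 0.5) for d in designs}
        cfg = vs.SimulationConfig(substitution_rate=0.0, reads_per_design=10, seed=1)
        reads, truth = vs.simulate_pool(designs, models, cfg)
        assert len(reads) == 20
        assert truth["design_id"].value_counts().to_dict() == {d.id: 10 for d in designs}
        assert set(truth.columns) == {
            "read_id", "design_id", "is_terminated", "termination_position",
            "truncation_position",
        }

    def test_fastq_output_is_byte_identical_across_runs(self, small_designs, tmp_path):
        designs = small_designs[:3]
        models = {d.id: vs.default_truth_model(d, 0.4) for d in designs}
        cfg = vs.SimulationConfig(substitution_rate=0.15, reads_per_design=20, seed=5)
        paths = []
        for name in ("a.fastq", "b.fastq"):
            reads, _ = vs.simulate_pool(designs, models, cfg)
            p = tmp_path / name
            vio.write_fastq(reads, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_reads_independent_of_design_iteration_order(self, small_designs):
        designs = small_designs[:3]
        models = {d.id: vs.default_truth_model(d, 0.4) for d in designs}
        cfg = vs.SimulationConfig(substitution_rate=0.15, reads_per_design=5, seed=5)
        fwd, _ = vs.simulate_pool(designs, models, cfg)
        rev, _ = vs.simulate_pool(list(reversed(designs)), models, cfg)
        by_id_fwd = {r.id: r.sequence for r in fwd}
        by_id_rev = {r.id: r.sequence for r in rev}
        assert by_id_fwd == by_id_rev

    def test_missing_truth_model_names_the_design(self, small_designs):
        designs = small_designs[:2]
        models = {designs[0].id: vs.default_truth_model(designs[0], 0.5)}
        with pytest.raises(ValueError, match=designs[1].id):
            vs.simulate_pool(designs, models, vs.SimulationConfig())

    def test_part_frequency_mode_matches_prediction(self, small_parts, small_designs):
        from valveseq.parts import Role

        freqs = {
            role.value: {p.id: 1 / len(small_parts.by_role[role]) for p in small_parts.by_role[role]}
            for role in (Role.SPACER, Role.MODIFIER, Role.TERMINATOR)
        }
        models = {d.id: vs.default_truth_model(d, 0.5) for d in small_designs}
        cfg = vs.SimulationConfig(
            substitution_rate=0.0, seed=2, design_frequency_mode="from_part_freqs",
            part_freqs=freqs, total_reads=4800,
        )
        reads, truth = vs.simulate_pool(small_designs, models, cfg)
        assert len(reads) == 4800
        counts = truth["design_id"].value_counts()
        # uniform prediction: 200 per design, multinomial spread ~ 14
        assert counts.min() > 120 and counts.max() < 280
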