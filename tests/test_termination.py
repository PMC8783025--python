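"""Termination efficiency, deviation correction, termination points, stoichiometry."""

import numpy as np
import pytest

import valveseq as vs
from conftest import measure_design


class TestComputeTe:
    def test_direct_values(self):
        depth = np.array([100] * 10 + [50] * 10)
        assert vs.compute_te(depth, 5, 15) == pytest.approx(0.5)
        assert vs.compute_te(depth, 2, 8) == 0.0

    def test_zero_depth_at_start_is_an_error(self):
        with pytest.raises(ValueError, match="zero read depth"):
            vs.compute_te(np.zeros(10), 2, 8)

    def test_equals_exact_terminated_fraction_on_clean_pool(self, small_designs, clean_pool):
        reads, truth, _ = clean_pool
        for d in small_designs:
            mine = [r for r in reads if r.design_id == d.id]
            profile, _, _ = measure_design(d, mine)
            te = vs.compute_te(profile, d.x_s, d.x_e)
            exact = sum(r.is_terminated for r in mine) / len(mine)
            assert te == pytest.approx(exact, abs=1e-12)

    def test_rmse_within_binomial_noise_across_seeds(self, one_design):
        # 100 seeds at n=500, true te 0.8: RMSE should sit at the binomial SE
        d = one_design
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            k = sum(rng.random() < 0.8 for _ in range(500))
            errs.append(k / 500 - 0.8)
        # oracle check of the estimator itself on one full-pipeline seed
        model = vs.default_truth_model(d, 0.8)
        cfg = vs.SimulationConfig(substitution_rate=0.0, reads_per_design=500, seed=4)
        reads, truth = vs.simulate_pool([d], {d.id: model}, cfg)
        profile, _, _ = measure_design(d, reads)
        te = vs.compute_te(profile, d.x_s, d.x_e)
        assert te == pytest.approx(truth["is_terminated"].mean(), abs=1e-12)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse <= 1.2 * np.sqrt(0.8 * 0.2 / 500)


class TestDeviationModel:
    def test_no_distortion_means_zero_deviation(self, small_designs):
        cfg = vs.SimulationConfig(substitution_rate=0.0, truncation_prob=0.0, seed=1)
        model = vs.fit_deviation_model(
            small_designs[:1], cfg, te_grid=np.linspace(0, 1, 6), reads_per_point=200
        )
        assert np.allclose(model.te_measured, model.te_true, atol=1e-12)
        assert model.deviation_at(0.37) == pytest.approx(0.0)

    def test_truncation_drives_deviation_negative(self, small_designs):
        cfg = vs.SimulationConfig(substitution_rate=0.0, truncation_prob=0.2, seed=1)
        model = vs.fit_deviation_model(
            small_designs[:1], cfg, te_grid=np.linspace(0, 1, 6), reads_per_point=400
        )
        # truncated read-through reads start past x_s, deflating R(x_s)
        assert model.deviation_at(0.5) < 0

    def test_two_read_toy_pool_sign(self, one_design):
        # hand-computed: one intact read-through + one read-through truncated
        # past x_s -> R(x_s) = 1, R(x_e) = 2, te_raw = -1 < 0
        d = one_design
        ref_len = len(d.reference_sequence)
        intact = vs.MappedRead("a", d.id, 0, ref_len, True)
        truncated = vs.MappedRead("b", d.id, d.x_s + 1, ref_len, False)
        profile = vs.build_depth_profile([intact, truncated], ref_len, d.id)
        assert vs.compute_te(profile, d.x_s, d.x_e) == pytest.approx(-1.0)

    def test_grid_must_cover_unit_interval(self):
        with pytest.raises(ValueError):
            vs.DeviationModel(np.array([0.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            vs.DeviationModel(np.array([0.1, 1.0]), np.array([0.1, 1.0]))


class TestCorrectTe:
    def test_zero_deviation_model_is_identity(self):
        model = vs.DeviationModel(np.linspace(0, 1, 11), np.linspace(0, 1, 11))
        for te in (0.0, 0.25, 0.8):
            assert vs.correct_te(te, model) == pytest.approx(te)

    def test_constant_negative_deviation_shifts_up(self):
        grid = np.linspace(0, 1, 11)
        model = vs.DeviationModel(grid, np.clip(grid - 0.1, 0, None))
        assert vs.correct_te(0.4, model) == pytest.approx(0.5)

    def test_out_of_range_raw_value_is_an_error(self):
        model = vs.DeviationModel(np.linspace(0, 1, 11), np.linspace(0, 1, 11))
        with pytest.raises(ValueError, match="upstream"):
            vs.correct_te(1.6, model)

    def test_non_monotone_fit_is_rejected(self):
        grid = np.linspace(0, 1, 5)
        measured = np.array([0.0, 0.4, 0.3, 0.8, 1.0])
        model = vs.DeviationModel(grid, measured)
        with pytest.raises(ValueError, match="monotone"):
            vs.correct_te(0.5, model)


class TestTerminationPoints:
    def test_single_step_profile(self):
        depth = np.array([10] * 8 + [2] * 8)
        p = vs.DepthProfile("d", depth, 10)
        _, drop = vs.normalize_and_delta(p, 0)
        points, dominant, max_drop = vs.call_termination_points(drop, 0, 12)
        assert points == [(8, 1.0)]
        assert dominant == 8
        assert max_drop == pytest.approx(0.8)

    def test_two_equal_steps_tie_toward_five_prime(self):
        depth = np.array([100] * 5 + [75] * 5 + [50] * 5)
        p = vs.DepthProfile("d", depth, 100)
        _, drop = vs.normalize_and_delta(p, 0)
        points, dominant, _ = vs.call_termination_points(drop, 0, 14)
        assert dominant == 5  # 5'-most of the tied maxima
        assert [p_ for p_, _ in points] == [5, 10]
        assert [w for _, w in points] == pytest.approx([0.5, 0.5])

    def test_flat_profile_yields_no_calls(self):
        drop = np.zeros(20)
        points, dominant, max_drop = vs.call_termination_points(drop, 2, 18)
        assert points == [] and dominant is None and max_drop == 0.0

    def test_bimodal_weights_recovered_from_simulation(self, one_design):
        d = one_design
        from valveseq.parts import Role

        ts, te_ = d.intervals[Role.TERMINATOR]
        p1, p2 = ts + 30, ts + 40
        model = vs.TruthModel(d.id, 1.0, {p1: 0.7, p2: 0.3})
        cfg = vs.SimulationConfig(substitution_rate=0.0, reads_per_design=2000, seed=21)
        reads, _ = vs.simulate_pool([d], {d.id: model}, cfg)
        profile, _, _ = measure_design(d, reads)
        _, drop = vs.normalize_and_delta(profile, d.x_s)
        points, dominant, _ = vs.call_termination_points(drop, d.x_s, d.x_e)
        weights = dict(points)
        assert dominant == p1
        assert weights[p1] == pytest.approx(0.7, abs=0.05)
        assert weights[p2] == pytest.approx(0.3, abs=0.05)


class TestUTract:
    @pytest.mark.parametrize(
        "window,expected",
        [("TTTTTTTT", 8), ("GCTTCTTT", 5), ("GCAGCAGC", 0)],
    )
    def test_counts_in_window(self, window, expected):
        ref = "ACGCACGC" + window + "GGCC"
        assert vs.count_u_tract(ref, 16) == expected

    def test_invariant_outside_window(self):
        ref_a = "AAAAAAAA" + "GCTTCTTT"
        ref_b = "CGCGCGCG" + "GCTTCTTT"
        assert vs.count_u_tract(ref_a, 16) == vs.count_u_tract(ref_b, 16) == 5

    def test_position_too_small_is_an_error(self):
        with pytest.raises(ValueError):
            vs.count_u_tract("ACGTACGTACGT", 7)

    def test_exclusive_mode_shifts_window(self):
        ref = "ACGCACGG" + "GCTTCTTT" + "GG"
        # inclusive window at position 16 is GCTTCTTT (5 U); exclusive shifts
        # one base upstream to GGCTTCTT (4 U)
        assert vs.count_u_tract(ref, 16, include_final=True) == 5
        assert vs.count_u_tract(ref, 16, include_final=False) == 4


class TestStoichiometry:
    def test_isoform_ratios(self):
        assert vs.isoform_stoichiometry(0.5) == pytest.approx(1.0)
        assert vs.isoform_stoichiometry(0.0) == 0.0
        assert vs.isoform_stoichiometry(11 / 12) == pytest.approx(11.0)
        with pytest.raises(ValueError):
            vs.isoform_stoichiometry(1.0)

    def test_array_product_rule(self):
        assert vs.array_stoichiometry([0.0, 0.0]) == pytest.approx([1, 1, 1])
        assert vs.array_stoichiometry([0.5, 0.5]) == pytest.approx([1, 0.5, 0.25])

    def test_array_abundances_non_increasing(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            tes = rng.uniform(0, 1, size=4)
            ab = vs.array_stoichiometry(tes)
            assert (np.diff(ab) <= 0).all()


class TestMeasureValve:
    def test_full_record_on_clean_profile(self, one_design):
        d = one_design
        model = vs.default_truth_model(d, 0.6)
        (pos,) = model.termination_weights
        cfg = vs.SimulationConfig(substitution_rate=0.0, reads_per_design=400, seed=31)
        reads, truth = vs.simulate_pool([d], {d.id: model}, cfg)
        profile, _, _ = measure_design(d, reads)
        m = vs.measure_valve(profile, d)
        assert m.te_raw == pytest.approx(truth["is_terminated"].mean(), abs=1e-12)
        assert m.dominant_position == pos
        assert m.u_count == 8  # synthetic terminators carry a pure 8-U tract
        assert m.depth_at_xs == len(reads)
        # telescoping equivalence with the profiles module
        _, drop = vs.normalize_and_delta(profile, d.x_s)
        assert drop[d.x_s + 1 : d.x_e + 1].sum() == pytest.approx(m.te_raw, abs=1e-12)
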