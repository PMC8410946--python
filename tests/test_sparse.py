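import numpy as np
import pytest

from epinet.landscapes import SyntheticSpec, generate_sparse_landscape
from epinet.sparse import (CountingOracle, SamplingPlan, compute_observations,
                           design_plan, detect_bin, peel, points_to_pm1,
                           recover_sparse_wht, sample_points)
from epinet.spectral import (Landscape, PseudoBooleanFunction,
                             enumerate_inputs, eval_pbf, fwht)

from conftest import spectra_close


def _random_pbf(d, k, seed, low=1.0, high=10.0):
    rng = np.random.default_rng(seed)
    masks = rng.choice(1 << min(d, 62), size=k, replace=False) if d <= 62 else None
    if masks is None:
        masks = set()
        while len(masks) < k:
            masks.add(int(rng.integers(0, 1 << 62)) << int(rng.integers(0, d - 62)))
        masks = list(masks)
    coefs = rng.uniform(low, high, size=k) * rng.choice([-1, 1], size=k)
    return PseudoBooleanFunction(d=d, terms=[(int(m), float(c))
                                             for m, c in zip(masks, coefs)])


class TestDesignPlan:
    def test_budget_arithmetic_d5(self):
        plan = design_plan(5, k_estimate=2, C=2, b=2, seed=0)
        assert plan.query_budget == 2 * 6 * 4 == 48

    def test_budget_arithmetic_d13(self):
        plan = design_plan(13, k_estimate=30, C=3, b=6, seed=0, strict=False)
        assert plan.query_budget == 3 * 14 * 64 == 2688

    def test_determinism(self):
        p1 = design_plan(8, 4, C=3, b=3, seed=42)
        p2 = design_plan(8, 4, C=3, b=3, seed=42)
        assert p1.columns == p2.columns

    def test_full_rank(self):
        plan = design_plan(10, 8, C=3, b=4, seed=1)
        from epinet.sparse import _gf2_rank
        for group in plan.columns:
            assert _gf2_rank(group) == plan.b

    def test_too_few_bins(self):
        with pytest.raises(ValueError, match="unlikely to converge"):
            design_plan(8, k_estimate=16, C=3, b=3, seed=0, strict=True)
        with pytest.warns(UserWarning):
            design_plan(8, k_estimate=16, C=3, b=3, seed=0, strict=False)

    def test_json_round_trip(self, tmp_path):
        plan = design_plan(7, 4, C=2, b=3, seed=5)
        path = tmp_path / "plan.json"
        plan.to_json(path)
        back = SamplingPlan.from_json(path)
        assert back.columns == plan.columns and back.d == plan.d


class TestSamplePoints:
    def test_reference_row_present(self):
        queries = sample_points(design_plan(5, 2, C=2, b=2, seed=0))
        assert 0 in queries.points  # zero delay, ell = 0

    def test_rows_are_pm1(self):
        queries = sample_points(design_plan(5, 2, C=2, b=2, seed=3))
        X = points_to_pm1(queries.points, 5)
        assert set(np.unique(X)) <= {-1, 1}
        assert X.shape[1] == 5

    def test_dedup_bound(self):
        plan = design_plan(6, 4, C=3, b=3, seed=7)
        queries = sample_points(plan)
        assert queries.n_unique <= plan.query_budget
        assert len(set(queries.points)) == queries.n_unique

    def test_slot_index_consistent(self):
        plan = design_plan(6, 4, C=2, b=3, seed=9)
        queries = sample_points(plan)
        # slot (c, t, ell) must point to the point M_c ell ^ delta_t
        for c in range(plan.C):
            for t, delta in enumerate(plan.delays):
                for ell in range(plan.n_bins):
                    expect = plan.bin_point(c, ell) ^ delta
                    assert queries.points[queries.slot_index[c, t, ell]] == expect


class TestComputeObservations:
    def test_single_term(self):
        # lone term 12 * x1 * x4 -> one nonzero bin per group, amplitude 12
        pbf = PseudoBooleanFunction(d=5, terms=[(0b01001, 12.0)])
        plan = design_plan(5, 1, C=3, b=2, seed=2)
        queries = sample_points(plan)
        values = eval_pbf(pbf, points_to_pm1(queries.points, 5))
        obs = compute_observations(values, queries)
        for c in range(plan.C):
            j = plan.hash_mask(0b01001, c)
            for t in range(plan.n_delays):
                col = obs.bins[c, t]
                assert abs(col[j]) == pytest.approx(12.0)
                others = np.delete(col, j)
                np.testing.assert_allclose(others, 0, atol=1e-9)

    def test_zero_values(self):
        plan = design_plan(5, 2, C=2, b=2, seed=1)
        queries = sample_points(plan)
        obs = compute_observations(np.zeros(queries.n_unique), queries)
        np.testing.assert_array_equal(obs.bins, 0)

    def test_linearity(self):
        plan = design_plan(6, 2, C=2, b=3, seed=4)
        queries = sample_points(plan)
        t1 = PseudoBooleanFunction(d=6, terms=[(0b000011, 5.0)])
        t2 = PseudoBooleanFunction(d=6, terms=[(0b110000, -2.0)])
        X = points_to_pm1(queries.points, 6)
        o1 = compute_observations(eval_pbf(t1, X), queries)
        o2 = compute_observations(eval_pbf(t2, X), queries)
        both = compute_observations(eval_pbf(t1, X) + eval_pbf(t2, X), queries)
        np.testing.assert_allclose(both.bins, o1.bins + o2.bins, atol=1e-9)

    def test_length_mismatch(self):
        queries = sample_points(design_plan(5, 2, C=2, b=2, seed=1))
        with pytest.raises(ValueError):
            compute_observations(np.zeros(queries.n_unique + 1), queries)


class TestDetectBin:
    def test_noiseless_singleton(self):
        d, mask, value = 6, 0b010010, -4.5
        obs = np.full(d + 1, value)
        for i in range(d):
            if (mask >> i) & 1:
                obs[i + 1] = -value
        state = detect_bin(obs, noise_threshold=1e-9)
        assert state.kind == "singleton"
        assert state.mask == mask
        assert state.value == pytest.approx(value)

    def test_zero_ton(self):
        state = detect_bin(np.zeros(8), noise_threshold=1e-9)
        assert state.kind == "zero-ton"

    def test_equal_magnitude_collision(self):
        # two coefficients a and -a in one bin: delay signatures clash
        d, a = 5, 3.0
        m1, m2 = 0b00001, 0b00110
        obs = np.zeros(d + 1)
        for t in range(d + 1):
            delta = 0 if t == 0 else 1 << (t - 1)
            s1 = -1 if (m1 & delta) else 1
            s2 = -1 if (m2 & delta) else 1
            obs[t] = a * s1 - a * s2
        state = detect_bin(obs, noise_threshold=1e-9)
        assert state.kind == "multi-ton"

    def test_hash_consistency_guard(self):
        plan = design_plan(6, 2, C=2, b=3, seed=0)
        mask, value = 0b000101, 2.0
        obs = np.full(7, value)
        for i in range(6):
            if (mask >> i) & 1:
                obs[i + 1] = -value
        wrong_bin = (plan.hash_mask(mask, 0) + 1) % plan.n_bins
        state = detect_bin(obs, 1e-9, plan=plan, group=0, bin_index=wrong_bin)
        assert state.kind == "multi-ton"


class TestPeel:
    def test_worked_example(self, worked_example):
        plan = design_plan(5, 3, C=3, b=3, seed=0)
        queries = sample_points(plan)
        values = eval_pbf(worked_example, points_to_pm1(queries.points, 5))
        result = peel(compute_observations(values, queries), plan)
        assert result.converged
        assert spectra_close(result.spectrum.coefficients,
                             dict(worked_example.terms), tol=1e-9)

    def test_zero_function(self):
        plan = design_plan(5, 2, C=2, b=2, seed=0)
        queries = sample_points(plan)
        result = peel(compute_observations(np.zeros(queries.n_unique), queries),
                      plan)
        assert result.spectrum.coefficients == {}
        assert result.iterations == 0
        assert result.converged

    def test_monte_carlo_d12(self):
        ok = 0
        for trial in range(20):
            pbf = _random_pbf(12, 6, seed=trial)
            plan = design_plan(12, 6, C=3, b=4, seed=100 + trial)
            queries = sample_points(plan)
            values = eval_pbf(pbf, points_to_pm1(queries.points, 12))
            result = peel(compute_observations(values, queries), plan)
            # independent dense oracle
            full = eval_pbf(pbf, enumerate_inputs(12))
            truth = fwht(Landscape(d=12, values=full), tol=1e-9).coefficients
            ok += spectra_close(result.spectrum.coefficients, truth, tol=1e-7)
        assert ok >= 18

    def test_progress_invariants(self):
        pbf = _random_pbf(10, 8, seed=5)
        plan = design_plan(10, 8, C=3, b=5, seed=5)
        queries = sample_points(plan)
        values = eval_pbf(pbf, points_to_pm1(queries.points, 10))
        result = peel(compute_observations(values, queries), plan)
        counts = [len(h) for h in result.history]
        assert counts == sorted(counts)  # nondecreasing recovery
        assert result.converged

    def test_linearity_disjoint(self):
        f1 = PseudoBooleanFunction(d=8, terms=[(0b00000011, 4.0)])
        f2 = PseudoBooleanFunction(d=8, terms=[(0b11000000, -7.0)])
        plan = design_plan(8, 2, C=3, b=3, seed=0)
        for c in range(plan.C):
            assert plan.hash_mask(3, c) != plan.hash_mask(0b11000000, c)
        queries = sample_points(plan)
        X = points_to_pm1(queries.points, 8)
        r1 = peel(compute_observations(eval_pbf(f1, X), queries), plan)
        r2 = peel(compute_observations(eval_pbf(f2, X), queries), plan)
        r12 = peel(compute_observations(eval_pbf(f1, X) + eval_pbf(f2, X),
                                        queries), plan)
        union = {**r1.spectrum.coefficients, **r2.spectrum.coefficients}
        assert spectra_close(r12.spectrum.coefficients, union, tol=1e-9)


class TestRecoverSparseWht:
    def test_d20_exact_and_sublinear(self):
        pbf = _random_pbf(20, 5, seed=8)
        result = recover_sparse_wht(lambda x: eval_pbf(pbf, x), d=20,
                                    k_estimate=5, C=3, b=4, seed=8)
        assert result.converged
        assert spectra_close(result.spectrum.coefficients, dict(pbf.terms),
                             tol=1e-8)
        assert result.queries_unique <= result.queries_planned < (1 << 20) // 100

    def test_constant_oracle(self):
        result = recover_sparse_wht(lambda x: np.full(x.shape[0], 3.25),
                                    d=10, k_estimate=1, C=3, b=2, seed=0)
        assert spectra_close(result.spectrum.coefficients, {0: 3.25}, tol=1e-9)

    def test_noisy_support_recovery(self):
        ok = 0
        for trial in range(10):
            pbf = _random_pbf(14, 6, seed=300 + trial, low=2.0, high=9.0)
            sigma = 0.01 * min(abs(c) for _, c in pbf.terms)
            rng = np.random.default_rng(trial)
            result = recover_sparse_wht(
                lambda x: eval_pbf(pbf, x) + rng.normal(0, sigma, x.shape[0]),
                d=14, k_estimate=6, C=3, b=4, seed=400 + trial)
            ok += set(result.spectrum.coefficients) == {m for m, _ in pbf.terms}
        assert ok >= 9

    def test_oracle_equivalence_dense(self):
        # recovered support/values equal the dense transform's nonzeros
        for trial in range(10):
            pbf = _random_pbf(11, 5, seed=40 + trial)
            result = recover_sparse_wht(lambda x: eval_pbf(pbf, x), d=11,
                                        k_estimate=5, C=3, b=4,
                                        seed=50 + trial)
            full = eval_pbf(pbf, enumerate_inputs(11))
            truth = fwht(Landscape(d=11, values=full), tol=1e-9).coefficients
            assert spectra_close(result.spectrum.coefficients, truth, tol=1e-7)

    def test_query_count_exact(self):
        pbf = _random_pbf(40, 4, seed=77)
        oracle = CountingOracle(lambda x: eval_pbf(pbf, x))
        result = recover_sparse_wht(oracle, d=40, k_estimate=4, C=3, b=3,
                                    seed=77)
        assert result.queries_planned == 3 * 41 * 8
        assert oracle.n_evaluated == result.queries_unique
        assert oracle.n_evaluated <= result.queries_planned
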