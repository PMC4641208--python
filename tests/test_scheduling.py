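import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcpsc.methods import ContactMapCache, DomainStore, default_registry
from mcpsc.scheduling import (
    CostModel,
    PSCJob,
    dispatch_round_robin,
    execute_parallel,
    fit_cost_model,
    generate_jobs,
    job_attribute,
    partition_greedy_lpt,
    partition_random,
    select_cost_model,
    simulate_partition_schedule,
    sort_jobs_desc,
)
from mcpsc.synthetic import FamilySpec, make_family_template, simulate_runtimes
from oracles import optimal_makespan


def weight_job(k: int, weight: int, method: str = "m") -> PSCJob:
    """Job whose product attribute equals `weight` (len_d = 1)."""
    return PSCJob(f"q{k:03d}", f"d{k:03d}", method, "parallel", weight, 1)


def make_domains(n, length=20):
    specs = [FamilySpec(f"dom{k:03d}", "helix", length, 1, 0.0, 0.0, seed=k) for k in range(n)]
    return [make_family_template(s) for s in specs]


class TestGenerateJobs:
    def test_ck34_counts(self):
        domains = make_domains(34, length=12)
        jobs = generate_jobs(domains, domains, [("tm", "parallel"), ("rmsd", "parallel"),
                                                ("usm", "sequential")])
        parallel = [j for j in jobs if j.routing == "parallel"]
        sequential = [j for j in jobs if j.routing == "sequential"]
        assert len(parallel) == 2 * 34 * 34 == 2312
        assert len(sequential) == 1156

    def test_single_pair_three_methods(self):
        d = make_domains(1, length=12)
        jobs = generate_jobs(d, d, [("a", "parallel"), ("b", "parallel"), ("c", "sequential")])
        assert len(jobs) == 3

    def test_many_to_many(self):
        q = make_domains(2, length=12)
        db = make_domains(3, length=14)
        jobs = generate_jobs(q, db, [("a", "parallel"), ("b", "parallel")])
        assert len(jobs) == 12

    def test_self_pairs_included(self):
        d = make_domains(3, length=12)
        jobs = generate_jobs(d, d, [("a", "parallel")])
        assert sum(1 for j in jobs if j.query_id == j.db_id) == 3

    def test_attrs_consistent(self):
        q = make_domains(2, length=16)
        db = make_domains(2, length=24)
        for j in generate_jobs(q, db, [("a", "parallel")]):
            assert j.attr_sum == j.len_q + j.len_d == 40
            assert j.attr_product == j.len_q * j.len_d == 384


class TestPartitionRandom:
    def test_equal_sizes_94_into_47(self):
        jobs = [weight_job(k, k + 1) for k in range(94)]
        parts = partition_random(jobs, 47, seed=0)
        assert all(len(p) == 2 for p in parts)

    def test_deterministic_per_seed(self):
        jobs = [weight_job(k, k + 1) for k in range(20)]
        assert partition_random(jobs, 4, seed=7) == partition_random(jobs, 4, seed=7)
        assert partition_random(jobs, 4, seed=7) != partition_random(jobs, 4, seed=8)

    def test_empty_parts_allowed(self):
        jobs = [weight_job(k, 1) for k in range(3)]
        parts = partition_random(jobs, 5, seed=1)
        assert sum(len(p) == 0 for p in parts) == 2

    @settings(max_examples=25, deadline=None)
    @given(n_jobs=st.integers(1, 40), n_parts=st.integers(1, 10), seed=st.integers(0, 99))
    def test_conservation_and_balance(self, n_jobs, n_parts, seed):
        jobs = [weight_job(k, k + 1) for k in range(n_jobs)]
        parts = partition_random(jobs, n_parts, seed)
        flat = [j for p in parts for j in p]
        assert sorted(j.query_id for j in flat) == sorted(j.query_id for j in jobs)
        sizes = [len(p) for p in parts]
        assert max(sizes) - min(sizes) <= 1


class TestPartitionGreedyLpt:
    def test_weights_54321(self):
        jobs = [weight_job(k, w) for k, w in enumerate([5, 4, 3, 2, 1])]
        parts = partition_greedy_lpt(jobs, 2, "product")
        sums = sorted(sum(j.attr_product for j in p) for p in parts)
        assert sums == [7, 8]
        assert max(sums) == optimal_makespan([5, 4, 3, 2, 1], 2)

    def test_equal_weights_divide_evenly(self):
        jobs = [weight_job(k, 6) for k in range(12)]
        parts = partition_greedy_lpt(jobs, 4, "sum")
        assert {sum(j.attr_sum for j in p) for p in parts} == {21}

    def test_single_job(self):
        parts = partition_greedy_lpt([weight_job(0, 9)], 3, "product")
        assert sorted(len(p) for p in parts) == [0, 0, 1]

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n_jobs=st.integers(1, 12),
        n_parts=st.integers(1, 4),
    )
    def test_lpt_within_guarantee_of_optimal(self, seed, n_jobs, n_parts):
        rng = np.random.default_rng(seed)
        weights = rng.integers(1, 50, size=n_jobs).tolist()
        jobs = [weight_job(k, int(w)) for k, w in enumerate(weights)]
        parts = partition_greedy_lpt(jobs, n_parts, "product")
        flat = sorted(j.query_id for p in parts for j in p)
        assert flat == sorted(j.query_id for j in jobs)  # conservation
        makespan = max(sum(j.attr_product for j in p) for p in parts)
        bound = (4.0 / 3.0 - 1.0 / (3.0 * n_parts)) * optimal_makespan(weights, n_parts)
        assert makespan <= bound + 1e-9


class TestSortJobsDesc:
    def test_basic_order(self):
        jobs = [weight_job(0, 3), weight_job(1, 9), weight_job(2, 1)]
        assert [j.attr_product for j in sort_jobs_desc(jobs, "product")] == [9, 3, 1]

    def test_ties_by_id(self):
        jobs = [weight_job(k, 5) for k in range(6)]
        out = sort_jobs_desc(jobs, "product")
        assert out == jobs  # ids ascend with input order here

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        jobs = [weight_job(k, int(w)) for k, w in enumerate(rng.integers(1, 30, 15))]
        once = sort_jobs_desc(jobs, "sum")
        assert sort_jobs_desc(once, "sum") == once


class TestDispatchRoundRobin:
    def test_descending_costs_two_workers(self):
        jobs = [weight_job(k, w) for k, w in enumerate([4, 3, 2, 1])]
        sched = dispatch_round_robin(jobs, 2, [4.0, 3.0, 2.0, 1.0])
        assert sched.finish_times == (5.0, 5.0)
        assert sched.makespan == 5.0 == optimal_makespan([4, 3, 2, 1], 2)

    def test_single_worker(self):
        jobs = [weight_job(k, 1) for k in range(5)]
        sched = dispatch_round_robin(jobs, 1, [1.0] * 5)
        assert sched.makespan == 5.0
        assert sched.speedup == pytest.approx(1.0)

    def test_equal_costs_zero_idle(self):
        jobs = [weight_job(k, 1) for k in range(12)]
        sched = dispatch_round_robin(jobs, 4, [2.0] * 12)
        assert sched.idle == (0.0,) * 4
        assert sched.efficiency == pytest.approx(1.0)

    def test_cost_count_mismatch(self):
        with pytest.raises(ValueError, match="costs for"):
            dispatch_round_robin([weight_job(0, 1)], 2, [1.0, 2.0])

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000), n_workers=st.integers(1, 8))
    def test_speedup_and_efficiency_bounds(self, seed, n_workers):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        jobs = [weight_job(k, 1) for k in range(n)]
        costs = rng.uniform(0.1, 5.0, n).tolist()
        sched = dispatch_round_robin(jobs, n_workers, costs)
        assert sched.speedup <= n_workers + 1e-9
        assert 0.0 < sched.efficiency <= 1.0 + 1e-12
        assert sched.makespan == pytest.approx(max(sched.finish_times))
        assert sum(len(a) for a in sched.assignments) == n


class TestSimulatePartitionSchedule:
    def test_arithmetic_example(self):
        jobs = [weight_job(k, w) for k, w in enumerate([5, 2, 1, 4, 3])]
        parts = [jobs[:3], jobs[3:]]
        costs = {j: float(j.attr_product) for j in jobs}
        sched = simulate_partition_schedule(parts, costs)
        assert sched.finish_times == (8.0, 7.0)
        assert sched.makespan == 8.0
        assert sched.speedup == pytest.approx(15.0 / 8.0)

    def test_single_partition(self):
        jobs = [weight_job(k, 2) for k in range(4)]
        sched = simulate_partition_schedule([jobs], {j: 2.0 for j in jobs})
        assert sched.speedup == pytest.approx(1.0)

    def test_efficiency_definition(self):
        jobs = [weight_job(k, 1) for k in range(94)]
        parts = partition_random(jobs, 47, seed=3)
        sched = simulate_partition_schedule(parts, {j: 1.0 for j in jobs})
        assert sched.efficiency == pytest.approx(sched.speedup / 47)


@pytest.fixture(scope="module")
def farm():
    domains = make_domains(4, length=20)
    registry = default_registry()
    jobs = generate_jobs(
        domains, domains,
        [(n, registry.routing(n)) for n in ("usm", "tm", "rmsd")],
    )
    return domains, registry, jobs


class TestExecuteParallel:

    def test_worker_count_does_not_change_results(self, farm):
        domains, registry, jobs = farm
        results = []
        for workers in (1, 4):
            store = DomainStore(domains=domains)
            results.append(
                execute_parallel(jobs, workers, registry, store, ContactMapCache(store))
            )
        assert results[0] == results[1]

    def test_usm_only_farm_runs_sequentially(self, farm):
        domains, registry, _ = farm
        jobs = generate_jobs(domains, domains, [("usm", "sequential")])
        store = DomainStore(domains=domains)
        scores = execute_parallel(jobs, 4, registry, store, ContactMapCache(store))
        assert len(scores) == 16
        assert all(s.method == "usm" for s in scores)

    def test_count_conservation(self, farm):
        domains, registry, jobs = farm
        store = DomainStore(domains=domains)
        scores = execute_parallel(jobs, 3, registry, store, ContactMapCache(store))
        assert len(scores) == len(jobs) == 48

    def test_failure_names_job(self, farm):
        domains, registry, _ = farm
        bad = [PSCJob("ghost", "ghost", "usm", "sequential", 5, 5)]
        store = DomainStore(domains=domains)
        with pytest.raises(RuntimeError, match=r"\(ghost, ghost, usm\)"):
            execute_parallel(bad, 1, registry, store, ContactMapCache(store))


class TestCostModel:
    def test_exact_quadratic_recovery(self):
        x = np.arange(1.0, 20.0)
        t = 2.0 * x**2 + 5.0
        model = fit_cost_model(x, t, form="quadratic")
        assert model.residual_ss <= 1e-6
        assert model.coefficients == pytest.approx((2.0, 0.0, 5.0), abs=1e-6)

    def test_quadratic_never_worse_than_linear(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.uniform(1, 100, 30)
            t = rng.uniform(0, 50, 30)
            lin = fit_cost_model(x, t, form="linear")
            quad = fit_cost_model(x, t, form="quadratic")
            assert quad.residual_ss <= lin.residual_ss + 1e-8

    def test_singular_design(self):
        with pytest.raises(ValueError, match="singular"):
            fit_cost_model([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_cost_model([1.0, 2.0], [1.0, 2.0])

    def test_product_model_selected_when_generating(self):
        # costs generated from a quadratic in the product attribute
        rng = np.random.default_rng(11)
        jobs = [
            PSCJob(f"q{k}", f"d{k}", "m", "parallel",
                   int(rng.integers(50, 300)), int(rng.integers(50, 300)))
            for k in range(80)
        ]
        model_true = CostModel("quadratic", "product", (3e-6, 0.0, 0.1), 0.0)
        times = simulate_runtimes(jobs, model_true, noise_sd=0.05, seed=2)
        best = select_cost_model(jobs, times)
        assert best.attribute == "product"
        assert best.form == "quadratic"

    def test_refit_recovers_generating_model(self):
        jobs = [
            PSCJob(f"q{k}", f"d{k}", "m", "parallel", 10 + k, 20 + k) for k in range(25)
        ]
        model_true = CostModel("quadratic", "product", (2.0, 1.0, 5.0), 0.0)
        times = simulate_runtimes(jobs, model_true, noise_sd=0.0, seed=0)
        x = np.array([job_attribute(j, "product") for j in jobs], dtype=float)
        refit = fit_cost_model(x, times, form="quadratic", attribute="product")
        assert refit.coefficients == pytest.approx((2.0, 1.0, 5.0), abs=1e-6)


class TestSchemeDominance:
    def test_table5_ordering_on_simulated_quadratic_costs(self):
        """sorted round-robin <= greedy LPT <= random, mean makespan, 20 seeds."""
        rng_len = np.random.default_rng(99)
        lengths = np.clip(rng_len.normal(180, 100, 34), 90, 497).astype(int)
        domains = [(f"d{k:02d}", int(l)) for k, l in enumerate(lengths)]
        jobs = [
            PSCJob(q, d, m, "parallel", lq, ld)
            for q, lq in domains
            for d, ld in domains
            for m in ("tm", "rmsd")
        ]
        assert len(jobs) == 2312
        model = CostModel("quadratic", "product", (5e-6, 0.0, 0.05), 0.0)
        mk_rand, mk_greedy, mk_rr = [], [], []
        for seed in range(20):
            costs_arr = simulate_runtimes(jobs, model, noise_sd=0.1, seed=seed)
            costs = {j: float(c) for j, c in zip(jobs, costs_arr)}
            parts = partition_random(jobs, 47, seed=seed)
            mk_rand.append(simulate_partition_schedule(parts, costs).makespan)
            parts = partition_greedy_lpt(jobs, 47, "product")
            mk_greedy.append(simulate_partition_schedule(parts, costs).makespan)
            ordered = sort_jobs_desc(jobs, "product")
            mk_rr.append(dispatch_round_robin(ordered, 47, costs).makespan)
        assert np.mean(mk_rr) <= np.mean(mk_greedy) <= np.mean(mk_rand)
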