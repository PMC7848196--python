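"""Objective arithmetic, global fitting and the two-stage shared protocol."""

import numpy as np
import pytest

import circabp as c
from circabp.estimation import FitConfig, fit, joint_fit, objective
from circabp.exceptions import InvalidConfigError
from circabp.model import StateTrajectory


def brute_force_objective(y_exp, y_mod):
    """Independent term-by-term accumulation of the normalized SSE."""
    k, n = y_exp.shape
    total = 0.0
    for i in range(k):
        for j in range(n):
            total += ((y_exp[i, j] - y_mod[i, j]) / y_exp[i, j]) ** 2
    return total / (k * n)


def dataset_from_arrays(grid, y_exp, group="dipper"):
    means = {name: y_exp[i] for i, name in enumerate(c.STATE_NAMES)}
    sds = {name: 0.01 * y_exp[i] for i, name in enumerate(c.STATE_NAMES)}
    return c.ObservedDataset(grid=grid, means=means, sds=sds, group=group)


def trajectory_from_arrays(grid, y_mod):
    return StateTrajectory(grid=grid,
                           values={name: y_mod[i]
                                   for i, name in enumerate(c.STATE_NAMES)})


class TestObjective:
    def test_perfect_model_gives_zero(self):
        grid = c.half_hour_grid(6, step=4.0)
        y = np.abs(np.random.default_rng(0).normal(100, 10, (4, 6)))
        ds = dataset_from_arrays(grid, y)
        traj = trajectory_from_arrays(grid, y.copy())
        assert objective(c.REFERENCE_DIPPER, ds, trajectory=traj) == 0.0

    def test_single_discrepant_point(self):
        # one variable off by 10% at one of N=1 nodes: F = 0.01/(k*N)
        grid = np.array([0.0])
        y_exp = np.full((4, 1), 100.0)
        y_mod = y_exp.copy()
        y_mod[2, 0] = 90.0
        ds = dataset_from_arrays(grid, y_exp)
        traj = trajectory_from_arrays(grid, y_mod)
        f = objective(c.REFERENCE_DIPPER, ds, trajectory=traj)
        assert f == pytest.approx(0.01 / 4.0, rel=1e-14)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        grid = c.half_hour_grid(9, step=2.5)
        y_exp = np.abs(rng.normal(100, 20, (4, 9))) + 1.0
        y_mod = y_exp * (1 + rng.normal(0, 0.05, (4, 9)))
        ds = dataset_from_arrays(grid, y_exp)
        traj = trajectory_from_arrays(grid, y_mod)
        f = objective(c.REFERENCE_DIPPER, ds, trajectory=traj)
        assert f == pytest.approx(brute_force_objective(y_exp, y_mod),
                                  rel=1e-12)

    def test_invariant_to_reordering(self):
        # permuting variables and time points leaves F unchanged
        rng = np.random.default_rng(4)
        grid = c.half_hour_grid(10, step=2.0)
        y_exp = np.abs(rng.normal(100, 20, (4, 10))) + 1.0
        y_mod = y_exp * (1 + rng.normal(0, 0.05, (4, 10)))
        f0 = brute_force_objective(y_exp, y_mod)
        pv, pt = rng.permutation(4), rng.permutation(10)
        f1 = brute_force_objective(y_exp[np.ix_(pv, pt)],
                                   y_mod[np.ix_(pv, pt)])
        ds = dataset_from_arrays(grid, y_exp)
        traj = trajectory_from_arrays(grid, y_mod)
        assert objective(c.REFERENCE_DIPPER, ds, trajectory=traj) == \
            pytest.approx(f0, rel=1e-12) == pytest.approx(f1, rel=1e-12)


FREE = ("ki1", "ki3", "ki4", "k2")
PERTURB = (1.8, 0.6, 1.5, 0.7)


def perturbed_base(params=c.REFERENCE_DIPPER, free=FREE, factors=PERTURB):
    return params.with_values(
        free, [getattr(params, n) * f for n, f in zip(free, factors)])


@pytest.fixture(scope="module")
def recovery(clean_dipper_dataset, dipper_inputs):
    cfg = FitConfig(free=FREE, base=perturbed_base(), n_starts=10,
                    n_refine=2, seed=3)
    return fit(clean_dipper_dataset, dipper_inputs, cfg)


class TestFit:
    def test_noise_free_recovery_within_5_percent(self, recovery):
        assert recovery.objective < 1e-6
        for name in FREE:
            est = getattr(recovery.params, name)
            true = getattr(c.REFERENCE_DIPPER, name)
            assert abs(est / true - 1) < 0.05

    def test_trace_monotone_nonincreasing(self, recovery):
        assert np.all(np.diff(recovery.trace) <= 0)

    def test_perturbing_optimum_increases_objective(self, recovery,
                                                    clean_dipper_dataset,
                                                    dipper_inputs):
        f_opt = objective(recovery.params, clean_dipper_dataset,
                          dipper_inputs)
        for name in FREE:
            for fac in (0.99, 1.01):
                p = recovery.params.replace(
                    **{name: getattr(recovery.params, name) * fac})
                assert objective(p, clean_dipper_dataset,
                                 dipper_inputs) > f_opt

    def test_same_seed_identical_result(self, clean_dipper_dataset,
                                        dipper_inputs):
        cfg = dict(free=("ki1", "ki4"), base=perturbed_base(), n_starts=6,
                   n_refine=1, max_nfev=30, seed=9)
        r1 = fit(clean_dipper_dataset, dipper_inputs, FitConfig(**cfg))
        r2 = fit(clean_dipper_dataset, dipper_inputs, FitConfig(**cfg))
        assert r1.objective == r2.objective
        assert r1.params == r2.params
        assert np.array_equal(r1.trace, r2.trace)

    def test_truth_at_bound_is_returned(self, dipper_inputs):
        # data generated at the lower bound of a 1-parameter search
        true = c.REFERENCE_DIPPER
        ds = c.generate_dataset(true, dipper_inputs, noise_cv=0.0, seed=0)
        lb = true.ki4
        cfg = FitConfig(free=("ki4",), base=true.replace(ki4=lb * 4),
                        bounds={"ki4": (lb, lb * 10)}, n_starts=5,
                        n_refine=1, seed=2)
        res = fit(ds, dipper_inputs, cfg)
        assert res.params.ki4 == pytest.approx(lb, rel=1e-4)

    def test_result_json_round_trip(self, recovery, tmp_path):
        path = tmp_path / "fit.json"
        recovery.to_json(path)
        back = c.FitResult.from_json(path)
        assert back.params == recovery.params
        assert back.objective == recovery.objective


class TestFitConfig:
    def test_shared_fixed_overlap_rejected(self):
        with pytest.raises(InvalidConfigError):
            FitConfig(shared=("k3",))

    def test_nonpositive_bounds_rejected(self):
        with pytest.raises(InvalidConfigError):
            FitConfig(bounds={"ki1": (-1.0, 10.0)})

    def test_round_trip_through_dict(self):
        cfg = FitConfig(free=("ki1", "ki4"), n_starts=7, seed=42,
                        bounds={"ki1": (10.0, 1e4)})
        back = FitConfig.from_dict(cfg.to_dict())
        assert back.free == cfg.free
        assert back.bounds == cfg.bounds
        assert back.seed == cfg.seed


class TestJointFit:
    def test_empty_shared_reduces_to_independent_fits(self,
                                                      clean_dipper_dataset,
                                                      dipper_inputs):
        ds_n = c.ObservedDataset(grid=clean_dipper_dataset.grid.copy(),
                                 means={k: v.copy() for k, v in
                                        clean_dipper_dataset.means.items()},
                                 sds={k: v.copy() for k, v in
                                      clean_dipper_dataset.sds.items()},
                                 group="non_dipper")
        cfg = FitConfig(free=("ki1", "ki4"), shared=(),
                        base=perturbed_base(), n_starts=5, n_refine=1,
                        max_nfev=30, seed=6)
        joint = joint_fit(clean_dipper_dataset, ds_n, dipper_inputs,
                          dipper_inputs, cfg)
        solo = fit(clean_dipper_dataset, dipper_inputs, cfg)
        assert joint.shared_values == {}
        assert joint.dipper.objective == solo.objective
        assert joint.dipper.params.to_array() == \
            pytest.approx(solo.params.to_array(), rel=0, abs=0)

    def test_identical_datasets_give_matching_group_parameters(
            self, clean_dipper_dataset, dipper_inputs):
        ds_n = c.ObservedDataset(grid=clean_dipper_dataset.grid.copy(),
                                 means={k: v.copy() for k, v in
                                        clean_dipper_dataset.means.items()},
                                 sds={k: v.copy() for k, v in
                                      clean_dipper_dataset.sds.items()},
                                 group="non_dipper")
        cfg = FitConfig(free=("k1", "ki1", "ki4"), shared=("k1",),
                        base=perturbed_base(), n_starts=6, n_refine=1,
                        seed=8)
        joint = joint_fit(clean_dipper_dataset, ds_n, dipper_inputs,
                          dipper_inputs, cfg)
        for name in ("ki1", "ki4"):
            a = getattr(joint.dipper.params, name)
            b = getattr(joint.non_dipper.params, name)
            assert a == pytest.approx(b, rel=1e-3)
        assert joint.dipper.params.k1 == joint.non_dipper.params.k1
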