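import numpy as np
import pytest
from scipy import sparse

from letimpt import (CompositeObjective, LETGoals, ObjectiveSpec, Scenario,
                     SolverParams, StructureSet, VoxelGrid,
                     dose_objective_and_gradient, let_objective_and_gradient,
                     optimize, run_dose_opt, run_let_opt)
from letimpt.phantom import PrescriptionSpec
from letimpt.planning import InfluenceSet
from letimpt.pencilbeam import Spot
from tests.conftest import toy_influence, toy_structures


def single_spot_problem():
    """1 voxel, 1 spot, dose-per-weight 2, uniform objective at 78."""
    grid = VoxelGrid((1, 1, 1), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    inf = InfluenceSet(
        engine="pb", spots=[Spot(0, 100.0, 0, 0, 0)], beams=[], grid=grid,
        scenarios=[Scenario()],
        matrices={"nominal": sparse.csc_matrix(np.array([[2.0]]))},
        row_subsets={"nominal": None},
    )
    ss = toy_structures(grid)
    objs = [ObjectiveSpec("ctv", "uniform_dose", 78.0, 1.0)]
    return inf, ss, objs


def test_closed_form_single_spot_optimum():
    inf, ss, objs = single_spot_problem()
    comp = CompositeObjective(inf, ss, objs)
    f, g = comp(np.array([39.0]))
    assert f == pytest.approx(0.0, abs=1e-12)
    plan = optimize(np.array([1.0]), comp)
    assert plan.weights[0] == pytest.approx(39.0, abs=1e-4)


def test_zero_penalties_give_zero_objective():
    inf, ss, _ = single_spot_problem()
    objs = [ObjectiveSpec("ctv", "uniform_dose", 78.0, 0.0)]
    f, g = dose_objective_and_gradient(np.array([5.0]), inf, objs, ss)
    assert f == 0.0 and np.all(g == 0.0)


def finite_difference(fun, w, h=1e-6):
    g = np.zeros_like(w)
    for j in range(w.size):
        wp, wm = w.copy(), w.copy()
        wp[j] += h
        wm[j] -= h
        g[j] = (fun(wp) - fun(wm)) / (2.0 * h)
    return g


def test_dose_gradient_matches_finite_differences():
    scens = [Scenario(), Scenario((2.0, 0, 0), 1.0, "sx"),
             Scenario((0, 0, 0), 1.02, "r+")]
    inf, grid = toy_influence(n_vox=20, n_spots=6, seed=3, with_let=False,
                              scenarios=scens)
    ss = toy_structures(grid, ("ctv", "rectum"))
    objs = [
        ObjectiveSpec("ctv", "uniform_dose", 10.0, 1.0, robust=True),
        ObjectiveSpec("ctv", "min_dose", 9.0, 2.0),
        ObjectiveSpec("rectum", "max_dose", 6.0, 0.5),
        ObjectiveSpec("rectum", "mean_dose", 3.0, 0.7),
        ObjectiveSpec("rectum", "eud_max", 5.0, 0.4, eud_a=4.0),
    ]
    comp = CompositeObjective(inf, ss, objs)
    rng = np.random.default_rng(0)
    for _ in range(3):
        w = rng.uniform(0.5, 3.0, 6)
        f, g = comp(w)
        g_fd = finite_difference(lambda x: comp(x)[0], w)
        assert np.allclose(g, g_fd, rtol=1e-5, atol=1e-7)


def test_let_gradient_matches_finite_differences():
    inf, grid = toy_influence(n_vox=15, n_spots=5, seed=11, with_let=True)
    ss = toy_structures(grid, ("ctv",))
    objs = [
        ObjectiveSpec("ctv", "uniform_dose", 8.0, 0.5),
        ObjectiveSpec("ctv", "let_min_target", 4.0, 3.0),
        ObjectiveSpec("ctv", "let_max_oar", 3.0, 1.5),
    ]
    comp = CompositeObjective(inf, ss, objs)
    rng = np.random.default_rng(1)
    for _ in range(3):
        w = rng.uniform(0.5, 3.0, 5)
        f, g = comp(w)
        g_fd = finite_difference(lambda x: comp(x)[0], w, h=1e-6)
        assert np.allclose(g, g_fd, rtol=1e-4, atol=1e-6)


def test_single_spot_let_term_scale_invariant():
    """With one spot, LET_d is weight-independent: LET gradient is zero."""
    grid = VoxelGrid((3, 1, 1), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    d = sparse.csc_matrix(np.array([[1.0], [2.0], [0.5]]))
    c = sparse.csc_matrix(np.array([[2.0], [4.0], [1.0]]))  # LET = 2 everywhere
    inf = InfluenceSet("mc", [Spot(0, 100.0, 0, 0, 0)], [], grid, [Scenario()],
                       {"nominal": d}, {"nominal": None}, dose_let=c)
    ss = toy_structures(grid)
    objs = [ObjectiveSpec("ctv", "let_min_target", 4.0, 1.0)]
    f, g = let_objective_and_gradient(np.array([2.0]), inf, objs, ss)
    assert f == pytest.approx(4.0)  # hinge (4 - 2)^2 everywhere
    assert np.allclose(g, 0.0, atol=1e-12)


def test_raising_high_let_spot_weight_raises_letd():
    d = np.array([[1.0, 1.0]])
    c = np.array([[1.0, 3.0]])  # spot 1 has LET 3, spot 0 LET 1
    from letimpt import combine_letd

    w = np.array([1.0, 1.0])
    l0, _ = combine_letd(d, c, w)
    l1, _ = combine_letd(d, c, np.array([1.0, 2.0]))
    assert l1[0] > l0[0]


def test_missing_dose_let_columns_error():
    inf, grid = toy_influence(with_let=False)
    ss = toy_structures(grid)
    objs = [ObjectiveSpec("ctv", "let_min_target", 4.0, 1.0)]
    with pytest.raises(ValueError, match="dose x LET"):
        CompositeObjective(inf, ss, objs)


def test_descent_and_iteration_log():
    inf, grid = toy_influence(n_vox=25, n_spots=8, seed=2, with_let=False)
    ss = toy_structures(grid)
    objs = [ObjectiveSpec("ctv", "uniform_dose", 12.0, 1.0)]
    comp = CompositeObjective(inf, ss, objs)
    plan = optimize(np.full(8, 0.1), comp)
    log = np.asarray(plan.iteration_log)
    assert np.all(np.diff(log) <= 1e-9)
    assert plan.provenance["objective"] <= log[0]


def test_small_instance_matches_multistart_oracle():
    inf, grid = toy_influence(n_vox=10, n_spots=5, seed=7, with_let=False)
    ss = toy_structures(grid)
    objs = [ObjectiveSpec("ctv", "uniform_dose", 10.0, 1.0),
            ObjectiveSpec("ctv", "max_dose", 10.5, 2.0)]
    comp = CompositeObjective(inf, ss, objs)
    plan = optimize(np.ones(5), comp, SolverParams(maxiter=500, ftol=1e-15))
    # dense multi-start oracle with an independent solver configuration
    from scipy.optimize import minimize

    best = np.inf
    rng = np.random.default_rng(3)
    for _ in range(8):
        w0 = rng.uniform(0.0, 5.0, 5)
        res = minimize(comp, w0, jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * 5,
                       options={"maxiter": 2000, "ftol": 1e-16})
        best = min(best, res.fun)
    assert plan.provenance["objective"] <= best + 1e-6


def test_unit_invariance_under_rescaling():
    """Scaling influence by k and weights by 1/k leaves doses unchanged."""
    inf, grid = toy_influence(n_vox=12, n_spots=4, seed=8, with_let=True)
    ss = toy_structures(grid)
    objs = [ObjectiveSpec("ctv", "uniform_dose", 9.0, 1.0),
            ObjectiveSpec("ctv", "let_min_target", 4.0, 2.0)]
    comp = CompositeObjective(inf, ss, objs)
    k = 3.7
    inf2, _ = toy_influence(n_vox=12, n_spots=4, seed=8, with_let=True)
    inf2.matrices = {lab: m * k for lab, m in inf2.matrices.items()}
    inf2.dose_let = inf2.dose_let * k
    comp2 = CompositeObjective(inf2, ss, objs)
    w = np.array([1.0, 2.0, 0.5, 3.0])
    f1, g1 = comp(w)
    f2, g2 = comp2(w / k)
    assert f1 == pytest.approx(f2, rel=1e-12)
    assert np.allclose(g1, g2 / k, rtol=1e-10)


def test_selective_robustness_isolation():
    """Worsening a scenario that only hurts the OAR never changes the
    robust target term's worst-scenario choice (OARs evaluate nominal)."""
    scens = [Scenario(), Scenario((1.0, 0, 0), 1.0, "s1"),
             Scenario((0, 1.0, 0), 1.0, "s2")]
    inf, grid = toy_influence(n_vox=16, n_spots=4, seed=13, with_let=False,
                              scenarios=scens)
    ss_masks = {"ctv": np.zeros(grid.dims, bool),
                "rectum": np.zeros(grid.dims, bool)}
    ss_masks["ctv"][:8] = True
    ss_masks["rectum"][8:] = True
    ss = StructureSet(grid, ss_masks)
    objs = [ObjectiveSpec("ctv", "uniform_dose", 10.0, 1.0, robust=True),
            ObjectiveSpec("rectum", "max_dose", 2.0, 1.0)]
    comp = CompositeObjective(inf, ss, objs)
    w = np.ones(4)
    f_before, _ = comp(w)
    # inflate scenario s2 rows only where the rectum lives
    mod = inf.matrices["s2"].toarray()
    mod[8:, :] *= 10.0
    inf.matrices["s2"] = sparse.csc_matrix(mod)
    comp2 = CompositeObjective(inf, ss, objs)
    f_after, _ = comp2(w)
    assert f_after == pytest.approx(f_before)


def test_run_dose_opt_rejects_let_objectives():
    inf, grid = toy_influence(with_let=False)
    ss = toy_structures(grid)
    with pytest.raises(ValueError):
        run_dose_opt(inf, ss, PrescriptionSpec(),
                     objectives=[ObjectiveSpec("ctv", "let_min_target", 4.0, 1.0)])


def test_zero_let_penalty_collapses_to_dose_only():
    inf, grid = toy_influence(n_vox=14, n_spots=5, seed=21, with_let=True)
    ss = toy_structures(grid)
    pres = PrescriptionSpec(total_dose_gy_rbe=10.0)
    objs = [ObjectiveSpec("ctv", "uniform_dose", 10.0, 1.0)]
    goals = LETGoals(ctv_goal_kev_um=4.5, ctv_weight=0.0, oar_weight=0.0,
                     oar_structures=())
    plan_let = run_let_opt(inf, ss, pres, np.ones(5), let_goals=goals,
                           objectives=objs)
    comp = CompositeObjective(inf, ss, objs)
    plan_dose = optimize(np.ones(5), comp)
    f_let, _ = comp(plan_let.weights)
    f_dose, _ = comp(plan_dose.weights)
    assert abs(f_let - f_dose) < 1e-8


def test_objective_spec_validation():
    with pytest.raises(ValueError):
        ObjectiveSpec("ctv", "banana", 1.0)
    with pytest.raises(ValueError):
        ObjectiveSpec("ctv", "uniform_dose", 1.0, weight=-1.0)
    with pytest.raises(ValueError):
        ObjectiveSpec("ctv", "eud_max", 1.0, eud_a=0.0)
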