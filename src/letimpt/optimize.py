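"""Inverse planning: robust dose optimization and LET-incorporated
re-optimization.

The dose stage minimizes a weighted sum of per-structure quadratic
penalties, with *selective* robustness: objectives flagged robust (the
targets) are evaluated on their worst uncertainty scenario each iteration,
while organ-at-risk objectives use the nominal scenario.  The LET stage
adds hinge-quadratic terms on the voxelwise dose-averaged LET

    L_i(w) = sum_j w_j c_ij / sum_j w_j d_ij

(c = dose x LET, d = dose columns of the stochastic engine), pushing
LET_d up toward a goal inside the CTV and down below caps in OARs, with
the exact ratio gradient dL_i/dw_j = (c_ij - L_i d_ij) / sum_k w_k d_ik.
Weights are optimized with projected quasi-Newton descent (L-BFGS-B)
under w >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize as sopt
from scipy import sparse

from .phantom import PrescriptionSpec, StructureSet
from .planning import InfluenceSet, Scenario

DOSE_KINDS = ("uniform_dose", "max_dose", "min_dose", "mean_dose", "eud_max")
LET_KINDS = ("let_min_target", "let_max_oar")


@dataclass(frozen=True)
class ObjectiveSpec:
    """One penalty term of the composite cost."""

    structure: str
    kind: str
    ref: float                  # Gy(RBE) for dose kinds, keV/um for LET kinds
    weight: float = 1.0
    eud_a: float | None = None  # exponent for eud kinds
    robust: bool = False        # worst-scenario (True) vs nominal evaluation

    def __post_init__(self):
        if self.kind not in DOSE_KINDS + LET_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.weight < 0:
            raise ValueError("penalty weight must be nonnegative")
        if self.kind == "eud_max" and (self.eud_a is None or self.eud_a == 0):
            raise ValueError("eud objectives need a nonzero exponent")


@dataclass
class Plan:
    """Optimized spot weights with provenance."""

    weights: np.ndarray
    provenance: dict = field(default_factory=dict)
    iteration_log: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if np.any(self.weights < 0) or np.any(~np.isfinite(self.weights)):
            raise ValueError("plan weights must be finite and nonnegative")


@dataclass(frozen=True)
class SolverParams:
    maxiter: int = 300
    gtol: float = 1e-6
    ftol: float = 1e-11


# ---------------------------------------------------------------------------
# composite objective


class CompositeObjective:
    """Precomputed structure submatrices + evaluation of value and gradient."""

    def __init__(self, influence: InfluenceSet, structures: StructureSet,
                 objectives: list[ObjectiveSpec], eud_floor_gy: float = 0.01,
                 let_dose_floor_rel: float = 1e-9):
        self.objectives = list(objectives)
        self.eud_floor = eud_floor_gy
        self.let_dose_floor_rel = let_dose_floor_rel
        self.scenario_labels = [s.label for s in influence.scenarios]
        self._dose_mats: list[list[sparse.csr_matrix]] = []
        self._let_mats: list[tuple[sparse.csr_matrix, sparse.csr_matrix] | None] = []
        for obj in self.objectives:
            if obj.structure not in structures:
                raise KeyError(f"unknown structure {obj.structure!r}")
            flat = np.flatnonzero(structures[obj.structure].ravel())
            if flat.size == 0:
                raise ValueError(f"structure {obj.structure!r} is empty")
            if obj.kind in DOSE_KINDS:
                labels = self.scenario_labels if obj.robust else ["nominal"]
                mats = []
                for label in labels:
                    rows = influence.rows_for(label, flat)
                    mats.append(influence.matrices[label][rows].tocsr())
                self._dose_mats.append(mats)
                self._let_mats.append(None)
            else:
                if influence.dose_let is None:
                    raise ValueError("LET objectives need dose x LET columns "
                                     "(stochastic-engine influence)")
                rows = influence.rows_for("nominal", flat)
                self._dose_mats.append([influence.matrices["nominal"][rows].tocsr()])
                self._let_mats.append((self._dose_mats[-1][0],
                                       influence.dose_let[rows].tocsr()))

    def _dose_term(self, obj: ObjectiveSpec, mat, w):
        d = mat @ w
        n = d.size
        if obj.kind == "uniform_dose":
            v = d - obj.ref
            return float(np.mean(v**2)), (2.0 / n) * (mat.T @ v)
        if obj.kind == "max_dose":
            v = np.maximum(d - obj.ref, 0.0)
            return float(np.mean(v**2)), (2.0 / n) * (mat.T @ v)
        if obj.kind == "min_dose":
            v = np.maximum(obj.ref - d, 0.0)
            return float(np.mean(v**2)), (-2.0 / n) * (mat.T @ v)
        if obj.kind == "mean_dose":
            v = max(float(d.mean()) - obj.ref, 0.0)
            g = (2.0 * v / n) * (mat.T @ np.ones(n)) if v > 0 else np.zeros(mat.shape[1])
            return v**2, g
        # eud_max
        a = obj.eud_a
        de = np.maximum(d, self.eud_floor)
        eud = float(np.mean(de**a) ** (1.0 / a))
        v = max(eud - obj.ref, 0.0)
        if v <= 0:
            return 0.0, np.zeros(mat.shape[1])
        inner = eud ** (1.0 - a) * de ** (a - 1.0) / n
        inner[d < self.eud_floor] = 0.0
        return v**2, (2.0 * v) * (mat.T @ inner)

    def _let_term(self, obj: ObjectiveSpec, mats, w):
        d_mat, c_mat = mats
        dw = d_mat @ w
        cw = c_mat @ w
        floor = self.let_dose_floor_rel * max(float(dw.max()), 1e-300)
        active = dw > floor
        n = int(active.sum())
        if n == 0:
            return 0.0, np.zeros(d_mat.shape[1])
        L = np.zeros_like(dw)
        L[active] = cw[active] / dw[active]
        if obj.kind == "let_min_target":
            h = np.maximum(obj.ref - L, 0.0) * active
            sign = -1.0
        else:
            h = np.maximum(L - obj.ref, 0.0) * active
            sign = 1.0
        f = float(np.sum(h**2)) / n
        a_vec = np.zeros_like(dw)
        a_vec[active] = h[active] / dw[active]
        grad = sign * (2.0 / n) * (c_mat.T @ a_vec - d_mat.T @ (a_vec * L))
        return f, grad

    def __call__(self, w: np.ndarray):
        w = np.asarray(w, float)
        total = 0.0
        grad = np.zeros_like(w)
        for obj, mats, lmats in zip(self.objectives, self._dose_mats, self._let_mats):
            if obj.weight == 0.0:
                continue
            if obj.kind in DOSE_KINDS:
                best_f, best_g = -1.0, None
                for mat in mats:  # worst scenario, ties -> lowest index
                    f, g = self._dose_term(obj, mat, w)
                    if f > best_f + 0.0:
                        best_f, best_g = f, g
                total += obj.weight * best_f
                grad += obj.weight * best_g
            else:
                f, g = self._let_term(obj, lmats, w)
                total += obj.weight * f
                grad += obj.weight * g
        if not np.isfinite(total):
            raise FloatingPointError("non-finite objective value")
        return total, grad


def dose_objective_and_gradient(w, influence: InfluenceSet,
                                objectives: list[ObjectiveSpec],
                                structures: StructureSet):
    """Composite dose objective and its exact (active-scenario) gradient."""
    dose_objs = [o for o in objectives if o.kind in DOSE_KINDS]
    return CompositeObjective(influence, structures, dose_objs)(w)


def let_objective_and_gradient(w, influence_mc: InfluenceSet,
                               objectives: list[ObjectiveSpec],
                               structures: StructureSet):
    """Composite dose + LET objective on stochastic-engine influence."""
    return CompositeObjective(influence_mc, structures, objectives)(w)


# ---------------------------------------------------------------------------
# solver


def optimize(w0: np.ndarray, objective, solver_params: SolverParams = SolverParams(),
             provenance: dict | None = None) -> Plan:
    """Projected quasi-Newton descent (L-BFGS-B) under w >= 0.

    Deterministic given (w0, parameters); the returned plan's objective
    never exceeds the starting value (the best iterate is kept).
    """
    w0 = np.asarray(w0, float)
    if np.any(w0 < 0):
        raise ValueError("initial weights must be nonnegative")
    f0, _ = objective(w0)
    if not np.isfinite(f0):
        raise ValueError("objective non-finite at the initial weights")
    best = {"f": f0, "w": w0.copy(), "last": f0}
    log: list[float] = [f0]

    def wrapped(w):
        f, g = objective(w)
        best["last"] = f
        if f < best["f"]:
            best["f"] = f
            best["w"] = w.copy()
        return f, g

    res = sopt.minimize(
        wrapped, w0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * w0.size,
        callback=lambda xk: log.append(best["last"]),
        options={"maxiter": solver_params.maxiter, "ftol": solver_params.ftol,
                 "gtol": solver_params.gtol, "maxls": 40},
    )
    plan = Plan(
        weights=best["w"],
        provenance={**(provenance or {}), "solver": "L-BFGS-B",
                    "maxiter": solver_params.maxiter, "status": int(res.status),
                    "message": str(res.message), "n_iter": int(res.nit),
                    "objective": float(best["f"])},
        iteration_log=log,
        flags={"iteration_cap_reached": bool(res.status == 1)},
    )
    return plan


# ---------------------------------------------------------------------------
# planning directives


@dataclass(frozen=True)
class LETGoals:
    """LET objectives of the re-optimization stage.

    The CTV goal (keV/um) is the level the hinge penalty pulls voxel
    LET_d up to; OAR caps bound LET_d where those structures receive
    dose.  Penalty weights are in (keV/um)^-2 relative to the Gy^-2 dose
    weights.
    """

    ctv_goal_kev_um: float = 4.5
    ctv_weight: float = 40.0
    oar_cap_kev_um: float = 3.0
    oar_weight: float = 2.0
    oar_structures: tuple[str, ...] = ("rectum", "bladder")

    def objectives(self) -> list[ObjectiveSpec]:
        out = [ObjectiveSpec("ctv", "let_min_target", self.ctv_goal_kev_um,
                             self.ctv_weight)]
        for s in self.oar_structures:
            out.append(ObjectiveSpec(s, "let_max_oar", self.oar_cap_kev_um,
                                     self.oar_weight))
        return out


def default_dose_objectives(prescription: PrescriptionSpec) -> list[ObjectiveSpec]:
    """Simplified planning directive for the prostate phantom.

    Uniform target dose slightly above prescription (so D98 clears it),
    robust on the targets only; nominal max-dose caps on the OARs and a
    mild hotspot control on the body.
    """
    rx = prescription.total_dose_gy_rbe
    return [
        ObjectiveSpec("stv", "uniform_dose", 1.02 * rx, weight=1.0, robust=True),
        ObjectiveSpec("ctv", "uniform_dose", 1.02 * rx, weight=2.0, robust=True),
        ObjectiveSpec("ctv", "min_dose", 1.015 * rx, weight=20.0),
        ObjectiveSpec("rectum", "max_dose", 1.00 * rx, weight=0.3),
        ObjectiveSpec("bladder", "max_dose", 1.00 * rx, weight=0.3),
        ObjectiveSpec("body", "max_dose", 1.07 * rx, weight=0.1),
    ]


def initial_weights(influence: InfluenceSet, structures: StructureSet,
                    prescription: PrescriptionSpec,
                    target: str = "stv") -> np.ndarray:
    """Uniform start: prescription over the mean target dose at unit weights."""
    flat = np.flatnonzero(structures[target].ravel())
    mean_dose = float((influence.nominal()[flat] @ np.ones(influence.n_spots)).mean())
    if mean_dose <= 0:
        raise ValueError("target receives no dose at unit weights")
    return np.full(influence.n_spots,
                   prescription.total_dose_gy_rbe / mean_dose)


def run_dose_opt(influence_pb: InfluenceSet, structures: StructureSet,
                 prescription: PrescriptionSpec,
                 objectives: list[ObjectiveSpec] | None = None,
                 solver_params: SolverParams = SolverParams()) -> Plan:
    """Dose-only selective robust optimization (targets robust, OARs nominal)."""
    objs = objectives if objectives is not None else default_dose_objectives(prescription)
    if any(o.kind in LET_KINDS for o in objs):
        raise ValueError("dose-only stage cannot take LET objectives")
    comp = CompositeObjective(influence_pb, structures, objs)
    w0 = initial_weights(influence_pb, structures, prescription)
    plan = optimize(w0, comp, solver_params,
                    provenance={"stage": "dose_opt", "engine": influence_pb.engine,
                                "objectives": [vars(o) for o in objs]})
    # post-hoc coverage check on the nominal dose
    flat = np.flatnonzero(structures["ctv"].ravel())
    d_ctv = influence_pb.nominal()[flat] @ plan.weights
    from .evaluate import dose_index  # local import to avoid a cycle

    d98 = dose_index(d_ctv, influence_pb.grid.voxel_volume_cc, "D98")
    plan.flags["d98_meets_prescription"] = bool(d98 >= prescription.total_dose_gy_rbe)
    plan.flags["ctv_d98"] = float(d98)
    return plan


def run_let_opt(influence_mc: InfluenceSet, structures: StructureSet,
                prescription: PrescriptionSpec, w_init: np.ndarray,
                let_goals: LETGoals = LETGoals(),
                objectives: list[ObjectiveSpec] | None = None,
                reference_geud: dict | None = None,
                solver_params: SolverParams = SolverParams()) -> Plan:
    """LET-incorporated re-optimization, warm-started from the dose plan.

    The composite cost keeps the dose objectives (evaluated on the
    stochastic influence, nominal scenario) and adds the LET terms.  If
    ``reference_geud`` carries the dose-optimized plan's gEUD values
    {structure: (value, exponent)}, the returned plan is checked post hoc
    against the acceptance criteria (CTV gEUD within 2%; OAR gEUD increase
    bounded by 2% or 2 Gy(RBE)) and flagged accordingly.
    """
    dose_objs = objectives if objectives is not None else default_dose_objectives(prescription)
    dose_objs = [replace(o, robust=False) for o in dose_objs if o.kind in DOSE_KINDS]
    objs = dose_objs + let_goals.objectives()
    comp = CompositeObjective(influence_mc, structures, objs)
    plan = optimize(np.asarray(w_init, float), comp, solver_params,
                    provenance={"stage": "let_opt", "engine": influence_mc.engine,
                                "warm_start": True,
                                "let_goals": vars(let_goals),
                                "objectives": [vars(o) for o in objs]})
    if reference_geud:
        from .evaluate import geud

        vv = influence_mc.grid.voxel_volume_cc
        for name, (ref_val, a) in reference_geud.items():
            flat = np.flatnonzero(structures[name].ravel())
            val = geud(influence_mc.matrices["nominal"][flat] @ plan.weights, a)
            if name == "ctv":
                ok = abs(val - ref_val) <= 0.02 * ref_val
            else:
                ok = (val - ref_val) <= max(0.02 * ref_val, 2.0)
            plan.flags[f"geud_{name}"] = float(val)
            plan.flags[f"geud_{name}_ok"] = bool(ok)
    return plan
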