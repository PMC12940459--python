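"""Surrogate inverse optimizer: gEUD objectives -> deliverable-style dose.

This stands in for the commercial treatment planning system inside the
outer search loop.  A plan candidate is a set of gEUD objectives — one
lower and one upper objective per target volume, one upper objective per
organ at risk, each with a goal (Gy), a volume-effect exponent ``a``
(+40 upper / -40 lower) and a priority in [0, 1000].  The engine finds
non-negative beamlet weights minimising a composite one-sided quadratic
penalty on the structure gEUDs plus a small quadratic smoothing term on
neighbouring beamlet weights (a stand-in for deliverability), by projected
gradient descent with backtracking line search from a deterministic cold
start.

The engine is a pluggable contract: the outer loop only needs a callable
mapping objectives to per-structure dose; any engine honouring that
contract can replace this one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .phantom import BeamletMatrix, Phantom
from .radbio import DoseDistribution, FractionationScheme, geud

__all__ = [
    "GEUDObjective",
    "EngineConfig",
    "PlanDose",
    "default_objective_template",
    "composite_penalty",
    "optimize_plan",
]


@dataclass(frozen=True)
class GEUDObjective:
    """One gEUD planning objective.

    ``direction`` "upper" penalises gEUD above the goal (a = +40),
    "lower" penalises gEUD below the goal (a = -40).
    """

    structure: str
    direction: str  # "lower" | "upper"
    goal_gy: float
    priority: float
    a: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in {"lower", "upper"}:
            raise ValueError(f"direction must be 'lower' or 'upper', got {self.direction!r}")
        if not 0.0 <= self.priority <= 1000.0:
            raise ValueError(f"priority must lie in [0, 1000], got {self.priority!r}")
        if self.goal_gy < 0:
            raise ValueError("goal must be non-negative")
        if self.a is None:
            object.__setattr__(self, "a", 40.0 if self.direction == "upper" else -40.0)
        elif self.a == 0:
            raise ValueError("gEUD exponent a must be nonzero")


def default_objective_template(
    target_names: Sequence[str], oar_names: Sequence[str]
) -> List[GEUDObjective]:
    """The canonical 13-objective layout: a lower and an upper objective per
    target volume, one upper objective per OAR (goals/priorities zeroed,
    to be filled by the search)."""
    objs: List[GEUDObjective] = []
    for name in target_names:
        objs.append(GEUDObjective(name, "lower", 0.0, 0.0))
        objs.append(GEUDObjective(name, "upper", 0.0, 0.0))
    for name in oar_names:
        objs.append(GEUDObjective(name, "upper", 0.0, 0.0))
    return objs


@dataclass(frozen=True)
class EngineConfig:
    """Numerical settings of the surrogate engine."""

    max_iterations: int = 120
    tolerance: float = 1e-6  # relative objective decrease
    smoothing: float = 2e-4  # weight-adjacency quadratic coefficient
    weight_floor: float = 0.0
    step_init: float = 1.0
    jitter: float = 0.0  # optional seeded start perturbation (Gy at peak)

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0 or self.smoothing < 0:
            raise ValueError("tolerance must be > 0 and smoothing >= 0")


@dataclass(frozen=True)
class PlanDose:
    """Optimised plan: beamlet weights, per-structure voxel doses, and
    convergence diagnostics."""

    weights: np.ndarray
    structure_dose: Dict[str, np.ndarray]
    voxel_volume_cm3: float
    penalty_history: np.ndarray
    converged: bool

    def distributions(
        self, scheme: FractionationScheme
    ) -> Dict[str, DoseDistribution]:
        return {
            name: DoseDistribution(
                dose, np.full(dose.shape, self.voxel_volume_cm3), scheme
            )
            for name, dose in self.structure_dose.items()
        }


def composite_penalty(
    structure_dose: Mapping[str, np.ndarray],
    objectives: Sequence[GEUDObjective],
    voxel_volume_cm3: float = 1.0,
    scheme: FractionationScheme = FractionationScheme(20),
) -> float:
    """Priority-weighted sum of squared one-sided gEUD deviations.

    Sum_k (priority_k / 1000) * max(0, +/-(gEUD_k - goal_k))^2; zero iff
    every objective is met.
    """
    total = 0.0
    for obj in objectives:
        if obj.structure not in structure_dose:
            raise KeyError(f"no dose for structure {obj.structure!r}")
        dose = np.asarray(structure_dose[obj.structure], dtype=float)
        dist = DoseDistribution(dose, np.full(dose.shape, voxel_volume_cm3), scheme)
        g = geud(dist, obj.a)
        dev = g - obj.goal_gy if obj.direction == "upper" else obj.goal_gy - g
        if dev > 0:
            total += (obj.priority / 1000.0) * dev * dev
    return total


def _geud_and_grad(dose: np.ndarray, a: float) -> tuple[float, np.ndarray]:
    """gEUD of an equal-volume voxel set and its gradient w.r.t. dose."""
    d = np.maximum(dose, 1e-6)  # keep a<0 powers finite on cold voxels
    ref = d.max() if a > 0 else d.min()
    r = d / ref
    mean_pow = float(np.mean(r**a))
    g = ref * mean_pow ** (1.0 / a)
    # dG/dD_i = (1/M) * (D_i/G)^(a-1) ... expressed stably via the ratios
    grad = (r ** (a - 1.0)) * mean_pow ** (1.0 / a - 1.0) / d.size
    return g, grad


def optimize_plan(
    objectives: Sequence[GEUDObjective],
    beamlets: BeamletMatrix,
    phantom: Phantom,
    config: EngineConfig = EngineConfig(),
    seed: int | None = None,
    scheme: FractionationScheme = FractionationScheme(20),
) -> PlanDose:
    """Minimise the composite gEUD penalty over non-negative beamlet weights.

    Projected gradient descent with Armijo backtracking; the penalty
    sequence is non-increasing by construction.  Start is a deterministic
    cold start (zero weights) unless ``config.jitter`` > 0, in which case a
    seeded uniform perturbation is added — candidate evaluation inside the
    outer loop stays reproducible for a fixed seed.
    """
    objs = list(objectives)
    for obj in objs:
        if obj.structure not in beamlets.structure_rows:
            raise KeyError(f"objective references unknown structure {obj.structure!r}")

    A = beamlets.matrix
    n = beamlets.n_beamlets
    w = np.zeros(n)
    if config.jitter > 0:
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.0, config.jitter, size=n)

    adj = beamlets.adjacency
    lam = config.smoothing

    def objective_and_grad(weights: np.ndarray):
        dose_roi = weights @ A
        total = 0.0
        grad_dose = np.zeros_like(dose_roi)
        for obj in objs:
            rows = beamlets.structure_rows[obj.structure]
            g, ggrad = _geud_and_grad(dose_roi[rows], obj.a)
            dev = g - obj.goal_gy if obj.direction == "upper" else obj.goal_gy - g
            if dev > 0:
                pr = obj.priority / 1000.0
                total += pr * dev * dev
                sign = 1.0 if obj.direction == "upper" else -1.0
                grad_dose[rows] += 2.0 * pr * dev * sign * ggrad
        grad_w = A @ grad_dose
        if adj.size:
            diff = weights[adj[:, 0]] - weights[adj[:, 1]]
            total += lam * float(np.sum(diff**2))
            np.add.at(grad_w, adj[:, 0], 2.0 * lam * diff)
            np.add.at(grad_w, adj[:, 1], -2.0 * lam * diff)
        return total, grad_w

    history = []
    f, grad = objective_and_grad(w)
    history.append(f)
    step = config.step_init
    converged = False
    slow_steps = 0  # consecutive steps with negligible relative decrease
    for _ in range(config.max_iterations):
        if f <= 1e-14:
            converged = True
            break
        improved = False
        for _ in range(40):  # backtracking
            w_new = np.maximum(w - step * grad, config.weight_floor)
            f_new, grad_new = objective_and_grad(w_new)
            if f_new < f - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True  # stationary within numeric resolution
            break
        rel_drop = (f - f_new) / max(f, 1e-30)
        w, f, grad = w_new, f_new, grad_new
        history.append(f)
        step *= 1.6  # re-expand after a successful step
        # a single tiny drop can be an unlucky step length, not
        # stationarity; require it to persist before stopping
        slow_steps = slow_steps + 1 if rel_drop < config.tolerance else 0
        if slow_steps >= 3:
            converged = True
            break

    return PlanDose(
        weights=w,
        structure_dose=beamlets.structure_dose(w),
        voxel_volume_cm3=beamlets.roi_volume_cm3,
        penalty_history=np.asarray(history),
        converged=converged,
    )
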