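"""Particle swarm search over gEUD goals and priorities.

The outer loop of prescription-free planning: each particle is a full plan
parameterization (a goal in Gy and a priority in [0, 1000] for each of the
13 gEUD objectives), the fitness is the complication-free tumor control
P_+ of the plan the dose engine produces for that parameterization, and
the search is confined to the clinically meaningful box derived from the
requested response levels — target-volume goal ranges spanning the doses
that yield the minimum acceptable and maximum aimed TCP (volume-dependent
through the TCP model), OAR goal ranges capped at the dose yielding the
maximum acceptable NTCP.

Candidates violating a response level are not discarded: they receive a
penalized fitness strictly below every feasible candidate so the swarm is
steered back into the feasible region while the archive keeps the full
search history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import EngineConfig, GEUDObjective, default_objective_template, optimize_plan
from .phantom import BeamletMatrix, Phantom
from .radbio import (
    DoseDistribution,
    FractionationScheme,
    NTCPParams,
    ResponseSummary,
    TCPParams,
    compute_response_summary,
    uniform_dose_for_level,
)

__all__ = [
    "SwarmConfig",
    "ResponseLevels",
    "SamplingBounds",
    "PlanRecord",
    "PSOResult",
    "CandidateEvaluator",
    "derive_sampling_bounds",
    "run_pso",
]


@dataclass(frozen=True)
class SwarmConfig:
    """PSO hyper-parameters (published defaults).

    ``initial_velocity_attenuation`` scales the uniform initial velocity
    draw; ``reset_probability`` is the per-particle, per-epoch chance of a
    uniform position re-draw (velocity zeroed, personal best retained).
    """

    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    initial_velocity_attenuation: float = 0.1
    reset_probability: float = 0.001
    n_particles: int = 150
    n_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_epochs < 1:
            raise ValueError("n_particles and n_epochs must be >= 1")
        if not 0.0 <= self.reset_probability <= 1.0:
            raise ValueError("reset_probability must lie in [0, 1]")


@dataclass(frozen=True)
class ResponseLevels:
    """Clinician-set TCP/NTCP levels confining the search."""

    tcp_min: float = 0.85
    tcp_max: float = 0.9999
    ntcp_max: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.tcp_min <= self.tcp_max < 1.0:
            raise ValueError("need 0 < tcp_min <= tcp_max < 1")
        if not 0.0 < self.ntcp_max < 1.0:
            raise ValueError("need 0 < ntcp_max < 1")


@dataclass(frozen=True)
class SamplingBounds:
    """Per-objective goal ranges plus the [0, 1000] priority box.

    The particle position is the concatenation [goals, priorities] over
    the objective template order (26 dimensions for 13 objectives).
    """

    template: Tuple[GEUDObjective, ...]
    goal_low: np.ndarray
    goal_high: np.ndarray
    priority_low: float = 0.0
    priority_high: float = 1000.0

    def __post_init__(self) -> None:
        lo = np.asarray(self.goal_low, dtype=float)
        hi = np.asarray(self.goal_high, dtype=float)
        if lo.shape != hi.shape or lo.size != len(self.template):
            raise ValueError("goal bounds must match the objective template")
        if np.any(lo > hi):
            raise ValueError("goal_low must not exceed goal_high")
        object.__setattr__(self, "goal_low", lo)
        object.__setattr__(self, "goal_high", hi)

    @property
    def n_objectives(self) -> int:
        return len(self.template)

    @property
    def lower(self) -> np.ndarray:
        return np.concatenate(
            [self.goal_low, np.full(self.n_objectives, self.priority_low)]
        )

    @property
    def upper(self) -> np.ndarray:
        return np.concatenate(
            [self.goal_high, np.full(self.n_objectives, self.priority_high)]
        )


def derive_sampling_bounds(
    levels: ResponseLevels,
    tcp_params: Mapping[str, TCPParams],
    ntcp_params: Mapping[str, NTCPParams],
    volumes: Mapping[str, float],
    scheme: FractionationScheme,
    oar_goal_floor: float = 0.0,
    template: Sequence[GEUDObjective] | None = None,
) -> SamplingBounds:
    """Goal sampling ranges from the requested TCP/NTCP levels.

    Target-volume goals range between the uniform physical doses yielding
    ``tcp_min`` and ``tcp_max`` for that structure's volume; OAR goals
    between ``oar_goal_floor`` and the dose yielding ``ntcp_max``.
    """
    if template is None:
        template = default_objective_template(
            list(tcp_params), list(ntcp_params)
        )
    lo, hi = [], []
    for obj in template:
        if obj.structure in tcp_params:
            params = tcp_params[obj.structure]
            vol = volumes[obj.structure]
            lo.append(uniform_dose_for_level(levels.tcp_min, params, vol, scheme))
            hi.append(uniform_dose_for_level(levels.tcp_max, params, vol, scheme))
        elif obj.structure in ntcp_params:
            params = ntcp_params[obj.structure]
            lo.append(oar_goal_floor)
            hi.append(uniform_dose_for_level(levels.ntcp_max, params, None, scheme))
        else:
            raise KeyError(f"no response parameters for {obj.structure!r}")
    return SamplingBounds(tuple(template), np.asarray(lo), np.asarray(hi))


@dataclass(frozen=True)
class PlanRecord:
    """One evaluated candidate: parameterization, response, provenance."""

    position: np.ndarray
    objectives: Tuple[GEUDObjective, ...]
    summary: Optional[ResponseSummary]
    feasible: bool
    violation: float
    fitness: float
    epoch: int = -1
    particle: int = -1
    seed: int = 0
    weights: Optional[np.ndarray] = None
    converged: bool = True
    error: Optional[str] = None

    @property
    def p_plus(self) -> float:
        return self.summary.p_plus if self.summary is not None else float("nan")


@dataclass
class CandidateEvaluator:
    """Maps a particle position to a :class:`PlanRecord`.

    Decodes the position into 13 gEUD objectives (sorting each target
    volume's goal pair so the lower goal never exceeds the upper), runs
    the dose engine, evaluates TCP/NTCP/P_B/P_I/P_+ on the resulting
    per-structure doses, and checks the response levels.
    """

    bounds: SamplingBounds
    beamlets: BeamletMatrix
    phantom: Phantom
    tcp_params: Mapping[str, TCPParams]
    ntcp_params: Mapping[str, NTCPParams]
    levels: ResponseLevels
    scheme: FractionationScheme
    engine_config: EngineConfig = field(default_factory=EngineConfig)
    store_weights: bool = True

    def decode(self, position: np.ndarray) -> Tuple[GEUDObjective, ...]:
        n = self.bounds.n_objectives
        goals = np.array(position[:n], dtype=float)
        priorities = np.array(position[n:], dtype=float)
        template = self.bounds.template
        # enforce lower <= upper per target volume by sorting the pair
        by_structure: Dict[str, List[int]] = {}
        for k, obj in enumerate(template):
            if obj.structure in self.tcp_params:
                by_structure.setdefault(obj.structure, []).append(k)
        for idxs in by_structure.values():
            if len(idxs) == 2:
                lo_k = next(k for k in idxs if template[k].direction == "lower")
                hi_k = next(k for k in idxs if template[k].direction == "upper")
                g_lo, g_hi = sorted((goals[lo_k], goals[hi_k]))
                goals[lo_k], goals[hi_k] = g_lo, g_hi
        return tuple(
            replace(obj, goal_gy=float(goals[k]), priority=float(np.clip(priorities[k], 0, 1000)))
            for k, obj in enumerate(template)
        )

    def __call__(
        self, position: np.ndarray, epoch: int = -1, particle: int = -1, seed: int = 0
    ) -> PlanRecord:
        objectives = self.decode(position)
        try:
            plan = optimize_plan(
                objectives,
                self.beamlets,
                self.phantom,
                self.engine_config,
                seed=seed,
                scheme=self.scheme,
            )
            dists = plan.distributions(self.scheme)
            summary = compute_response_summary(
                {n: dists[n] for n in self.tcp_params},
                self.tcp_params,
                {n: dists[n] for n in self.ntcp_params},
                self.ntcp_params,
            )
        except Exception as exc:  # engine failure: log and continue
            return PlanRecord(
                position=np.array(position, dtype=float),
                objectives=objectives,
                summary=None,
                feasible=False,
                violation=float("inf"),
                fitness=-float("inf"),
                epoch=epoch,
                particle=particle,
                seed=seed,
                error=f"{type(exc).__name__}: {exc}",
            )
        violation = 0.0
        for name in self.tcp_params:
            violation += max(0.0, self.levels.tcp_min - summary.tcp_by_target[name])
        for name in self.ntcp_params:
            violation += max(0.0, summary.ntcp_by_oar[name] - self.levels.ntcp_max)
        feasible = violation == 0.0
        fitness = summary.p_plus if feasible else summary.p_plus - 1.0 - violation
        return PlanRecord(
            position=np.array(position, dtype=float),
            objectives=objectives,
            summary=summary,
            feasible=feasible,
            violation=violation,
            fitness=fitness,
            epoch=epoch,
            particle=particle,
            seed=seed,
            weights=plan.weights if self.store_weights else None,
            converged=plan.converged,
        )


@dataclass(frozen=True)
class PSOResult:
    """Search outcome: the full candidate archive, the incumbent, and the
    per-epoch progress log."""

    archive: Tuple[PlanRecord, ...]
    best: PlanRecord
    progress: pd.DataFrame


def run_pso(
    swarm: SwarmConfig,
    bounds: SamplingBounds,
    evaluate: Callable[..., PlanRecord],
) -> PSOResult:
    """Standard global-best PSO over the bounded box.

    Velocity update v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x);
    positions are clamped to the bounds with the velocity zeroed on
    clamped coordinates; ties on equal fitness keep the earlier candidate.
    Fully reproducible for a fixed ``swarm.seed``.
    """
    rng = np.random.default_rng(swarm.seed)
    lower, upper = bounds.lower, bounds.upper
    span = upper - lower
    dim = lower.size

    pos = lower + rng.uniform(size=(swarm.n_particles, dim)) * span
    vel = (
        rng.uniform(-1.0, 1.0, size=(swarm.n_particles, dim))
        * span
        * swarm.initial_velocity_attenuation
    )

    archive: List[PlanRecord] = []
    pbest: List[PlanRecord] = [None] * swarm.n_particles  # type: ignore[list-item]
    gbest: Optional[PlanRecord] = None
    progress_rows = []

    for epoch in range(swarm.n_epochs):
        for i in range(swarm.n_particles):
            rec = evaluate(pos[i], epoch=epoch, particle=i, seed=swarm.seed)
            archive.append(rec)
            if pbest[i] is None or rec.fitness > pbest[i].fitness:
                pbest[i] = rec
            if gbest is None or rec.fitness > gbest.fitness:
                gbest = rec
        n_feas = sum(r.feasible for r in archive)
        feas_pplus = [r.p_plus for r in archive if r.feasible]
        progress_rows.append(
            {
                "epoch": epoch,
                "best_fitness": gbest.fitness,
                "best_p_plus": max(feas_pplus) if feas_pplus else float("nan"),
                "median_fitness": float(
                    np.median([r.fitness for r in archive[-swarm.n_particles:]])
                ),
                "n_feasible_total": n_feas,
            }
        )
        if epoch == swarm.n_epochs - 1:
            break
        r1 = rng.uniform(size=(swarm.n_particles, dim))
        r2 = rng.uniform(size=(swarm.n_particles, dim))
        pb = np.array([p.position for p in pbest])
        vel = (
            swarm.inertia * vel
            + swarm.cognitive * r1 * (pb - pos)
            + swarm.social * r2 * (gbest.position - pos)
        )
        pos = pos + vel
        low_hit = pos < lower
        high_hit = pos > upper
        pos = np.clip(pos, lower, upper)
        vel[low_hit | high_hit] = 0.0
        # occasional diversification: re-draw position, keep personal best
        resets = rng.uniform(size=swarm.n_particles) < swarm.reset_probability
        if np.any(resets):
            pos[resets] = lower + rng.uniform(size=(resets.sum(), dim)) * span
            vel[resets] = 0.0

    return PSOResult(
        archive=tuple(archive), best=gbest, progress=pd.DataFrame(progress_rows)
    )
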