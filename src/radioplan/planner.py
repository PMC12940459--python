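"""High-level facade: one object that runs the whole prescription-free
planning pipeline and one that carries its results.

``PrescriptionFreePlanner`` wires the synthetic phantom, the beamlet
influence matrix, the radiobiological parameter sets, the response-level
bounds and the particle swarm together; ``run()`` returns a
``PlanningResult`` holding the candidate archive, the Pareto front in
(P_I, 1 - P_B), the selected highest-P_+ plan, its dose and DVHs, and a
text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from . import datasets
from .config import RunConfig
from .engine import EngineConfig
from .evaluation import DifferentialDVH, build_dvh, cumulative, homogeneity_index
from .pareto import ParetoFront, ParetoPoint, build_front, front_table
from .phantom import BeamletMatrix, Phantom, generate_beamlets, generate_phantom
from .radbio import DoseDistribution, FractionationScheme, NTCPParams, TCPParams
from .swarm import (
    CandidateEvaluator,
    PlanRecord,
    PSOResult,
    ResponseLevels,
    SamplingBounds,
    SwarmConfig,
    derive_sampling_bounds,
    run_pso,
)

__all__ = ["PrescriptionFreePlanner", "PlanningResult"]


@dataclass(frozen=True)
class PlanningResult:
    """Outcome of one prescription-free optimization run."""

    archive: tuple
    front: ParetoFront
    selected: PlanRecord
    progress: pd.DataFrame
    planner: "PrescriptionFreePlanner"

    @property
    def selected_summary(self):
        return self.selected.summary

    def selected_doses(self) -> Dict[str, DoseDistribution]:
        """Per-structure dose distributions of the selected plan."""
        doses = self.planner.beamlets.structure_dose(self.selected.weights)
        vol = self.planner.beamlets.roi_volume_cm3
        return {
            name: DoseDistribution(d, np.full(d.shape, vol), self.planner.scheme)
            for name, d in doses.items()
        }

    def selected_dvhs(self, bin_width: float = 0.05) -> Dict[str, DifferentialDVH]:
        return {
            name: build_dvh(dist, bin_width, name)
            for name, dist in self.selected_doses().items()
        }

    def selected_target_dose_grid(self) -> np.ndarray:
        """Selected plan's dose on the phantom grid, masked to the target
        volumes (for gamma comparison between runs)."""
        grid = self.planner.beamlets.dose_grid(self.selected.weights)
        tv = np.zeros(self.planner.phantom.grid_shape, dtype=bool)
        for name in self.planner.phantom.target_names:
            tv |= self.planner.phantom.structure_masks[name]
        return np.where(tv, grid, 0.0)

    def front_table(self) -> pd.DataFrame:
        return front_table(self.front)

    def archive_table(self) -> pd.DataFrame:
        from .dvhio import archive_frame

        return archive_frame(self.archive)

    def summary(self) -> str:
        s = self.selected.summary
        lines = [
            "Prescription-free planning result",
            "=================================",
            f"candidates evaluated : {len(self.archive)}",
            f"feasible candidates  : {sum(r.feasible for r in self.archive)}",
            f"Pareto front size    : {len(self.front.points)}",
            f"utopia point (P_I, 1-P_B): ({self.front.utopia[0]:.5f}, "
            f"{self.front.utopia[1]:.5f})",
            "",
            "Selected (highest P_+) plan",
            "---------------------------",
        ]
        for name, tcp in s.tcp_by_target.items():
            lines.append(f"TCP  {name:<18s}: {100*tcp:7.2f} %")
        for name, ntcp in s.ntcp_by_oar.items():
            lines.append(f"NTCP {name:<18s}: {100*ntcp:7.2f} %")
        lines += [
            f"P_B  = {100*s.p_benefit:7.2f} %",
            f"P_I  = {100*s.p_injury:7.2f} %",
            f"P_+  = {100*s.p_plus:7.2f} %",
        ]
        hi = {
            name: homogeneity_index(cumulative(dvh))
            for name, dvh in self.selected_dvhs().items()
            if name in self.planner.phantom.target_names
        }
        lines.append("")
        for name, value in hi.items():
            lines.append(f"HI   {name:<18s}: {value:7.3f}")
        return "\n".join(lines)


class PrescriptionFreePlanner:
    """End-to-end prescription-free planning on a synthetic phantom.

    Parameters mirror the run configuration: a phantom (or a config to
    generate one), the TCP parameter set id or explicit parameter
    mappings, the response levels, the fractionation, and the swarm and
    engine settings.
    """

    def __init__(
        self,
        phantom: Phantom,
        beamlets: BeamletMatrix,
        tcp_params: Mapping[str, TCPParams],
        ntcp_params: Mapping[str, NTCPParams],
        levels: ResponseLevels = ResponseLevels(),
        scheme: FractionationScheme = FractionationScheme(20),
        swarm: SwarmConfig = SwarmConfig(),
        engine: EngineConfig = EngineConfig(),
    ) -> None:
        self.phantom = phantom
        self.beamlets = beamlets
        self.tcp_params = dict(tcp_params)
        self.ntcp_params = dict(ntcp_params)
        self.levels = levels
        self.scheme = scheme
        self.swarm = swarm
        self.engine = engine
        self.bounds: SamplingBounds = derive_sampling_bounds(
            levels,
            self.tcp_params,
            self.ntcp_params,
            self.phantom.volumes,
            scheme,
        )
        self.evaluator = CandidateEvaluator(
            bounds=self.bounds,
            beamlets=beamlets,
            phantom=phantom,
            tcp_params=self.tcp_params,
            ntcp_params=self.ntcp_params,
            levels=levels,
            scheme=scheme,
            engine_config=engine,
        )

    @classmethod
    def from_config(cls, config: RunConfig, parameter_set: int | None = None
                    ) -> "PrescriptionFreePlanner":
        seeds = config.sub_seeds()
        phantom = generate_phantom(config.phantom_config(), seed=seeds["phantom"])
        beamlets = generate_beamlets(
            phantom,
            n_beams=config.n_beams,
            beamlet_width_mm=config.beamlet_width_mm,
            attenuation_coeff=config.attenuation_coeff,
        )
        set_id = config.parameter_set if parameter_set is None else parameter_set
        tcp = datasets.tcp_parameter_set(set_id)
        ntcp = datasets.ntcp_parameter_set(phantom.oar_names)
        swarm = SwarmConfig(
            **{
                **{f: getattr(config.swarm, f) for f in (
                    "inertia", "cognitive", "social",
                    "initial_velocity_attenuation", "reset_probability",
                    "n_particles", "n_epochs",
                )},
                "seed": seeds["pso"],
            }
        )
        return cls(
            phantom=phantom,
            beamlets=beamlets,
            tcp_params=tcp,
            ntcp_params=ntcp,
            levels=config.levels,
            scheme=config.scheme,
            swarm=swarm,
            engine=config.engine,
        )

    def run(self) -> PlanningResult:
        """Run the swarm, build the Pareto front from the feasible archive,
        and select the highest-P_+ plan."""
        result: PSOResult = run_pso(self.swarm, self.bounds, self.evaluator)
        feasible = [r for r in result.archive if r.feasible]
        if not feasible:
            raise RuntimeError(
                "no feasible candidate satisfied the TCP/NTCP levels; "
                "widen the levels or increase the search budget"
            )
        points = [
            ParetoPoint(
                p_injury=r.summary.p_injury,
                one_minus_p_benefit=1.0 - r.summary.p_benefit,
                plan=r,
            )
            for r in feasible
        ]
        front = build_front(points)
        selected: PlanRecord = front.highest.plan
        return PlanningResult(
            archive=result.archive,
            front=front,
            selected=selected,
            progress=result.progress,
            planner=self,
        )
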