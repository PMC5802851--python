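"""Parameter-space fitting and control scenarios.

Brute-force sweep over the three global parameters -- long-range coupling
G and the excitatory/inhibitory drive scalings w_BG -- with feedback
inhibition control re-run inside every combination, scored against a
target fMRI series.  Also the control pipelines: the noise-driven original
mean-field model (no injected drive) and the time-permuted-drive variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .connectome import StructuralConnectome
from .drive import DriveTimeSeries
from .fic import FICConfig, fic_tune
from .hemodynamics import BOLDSeries, HemodynamicParameters, balloon_windkessel, downsample_to_TR
from .model import SimulationConfig, SimulationTrace, simulate
from .params import ModelParameters
from .synthetic import permute_drive
from . import analysis

__all__ = ["SweepSpec", "SweepResult", "simulate_bold", "run_sweep",
           "control_noise_model", "control_permuted"]


def simulate_bold(C: StructuralConnectome, drive: DriveTimeSeries,
                  J: np.ndarray, p: ModelParameters,
                  sim_config: SimulationConfig | None = None,
                  hp: HemodynamicParameters | None = None,
                  TR: float = 1.94, discard: int = 11
                  ) -> tuple[SimulationTrace, BOLDSeries]:
    """Full forward pipeline: network simulation -> BOLD at TR resolution."""
    trace = simulate(C, drive, J, p, sim_config)
    bold_1k = balloon_windkessel(trace.S_E, hp, sample_rate=trace.sample_rate)
    return trace, downsample_to_TR(bold_1k, TR=TR, discard=discard,
                                   sample_rate=trace.sample_rate)


@dataclass
class SweepSpec:
    """Grid and scoring settings for :func:`run_sweep`.

    The inhibitory drive scaling is parameterized through the ratio
    w_BG_I / w_BG_E, constrained to [5, 200] (inhibition stronger than
    excitation at the injected synapses).
    """

    G_grid: tuple[float, ...] = (0.05, 0.2, 0.5)
    w_BG_E_grid: tuple[float, ...] = (0.005, 0.02, 0.08)
    ratio_grid: tuple[float, ...] = (5.0, 10.0, 50.0)
    ratio_bounds: tuple[float, float] = (5.0, 200.0)
    objective: str = "timeseries"  # timeseries | static_fc | dynamic_fc
    fic: FICConfig = field(default_factory=FICConfig)
    TR: float = 1.94
    discard: int = 11
    fc_window: int = 100

    def combinations(self) -> list[tuple[float, float, float]]:
        """Admissible (G, w_BG_E, w_BG_I) triples under the ratio bounds."""
        out = []
        for G, wE, ratio in itertools.product(self.G_grid, self.w_BG_E_grid,
                                              self.ratio_grid):
            if self.ratio_bounds[0] <= ratio <= self.ratio_bounds[1]:
                out.append((G, wE, wE * ratio))
        if not out:
            raise ValueError("ratio bounds exclude every grid combination")
        return out


@dataclass
class SweepResult:
    """All per-combination scores and the winning combination."""

    records: list[dict]
    objective: str

    @property
    def best(self) -> dict:
        ok = [r for r in self.records if r["status"] == "ok"]
        if not ok:
            raise RuntimeError("every sweep combination failed")
        return max(ok, key=lambda r: r["score"])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def _score(objective: str, sim: BOLDSeries, target: BOLDSeries,
           window: int) -> float:
    if objective == "timeseries":
        return analysis.prediction_quality(sim, target)
    if objective == "static_fc":
        return analysis.fc_similarity(analysis.functional_connectivity(sim),
                                      analysis.functional_connectivity(target))
    if objective == "dynamic_fc":
        return analysis.dynamic_fc_quality(sim, target, window=window)
    raise ValueError(f"unknown objective {objective!r}")


def run_sweep(C: StructuralConnectome, drive: DriveTimeSeries,
              target_bold: BOLDSeries, spec: SweepSpec,
              base_params: ModelParameters | None = None) -> SweepResult:
    """Exhaustive scan of (G, w_BG_E, w_BG_I) with FIC inside the loop.

    Every admissible combination is FIC-tuned, simulated and scored by the
    configured objective against the target; failing combinations are
    recorded and skipped rather than aborting the sweep.
    """
    base = base_params or ModelParameters()
    records: list[dict] = []
    for G, wE, wI in spec.combinations():
        p = base.with_(G=G, w_BG_E=wE, w_BG_I=wI)
        rec = {"G": G, "w_BG_E": wE, "w_BG_I": wI, "status": "ok",
               "score": float("nan")}
        try:
            J, fic_state = fic_tune(C, drive, p, spec.fic)
            _, bold = simulate_bold(C, drive, J, p, spec.fic.simulation,
                                    TR=spec.TR, discard=spec.discard)
            rec["score"] = _score(spec.objective, bold, target_bold,
                                  spec.fc_window)
            rec["fic_best_error"] = fic_state.global_error(
                fic_state.best_iteration())
        except Exception as exc:  # record-and-continue policy
            rec["status"] = f"failed: {exc}"
        records.append(rec)
    return SweepResult(records=records, objective=spec.objective)


def control_noise_model(C: StructuralConnectome, p: ModelParameters,
                        duration: float, seed: int,
                        noise_sigma: float = 0.01,
                        fic: FICConfig | None = None,
                        J: np.ndarray | None = None,
                        TR: float = 1.94, discard: int = 11
                        ) -> tuple[BOLDSeries, np.ndarray]:
    """Noise-driven original mean-field model (no injected drive).

    Uses the identical simulation, FIC and hemodynamic machinery with the
    drive weights zeroed, local recurrence enabled and additive current
    noise.  Returns the TR-resolution BOLD and the J vector used.
    """
    p = p.with_(w_BG_E=0.0, w_BG_I=0.0, noise_sigma=noise_sigma,
                recurrence_enabled=True)
    n_samples = int(round(duration * 1000.0))
    drive = DriveTimeSeries(np.zeros((C.n_regions, n_samples)), 1000.0)
    sim_config = SimulationConfig(seed=seed)
    if J is None:
        if fic is not None:
            fic.simulation = sim_config
            J, _ = fic_tune(C, drive, p, fic)
        else:
            J = np.ones(C.n_regions)
    _, bold = simulate_bold(C, drive, J, p, sim_config, TR=TR,
                            discard=discard)
    return bold, np.asarray(J)


def control_permuted(C: StructuralConnectome, drive: DriveTimeSeries,
                     p: ModelParameters, seed: int,
                     fic: FICConfig | None = None,
                     J: np.ndarray | None = None,
                     TR: float = 1.94, discard: int = 11
                     ) -> tuple[BOLDSeries, np.ndarray]:
    """Time-permuted-drive control: shuffle each region's samples, then
    run the identical pipeline (FIC included unless J is given)."""
    shuffled = permute_drive(drive, seed)
    if J is None:
        if fic is not None:
            J, _ = fic_tune(C, shuffled, p, fic)
        else:
            J = np.ones(C.n_regions)
    _, bold = simulate_bold(C, shuffled, J, p,
                            fic.simulation if fic else None,
                            TR=TR, discard=discard)
    return bold, np.asarray(J)
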