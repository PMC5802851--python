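"""Feedback inhibition control (FIC).

Iteratively tunes the per-region inhibitory coupling weights J_i so that
every excitatory population attains a target mean firing rate (3.06 Hz, the
isolated-node rate of the underlying mean-field model) over the whole
simulated series.  Each iteration runs a full-length simulation, then
nudges J_i proportionally to the node's rate error with an adaptive tuning
factor tau:

    J_i(k+1) = J_i(k) + (rhat_i(k) - target) * tau_k

tau is adapted between iterations by a secant-style rule on the global
mean rate -- the mean weight change per node divided by the change of the
global mean rate -- and is halved instead whenever the global error failed
to improve.  After the fixed iteration budget the J vector from the
iteration with the smallest global error is returned.

Per-node rate errors drive the per-node J updates (a global error could
never produce the heterogeneous inhibition that compensates region-wise
variation in white-matter coupling); the global mean rate drives tau
adaptation and the improvement test.  The secant ratio is taken in
magnitude (keeping the corrective sign in the J update itself) and per
node, so it estimates the inverse slope of the scalar uniform-J ->
mean-rate response, which stays stable at any network size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import StructuralConnectome
from .drive import DriveTimeSeries
from .model import SimulationConfig, simulate
from .params import ModelParameters

__all__ = ["FICState", "FICConfig", "fic_update", "adapt_tau", "fic_tune"]

J_FLOOR = 1e-6  # nA; preserves positivity of inhibitory weights


@dataclass
class FICState:
    """History of one FIC run: J vectors, rates and tuning factors."""

    target_rate: float = 3.06
    max_iterations: int = 12
    J_history: list[np.ndarray] = field(default_factory=list)
    node_rate_history: list[np.ndarray] = field(default_factory=list)
    global_rate_history: list[float] = field(default_factory=list)
    tau_history: list[float] = field(default_factory=list)

    @property
    def iteration(self) -> int:
        return len(self.global_rate_history)

    def global_error(self, k: int) -> float:
        return abs(self.global_rate_history[k] - self.target_rate)

    def node_error(self, k: int) -> float:
        """Mean absolute per-node rate error at iteration k.

        This is the quantity FIC exists to minimize: the global mean can
        balance to the set-point while individual regions remain far from
        it, so improvement is judged on the per-node errors.
        """
        return float(np.mean(np.abs(self.node_rate_history[k]
                                    - self.target_rate)))

    def best_iteration(self) -> int:
        """Index of the iteration with the smallest per-node rate error."""
        errs = [self.node_error(k) for k in range(self.iteration)]
        return int(np.argmin(errs))


def fic_update(J_k: np.ndarray, node_mean_rates: np.ndarray, tau_k: float,
               target_rate: float = 3.06,
               step_clamp: float | None = None) -> np.ndarray:
    """One per-node corrective step of the inhibitory weights.

    ``step_clamp`` bounds each weight change to that fraction of the
    current weight (trust region): the rate response to J is convex, so
    unbounded secant steps systematically overshoot on stiff networks.
    """
    if tau_k <= 0:
        raise ValueError("tau_k must be positive")
    node_mean_rates = np.asarray(node_mean_rates, dtype=float)
    if not np.all(np.isfinite(node_mean_rates)):
        raise ValueError("non-finite node rates")
    J_k = np.asarray(J_k, dtype=float)
    step = (node_mean_rates - target_rate) * tau_k
    if step_clamp is not None:
        lim = step_clamp * np.maximum(J_k, 0.1)
        step = np.clip(step, -lim, lim)
    return np.maximum(J_k + step, J_FLOOR)


def adapt_tau(state: FICState) -> float:
    """Tuning factor for the next iteration.

    Requires at least two completed iterations.  If the per-node rate
    error did not improve the previous tau is halved; otherwise a
    secant-style estimate of the inverse rate-vs-weight slope is used:
    the mean absolute weight change divided by the mean absolute
    per-node rate change between the last two iterations.  A vanishing
    rate change keeps tau unchanged.
    """
    k = state.iteration
    if k < 2:
        raise ValueError("adapt_tau requires at least two completed iterations")
    tau_prev = state.tau_history[-1]
    if state.node_error(k - 1) >= state.node_error(k - 2):
        return 0.5 * tau_prev
    dJ = float(np.mean(np.abs(state.J_history[k - 2]
                              - state.J_history[k - 1])))
    dr = float(np.mean(np.abs(state.node_rate_history[k - 2]
                              - state.node_rate_history[k - 1])))
    if dr == 0.0 or dJ == 0.0:
        return tau_prev
    tau = dJ / dr
    if not np.isfinite(tau) or tau <= 0:
        return tau_prev
    return tau


@dataclass
class FICConfig:
    """Settings for :func:`fic_tune`."""

    target_rate: float = 3.06
    max_iterations: int = 12
    tau_init: float = 0.005
    step_clamp: float = 0.8  # max relative J change per iteration
    global_J: bool = False  # control mode: one scalar J for all nodes
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


def fic_tune(C: StructuralConnectome, drive: DriveTimeSeries,
             p: ModelParameters, config: FICConfig | None = None
             ) -> tuple[np.ndarray, FICState]:
    """Tune the inhibitory weights by iterated full-length simulation.

    Returns the J vector of the best iteration together with the full
    diagnostic history.  In ``global_J`` mode a single scalar weight is
    adapted (driven by the global mean-rate error) and broadcast to all
    nodes, the control configuration used to probe whether region-wise
    tuning is necessary.
    """
    config = config or FICConfig()
    n = C.n_regions
    state = FICState(target_rate=config.target_rate,
                     max_iterations=config.max_iterations)
    J = np.ones(n)
    tau = config.tau_init
    for k in range(config.max_iterations):
        trace = simulate(C, drive, J, p, config.simulation)
        node_rates = trace.mean_rates()
        state.J_history.append(J.copy())
        state.node_rate_history.append(node_rates)
        state.global_rate_history.append(float(node_rates.mean()))
        state.tau_history.append(tau)
        if k + 1 == config.max_iterations:
            break
        if k >= 1:
            tau = adapt_tau(state)
        rates = (np.full(n, node_rates.mean()) if config.global_J
                 else node_rates)
        J = fic_update(J, rates, tau, config.target_rate,
                       step_clamp=config.step_clamp)
    best = state.best_iteration()
    return state.J_history[best].copy(), state


def diagnostics_frame(state: FICState):
    """FIC history as a pandas DataFrame (iteration, tau, rates)."""
    import pandas as pd

    rows = []
    for k in range(state.iteration):
        row = {"iteration": k, "tau": state.tau_history[k],
               "global_mean_rate": state.global_rate_history[k],
               "global_error": state.global_error(k)}
        for i, r in enumerate(state.node_rate_history[k]):
            row[f"rate_node_{i}"] = r
        rows.append(row)
    return pd.DataFrame(rows)
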