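"""Hybrid dynamic mean-field network core.

Each brain region is a pair of coupled excitatory (E) and inhibitory (I)
neural-mass populations.  Input currents sum external input, long-range
excitation through the structural connectome, local feedback inhibition,
optional local excitatory recurrence, and an injected drive current
(region-wise electrical source activity scaled by ``w_BG``).  Sigmoidal
f-I curves convert currents to population rates, which drive first-order
synaptic gating kinetics.  Integration is explicit Euler at 10 kHz
(dt = 0.1 ms) with each 1 kHz drive sample held constant for 10 steps
(sample-and-hold injection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .connectome import StructuralConnectome
from .drive import DriveTimeSeries
from .params import ModelParameters

__all__ = [
    "RegionState",
    "SimulationConfig",
    "SimulationTrace",
    "IntegrationDivergedError",
    "compute_input_currents",
    "firing_rate",
    "gating_derivatives",
    "step",
    "simulate",
    "isolated_fixed_point",
]


class IntegrationDivergedError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, region: int, time_ms: float):
        self.region = region
        self.time_ms = time_ms
        super().__init__(
            f"integration diverged (non-finite state) in region {region} "
            f"near t = {time_ms:.1f} ms"
        )


@dataclass
class RegionState:
    """Synaptic gating state of all regions: S_E in [0, 1], S_I >= 0."""

    S_E: np.ndarray
    S_I: np.ndarray

    def __post_init__(self) -> None:
        self.S_E = np.atleast_1d(np.asarray(self.S_E, dtype=float))
        self.S_I = np.atleast_1d(np.asarray(self.S_I, dtype=float))
        if self.S_E.shape != self.S_I.shape:
            raise ValueError("S_E and S_I must have the same shape")

    @classmethod
    def initial(cls, n_regions: int, value: float = 0.1) -> "RegionState":
        return cls(np.full(n_regions, value), np.full(n_regions, value))

    @property
    def n_regions(self) -> int:
        return self.S_E.shape[0]

    def copy(self) -> "RegionState":
        return RegionState(self.S_E.copy(), self.S_I.copy())


def compute_input_currents(state: RegionState, drive_sample: np.ndarray,
                           C: StructuralConnectome, J: np.ndarray,
                           p: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Summed input currents (nA) to the E and I populations.

    I_E = W_E*I0 [+ w_plus*J_NMDA*S_E] + G*(C @ S_E) - J*S_I + w_BG_E*drive
    I_I = W_I*I0 [+ J_NMDA*S_E]                       - S_I + w_BG_I*drive

    The bracketed local-recurrence terms are included only when
    ``p.recurrence_enabled``.
    """
    drive_sample = np.atleast_1d(np.asarray(drive_sample, dtype=float))
    J = np.atleast_1d(np.asarray(J, dtype=float))
    n = state.n_regions
    if C.n_regions != n or drive_sample.shape[0] != n or J.shape[0] != n:
        raise ValueError(
            f"dimension mismatch: state has {n} regions, C {C.n_regions}, "
            f"drive {drive_sample.shape[0]}, J {J.shape[0]}"
        )
    if not (np.all(np.isfinite(drive_sample)) and np.all(np.isfinite(J))):
        raise ValueError("non-finite drive sample or inhibitory weights")
    I_E = (p.W_E * p.I0 + p.G * (C.weights @ state.S_E)
           - J * state.S_I + p.w_BG_E * drive_sample)
    I_I = p.W_I * p.I0 - state.S_I + p.w_BG_I * drive_sample
    if p.recurrence_enabled:
        I_E = I_E + p.w_plus * p.J_NMDA * state.S_E
        I_I = I_I + p.J_NMDA * state.S_E
    return I_E, I_I


def firing_rate(I, pop: str, p: ModelParameters):
    """Population f-I transfer function, Hz.

    r(I) = (a*I - b) / (1 - exp(-d*(a*I - b))), continuous across the
    removable singularity at a*I = b where it equals 1/d.
    """
    if pop == "E":
        a, b, d = p.a_E, p.b_E, p.d_E
    elif pop == "I":
        a, b, d = p.a_I, p.b_I, p.d_I
    else:
        raise ValueError(f"pop must be 'E' or 'I', got {pop!r}")
    x = a * np.asarray(I, dtype=float) - b
    near = np.abs(x) < 1e-6
    safe = np.where(near, 1.0, x)
    r = np.where(near,
                 1.0 / d + x / 2.0 + d * x * x / 12.0,  # series at x = 0
                 safe / (1.0 - np.exp(-d * safe)))
    return r if r.ndim else float(r)


def gating_derivatives(state: RegionState, r_E: np.ndarray, r_I: np.ndarray,
                       p: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives of the gating variables, per ms."""
    dS_E = -state.S_E / p.tau_E + (1.0 - state.S_E) * p.gamma_E * r_E
    dS_I = -state.S_I / p.tau_I + p.gamma_I * r_I
    return dS_E, dS_I


def step(state: RegionState, drive_sample: np.ndarray,
         C: StructuralConnectome, J: np.ndarray, p: ModelParameters,
         dt: float = 0.1, rng: np.random.Generator | None = None) -> RegionState:
    """One forward-Euler update of the gating state (dt in ms).

    When ``p.noise_sigma > 0`` (noise-driven control model) additive
    Gaussian current noise is drawn from ``rng`` for both populations.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    I_E, I_I = compute_input_currents(state, drive_sample, C, J, p)
    if p.noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng for reproducibility")
        I_E = I_E + p.noise_sigma * rng.standard_normal(state.n_regions)
        I_I = I_I + p.noise_sigma * rng.standard_normal(state.n_regions)
    r_E = firing_rate(I_E, "E", p)
    r_I = firing_rate(I_I, "I", p)
    dS_E, dS_I = gating_derivatives(state, r_E, r_I, p)
    S_E = np.clip(state.S_E + dt * dS_E, 0.0, 1.0)
    S_I = np.maximum(state.S_I + dt * dS_I, 0.0)
    if not np.all(np.isfinite(S_E)) or not np.all(np.isfinite(S_I)):
        bad = int(np.argmax(~(np.isfinite(S_E) & np.isfinite(S_I))))
        raise IntegrationDivergedError(bad, float("nan"))
    return RegionState(S_E, S_I)


@dataclass
class SimulationConfig:
    """Run configuration for :func:`simulate`.

    ``dt`` is the integration step in ms (0.1 ms = 10 kHz model rate);
    each drive sample is held for ``model_rate / drive_rate`` steps.
    Recorded series are decimated to the drive rate (one record per drive
    sample).  ``record_full`` additionally stores input currents, the
    long-range input term and the injected drive term.
    """

    duration: float | None = None  # seconds; None = full drive length
    dt: float = 0.1  # ms
    initial_gating: float = 0.1  # scalar applied to both S_E and S_I
    initial_state: RegionState | None = None  # overrides initial_gating
    record_full: bool = False
    seed: int | None = None  # required when noise_sigma > 0


@dataclass
class SimulationTrace:
    """Decimated state-variable series from one simulation run."""

    time: np.ndarray  # ms
    S_E: np.ndarray  # regions x samples
    S_I: np.ndarray
    r_E: np.ndarray  # Hz
    r_I: np.ndarray
    sample_rate: float  # Hz of the stored series
    decimation: int  # integration steps per stored sample
    I_E: np.ndarray | None = None  # nA, only when record_full
    I_I: np.ndarray | None = None
    long_range: np.ndarray | None = None  # G * (C @ S_E)
    injected_E: np.ndarray | None = None  # w_BG_E * drive
    extras: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.S_E.shape[0]

    @property
    def n_samples(self) -> int:
        return self.S_E.shape[1]

    def mean_rates(self) -> np.ndarray:
        """Per-region mean excitatory firing rate over the whole trace."""
        return self.r_E.mean(axis=1)

    def _series(self) -> dict[str, np.ndarray]:
        out = {"S_E": self.S_E, "S_I": self.S_I,
               "r_E": self.r_E, "r_I": self.r_I}
        for name in ("I_E", "I_I", "long_range", "injected_E"):
            val = getattr(self, name)
            if val is not None:
                out[name] = val
        return out


def write_trace(trace: SimulationTrace, path) -> None:
    """Write a trace to HDF5 (named dataset per state variable) or, for
    small runs, to a wide CSV with one (variable, region) column pair."""
    from pathlib import Path

    path = Path(path)
    series = trace._series()
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=trace.time)
            for name, val in series.items():
                f.create_dataset(name, data=val)
            f.attrs["sample_rate"] = trace.sample_rate
            f.attrs["decimation"] = trace.decimation
    else:
        import pandas as pd

        cols = {"time_ms": trace.time}
        for name, val in series.items():
            for i in range(val.shape[0]):
                cols[f"{name}_{i}"] = val[i]
        pd.DataFrame(cols).to_csv(path, index=False)


def read_trace(path) -> SimulationTrace:
    """Read an HDF5 trace written by :func:`write_trace`."""
    import h5py

    with h5py.File(path, "r") as f:
        kw = {}
        for name in ("I_E", "I_I", "long_range", "injected_E"):
            if name in f:
                kw[name] = np.asarray(f[name])
        return SimulationTrace(
            time=np.asarray(f["time"]),
            S_E=np.asarray(f["S_E"]), S_I=np.asarray(f["S_I"]),
            r_E=np.asarray(f["r_E"]), r_I=np.asarray(f["r_I"]),
            sample_rate=float(f.attrs["sample_rate"]),
            decimation=int(f.attrs["decimation"]), **kw)


@njit(cache=True, fastmath=True)
def _run_kernel(C, J, drive, hold, dt, n_samples,
                W_E, W_I, I0, a_E, b_E, d_E, a_I, b_I, d_I,
                tau_E, tau_I, gamma_E, gamma_I, w_plus, J_NMDA,
                G, w_BG_E, w_BG_I, noise_sigma, seed, recurrence,
                S_E, S_I, rec_S_E, rec_S_I, rec_r_E, rec_r_I,
                full, rec_I_E, rec_I_I, rec_lr, rec_inj):
    n = S_E.shape[0]
    if noise_sigma > 0.0:
        np.random.seed(seed)
    wpJ = w_plus * J_NMDA
    base_E = W_E * I0
    base_I = W_I * I0
    lr = np.empty(n)
    for k in range(n_samples):
        for sub in range(hold):
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    acc += C[i, j] * S_E[j]
                lr[i] = G * acc
            for i in range(n):
                I_E = base_E + lr[i] - J[i] * S_I[i] + w_BG_E * drive[i, k]
                I_I = base_I - S_I[i] + w_BG_I * drive[i, k]
                if recurrence:
                    I_E += wpJ * S_E[i]
                    I_I += J_NMDA * S_E[i]
                if noise_sigma > 0.0:
                    I_E += noise_sigma * np.random.normal()
                    I_I += noise_sigma * np.random.normal()
                x = a_E * I_E - b_E
                if abs(x) < 1e-6:
                    r_E = 1.0 / d_E + x / 2.0 + d_E * x * x / 12.0
                else:
                    r_E = x / (1.0 - np.exp(-d_E * x))
                x = a_I * I_I - b_I
                if abs(x) < 1e-6:
                    r_I = 1.0 / d_I + x / 2.0 + d_I * x * x / 12.0
                else:
                    r_I = x / (1.0 - np.exp(-d_I * x))
                if sub == 0:
                    rec_r_E[i, k] = r_E
                    rec_r_I[i, k] = r_I
                    rec_S_E[i, k] = S_E[i]
                    rec_S_I[i, k] = S_I[i]
                    if full:
                        rec_I_E[i, k] = I_E
                        rec_I_I[i, k] = I_I
                        rec_lr[i, k] = lr[i]
                        rec_inj[i, k] = w_BG_E * drive[i, k]
                S_E[i] += dt * (-S_E[i] / tau_E + (1.0 - S_E[i]) * gamma_E * r_E)
                S_I[i] += dt * (-S_I[i] / tau_I + gamma_I * r_I)
                if S_E[i] < 0.0:
                    S_E[i] = 0.0
                elif S_E[i] > 1.0:
                    S_E[i] = 1.0
                if S_I[i] < 0.0:
                    S_I[i] = 0.0
        for i in range(n):
            if not (np.isfinite(S_E[i]) and np.isfinite(S_I[i])):
                return i, (k + 1) * hold * dt
    return -1, 0.0


def simulate(C: StructuralConnectome, drive: DriveTimeSeries,
             J: np.ndarray, p: ModelParameters,
             config: SimulationConfig | None = None) -> SimulationTrace:
    """Integrate the network, holding each drive sample for 10 steps.

    The model rate is ``1000/dt`` Hz (10 kHz by default); the ratio of
    model rate to drive sample rate must be a whole number of integration
    steps.  Recorded series are stored once per drive sample (1 kHz by
    default).  Recorded rates/currents at sample k are those computed from
    the state at the start of that sample's hold interval.
    """
    config = config or SimulationConfig()
    n = C.n_regions
    if drive.n_regions != n:
        raise ValueError(
            f"drive has {drive.n_regions} regions but connectome has {n}")
    J = np.ascontiguousarray(np.atleast_1d(np.asarray(J, dtype=float)))
    if J.shape[0] != n:
        raise ValueError("J length does not match connectome size")
    model_rate = 1000.0 / config.dt  # Hz
    hold_f = model_rate / drive.sample_rate
    hold = int(round(hold_f))
    if hold < 1 or abs(hold_f - hold) > 1e-9:
        raise ValueError(
            f"model rate {model_rate} Hz is not an integer multiple of the "
            f"drive rate {drive.sample_rate} Hz")
    if config.duration is None:
        n_samples = drive.n_samples
    else:
        n_samples = int(round(config.duration * drive.sample_rate))
        if n_samples > drive.n_samples:
            raise ValueError(
                f"requested {config.duration} s but drive holds only "
                f"{drive.duration} s")
    if p.noise_sigma > 0 and config.seed is None:
        raise ValueError("noise_sigma > 0 requires config.seed")

    if config.initial_state is not None:
        if config.initial_state.n_regions != n:
            raise ValueError("initial_state size does not match connectome")
        S_E = config.initial_state.S_E.astype(float).copy()
        S_I = config.initial_state.S_I.astype(float).copy()
    else:
        S_E = np.full(n, float(config.initial_gating))
        S_I = np.full(n, float(config.initial_gating))
    rec_shape = (n, n_samples)
    rec_S_E = np.empty(rec_shape)
    rec_S_I = np.empty(rec_shape)
    rec_r_E = np.empty(rec_shape)
    rec_r_I = np.empty(rec_shape)
    full = bool(config.record_full)
    small = (n, max(n_samples, 1) if full else 1)
    rec_I_E = np.empty(small if full else (n, 1))
    rec_I_I = np.empty_like(rec_I_E)
    rec_lr = np.empty_like(rec_I_E)
    rec_inj = np.empty_like(rec_I_E)

    if n_samples > 0:
        bad, t_bad = _run_kernel(
            np.ascontiguousarray(C.weights), J,
            np.ascontiguousarray(drive.values[:, :n_samples]),
            hold, config.dt, n_samples,
            p.W_E, p.W_I, p.I0, p.a_E, p.b_E, p.d_E, p.a_I, p.b_I, p.d_I,
            p.tau_E, p.tau_I, p.gamma_E, p.gamma_I, p.w_plus, p.J_NMDA,
            p.G, p.w_BG_E, p.w_BG_I, p.noise_sigma,
            0 if config.seed is None else int(config.seed) % (2**31),
            p.recurrence_enabled,
            S_E, S_I, rec_S_E, rec_S_I, rec_r_E, rec_r_I,
            full, rec_I_E, rec_I_I, rec_lr, rec_inj)
        if bad >= 0:
            raise IntegrationDivergedError(bad, t_bad)

    time = np.arange(n_samples) * (1000.0 / drive.sample_rate)
    return SimulationTrace(
        time=time, S_E=rec_S_E, S_I=rec_S_I, r_E=rec_r_E, r_I=rec_r_I,
        sample_rate=drive.sample_rate, decimation=hold,
        I_E=rec_I_E if full else None, I_I=rec_I_I if full else None,
        long_range=rec_lr if full else None,
        injected_E=rec_inj if full else None)


def isolated_fixed_point(p: ModelParameters, J: float = 1.0
                         ) -> tuple[float, float, float]:
    """Analytic steady state (S_E*, S_I*, r_E*) of an isolated node.

    Solves the coupled self-consistency equations of a single region with
    no long-range input and no drive by nested bisection.  Used as the
    calibration oracle: with default parameters, J = 1 and recurrence on,
    r_E* is approximately 3.06 Hz.
    """
    from scipy.optimize import brentq

    def S_I_star(S_E: float) -> float:
        rec = p.J_NMDA * S_E if p.recurrence_enabled else 0.0

        def f(S_I: float) -> float:
            I_I = p.W_I * p.I0 + rec - S_I
            return p.tau_I * p.gamma_I * firing_rate(I_I, "I", p) - S_I

        return brentq(f, 0.0, 5.0)

    def dS_E(S_E: float) -> float:
        rec = p.w_plus * p.J_NMDA * S_E if p.recurrence_enabled else 0.0
        I_E = p.W_E * p.I0 + rec - J * S_I_star(S_E)
        r_E = firing_rate(I_E, "E", p)
        return -S_E / p.tau_E + (1.0 - S_E) * p.gamma_E * r_E

    S_E = brentq(dS_E, 1e-9, 1.0 - 1e-9)
    S_I = S_I_star(S_E)
    rec = p.w_plus * p.J_NMDA * S_E if p.recurrence_enabled else 0.0
    r_E = firing_rate(p.W_E * p.I0 + rec - J * S_I, "E", p)
    return float(S_E), float(S_I), float(r_E)
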