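"""Balloon-Windkessel hemodynamic forward model.

Transforms excitatory synaptic gating into a BOLD signal through four
coupled ODEs per region -- vasodilatory signal s, blood inflow f, venous
volume v and deoxyhemoglobin content q:

    ds/dt = z - kappa*s - gamma_h*(f - 1)
    df/dt = s
    dv/dt = (f - v**(1/alpha_h)) / tau_h
    dq/dt = (f*E(f)/rho - q*v**(1/alpha_h - 1)) / tau_h

with oxygen extraction E(f) = 1 - (1 - rho)**(1/f), driven by the neural
input z (here: S_E minus its resting value, so rest maps to the fixed
point s=0, f=v=q=1).  The BOLD readout is the static nonlinearity

    y = V0 * (k1*(1-q) + k2*(1-q/v) + k3*(1-v)) * 100

in percent signal change.  The model acts as a low-pass filter
(attenuating fluctuations above roughly 0.15 Hz), so simulated fMRI is
obtained by plain decimation to the repetition time without extra
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import HemodynamicParameters

__all__ = ["BOLDSeries", "balloon_windkessel", "downsample_to_TR",
           "read_bold", "write_bold"]


@dataclass
class BOLDSeries:
    """Simulated fMRI: regions x scans at repetition time TR (s)."""

    values: np.ndarray
    TR: float = 1.94
    discarded_scans: int = 11

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.TR <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_scans(self) -> int:
        return self.values.shape[1]

    def scan_times(self) -> np.ndarray:
        """Time (s) of each retained scan on the original acquisition grid."""
        return (self.discarded_scans + np.arange(self.n_scans)) * self.TR


@njit(cache=True)
def _bw_kernel(z, dt, kappa, gamma_h, tau_h, alpha_h, rho, V0, k1, k2, k3):
    # f, v, q are integrated in log-space, which keeps them positive for
    # arbitrarily strong neural input (the standard robust formulation).
    n, T = z.shape
    bold = np.empty((n, T))
    inv_alpha = 1.0 / alpha_h
    for i in range(n):
        s = 0.0
        lf = 0.0  # ln f
        lv = 0.0  # ln v
        lq = 0.0  # ln q
        for t in range(T):
            f = np.exp(lf)
            v = np.exp(lv)
            q = np.exp(lq)
            if f < 1e-9 or v < 1e-9 or q < 1e-9 or f > 1e9:
                return bold, i
            bold[i, t] = 100.0 * V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v)
                                       + k3 * (1.0 - v))
            fv = v ** inv_alpha
            E = 1.0 - (1.0 - rho) ** (1.0 / f)
            s += dt * (z[i, t] - kappa * s - gamma_h * (f - 1.0))
            lf += dt * s / f
            lv += dt * (f - fv) / (tau_h * v)
            lq += dt * (f * E / rho - q * fv / v) / (tau_h * q)
            if not (np.isfinite(lf) and np.isfinite(lv) and np.isfinite(lq)):
                return bold, i
    return bold, -1


def balloon_windkessel(S_E: np.ndarray, hp: HemodynamicParameters | None = None,
                       sample_rate: float = 1000.0,
                       baseline: float | None = None) -> np.ndarray:
    """BOLD (percent signal change) from excitatory gating at 1 kHz.

    The neurovascular input is ``S_E - baseline``; by default the baseline
    is the per-region mean of the series, so that resting activity maps to
    the hemodynamic fixed point.  Integration is explicit Euler at the
    input rate (1 ms steps), which is ample for dynamics with ~1 s time
    constants.
    """
    hp = hp or HemodynamicParameters()
    S_E = np.atleast_2d(np.asarray(S_E, dtype=float))
    if baseline is None:
        z = S_E - S_E.mean(axis=1, keepdims=True)
    else:
        z = S_E - baseline
    dt = 1.0 / sample_rate  # s
    bold, bad = _bw_kernel(np.ascontiguousarray(z), dt, hp.kappa, hp.gamma_h,
                           hp.tau_h, hp.alpha_h, hp.rho, hp.V0,
                           hp.k1, hp.k2, hp.k3)
    if bad >= 0:
        raise RuntimeError(
            f"hemodynamic state became non-finite in region {bad}")
    return bold


def downsample_to_TR(bold_1khz: np.ndarray, TR: float = 1.94,
                     discard: int = 11, sample_rate: float = 1000.0
                     ) -> BOLDSeries:
    """Decimate 1 kHz BOLD to the scanner grid and drop initial scans.

    Takes every ``TR * sample_rate``-th sample (every 1940th at the default
    TR of 1.94 s), then discards the first ``discard`` scans so that model
    and hemodynamic transients do not contaminate the series.  Retained
    scan m sits at time (discard + m) * TR.
    """
    bold_1khz = np.atleast_2d(np.asarray(bold_1khz, dtype=float))
    stride = int(round(TR * sample_rate))
    scans = bold_1khz[:, ::stride]
    if scans.shape[1] <= discard + 1:
        raise ValueError(
            f"series yields only {scans.shape[1]} scans; need more than "
            f"{discard + 1} to discard {discard}")
    return BOLDSeries(scans[:, discard:], TR=TR, discarded_scans=discard)


def read_bold(path, dataset: str = "bold") -> BOLDSeries:
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            d = f[dataset]
            return BOLDSeries(np.asarray(d), TR=float(d.attrs["TR"]),
                              discarded_scans=int(d.attrs["discarded_scans"]))
    v = np.loadtxt(path, delimiter=",")
    return BOLDSeries(np.atleast_2d(v))


def write_bold(bold: BOLDSeries, path, dataset: str = "bold") -> None:
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset(dataset, data=bold.values)
            d.attrs["TR"] = bold.TR
            d.attrs["discarded_scans"] = bold.discarded_scans
    else:
        np.savetxt(path, bold.values, delimiter=",")
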