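"""Synthetic inputs: artificial alpha-activity, surrogate source activity,
permutation controls and random connectomes.

These generators produce every input the model experiments need without
any external data: 10 Hz (configurable 8-12 Hz) sinusoidal drives with
burst or slow amplitude-modulated envelopes, broadband 1/f surrogate
source activity with a fluctuating alpha component, per-region time
permutations, and heavy-tailed max-normalized random connectomes.  All
generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .connectome import StructuralConnectome
from .drive import DriveTimeSeries

__all__ = [
    "AlphaDriveSpec",
    "make_burst_alpha",
    "make_am_alpha",
    "make_surrogate_source_activity",
    "permute_drive",
    "make_synthetic_connectome",
]


@dataclass
class AlphaDriveSpec:
    """Specification of an artificial alpha-band drive.

    The carrier is a zero-mean sine in the alpha band (8-12 Hz).  The
    envelope is either constant, a single raised-cosine high-power burst
    centered mid-series, or a strictly positive slow amplitude modulation
    built from components in the 0.01-0.03 Hz band with equal modulation
    depth per component.
    """

    carrier_freq: float = 10.0  # Hz
    duration: float = 300.0  # s
    sample_rate: float = 1000.0  # Hz
    n_regions: int = 1
    envelope_kind: str = "slow_am"  # constant | single_burst | slow_am
    burst_amplitude_ratio: float = 4.0  # burst peak / baseline amplitude
    burst_duration: float = 10.0  # s
    am_frequencies: tuple[float, ...] = (0.01, 0.02, 0.03)  # Hz
    am_depth: float = 0.8  # envelope swings baseline*(1 +/- depth)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 8.0 <= self.carrier_freq <= 12.0:
            raise ValueError("carrier_freq must lie in the alpha band [8, 12] Hz")
        if self.envelope_kind not in ("constant", "single_burst", "slow_am"):
            raise ValueError(f"unknown envelope_kind {self.envelope_kind!r}")
        for f in self.am_frequencies:
            if not 0.005 <= f <= 0.1:
                raise ValueError("AM frequencies must be slow (0.005-0.1 Hz)")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


def _carrier(spec: AlphaDriveSpec) -> np.ndarray:
    return np.sin(2.0 * np.pi * spec.carrier_freq * spec.times())


def burst_envelope(spec: AlphaDriveSpec) -> np.ndarray:
    """Unit baseline with one raised-cosine burst centered mid-series."""
    if spec.burst_duration > spec.duration:
        raise ValueError("burst longer than the series")
    t = spec.times()
    env = np.ones(spec.n_samples)
    center = spec.duration / 2.0
    half = spec.burst_duration / 2.0
    inside = np.abs(t - center) <= half
    ramp = 0.5 * (1.0 + np.cos(np.pi * (t[inside] - center) / half))
    env[inside] += (spec.burst_amplitude_ratio - 1.0) * ramp
    return env


def am_envelope(spec: AlphaDriveSpec) -> np.ndarray:
    """Strictly positive slow envelope with equal depth per AM component."""
    if not spec.am_frequencies:
        raise ValueError("am_frequencies must not be empty")
    t = spec.times()
    depth = spec.am_depth / len(spec.am_frequencies)
    env = np.ones(spec.n_samples)
    for f in spec.am_frequencies:
        env += depth * np.sin(2.0 * np.pi * f * t)
    return env


def make_burst_alpha(spec: AlphaDriveSpec) -> DriveTimeSeries:
    """Alpha carrier with a single brief high-power burst (all regions)."""
    if spec.envelope_kind != "single_burst":
        raise ValueError("spec.envelope_kind must be 'single_burst'")
    sig = _carrier(spec) * burst_envelope(spec)
    return DriveTimeSeries(np.tile(sig, (spec.n_regions, 1)),
                           spec.sample_rate)


def make_am_alpha(spec: AlphaDriveSpec) -> DriveTimeSeries:
    """Alpha carrier amplitude-modulated by slow (0.01-0.03 Hz) components."""
    if spec.envelope_kind != "slow_am":
        raise ValueError("spec.envelope_kind must be 'slow_am'")
    sig = _carrier(spec) * am_envelope(spec)
    return DriveTimeSeries(np.tile(sig, (spec.n_regions, 1)),
                           spec.sample_rate)


def make_constant_alpha(spec: AlphaDriveSpec) -> DriveTimeSeries:
    """Pure constant-amplitude alpha carrier."""
    return DriveTimeSeries(np.tile(_carrier(spec), (spec.n_regions, 1)),
                           spec.sample_rate)


def make_surrogate_source_activity(n_regions: int, duration: float,
                                   seed: int = 0,
                                   native_rate: float = 200.0,
                                   target_rate: float = 1000.0,
                                   spectral_slope: float = -0.5
                                   ) -> DriveTimeSeries:
    """Surrogate region-wise electrical source activity.

    Emulates the statistical fingerprint of preprocessed empirical source
    activity: per-region broadband noise with a shallow 1/f spectrum
    (power ~ f^-0.5, echoing wide-band electrophysiology), plus an alpha
    component (8-12 Hz) whose amplitude fluctuates with a slow random
    envelope (0.01-0.1 Hz).  Each region is z-scored at the native 200 Hz
    rate and then spline-upsampled to 1 kHz, mirroring the empirical
    preprocessing chain.
    """
    if duration < 60:
        raise ValueError("duration must be at least 60 s")
    rng = np.random.default_rng(seed)
    n_native = int(round(duration * native_rate))
    freqs = np.fft.rfftfreq(n_native, d=1.0 / native_rate)
    out = np.empty((n_regions, int(round(duration * target_rate))))
    t = np.arange(n_native) / native_rate
    t_up = np.arange(out.shape[1]) / target_rate
    for i in range(n_regions):
        # broadband 1/f component via spectral shaping of white noise
        spec = (rng.standard_normal(len(freqs))
                + 1j * rng.standard_normal(len(freqs)))
        amp = np.zeros(len(freqs))
        amp[1:] = freqs[1:] ** (spectral_slope / 2.0)
        broadband = np.fft.irfft(spec * amp, n=n_native)
        broadband /= broadband.std()
        # alpha carrier with slow random power fluctuation
        f_alpha = rng.uniform(8.0, 12.0)
        f_slow = rng.uniform(0.01, 0.1)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        envelope = 1.0 + 0.8 * np.sin(2 * np.pi * f_slow * t + phase[0])
        alpha = envelope * np.sin(2 * np.pi * f_alpha * t + phase[1])
        x = broadband + alpha
        x = (x - x.mean()) / x.std()
        out[i] = CubicSpline(t, x)(t_up)
    return DriveTimeSeries(out, target_rate)


def permute_drive(drive: DriveTimeSeries, seed: int = 0) -> DriveTimeSeries:
    """Independently shuffle the time samples of each region.

    Destroys all temporal structure while preserving each region's value
    distribution -- the control that isolates the contribution of drive
    timing to prediction quality.
    """
    rng = np.random.default_rng(seed)
    out = np.empty_like(drive.values)
    for i in range(drive.n_regions):
        out[i] = drive.values[i, rng.permutation(drive.n_samples)]
    return DriveTimeSeries(out, drive.sample_rate)


def make_synthetic_connectome(n_regions: int, density: float = 1.0,
                              seed: int = 0,
                              log_sigma: float = 2.0) -> StructuralConnectome:
    """Random symmetric connectome with heavy-tailed weights.

    Log-normal magnitudes (``log_sigma`` = 2, so weights span roughly
    four orders of magnitude) mimic the wide weight distribution of
    tractography-derived connectomes, in which a few strong connections
    dominate many weak ones; the matrix is symmetrized, its diagonal
    zeroed, optionally sparsified to the requested density, and
    max-normalized so the largest entry is exactly 1.  The heavy tail
    keeps row sums of the normalized matrix near or below one, matching
    the regime in which coupled networks retain plausible firing rates.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be at least 2")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=log_sigma, size=(n_regions, n_regions))
    w = (w + w.T) / 2.0
    if density < 1.0:
        mask = rng.random((n_regions, n_regions)) < density
        mask = np.triu(mask, 1)
        w = w * (mask + mask.T)
    np.fill_diagonal(w, 0.0)
    m = w.max()
    if m > 0:
        w = w / m
    return StructuralConnectome(w)
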