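"""Derived measurements on drives, model traces and simulated fMRI.

Covers alpha-band filtering and Hilbert power envelopes, the HRF-convolved
alpha regressor, cycle-locked grand-average waveforms, phase-binned firing
histograms, static and sliding-window functional connectivity, region-wise
prediction quality, Welch power-spectrum power-law fitting, and a DFA-based
scale-invariance test with model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.special import gammaln

from .hemodynamics import BOLDSeries

__all__ = [
    "GrandAverageWaveforms", "PowerLawFit", "ScaleFreeVerdict",
    "bandpass", "alpha_power_envelope", "canonical_hrf", "alpha_regressor",
    "detect_cycles", "cycle_locked_average", "phase_bin_firing",
    "functional_connectivity", "fc_similarity", "sliding_window_fc",
    "dynamic_fc_quality", "prediction_quality", "welch_powerlaw",
    "dfa_fluctuation", "dfa_scalefree_test", "moving_average_rate",
]


# ---------------------------------------------------------------------------
# filtering and envelopes

def bandpass(series: np.ndarray, lo: float, hi: float,
             sample_rate: float = 1000.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    nyq = sample_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(
            f"band ({lo}, {hi}) Hz invalid for Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="band", fs=sample_rate,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


def alpha_power_envelope(series: np.ndarray, sample_rate: float = 1000.0,
                         band: tuple[float, float] = (8.0, 10.0),
                         trim: float = 50.0) -> np.ndarray:
    """Instantaneous alpha-power time course.

    Band-pass in ``band`` (8-10 Hz for power envelopes), magnitude of the
    analytic signal (Hilbert transform), then ``trim`` seconds removed from
    both ends to control for filter and Hilbert edge effects.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n <= int(2 * trim * sample_rate) or n / sample_rate <= 120.0:
        raise ValueError(
            "series too short for envelope estimation (need > 120 s and "
            "more than twice the trim span)")
    filtered = bandpass(series, band[0], band[1], sample_rate)
    env = np.abs(sps.hilbert(filtered, axis=-1))
    cut = int(round(trim * sample_rate))
    return env[..., cut:n - cut]


def canonical_hrf(sample_rate: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Response peak at 6 s, undershoot peak at 16 s, peak-to-undershoot
    amplitude ratio 6; unit-sum normalized.
    """
    t = np.arange(int(round(duration * sample_rate))) / sample_rate

    def gpdf(t, a, b):
        # gamma density with shape a, rate b
        out = np.zeros_like(t)
        pos = t > 0
        out[pos] = np.exp((a - 1) * np.log(t[pos]) + a * np.log(b)
                          - b * t[pos] - gammaln(a))
        return out

    h = gpdf(t, 6.0, 1.0) - gpdf(t, 16.0, 1.0) / 6.0
    return h / h.sum()


def alpha_regressor(envelope: np.ndarray, TR: float, n_scans: int,
                    fmri: np.ndarray, sample_rate: float = 1000.0,
                    max_shift: int = 3, offset_scans: int | None = None
                    ) -> tuple[np.ndarray, int, float]:
    """HRF-convolved, TR-resampled alpha-power regressor.

    Convolves the power envelope with the canonical HRF, decimates to the
    fMRI repetition time, and searches integer scan shifts in
    [-max_shift, +max_shift] for the most negative mean regional
    correlation with the fMRI series (the hemodynamic lag is unknown a
    priori; the alpha-fMRI coupling is negative).  ``offset_scans`` is the
    index on the decimated regressor grid where scan 0 of ``fmri`` sits
    (e.g. the number of discarded initial scans when the envelope starts
    at simulation time zero); by default the unshifted regressor is
    centered in whatever margin the envelope leaves.  Returns the aligned
    regressor, the best shift and that correlation.
    """
    envelope = np.asarray(envelope, dtype=float).ravel()
    if np.ptp(envelope) == 0:
        raise ValueError("constant envelope: regressor correlation undefined")
    fmri = np.atleast_2d(np.asarray(fmri, dtype=float))
    conv = np.convolve(envelope, canonical_hrf(sample_rate))[:len(envelope)]
    stride = int(round(TR * sample_rate))
    reg = conv[::stride]
    if offset_scans is None:
        offset_scans = (len(reg) - n_scans) // 2
    if offset_scans < max_shift or len(reg) < offset_scans + max_shift + n_scans:
        raise ValueError(
            f"envelope covers {len(reg)} scans; cannot search shifts of "
            f"+/-{max_shift} around offset {offset_scans} for {n_scans} scans")
    best = (0, np.inf, None)
    for shift in range(-max_shift, max_shift + 1):
        start = offset_scans + shift
        cand = reg[start:start + n_scans]
        rs = [np.corrcoef(cand, row)[0, 1] for row in fmri]
        mean_r = float(np.mean(rs))
        if mean_r < best[1]:
            best = (shift, mean_r, cand)
    return best[2], best[0], best[1]


# ---------------------------------------------------------------------------
# cycle-locked analyses

def detect_cycles(alpha_ref: np.ndarray, sample_rate: float = 1000.0,
                  accept_ms: tuple[float, float] = (95.0, 105.0)
                  ) -> list[tuple[int, int]]:
    """Accepted alpha cycles as (start, end) sample index pairs.

    Cycle onsets are rising zero crossings of the (band-passed) reference;
    cycles are kept when their length falls inside the acceptance window
    (95-105 ms by default, i.e. near-10 Hz cycles).
    """
    x = np.asarray(alpha_ref, dtype=float).ravel()
    rising = np.flatnonzero((x[:-1] < 0) & (x[1:] >= 0)) + 1
    lo = accept_ms[0] * sample_rate / 1000.0
    hi = accept_ms[1] * sample_rate / 1000.0
    return [(int(a), int(b)) for a, b in zip(rising[:-1], rising[1:])
            if lo <= b - a <= hi]


@dataclass
class GrandAverageWaveforms:
    """Mean state-variable waveforms over one alpha cycle."""

    waveforms: dict[str, np.ndarray]
    cycle_count: int
    accept_ms: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.cycle_count <= 0:
            raise ValueError("no accepted cycles")
        for name, w in self.waveforms.items():
            if len(w) != self.n_points:
                raise ValueError(f"waveform {name!r} has wrong length")


def cycle_locked_average(series_by_name: dict[str, np.ndarray],
                         alpha_ref: np.ndarray,
                         sample_rate: float = 1000.0,
                         accept_ms: tuple[float, float] = (95.0, 105.0),
                         n_points: int = 100) -> GrandAverageWaveforms:
    """Grand-average waveforms time-locked to alpha-cycle onsets.

    Each accepted cycle of every series (2-D series contribute one epoch
    per region) is linearly resampled to ``n_points`` and averaged.
    """
    cycles = detect_cycles(alpha_ref, sample_rate, accept_ms)
    if not cycles:
        raise ValueError("no cycles within the acceptance window")
    grid = np.linspace(0.0, 1.0, n_points)
    out: dict[str, np.ndarray] = {}
    for name, series in series_by_name.items():
        series = np.atleast_2d(np.asarray(series, dtype=float))
        acc = np.zeros(n_points)
        count = 0
        for a, b in cycles:
            seg_x = np.linspace(0.0, 1.0, b - a)
            for row in series:
                acc += np.interp(grid, seg_x, row[a:b])
                count += 1
        out[name] = acc / count
    return GrandAverageWaveforms(out, cycle_count=len(cycles),
                                 accept_ms=accept_ms, n_points=n_points)


def phase_bin_firing(rates: np.ndarray, alpha_ref: np.ndarray,
                     n_bins: int = 6, sample_rate: float = 1000.0,
                     accept_ms: tuple[float, float] = (95.0, 105.0)
                     ) -> np.ndarray:
    """Firing rate by alpha-cycle segment, normalized per cycle.

    Each accepted cycle is divided into ``n_bins`` equal segments; the mean
    rate per segment is divided by that cycle's mean rate, and the
    normalized histograms are averaged over cycles (and regions, for 2-D
    input).  Cycles with zero mean rate are skipped.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    cycles = detect_cycles(alpha_ref, sample_rate, accept_ms)
    if not cycles:
        raise ValueError("no cycles within the acceptance window")
    acc = np.zeros(n_bins)
    count = 0
    for a, b in cycles:
        edges = np.linspace(a, b, n_bins + 1).astype(int)
        for row in rates:
            m = row[a:b].mean()
            if m == 0:
                continue
            seg = np.array([row[edges[j]:edges[j + 1]].mean()
                            for j in range(n_bins)])
            acc += seg / m
            count += 1
    if count == 0:
        raise ValueError("all cycles had zero mean rate")
    return acc / count


# ---------------------------------------------------------------------------
# functional connectivity and prediction quality

def _values(x) -> np.ndarray:
    return x.values if isinstance(x, BOLDSeries) else np.atleast_2d(np.asarray(x, dtype=float))


def functional_connectivity(bold) -> np.ndarray:
    """Pairwise Pearson correlation matrix of regional series.

    Regions with constant series get NaN rows/columns (undefined and
    excluded downstream).
    """
    v = _values(bold)
    if v.shape[1] < 3:
        raise ValueError("need at least 3 scans for FC")
    sd = v.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(v)
    fc[sd == 0, :] = np.nan
    fc[:, sd == 0] = np.nan
    np.fill_diagonal(fc, 1.0)
    return fc


def fc_similarity(A: np.ndarray, B: np.ndarray) -> float:
    """Pearson correlation of the strictly-subdiagonal FC entries."""
    A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("FC matrices must have the same shape")
    idx = np.tril_indices_from(A, k=-1)
    a, b = A[idx], B[idx]
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def sliding_window_fc(bold, window: int = 100, step: int = 1
                      ) -> list[np.ndarray]:
    """FC matrices over sliding windows (100 scans = 194 s at TR 1.94)."""
    v = _values(bold)
    if v.shape[1] < window:
        raise ValueError(
            f"series has {v.shape[1]} scans, shorter than window {window}")
    return [functional_connectivity(v[:, s:s + window])
            for s in range(0, v.shape[1] - window + 1, step)]


def dynamic_fc_quality(sim, emp, window: int = 100, step: int = 1) -> float:
    """Mean over windows of the window-wise FC similarity."""
    fcs_sim = sliding_window_fc(sim, window, step)
    fcs_emp = sliding_window_fc(emp, window, step)
    return float(np.mean([fc_similarity(a, b)
                          for a, b in zip(fcs_sim, fcs_emp)]))


def prediction_quality(sim, emp) -> float:
    """Mean Pearson correlation over corresponding region pairs."""
    s, e = _values(sim), _values(emp)
    if s.shape != e.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {e.shape}")
    rs = [np.corrcoef(a, b)[0, 1] for a, b in zip(s, e)]
    return float(np.mean(rs))


# ---------------------------------------------------------------------------
# spectral scaling

@dataclass
class PowerLawFit:
    """Least-squares fit of P = a * f**beta to a normalized Welch PSD."""

    beta: float
    amplitude: float
    band: tuple[float, float]
    freqs: np.ndarray = field(repr=False)
    psd: np.ndarray = field(repr=False)
    r_squared: float = float("nan")


def welch_powerlaw(series: np.ndarray, sample_rate: float,
                   band: tuple[float, float] = (0.01, 0.17)) -> PowerLawFit:
    """Power-law exponent of the Welch PSD in a low-frequency band.

    The PSD is normalized by total power (unit integral); for matrix input
    the normalized PSDs are averaged across regions.  The fit is linear
    least squares in log-log space over the requested band.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    n = series.shape[1]
    if band[0] < 2.0 * sample_rate / n:
        raise ValueError(
            f"series too short to resolve {band[0]} Hz (length {n} at "
            f"{sample_rate} Hz)")
    nperseg = n // 4
    f, p = sps.welch(series, fs=sample_rate, nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant", axis=-1)
    df = f[1] - f[0]
    p = p / np.trapezoid(p, dx=df, axis=-1)[..., None]
    p = p.mean(axis=0)
    sel = (f >= band[0]) & (f <= band[1]) & (p > 0) & (f > 0)
    if sel.sum() < 4:
        raise ValueError("band unresolvable: too few PSD points in range")
    lf, lp = np.log(f[sel]), np.log(p[sel])
    beta, loga = np.polyfit(lf, lp, 1)
    resid = lp - (loga + beta * lf)
    ss_tot = np.sum((lp - lp.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else float("nan")
    return PowerLawFit(beta=float(beta), amplitude=float(np.exp(loga)),
                       band=band, freqs=f[sel], psd=p[sel], r_squared=r2)


# ---------------------------------------------------------------------------
# detrended fluctuation analysis

def dfa_fluctuation(series: np.ndarray, box_sizes: np.ndarray
                    ) -> np.ndarray:
    """First-order DFA fluctuation function F(n) over the given box sizes."""
    x = np.asarray(series, dtype=float).ravel()
    profile = np.cumsum(x - x.mean())
    F = np.empty(len(box_sizes))
    for j, n in enumerate(box_sizes):
        n = int(n)
        n_boxes = len(profile) // n
        seg = profile[:n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        # least-squares linear detrend per box, vectorized
        coef = np.polynomial.polynomial.polyfit(t, seg.T, 1)
        trend = coef[0][:, None] + coef[1][:, None] * t
        F[j] = np.sqrt(np.mean((seg - trend) ** 2))
    return F


@dataclass
class ScaleFreeVerdict:
    """Outcome of the DFA scale-invariance test."""

    dfa_exponent: float
    is_scale_free: bool
    model_scores: dict[str, float]  # small-sample AIC per candidate model
    box_sizes: np.ndarray = field(repr=False)
    fluctuation: np.ndarray = field(repr=False)


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood AIC with small-sample correction
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def dfa_scalefree_test(series: np.ndarray, min_box: int = 16,
                       n_boxes: int = 16,
                       aic_margin: float = 2.0) -> ScaleFreeVerdict:
    """Scale-invariance test: DFA plus log-log model comparison.

    Computes the first-order DFA fluctuation function over at least 12
    logarithmically spaced box sizes in [min_box, T/4], then compares a
    straight line (power law) against curved alternatives (quadratic and
    saturating exponential) in log-log space by small-sample-corrected
    AIC.  The series is scale-free unless an alternative beats the
    straight line by more than ``aic_margin`` (score differences below ~2
    are conventionally indistinguishable); the DFA exponent is the
    straight-line slope.
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) < 512:
        raise ValueError("series too short for DFA (need >= 512 samples)")
    max_box = len(x) // 4
    if max_box <= min_box * 2:
        raise ValueError("insufficient box-size span for DFA")
    sizes = np.unique(np.round(np.geomspace(min_box, max_box, n_boxes))
                      .astype(int))
    if len(sizes) < 12:
        raise ValueError("insufficient distinct box sizes for DFA")
    F = dfa_fluctuation(x, sizes)
    lx, ly = np.log(sizes), np.log(F)
    n = len(lx)

    scores: dict[str, float] = {}
    # linear: power law F ~ n**alpha
    slope, intercept = np.polyfit(lx, ly, 1)
    rss_lin = float(np.sum((ly - (intercept + slope * lx)) ** 2))
    scores["powerlaw"] = _aicc(rss_lin, n, 2)
    # quadratic curvature in log-log space
    c2 = np.polyfit(lx, ly, 2)
    rss_q = float(np.sum((ly - np.polyval(c2, lx)) ** 2))
    scores["quadratic"] = _aicc(rss_q, n, 3)
    # saturating exponential y = c - a*exp(-b*x)
    from scipy.optimize import curve_fit

    def satexp(xv, c, a, b):
        return c - a * np.exp(-b * xv)

    try:
        p0 = (ly[-1], ly[-1] - ly[0], 1.0 / (lx[-1] - lx[0]))
        popt, _ = curve_fit(satexp, lx, ly, p0=p0, maxfev=20000)
        rss_s = float(np.sum((ly - satexp(lx, *popt)) ** 2))
        scores["saturating_exp"] = _aicc(rss_s, n, 3)
    except RuntimeError:
        scores["saturating_exp"] = float("inf")

    is_scale_free = scores["powerlaw"] <= min(scores.values()) + aic_margin
    return ScaleFreeVerdict(dfa_exponent=float(slope),
                            is_scale_free=bool(is_scale_free),
                            model_scores=scores, box_sizes=sizes,
                            fluctuation=F)


# ---------------------------------------------------------------------------
# misc

def moving_average_rate(series: np.ndarray, window_ms: float = 100.0,
                        sample_rate: float = 1000.0) -> np.ndarray:
    """Centered moving mean; edge windows shrink to the available span."""
    series = np.asarray(series, dtype=float)
    w = max(int(round(window_ms * sample_rate / 1000.0)), 1)
    if w == 1:
        return series.copy()

    def smooth(row: np.ndarray) -> np.ndarray:
        csum = np.cumsum(np.concatenate(([0.0], row)))
        n = len(row)
        idx = np.arange(n)
        left = np.maximum(idx - (w - 1) // 2, 0)
        right = np.minimum(idx + w // 2 + 1, n)
        return (csum[right] - csum[left]) / (right - left)

    if series.ndim == 1:
        return smooth(series)
    return np.vstack([smooth(row) for row in series])
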