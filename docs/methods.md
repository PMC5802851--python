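# Methods

## Model

Each brain region is a pair of coupled neural-mass populations — one
excitatory (E, NMDA-like kinetics, τ_E = 100 ms) and one inhibitory
(I, GABA-like, τ_I = 10 ms) — described by its average synaptic gating
S^(E), S^(I). Input currents sum five contributions:

    I_E = W_E·I0 + [w+·J_NMDA·S_E] + G·Σ_j C_ij·S_j^E − J_i·S_I + w_BG^E·u(t)
    I_I = W_I·I0 + [J_NMDA·S_E]                       − S_I   + w_BG^I·u(t)

where u(t) is the injected per-region drive (z-scored electrical source
activity, or an artificial alpha signal), C is the max-normalized
structural connectome, G the global coupling, and J_i the region-wise
feedback inhibitory weight. Sigmoidal f–I curves r(I) = (aI−b)/(1−e^{−d(aI−b)})
convert currents to rates; rates drive first-order gating kinetics
(dS_E = −S_E/τ_E + (1−S_E)γ_E r_E; dS_I = −S_I/τ_I + γ_I r_I). The unit
convention is ms / Hz / nA; the default constants are the standard reduced
Wong–Wang set (I0 = 0.382 nA, a_E = 310 nC⁻¹, b_E = 125 Hz, d_E = 0.16 s,
γ_E = 6.41·10⁻⁴, etc.).

The bracketed local-recurrence terms are controlled by
`recurrence_enabled`. With them, an isolated node with J = 1 settles at
3.06 Hz — the calibration the feedback-inhibition-control (FIC) set-point
is built on (we verify the analytic fixed point to 3.077 Hz and the
simulated rate against it). Without them the equations contain no local
excitatory coupling at all: the injected drive stands in for it. Both
variants are first-class; see "Operating regimes" below for which
experiments use which.

Integration is explicit Euler at 10 kHz (dt = 0.1 ms), with each 1 kHz
drive sample held for 10 consecutive steps (sample-and-hold injection).
Recorded series are decimated to the drive rate. Gating is clamped to
[0, 1] (E) and [0, ∞) (I) after each step. A reduced-step oracle
(dt/100) bounds the integration error below 10⁻⁴ in the gating variables
over 1 s, which justifies the scheme. The integration loop is compiled
(numba); a pure-Python stepper with identical semantics exists for
verification, and a test asserts the two match to machine precision.

## Feedback inhibition control

FIC tunes the J_i so every excitatory population attains a whole-series
mean rate of 3.06 Hz. Each of (by default) 12 iterations simulates the
full series, measures per-node mean rates, and applies

    J_i ← J_i + (r̂_i − 3.06)·τ,   J_i ≥ 10⁻⁶ nA

with J initialized at 1 and τ at 0.005. τ adapts between iterations by a
secant rule — the mean |ΔJ| per node divided by the mean |Δr̂| per node,
an estimate of the inverse rate-vs-weight slope — and is halved instead
whenever the mean absolute per-node error failed to improve. After the
iteration budget, the J vector of the iteration with the smallest
per-node error is selected.

Two numerical safeguards matter in practice. First, the improvement
test, the secant and the selection all use the *per-node* error: the
global mean rate balances early while individual regions remain off, and
a global criterion then freezes τ prematurely. Second, each weight step
is clamped to 80% of the current weight (`step_clamp`): the rate
response to J is convex, so unclamped secant steps systematically
overshoot on networks with strong hubs. With both, 13/14 random 8-node
networks converge to ≤0.1 Hz per node within 12 iterations at the
default conditions. A `global_J` control mode adapts a single scalar
weight instead of N, reproducing the no-FIC control configuration.

## Hemodynamics

BOLD is generated from excitatory gating alone through the canonical
four-state Balloon–Windkessel model (vasodilatory signal, inflow, venous
volume, deoxyhemoglobin; κ = 0.65 s⁻¹, γ = 0.41 s⁻¹, τ = 0.98 s,
α = 0.32, ρ = 0.34, V0 = 0.02, k1 = 7ρ, k2 = 2, k3 = 2ρ−0.2), with the
neural input taken as S_E minus its per-region mean so rest maps to the
hemodynamic fixed point. Flow, volume and deoxyhemoglobin are integrated
in log-space at 1 ms Euler steps, which keeps them positive under
arbitrarily strong input; a 10× finer reference agrees within 1%. The
model low-passes above ~0.15 Hz, so simulated fMRI is obtained by plain
decimation: every 1940th millisecond sample (TR = 1.94 s), with the
first 11 scans (21.34 s) discarded.

## Synthetic inputs

The generators are pure functions of (spec, seed).

- **Artificial alpha**: a zero-mean sine at 8–12 Hz (default 10 Hz)
  multiplied by an envelope — constant; a single raised-cosine burst
  (default 10 s long, 4× baseline, centered mid-series, long flat
  stabilization epochs on either side); or a strictly positive slow
  amplitude modulation built from equal-depth components at 0.01–0.03 Hz
  (default total depth 0.8, envelope swinging 0.2×–1.8×).
- **Surrogate source activity**: per-region 1/f^0.5 broadband noise plus
  an alpha component with a slow random power envelope, z-scored at
  200 Hz and spline-upsampled to 1 kHz, mirroring the preprocessing
  chain of empirical source activity.
- **Permutation control**: independent uniform shuffling of each
  region's samples (value distribution preserved, all timing destroyed).
- **Connectomes**: symmetric log-normal weights with σ = 2 in log-space
  (about four decades of weight magnitudes, as in tractography-derived
  connectomes), zero diagonal, max-normalized. The heavy tail keeps row
  sums of the normalized matrix near or below one; near-homogeneous
  matrices (small σ) would put coupled networks into excitatory runaway
  at moderate G, a regime the whole-brain models this emulates never
  occupy.

What the generators do **not** emulate: volume conduction and source
mixing, inter-subject variability, spatially correlated drive, or the
full broadband spectrum of EEG. Passing tests demonstrate the internal
mechanisms of the model under controlled drive, not prediction of any
empirical recording.

## Operating regimes

Two parameter regimes are used, corresponding to the two roles the model
plays:

- **Tuning regime** (FIC convergence): recurrence on, G = 0.2,
  w_BG^E = 0.005, w_BG^I = 0.05 (the median of the fitted range). The
  local E→I coupling makes the J→rate map smooth and monotone, which is
  what allows per-node convergence on arbitrary random connectomes.
- **Mechanism regime** (burst, slow-AM, phase locking, carrier
  robustness, coupling profile): recurrence off (input currents exactly
  as written above without brackets), w_BG^E = 0.05, w_BG^I = 0.25.
  These scalings realize inhibitory postsynaptic current amplitudes
  about three times the excitatory ones at E populations — the balance
  the fitted full-scale models exhibit — and only near that balance do
  the mechanism signs emerge: with EPSCs negligible, the periodic
  collapse of inhibition during alpha troughs dominates and alpha power
  *raises* rather than lowers excitatory activity.

The alpha mechanisms themselves, in this package's experiments:
half-wave rectification makes the cycle-averaged inhibitory rate grow
with alpha amplitude; feedback inhibition therefore tracks alpha power,
suppressing excitatory rates, gating and BOLD (burst response and an
alpha-regressor correlation of about −0.8 in the slow-AM experiment);
the effect depends on alpha power, not phase, so 9/11 Hz carriers
reproduce the 10 Hz outputs with r > 0.99.

**Coupling-dependent steepening** requires one more ingredient:
proximity to criticality. The long-range excitatory loop has gain
g = G·λ_max(C)·s, where s is the steady-state sensitivity of mean
gating to input current at the operating point; amplification of a slow
co-fluctuation is 1/(1−g) with corner frequency ≈ (1−g)/(2πτ_E). For
frequency selectivity inside 0.01–0.03 Hz the network must sit near
g = 1. The coupling-profile experiment therefore estimates the critical
coupling G_c at run time — λ_max from the connectome, s from two short
perturbed simulations — and runs the coupled case at 0.8·G_c, the
desk-scale analog of fitting G to data (which, by the model family's own
account, selects near-critical coupling). Amplitudes are measured by
Fourier projection of the regional-mean BOLD at each AM frequency over a
whole number of cycles; peak-to-peak measures are confounded by slow
transients near criticality.

## Analyses

Band-pass filters are 4th-order zero-phase Butterworth. Alpha power
envelopes are analytic-signal magnitudes of the 8–10 Hz band, with ~50 s
trimmed at each end against edge effects. The alpha regressor convolves
the envelope with a canonical double-gamma HRF (peak 6 s, undershoot
16 s, ratio 6), decimates to TR, and searches ±3 scan shifts for the
most negative mean regional correlation. Cycle-locked averages and the
six-bin phase histogram use rising zero crossings as cycle onsets and
accept cycles of 95–105 ms; phase segments are sixths of the cycle from
onset, so the drive peak falls in the second segment and the trough in
the fifth. Because feedback inhibition integrates the drive with the
10 ms inhibitory time constant (plus rectification asymmetry), the
excitatory firing maximum genuinely lags the trough by 30–70°: tests
assert the minimum in the peak segment and the maximum within the trough
half-cycle rather than pinning the maximum to the trough-centered sixth.

FC is the pair-wise Pearson matrix (constant regions excluded as NaN);
FC similarity is the Pearson correlation of strictly-subdiagonal
entries; dynamic FC uses 100-scan (194 s) sliding windows with 1-scan
step. Prediction quality is the mean correlation over corresponding
region pairs. Welch PSDs (segments of a quarter of the series, 50%
overlap, unit-integral normalization) are fitted with a·f^β by linear
least squares in log-log space over 0.01–0.17 Hz. The scale-invariance
test combines first-order DFA (≥12 log-spaced box sizes in [16, T/4])
with small-sample-corrected AIC comparison of a straight line against a
quadratic and a saturating exponential in log-log fluctuation space; an
alternative must win by more than 2 AICc units to reject scale freeness
(DFA's small-box curvature bias otherwise rejects even white noise).

## Problem sizes and defaults

Experiments default to one synthetic connectome of 8–16 regions and 2–8
simulated minutes (the full study: 15 subjects × 68 regions × 21.6 min);
all sizes are plain function arguments, and the parameter sweep runs a
3×3×3 grid by default with FIC inside every combination. The sweep's
generate-then-recover check selects the exact generating triple with
score 1.0 because the pipeline is deterministic given seed and config.

## Known limitations

- FIC convergence to ±0.1 Hz per node fails on roughly 1 in 14 random
  connectomes (extreme hub structure); the grand-mean rate still lands
  within ±0.1 Hz of the set-point in those cases.
- The steepening contrast at 0.8·G_c is a few percent per octave of AM
  frequency — qualitatively correct, far shallower than a fitted
  full-scale cohort; pushing closer to G_c strengthens it but makes FIC
  unstable.
- The scale-free experiment on surrogate drive produces steeper BOLD
  spectra than the empirical reference values, as expected: the
  surrogate envelope spectrum is not calibrated to any subject's EEG.
- Conduction delays are not modeled (deliberately, matching the model
  family this implements).
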