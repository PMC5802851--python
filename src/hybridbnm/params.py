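"""Model and hemodynamic parameter containers.

Default values are the standard reduced Wong-Wang (dynamic mean field)
parameter set; the unit convention is time in ms, firing rates in Hz,
currents in nA.  Under this convention the kinetic parameters are
``gamma_E = 6.41e-4`` and ``gamma_I = 1.0e-3`` per ms, consistent with
synaptic time constants of 100 ms (NMDA) and 10 ms (GABA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the coupled excitatory/inhibitory neural-mass node.

    Attributes
    ----------
    W_E, W_I : float
        Dimensionless scalings of the overall effective external input for
        the excitatory and inhibitory populations.
    I0 : float
        Overall effective external input, nA.
    a_E, a_I : float
        Gains of the f-I transfer functions, 1/nC.
    b_E, b_I : float
        Thresholds of the f-I transfer functions, Hz.
    d_E, d_I : float
        Curvature constants of the f-I transfer functions, s.
    tau_E, tau_I : float
        Synaptic gating time constants, ms.
    gamma_E, gamma_I : float
        Kinetic rate parameters, 1/ms scale.
    w_plus : float
        Local excitatory recurrence weight (dimensionless).
    J_NMDA : float
        Excitatory synaptic coupling, nA.
    G : float
        Global long-range coupling scaling factor (dimensionless).
    w_BG_E, w_BG_I : float
        Scalings applied to the injected (z-scored) drive current before it
        enters the excitatory and inhibitory populations.
    noise_sigma : float
        Standard deviation of additive Gaussian current noise per
        integration step, nA.  Zero for the drive-injected model; positive
        only for the noise-driven control model.
    recurrence_enabled : bool
        When True the local excitatory recurrence terms
        ``w_plus*J_NMDA*S_E`` (onto E) and ``J_NMDA*S_E`` (onto I) are
        included, matching the original noise-driven mean-field model and
        the isolated-node 3.06 Hz calibration.  When False, input currents
        contain no local excitatory feedback.
    """

    W_E: float = 1.0
    W_I: float = 0.7
    I0: float = 0.382
    a_E: float = 310.0
    b_E: float = 125.0
    d_E: float = 0.16
    a_I: float = 615.0
    b_I: float = 177.0
    d_I: float = 0.087
    tau_E: float = 100.0
    tau_I: float = 10.0
    gamma_E: float = 6.41e-4
    gamma_I: float = 1.0e-3
    w_plus: float = 1.4
    J_NMDA: float = 0.15
    G: float = 0.0
    w_BG_E: float = 0.0
    w_BG_I: float = 0.0
    noise_sigma: float = 0.0
    recurrence_enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("tau_E", "tau_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("a_E", "a_I", "d_E", "d_I", "gamma_E", "gamma_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("G", "w_BG_E", "w_BG_I", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class HemodynamicParameters:
    """Balloon-Windkessel constants (canonical four-state formulation).

    ``kappa`` (1/s) is the vasodilatory signal decay rate, ``gamma_h``
    (1/s) the flow autoregulation rate, ``tau_h`` (s) the venous transit
    time, ``alpha_h`` the Grubb vessel stiffness exponent, ``rho`` the
    resting oxygen extraction fraction, ``V0`` the resting venous blood
    volume fraction, and ``k1``-``k3`` the coefficients of the nonlinear
    BOLD readout.
    """

    kappa: float = 0.65
    gamma_h: float = 0.41
    tau_h: float = 0.98
    alpha_h: float = 0.32
    rho: float = 0.34
    V0: float = 0.02
    k1: float = field(default=7.0 * 0.34)
    k2: float = 2.0
    k3: float = field(default=2.0 * 0.34 - 0.2)

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma_h", "tau_h", "alpha_h", "rho", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
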