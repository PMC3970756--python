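"""Hybrid membrane model of a primary-afferent soma.

The model couples a two-variable Morris-Lecar (ML) spike generator —
membrane potential ``V`` and a slow recovery variable ``w`` — with
additive Hodgkin-Huxley-style subthreshold conductances and an optional
slow after-hyperpolarization (AHP, spike-dependent adaptation) current.
The ML core produces the spike upstroke/downstroke; the added
first-order channels (activation exponent 1, no inactivation) are tuned
to activate in the perithreshold voltage range and serve purely to bias
the competition between net inward and net outward subthreshold current,
which is what moves the cell toward or away from its tipping point.

Currents (densities, |muA/cm^2):

    I_fast = gbar_fast * m_inf(V) * (V - E_Na)      (instantaneous)
    I_slow = gbar_slow * w * (V - E_K)
    I_leak = g_leak * (V - E_leak)
    I_ch   = gbar * m * (V - E_rev)                 (per added channel)
    I_AHP  = gbar_AHP * z * (V - E_K)

ML gating uses the standard hyperbolic-tangent formulation

    m_inf(V)  = 0.5 * (1 + tanh((V - beta_m) / gamma_m))
    w_inf(V)  = 0.5 * (1 + tanh((V - beta_w) / gamma_w))
    tau_w(V)  = 1 / cosh((V - beta_w) / (2 gamma_w))
    dw/dt     = phi_w * (w_inf(V) - w) / tau_w(V)

Added channels use linoid/exponential rate kinetics

    alpha(V) = k_a * x / (exp(x) - 1),   x = (V - V_a) / s_a
    beta(V)  = k_b * exp((V - V_b) / s_b)
    dm/dt    = alpha(V) (1 - m) - beta(V) m

and the AHP gate relaxes to a sigmoid with a suprathreshold
half-activation, making it effectively spike-triggered:

    z_inf(V) = 1 / (1 + exp((beta_z - V) / gamma_z))
    dz/dt    = (z_inf(V) - z) / tau_z
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "MLCoreParams",
    "LinoidGateParams",
    "SubthresholdChannel",
    "AHPParams",
    "NoiseSpec",
    "CellModel",
    "State",
    "GateKinetics",
    "gate_kinetics",
    "membrane_currents",
    "rhs",
    "sodium_channel",
    "potassium_channel",
]


class ModelStructureError(ValueError):
    """State and model disagree on the number of gating variables."""


class GateKinetics(NamedTuple):
    """Voltage-dependent rate quantities of a first-order gate."""

    alpha: float  # ms^-1
    beta: float  # ms^-1
    m_inf: float  # steady-state activation
    tau: float  # ms


@dataclass(frozen=True)
class MLCoreParams:
    """Morris-Lecar core parameters (densities; mV, ms, mS/cm^2, uF/cm^2).

    Defaults give a spike threshold near -35 mV, appropriate for the
    soma of a myelinated afferent, and are held fixed throughout: all
    excitability manipulations act on the added channels.
    """

    C: float = 2.0
    E_Na: float = 50.0
    E_K: float = -100.0
    E_leak: float = -70.0
    phi_w: float = 0.15
    gbar_fast: float = 20.0
    gbar_slow: float = 20.0
    g_leak: float = 2.0
    beta_m: float = -1.2
    gamma_m: float = 14.0
    beta_w: float = -10.0
    gamma_w: float = 10.0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"capacitance must be positive, got {self.C}")
        for name in ("gbar_fast", "gbar_slow", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gamma_m == 0 or self.gamma_w == 0:
            raise ValueError("slope factors gamma_m, gamma_w must be nonzero")
        if not (self.E_K < self.E_leak < self.E_Na):
            raise ValueError("require E_K < E_leak < E_Na")

    def m_inf(self, V: float) -> float:
        return 0.5 * (1.0 + np.tanh((V - self.beta_m) / self.gamma_m))

    def w_inf(self, V: float) -> float:
        return 0.5 * (1.0 + np.tanh((V - self.beta_w) / self.gamma_w))

    def tau_w(self, V: float) -> float:
        return 1.0 / np.cosh((V - self.beta_w) / (2.0 * self.gamma_w))


@dataclass(frozen=True)
class LinoidGateParams:
    """Rate parameters of a linoid/exponential first-order gate.

    Defaults place half-activation at -24 mV with a ~0.5 ms time
    constant there (k = 1 ms^-1), i.e. fast perithreshold activation.
    """

    k_alpha: float = 1.0
    k_beta: float = 1.0
    V_alpha: float = -24.0
    V_beta: float = -24.0
    s_alpha: float = -17.0
    s_beta: float = -17.0

    def __post_init__(self) -> None:
        if self.k_alpha <= 0 or self.k_beta <= 0:
            raise ValueError("rate constants k_alpha, k_beta must be positive")
        if self.s_alpha == 0 or self.s_beta == 0:
            raise ValueError("slope voltages s_alpha, s_beta must be nonzero")

    def shifted(self, dV: float) -> "LinoidGateParams":
        """Shift the voltage dependence by ``dV`` (mV)."""
        return replace(self, V_alpha=self.V_alpha + dV, V_beta=self.V_beta + dV)


@dataclass(frozen=True)
class SubthresholdChannel:
    """A first-order added conductance; Na-like or K-like by reversal."""

    gbar: float  # mS/cm^2
    E_rev: float  # mV
    label: str
    gate: LinoidGateParams = field(default_factory=LinoidGateParams)

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError(f"channel {self.label!r}: gbar must be >= 0")

    def current(self, V: float, m: float) -> float:
        return self.gbar * m * (V - self.E_rev)


def sodium_channel(
    gbar: float, label: str = "Na", gate: LinoidGateParams | None = None
) -> SubthresholdChannel:
    """Na-like subthreshold channel (E_rev = +50 mV)."""
    return SubthresholdChannel(gbar, 50.0, label, gate or LinoidGateParams())


def potassium_channel(
    gbar: float, label: str = "K", gate: LinoidGateParams | None = None
) -> SubthresholdChannel:
    """K-like subthreshold channel (E_rev = -100 mV)."""
    return SubthresholdChannel(gbar, -100.0, label, gate or LinoidGateParams())


@dataclass(frozen=True)
class AHPParams:
    """Slow AHP (adaptation) current gate.

    beta_z = 0 mV sits above spike threshold, so z integrates spikes;
    tau_z = 300 ms makes the resulting outward current slow enough to
    sweep the effective stimulus back and forth across a bistable
    window.  The default density gives an adaptation current large
    enough to traverse the reference neuropathic cell's bistable window
    (a prerequisite for hysteresis bursting).
    """

    gbar: float = 2.0  # mS/cm^2
    beta_z: float = 0.0
    gamma_z: float = 5.0
    tau_z: float = 300.0

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError("gbar_AHP must be >= 0")
        if self.tau_z <= 0:
            raise ValueError("tau_z must be positive")

    def z_inf(self, V: float) -> float:
        return 1.0 / (1.0 + np.exp((self.beta_z - V) / self.gamma_z))


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian current noise added to the stimulus.

    ``sigma`` is the standard deviation (uA/cm^2) of the noise current
    when held piecewise-constant over steps of ``dt_ref`` ms; integrating
    at a different dt rescales the per-step SD by sqrt(dt_ref/dt) so that
    trace statistics are dt-invariant.  ``mode`` may be "white" or "ou"
    (Ornstein-Uhlenbeck with correlation time ``tau_corr``).
    """

    sigma: float = 0.3
    dt_ref: float = 0.1
    mode: str = "white"
    tau_corr: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.mode not in ("white", "ou"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.tau_corr <= 0:
            raise ValueError("tau_corr must be positive")


@dataclass(frozen=True)
class CellModel:
    """A fully parameterized model cell.

    Aggregates the ML core, an ordered collection of added subthreshold
    channels (unique labels), an optional AHP current and an optional
    noise specification.  Immutable; manipulations return new models.
    """

    core: MLCoreParams = field(default_factory=MLCoreParams)
    channels: tuple[SubthresholdChannel, ...] = ()
    ahp: AHPParams | None = None
    noise: NoiseSpec | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        labels = [ch.label for ch in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"channel labels must be unique, got {labels}")

    # -- structural helpers -------------------------------------------------

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def dim(self) -> int:
        """State dimension: V, w, one m per channel, z."""
        return 2 + self.n_channels + 1

    def channel(self, label: str) -> SubthresholdChannel:
        for ch in self.channels:
            if ch.label == label:
                return ch
        raise KeyError(f"no channel labeled {label!r}")

    def with_channel(self, channel: SubthresholdChannel) -> "CellModel":
        """Return a model with ``channel`` appended (label must be new)."""
        return replace(self, channels=self.channels + (channel,))

    def scale_channel(self, label: str, factor: float) -> "CellModel":
        """Multiply the maximal conductance of one channel by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        new = tuple(
            replace(ch, gbar=ch.gbar * factor) if ch.label == label else ch
            for ch in self.channels
        )
        self.channel(label)  # raises KeyError if absent
        return replace(self, channels=new)

    def with_noise(self, noise: NoiseSpec | None) -> "CellModel":
        return replace(self, noise=noise)

    def with_ahp(self, ahp: AHPParams | None) -> "CellModel":
        return replace(self, ahp=ahp)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"core": vars(self.core).copy()}
        d["channels"] = [
            {
                "gbar": ch.gbar,
                "E_rev": ch.E_rev,
                "label": ch.label,
                "gate": vars(ch.gate).copy(),
            }
            for ch in self.channels
        ]
        d["ahp"] = vars(self.ahp).copy() if self.ahp is not None else None
        d["noise"] = vars(self.noise).copy() if self.noise is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellModel":
        channels = tuple(
            SubthresholdChannel(
                gbar=c["gbar"],
                E_rev=c["E_rev"],
                label=c["label"],
                gate=LinoidGateParams(**c["gate"]),
            )
            for c in d.get("channels", ())
        )
        ahp = AHPParams(**d["ahp"]) if d.get("ahp") else None
        noise = NoiseSpec(**d["noise"]) if d.get("noise") else None
        return cls(
            core=MLCoreParams(**d.get("core", {})),
            channels=channels,
            ahp=ahp,
            noise=noise,
        )

    # -- packed parameter arrays for the numerical kernels ------------------

    def _packed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        c = self.core
        core = np.array(
            [
                c.C, c.E_Na, c.E_K, c.E_leak, c.phi_w,
                c.gbar_fast, c.gbar_slow, c.g_leak,
                c.beta_m, c.gamma_m, c.beta_w, c.gamma_w,
            ],
            dtype=np.float64,
        )
        chan = np.empty((self.n_channels, 8), dtype=np.float64)
        for i, ch in enumerate(self.channels):
            g = ch.gate
            chan[i] = (
                g.k_alpha, g.V_alpha, g.s_alpha,
                g.k_beta, g.V_beta, g.s_beta,
                ch.gbar, ch.E_rev,
            )
        if self.ahp is not None:
            a = self.ahp
            ahp = np.array([a.gbar, a.beta_z, a.gamma_z, a.tau_z], dtype=np.float64)
        else:
            ahp = np.array([0.0, 0.0, 5.0, 300.0], dtype=np.float64)
        return core, chan, ahp


@dataclass
class State:
    """Instantaneous model state: V (mV), w, per-channel m, z (all in [0,1])."""

    V: float
    w: float
    m: np.ndarray = field(default_factory=lambda: np.empty(0))
    z: float = 0.0

    def __post_init__(self) -> None:
        self.m = np.atleast_1d(np.asarray(self.m, dtype=np.float64))
        if not np.isfinite(self.V):
            raise ValueError("V must be finite")
        vals = np.concatenate([[self.w], self.m, [self.z]])
        if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
            raise ValueError("gating variables must lie in [0, 1]")

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.V, self.w], self.m, [self.z]])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "State":
        y = np.asarray(y, dtype=np.float64)
        return cls(V=y[0], w=y[1], m=y[2:-1].copy(), z=y[-1])


def steady_state(model: CellModel, V: float) -> State:
    """State with every gate at its voltage-dependent steady state."""
    m = np.array([gate_kinetics(V, ch.gate).m_inf for ch in model.channels])
    z_inf = model.ahp.z_inf(V) if model.ahp is not None else AHPParams().z_inf(V)
    return State(V=V, w=float(model.core.w_inf(V)), m=m, z=float(z_inf))


def _linoid(x: float) -> float:
    # x / (exp(x) - 1), with the removable singularity at x = 0 filled in
    if abs(x) < 1e-4:
        return 1.0 - 0.5 * x + x * x / 12.0
    return x / math.expm1(x)


def gate_kinetics(V: float, gate: LinoidGateParams) -> GateKinetics:
    """Rates, steady-state activation and time constant of a linoid gate.

    alpha uses the linoid form k_a*x/(exp(x)-1) with x = (V-V_a)/s_a
    (evaluated by its limit k_a at V = V_a); beta = k_b*exp((V-V_b)/s_b).
    """
    if not np.isfinite(V):
        raise ValueError(f"V must be finite, got {V}")
    alpha = gate.k_alpha * _linoid((V - gate.V_alpha) / gate.s_alpha)
    beta = gate.k_beta * math.exp((V - gate.V_beta) / gate.s_beta)
    total = alpha + beta
    return GateKinetics(alpha=alpha, beta=beta, m_inf=alpha / total, tau=1.0 / total)


def membrane_currents(
    state: State, model: CellModel, I_stim: float = 0.0
) -> dict[str, float]:
    """Per-term membrane currents (uA/cm^2) at ``state``.

    Returns a mapping with keys ``fast``, ``slow``, ``leak``, one per
    added-channel label, and ``AHP``; outward positive, so that
    C dV/dt = I_stim - sum(currents).
    """
    if state.m.shape[0] != model.n_channels:
        raise ModelStructureError(
            f"state carries {state.m.shape[0]} channel gates, "
            f"model has {model.n_channels}"
        )
    c = model.core
    V = state.V
    out = {
        "fast": c.gbar_fast * float(c.m_inf(V)) * (V - c.E_Na),
        "slow": c.gbar_slow * state.w * (V - c.E_K),
        "leak": c.g_leak * (V - c.E_leak),
    }
    for ch, m in zip(model.channels, state.m):
        out[ch.label] = ch.current(V, float(m))
    g_ahp = model.ahp.gbar if model.ahp is not None else 0.0
    out["AHP"] = g_ahp * state.z * (V - c.E_K)
    return out


def rhs(state: State, model: CellModel, I_stim: float = 0.0) -> np.ndarray:
    """Time derivative of the packed state vector [V, w, m_i..., z].

    Deterministic part only; noise enters through the integrator.
    """
    if state.m.shape[0] != model.n_channels:
        raise ModelStructureError(
            f"state carries {state.m.shape[0]} channel gates, "
            f"model has {model.n_channels}"
        )
    from ._kernels import rhs_vec  # local import: avoid jit cost at module load

    core, chan, ahp = model._packed()
    y = state.to_vector()
    dy = np.empty_like(y)
    rhs_vec(y, float(I_stim), core, chan, ahp, dy)
    return dy
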