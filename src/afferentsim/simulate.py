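"""Integration of the membrane model under step-stimulus protocols.

Deterministic runs use fixed-step 4th-order Runge-Kutta; runs with
current noise use Euler-Maruyama with the noise held piecewise-constant
per step and its per-step standard deviation scaled by sqrt(dt_ref/dt),
so that trace statistics do not depend on the integration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from . import _kernels
from .model_core import CellModel, State, steady_state

__all__ = [
    "StimulusProtocol",
    "Trace",
    "SimulationDivergedError",
    "HoldingInfeasibleError",
    "integrate",
    "stationary_current",
    "find_holding_current",
]

#: default integration step (ms); spike upstrokes are well resolved at
#: dt <= 0.05, and RK4 at 0.02 is converged for spike counts
DT_DEFAULT = 0.02
#: default integration step for stochastic (Euler-Maruyama) runs
DT_STOCHASTIC = 0.05
#: default sampling interval of recorded traces (ms)
RECORD_DT_DEFAULT = 0.05


class SimulationDivergedError(RuntimeError):
    """The state became non-finite during integration."""

    def __init__(self, t_ms: float):
        self.t_ms = t_ms
        super().__init__(f"simulation diverged at t = {t_ms:.3f} ms")


class HoldingInfeasibleError(RuntimeError):
    """No stable equilibrium exists at the requested holding potential."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Tonic holding current plus rectangular current steps.

    ``steps`` is a sequence of (onset_ms, duration_ms, amplitude) tuples;
    amplitudes are in uA/cm^2 and add to ``I_hold``.
    """

    T_total: float  # ms
    dt: float = DT_DEFAULT
    I_hold: float = 0.0
    steps: tuple[tuple[float, float, float], ...] = ()
    record_dt: float = RECORD_DT_DEFAULT

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T_total <= 0:
            raise ValueError("T_total must be positive")
        object.__setattr__(self, "steps", tuple(tuple(s) for s in self.steps))
        for onset, duration, amplitude in self.steps:
            if onset < 0 or duration < 0 or onset + duration > self.T_total + 1e-9:
                raise ValueError("steps must lie within [0, T_total]")
            if not np.isfinite(amplitude):
                raise ValueError("step amplitudes must be finite")

    @classmethod
    def step(
        cls,
        amplitude: float,
        onset: float = 100.0,
        duration: float = 1000.0,
        tail: float = 100.0,
        I_hold: float = 0.0,
        dt: float = DT_DEFAULT,
        record_dt: float = RECORD_DT_DEFAULT,
    ) -> "StimulusProtocol":
        """A single rectangular step with pre- and post-stimulus padding."""
        return cls(
            T_total=onset + duration + tail,
            dt=dt,
            I_hold=I_hold,
            steps=((onset, duration, amplitude),),
            record_dt=record_dt,
        )

    def applied_current(self) -> np.ndarray:
        """Deterministic applied current per integration step."""
        n_steps = int(round(self.T_total / self.dt))
        t = np.arange(n_steps) * self.dt
        I = np.full(n_steps, self.I_hold, dtype=np.float64)
        for onset, duration, amplitude in self.steps:
            I[(t >= onset) & (t < onset + duration)] += amplitude
        return I


@dataclass
class Trace:
    """Recorded time series of a single simulation."""

    t: np.ndarray  # ms
    V: np.ndarray  # mV
    w: np.ndarray
    m: np.ndarray  # shape (n_samples, n_channels)
    z: np.ndarray
    I_applied: np.ndarray  # uA/cm^2, stimulus + noise at recorded samples
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        if not all(len(a) == n for a in (self.V, self.w, self.z, self.I_applied)):
            raise ValueError("trace arrays must have equal length")
        if self.m.shape[0] != n:
            raise ValueError("trace arrays must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def final_state(self) -> State:
        return State(
            V=float(self.V[-1]),
            w=float(self.w[-1]),
            m=self.m[-1].copy(),
            z=float(self.z[-1]),
        )

    def window(self, t0: float, t1: float) -> "Trace":
        """Restrict the trace to t in [t0, t1)."""
        sel = (self.t >= t0) & (self.t < t1)
        return Trace(
            t=self.t[sel],
            V=self.V[sel],
            w=self.w[sel],
            m=self.m[sel],
            z=self.z[sel],
            I_applied=self.I_applied[sel],
            meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_ms": self.t, "V_mV": self.V, "w": self.w})
        for i in range(self.m.shape[1]):
            label = self.meta.get("channel_labels", [f"ch{i}"] * (i + 1))[i]
            df[f"m_{label}"] = self.m[:, i]
        df["z"] = self.z
        df["I_uAcm2"] = self.I_applied
        return df


def _noise_current(
    model: CellModel, n_steps: int, dt: float, seed: int | None
) -> np.ndarray:
    spec = model.noise
    if spec is None or spec.sigma == 0.0:
        return np.zeros(n_steps)
    if seed is None:
        raise ValueError("a seed is required when noise sigma > 0")
    rng = np.random.default_rng(seed)
    if spec.mode == "white":
        sigma_eff = spec.sigma * np.sqrt(spec.dt_ref / dt)
        return rng.standard_normal(n_steps) * sigma_eff
    # OU: sigma is the stationary SD, tau_corr the correlation time
    x = np.empty(n_steps)
    x[0] = rng.standard_normal() * spec.sigma
    coef = np.sqrt(2.0 * spec.sigma**2 * dt / spec.tau_corr)
    xi = rng.standard_normal(n_steps - 1)
    decay = dt / spec.tau_corr
    for i in range(1, n_steps):
        x[i] = x[i - 1] * (1.0 - decay) + coef * xi[i - 1]
    return x


def relax_to_rest(
    model: CellModel, I_hold: float = 0.0, T: float = 1000.0, V0: float = -70.0
) -> State:
    """Relax the noise-free model at ``I_hold`` and return the final state.

    Used as the default initial condition so that step responses are not
    contaminated by onset transients.
    """
    det = model.with_noise(None)
    proto = StimulusProtocol(T_total=T, dt=0.05, I_hold=I_hold, record_dt=10.0)
    tr = integrate(det, proto, initial_state=steady_state(det, V0))
    return tr.final_state()


def integrate(
    model: CellModel,
    protocol: StimulusProtocol,
    seed: int | None = None,
    initial_state: State | None = None,
) -> Trace:
    """Integrate ``model`` under ``protocol`` and return the recorded trace.

    Deterministic (no noise attached, or sigma = 0) runs use RK4;
    stochastic runs use Euler-Maruyama and require ``seed``.  Identical
    (model, protocol, seed, initial_state) yield bit-identical traces.
    """
    core, chan, ahp = model._packed()
    I_app = protocol.applied_current()
    n_steps = len(I_app)
    dt = protocol.dt
    stride = max(1, int(round(protocol.record_dt / dt)))

    if initial_state is None:
        y0 = relax_to_rest(model, protocol.I_hold).to_vector()
    else:
        if initial_state.m.shape[0] != model.n_channels:
            raise ValueError("initial state does not match model channel count")
        y0 = initial_state.to_vector()

    n_rec = 1 + n_steps // stride
    out = np.empty((n_rec, model.dim))
    noisy = model.noise is not None and model.noise.sigma > 0
    if noisy:
        I_noise = _noise_current(model, n_steps, dt, seed)
        status = _kernels.integrate_em(y0, dt, I_app, I_noise, core, chan, ahp, stride, out)
    else:
        I_noise = np.zeros(n_steps)
        status = _kernels.integrate_rk4(y0, dt, I_app, core, chan, ahp, stride, out)
    if status >= 0:
        raise SimulationDivergedError(status * dt)

    # applied current at recorded samples (sample 0 precedes the first step)
    I_total = I_app + I_noise
    idx = np.arange(1, n_rec) * stride - 1
    I_rec = np.concatenate([[I_total[0]], I_total[idx]])
    t = np.arange(n_rec) * (stride * dt)
    meta = {
        "dt": dt,
        "record_dt": stride * dt,
        "seed": seed,
        "I_hold": protocol.I_hold,
        "steps": protocol.steps,
        "channel_labels": [ch.label for ch in model.channels],
        "model": model.to_dict(),
    }
    return Trace(
        t=t,
        V=out[:, 0],
        w=out[:, 1],
        m=out[:, 2:-1],
        z=out[:, -1],
        I_applied=I_rec,
        meta=meta,
    )


def stationary_current(model: CellModel, V: float) -> float:
    """Net membrane current (uA/cm^2) with all gates at steady state.

    The tonic current required to hold the membrane at V, i.e. the
    right-hand side of the scalar stationary current balance.
    """
    from .model_core import membrane_currents

    s = steady_state(model, V)
    return float(sum(membrane_currents(s, model, 0.0).values()))


def find_holding_current(model: CellModel, V_target: float) -> float:
    """Tonic bias current that holds the resting potential at ``V_target``.

    Mirrors the experimental convention of adjusting the membrane to a
    reference potential (e.g. -65 mV) by tonic current injection.
    Raises :class:`HoldingInfeasibleError` if the equilibrium at
    ``V_target`` is not stable under that current.
    """
    core = model.core
    if not (core.E_K < V_target < core.E_Na):
        raise ValueError("V_target must lie between E_K and E_Na")
    I_hold = stationary_current(model, V_target)
    # stability check via the Jacobian eigenvalues at the equilibrium
    from .dynamics import _eigenvalues_at

    eig = _eigenvalues_at(model, V_target, I_hold)
    if np.max(eig.real) >= 0:
        raise HoldingInfeasibleError(
            f"equilibrium at {V_target} mV is unstable under I_hold = {I_hold:.4f}"
        )
    return I_hold
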