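"""Scripted in-silico experiments: the six tipping-point predictions,
voltage-clamp-style current-density measurements, passive properties and
unit conversions.

The six predictions mirror dynamic-clamp/pharmacology manipulations on
the excitability diagram: a normal cell is converted to neuropathic
excitability by decreasing subthreshold K conductance (1), increasing
subthreshold Na conductance (2), or a combination (3); matched Na+K
increases offset one another (4); a neuropathic cell is normalized by
adding K conductance (5) or scaling Na conductance down, riluzole-like
(6).  Drug analogies are pure conductance scalings (4-AP/dendrotoxin:
scale K by f in [0,1]; riluzole: scale Na); no state-dependent block is
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .classify import ExcitabilityLabel, classify_excitability, detect_spikes
from .dynamics import I_RANGE_DEFAULT, _set_na_k, hopf_bearing
from .model_core import (
    CellModel,
    gate_kinetics,
    potassium_channel,
    sodium_channel,
)
from .simulate import StimulusProtocol, Trace, integrate, relax_to_rest

__all__ = [
    "PredictionOutcome",
    "PassiveProperties",
    "run_prediction",
    "run_all_predictions",
    "measure_subthreshold_K_density",
    "density_conversion",
    "measure_passive",
    "local_boundary_gNa",
    "spike_threshold_voltage",
]


class PredictionStateError(RuntimeError):
    """The starting model is on the wrong side of the tipping point."""


@dataclass
class PredictionOutcome:
    """Result of one tipping-point prediction experiment."""

    prediction_id: int
    manipulation: str
    label_before: ExcitabilityLabel
    label_after: ExcitabilityLabel
    confirmed: bool
    parameters: dict


#: expected before -> after transition per prediction
_EXPECTED = {
    1: ("onset-only", "repetitive"),
    2: ("onset-only", "repetitive"),
    3: ("onset-only", "repetitive"),
    4: ("onset-only", "onset-only"),
    5: ("repetitive", "onset-only"),
    6: ("repetitive", "onset-only"),
}


def local_boundary_gNa(
    model: CellModel,
    gK: float,
    gNa_max: float = 8.0,
    tol: float = 0.005,
    I_range: tuple[float, float] = I_RANGE_DEFAULT,
) -> float | None:
    """Tipping-boundary gbar_Na at fixed gbar_K, by bisection on the
    existence of a Hopf-bearing regime; None if no crossing below
    ``gNa_max``."""
    if not hopf_bearing(_set_na_k(model, gNa_max, gK), I_range):
        return None
    lo, hi = 0.0, gNa_max
    if hopf_bearing(_set_na_k(model, lo, gK), I_range):
        return 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if hopf_bearing(_set_na_k(model, mid, gK), I_range):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _classify(model: CellModel, classifier: str, **kwargs) -> ExcitabilityLabel:
    if classifier == "hopf":
        bearing = hopf_bearing(model, kwargs.get("I_range", I_RANGE_DEFAULT))
        return ExcitabilityLabel(
            pattern="repetitive" if bearing else "onset-only",
            spike_count=3 if bearing else 0,
        )
    return classify_excitability(model, **kwargs)


def run_prediction(
    model: CellModel,
    prediction_id: int,
    magnitudes: dict | None = None,
    classifier: str = "simulate",
    **classify_kwargs,
) -> PredictionOutcome:
    """Apply one of the six boundary-crossing manipulations and record
    whether the excitability transition matches the predicted direction.

    ``magnitudes`` overrides the default manipulation sizes:
    ``scale_K``/``scale_Na`` (multiplicative factors on the native added
    channels) and ``add_Na``/``add_K`` (virtual densities, mS/cm^2).
    Prediction 4 defaults to matched increments along the local tangent
    of the tipping boundary, which leave the classification unchanged.
    """
    if prediction_id not in _EXPECTED:
        raise ValueError("prediction_id must be 1..6")
    mag = dict(magnitudes or {})
    before, after_expected = _EXPECTED[prediction_id]
    label_before = _classify(model, classifier, **classify_kwargs)
    if label_before.pattern != before:
        raise PredictionStateError(
            f"prediction {prediction_id} starts from a {before} cell; "
            f"model classified as {label_before.pattern}"
        )

    m = model
    changed = True
    if prediction_id == 1:  # 4-AP-like: scale native K down
        f = mag.setdefault("scale_K", 0.5)
        m = m.scale_channel("K", f)
        changed = f != 1.0
        desc = f"scale native gK by {f}"
    elif prediction_id == 2:  # dynamic-clamp: add virtual Na
        g = mag.setdefault("add_Na", 1.5)
        m = m.with_channel(sodium_channel(g, label="virtual-Na"))
        changed = g > 0.0
        desc = f"add {g} mS/cm^2 virtual Na"
    elif prediction_id == 3:  # subthreshold combination of both
        f = mag.setdefault("scale_K", 0.8)
        g = mag.setdefault("add_Na", 0.8)
        m = m.scale_channel("K", f).with_channel(
            sodium_channel(g, label="virtual-Na")
        )
        changed = f != 1.0 or g > 0.0
        desc = f"scale native gK by {f} and add {g} mS/cm^2 virtual Na"
    elif prediction_id == 4:  # matched, offsetting increments
        if "add_K" not in mag or "add_Na" not in mag:
            gK0 = model.channel("K").gbar
            dK = mag.setdefault("add_K", 0.5)
            b0 = local_boundary_gNa(model, gK0)
            b1 = local_boundary_gNa(model, gK0 + dK)
            if b0 is None or b1 is None:
                raise RuntimeError("no local boundary found for tangent")
            mag.setdefault("add_Na", (b1 - b0))
        m = m.with_channel(sodium_channel(mag["add_Na"], label="virtual-Na"))
        m = m.with_channel(potassium_channel(mag["add_K"], label="virtual-K"))
        changed = mag["add_Na"] > 0.0 or mag["add_K"] > 0.0
        desc = (
            f"add matched {mag['add_Na']:.3f} mS/cm^2 Na and "
            f"{mag['add_K']:.3f} mS/cm^2 K along the boundary tangent"
        )
    elif prediction_id == 5:  # normalize by adding K
        g = mag.setdefault("add_K", 1.0)
        m = m.with_channel(potassium_channel(g, label="virtual-K"))
        changed = g > 0.0
        desc = f"add {g} mS/cm^2 virtual K"
    else:  # 6: riluzole-like: scale Na down
        f = mag.setdefault("scale_Na", 0.5)
        m = m.scale_channel("Na", f)
        changed = f != 1.0
        desc = f"scale native gNa by {f}"

    label_after = _classify(m, classifier, **classify_kwargs)
    # a no-op manipulation confirms nothing, even when the (unchanged)
    # classification happens to match the expected direction
    confirmed = changed and label_after.pattern == after_expected
    return PredictionOutcome(
        prediction_id=prediction_id,
        manipulation=desc,
        label_before=label_before,
        label_after=label_after,
        confirmed=confirmed,
        parameters={"magnitudes": mag, "model": model.to_dict()},
    )


def run_all_predictions(
    normal_model: CellModel,
    neuropathic_model: CellModel,
    classifier: str = "simulate",
    **classify_kwargs,
) -> list[PredictionOutcome]:
    """The full six-arrow prediction table in one scripted run."""
    out = []
    for pid in (1, 2, 3, 4):
        out.append(
            run_prediction(normal_model, pid, classifier=classifier, **classify_kwargs)
        )
    for pid in (5, 6):
        out.append(
            run_prediction(
                neuropathic_model, pid, classifier=classifier, **classify_kwargs
            )
        )
    return out


def measure_subthreshold_K_density(
    model: CellModel,
    clamp_voltages,
    channel_label: str = "K",
) -> np.ndarray:
    """Steady-state added-K current density (pA/pF) at clamp voltages.

    Emulates a voltage-clamp measurement of the persistent subthreshold
    outward current carried by the added K channel alone (the analog of
    a dendrotoxin-sensitive difference current): density =
    gbar_K * m_inf(V) * (V - E_K) / C.
    """
    V = np.asarray(clamp_voltages, dtype=np.float64)
    if V.size == 0:
        raise ValueError("clamp voltage list must be non-empty")
    if np.any(V <= model.core.E_K) or np.any(V >= 0.0):
        raise ValueError("clamp voltages must lie in (E_K, 0)")
    ch = model.channel(channel_label)
    m_inf = np.array([gate_kinetics(v, ch.gate).m_inf for v in V])
    return ch.gbar * m_inf * (V - ch.E_rev) / model.core.C


_UNIT_ALIASES = {
    "ns/pf": "nS/pF",
    "ms/cm2": "mS/cm2",
    "ms/cm^2": "mS/cm2",
}


def density_conversion(value: float, from_unit: str, C_spec: float = 1.0) -> float:
    """Convert a conductance density between nS/pF and mS/cm^2.

    With specific membrane capacitance ``C_spec`` (uF/cm^2):
    g[mS/cm^2] = g[nS/pF] * C_spec, exactly; 1 nS/pF corresponds to
    1 mS/cm^2 at C_spec = 1.
    """
    if C_spec <= 0:
        raise ValueError("C_spec must be positive")
    unit = _UNIT_ALIASES.get(from_unit.strip().lower())
    if unit == "nS/pF":
        return value * C_spec
    if unit == "mS/cm2":
        return value / C_spec
    raise ValueError(f"unknown unit {from_unit!r}")


@dataclass
class PassiveProperties:
    """Passive membrane properties from a small hyperpolarizing step."""

    R_in: float  # kOhm cm^2  (= mV per uA/cm^2)
    tau_m: float  # ms
    C: float  # uF/cm^2, = tau_m / R_in
    linear: bool  # response scaled linearly with a half-amplitude step


def _step_response(model: CellModel, amplitude: float, I_hold: float):
    proto = StimulusProtocol.step(
        amplitude, onset=50.0, duration=300.0, tail=150.0, I_hold=I_hold,
        dt=0.02, record_dt=0.05,
    )
    rest = relax_to_rest(model, I_hold)
    tr = integrate(model.with_noise(None), proto, initial_state=rest)
    return tr, rest.V


def measure_passive(
    model: CellModel,
    amplitude: float = -1.0,
    I_hold: float = 0.0,
    linearity_rtol: float = 0.05,
) -> PassiveProperties:
    """Input resistance, membrane time constant and derived capacitance.

    Applies a small hyperpolarizing current step, reads R_in from the
    steady-state voltage deflection, fits a single exponential to the
    charging transient for tau_m, and reports C = tau_m / R_in.  A
    half-amplitude control step checks that the response is linear; a
    nonlinear response is flagged, not raised.
    """
    if amplitude >= 0:
        raise ValueError("passive measurement uses a hyperpolarizing step")
    tr, V_rest = _step_response(model, amplitude, I_hold)
    on, off = 50.0, 350.0
    ss = tr.window(off - 50.0, off)
    dV_ss = float(np.mean(ss.V)) - V_rest
    R_in = dV_ss / amplitude  # mV per uA/cm^2 = kOhm cm^2

    seg = tr.window(on, off)
    t = seg.t - on

    def charging(t, tau):
        return V_rest + dV_ss * (1.0 - np.exp(-t / tau))

    tau0 = model.core.C * R_in
    (tau_m,), _ = curve_fit(charging, t, seg.V, p0=[tau0], maxfev=10000)
    tau_m = float(tau_m)

    tr2, _ = _step_response(model, amplitude / 2.0, I_hold)
    dV2 = float(np.mean(tr2.window(off - 50.0, off).V)) - V_rest
    linear = abs(2.0 * dV2 - dV_ss) <= linearity_rtol * abs(dV_ss)
    return PassiveProperties(R_in=R_in, tau_m=tau_m, C=tau_m / R_in, linear=linear)


def spike_threshold_voltage(
    model: CellModel,
    dVdt_criterion: float = 5.0,
    amp_tol: float = 0.1,
    I_max: float = 200.0,
    duration: float = 500.0,
    dt: float = 0.01,
) -> float:
    """Spike-initiation voltage of a just-suprathreshold step response.

    Bisects the step amplitude to the minimal spiking current (within
    ``amp_tol``), then reads the membrane potential at which the
    depolarization rate falls to ``dVdt_criterion`` mV/ms: the point
    where the stimulus-driven charging hands off to the intrinsic
    threshold crawl that initiates the spike.  (The upward dV/dt
    crossing is unusable under step stimulation because the stimulus
    onset itself exceeds the criterion.)
    """
    rest = relax_to_rest(model, 0.0)

    def trace_at(amp: float) -> Trace:
        proto = StimulusProtocol.step(
            amp, onset=50.0, duration=duration, tail=50.0, dt=dt, record_dt=dt
        )
        return integrate(model.with_noise(None), proto, initial_state=rest)

    lo, hi = 0.0, I_max
    if len(detect_spikes(trace_at(hi))) == 0:
        raise RuntimeError(f"no spike up to {I_max} uA/cm^2")
    while hi - lo > amp_tol:
        mid = 0.5 * (lo + hi)
        if len(detect_spikes(trace_at(mid))) >= 1:
            hi = mid
        else:
            lo = mid
    tr = trace_at(hi)
    dVdt = np.gradient(tr.V, tr.t)
    peak = int(np.argmax(tr.V))
    onset = int(np.searchsorted(tr.t, 50.0 + 1.0))  # skip the onset transient edge
    below = np.nonzero(dVdt[onset:peak] < dVdt_criterion)[0]
    if len(below) == 0:
        raise RuntimeError("depolarization never decelerates below the criterion")
    return float(tr.V[onset + below[0]])
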