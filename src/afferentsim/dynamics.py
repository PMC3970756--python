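"""Nonlinear-dynamics engine: equilibria, stability, bifurcation scans.

The resting state of the model is an equilibrium of the full system;
because every gate relaxes monotonically to its voltage-dependent steady
state, equilibria correspond one-to-one with roots of the scalar
stationary current balance I_stim = I_ss(V).  Stability comes from the
eigenvalues of the Jacobian at the equilibrium.  Repetitive spiking
becomes possible when the equilibrium destabilizes through a subcritical
Hopf bifurcation at a critical stimulus I*; between the saddle-node of
limit cycles (SNLC) and I* the system is bistable (quiescence and
repetitive spiking coexist), which is the substrate for hysteresis-driven
bursting.  Instead of numerical continuation, Hopf points are located by
bisection on the leading eigenvalue's real part along the equilibrium
branch, and limit cycles / bistability are established by direct
simulation — adequate for this planar-plus system and independently
testable against brute-force simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .model_core import CellModel, State, steady_state
from .simulate import StimulusProtocol, integrate

__all__ = [
    "Equilibrium",
    "BifurcationDiagram1D",
    "TippingMap",
    "find_equilibria",
    "find_hopf",
    "hopf_bearing",
    "scan_Istim",
    "tipping_map",
    "apply_context",
    "stationary_current_curve",
]

#: default stimulus range scanned for bifurcations (uA/cm^2).  The cap
#: sits below the stimulus (~74 uA/cm^2) at which the bare ML core's own
#: equilibrium destabilizes, so regime classification reflects the
#: added-conductance tipping point rather than the core's high-stimulus
#: instability; within this range the base cell and the normal reference
#: cell are onset-only while the neuropathic reference cell is
#: Hopf-bearing.
I_RANGE_DEFAULT = (0.0, 70.0)
#: bisection tolerance on the Hopf stimulus (uA/cm^2)
I_STAR_TOL = 0.01


@dataclass
class Equilibrium:
    """A fixed point of the noise-free model at a given stimulus."""

    state: State
    I_stim: float
    eigenvalues: np.ndarray
    stability: str  # stable-focus|stable-node|unstable-focus|unstable-node|saddle

    @property
    def is_stable(self) -> bool:
        return self.stability.startswith("stable")

    @property
    def V(self) -> float:
        return self.state.V


@dataclass
class BifurcationDiagram1D:
    """Equilibrium branch and limit-cycle extent versus stimulus current."""

    I_samples: np.ndarray
    V_eq: np.ndarray  # equilibrium V* per sample (NaN where absent)
    eq_stable: np.ndarray  # bool per sample
    hopf_I_star: float | None = None
    hopf_type: str = "absent"  # subcritical | supercritical | absent
    bistable_interval: tuple[float, float] | None = None  # (I_SNLC, I*)
    lc_I: np.ndarray = field(default_factory=lambda: np.empty(0))
    lc_V_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    lc_V_max: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.hopf_I_star is None and self.bistable_interval is not None:
            raise ValueError("bistable interval requires a Hopf point")
        if self.bistable_interval is not None:
            lo, hi = self.bistable_interval
            if lo > hi + 1e-12:
                raise ValueError("I_SNLC must not exceed I*")

    @property
    def has_hopf(self) -> bool:
        return self.hopf_I_star is not None


@dataclass
class TippingMap:
    """Two-parameter map of (gbar_Na, gbar_K) into excitability regimes.

    ``I_star[i, j]`` is the Hopf stimulus for gK_grid[i], gNa_grid[j]
    (NaN where no Hopf exists in the scanned range, i.e. no repetitive
    spiking).  ``boundary`` holds, per gK row, the interpolated gbar_Na
    at which the Hopf-bearing regime begins (NaN if the row never
    crosses).
    """

    gNa_grid: np.ndarray
    gK_grid: np.ndarray
    I_star: np.ndarray  # shape (len(gK_grid), len(gNa_grid))
    boundary: np.ndarray  # shape (len(gK_grid),)
    context: dict = field(default_factory=dict)

    @property
    def hopf_bearing(self) -> np.ndarray:
        return np.isfinite(self.I_star)

    def check_boundary_monotone(self) -> bool:
        b = self.boundary[np.isfinite(self.boundary)]
        return bool(np.all(np.diff(b) >= -1e-9))


# ---------------------------------------------------------------------------
# equilibria and eigenvalues
# ---------------------------------------------------------------------------


def stationary_current_curve(model: CellModel, V: np.ndarray) -> np.ndarray:
    """Vectorized net membrane current with all gates at steady state."""
    V = np.asarray(V, dtype=np.float64)
    c = model.core
    m_inf = 0.5 * (1.0 + np.tanh((V - c.beta_m) / c.gamma_m))
    w_inf = 0.5 * (1.0 + np.tanh((V - c.beta_w) / c.gamma_w))
    I = (
        c.gbar_fast * m_inf * (V - c.E_Na)
        + c.gbar_slow * w_inf * (V - c.E_K)
        + c.g_leak * (V - c.E_leak)
    )
    for ch in model.channels:
        g = ch.gate
        x = np.atleast_1d((V - g.V_alpha) / g.s_alpha)
        lin = np.empty_like(x)
        small = np.abs(x) < 1e-4
        lin[small] = 1.0 - 0.5 * x[small] + x[small] ** 2 / 12.0
        lin[~small] = x[~small] / np.expm1(x[~small])
        alpha = g.k_alpha * lin
        beta = g.k_beta * np.exp((V - g.V_beta) / g.s_beta)
        I += ch.gbar * (alpha / (alpha + beta)) * (V - ch.E_rev)
    if model.ahp is not None:
        a = model.ahp
        z_inf = 1.0 / (1.0 + np.exp((a.beta_z - V) / a.gamma_z))
        I += a.gbar * z_inf * (V - c.E_K)
    return I


def _jacobian(model: CellModel, y: np.ndarray, I_stim: float) -> np.ndarray:
    """Central finite-difference Jacobian of the packed right-hand side."""
    core, chan, ahp = model._packed()
    dim = len(y)
    J = np.empty((dim, dim))
    d1 = np.empty(dim)
    d2 = np.empty(dim)
    for j in range(dim):
        eps = 1e-6 * max(1.0, abs(y[j]))
        yp = y.copy()
        ym = y.copy()
        yp[j] += eps
        ym[j] -= eps
        _kernels.rhs_vec(yp, I_stim, core, chan, ahp, d1)
        _kernels.rhs_vec(ym, I_stim, core, chan, ahp, d2)
        J[:, j] = (d1 - d2) / (2.0 * eps)
    return J


def _classify_eigenvalues(eig: np.ndarray) -> str:
    re = eig.real
    complex_pair = np.any(np.abs(eig.imag) > 1e-9)
    if np.all(re < 0):
        return "stable-focus" if complex_pair else "stable-node"
    if not complex_pair and np.any(re > 0) and np.any(re < 0):
        return "saddle"
    return "unstable-focus" if complex_pair else "unstable-node"


def _eigenvalues_at(model: CellModel, V: float, I_stim: float) -> np.ndarray:
    """Eigenvalues of the Jacobian at the steady state with potential V."""
    y = steady_state(model, V).to_vector()
    return np.linalg.eigvals(_jacobian(model, y, I_stim))


def find_equilibria(
    model: CellModel,
    I_stim: float,
    V_range: tuple[float, float] = (-90.0, 0.0),
    resolution: float = 0.1,
) -> list[Equilibrium]:
    """All equilibria with V in ``V_range`` at a fixed stimulus current.

    Roots of the stationary current balance are bracketed by a dense
    scan at ``resolution`` mV and polished with Brent's method; each is
    returned with Jacobian eigenvalues and a stability label.  An empty
    list (no root in range) is not an error.
    """
    V = np.arange(V_range[0], V_range[1] + resolution / 2, resolution)
    f = I_stim - stationary_current_curve(model, V)
    roots: list[float] = []
    for i in np.nonzero(f[:-1] * f[1:] <= 0)[0]:
        if f[i] == 0.0 and (not roots or abs(V[i] - roots[-1]) > resolution):
            roots.append(float(V[i]))
        elif f[i] * f[i + 1] < 0:
            r = brentq(
                lambda v: I_stim - float(stationary_current_curve(model, np.array([v]))[0]),
                V[i],
                V[i + 1],
                xtol=1e-10,
            )
            roots.append(float(r))
    out = []
    for V_star in roots:
        s = steady_state(model, V_star)
        eig = np.linalg.eigvals(_jacobian(model, s.to_vector(), I_stim))
        out.append(
            Equilibrium(
                state=s,
                I_stim=I_stim,
                eigenvalues=eig,
                stability=_classify_eigenvalues(eig),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Hopf detection along the equilibrium branch
# ---------------------------------------------------------------------------


def _branch_arrays(
    model: CellModel, Vs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(I_ss, leading real part, oscillatory flag) along the branch.

    The branch is parametrized by V: the stimulus that makes V an
    equilibrium is I_ss(V), so each V indexes one equilibrium.
    """
    core, chan, ahp = model._packed()
    Vs = np.ascontiguousarray(Vs, dtype=np.float64)
    I_out = np.empty(len(Vs))
    re_out = np.empty(len(Vs))
    osc_out = np.empty(len(Vs))
    _kernels.branch_scan_kernel(Vs, core, chan, ahp, I_out, re_out, osc_out)
    return I_out, re_out, osc_out


def _branch_max_real(model: CellModel, V: float) -> float:
    _, re, _ = _branch_arrays(model, np.array([V]))
    return float(re[0])


def _branch_scan(
    model: CellModel,
    I_range: tuple[float, float],
    V_scan: tuple[float, float, float],
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(V, I, leading real part) along the branch, restricted to I_range."""
    lo, hi = I_range
    Vs = np.arange(*V_scan)
    I_of_V, re, _ = _branch_arrays(model, Vs)
    in_range = (I_of_V >= lo - tol) & (I_of_V <= hi + tol)
    idx = np.nonzero(in_range)[0]
    return Vs[idx], I_of_V[idx], re[idx]


def find_hopf(
    model: CellModel,
    I_range: tuple[float, float] = I_RANGE_DEFAULT,
    V_scan: tuple[float, float, float] = (-80.0, -5.0, 0.25),
    tol: float = I_STAR_TOL,
) -> float | None:
    """Hopf stimulus I* in ``I_range``, or None if the branch never
    destabilizes through a complex pair within the range.

    Scans the equilibrium branch parametrized by V, looks for a sign
    change of the leading real part, bisects it, and verifies that the
    destabilizing eigenvalues are a complex-conjugate pair.  A model
    whose equilibrium is already unstable at the bottom of ``I_range``
    (its Hopf lies below the range) yields None here; use
    :func:`hopf_bearing` for regime classification.
    """
    lo, hi = I_range
    Vb, Ib, re = _branch_scan(model, I_range, V_scan, tol)
    if len(Vb) == 0:
        return None
    sign_change = np.nonzero((re[:-1] < 0) & (re[1:] >= 0))[0]
    if len(sign_change) == 0:
        return None
    k = sign_change[0]
    V_lo, V_hi = Vb[k], Vb[k + 1]
    # bisect on V until the I interval is tighter than tol
    for _ in range(80):
        V_mid = 0.5 * (V_lo + V_hi)
        if _branch_max_real(model, V_mid) < 0:
            V_lo = V_mid
        else:
            V_hi = V_mid
        I_lo = float(stationary_current_curve(model, np.array([V_lo]))[0])
        I_hi = float(stationary_current_curve(model, np.array([V_hi]))[0])
        if abs(I_hi - I_lo) < tol:
            break
    V_star = 0.5 * (V_lo + V_hi)
    I_star = float(stationary_current_curve(model, np.array([V_star]))[0])
    if not (lo - tol <= I_star <= hi + tol):
        return None
    eig = _eigenvalues_at(model, V_star, I_star)
    leading = eig[np.argsort(eig.real)[::-1]]
    if abs(leading[0].imag) < 1e-9:  # destabilization is not oscillatory
        return None
    return I_star


def hopf_bearing(
    model: CellModel,
    I_range: tuple[float, float] = I_RANGE_DEFAULT,
    V_scan: tuple[float, float, float] = (-80.0, -5.0, 0.25),
    tol: float = I_STAR_TOL,
) -> bool:
    """Is repetitive spiking dynamically possible within ``I_range``?

    True iff the equilibrium branch either crosses a Hopf bifurcation
    inside the range or is already unstable at some in-range stimulus
    (its Hopf lies below the bottom of the range).
    """
    _, _, re = _branch_scan(model, I_range, V_scan, tol)
    return len(re) > 0 and bool(np.any(re >= 0))


# ---------------------------------------------------------------------------
# one-parameter bifurcation diagram
# ---------------------------------------------------------------------------


def _spiking_seed_state(model: CellModel, I_seed: float) -> State:
    """A state on (or near) the spiking attractor at stimulus I_seed."""
    eqs = find_equilibria(model, I_seed)
    V0 = eqs[0].V if eqs else -60.0
    s0 = steady_state(model, min(V0 + 25.0, -5.0))
    proto = StimulusProtocol(T_total=500.0, dt=0.02, I_hold=I_seed, record_dt=1.0)
    tr = integrate(model.with_noise(None), proto, initial_state=s0)
    return tr.final_state()


def _spiking_persists(
    model: CellModel, I_stim: float, seed_state: State, T: float = 1200.0
) -> bool:
    """Does a sustained-spiking attractor exist at I_stim?

    Simulates from a spiking seed state and requires >= 3 spikes in the
    final half of the run.
    """
    from .classify import detect_spikes

    proto = StimulusProtocol(T_total=T, dt=0.02, I_hold=I_stim, record_dt=0.05)
    tr = integrate(model.with_noise(None), proto, initial_state=seed_state)
    spikes = detect_spikes(tr)
    return int(np.sum(spikes >= T / 2.0)) >= 3


def scan_Istim(
    model: CellModel,
    I_range: tuple[float, float] = I_RANGE_DEFAULT,
    n_samples: int = 81,
    simulate_cycles: bool = True,
    snlc_tol: float = 0.05,
) -> BifurcationDiagram1D:
    """One-parameter bifurcation diagram of the noise-free model in I_stim.

    Locates the Hopf point by eigenvalue bisection, establishes
    subcriticality by demonstrating coexistence of the spiking attractor
    with the stable equilibrium just below I*, bisects the lower edge of
    the bistable window (SNLC), and measures limit-cycle V extrema from
    post-transient simulation.
    """
    model = model.with_noise(None)
    lo, hi = I_range
    I_samples = np.linspace(lo, hi, n_samples)
    V_eq = np.full(n_samples, np.nan)
    eq_stable = np.zeros(n_samples, dtype=bool)
    prev_V: float | None = None
    for i, I in enumerate(I_samples):
        eqs = find_equilibria(model, I)
        if not eqs:
            prev_V = None
            continue
        if prev_V is None:
            eq = eqs[0]
        else:
            eq = min(eqs, key=lambda e: abs(e.V - prev_V))
        V_eq[i] = eq.V
        eq_stable[i] = eq.is_stable
        prev_V = eq.V

    I_star = find_hopf(model, I_range)
    if I_star is None:
        return BifurcationDiagram1D(I_samples, V_eq, eq_stable)

    hopf_type = "supercritical"
    bistable: tuple[float, float] | None = None
    lc_I = np.empty(0)
    lc_Vmin = np.empty(0)
    lc_Vmax = np.empty(0)
    if simulate_cycles:
        I_seed = min(I_star + max(2.0, 0.05 * (hi - I_star)), hi)
        seed_state = _spiking_seed_state(model, I_seed)
        I_probe = max(I_star - 10.0 * I_STAR_TOL, lo)
        eqs_below = find_equilibria(model, I_probe)
        stable_below = any(e.is_stable for e in eqs_below)
        if stable_below and _spiking_persists(model, I_probe, seed_state):
            hopf_type = "subcritical"
            # bisect the SNLC: largest I at which spiking does not persist
            I_lo_b, I_hi_b = lo, I_probe
            if _spiking_persists(model, I_lo_b, seed_state):
                bistable = (lo, I_star)
            else:
                while I_hi_b - I_lo_b > snlc_tol:
                    mid = 0.5 * (I_lo_b + I_hi_b)
                    if _spiking_persists(model, mid, seed_state):
                        I_hi_b = mid
                    else:
                        I_lo_b = mid
                bistable = (0.5 * (I_lo_b + I_hi_b), I_star)
        # limit-cycle extrema on samples inside the spiking regime
        from .classify import detect_spikes

        lc_lo = bistable[0] if bistable is not None else I_star
        sel = I_samples[I_samples >= lc_lo - 1e-9]
        vals = []
        for I in sel:
            proto = StimulusProtocol(T_total=1000.0, dt=0.02, I_hold=I, record_dt=0.05)
            tr = integrate(model, proto, initial_state=seed_state)
            tail = tr.window(500.0, 1000.0)
            if int(np.sum(detect_spikes(tr) >= 500.0)) >= 3:
                vals.append((I, float(tail.V.min()), float(tail.V.max())))
        if vals:
            lc_I, lc_Vmin, lc_Vmax = (np.array(v) for v in zip(*vals))

    return BifurcationDiagram1D(
        I_samples=I_samples,
        V_eq=V_eq,
        eq_stable=eq_stable,
        hopf_I_star=I_star,
        hopf_type=hopf_type,
        bistable_interval=bistable,
        lc_I=lc_I,
        lc_V_min=lc_Vmin,
        lc_V_max=lc_Vmax,
    )


# ---------------------------------------------------------------------------
# two-parameter tipping map
# ---------------------------------------------------------------------------


def apply_context(
    model: CellModel,
    g_leak: float | None = None,
    activation_shift: float | None = None,
    E_K: float | None = None,
) -> CellModel:
    """Apply contextual parameter overrides that move the tipping point.

    ``g_leak`` replaces the leak conductance; ``activation_shift``
    shifts the voltage dependence of every added channel by the given
    mV; ``E_K`` replaces the potassium reversal potential everywhere it
    appears (ML slow current, AHP, and K-like added channels).
    """
    core = model.core
    channels = model.channels
    if g_leak is not None:
        core = replace(core, g_leak=g_leak)
    if E_K is not None:
        old_EK = model.core.E_K
        core = replace(core, E_K=E_K)
        channels = tuple(
            replace(ch, E_rev=E_K) if ch.E_rev == old_EK else ch for ch in channels
        )
    if activation_shift is not None:
        channels = tuple(
            replace(ch, gate=ch.gate.shifted(activation_shift)) for ch in channels
        )
    return replace(model, core=core, channels=channels)


def _set_na_k(model: CellModel, gNa: float, gK: float) -> CellModel:
    from .model_core import potassium_channel, sodium_channel

    labels = {ch.label for ch in model.channels}
    m = model
    if "Na" not in labels:
        m = m.with_channel(sodium_channel(0.0))
    if "K" not in labels:
        m = m.with_channel(potassium_channel(0.0))
    channels = tuple(
        replace(ch, gbar=gNa if ch.label == "Na" else gK)
        if ch.label in ("Na", "K")
        else ch
        for ch in m.channels
    )
    return replace(m, channels=channels)


def tipping_map(
    model_template: CellModel,
    gNa_grid: Sequence[float],
    gK_grid: Sequence[float],
    I_range: tuple[float, float] = I_RANGE_DEFAULT,
    context_overrides: dict | None = None,
    refine_boundary: bool = False,
    boundary_tol: float = 0.01,
) -> TippingMap:
    """Classify a (gbar_Na, gbar_K) grid into excitability regimes.

    Each cell is Hopf-bearing (repetitive spiking possible for some
    I_stim in ``I_range``) or not; the tipping boundary is the gbar_Na at
    which each gK row first becomes Hopf-bearing (linear mid-point
    interpolation between grid columns, or bisection to ``boundary_tol``
    when ``refine_boundary`` is set).
    """
    gNa_grid = np.asarray(gNa_grid, dtype=np.float64)
    gK_grid = np.asarray(gK_grid, dtype=np.float64)
    if gNa_grid.size == 0 or gK_grid.size == 0:
        raise ValueError("conductance grids must be non-empty")
    if np.any(np.diff(gNa_grid) <= 0) or np.any(np.diff(gK_grid) <= 0):
        raise ValueError("conductance grids must be sorted ascending")
    context = dict(context_overrides or {})
    # ensure the Na/K channels exist before applying context so that an
    # activation-voltage shift reaches them
    template = apply_context(
        _set_na_k(model_template.with_noise(None), 0.0, 0.0), **context
    )

    I_star = np.full((gK_grid.size, gNa_grid.size), np.nan)
    for i, gK in enumerate(gK_grid):
        for j, gNa in enumerate(gNa_grid):
            m = _set_na_k(template, gNa, gK)
            res = find_hopf(m, I_range)
            if res is not None:
                I_star[i, j] = res
            elif hopf_bearing(m, I_range):
                # Hopf lies below the scanned range: spiking from the start
                I_star[i, j] = I_range[0]

    boundary = np.full(gK_grid.size, np.nan)
    bearing = np.isfinite(I_star)
    for i in range(gK_grid.size):
        row = bearing[i]
        if row.all():
            boundary[i] = gNa_grid[0]
            continue
        if not row.any():
            continue
        j = int(np.argmax(row))  # first Hopf-bearing column
        if refine_boundary and j > 0:
            lo, hi = gNa_grid[j - 1], gNa_grid[j]
            while hi - lo > boundary_tol:
                mid = 0.5 * (lo + hi)
                if hopf_bearing(_set_na_k(template, mid, gK_grid[i]), I_range):
                    hi = mid
                else:
                    lo = mid
            boundary[i] = 0.5 * (lo + hi)
        elif j > 0:
            boundary[i] = 0.5 * (gNa_grid[j - 1] + gNa_grid[j])
        else:
            boundary[i] = gNa_grid[0]
    return TippingMap(
        gNa_grid=gNa_grid,
        gK_grid=gK_grid,
        I_star=I_star,
        boundary=boundary,
        context=context,
    )
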