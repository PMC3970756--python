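"""Numba-compiled numerical kernels for the membrane model.

The state vector is packed as [V, w, m_0..m_{n-1}, z].  Parameters are
passed as flat float64 arrays (see ``CellModel._packed``):

    core: C, E_Na, E_K, E_leak, phi_w, gbar_fast, gbar_slow, g_leak,
          beta_m, gamma_m, beta_w, gamma_w
    chan: one row per channel: k_a, V_a, s_a, k_b, V_b, s_b, gbar, E_rev
    ahp:  gbar_AHP, beta_z, gamma_z, tau_z       (E_rev of the AHP = E_K)

Deterministic integration uses classic fixed-step RK4; stochastic
integration uses Euler-Maruyama with the noise current supplied per step
(already scaled for dt by the caller).
"""

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _linoid(x):
    if abs(x) < 1e-4:
        return 1.0 - 0.5 * x + x * x / 12.0
    return x / math.expm1(x)


@njit(cache=True)
def rhs_vec(y, I_stim, core, chan, ahp, dy):
    """In-place evaluation of the deterministic right-hand side."""
    V = y[0]
    w = y[1]
    C = core[0]
    E_Na = core[1]
    E_K = core[2]
    E_leak = core[3]
    phi_w = core[4]
    gbar_fast = core[5]
    gbar_slow = core[6]
    g_leak = core[7]
    beta_m = core[8]
    gamma_m = core[9]
    beta_w = core[10]
    gamma_w = core[11]

    m_inf = 0.5 * (1.0 + math.tanh((V - beta_m) / gamma_m))
    w_inf = 0.5 * (1.0 + math.tanh((V - beta_w) / gamma_w))
    inv_tau_w = math.cosh((V - beta_w) / (2.0 * gamma_w))

    I_total = (
        gbar_fast * m_inf * (V - E_Na)
        + gbar_slow * w * (V - E_K)
        + g_leak * (V - E_leak)
    )

    n = chan.shape[0]
    for i in range(n):
        k_a = chan[i, 0]
        V_a = chan[i, 1]
        s_a = chan[i, 2]
        k_b = chan[i, 3]
        V_b = chan[i, 4]
        s_b = chan[i, 5]
        gbar = chan[i, 6]
        E_rev = chan[i, 7]
        m = y[2 + i]
        alpha = k_a * _linoid((V - V_a) / s_a)
        beta = k_b * math.exp((V - V_b) / s_b)
        I_total += gbar * m * (V - E_rev)
        dy[2 + i] = alpha * (1.0 - m) - beta * m

    z = y[2 + n]
    g_ahp = ahp[0]
    beta_z = ahp[1]
    gamma_z = ahp[2]
    tau_z = ahp[3]
    I_total += g_ahp * z * (V - E_K)
    z_inf = 1.0 / (1.0 + math.exp((beta_z - V) / gamma_z))
    dy[2 + n] = (z_inf - z) / tau_z

    dy[0] = (I_stim - I_total) / C
    dy[1] = phi_w * (w_inf - w) * inv_tau_w
    return dy


@njit(cache=True)
def integrate_rk4(y0, dt, I_app, core, chan, ahp, stride, out):
    """Fixed-step RK4 over len(I_app) steps; record every ``stride`` steps.

    ``out`` must have shape (1 + n_steps//stride, len(y0)).  The applied
    current is held constant within each step.  Returns the step index
    at which the state first became non-finite, or -1 on success.
    """
    dim = y0.shape[0]
    n_steps = I_app.shape[0]
    y = y0.copy()
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    tmp = np.empty(dim)
    out[0] = y
    rec = 1
    for step in range(n_steps):
        I = I_app[step]
        rhs_vec(y, I, core, chan, ahp, k1)
        for j in range(dim):
            tmp[j] = y[j] + 0.5 * dt * k1[j]
        rhs_vec(tmp, I, core, chan, ahp, k2)
        for j in range(dim):
            tmp[j] = y[j] + 0.5 * dt * k2[j]
        rhs_vec(tmp, I, core, chan, ahp, k3)
        for j in range(dim):
            tmp[j] = y[j] + dt * k3[j]
        rhs_vec(tmp, I, core, chan, ahp, k4)
        ok = True
        for j in range(dim):
            y[j] = y[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if not math.isfinite(y[j]):
                ok = False
        # clip gating variables against integration overshoot
        for j in range(1, dim):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        if not ok:
            return step
        if (step + 1) % stride == 0:
            out[rec] = y
            rec += 1
    return -1


@njit(cache=True)
def steady_state_vec(V, core, chan, ahp, y):
    """Fill ``y`` with the state where every gate sits at its V-dependent
    steady state."""
    n = chan.shape[0]
    y[0] = V
    y[1] = 0.5 * (1.0 + math.tanh((V - core[10]) / core[11]))  # w_inf
    for i in range(n):
        alpha = chan[i, 0] * _linoid((V - chan[i, 1]) / chan[i, 2])
        beta = chan[i, 3] * math.exp((V - chan[i, 4]) / chan[i, 5])
        y[2 + i] = alpha / (alpha + beta)
    y[2 + n] = 1.0 / (1.0 + math.exp((ahp[1] - V) / ahp[2]))  # z_inf


@njit(cache=True)
def branch_scan_kernel(Vs, core, chan, ahp, I_out, re_out, osc_out):
    """Equilibrium-branch scan parametrized by V.

    For each V: the stimulus making V an equilibrium (I_ss), the leading
    real part of the finite-difference Jacobian eigenvalues there, and
    whether the leading eigenvalue belongs to a complex pair.
    """
    dim = 2 + chan.shape[0] + 1
    y = np.empty(dim)
    d0 = np.empty(dim)
    d1 = np.empty(dim)
    d2 = np.empty(dim)
    # complex dtype: eigenvalues of the (real) Jacobian come in complex pairs
    J = np.empty((dim, dim), dtype=np.complex128)
    for k in range(Vs.shape[0]):
        V = Vs[k]
        steady_state_vec(V, core, chan, ahp, y)
        # stimulus balancing the net current: dV/dt = (I - I_total)/C = 0
        rhs_vec(y, 0.0, core, chan, ahp, d0)
        I_ss = -d0[0] * core[0]
        I_out[k] = I_ss
        for j in range(dim):
            eps = 1e-6 * max(1.0, abs(y[j]))
            tmp = y[j]
            y[j] = tmp + eps
            rhs_vec(y, I_ss, core, chan, ahp, d1)
            y[j] = tmp - eps
            rhs_vec(y, I_ss, core, chan, ahp, d2)
            y[j] = tmp
            for r in range(dim):
                J[r, j] = complex((d1[r] - d2[r]) / (2.0 * eps), 0.0)
        eig = np.linalg.eigvals(J)
        best = 0
        for r in range(1, dim):
            if eig[r].real > eig[best].real:
                best = r
        re_out[k] = eig[best].real
        osc_out[k] = 1.0 if abs(eig[best].imag) > 1e-9 else 0.0


@njit(cache=True)
def integrate_em(y0, dt, I_app, I_noise, core, chan, ahp, stride, out):
    """Euler-Maruyama with a per-step noise current added to the stimulus.

    ``I_noise`` holds the pre-drawn, pre-scaled noise current for each
    step.  Recording and the return convention match ``integrate_rk4``.
    """
    dim = y0.shape[0]
    n_steps = I_app.shape[0]
    y = y0.copy()
    dy = np.empty(dim)
    out[0] = y
    rec = 1
    for step in range(n_steps):
        I = I_app[step] + I_noise[step]
        rhs_vec(y, I, core, chan, ahp, dy)
        ok = True
        for j in range(dim):
            y[j] = y[j] + dt * dy[j]
            if not math.isfinite(y[j]):
                ok = False
        for j in range(1, dim):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        if not ok:
            return step
        if (step + 1) % stride == 0:
            out[rec] = y
            rec += 1
    return -1
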