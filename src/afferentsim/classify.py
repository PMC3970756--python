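"""Phenotype classification of model cells and distance-to-tipping titration.

The qualitative phenotypes of interest form the triad seen in
hyperexcitable afferents: repetitive spiking during sustained
stimulation (defined as at least three spikes during the step),
subthreshold membrane-potential oscillations (MPOs, a noise-driven
spectral peak that appears when the resting equilibrium approaches a
Hopf bifurcation), and bursting (which requires both bistability and a
slow adaptation current).  Cells that are not repetitively spiking can
still be ranked by how close they sit to the tipping point, measured as
the minimal virtual conductance that must be added (or removed) to flip
their classification — the in-silico analog of a dynamic-clamp
titration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .model_core import CellModel, potassium_channel, sodium_channel
from .simulate import StimulusProtocol, Trace, integrate, relax_to_rest

__all__ = [
    "MPOResult",
    "BurstResult",
    "ExcitabilityLabel",
    "TitrationResult",
    "detect_spikes",
    "classify_excitability",
    "detect_mpo",
    "detect_bursts",
    "titrate_to_tipping",
]

#: spike criterion: upward crossing of this voltage (mV) ...
SPIKE_THRESHOLD = 0.0
#: ... with this refractory gap between detections (ms)
SPIKE_REFRACTORY = 2.0
#: repetitive spiking requires at least this many spikes during the step
REPETITIVE_MIN_SPIKES = 3
#: default rheobase multiples tested by the classification ladder
LADDER_DEFAULT = (1.0, 1.5, 2.0, 3.0)
#: MPO detection: spectral peak must exceed the smoothed background by
#: this factor, at or above this frequency (Hz)
MPO_RATIO_THRESHOLD = 3.0
MPO_MIN_FREQ = 5.0


class InsufficientDataError(ValueError):
    """The trace segment is too short for the requested analysis."""


def detect_spikes(
    trace: Trace,
    threshold: float = SPIKE_THRESHOLD,
    refractory: float = SPIKE_REFRACTORY,
) -> np.ndarray:
    """Spike times (ms): upward threshold crossings with a refractory gap."""
    if trace.dt > 0.1 + 1e-9:
        raise ValueError("spike detection requires sampling at <= 0.1 ms")
    V = trace.V
    crossings = np.nonzero((V[:-1] < threshold) & (V[1:] >= threshold))[0] + 1
    if len(crossings) == 0:
        return np.empty(0)
    times = trace.t[crossings]
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


@dataclass
class MPOResult:
    """Outcome of subthreshold oscillation detection."""

    present: bool
    peak_freq: float = float("nan")  # Hz
    peak_to_background: float = float("nan")
    freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    power: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class BurstResult:
    """Outcome of burst detection on a spike train."""

    present: bool
    bursts: list[tuple[float, float, int]] = field(default_factory=list)


@dataclass
class ExcitabilityLabel:
    """Phenotype of one model cell under the step-classification protocol."""

    pattern: str  # "onset-only" | "repetitive"
    spike_count: int
    rheobase: float = float("nan")  # uA/cm^2, minimal step evoking >= 1 spike
    mpo: MPOResult = field(default_factory=lambda: MPOResult(present=False))
    bursting: BurstResult = field(default_factory=lambda: BurstResult(present=False))
    no_spikes: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in ("onset-only", "repetitive"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if (self.pattern == "repetitive") != (
            self.spike_count >= REPETITIVE_MIN_SPIKES
        ):
            raise ValueError("repetitive <=> spike_count >= 3 during the step")

    @property
    def is_repetitive(self) -> bool:
        return self.pattern == "repetitive"


def _count_step_spikes(
    model: CellModel,
    amplitude: float,
    I_hold: float,
    duration: float,
    dt: float,
    rest_state,
    seed: int | None,
) -> int:
    proto = StimulusProtocol.step(
        amplitude, onset=50.0, duration=duration, tail=50.0, I_hold=I_hold, dt=dt
    )
    tr = integrate(model, proto, seed=seed, initial_state=rest_state)
    spikes = detect_spikes(tr)
    return int(np.sum((spikes >= 50.0) & (spikes < 50.0 + duration)))


def classify_excitability(
    model: CellModel,
    I_hold: float = 0.0,
    duration: float = 1000.0,
    ladder: tuple[float, ...] = LADDER_DEFAULT,
    amplitudes: tuple[float, ...] | None = None,
    I_max: float = 70.0,
    rheobase_tol: float = 0.1,
    dt: float = 0.02,
    seed: int | None = None,
    mpo_check: bool = False,
) -> ExcitabilityLabel:
    """Classify a model cell as onset-only or repetitively spiking.

    The cell is stimulated with sustained steps (``duration`` >= 500 ms).
    By default the minimal amplitude evoking at least one spike is found
    by doubling then bisection, and the cell is probed at that rheobase
    times each ``ladder`` multiple; alternatively an explicit tuple of
    ``amplitudes`` can be tested.  The cell is repetitive iff any probed
    step evokes at least ``REPETITIVE_MIN_SPIKES`` spikes during the
    step.  When the model carries noise, classification runs use it
    (seeded); when it carries an AHP current, burst detection is applied
    to the spike train of the classifying step.
    """
    if duration < 500.0:
        raise ValueError("classification requires step duration >= 500 ms")
    det = model if (model.noise and model.noise.sigma > 0) else model.with_noise(None)
    rest = relax_to_rest(det, I_hold)

    def count(amp: float) -> int:
        return _count_step_spikes(det, amp, I_hold, duration, dt, rest, seed)

    rheobase = float("nan")
    if amplitudes is None:
        # coarse doubling to bracket the first spike, then bisection
        amp, prev = 1.0, 0.0
        n = count(amp)
        while n == 0 and amp < I_max:
            prev = amp
            amp = min(amp * 2.0, I_max)
            n = count(amp)
        if n == 0:
            return ExcitabilityLabel(
                pattern="onset-only", spike_count=0, no_spikes=True
            )
        lo, hi = prev, amp
        while hi - lo > rheobase_tol:
            mid = 0.5 * (lo + hi)
            if count(mid) >= 1:
                hi = mid
            else:
                lo = mid
        rheobase = hi
        probe_amps = tuple(min(rheobase * f, I_max) for f in ladder)
    else:
        probe_amps = tuple(amplitudes)

    best_count = 0
    best_amp = probe_amps[0]
    for amp in probe_amps:
        n = count(amp)
        if n > best_count:
            best_count, best_amp = n, amp
        if n >= REPETITIVE_MIN_SPIKES:
            break
    pattern = "repetitive" if best_count >= REPETITIVE_MIN_SPIKES else "onset-only"
    label = ExcitabilityLabel(
        pattern=pattern,
        spike_count=best_count,
        rheobase=rheobase,
        no_spikes=best_count == 0,
    )

    if model.ahp is not None and best_count > 0:
        proto = StimulusProtocol.step(
            best_amp, onset=50.0, duration=duration, tail=50.0, I_hold=I_hold, dt=dt
        )
        tr = integrate(det, proto, seed=seed, initial_state=rest)
        label.bursting = detect_bursts(detect_spikes(tr))
    if mpo_check and model.noise is not None and model.noise.sigma > 0:
        sub_amp = 0.8 * rheobase if np.isfinite(rheobase) else 0.0
        label.mpo = detect_mpo(
            model, I_stim=I_hold + sub_amp, seed=seed if seed is not None else 0
        )
    return label


def detect_mpo(
    model: CellModel,
    I_stim: float,
    seed: int = 0,
    T: float = 5000.0,
    record_dt: float = 0.5,
    segment_ms: float = 1000.0,
    spike_margin: float = 10.0,
    ratio_threshold: float = MPO_RATIO_THRESHOLD,
    min_freq: float = MPO_MIN_FREQ,
    max_freq: float = 200.0,
    background_halfwidth: float = 40.0,
    trace: Trace | None = None,
) -> MPOResult:
    """Detect membrane-potential oscillations from a noisy subthreshold run.

    Simulates ``T`` ms at constant ``I_stim`` with the model's noise (a
    pre-computed ``trace`` can be supplied instead), excises spikes with
    +/- ``spike_margin`` ms margins, and averages detrended 50%-overlap
    Welch periodograms over ``segment_ms`` windows of the spike-free
    segments.  MPOs are present iff a local spectral peak at or above
    ``min_freq`` exceeds the median-filtered background by
    ``ratio_threshold``.
    """
    if trace is None:
        if T < 5000.0:
            raise InsufficientDataError("MPO detection requires >= 5 s of data")
        if model.noise is None or model.noise.sigma == 0:
            # noise-free runs settle to the fixed point; classify on the
            # trace anyway (flat spectrum -> absent)
            pass
        proto = StimulusProtocol(
            T_total=T, dt=0.05, I_hold=I_stim, record_dt=record_dt
        )
        trace = integrate(model, proto, seed=seed)
    fs = 1000.0 / trace.dt  # Hz

    # excise spike windows, keep contiguous subthreshold segments
    V = trace.V
    keep = np.ones(len(V), dtype=bool)
    if trace.dt <= 0.1:
        spikes = detect_spikes(trace)
    else:  # coarse sampling: mask suprathreshold excursions instead
        spikes = trace.t[
            np.nonzero((V[:-1] < SPIKE_THRESHOLD) & (V[1:] >= SPIKE_THRESHOLD))[0]
        ]
    for ts in np.atleast_1d(spikes):
        keep &= ~((trace.t >= ts - spike_margin) & (trace.t <= ts + spike_margin))

    nperseg = int(round(segment_ms / trace.dt))
    # contiguous kept runs long enough for at least one Welch segment
    edges = np.diff(keep.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if keep[0]:
        starts.insert(0, 0)
    if keep[-1]:
        stops.append(len(keep))
    psd_sum = None
    n_windows = 0
    freqs = np.empty(0)
    for a, b in zip(starts, stops):
        if b - a < nperseg:
            continue
        f, p = signal.welch(
            V[a:b], fs=fs, nperseg=nperseg, noverlap=nperseg // 2, detrend="linear"
        )
        wins = 1 + (b - a - nperseg) // (nperseg // 2)
        psd_sum = p * wins if psd_sum is None else psd_sum + p * wins
        n_windows += wins
        freqs = f
    if n_windows == 0:
        raise InsufficientDataError(
            "no spike-free segment long enough for spectral analysis"
        )
    psd = psd_sum / n_windows
    # a numerically flat trace (noise-free run settled at the fixed
    # point) has no oscillation by definition
    if np.sqrt(np.trapezoid(psd, freqs)) < 1e-6:  # < 1 uV RMS
        return MPOResult(present=False, freqs=freqs, power=psd)
    # light boxcar smoothing across frequency suppresses single-bin
    # periodogram fluctuation without flattening the (broad) MPO peak
    box = np.ones(5) / 5.0
    psd = np.convolve(psd, box, mode="same")

    # smoothed background: median filter across frequency, much wider
    # than the (broad) resonance so it does not absorb the peak
    kernel = max(3, 2 * int(background_halfwidth / (freqs[1] - freqs[0])) + 1)
    background = signal.medfilt(psd, kernel_size=min(kernel, 2 * (len(psd) // 2) - 1))
    background = np.maximum(background, np.finfo(float).tiny)
    band = (freqs >= min_freq) & (freqs <= max_freq)
    ratio = psd / background
    peaks, _ = signal.find_peaks(psd)
    peaks = peaks[band[peaks]] if len(peaks) else peaks
    if len(peaks) == 0:
        return MPOResult(present=False, freqs=freqs, power=psd)
    best = peaks[np.argmax(ratio[peaks])]
    peak_ratio = float(ratio[best])
    return MPOResult(
        present=peak_ratio >= ratio_threshold,
        peak_freq=float(freqs[best]),
        peak_to_background=peak_ratio,
        freqs=freqs,
        power=psd,
    )


def detect_bursts(
    spike_times: np.ndarray,
    theta_intra: float = 50.0,
    theta_inter: float | None = None,
) -> BurstResult:
    """Group a spike train into bursts by inter-spike-interval thresholds.

    A burst is a maximal run of >= 2 spikes with ISI < ``theta_intra``
    ms, flanked by gaps > ``theta_inter`` (default 3 * theta_intra).
    Bursting is present iff at least two bursts occur; trains with fewer
    than 6 spikes are never called bursting.
    """
    if theta_inter is None:
        theta_inter = 3.0 * theta_intra
    spike_times = np.sort(np.asarray(spike_times, dtype=np.float64))
    if len(spike_times) < 6:
        return BurstResult(present=False)
    # split into maximal runs with ISI < theta_intra
    isi = np.diff(spike_times)
    breaks = np.nonzero(isi >= theta_intra)[0]
    groups = np.split(spike_times, breaks + 1)
    bursts: list[tuple[float, float, int]] = []
    for gi, g in enumerate(groups):
        if len(g) < 2:
            continue
        gap_before = g[0] - groups[gi - 1][-1] if gi > 0 else np.inf
        gap_after = groups[gi + 1][0] - g[-1] if gi + 1 < len(groups) else np.inf
        if gap_before > theta_inter and gap_after > theta_inter:
            bursts.append((float(g[0]), float(g[-1]), len(g)))
    return BurstResult(present=len(bursts) >= 2, bursts=bursts)


@dataclass
class TitrationResult:
    """Minimal conductance change flipping the excitability classification."""

    direction: str  # add-Na | add-K | scale-K | scale-Na
    minimal_density: float  # mS/cm^2 (added, or removed for scale-*)
    minimal_density_nS_per_pF: float
    converged: bool
    tolerance: float
    bracket: tuple[float, float]

    def __post_init__(self) -> None:
        if self.minimal_density < -1e-12:
            raise ValueError("minimal density must be >= 0")


VIRTUAL_NA_LABEL = "virtual-Na"
VIRTUAL_K_LABEL = "virtual-K"


def _apply_manipulation(model: CellModel, direction: str, g: float) -> CellModel:
    """Model with the titration manipulation of magnitude ``g`` applied."""
    if direction == "add-Na":
        if VIRTUAL_NA_LABEL in [c.label for c in model.channels]:
            return model.scale_channel(VIRTUAL_NA_LABEL, 0.0).with_channel(
                sodium_channel(g, label=VIRTUAL_NA_LABEL + "+")
            )
        return model.with_channel(sodium_channel(g, label=VIRTUAL_NA_LABEL))
    if direction == "add-K":
        if VIRTUAL_K_LABEL in [c.label for c in model.channels]:
            return model.scale_channel(VIRTUAL_K_LABEL, 0.0).with_channel(
                potassium_channel(g, label=VIRTUAL_K_LABEL + "+")
            )
        return model.with_channel(potassium_channel(g, label=VIRTUAL_K_LABEL))
    if direction in ("scale-K", "scale-Na"):
        label = "K" if direction == "scale-K" else "Na"
        ch = model.channel(label)
        if g > ch.gbar + 1e-12:
            raise ValueError(
                f"cannot remove {g} mS/cm^2 from channel {label!r} with "
                f"gbar = {ch.gbar}"
            )
        factor = 0.0 if ch.gbar == 0 else (ch.gbar - g) / ch.gbar
        return model.scale_channel(label, factor)
    raise ValueError(f"unknown titration direction {direction!r}")


def _is_repetitive(model: CellModel, classifier: str, **kwargs) -> bool:
    if classifier == "hopf":
        from .dynamics import I_RANGE_DEFAULT, hopf_bearing

        return hopf_bearing(model, kwargs.get("I_range", I_RANGE_DEFAULT))
    if classifier == "simulate":
        cls_kwargs = {
            k: v for k, v in kwargs.items() if k in (
                "I_hold", "duration", "ladder", "amplitudes", "I_max", "dt", "seed"
            )
        }
        return classify_excitability(model, **cls_kwargs).is_repetitive
    raise ValueError(f"unknown classifier {classifier!r}")


def titrate_to_tipping(
    model: CellModel,
    direction: str = "add-Na",
    tolerance: float = 0.005,
    g_max: float | None = None,
    classifier: str = "simulate",
    **classify_kwargs,
) -> TitrationResult:
    """Bisect the conductance change needed to flip the classification.

    Conversion directions (``add-Na``, ``scale-K``) search for the
    minimal density that makes an onset-only cell repetitive; reversal
    directions (``add-K``, ``scale-Na``) for the minimal density that
    silences a repetitive cell.  For ``scale-*`` the density is the
    amount of native conductance removed.  ``classifier`` selects the
    flip criterion: ``"simulate"`` (step-protocol classification) or
    ``"hopf"`` (existence of a Hopf bifurcation in the stimulus range);
    the two agree on the tipping boundary.  The result reports the
    density both in mS/cm^2 and in nS/pF via the capacitance convention
    (1 nS/pF = C_spec mS/cm^2).
    """
    want_repetitive = direction in ("add-Na", "scale-K")
    if direction in ("scale-K", "scale-Na"):
        native = model.channel("K" if direction == "scale-K" else "Na").gbar
        hi_limit = native if g_max is None else min(g_max, native)
    else:
        hi_limit = 5.0 if g_max is None else g_max

    def flipped(g: float) -> bool:
        m = _apply_manipulation(model, direction, g)
        rep = _is_repetitive(m, classifier, **classify_kwargs)
        return rep == want_repetitive

    C = model.core.C
    if flipped(0.0):
        return TitrationResult(
            direction=direction,
            minimal_density=0.0,
            minimal_density_nS_per_pF=0.0,
            converged=True,
            tolerance=tolerance,
            bracket=(0.0, 0.0),
        )
    if not flipped(hi_limit):
        return TitrationResult(
            direction=direction,
            minimal_density=hi_limit,
            minimal_density_nS_per_pF=hi_limit / C,
            converged=False,
            tolerance=tolerance,
            bracket=(hi_limit, float("inf")),
        )
    lo, hi = 0.0, hi_limit
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if flipped(mid):
            hi = mid
        else:
            lo = mid
    g_min = 0.5 * (lo + hi)
    return TitrationResult(
        direction=direction,
        minimal_density=g_min,
        minimal_density_nS_per_pF=g_min / C,
        converged=True,
        tolerance=tolerance,
        bracket=(lo, hi),
    )
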