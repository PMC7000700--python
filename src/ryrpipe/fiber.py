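"""Skinned-fiber calcium analyses.

Mechanically skinned skeletal muscle fibers seal off their transverse
tubular (t-) system with a Ca2+ indicator (rhod-5N) trapped inside.  At
rest, Ca2+ leaking through RyR1 into the junctional space is pumped into
the t-system, so the steady-state [Ca2+]_t-sys reports RyR1 leak.  This
module converts fluorescence to [Ca2+] via the single-site indicator
calibration

    [Ca2+] = Kd * (F - Fmin) / (Fmax - F),

extracts plateau steady states between solution changes, expresses a
drug's effect as a leak fraction on the tetracaine(=0)/no-drug(=1) scale,
and measures electrically evoked Ca2+ transient amplitudes (rhod-2 F/F0)
for excitation-contraction coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationParams",
    "FiberTrace",
    "LeakResult",
    "TransientResult",
    "calibrate_ca",
    "inverse_calibrate",
    "extract_steady_state",
    "leak_metric",
    "analyze_transients",
]


@dataclass(frozen=True)
class CalibrationParams:
    """Single-site indicator calibration constants.

    kd : indicator/Ca2+ dissociation constant, mM (rhod-5N: 0.8 mM).
    f_min, f_max : fluorescence at zero and saturating Ca2+, a.u.
    """

    kd: float = 0.8
    f_min: float = 0.0
    f_max: float = 1.0

    def validate(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if not self.f_max > self.f_min:
            raise ValueError("f_max must exceed f_min")


@dataclass
class FiberTrace:
    """Time-stamped fluorescence with solution-change event markers.

    events are ordered (time_s, label) pairs; labels follow the
    convention ``standard``, ``drug@dose`` (e.g. ``"myricetin@10uM"``),
    ``caffeine``, ``tetracaine``, ``washout``.
    """

    time: np.ndarray
    fluorescence: np.ndarray
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)

    def validate(self) -> None:
        if self.time.size != self.fluorescence.size:
            raise ValueError("time and fluorescence must have equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        for t_ev, _label in self.events:
            if not (self.time[0] <= t_ev <= self.time[-1]):
                raise ValueError(f"event at t={t_ev} s lies outside the trace")


@dataclass
class LeakResult:
    ss_drug: float
    ss_control: float
    ss_tetracaine: float
    leak_fraction: float
    beyond_tetracaine: bool


@dataclass
class TransientResult:
    baseline: float
    amplitudes: np.ndarray
    mean_amplitude: float
    percent_of_control: float = float("nan")


def calibrate_ca(f, params: CalibrationParams):
    """Convert indicator fluorescence to [Ca2+] (same unit as ``params.kd``).

    Valid for f_min <= f < f_max; f at or above f_max means the indicator
    is saturated and the concentration is undefined.
    """
    params.validate()
    f = np.asarray(f, dtype=float)
    if np.any(f < params.f_min):
        raise ValueError("fluorescence below f_min")
    if np.any(f >= params.f_max):
        raise ValueError("fluorescence at or above f_max (indicator saturated)")
    ca = params.kd * (f - params.f_min) / (params.f_max - f)
    return float(ca) if ca.ndim == 0 else ca


def inverse_calibrate(ca, params: CalibrationParams):
    """[Ca2+] -> fluorescence; exact inverse of :func:`calibrate_ca`."""
    params.validate()
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("concentration must be non-negative")
    f = (params.f_min * params.kd + params.f_max * ca) / (params.kd + ca)
    return float(f) if f.ndim == 0 else f


def extract_steady_state(
    trace: FiberTrace,
    event_index: int,
    plateau_frac: float = 0.2,
    drift_tol: float = 0.02,
    min_samples: int = 10,
) -> dict:
    """Plateau value of the segment following one solution-change event.

    The plateau is the mean of the final ``plateau_frac`` of the window
    between this event and the next (or end of trace).  A linear drift
    check guards against windows that have not reached steady state: if
    |slope| * window_duration exceeds ``drift_tol`` times the full trace
    range, the segment is flagged ``plateau=False``.

    Returns a dict with keys ``value``, ``se``, ``n``, ``plateau``, ``slope``.
    """
    trace.validate()
    if not 0 <= event_index < len(trace.events):
        raise IndexError(f"no event with index {event_index}")
    t0 = trace.events[event_index][0]
    t1 = trace.events[event_index + 1][0] if event_index + 1 < len(trace.events) else trace.time[-1]
    seg = (trace.time >= t0) & (trace.time <= t1)
    if seg.sum() < min_samples:
        raise ValueError("segment too short to estimate a steady state")
    t_seg = trace.time[seg]
    f_seg = trace.fluorescence[seg]

    n_tail = max(min_samples, int(np.ceil(plateau_frac * t_seg.size)))
    tail_t = t_seg[-n_tail:]
    tail_f = f_seg[-n_tail:]
    value = float(np.mean(tail_f))
    se = float(np.std(tail_f, ddof=1) / np.sqrt(n_tail)) if n_tail > 1 else 0.0

    if np.ptp(tail_f) == 0:
        slope = 0.0
    else:
        slope = float(np.polyfit(tail_t, tail_f, 1)[0])
    trace_range = float(np.ptp(trace.fluorescence))
    window = float(tail_t[-1] - tail_t[0])
    drift = abs(slope) * window
    is_plateau = trace_range == 0 or drift <= drift_tol * trace_range

    return {"value": value, "se": se, "n": int(n_tail), "plateau": bool(is_plateau), "slope": slope}


def leak_metric(ss_drug: float, ss_control: float, ss_tetracaine: float) -> LeakResult:
    """Normalized RyR leak from three t-system steady states.

    tetracaine (full RyR block) maps to 0, the no-drug control (full
    t-system uptake) to 1:

        leak_fraction = (ss_drug - ss_tetracaine) / (ss_control - ss_tetracaine)

    Values below 0 are kept and flagged ``beyond_tetracaine``: the drug
    lowered t-system Ca2+ below the zero-leak reference, implying an
    off-target effect (e.g. on t-system Ca2+ uptake).
    """
    if not ss_control > ss_tetracaine:
        raise ValueError("ss_control must exceed ss_tetracaine")
    frac = (ss_drug - ss_tetracaine) / (ss_control - ss_tetracaine)
    return LeakResult(
        ss_drug=float(ss_drug),
        ss_control=float(ss_control),
        ss_tetracaine=float(ss_tetracaine),
        leak_fraction=float(frac),
        beyond_tetracaine=bool(frac < 0),
    )


def analyze_transients(
    time: np.ndarray,
    f_over_f0: np.ndarray,
    stimulus_times: np.ndarray,
    peak_window: float = 0.1,
    baseline_window: float = 0.2,
    control_amplitude: float | None = None,
) -> TransientResult:
    """Peak amplitudes of electrically evoked Ca2+ transients.

    For each stimulus, the amplitude is max(F/F0) within ``peak_window``
    seconds after the stimulus minus the mean F/F0 over
    ``baseline_window`` seconds before it.  ``percent_of_control`` is the
    mean amplitude relative to a DMSO-control amplitude when supplied.

    Expects a sampling interval of at most 10 ms (line-scan resolution);
    stimuli at 1 Hz leave unambiguous pre/post windows.
    """
    time = np.asarray(time, dtype=float)
    f = np.asarray(f_over_f0, dtype=float)
    stim = np.atleast_1d(np.asarray(stimulus_times, dtype=float))
    if stim.size < 1:
        raise ValueError("at least one stimulus required")
    dt = float(np.median(np.diff(time)))
    if dt > 0.010 + 1e-12:
        raise ValueError(f"sampling interval {dt*1e3:.1f} ms too coarse (need <= 10 ms)")
    if np.any(stim < time[0]) or np.any(stim > time[-1]):
        raise ValueError("stimulus outside trace")

    amps = []
    for s in stim:
        pre = (time >= s - baseline_window) & (time < s)
        post = (time >= s) & (time <= s + peak_window)
        if pre.sum() < 2 or post.sum() < 2:
            raise ValueError(f"too few samples around stimulus at t={s} s")
        base = float(np.mean(f[pre]))
        amps.append(max(float(np.max(f[post]) - base), 0.0))
    amps = np.asarray(amps)

    baseline_all = float(np.mean(f[(time >= stim[0] - baseline_window) & (time < stim[0])]))
    mean_amp = float(np.mean(amps))
    pct = float("nan")
    if control_amplitude is not None:
        if control_amplitude <= 0:
            raise ValueError("control_amplitude must be positive")
        pct = 100.0 * mean_amp / control_amplitude
    return TransientResult(
        baseline=baseline_all,
        amplitudes=amps,
        mean_amplitude=mean_amp,
        percent_of_control=pct,
    )
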