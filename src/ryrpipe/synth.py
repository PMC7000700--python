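"""Synthetic-data generators for every pipeline stage.

The screen generator emulates the statistical structure of the 1536-well
FLT-FRET primary screen: three runs of three companion plates
(unlabeled / donor-only / donor-acceptor) on the LOPAC-style layout
(1280 compound wells in columns 3-22 and 27-46, 256 DMSO wells in
columns 1-2, 23-26, 47-48).  Null compound wells draw their normalized
FRET ratio E/E0 from the narrow control Gaussian observed in the screen
(sigma 0.016 around 1.004 relative to the DMSO mean); true modulators
add a signed shift.  Per-well donor-acceptor lifetimes are derived from
E via tau_DA = tau_D * (1 - E), so the analysis chain recovers the
generating values by construction.

Dose-response and fiber-trace generators are exact inverses of their
analysis stages (Hill curve plus replicate noise; piecewise-exponential
plateaus encoded through the rhod-5N calibration), which makes
round-trip parameter recovery the backbone of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose import DoseResponseSeries, HillFit
from .fiber import CalibrationParams, FiberTrace, inverse_calibrate
from .screen import DEFAULT_LAYOUT, PlateLayout, PlateRun

__all__ = [
    "ScreenSimConfig",
    "FiberSimConfig",
    "simulate_screen",
    "simulate_dose_response",
    "simulate_fiber_trace",
    "simulate_zprime_plates",
    "simulate_transient_train",
    "default_scenario",
]


@dataclass
class ScreenSimConfig:
    """Conditions of a simulated primary screen.

    The null E/E0 distribution of compound wells is
    N(control_mu, control_sigma) relative to the DMSO mean (DMSO wells
    draw from N(1, control_sigma)); ``effect_table`` adds a per-compound
    signed E/E0 shift, given either as a scalar (identical in all runs)
    or as a length-``n_runs`` sequence.  ``donor_artifact_table`` /
    ``intensity_artifact_table`` shift a compound's donor-only lifetime /
    unlabeled-plate intensity, in units of that plate's control SD, to
    emulate fluorescent or donor-perturbing compounds.
    """

    n_runs: int = 3
    control_mu: float = 1.004
    control_sigma: float = 0.016
    library_size: int = 1280
    effect_table: Mapping[str, float | Sequence[float]] = field(default_factory=dict)
    donor_tau: float = 4.0  # ns, donor-only lifetime
    fret_E_baseline: float = 0.3  # DMSO-control FRET efficiency E0
    photons_per_well: int = 100_000
    donor_tau_cv: float = 0.005  # instrument lifetime precision (CV)
    intensity_cv: float = 0.01
    intensity_mean: float = 1000.0  # a.u.
    donor_artifact_table: Mapping[str, float] = field(default_factory=dict)
    intensity_artifact_table: Mapping[str, float] = field(default_factory=dict)
    read_times: tuple = (20.0, 120.0)  # minutes post compound exposure
    early_read_attenuation: float = 0.5  # effect fraction realized at early reads
    seed: int = 0

    def validate(self, layout: PlateLayout) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.control_sigma <= 0:
            raise ValueError("control_sigma must be positive")
        if not 0 <= self.fret_E_baseline < 1:
            raise ValueError("fret_E_baseline must lie in [0, 1)")
        if self.library_size != layout.n_compound_wells:
            raise ValueError(
                f"library_size {self.library_size} does not match layout "
                f"({layout.n_compound_wells} compound wells)"
            )


def _effects_for_run(
    table: Mapping[str, float | Sequence[float]], run_index: int, n_runs: int
) -> dict[str, float]:
    out = {}
    for cid, eff in table.items():
        if np.isscalar(eff):
            out[cid] = float(eff)
        else:
            eff = list(eff)
            if len(eff) != n_runs:
                raise ValueError(
                    f"effect for {cid} must be scalar or length {n_runs}, got {len(eff)}"
                )
            out[cid] = float(eff[run_index])
    return out


def simulate_screen(
    config: ScreenSimConfig, layout: PlateLayout = DEFAULT_LAYOUT
) -> list[PlateRun]:
    """Generate ``config.n_runs`` screen runs on the given layout.

    Run-to-run variability is modeled as independent noise redraws (true
    effects repeat unless given per run).  Fixed seed gives bit-identical
    output.
    """
    config.validate(layout)
    wells = layout.well_table()
    known = set(wells.loc[wells["role"] == "compound", "compound_id"])
    for table in (config.effect_table, config.donor_artifact_table, config.intensity_artifact_table):
        unknown = set(table) - known
        if unknown:
            raise ValueError(f"effect table keys not in library: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(config.seed)
    runs = []
    n = len(wells)
    is_compound = (wells["role"] == "compound").to_numpy()

    for r in range(config.n_runs):
        effects = _effects_for_run(config.effect_table, r, config.n_runs)
        effect_vec = wells["compound_id"].map(effects).fillna(0.0).to_numpy()
        d_shift = wells["compound_id"].map(dict(config.donor_artifact_table)).fillna(0.0).to_numpy()
        i_shift = (
            wells["compound_id"].map(dict(config.intensity_artifact_table)).fillna(0.0).to_numpy()
        )

        frames = []
        for read_time in config.read_times:
            scale = (
                1.0
                if read_time == max(config.read_times)
                else config.early_read_attenuation
            )
            # --- donor-acceptor plate: E/E0 ratios -> lifetimes
            ratio = np.where(is_compound, config.control_mu, 1.0) + rng.normal(
                0.0, config.control_sigma, n
            )
            ratio = ratio + scale * effect_vec
            e = ratio * config.fret_E_baseline
            tau_da = config.donor_tau * (1.0 - e)
            da = wells.copy()
            da["sample_type"] = "donor_acceptor"
            da["tau_ns"] = tau_da
            da["intensity"] = config.intensity_mean * (
                1.0 + rng.normal(0.0, config.intensity_cv, n)
            )

            # --- donor-only plate: lifetimes around tau_D, artifact shifts in SD units
            donor_sd = config.donor_tau * config.donor_tau_cv
            tau_donly = config.donor_tau + rng.normal(0.0, donor_sd, n)
            tau_donly = tau_donly + scale * d_shift * donor_sd
            donly = wells.copy()
            donly["sample_type"] = "donor_only"
            donly["tau_ns"] = tau_donly
            donly["intensity"] = config.intensity_mean * (
                1.0 + rng.normal(0.0, config.intensity_cv, n)
            )

            # --- unlabeled plate: integrated spectral intensity
            int_sd = config.intensity_mean * config.intensity_cv
            intensity = config.intensity_mean + rng.normal(0.0, int_sd, n)
            intensity = intensity + scale * i_shift * int_sd
            unlab = wells.copy()
            unlab["sample_type"] = "unlabeled"
            unlab["tau_ns"] = np.nan
            unlab["intensity"] = intensity

            for df in (da, donly, unlab):
                df["read_time_min"] = read_time
                frames.append(df)

        run_wells = pd.concat(frames, ignore_index=True)
        runs.append(PlateRun(run_id=f"run{r + 1}", wells=run_wells, layout=layout))
    return runs


def default_scenario(
    layout: PlateLayout = DEFAULT_LAYOUT,
    control_sigma: float = 0.016,
    n_runs: int = 3,
) -> dict:
    """The shipped demonstration scenario.

    17 strong modulators (|shift| = 10 control SDs, identical in all
    runs; 9 increase FRET, 8 decrease it) and 5 marginal modulators
    (6 SDs in two runs, 0.5 SDs in the third, rotating which run is
    weak), mirroring a screen in which 17 compounds reproduce in all
    three runs and ~22 in at least two.

    Returns a dict with ``effect_table``, ``strong`` and ``marginal``
    compound-id lists.
    """
    ids = sorted(
        layout.well_table().loc[lambda d: d["role"] == "compound", "compound_id"]
    )
    strong = [ids[50 * k + 7] for k in range(17)]
    marginal = [ids[900 + 40 * k] for k in range(5)]

    table: dict[str, float | list[float]] = {}
    for i, cid in enumerate(strong):
        sign = 1.0 if i % 2 == 0 else -1.0  # 9 up, 8 down
        table[cid] = sign * 10.0 * control_sigma
    for i, cid in enumerate(marginal):
        sign = 1.0 if i % 2 == 0 else -1.0  # 3 up, 2 down
        eff = [sign * 6.0 * control_sigma] * n_runs
        eff[i % n_runs] = sign * 0.5 * control_sigma
        table[cid] = eff
    return {"effect_table": table, "strong": strong, "marginal": marginal}


def simulate_zprime_plates(
    donor_tau: float = 4.0,
    fret_E_baseline: float = 0.3,
    tau_cv: float = 0.005,
    n_each: int = 128,
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Donor-acceptor lifetimes of DMSO wells versus 20 uM suramin wells.

    Suramin abolishes FRET, so its tau_DA equals the donor-only
    lifetime; both groups carry the instrument's lifetime CV.  Returns
    (dmso_taus, suramin_taus) for :func:`ryrpipe.screen.z_prime`.
    """
    rng = np.random.default_rng(seed)
    mu_dmso = donor_tau * (1.0 - fret_E_baseline)
    dmso = mu_dmso * (1.0 + rng.normal(0.0, tau_cv, n_each))
    suramin = donor_tau * (1.0 + rng.normal(0.0, tau_cv, n_each))
    return dmso, suramin


def simulate_dose_response(
    hill: HillFit,
    concentrations: Sequence[float],
    n_replicates: int = 4,
    noise_sd: float = 0.03,
    seed: int | np.random.Generator | None = 0,
    compound_id: str = "compound",
    assay: str = "fret",
    isoform: str = "RyR1",
    redox: str = "GSH",
    free_ca_nM: float = 30.0,
) -> DoseResponseSeries:
    """Replicate responses from a Hill curve plus Gaussian noise.

    Emulates the dose-response design used to profile screen hits:
    log-spaced concentrations, n = 4 replicates per dose, responses
    normalized to the DMSO control.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("concentration list is empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(conc) < 0):
        raise ValueError("concentrations must be sorted ascending")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")

    rng = np.random.default_rng(seed)
    rows = []
    truth = hill.predict(conc)
    for rep in range(n_replicates):
        resp = truth + rng.normal(0.0, noise_sd, conc.size) if noise_sd > 0 else truth.copy()
        for c, v in zip(conc, resp):
            rows.append({"conc_um": c, "replicate": rep, "response": v})
    return DoseResponseSeries(
        compound_id=compound_id,
        points=pd.DataFrame(rows),
        assay=assay,
        isoform=isoform,
        redox=redox,
        free_ca_nM=free_ca_nM,
    )


@dataclass
class FiberSimConfig:
    """Conditions of a simulated t-system Ca2+ leak experiment.

    Steady-state [Ca2+]_t-sys levels are in mM: ``ss_control`` is the
    no-drug level (full t-system uptake, leak fraction 1), and
    ``ss_tetracaine`` the fully RyR-blocked floor (leak fraction 0);
    ``drug_effects`` maps ``"compound@dose"`` labels to the steady state
    reached under that condition.  The trace relaxes toward each target
    with a single-exponential time constant ``approach_tau``; kinetics
    are plumbing — the analysis consumes plateau values only.
    """

    ss_control: float = 0.6  # mM
    ss_tetracaine: float = 0.2  # mM
    ss_caffeine: float = 0.01  # mM, SOCE-depleted t-system
    drug_effects: Mapping[str, float] = field(default_factory=dict)
    approach_tau: float = 20.0  # s
    noise_sd: float = 0.0  # fluorescence a.u.
    calibration: CalibrationParams = field(
        default_factory=lambda: CalibrationParams(kd=0.8, f_min=100.0, f_max=1000.0)
    )
    sample_dt: float = 0.8  # s, xyt frame interval
    seed: int = 0

    def validate(self) -> None:
        if not self.ss_tetracaine < self.ss_control:
            raise ValueError("ss_tetracaine must be below ss_control")
        if self.approach_tau <= 0:
            raise ValueError("approach_tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        self.calibration.validate()


def _target_level(config: FiberSimConfig, label: str) -> float:
    if label in ("standard", "washout"):
        return config.ss_control
    if label == "tetracaine":
        return config.ss_tetracaine
    if label == "caffeine":
        return config.ss_caffeine
    if label in config.drug_effects:
        return float(config.drug_effects[label])
    raise KeyError(f"no steady-state level defined for solution {label!r}")


def simulate_fiber_trace(
    config: FiberSimConfig,
    protocol: Sequence[tuple[float, str]],
    duration: float | None = None,
) -> FiberTrace:
    """Piecewise-exponential [Ca2+]_t-sys trace under a solution protocol.

    ``protocol`` is an ordered list of (time_s, solution_label) events;
    after each event the t-system calcium relaxes exponentially from its
    current level toward the solution's steady state.  Fluorescence is
    produced by inverting the rhod-5N calibration, so the calibration +
    plateau analysis recovers the generating levels exactly in the
    noiseless case.
    """
    config.validate()
    if not protocol:
        raise ValueError("protocol must contain at least one event")
    times = [t for t, _ in protocol]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("protocol events must be strictly time-ordered")
    if duration is None:
        duration = times[-1] + 8.0 * config.approach_tau
    if times[-1] >= duration:
        raise ValueError("event beyond trace duration")

    t = np.arange(0.0, duration, config.sample_dt)
    ca = np.empty_like(t)
    level = _target_level(config, protocol[0][1])
    current = level  # start already at the first solution's steady state
    boundaries = times + [duration + config.sample_dt]
    for (t_ev, label), t_next in zip(protocol, boundaries[1:]):
        target = _target_level(config, label)
        seg = (t >= t_ev) & (t < t_next)
        ca[seg] = target + (current - target) * np.exp(-(t[seg] - t_ev) / config.approach_tau)
        if seg.any():
            elapsed = t_next - t_ev
            current = target + (current - target) * np.exp(-elapsed / config.approach_tau)
    ca[t < times[0]] = level

    f = inverse_calibrate(ca, config.calibration)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        f = f + rng.normal(0.0, config.noise_sd, f.size)
    return FiberTrace(time=t, fluorescence=f, events=list(protocol))


def simulate_transient_train(
    amplitude: float,
    n_stimuli: int = 10,
    stim_interval: float = 1.0,
    decay_tau: float = 0.05,
    rise_tau: float = 0.005,
    baseline: float = 1.0,
    sample_dt: float = 0.002,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Electrically evoked rhod-2 F/F0 transient train at 1 Hz.

    Each stimulus produces a fast-rising, exponentially decaying
    transient of peak height ``amplitude`` above baseline.  Returns
    (time_s, f_over_f0, stimulus_times).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    duration = (n_stimuli + 1) * stim_interval
    t = np.arange(0.0, duration, sample_dt)
    stim_times = stim_interval * (0.5 + np.arange(n_stimuli))
    f = np.full_like(t, baseline)
    # normalize the double-exponential pulse so its peak equals `amplitude`
    t_peak = decay_tau * rise_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    norm = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    for s in stim_times:
        dt = t - s
        m = dt >= 0
        pulse = np.exp(-dt[m] / decay_tau) - np.exp(-dt[m] / rise_tau)
        f[m] += amplitude * pulse / norm
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, f.size)
    return t, f, stim_times
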