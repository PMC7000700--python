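"""Shared fixtures: expensive simulations are session-scoped so module
tests and acceptance tests reuse the same computation."""

from __future__ import annotations

import numpy as np
import pytest

from ryrpipe import (
    ScreenSimConfig,
    analyze_screen,
    call_hits,
    fit_lifetime,
    normalize_plate,
    simulate_decay,
    simulate_screen,
)
from ryrpipe.synth import default_scenario

SEED = 20200204  # fixed once for the whole suite


@pytest.fixture(scope="session")
def null_screen_runs():
    """Three-run screen with all true effects zero, generated at the
    reported control-distribution conditions (mu=1.004, sigma=0.016)."""
    return simulate_screen(ScreenSimConfig(seed=SEED))


@pytest.fixture(scope="session")
def demo_screen():
    """The shipped demonstration scenario (17 strong + 5 marginal spiked
    modulators), simulated and analyzed end to end."""
    scenario = default_scenario()
    runs = simulate_screen(ScreenSimConfig(effect_table=scenario["effect_table"], seed=SEED))
    result = analyze_screen(runs)
    return {"scenario": scenario, "runs": runs, "result": result}


@pytest.fixture(scope="session")
def null_tail_hits():
    """False-positive hit count over ~1e5 compound wells of a centered
    null screen (control_mu = 1: the proper null for the Gaussian tail
    oracle, with no built-in compound-vs-control offset)."""
    n_runs = 79  # 79 * 1280 = 101,120 compound wells
    cfg = ScreenSimConfig(
        n_runs=n_runs, control_mu=1.0, read_times=(120.0,), seed=SEED + 1
    )
    runs = simulate_screen(cfg)
    n_hits = 0
    n_wells = 0
    for run in runs:
        hits = call_hits(normalize_plate(run), k_sd=4.0)
        n_hits += int(hits["hit"].sum())
        n_wells += len(hits)
    m_controls = runs[0].layout.n_control_wells
    return {"n_hits": n_hits, "n_wells": n_wells, "m_controls": m_controls}


@pytest.fixture(scope="session")
def lifetime_mc_taus():
    """200 Monte-Carlo lifetime fits of Poisson waveforms with ~1e5 total
    photons each (tau = 4 ns, 200 bins of 0.1 ns)."""
    tau, n_bins, bw = 4.0, 200, 0.1
    window = n_bins * bw
    amplitude = 1e5 * bw / tau / (1.0 - np.exp(-window / tau))
    taus = []
    for k in range(200):
        wf = simulate_decay(
            tau, amplitude, n_bins=n_bins, bin_width=bw, noise="poisson", seed=SEED + k
        )
        taus.append(fit_lifetime(wf).tau)
    return {"taus": np.asarray(taus), "tau_true": tau}
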