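"""Plate layout, normalization, hit calling, false-hit filters, and QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ryrpipe import (
    PlateLayout,
    PlateRun,
    ScreenSimConfig,
    aggregate_reproducibility,
    call_hits,
    filter_false_hits,
    fit_control_gaussian,
    hit_rate,
    normalize_plate,
    simulate_screen,
    simulate_zprime_plates,
    z_prime,
)

SMALL = PlateLayout(n_rows=4, n_cols=6, compound_cols=(2, 3, 4), control_cols=(1, 5, 6))


def make_run(layout, tau_da, tau_donor=4.0, intensity=1000.0, run_id="r1"):
    """Build a three-plate run with given donor-acceptor lifetimes.

    tau_da: scalar or dict well->tau for the donor-acceptor plate;
    tau_donor / intensity: scalar or dict for the companion plates.
    """
    wells = layout.well_table()

    def expand(val, default):
        if isinstance(val, dict):
            return wells["well"].map(val).fillna(default).to_numpy()
        return np.full(len(wells), float(val))

    frames = []
    for stype, tau_vals, int_vals in [
        ("donor_acceptor", expand(tau_da, np.nan), expand(1000.0, 1000.0)),
        ("donor_only", expand(tau_donor, 4.0), expand(1000.0, 1000.0)),
        ("unlabeled", np.full(len(wells), np.nan), expand(intensity, 1000.0)),
    ]:
        df = wells.copy()
        df["sample_type"] = stype
        df["tau_ns"] = tau_vals
        df["intensity"] = int_vals
        df["read_time_min"] = 120.0
        frames.append(df)
    return PlateRun(run_id=run_id, wells=pd.concat(frames, ignore_index=True), layout=layout)


class TestPlateLayout:
    def test_default_well_counts(self):
        layout = PlateLayout()
        assert layout.n_compound_wells == 1280
        assert layout.n_control_wells == 256

    def test_well_naming_spans_A01_to_AF48(self):
        layout = PlateLayout()
        table = layout.well_table()
        assert layout.well_name(0, 1) == "A01"
        assert layout.well_name(31, 48) == "AF48"
        assert table["well"].is_unique
        assert len(table) == 1536

    def test_overlapping_column_sets_rejected(self):
        with pytest.raises(ValueError):
            PlateLayout(compound_cols=(1, 2), control_cols=(2, 3))

    def test_compound_ids_unique_and_complete(self):
        table = PlateLayout().well_table()
        ids = table.loc[table["role"] == "compound", "compound_id"]
        assert ids.is_unique and len(ids) == 1280
        assert (table.loc[table["role"] == "control", "compound_id"] == "DMSO").all()


class TestNormalizePlate:
    def test_uniform_plate_gives_unit_ratios(self):
        run = make_run(SMALL, tau_da=2.8)
        norm = normalize_plate(run)
        np.testing.assert_allclose(norm["e_ratio"], 1.0)
        np.testing.assert_allclose(norm["E"], 0.3)

    def test_fret_abolished_well_maps_to_zero(self):
        # a suramin-like compound well with tau_DA = tau_D has E = 0, E/E0 = 0
        well = SMALL.well_table().query("role == 'compound'")["well"].iloc[0]
        run = make_run(SMALL, tau_da={well: 4.0}, tau_donor=4.0)
        # fill remaining DA wells with the FRET level
        run.wells.loc[
            (run.wells["sample_type"] == "donor_acceptor") & (run.wells["well"] != well),
            "tau_ns",
        ] = 2.8
        norm = normalize_plate(run)
        row = norm[norm["well"] == well].iloc[0]
        assert row["E"] == pytest.approx(0.0, abs=1e-12)
        assert row["e_ratio"] == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_matches_generated_ratios(self):
        cfg = ScreenSimConfig(seed=123, read_times=(120.0,))
        run = simulate_screen(cfg)[0]
        norm = normalize_plate(run)
        cmpd = norm[norm["role"] == "compound"]
        # generated null ratios are N(1.004, 0.016); recovery is exact up to
        # the plate-level tau_D / E0 estimation error (~0.1 sigma)
        assert cmpd["e_ratio"].mean() == pytest.approx(1.004, abs=3 * 0.016 / np.sqrt(1280))
        assert cmpd["e_ratio"].std() == pytest.approx(0.016, rel=0.05)

    def test_too_few_controls_rejected(self):
        run = make_run(SMALL, tau_da=2.8)
        # keep only one control column (4 wells) on the donor-acceptor plate
        drop = (run.wells["sample_type"] == "donor_acceptor") & run.wells["col"].isin([5, 6])
        run2 = PlateRun(run_id="r1", wells=run.wells[~drop].reset_index(drop=True), layout=SMALL)
        with pytest.raises(ValueError, match="control wells"):
            normalize_plate(run2)


class TestFilterFalseHits:
    def test_clean_plates_produce_no_flags(self):
        run = make_run(SMALL, tau_da=2.8)
        flags = filter_false_hits(run)
        assert not flags["artifact"].any()

    def test_spiked_companion_wells_are_flagged(self):
        cfg = ScreenSimConfig(
            seed=5,
            read_times=(120.0,),
            donor_artifact_table={"C0001": 10.0},
            intensity_artifact_table={"C0002": -10.0},
        )
        run = simulate_screen(cfg)[0]
        flags = filter_false_hits(run)
        assert flags.loc["C0001", "donor_only_artifact"]
        assert flags.loc["C0002", "intensity_artifact"]
        assert flags["artifact"].sum() <= 25  # the 2 spikes + ~0.27% per-filter nulls

    def test_null_flag_rate_matches_three_sd_tail(self):
        # per filter the null flag rate is ~2*Phi(-3) = 0.27%
        runs = simulate_screen(ScreenSimConfig(n_runs=10, read_times=(120.0,), seed=77))
        n_flags = sum(
            int(filter_false_hits(run)["donor_only_artifact"].sum()) for run in runs
        )
        n = 10 * 1280
        p = 2 * stats.norm.sf(3)
        assert abs(n_flags - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_missing_companion_plate_rejected(self):
        run = make_run(SMALL, tau_da=2.8)
        wells = run.wells[run.wells["sample_type"] != "unlabeled"].reset_index(drop=True)
        with pytest.raises(ValueError, match="unlabeled"):
            filter_false_hits(PlateRun(run_id="r1", wells=wells, layout=SMALL))


class TestCallHits:
    @staticmethod
    def _normalized_with_known_sd(delta_in_sd):
        """Controls with exactly-zero mean plus one offset compound.

        Control values alternate +/-0.5 so the mean is exactly 0 and the
        compound deviation ``delta_in_sd * sd`` divides back to exactly
        ``delta_in_sd`` in floating point, making the strict-inequality
        boundary test well defined.
        """
        n_ctrl = 200
        ctrl_vals = np.tile([0.5, -0.5], n_ctrl // 2)
        ctrl = pd.DataFrame(
            {
                "well": [f"A{i:02d}" for i in range(n_ctrl)],
                "role": "control",
                "compound_id": "DMSO",
                "E": 0.3,
                "e_ratio": ctrl_vals,
            }
        )
        sd = ctrl["e_ratio"].std(ddof=1)
        cmpd = pd.DataFrame(
            {
                "well": ["B01"],
                "role": "compound",
                "compound_id": ["CX"],
                "E": [0.3],
                "e_ratio": [delta_in_sd * sd],
            }
        )
        return pd.concat([ctrl, cmpd], ignore_index=True)

    def test_boundary_at_exactly_four_sd_is_not_a_hit(self):
        hits = call_hits(self._normalized_with_known_sd(4.0))
        assert not hits["hit"].iloc[0]  # strict inequality

    def test_just_beyond_four_sd_is_a_hit(self):
        hits = call_hits(self._normalized_with_known_sd(4.001))
        assert hits["hit"].iloc[0]
        assert hits["sign"].iloc[0] == 1

    def test_zero_control_sd_rejected(self):
        norm = self._normalized_with_known_sd(4.0)
        norm.loc[norm["role"] == "control", "e_ratio"] = 1.0
        with pytest.raises(ValueError, match="SD"):
            call_hits(norm)

    def test_raising_threshold_shrinks_hit_set(self, demo_screen):
        run = demo_screen["runs"][0]
        norm = normalize_plate(run)
        flags = filter_false_hits(run)
        hits4 = set(call_hits(norm, flags, k_sd=4.0).query("hit")["compound_id"])
        hits6 = set(call_hits(norm, flags, k_sd=6.0).query("hit")["compound_id"])
        assert hits6 <= hits4

    def test_artifact_flagged_compounds_never_hits(self):
        sigma = 0.016
        cfg = ScreenSimConfig(
            seed=9,
            read_times=(120.0,),
            effect_table={"C0010": 12 * sigma},
            donor_artifact_table={"C0010": 12.0},
        )
        run = simulate_screen(cfg)[0]
        norm = normalize_plate(run)
        flags = filter_false_hits(run)
        hits = call_hits(norm, flags)
        row = hits[hits["compound_id"] == "C0010"].iloc[0]
        assert row["donor_only_artifact"] and not row["hit"]
        assert abs(row["delta_sd"]) > 4  # it would have been a hit otherwise

    def test_null_false_positive_rate_matches_tail_oracle(self, null_tail_hits):
        """FP rate over ~1e5 null wells matches the Gaussian 4-SD tail.

        The exact oracle accounts for the plug-in control SD (m = 256
        control wells): the deviation statistic is t-distributed, so
        p = 2 * P(t_{m-1} > 4 / sqrt(1 + 1/m)).
        """
        n, k = null_tail_hits["n_wells"], null_tail_hits["n_hits"]
        m = null_tail_hits["m_controls"]
        p_exact = 2 * stats.t.sf(4.0 / np.sqrt(1 + 1 / m), m - 1)
        assert abs(k - n * p_exact) < 3 * np.sqrt(n * p_exact * (1 - p_exact))


class TestAggregateReproducibility:
    @staticmethod
    def _hit_df(compounds, hits, signs):
        return pd.DataFrame(
            {
                "compound_id": compounds,
                "e_ratio": 1.0,
                "hit": hits,
                "sign": signs,
            }
        )

    def test_hit_in_two_of_three_runs_is_reproducible(self):
        c = ["C1"]
        runs = {
            "r1": self._hit_df(c, [True], [1]),
            "r2": self._hit_df(c, [False], [1]),
            "r3": self._hit_df(c, [True], [1]),
        }
        agg = aggregate_reproducibility(runs)
        assert agg["reproducible"].iloc[0]
        assert agg["direction"].iloc[0] == 1

    def test_opposite_signs_are_not_reproducible(self):
        c = ["C1"]
        runs = {
            "r1": self._hit_df(c, [True], [1]),
            "r2": self._hit_df(c, [True], [-1]),
            "r3": self._hit_df(c, [False], [1]),
        }
        assert not aggregate_reproducibility(runs)["reproducible"].iloc[0]

    def test_mismatched_libraries_rejected(self):
        runs = {
            "r1": self._hit_df(["C1"], [True], [1]),
            "r2": self._hit_df(["C2"], [True], [1]),
        }
        with pytest.raises(ValueError, match="mismatched"):
            aggregate_reproducibility(runs)

    def test_demo_scenario_recovers_spiked_truth(self, demo_screen):
        result = demo_screen["result"]
        scenario = demo_screen["scenario"]
        rep = result.reproducible
        reproducible = set(rep.loc[rep["reproducible"], "compound_id"])
        strong, marginal = set(scenario["strong"]), set(scenario["marginal"])
        assert reproducible >= strong
        assert reproducible <= strong | marginal


class TestZPrime:
    def test_zero_variance_gives_unity(self):
        assert z_prime([2.8, 2.8], [4.0, 4.0]) == pytest.approx(1.0)

    def test_arithmetic_example(self):
        # sigmas 0.05 each, |delta mu| = 1 -> Z' = 1 - 3*0.1/1 = 0.7
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.05, 20000)
        b = rng.normal(1.0, 0.05, 20000)
        assert z_prime(a, b) == pytest.approx(0.7, abs=0.01)

    def test_equal_means_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            z_prime([1.0, 1.0], [1.0, 1.0])

    def test_simulated_suramin_plates_reach_excellent_quality(self):
        # 0.5% lifetime CV on DMSO vs FRET-abolished wells -> Z' > 0.8
        dmso, suramin = simulate_zprime_plates(tau_cv=0.005, n_each=128, seed=2)
        assert z_prime(dmso, suramin) > 0.8

    def test_affine_invariance(self):
        dmso, suramin = simulate_zprime_plates(seed=4)
        z0 = z_prime(dmso, suramin)
        z1 = z_prime(3.0 * dmso + 7.0, 3.0 * suramin + 7.0)
        assert z1 == pytest.approx(z0, rel=1e-9)


class TestControlGaussian:
    def test_degenerate_data_warns(self):
        with pytest.warns(RuntimeWarning, match="sigma = 0"):
            fit = fit_control_gaussian(np.full(100, 1.5))
        assert fit.mu == pytest.approx(1.5)
        assert fit.sigma == 0.0

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(10)
        x = rng.normal(1.004, 0.016, 5000)
        fit = fit_control_gaussian(x)
        assert abs(fit.mu - 1.004) < 3 * fit.se_mu
        assert abs(fit.sigma - 0.016) < 3 * fit.se_sigma

    def test_robust_mode_resists_spiked_hits(self):
        rng = np.random.default_rng(11)
        x = rng.normal(1.004, 0.016, 4000)
        x[:80] += 10 * 0.016  # 2% large-effect spikes
        fit = fit_control_gaussian(x, robust=True)
        assert fit.sigma == pytest.approx(0.016, rel=0.05)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_control_gaussian(np.ones(10))


class TestHitRate:
    @pytest.mark.parametrize("n_hits, size, expected", [(0, 1280, 0.0), (25, 1280, 25 / 1280)])
    def test_fraction(self, n_hits, size, expected):
        assert hit_rate(n_hits, size) == pytest.approx(expected)

    def test_demo_rates_within_acceptable_band(self, demo_screen):
        # the 0.5-3% range considered workable for a primary HTS assay
        for rate in demo_screen["result"].qc["hit_rate"].values():
            assert 0.005 <= rate <= 0.03

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            hit_rate(1, 0)
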