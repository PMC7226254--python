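"""Generator ground truth: library composition, kill curves, noise model,
renderer, dose-response series and clonal competition."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage.measure import label

from collatscreen.config import (
    CompetitionParams,
    CompoundEffectProfile,
    EffectClass,
    FieldImageSpec,
    GenerationError,
    LayoutError,
    SimulationConfig,
)
from collatscreen.simulate import (
    allocate_class_counts,
    build_plate_layout,
    generate_library,
    render_field,
    simulate_competition,
    simulate_dose_response,
    simulate_plate,
    simulate_screen,
    true_kill_fraction,
)

from conftest import vehicle_only_layout


def make_profile(effect_class=EffectClass.cytotoxic, ic50_s=100.0, ic50_r=100.0,
                 hill=1.0, max_kill=1.0, cid="X"):
    return CompoundEffectProfile(
        compound_id=cid, effect_class=effect_class, ic50_sensitive_line=ic50_s,
        ic50_resistant_line=ic50_r, hill_slope=hill, max_kill=max_kill,
    )


class TestLibrary:
    @pytest.mark.parametrize(
        "n, proportions, expected",
        [
            # exact halves: 5 and 5
            (10, {EffectClass.btk_inhibitor: 0.5, EffectClass.inert: 0.5},
             {EffectClass.btk_inhibitor: 5, EffectClass.inert: 5}),
            # largest-remainder: quotas 2.8 / 2.45 / 1.75 -> floors 2/2/1, the
            # two units left go to the largest remainders .8 and .75
            (7, {EffectClass.btk_inhibitor: 0.4, EffectClass.pi3k_inhibitor: 0.35,
                 EffectClass.cytotoxic: 0.25},
             {EffectClass.btk_inhibitor: 3, EffectClass.pi3k_inhibitor: 2,
              EffectClass.cytotoxic: 2}),
        ],
    )
    def test_largest_remainder_allocation(self, n, proportions, expected):
        assert allocate_class_counts(proportions, n) == expected

    def test_full_size_library_is_reproducible(self):
        cfg = SimulationConfig(rng_seed=11)
        lib1 = generate_library(cfg)
        lib2 = generate_library(cfg)
        assert len(lib1) == 590
        assert [p.model_dump() for p in lib1] == [p.model_dump() for p in lib2]
        counts = allocate_class_counts(cfg.class_proportions, cfg.n_compounds)
        observed = pd.Series([p.effect_class for p in lib1]).value_counts().to_dict()
        assert observed == {k: v for k, v in counts.items() if v > 0}

    def test_degenerate_all_inert_mixture(self):
        cfg = SimulationConfig(n_compounds=12, class_proportions={EffectClass.inert: 1.0})
        assert all(p.max_kill == 0.0 for p in generate_library(cfg))

    def test_class_invariants_enforced(self):
        with pytest.raises(ValueError, match="resistance mutation protects"):
            make_profile(EffectClass.btk_inhibitor, ic50_s=200.0, ic50_r=100.0)
        with pytest.raises(ValueError, match="collateral_sensitive"):
            make_profile(EffectClass.collateral_sensitive, ic50_s=100.0, ic50_r=200.0)
        with pytest.raises(ValueError, match="max_kill = 0"):
            make_profile(EffectClass.inert, max_kill=0.5)


class TestKillFraction:
    def test_half_maximal_at_ic50(self):
        assert true_kill_fraction(make_profile(), "sensitive", 100.0) == pytest.approx(0.5)

    def test_hand_arithmetic_point(self):
        # max_kill 0.8, h=1, dose = 9 * ic50 -> 0.8 * 9/10 = 0.72
        p = make_profile(max_kill=0.8)
        assert true_kill_fraction(p, "sensitive", 900.0) == pytest.approx(0.72)

    def test_inert_and_zero_dose(self):
        inert = make_profile(EffectClass.inert, max_kill=0.0)
        assert true_kill_fraction(inert, "resistant", 1e6) == 0.0
        assert true_kill_fraction(make_profile(), "sensitive", 0.0) == 0.0

    def test_monotone_in_dose_and_line_resolution(self):
        p = make_profile(EffectClass.btk_inhibitor, ic50_s=50.0, ic50_r=5000.0, max_kill=0.9)
        doses = np.geomspace(0.1, 1e6, 60)
        ks = true_kill_fraction(p, "E41K", doses)
        kr = true_kill_fraction(p, "E41K_C481S", doses)
        assert np.all(np.diff(ks) >= 0) and np.all(np.diff(kr) >= 0)
        assert np.all(ks >= kr)  # protected line is always less killed
        with pytest.raises(ValueError, match="unknown line"):
            true_kill_fraction(p, "HEK293", 10.0)


class TestPlateSimulation:
    def test_noise_free_inert_matches_vehicle_exactly(self, small_config):
        cfg = small_config.model_copy(update={"cv_well_noise": 0.0})
        profiles, wells = simulate_screen(cfg)
        inert_ids = {p.compound_id for p in profiles if p.effect_class is EffectClass.inert}
        veh = wells.loc[wells.role == "vehicle", "count"].iloc[0]
        inert_counts = wells.loc[wells.compound_id.isin(inert_ids), "count"]
        assert np.all(inert_counts == veh)

    def test_saturating_kill_empties_well(self):
        cfg = SimulationConfig(n_compounds=1, cv_well_noise=0.0,
                               class_proportions={EffectClass.cytotoxic: 1.0},
                               doses=[1e7])
        profiles = generate_library(cfg)
        profiles[0] = make_profile(max_kill=1.0, ic50_s=1.0, ic50_r=1.0,
                                   cid=profiles[0].compound_id)
        layout = build_plate_layout(profiles, cfg)
        wells = simulate_plate(layout, profiles, cfg)
        treated = wells.loc[wells.role == "compound", "count"]
        assert np.all(treated < 1.0)

    def test_lognormal_noise_cv_calibration(self):
        """Monte-Carlo: 10,000 vehicle wells at cv=0.1 show sample CV 0.1 +/- 0.01
        and unit-mean noise (mean equals the deterministic expectation to ~1%)."""
        cfg = SimulationConfig(cv_well_noise=0.1, rng_seed=5)
        layout = vehicle_only_layout(10_000)
        wells = simulate_plate(layout, [], cfg)
        counts = wells["count"].to_numpy()
        cv = counts.std(ddof=1) / counts.mean()
        assert abs(cv - 0.1) < 0.01
        expected = cfg.cells_seeded_per_well * cfg.growth_factor
        assert counts.mean() == pytest.approx(expected, rel=0.01)

    def test_unknown_compound_raises_layout_error(self, small_config):
        profiles = generate_library(small_config)
        layout = build_plate_layout(profiles, small_config)
        layout.loc[layout.role == "compound", "compound_id"] = "GHOST"
        with pytest.raises(LayoutError, match="GHOST"):
            simulate_plate(layout, profiles, small_config)

    def test_layout_covers_design(self, small_config):
        layout = build_plate_layout(generate_library(small_config), small_config)
        # 2 lines x 2 doses x 2 replicates, all compounds on each plate set
        assert set(layout["line"]) == {"E41K", "E41K_C481S"}
        comp = layout[layout.role == "compound"]
        assert comp.groupby(["line", "dose_nM", "replicate"]).size().eq(20).all()
        assert (layout[layout.role == "vehicle"].groupby("plate_id").size() == 16).all()


class TestRenderer:
    def test_blank_field(self, noise_free_spec, rng):
        img, truth = render_field(0, noise_free_spec, rng)
        assert truth.empty
        assert np.all(img == noise_free_spec.background_mean)

    def test_noise_free_components_match_ground_truth(self, noise_free_spec, rng):
        """Connected-component oracle: without background noise the image must
        contain exactly n bright 8-connected blobs."""
        img, truth = render_field(50, noise_free_spec, rng)
        n_components = label(img > noise_free_spec.background_mean, connectivity=2).max()
        assert n_components == 50 == len(truth)

    def test_packing_infeasibility_raises(self, rng):
        spec = FieldImageSpec(height=32, width=32)
        with pytest.raises(GenerationError, match="packing"):
            render_field(100, spec, rng)

    def test_deterministic_given_seed(self, noise_free_spec):
        img1, t1 = render_field(20, noise_free_spec, np.random.default_rng(3))
        img2, t2 = render_field(20, noise_free_spec, np.random.default_rng(3))
        assert np.array_equal(img1, img2)
        pd.testing.assert_frame_equal(t1, t2)


class TestDoseResponseGenerator:
    DOSES = [0.0, 10.0, 100.0, 1000.0, 10_000.0]

    def test_noise_free_percent_scale(self, rng):
        p = make_profile(max_kill=1.0)
        df = simulate_dose_response(p, "E41K", self.DOSES, n_replicates=1, cv=0.0, rng=rng)
        assert df.loc[df.dose_nM == 0.0, "viability_pct"].item() == 100.0
        assert df.loc[df.dose_nM == 100.0, "viability_pct"].item() == pytest.approx(50.0)

    def test_il3_rescue_flattens_series(self, rng):
        p = make_profile(max_kill=1.0)
        df = simulate_dose_response(p, "E41K", self.DOSES, n_replicates=2, cv=0.0,
                                    rng=rng, il3=True)
        assert np.all(df["viability_pct"] == 100.0)

    def test_requires_four_distinct_doses(self, rng):
        with pytest.raises(ValueError, match="4 distinct doses"):
            simulate_dose_response(make_profile(), "E41K", [10, 10, 100], rng=rng)

    def test_log_spaced_series_brackets_ic50(self, rng):
        p = make_profile(ic50_s=100.0, max_kill=1.0)
        doses = np.geomspace(1, 1e5, 8)
        df = simulate_dose_response(p, "E41K", doses, n_replicates=1, cv=0.0, rng=rng)
        v = df.sort_values("dose_nM")["viability_pct"].to_numpy()
        assert v[0] > 50.0 > v[-1]


class TestCompetition:
    def test_closed_form_oracle(self):
        """f(t) = f0 e^{rm t} / (f0 e^{rm t} + (1-f0) e^{rw t}) to 1e-9."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            p = CompetitionParams(
                growth_rate_mut_no_il3=rng.uniform(-1, 2),
                growth_rate_wt_no_il3=rng.uniform(-2, 0),
                initial_fraction_mut=rng.uniform(0.05, 0.95),
                horizon_days=rng.uniform(1, 6),
            )
            traj = simulate_competition(p, il3=False)
            t = traj["t_days"].to_numpy()
            f0 = p.initial_fraction_mut
            num = f0 * np.exp(p.growth_rate_mut_no_il3 * t)
            den = num + (1 - f0) * np.exp(p.growth_rate_wt_no_il3 * t)
            np.testing.assert_allclose(traj["fraction_mut"], num / den, atol=1e-9)

    def test_equal_rates_hold_fraction_constant(self):
        p = CompetitionParams(growth_rate_mut_with_il3=0.8, growth_rate_wt_with_il3=0.8,
                              initial_fraction_mut=0.37)
        traj = simulate_competition(p, il3=True)
        np.testing.assert_allclose(traj["fraction_mut"], 0.37, atol=1e-12)

    def test_symmetric_rates_closed_form_point(self):
        # rw=-1/day, rm=+1/day, f0=0.5, t=3 -> e^3/(e^3+e^-3)
        p = CompetitionParams(growth_rate_mut_no_il3=1.0, growth_rate_wt_no_il3=-1.0,
                              initial_fraction_mut=0.5, horizon_days=3.0)
        f3 = simulate_competition(p, il3=False)["fraction_mut"].iloc[-1]
        expected = math.exp(3) / (math.exp(3) + math.exp(-3))
        assert f3 == pytest.approx(expected, abs=1e-12)
        assert f3 == pytest.approx(0.9975, abs=5e-4)

    def test_default_parameters_reproduce_selection_sweep(self):
        """GFP+ fraction stays ~49% with IL3 and sweeps past 90% without it."""
        p = CompetitionParams()
        with_il3 = simulate_competition(p, il3=True)["fraction_mut"].iloc[-1]
        no_il3 = simulate_competition(p, il3=False)["fraction_mut"].iloc[-1]
        assert with_il3 == pytest.approx(0.49, abs=0.05)
        assert no_il3 > 0.90
        traj = simulate_competition(p, il3=False)["fraction_mut"]
        assert np.all(np.diff(traj) > 0)  # mutant advantage -> monotone sweep

    def test_wt_must_die_without_il3(self):
        with pytest.raises(ValueError, match="wt_no_il3"):
            CompetitionParams(growth_rate_wt_no_il3=0.2)
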