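"""Generator: composition, drug effects, noise model, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from nichescreen import (
    DrugEffect,
    GroundTruth,
    Hill,
    PlateConfig,
    build_fixed_ratio_series,
    default_panel,
    expected_viable_fractions,
    load_plate_config,
    simulate_plate,
    simulate_well,
)
from nichescreen.synth import BULK_POPULATIONS, POPULATIONS, build_layout


def _counts(events):
    return events["label"].value_counts()


class TestSimulateWell:
    def test_vehicle_well_matches_baseline_composition(self, truth_quiet, panel):
        events = simulate_well(truth_quiet, {"treatment": []}, panel, seed=3)
        n = len(events)
        assert n == truth_quiet.seeding
        counts = _counts(events)
        for pop in POPULATIONS:
            p = truth_quiet.fractions[pop]
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts.get(pop, 0) - n * p) < 4 * sd

    def test_expected_lymphocyte_count_at_screen_seeding(self, truth_quiet, panel):
        # 50,000 seeded x 0.10 lymphocyte fraction -> 5,000 expected
        frac = expected_viable_fractions(truth_quiet, [])
        assert frac["lymphocyte"] * truth_quiet.seeding == pytest.approx(5000)
        events = simulate_well(truth_quiet, {"treatment": []}, panel, seed=4)
        obs = _counts(events)["lymphocyte"]
        sd = np.sqrt(50_000 * 0.10 * 0.90)
        assert abs(obs - 5000) < 4 * sd

    def test_saturating_kill_spares_only_diff(self, panel):
        # steep full-kill drug on basal+LSC at 100x EC50 wipes both states
        drug = DrugEffect(kill={"basal": Hill(1.0, 1.0, 8.0),
                                "lsc": Hill(1.0, 1.0, 8.0)})
        truth = GroundTruth(replicate_cv=0.0, seeding=20_000,
                            drugs={"x": drug})
        events = simulate_well(truth, {"treatment": [("x", 100.0)]}, panel, seed=5)
        counts = _counts(events)
        # survival at 100x EC50 with slope 8 is ~1e-16: 0 survivors within 3 SD
        assert counts.get("basal", 0) == 0
        assert counts.get("lsc", 0) == 0
        n_diff = counts.get("diff", 0)
        exp_diff = 20_000 * truth.fractions["diff"]
        assert abs(n_diff - exp_diff) < 4 * np.sqrt(exp_diff)

    def test_total_events_conserved(self, truth_quiet, panel):
        truth = GroundTruth(replicate_cv=0.0, seeding=10_000,
                            drugs={"x": DrugEffect(kill={"bulk": Hill(0.7, 1.0)})})
        events = simulate_well(truth, {"treatment": [("x", 5.0)]}, panel, seed=6)
        assert len(events) == 10_000  # viable + dead = seeded

    def test_same_seed_identical_different_seed_distinct(self, truth_quiet, panel):
        a = simulate_well(truth_quiet, {"treatment": []}, panel, seed=7)
        b = simulate_well(truth_quiet, {"treatment": []}, panel, seed=7)
        c = simulate_well(truth_quiet, {"treatment": []}, panel, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not a.drop(columns="label").equals(c.drop(columns="label"))

    def test_unknown_drug_and_negative_concentration_error(self, truth_quiet, panel):
        with pytest.raises(KeyError):
            simulate_well(truth_quiet, {"treatment": [("nope", 1.0)]}, panel, 1)
        truth = GroundTruth(drugs={"x": DrugEffect(kill={"bulk": Hill(0.5, 1.0)})})
        with pytest.raises(ValueError):
            simulate_well(truth, {"treatment": [("x", -1.0)]}, panel, 1)


class TestExpectations:
    def test_analytic_means_match_empirical_over_replicates(self, panel):
        # >=50 replicate wells: per-population mean within 3 standard errors
        truth = GroundTruth(
            seeding=2000, replicate_cv=0.0,
            drugs={"x": DrugEffect(kill={"basal": Hill(0.6, 1.0),
                                         "lsc": Hill(0.3, 1.0)},
                                   differentiation=Hill(0.3, 1.0))})
        treatment = [("x", 1.0)]  # half-effect concentration
        frac = expected_viable_fractions(truth, treatment)
        n_wells = 60
        ss = np.random.SeedSequence(42).spawn(n_wells)
        totals = {p: 0 for p in list(POPULATIONS) + ["dp"]}
        for child in ss:
            ev = simulate_well(truth, {"treatment": treatment}, panel, child)
            counts = _counts(ev)
            for p in totals:
                totals[p] += counts.get(p, 0)
        for pop, expected_frac in frac.items():
            if expected_frac == 0:
                assert totals.get(pop, 0) == 0
                continue
            exp = expected_frac * truth.seeding
            se = np.sqrt(expected_frac * (1 - expected_frac) * truth.seeding
                         / n_wells)
            mean = totals[pop] / n_wells
            assert abs(mean - exp) < 3 * se, pop

    def test_cytotoxic_expected_bulk_nonincreasing_in_dose(self):
        truth = GroundTruth(drugs={"x": DrugEffect(kill={"bulk": Hill(0.9, 1.0, 2.0)})})
        doses = np.logspace(-3, 3, 25)
        bulk = [sum(expected_viable_fractions(truth, [("x", c)])[p]
                    for p in BULK_POPULATIONS) for c in doses]
        assert np.all(np.diff(bulk) <= 1e-15)

    def test_differentiation_applied_before_survival(self):
        # a drug that differentiates and then kills Diff+ cells: transitioned
        # LSC/basal must be exposed to the Diff+ kill, not their origin's
        drug = DrugEffect(kill={"diff": Hill(1.0, 1e-3, 8.0)},
                          differentiation=Hill(0.5, 1e-3, 8.0))
        truth = GroundTruth(drugs={"x": drug})
        frac = expected_viable_fractions(truth, [("x", 1.0)])
        assert frac["diff"] == pytest.approx(0.0, abs=1e-9)
        assert frac["lsc"] == pytest.approx(0.04, rel=1e-6)
        assert frac["basal"] == pytest.approx(0.275, rel=1e-6)

    def test_replicate_noise_cv_recovered(self, panel):
        truth = GroundTruth(seeding=20_000, replicate_cv=0.10)
        ss = np.random.SeedSequence(9).spawn(80)
        sizes = np.array([len(simulate_well(truth, {"treatment": []}, panel, c))
                          for c in ss], dtype=float)
        cv = sizes.std(ddof=1) / sizes.mean()
        # seeding CV 0.10 dominates the multinomial component at n=20,000
        assert 0.07 < cv < 0.13


class TestPlate:
    def test_fixed_ratio_series_spans_four_decades_at_ratio_20(self):
        series = build_fixed_ratio_series(1.0, 20.0, 5, 10.0)
        firsts = [a for a, _ in series]
        assert firsts == pytest.approx([1.0, 0.1, 0.01, 0.001, 0.0001])
        for a, b in series:
            assert b == pytest.approx(20.0 * a)  # ratio preserved exactly

    def test_fixed_ratio_series_two_points(self):
        assert build_fixed_ratio_series(1.0, 1.0, 2, 2.0) == [(1.0, 1.0), (0.5, 0.5)]

    @pytest.mark.parametrize("kwargs", [
        dict(base_conc=0.0, ratio=1, n_points=2, fold=2),
        dict(base_conc=1.0, ratio=-1, n_points=2, fold=2),
        dict(base_conc=1.0, ratio=1, n_points=1, fold=2),
        dict(base_conc=1.0, ratio=1, n_points=2, fold=1.0),
    ])
    def test_fixed_ratio_series_rejects_bad_parameters(self, kwargs):
        with pytest.raises(ValueError):
            build_fixed_ratio_series(**kwargs)

    def test_plate_reproducible_and_seed_sensitive(self, backbone_truth):
        cfg = PlateConfig(truth=backbone_truth,
                          arms=[[("dnr", 0.1), ("arac", 2.0)]],
                          vehicle_replicates=2, treated_replicates=1)
        ev1, lay1, _ = simulate_plate(cfg, seed=21)
        ev2, lay2, _ = simulate_plate(cfg, seed=21)
        ev3, _, _ = simulate_plate(cfg, seed=22)
        pd.testing.assert_frame_equal(lay1, lay2)
        for w in ev1:
            pd.testing.assert_frame_equal(ev1[w], ev2[w])
        assert any(not ev1[w].equals(ev3[w]) for w in ev1)

    def test_vehicle_only_plate_wells_exchangeable(self, panel):
        truth = GroundTruth(seeding=5000, replicate_cv=0.0)
        cfg = PlateConfig(truth=truth, arms=[], vehicle_replicates=6,
                          treated_replicates=0)
        events, layout, _ = simulate_plate(cfg, seed=2)
        assert set(layout["role"]) == {"vehicle"}
        viable = np.array([(ev["label"] != "dead").sum() for ev in events.values()],
                          dtype=float)
        p = 1 - truth.dead_fraction
        sd = np.sqrt(5000 * p * (1 - p))
        assert np.all(np.abs(viable - 5000 * p) < 5 * sd)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg_yaml = tmp_path / "plate.yaml"
        cfg_yaml.write_text("""
samples: [SLS305]
seeding: 2000
replicate_cv: 0.0
vehicle_replicates: 2
treated_replicates: 1
drugs:
  DNR: {kill: {bulk: {emax: 0.9, ec50: 0.1}}}
  AraC: {kill: {bulk: {emax: 0.8, ec50: 2.0}}}
treatments:
  - series: {drugs: [DNR, AraC], top: 1.0, ratio: 20, points: 5, fold: 10}
""")
        cfg = load_plate_config(cfg_yaml)
        assert len(cfg.arms) == 5
        for (d1, c1), (d2, c2) in cfg.arms:
            assert (d1, d2) == ("DNR", "AraC")
            assert c2 == pytest.approx(20 * c1)
        events, layout, _ = simulate_plate(cfg, seed=1)
        assert len(events) == 2 + 5  # vehicles + one replicate per dose

    def test_malformed_config_errors(self):
        with pytest.raises(ValueError):
            load_plate_config({"treatments": [{"bogus": 1}]})

    def test_layout_requires_vehicle_wells(self, backbone_truth):
        cfg = PlateConfig(truth=backbone_truth, arms=[[("dnr", 1.0)]],
                          vehicle_replicates=0, treated_replicates=1)
        with pytest.raises(ValueError, match="no vehicle"):
            build_layout(cfg)


class TestValidation:
    def test_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError):
            GroundTruth(fractions={"stroma": 0.5, "lymphocyte": 0.5,
                                   "lsc": 0.5, "diff": 0.1, "basal": 0.1})

    def test_hill_parameter_bounds(self):
        with pytest.raises(ValueError):
            Hill(1.5, 1.0)
        with pytest.raises(ValueError):
            Hill(0.5, -1.0)
        with pytest.raises(ValueError):
            Hill(0.5, 1.0, 0.0)

    def test_panel_requires_distinct_channels_and_ordered_means(self):
        from nichescreen.panel import ChannelModel, PanelMap
        with pytest.raises(ValueError):
            ChannelModel("X", negative_mean=3.0, positive_mean=1.0)
        chans = {m: "SAME" for m in
                 ("viability", "gfp", "cd45", "gpr56", "diff", "lymph")}
        with pytest.raises(ValueError):
            PanelMap(channels=chans)
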