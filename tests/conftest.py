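import numpy as np
import pytest

from nichescreen import (
    DrugEffect,
    GroundTruth,
    Hill,
    PlateConfig,
    default_panel,
    simulate_plate,
)


@pytest.fixture(scope="session")
def panel():
    """Default six-marker panel (means 1.0/3.0, sd 0.25)."""
    return default_panel()


@pytest.fixture(scope="session")
def truth_quiet():
    """Noise-free ground truth at the screen's seeding scale."""
    return GroundTruth(replicate_cv=0.0)


@pytest.fixture(scope="session")
def backbone_truth():
    """Two-drug cytotoxic backbone with distinct potencies."""
    return GroundTruth(
        seeding=5000, replicate_cv=0.0,
        drugs={
            "dnr": DrugEffect(kill={"bulk": Hill(0.9, 0.1)}),
            "arac": DrugEffect(kill={"bulk": Hill(0.8, 2.0)}),
        })


@pytest.fixture(scope="session")
def gated_plate(backbone_truth):
    """A simulated, gated and normalized backbone dilution plate."""
    from nichescreen import estimate_thresholds, normalize_plate
    from nichescreen.activity import build_fixed_ratio_series
    from nichescreen.gating import gate_plate

    cfg = PlateConfig(
        truth=backbone_truth,
        arms=[[("dnr", c), ("arac", r)]
              for c, r in build_fixed_ratio_series(1.0, 20, 5, 10)],
        vehicle_replicates=3, treated_replicates=3)
    events, layout, truth = simulate_plate(cfg, seed=11)
    vehicle = layout.loc[layout["role"] == "vehicle", "well"]
    thresholds = estimate_thresholds([events[w] for w in vehicle], cfg.panel)
    counts = gate_plate(events, thresholds, cfg.panel)
    readouts = normalize_plate(counts, layout)
    return {"config": cfg, "events": events, "layout": layout, "truth": truth,
            "thresholds": thresholds, "counts": counts, "readouts": readouts}


def label_fractions(events):
    """Ground-truth label counts of one simulated event table."""
    return events["label"].value_counts().to_dict()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
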