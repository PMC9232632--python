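"""Synthetic plate generator with known ground truth.

Emulates a niche-like ex vivo drug screen on primary AML mononuclear cells:
each well is seeded at 50,000 cells and contains GFP+ stromal feeder cells,
CD3/CD19+ lymphocytes and a leukemic bulk partitioned into a GPR56+/Diff-
stem-enriched state (LSC), a GPR56-/Diff+ differentiating state (DIFF) and a
GPR56-/Diff- basal blast state.  Drugs act through per-population Hill
survival models (cytotoxic / stemness-depleting) and an optional
differentiation-induction model that moves basal and LSC events into the
Diff+ state before survival is applied.  Technical replicate noise is a
multiplicative log-normal factor on the seeding count.

All randomness flows from one integer seed: ``simulate_plate`` builds a
``numpy.random.SeedSequence`` from it and spawns one child per well in layout
order, so the same seed always reproduces the same plate and different wells
are independent streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .activity import build_fixed_ratio_series, compute_aoc
from .panel import MARKERS, PanelMap, default_panel

#: viable ground-truth populations (dead completes the seeding)
POPULATIONS = ("stroma", "lymphocyte", "lsc", "diff", "basal")

#: markers that are positive in each population (all others negative)
POSITIVE_MARKERS = {
    "stroma": frozenset({"gfp"}),
    "lymphocyte": frozenset({"cd45", "lymph"}),
    "lsc": frozenset({"cd45", "gpr56"}),
    "diff": frozenset({"cd45", "diff"}),
    "basal": frozenset({"cd45"}),
    "dp": frozenset({"cd45", "gpr56", "diff"}),  # GPR56+/Diff+ double positive
}

#: populations composing the leukemic bulk
BULK_POPULATIONS = ("lsc", "diff", "basal", "dp")


@dataclass(frozen=True)
class Hill:
    """Saturating concentration-effect model e(c) = emax * c^h / (c^h + ec50^h)."""

    emax: float
    ec50: float
    slope: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.emax <= 1.0:
            raise ValueError(f"emax must lie in [0, 1], got {self.emax}")
        if self.ec50 <= 0 or self.slope <= 0:
            raise ValueError("ec50 and slope must be strictly positive")

    def effect(self, conc: float) -> float:
        if conc < 0:
            raise ValueError(f"negative concentration: {conc}")
        if conc == 0.0:
            return 0.0
        ch = conc ** self.slope
        return self.emax * ch / (ch + self.ec50 ** self.slope)


@dataclass
class DrugEffect:
    """State-specific action of one drug.

    ``kill`` maps population -> Hill giving the maximal killed fraction; the
    pseudo-population key ``"bulk"`` expands to all four leukemic states.
    ``differentiation`` moves basal and LSC events into the Diff+ state
    (applied before survival); transitioning LSC events keep GPR56 with
    probability ``gpr56_retention`` (becoming double positives) and otherwise
    land in DIFF.
    """

    kill: dict = field(default_factory=dict)
    differentiation: Hill | None = None
    gpr56_retention: float = 0.0

    def __post_init__(self) -> None:
        expanded = {}
        for pop, hill in self.kill.items():
            if pop == "bulk":
                for p in BULK_POPULATIONS:
                    expanded.setdefault(p, hill)
            else:
                if pop not in POPULATIONS and pop != "dp":
                    raise ValueError(f"unknown population in kill model: {pop}")
                expanded[pop] = hill
        self.kill = expanded
        if not 0.0 <= self.gpr56_retention <= 1.0:
            raise ValueError("gpr56_retention must lie in [0, 1]")

    def survival(self, pop: str, conc: float) -> float:
        hill = self.kill.get(pop)
        return 1.0 if hill is None else 1.0 - hill.effect(conc)

    def transition(self, conc: float) -> float:
        return 0.0 if self.differentiation is None else self.differentiation.effect(conc)


@dataclass
class GroundTruth:
    """Well composition and drug-effect models used by the generator."""

    fractions: dict = field(default_factory=lambda: {
        "stroma": 0.05, "lymphocyte": 0.10,
        "lsc": 0.08, "diff": 0.12, "basal": 0.55,
    })
    seeding: int = 50_000
    replicate_cv: float = 0.10
    drugs: dict = field(default_factory=dict)
    acquired_fraction: float = 1.0

    def __post_init__(self) -> None:
        missing = [p for p in POPULATIONS if p not in self.fractions]
        if missing:
            raise ValueError(f"fractions missing populations: {missing}")
        vals = [self.fractions[p] for p in POPULATIONS]
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(vals) > 1.0 + 1e-12:
            raise ValueError("viable fractions must sum to at most 1")
        if not (isinstance(self.seeding, (int, np.integer)) and self.seeding > 0):
            raise ValueError("seeding must be a positive integer")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be non-negative")
        if not 0.0 < self.acquired_fraction <= 1.0:
            raise ValueError("acquired_fraction must lie in (0, 1]")

    @property
    def dead_fraction(self) -> float:
        return 1.0 - sum(self.fractions[p] for p in POPULATIONS)


def expected_viable_fractions(truth: GroundTruth, treatment) -> dict:
    """Closed-form expected viable fraction of seeded cells per population.

    ``treatment`` is a list of ``(drug_id, concentration)`` pairs.
    Differentiation transitions are applied before survival, matching the
    stochastic generator, so this is the exact expectation of the simulated
    counts divided by the (noise-free) seeding count.
    """
    frac = {p: truth.fractions[p] for p in POPULATIONS}
    frac["dp"] = 0.0
    effects = []
    for drug_id, conc in treatment:
        if drug_id not in truth.drugs:
            raise KeyError(f"unknown drug id: {drug_id}")
        if conc < 0:
            raise ValueError(f"negative concentration for {drug_id}: {conc}")
        effects.append((truth.drugs[drug_id], conc))

    # combined transition probability across drugs
    stay = 1.0
    retention_num = 0.0
    for eff, conc in effects:
        t = eff.transition(conc)
        retention_num += t * eff.gpr56_retention
        stay *= 1.0 - t
    moved = 1.0 - stay
    # retention prob of the (first-order) blended transition models
    p_ret = 0.0
    if moved > 0:
        tot = sum(eff.transition(conc) for eff, conc in effects)
        p_ret = retention_num / tot if tot > 0 else 0.0

    moved_lsc = frac["lsc"] * moved
    moved_basal = frac["basal"] * moved
    frac["lsc"] -= moved_lsc
    frac["basal"] -= moved_basal
    frac["dp"] += moved_lsc * p_ret
    frac["diff"] += moved_lsc * (1.0 - p_ret) + moved_basal

    for pop in list(frac):
        s = 1.0
        for eff, conc in effects:
            s *= eff.survival(pop, conc)
        frac[pop] *= s
    return frac


def _draw_intensities(rng, panel: PanelMap, pop: str, n: int, dead: bool) -> dict:
    """Log-intensity draws for ``n`` events of one population."""
    out = {}
    positives = POSITIVE_MARKERS[pop]
    for marker in MARKERS:
        cm = panel.model_of(marker)
        if marker == "viability":
            mean = cm.positive_mean if dead else cm.negative_mean
        else:
            mean = cm.positive_mean if marker in positives else cm.negative_mean
        out[cm.channel] = rng.normal(mean, cm.sd, size=n)
    return out


def simulate_well(truth: GroundTruth, layout_entry, panel: PanelMap, seed) -> pd.DataFrame:
    """Simulate one well's event table.

    ``layout_entry`` is a mapping with at least ``treatment`` (list of
    ``(drug_id, concentration)`` pairs; empty for vehicle wells).  ``seed``
    may be an int, a ``SeedSequence`` or a ``Generator``.  The returned frame
    has one row per acquired event, one column per panel channel, plus a
    ground-truth ``label`` column ("dead" or the viable population) that
    downstream gating never reads.
    """
    rng = np.random.default_rng(seed)
    treatment = list(layout_entry.get("treatment", []) or [])
    for drug_id, conc in treatment:
        if drug_id not in truth.drugs:
            raise KeyError(f"unknown drug id: {drug_id}")
        if conc < 0:
            raise ValueError(f"negative concentration for {drug_id}: {conc}")

    # technical replicate noise on the realized seeding count
    if truth.replicate_cv > 0:
        sigma = np.sqrt(np.log1p(truth.replicate_cv ** 2))
        factor = rng.lognormal(-0.5 * sigma ** 2, sigma)
    else:
        factor = 1.0
    n_seeded = max(1, int(round(truth.seeding * factor)))

    probs = [truth.fractions[p] for p in POPULATIONS] + [truth.dead_fraction]
    counts = rng.multinomial(n_seeded, probs)
    viable = dict(zip(POPULATIONS, counts[:-1]))
    viable["dp"] = 0
    baseline_dead = int(counts[-1])

    effects = [(truth.drugs[d], c) for d, c in treatment]

    # differentiation induction first: basal/LSC -> Diff+ states
    stay = 1.0
    for eff, conc in effects:
        stay *= 1.0 - eff.transition(conc)
    moved_p = 1.0 - stay
    if moved_p > 0:
        tot = sum(eff.transition(conc) for eff, conc in effects)
        p_ret = (sum(eff.transition(conc) * eff.gpr56_retention for eff, conc in effects)
                 / tot) if tot > 0 else 0.0
        m_lsc = rng.binomial(viable["lsc"], moved_p)
        m_basal = rng.binomial(viable["basal"], moved_p)
        kept = rng.binomial(m_lsc, p_ret)
        viable["lsc"] -= m_lsc
        viable["basal"] -= m_basal
        viable["dp"] += kept
        viable["diff"] += (m_lsc - kept) + m_basal

    # survival, with killed cells joining the dead pool (source tracked for staining)
    dead_by_source = {"baseline": baseline_dead}
    for pop in list(viable):
        s = 1.0
        for eff, conc in effects:
            s *= eff.survival(pop, conc)
        survivors = rng.binomial(viable[pop], s)
        killed = viable[pop] - survivors
        viable[pop] = survivors
        if killed:
            dead_by_source[pop] = killed

    # assemble event blocks
    blocks = []
    for pop, n in viable.items():
        n = int(rng.binomial(n, truth.acquired_fraction)) if truth.acquired_fraction < 1 else int(n)
        if n == 0:
            continue
        cols = _draw_intensities(rng, panel, pop, n, dead=False)
        cols["label"] = np.repeat(pop, n)
        blocks.append(pd.DataFrame(cols))
    for src, n in dead_by_source.items():
        n = int(rng.binomial(n, truth.acquired_fraction)) if truth.acquired_fraction < 1 else int(n)
        if n == 0:
            continue
        pop = "basal" if src == "baseline" else src
        cols = _draw_intensities(rng, panel, pop, n, dead=True)
        cols["label"] = np.repeat("dead", n)
        blocks.append(pd.DataFrame(cols))

    if not blocks:
        return pd.DataFrame(columns=panel.channel_names() + ["label"])
    events = pd.concat(blocks, ignore_index=True)
    order = rng.permutation(len(events))
    return events.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# plate-level simulation


@dataclass
class PlateConfig:
    """Declarative plate description consumed by :func:`simulate_plate`.

    ``arms`` is a list of treatment arms; each arm is a list of
    ``(drug_id, concentration)`` pairs applied together to one well.
    """

    samples: list = field(default_factory=lambda: ["S1"])
    truth: GroundTruth = field(default_factory=GroundTruth)
    panel: PanelMap = field(default_factory=default_panel)
    arms: list = field(default_factory=list)
    vehicle_replicates: int = 3
    treated_replicates: int = 3
    units: str = "nM"


def _arm_from_config(entry) -> list:
    """One config entry -> list of arms (a dilution series yields several)."""
    if "series" in entry:
        s = entry["series"]
        drugs = s["drugs"] if isinstance(s["drugs"], list) else [s["drugs"]]
        n, fold, top = int(s.get("points", 5)), float(s.get("fold", 10)), float(s["top"])
        if len(drugs) == 2:
            ratio = float(s.get("ratio", 1.0))
            pairs = build_fixed_ratio_series(top, ratio, n, fold)
            arms = [[(drugs[0], a), (drugs[1], b)] for a, b in pairs]
        elif len(drugs) == 1:
            arms = [[(drugs[0], top / fold ** k)] for k in range(n)]
        else:
            raise ValueError("series supports one or two drugs")
        extra = [(d, float(c)) for d, c in (s.get("plus") or [])]
        return [arm + extra for arm in arms]
    if "treatment" in entry:
        return [[(d, float(c)) for d, c in entry["treatment"]]]
    raise ValueError(f"malformed treatment entry: {entry!r}")


def load_plate_config(source) -> PlateConfig:
    """Build a :class:`PlateConfig` from a YAML file path or a dict."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    drugs = {}
    for name, spec in (raw.get("drugs") or {}).items():
        kill = {pop: Hill(**h) for pop, h in (spec.get("kill") or {}).items()}
        diff = Hill(**spec["differentiation"]) if spec.get("differentiation") else None
        drugs[name] = DrugEffect(kill=kill, differentiation=diff,
                                 gpr56_retention=float(spec.get("gpr56_retention", 0.0)))
    truth_kw = {k: raw[k] for k in
                ("fractions", "seeding", "replicate_cv", "acquired_fraction") if k in raw}
    truth = GroundTruth(drugs=drugs, **truth_kw)
    panel = default_panel(**raw["panel"]) if "panel" in raw else default_panel()
    arms = []
    for entry in raw.get("treatments", []):
        arms.extend(_arm_from_config(entry))
    return PlateConfig(
        samples=list(raw.get("samples", ["S1"])), truth=truth, panel=panel,
        arms=arms,
        vehicle_replicates=int(raw.get("vehicle_replicates", 3)),
        treated_replicates=int(raw.get("treated_replicates", 3)),
        units=str(raw.get("units", "nM")),
    )


def _well_name(i: int) -> str:
    return f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}"


def build_layout(config: PlateConfig) -> pd.DataFrame:
    """Deterministic layout: vehicle wells first, then arms, per sample."""
    rows = []
    i = 0
    for sample in config.samples:
        for r in range(config.vehicle_replicates):
            rows.append({"well": _well_name(i), "sample": sample, "role": "vehicle",
                         "replicate": r + 1, "drugs": "", "concentrations": "",
                         "units": config.units})
            i += 1
        for arm in config.arms:
            for r in range(config.treated_replicates):
                rows.append({
                    "well": _well_name(i), "sample": sample, "role": "treated",
                    "replicate": r + 1,
                    "drugs": "|".join(d for d, _ in arm),
                    "concentrations": "|".join(repr(float(c)) for _, c in arm),
                    "units": config.units})
                i += 1
    layout = pd.DataFrame(rows)
    _validate_layout(layout)
    return layout


def _validate_layout(layout: pd.DataFrame) -> None:
    for sample, grp in layout.groupby("sample"):
        if not (grp["role"] == "vehicle").any():
            raise ValueError(f"sample {sample} has no vehicle well")
    for _, row in layout.iterrows():
        t = parse_treatment(row)
        if row["role"] == "vehicle" and t:
            raise ValueError(f"vehicle well {row['well']} carries a drug")
        if any(c < 0 for _, c in t):
            raise ValueError(f"negative concentration in well {row['well']}")


def parse_treatment(layout_row) -> list:
    """Decode the ``drugs``/``concentrations`` columns of one layout row."""
    drugs = str(layout_row["drugs"]) if pd.notna(layout_row["drugs"]) else ""
    if not drugs:
        return []
    concs = [float(c) for c in str(layout_row["concentrations"]).split("|")]
    return list(zip(drugs.split("|"), concs))


def condition_id(layout_row) -> str:
    """Canonical condition key: sample + treatment, ignoring replicate."""
    t = parse_treatment(layout_row)
    if not t:
        return f"{layout_row['sample']}|vehicle"
    body = ";".join(f"{d}@{c:g}" for d, c in t)
    return f"{layout_row['sample']}|{body}"


def simulate_plate(config, seed: int):
    """Simulate every well of a plate.

    Returns ``(events, layout, truth)`` where ``events`` maps well id to an
    event table.  Deterministic given ``seed``: one ``SeedSequence`` child is
    spawned per well in layout order.
    """
    if not isinstance(config, PlateConfig):
        config = load_plate_config(config)
    layout = build_layout(config)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(len(layout))
    events = {}
    for (_, row), child in zip(layout.iterrows(), children):
        entry = {"treatment": parse_treatment(row)}
        events[row["well"]] = simulate_well(config.truth, entry, config.panel, child)
    return events, layout, config.truth


def truth_sidecar(truth: GroundTruth) -> dict:
    """JSON-serializable ground-truth description for recovery tests."""
    return {
        "fractions": dict(truth.fractions),
        "seeding": int(truth.seeding),
        "replicate_cv": truth.replicate_cv,
        "acquired_fraction": truth.acquired_fraction,
        "drugs": {
            name: {
                "kill": {pop: vars(h) for pop, h in eff.kill.items()},
                "differentiation": vars(eff.differentiation) if eff.differentiation else None,
                "gpr56_retention": eff.gpr56_retention,
            } for name, eff in truth.drugs.items()
        },
    }


def save_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_sidecar(truth), fh, indent=2)


# ---------------------------------------------------------------------------
# readout-level simulators for recovery studies
#
# These sample directly from the generator's closed-form expectations
# (expected_viable_fractions / Hill survival) with replicate noise, skipping
# event-level sampling so that many-replicate recovery studies stay cheap.


ARCHETYPES = ("cytotoxic", "stemness_specific", "differentiating")


def _archetype_effect(kind: str, jitter: float) -> DrugEffect:
    e = jitter  # small per-drug perturbation of maximal effects
    if kind == "cytotoxic":
        return DrugEffect(kill={
            "basal": Hill(0.75 + e, 1.0), "diff": Hill(0.75 + e, 1.0),
            "dp": Hill(0.75 + e, 1.0), "lsc": Hill(0.55 + e, 1.0)})
    if kind == "stemness_specific":
        return DrugEffect(kill={"lsc": Hill(0.75 + e, 1.0),
                                "basal": Hill(0.05, 1.0), "diff": Hill(0.05, 1.0)})
    if kind == "differentiating":
        return DrugEffect(kill={"bulk": Hill(0.10, 1.0)},
                          differentiation=Hill(0.60 + e, 1.0))
    raise ValueError(f"unknown archetype: {kind}")


def simulate_archetype_readouts(n_per_archetype: int = 5, seed=0,
                                dose: float = 10.0,
                                bulk_noise_sd: float = 0.04,
                                prop_noise_sd: float = 0.015):
    """Fixed-dose readout triples for drugs drawn from the three archetypes.

    Returns ``(readouts, labels)``: a drugs x (bulk_ratio, prop_lsc,
    prop_diff) frame plus the generating archetype per drug.  Readouts are
    the generator's expected values at ``dose`` (about 10x EC50, i.e. near
    maximal effect) with Gaussian replicate noise.
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    bulk0 = sum(truth.fractions[p] for p in ("lsc", "diff", "basal"))
    rows, labels = [], {}
    for kind in ARCHETYPES:
        for i in range(n_per_archetype):
            name = f"{kind[:4]}_{i + 1}"
            eff = _archetype_effect(kind, rng.uniform(-0.05, 0.05))
            t = GroundTruth(drugs={"d": eff})
            frac = expected_viable_fractions(t, [("d", dose)])
            bulk = sum(frac[p] for p in BULK_POPULATIONS)
            rows.append({
                "drug": name,
                "bulk_ratio": bulk / bulk0 + rng.normal(0, bulk_noise_sd),
                "prop_lsc": (frac["lsc"] + frac["dp"]) / bulk + rng.normal(0, prop_noise_sd),
                "prop_diff": frac["diff"] / bulk + rng.normal(0, prop_noise_sd),
            })
            labels[name] = kind
    readouts = pd.DataFrame(rows).set_index("drug")
    return readouts, pd.Series(labels, name="archetype")


def simulate_benefit_screen(n_patients: int = 20, n_agents: int = 23,
                            effect_agent: str | None = "agent_01",
                            effect_emax: float = 0.3,
                            noise_sd: float = 0.1,
                            n_replicates: int = 3,
                            seed=0) -> pd.DataFrame:
    """Simulate per-patient LSC AOC values for a backbone +/- third agents.

    Each patient carries a Hill dose-response of the LSC count to a 5-point
    fixed-ratio backbone series; ``effect_agent`` multiplies LSC survival by
    ``1 - effect_emax`` at its fixed low dose while every other agent adds
    nothing.  Gaussian replicate noise of ``noise_sd`` is applied to each
    normalized value and averaged over ``n_replicates`` technical replicates
    before AOC integration, mirroring the screening design.

    Returns a long frame (patient, arm, aoc) with arm ``"backbone"`` or the
    agent id, suitable for :func:`nichescreen.stats.combination_benefit`.
    """
    rng = np.random.default_rng(seed)
    pairs = build_fixed_ratio_series(1.0, 20.0, 5, 10.0)
    conc = np.array(sorted(c for c, _ in pairs))  # ascending first component
    agents = [f"agent_{i + 1:02d}" for i in range(n_agents)]
    if effect_agent is not None and effect_agent not in agents:
        raise ValueError(f"effect agent {effect_agent!r} not among agents")
    rows = []
    for p in range(n_patients):
        patient = f"P{p + 1:02d}"
        hill = Hill(emax=rng.uniform(0.6, 0.9),
                    ec50=10 ** rng.uniform(-2.5, -0.5), slope=1.0)
        v_back = np.array([1.0 - hill.effect(c) for c in conc])
        for arm, extra in [("backbone", 0.0)] + [
                (a, effect_emax if a == effect_agent else 0.0) for a in agents]:
            v = v_back * (1.0 - extra)
            v_obs = (v[None, :] + rng.normal(0, noise_sd, (n_replicates, conc.size))
                     ).mean(axis=0)
            aoc = compute_aoc(conc, v_obs).value
            rows.append({"patient": patient, "arm": arm, "aoc": aoc})
    return pd.DataFrame(rows)
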