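"""Automated hierarchical gating.

Reproduces the screen's manual gating tree deterministically:

    all events -> viable (viability stain low; the fixable stain labels
    dead cells) -> GFP- (stromal feeder exclusion) -> lymphocytes
    (CD3/CD19 dump high) vs leukemic bulk -> GPR56 x Diff quadrants
    (LSC = GPR56+/Diff-, DIFF = GPR56-/Diff+, basal = double negative,
    plus GPR56+/Diff+ double positives counted inside bulk only).

Per-channel cutoffs are estimated from pooled vehicle-well events by a
two-component one-dimensional Gaussian mixture fitted by EM with fixed
initialization (component means at the 25th/75th percentiles), with the
cutoff placed at the equal-posterior point between the components.  Every
cutoff can be overridden from configuration; overrides always win and are
flagged as such in the audit trail.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MARKERS, PanelMap

#: terminal leukemic-bulk populations in reporting order
QUADRANTS = ("lsc", "diff", "basal", "double_positive")


@dataclass
class GateThresholds:
    """Per-marker scalar cutoffs on log intensity with provenance."""

    cutoffs: dict
    provenance: dict = field(default_factory=dict)
    components: dict = field(default_factory=dict)  # marker -> fitted mixture

    def __post_init__(self) -> None:
        for marker, cut in self.cutoffs.items():
            if not math.isfinite(cut):
                raise ValueError(f"non-finite cutoff for {marker}")
            self.provenance.setdefault(marker, "configured")

    def to_json(self, path) -> None:
        payload = {
            m: {"cutoff": float(self.cutoffs[m]),
                "provenance": self.provenance[m],
                **({"mixture": self.components[m]} if m in self.components else {})}
            for m in self.cutoffs
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GateThresholds":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            cutoffs={m: d["cutoff"] for m, d in payload.items()},
            provenance={m: d["provenance"] for m, d in payload.items()},
            components={m: d["mixture"] for m, d in payload.items() if "mixture" in d},
        )


@dataclass
class WellCounts:
    """Viable cell counts per gated population for one well.

    Invariants (checked): bulk = lsc + diff + basal + double_positive and
    lymphocytes + bulk = viable GFP- events.
    """

    well: str
    total: int
    viable: int
    gfp_negative: int
    lymphocytes: int
    bulk: int
    lsc: int
    diff: int
    basal: int
    double_positive: int

    def __post_init__(self) -> None:
        fields = ("total", "viable", "gfp_negative", "lymphocytes", "bulk",
                  "lsc", "diff", "basal", "double_positive")
        for f in fields:
            v = getattr(self, f)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{f} must be a non-negative integer, got {v!r}")
        if self.bulk != self.lsc + self.diff + self.basal + self.double_positive:
            raise ValueError("bulk must equal the sum of its quadrants")
        if self.lymphocytes + self.bulk != self.gfp_negative:
            raise ValueError("lymphocytes + bulk must equal viable GFP- events")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("well", "total", "viable", "gfp_negative", "lymphocytes",
                 "bulk", "lsc", "diff", "basal", "double_positive")}


# ---------------------------------------------------------------------------
# threshold estimation


def _em_two_gaussians(x: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    """Two-component 1-D Gaussian mixture by EM, deterministically initialized.

    Means start at the 25th/75th percentiles, both variances at the pooled
    variance, weights at 0.5.  Returns (weights, means, sds) with means
    sorted ascending.
    """
    q25, q75 = np.percentile(x, [25, 75])
    mu = np.array([q25, q75], dtype=float)
    var = np.full(2, max(x.var(), 1e-12))
    w = np.array([0.5, 0.5])
    ll_prev = -np.inf
    for _ in range(max_iter):
        # E step in log space for stability
        log_p = (np.log(w)[:, None]
                 - 0.5 * np.log(2 * np.pi * var)[:, None]
                 - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None])
        m = log_p.max(axis=0)
        lse = m + np.log(np.exp(log_p - m).sum(axis=0))
        resp = np.exp(log_p - lse)
        nk = resp.sum(axis=1)
        if np.any(nk < 1e-10):
            break
        w = nk / x.size
        mu = resp @ x / nk
        var = np.maximum((resp * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk,
                         1e-12)
        ll = lse.sum()
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            break
        ll_prev = ll
    # final log-likelihood at the returned parameters
    log_p = (np.log(w)[:, None]
             - 0.5 * np.log(2 * np.pi * var)[:, None]
             - 0.5 * (x[None, :] - mu[:, None]) ** 2 / var[:, None])
    m = log_p.max(axis=0)
    ll = float((m + np.log(np.exp(log_p - m).sum(axis=0))).sum())
    order = np.argsort(mu)
    return w[order], mu[order], np.sqrt(var[order]), ll


def _equal_posterior_cutoff(w, mu, sd):
    """Point between the component means with equal posterior probability.

    Solves w0 N(x; mu0, sd0) = w1 N(x; mu1, sd1) (a quadratic in x) and
    returns the root strictly between the means; falls back to the midpoint
    of the component medians (= means for Gaussians) if no root is bracketed.
    """
    a = 1.0 / sd[0] ** 2 - 1.0 / sd[1] ** 2
    b = -2.0 * (mu[0] / sd[0] ** 2 - mu[1] / sd[1] ** 2)
    c = (mu[0] ** 2 / sd[0] ** 2 - mu[1] ** 2 / sd[1] ** 2
         - 2.0 * (np.log(w[0] / sd[0]) - np.log(w[1] / sd[1])))
    lo, hi = mu[0], mu[1]
    roots = []
    if abs(a) < 1e-14:
        if abs(b) > 1e-300:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    bracketed = [r for r in roots if lo < r < hi]
    if bracketed:
        return float(bracketed[0])
    return float(0.5 * (mu[0] + mu[1]))


def estimate_thresholds(vehicle_events, panel: PanelMap, overrides=None,
                        min_events: int = 100,
                        min_separation: float = 1e-6) -> GateThresholds:
    """Estimate per-marker cutoffs from pooled vehicle-well events.

    ``vehicle_events`` is one event table or a collection of them; at least
    ``min_events`` pooled events are required.  The viability cutoff is
    estimated on all events; the remaining markers are estimated on viable
    events only (live-gated), which mirrors the gating hierarchy.  Entries in
    ``overrides`` (marker -> cutoff) bypass estimation and are flagged with
    provenance "configured".  A channel whose pooled intensities are
    degenerate (near-zero spread or collapsed mixture components) raises
    unless an override is supplied.
    """
    overrides = dict(overrides or {})
    if isinstance(vehicle_events, pd.DataFrame):
        vehicle_events = [vehicle_events]
    tables = [t for t in vehicle_events if len(t)]
    if not tables:
        raise ValueError("no vehicle events supplied")
    pooled = pd.concat(tables, ignore_index=True)

    cutoffs, provenance, components = {}, {}, {}

    def fit_marker(marker: str, values: np.ndarray) -> None:
        if marker in overrides:
            cutoffs[marker] = float(overrides[marker])
            provenance[marker] = "configured"
            return
        if values.size < min_events:
            raise ValueError(
                f"{marker}: {values.size} events pooled, need >= {min_events}")
        if values.std() < min_separation:
            raise ValueError(
                f"{marker}: zero-variance channel; supply an override")
        x = values.astype(float)
        w, mu, sd, ll2 = _em_two_gaussians(x)
        # one-component alternative: reject the split if BIC prefers a
        # single Gaussian (no real positive population in the vehicle wells)
        var1 = max(x.var(), 1e-12)
        ll1 = float(-0.5 * x.size * (np.log(2 * np.pi * var1) + 1.0))
        n = x.size
        bic2 = 5 * np.log(n) - 2 * ll2
        bic1 = 2 * np.log(n) - 2 * ll1
        if bic2 >= bic1 or min(w) < 1e-3:
            raise ValueError(
                f"{marker}: no two-component structure detected "
                f"(means {mu[0]:.3g}/{mu[1]:.3g}); supply an override")
        cut = _equal_posterior_cutoff(w, mu, sd)
        if not mu[0] < cut < mu[1]:  # invariant: cutoff strictly between means
            cut = float(0.5 * (mu[0] + mu[1]))
        cutoffs[marker] = cut
        provenance[marker] = "estimated"
        components[marker] = {"weights": list(map(float, w)),
                              "means": list(map(float, mu)),
                              "sds": list(map(float, sd))}

    viab_channel = panel.channel_of("viability")
    fit_marker("viability", pooled[viab_channel].to_numpy())
    viable = pooled[pooled[viab_channel] <= cutoffs["viability"]]
    for marker in MARKERS:
        if marker == "viability":
            continue
        fit_marker(marker, viable[panel.channel_of(marker)].to_numpy())
    return GateThresholds(cutoffs=cutoffs, provenance=provenance,
                          components=components)


# ---------------------------------------------------------------------------
# gating


def gate_well(events: pd.DataFrame, thresholds: GateThresholds,
              panel: PanelMap, well: str = "", use_cd45_gate: bool = False) -> WellCounts:
    """Apply the gating hierarchy to one event table.

    Every viable GFP- event is assigned to exactly one terminal population.
    An empty table yields all-zero counts.  ``use_cd45_gate`` inserts an
    optional CD45+ requirement before the lymphocyte split (off by default;
    the default readout carries CD45 in the panel without gating on it).
    """
    needed = [panel.channel_of(m) for m in MARKERS]
    missing = [ch for ch in needed if ch not in events.columns]
    if missing and len(events):
        raise ValueError(f"missing channels: {missing}")
    if not len(events):
        return WellCounts(well, 0, 0, 0, 0, 0, 0, 0, 0, 0)

    cut = thresholds.cutoffs
    col = {m: events[panel.channel_of(m)].to_numpy() for m in MARKERS}

    viable = col["viability"] <= cut["viability"]  # stain labels dead cells
    gfp_neg = viable & (col["gfp"] <= cut["gfp"])
    if use_cd45_gate:
        gfp_neg = gfp_neg & (col["cd45"] > cut["cd45"])
    lymph = gfp_neg & (col["lymph"] > cut["lymph"])
    bulk = gfp_neg & ~lymph
    gpr56_pos = col["gpr56"] > cut["gpr56"]
    diff_pos = col["diff"] > cut["diff"]

    n_lsc = int(np.sum(bulk & gpr56_pos & ~diff_pos))
    n_diff = int(np.sum(bulk & ~gpr56_pos & diff_pos))
    n_basal = int(np.sum(bulk & ~gpr56_pos & ~diff_pos))
    n_dp = int(np.sum(bulk & gpr56_pos & diff_pos))

    return WellCounts(
        well=well, total=int(len(events)), viable=int(viable.sum()),
        gfp_negative=int(gfp_neg.sum()), lymphocytes=int(lymph.sum()),
        bulk=int(bulk.sum()), lsc=n_lsc, diff=n_diff, basal=n_basal,
        double_positive=n_dp)


def assign_events(events: pd.DataFrame, thresholds: GateThresholds,
                  panel: PanelMap, use_cd45_gate: bool = False) -> pd.Series:
    """Per-event population assignment mirroring :func:`gate_well`.

    Labels: "dead", "stroma", "lymphocyte", "lsc", "diff", "basal", "dp".
    Used for event-level accuracy checks against generator labels.
    """
    cut = thresholds.cutoffs
    col = {m: events[panel.channel_of(m)].to_numpy() for m in MARKERS}
    out = np.full(len(events), "unassigned", dtype=object)
    viable = col["viability"] <= cut["viability"]
    out[~viable] = "dead"
    stroma = viable & (col["gfp"] > cut["gfp"])
    out[stroma] = "stroma"
    gfp_neg = viable & ~stroma
    if use_cd45_gate:
        gfp_neg = gfp_neg & (col["cd45"] > cut["cd45"])
    lymph = gfp_neg & (col["lymph"] > cut["lymph"])
    out[lymph] = "lymphocyte"
    bulk = gfp_neg & ~lymph
    g, d = col["gpr56"] > cut["gpr56"], col["diff"] > cut["diff"]
    out[bulk & g & ~d] = "lsc"
    out[bulk & ~g & d] = "diff"
    out[bulk & g & d] = "dp"
    out[bulk & ~g & ~d] = "basal"
    return pd.Series(out, index=events.index, name="population")


def gate_plate(events_by_well: dict, thresholds: GateThresholds,
               panel: PanelMap, use_cd45_gate: bool = False) -> pd.DataFrame:
    """Gate every well; returns a counts table with one row per well."""
    rows = [gate_well(tbl, thresholds, panel, well=w, use_cd45_gate=use_cd45_gate).as_dict()
            for w, tbl in events_by_well.items()]
    return pd.DataFrame(rows)
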