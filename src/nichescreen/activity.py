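"""Drug-activity scoring.

Activity is the actual (trapezoidal) area over the dose-response curve of
vehicle-normalized cell counts — no parametric dose-response fit, and no
truncation: normalized values above 1 (outgrowth under treatment) are
integrated as-is and may drive the AOC negative.  Higher AOC means greater
drug activity.

The x-axis is log10 concentration, affinely rescaled to [0, 1] by default so
that scores are comparable across drugs screened over different dose ranges;
``rescale=False`` integrates over the raw log10 width instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DoseResponseProfile:
    """Vehicle-normalized response of one readout to one treatment.

    Concentrations must be strictly ascending and positive; values are
    normalized counts (vehicle = 1), already averaged over replicates.
    """

    concentrations: np.ndarray
    values: np.ndarray
    sample: str = ""
    drug: str = ""
    readout: str = ""
    units: str = "nM"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.concentrations.size < 2:
            raise ValueError("a profile needs at least 2 doses")
        if self.concentrations.size != self.values.size:
            raise ValueError("concentrations and values differ in length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


@dataclass
class ActivityScore:
    """An AOC (or fixed-dose) activity value with scoring metadata."""

    value: float
    readout: str = ""
    drug: str = ""
    sample: str = ""
    dose_range: tuple = (np.nan, np.nan)
    method: str = "trapezoid-untruncated"
    truncated: bool = field(default=False)


def compute_aoc(profile, values=None, rescale: bool = True, **meta) -> ActivityScore:
    """Untruncated trapezoidal area over the curve.

    Accepts a :class:`DoseResponseProfile`, or concentration and value
    arrays.  With ``rescale`` (default) x = log10(c) is affinely mapped to
    [0, 1] and AOC is the trapezoidal integral of 1 - v(x) over [0, 1]; with
    ``rescale=False`` the integral runs over the raw log10 width.  Neither
    v nor the result is clipped; v identically 1 gives 0, identically 0
    gives 1, and v > 1 can give a negative score (outgrowth).
    """
    if isinstance(profile, DoseResponseProfile):
        prof = profile
        meta = {"sample": prof.sample, "drug": prof.drug,
                "readout": prof.readout, **meta}
    else:
        prof = DoseResponseProfile(np.asarray(profile), np.asarray(values))
    x = np.log10(prof.concentrations)
    if rescale:
        x = (x - x[0]) / (x[-1] - x[0])
    aoc = float(np.trapezoid(1.0 - prof.values, x))
    return ActivityScore(
        value=aoc,
        dose_range=(float(prof.concentrations[0]), float(prof.concentrations[-1])),
        method="trapezoid-untruncated" + ("" if rescale else "-rawlog"),
        **{k: meta.get(k, "") for k in ("readout", "drug", "sample")})


def profiles_from_summary(summary: pd.DataFrame, readout: str = "bulk_ratio",
                          layout_units: str = "nM") -> list:
    """Build dose-response profiles from a replicate summary table.

    Groups the condition-level means by (sample, drug combination) and
    orders by concentration of the first listed drug.  Vehicle conditions
    anchor nothing here (they are already the normalization reference).
    """
    col = f"{readout}_mean"
    profs = []
    rows = summary[~summary["condition"].str.endswith("|vehicle")].copy()
    if rows.empty:
        return profs

    def split(cond):
        sample, body = cond.split("|", 1)
        parts = [p.split("@") for p in body.split(";")]
        drugs = "+".join(d for d, _ in parts)
        return sample, drugs, float(parts[0][1])

    parsed = rows["condition"].map(split)
    rows["_sample"] = [p[0] for p in parsed]
    rows["_drugs"] = [p[1] for p in parsed]
    rows["_conc"] = [p[2] for p in parsed]
    for (sample, drugs), grp in rows.groupby(["_sample", "_drugs"], sort=False):
        grp = grp.sort_values("_conc")
        if len(grp) < 2:
            continue
        profs.append(DoseResponseProfile(
            concentrations=grp["_conc"].to_numpy(),
            values=grp[col].to_numpy(),
            sample=sample, drug=drugs, readout=readout, units=layout_units))
    return profs


def fixed_dose_activity(treated_summary_row, vehicle_summary_row) -> dict:
    """Raw fixed-dose activity triple for one treatment vs matched vehicle.

    Returns ``bulk_activity`` = 1 - normalized bulk count, plus the signed
    within-bulk proportion deltas for the LSC and DIFF states (treated minus
    vehicle).  No scaling or sign flipping is done here; the pattern module
    owns display conventions.
    """
    t, v = treated_summary_row, vehicle_summary_row
    for row in (t, v):
        if row is None:
            raise ValueError("matched vehicle statistics are required")
    return {
        "bulk_activity": 1.0 - float(t["bulk_ratio_mean"]),
        "lsc_prop_delta": float(t["prop_lsc_mean"]) - float(v["prop_lsc_mean"]),
        "diff_prop_delta": float(t["prop_diff_mean"]) - float(v["prop_diff_mean"]),
    }


def build_fixed_ratio_series(base_conc: float, ratio: float, n_points: int,
                             fold: float) -> list:
    """Fixed-ratio two-drug dilution series, descending from ``base_conc``.

    Returns ``[(base/fold**k, ratio*base/fold**k) for k in 0..n_points-1]``;
    the screen's backbone uses a 5-point, 10-fold series at a fixed 1:20
    ratio, spanning four decades with the second component exactly 20x the
    first at every point.
    """
    if base_conc <= 0 or ratio <= 0:
        raise ValueError("base_conc and ratio must be positive")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    return [(base_conc / fold ** k, ratio * base_conc / fold ** k)
            for k in range(n_points)]


# ---------------------------------------------------------------------------
# screening-concentration selection


@dataclass
class ConcentrationPolicy:
    """PK/toxicity-bounded choice of the screening concentration.

    ``screen_max`` mode returns min(Cmax, IC40 on healthy CD34+ cells): the
    clinically relevant maximal test concentration.  ``screen_low`` returns
    min(0.2 x Cmax, IC10): the fixed low dose used for third agents on top
    of a chemotherapy backbone.  ICx values come from log-linear
    interpolation of the healthy-CD34 dose-response profile.
    """

    drug: str
    cmax: float
    cd34_profile: DoseResponseProfile
    mode: str = "screen_max"
    units: str = "nM"

    def __post_init__(self) -> None:
        if self.cmax <= 0:
            raise ValueError("Cmax must be positive")
        if self.mode not in ("screen_max", "screen_low"):
            raise ValueError("mode must be screen_max or screen_low")
        if self.units != self.cd34_profile.units:
            raise ValueError(
                f"unit mismatch: Cmax in {self.units}, CD34 profile in "
                f"{self.cd34_profile.units}")


def interpolate_icx(profile: DoseResponseProfile, inhibition_pct: float) -> float:
    """Concentration inhibiting ``inhibition_pct``% of growth.

    Finds the first dose interval (ascending) whose normalized values
    bracket the target level 1 - pct/100 and interpolates v linearly against
    log10 concentration within it.  Errors, naming the level, if no interval
    brackets the target.
    """
    target = 1.0 - inhibition_pct / 100.0
    c, v = profile.concentrations, profile.values
    for i in range(c.size - 1):
        lo, hi = v[i], v[i + 1]
        if (lo - target) * (hi - target) <= 0 and lo != hi:
            x0, x1 = np.log10(c[i]), np.log10(c[i + 1])
            frac = (lo - target) / (lo - hi)
            return float(10 ** (x0 + frac * (x1 - x0)))
        if lo == target:
            return float(c[i])
    raise ValueError(
        f"IC{inhibition_pct:g} not bracketed by the CD34 profile "
        f"(values {v.min():.3g}..{v.max():.3g}, target v={target:.3g})")


def select_screen_concentration(policy: ConcentrationPolicy) -> float:
    """Apply the concentration-selection rule for the policy's mode."""
    if policy.mode == "screen_max":
        return min(policy.cmax, interpolate_icx(policy.cd34_profile, 40.0))
    return min(0.2 * policy.cmax, interpolate_icx(policy.cd34_profile, 10.0))
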