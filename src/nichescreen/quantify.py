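"""Vehicle normalization of gated counts.

Counts in each gate are normalized to the negative-control (DMSO vehicle)
wells of the same sample: each treated well's count is divided by the
arithmetic mean (configurable to median) of that sample's vehicle wells.
Within-bulk state proportions are reported raw, computed from counts before
any normalization.  Replicate wells are kept separate here; aggregation to
condition-level mean +/- SD is a separate step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import condition_id

#: count columns that get vehicle-normalized, and their ratio names
RATIO_READOUTS = {"bulk": "bulk_ratio", "lsc": "lsc_ratio",
                  "lymphocytes": "lymph_ratio"}


def _proportions(row) -> tuple:
    bulk = row["bulk"]
    if bulk == 0:
        return np.nan, np.nan
    return row["lsc"] / bulk, row["diff"] / bulk


def normalize_plate(counts: pd.DataFrame, layout: pd.DataFrame,
                    vehicle_stat: str = "mean") -> pd.DataFrame:
    """Vehicle-normalize a plate's counts table.

    ``counts`` has one row per well (columns from
    :class:`~nichescreen.gating.WellCounts`); ``layout`` supplies sample,
    role and treatment per well.  Returns one row per well with ratio
    readouts (count / same-sample vehicle mean), raw within-bulk proportions,
    the vehicle mean used per readout, and a ``condition`` key.

    A sample with no vehicle wells is a hard error.  A readout whose vehicle
    mean is zero is flagged unusable (NaN ratio, flag column set) while the
    other readouts proceed.
    """
    if vehicle_stat not in ("mean", "median"):
        raise ValueError("vehicle_stat must be 'mean' or 'median'")
    merged = counts.merge(layout, on="well", validate="one_to_one")
    out_rows = []
    for sample, grp in merged.groupby("sample", sort=False):
        veh = grp[grp["role"] == "vehicle"]
        if veh.empty:
            raise ValueError(f"sample {sample} has no vehicle wells")
        agg = veh[list(RATIO_READOUTS)].agg(vehicle_stat)
        for _, row in grp.iterrows():
            rec = {"well": row["well"], "sample": sample, "role": row["role"],
                   "replicate": row["replicate"],
                   "condition": condition_id(row),
                   "drugs": row["drugs"], "concentrations": row["concentrations"]}
            for count_col, ratio_col in RATIO_READOUTS.items():
                vmean = float(agg[count_col])
                rec[f"vehicle_{count_col}"] = vmean
                if vmean > 0:
                    rec[ratio_col] = row[count_col] / vmean
                    rec[f"{ratio_col}_unusable"] = False
                else:
                    rec[ratio_col] = np.nan
                    rec[f"{ratio_col}_unusable"] = True
            rec["prop_lsc"], rec["prop_diff"] = _proportions(row)
            out_rows.append(rec)
    return pd.DataFrame(out_rows)


def summarize_replicates(readouts: pd.DataFrame,
                         value_cols=("bulk_ratio", "lsc_ratio", "lymph_ratio",
                                     "prop_lsc", "prop_diff")) -> pd.DataFrame:
    """Condition-level mean +/- SD over technical replicates.

    SD uses the sample convention (ddof=1); a condition observed once gets
    SD 0 with ``single_replicate`` flagged.
    """
    value_cols = [c for c in value_cols if c in readouts.columns]
    rows = []
    for (sample, condition), grp in readouts.groupby(["sample", "condition"],
                                                     sort=False):
        rec = {"sample": sample, "condition": condition, "n": len(grp),
               "single_replicate": len(grp) == 1}
        for c in value_cols:
            vals = grp[c].to_numpy(dtype=float)
            rec[f"{c}_mean"] = float(np.nanmean(vals)) if len(vals) else np.nan
            rec[f"{c}_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(rec)
    return pd.DataFrame(rows)
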