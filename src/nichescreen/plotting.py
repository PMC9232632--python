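"""Minimal plotting helpers (matplotlib)."""

from __future__ import annotations

import numpy as np

from .patterns import READOUT_COLUMNS, ScaledActivityMatrix


def plot_pattern_heatmap(scaled: ScaledActivityMatrix, assignments=None, ax=None):
    """Drugs x scaled-readouts heatmap, optionally annotated with labels."""
    import matplotlib.pyplot as plt

    mat = scaled.values
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 0.35 * len(mat) + 1))
    vmax = max(1.0, np.abs(mat.to_numpy()).max())
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(3), ["BULK", "%LSC", "%DIFF"])
    labels = dict()
    if assignments:
        labels = {a.drug: a.label for a in assignments}
    ax.set_yticks(range(len(mat)),
                  [f"{d} [{labels[d]}]" if d in labels else str(d)
                   for d in mat.index], fontsize=8)
    ax.figure.colorbar(im, ax=ax, label="scaled activity")
    return ax


def plot_dose_response(profile, score=None, ax=None):
    """One vehicle-normalized dose-response curve with its AOC in the title."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.log10(profile.concentrations), profile.values, "o-")
    ax.axhline(1.0, ls="--", c="grey", lw=0.8)
    ax.set_xlabel(f"log10 concentration ({profile.units})")
    ax.set_ylabel("normalized count")
    title = f"{profile.drug} on {profile.readout}"
    if score is not None:
        title += f"  (AOC = {score.value:.3f})"
    ax.set_title(title)
    return ax
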