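"""Flow-cytometry panel description.

The screening readout uses a six-marker panel: a fixable viability stain
(labels dead cells, so dead events are *bright*), GFP (identifies the
immortalized stromal feeder layer), CD45, GPR56 (leukemic-stem-cell
surrogate), a pooled differentiation dump channel (CD11b/CD14/CD15) and a
pooled lymphocyte dump channel (CD3/CD19).

Intensities are modelled post-compensation on a log10 scale: each channel
carries a two-component location model (negative and positive log-intensity
means with a shared spread).  No spillover is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: canonical marker keys, in gating order
MARKERS = ("viability", "gfp", "cd45", "gpr56", "diff", "lymph")

#: default physical channel names (Attune-style labels)
DEFAULT_CHANNELS = {
    "viability": "APC-Cy7-A",   # Fixable Viability Stain eFluor 780
    "gfp": "FITC-A",
    "cd45": "PerCP-Cy5-5-A",
    "gpr56": "PE-A",
    "diff": "APC-A",            # pooled CD11b/CD14/CD15
    "lymph": "BV421-A",         # pooled CD3/CD19
}


@dataclass(frozen=True)
class ChannelModel:
    """Two-component log-intensity model for one channel.

    Parameters are on the log10 scale. ``sd`` is the common spread of the
    negative and positive components; the distance from each component mean
    to the midpoint, in units of ``sd``, controls how cleanly populations
    separate.
    """

    channel: str
    negative_mean: float = 1.0
    positive_mean: float = 3.0
    sd: float = 0.25

    def __post_init__(self) -> None:
        if not self.positive_mean > self.negative_mean:
            raise ValueError(
                f"{self.channel}: positive mean ({self.positive_mean}) must "
                f"exceed negative mean ({self.negative_mean})"
            )
        if self.sd <= 0:
            raise ValueError(f"{self.channel}: sd must be positive")

    @property
    def separation_sd(self) -> float:
        """Distance between component means in units of sd."""
        return (self.positive_mean - self.negative_mean) / self.sd


@dataclass(frozen=True)
class PanelMap:
    """Marker -> channel mapping plus per-channel intensity models.

    Invariants: all six markers map to distinct channels and every channel
    model has positive mean > negative mean (enforced at construction).
    """

    channels: dict = field(default_factory=lambda: dict(DEFAULT_CHANNELS))
    models: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in MARKERS if m not in self.channels]
        if missing:
            raise ValueError(f"panel missing markers: {missing}")
        names = [self.channels[m] for m in MARKERS]
        if len(set(names)) != len(names):
            raise ValueError("markers must map to distinct channels")
        # fill in default models for unconfigured markers
        for m in MARKERS:
            if m not in self.models:
                self.models[m] = ChannelModel(channel=self.channels[m])

    def channel_of(self, marker: str) -> str:
        return self.channels[marker]

    def model_of(self, marker: str) -> ChannelModel:
        return self.models[marker]

    def channel_names(self) -> list:
        return [self.channels[m] for m in MARKERS]


def default_panel(sd: float = 0.25, negative_mean: float = 1.0,
                  positive_mean: float = 3.0) -> PanelMap:
    """Panel with identical two-component models on every channel."""
    models = {
        m: ChannelModel(DEFAULT_CHANNELS[m], negative_mean, positive_mean, sd)
        for m in MARKERS
    }
    return PanelMap(channels=dict(DEFAULT_CHANNELS), models=models)


def load_panel(path) -> PanelMap:
    """Read a panel from YAML.

    Schema::

        channels: {viability: APC-Cy7-A, ...}
        models:
          gpr56: {negative_mean: 1.0, positive_mean: 3.0, sd: 0.25}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    channels = dict(DEFAULT_CHANNELS)
    channels.update(raw.get("channels", {}))
    models = {}
    for marker, cfg in (raw.get("models") or {}).items():
        models[marker] = ChannelModel(channel=channels[marker], **cfg)
    return PanelMap(channels=channels, models=models)


def save_panel(panel: PanelMap, path) -> None:
    raw = {
        "channels": dict(panel.channels),
        "models": {
            m: {
                "negative_mean": cm.negative_mean,
                "positive_mean": cm.positive_mean,
                "sd": cm.sd,
            }
            for m, cm in panel.models.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
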