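"""Probe montage: channel definitions and anatomical region labels.

The default montage mirrors a 20-source / 16-detector neonatal whole-head
array with 52 measurement channels, symmetric between hemispheres, with a
mean source-detector separation of 2.3 cm.  Region labels (inferior frontal,
superior temporal, supramarginal, inferior parietal, angular) are montage
metadata; no spatial registration is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ChannelDef", "Montage", "make_montage", "REGION_LABELS"]

REGION_LABELS = ("IF", "ST", "SM", "IP", "angular", "other")

# Anatomical labels for the default 52-channel montage.  The left-hemisphere
# assignments follow the array's frontal/temporal/parietal coverage; the right
# hemisphere carries the mirrored set of labels (counts equal per hemisphere).
_DEFAULT_REGIONS_52 = {
    2: "IF", 6: "IF", 16: "IF",
    7: "ST", 10: "ST",
    19: "SM",
    25: "IP",
    23: "angular",
    42: "IF", 43: "IF", 44: "IF",
    33: "ST", 45: "ST",
    37: "SM",
    51: "IP",
    49: "angular",
}


@dataclass(frozen=True)
class ChannelDef:
    channel_id: int
    region_label: str
    hemisphere: str  # "left" | "right"
    source_detector_distance: float = 2.3  # cm


@dataclass(frozen=True)
class Montage:
    channels: tuple[ChannelDef, ...]
    n_sources: int = 20
    n_detectors: int = 16

    def __post_init__(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("channel_ids must be unique and contiguous from 1")
        if any(c.source_detector_distance <= 0 for c in self.channels):
            raise ValueError("source-detector distances must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[int]:
        return [c.channel_id for c in self.channels]

    def channel(self, channel_id: int) -> ChannelDef:
        try:
            ch = self.channels[channel_id - 1]
        except IndexError:
            raise KeyError(f"no channel {channel_id} in montage") from None
        return ch

    def region(self, channel_id: int) -> str:
        return self.channel(channel_id).region_label

    def hemisphere_counts(self) -> dict[str, int]:
        out = {"left": 0, "right": 0}
        for c in self.channels:
            out[c.hemisphere] += 1
        return out


def make_montage(n_channels: int = 52, seed: int | None = None,
                 distance: float = 2.3) -> Montage:
    """Build a symmetric montage with ``n_channels`` channels.

    Channels 1..n/2 sit over the left hemisphere, n/2+1..n over the right.
    For the default 52-channel array the named anatomical labels are applied;
    for other sizes, labels cycle through the region set symmetrically so that
    each hemisphere carries the same label counts.  ``seed`` is accepted for
    interface uniformity; the montage is deterministic.

    Parameters
    ----------
    n_channels : even channel count (>= 2).
    distance : source-detector separation in cm applied to every channel.
    """
    if n_channels < 2 or n_channels % 2 != 0:
        raise ValueError("n_channels must be even and >= 2")
    half = n_channels // 2
    channels = []
    for cid in range(1, n_channels + 1):
        hemi = "left" if cid <= half else "right"
        if n_channels == 52:
            region = _DEFAULT_REGIONS_52.get(cid, "other")
        else:
            # mirrored cycle: channel k on the left matches k+half on the right
            k = cid - 1 if cid <= half else cid - half - 1
            region = REGION_LABELS[k % len(REGION_LABELS)]
        channels.append(ChannelDef(cid, region, hemi, distance))
    return Montage(tuple(channels))
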