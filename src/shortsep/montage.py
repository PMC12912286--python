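"""Probe geometry: long channels, ROIs, and short-channel (SC) assignments.

The standard montage covers the occipital lobe (7 channels) and the left and
right temporal lobes (4 channels each) with 8 sources / 8 detectors at 25-40 mm
separations, plus one 8-mm short channel per source.  Channel 16 sits over the
right posterior temporal area and is excluded from statistical analysis (it has
no left-hemisphere counterpart).  Three named SC sources (C5, POz, CP6) form the
"limited availability" subset: one representative SC per lobe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

ROIS = ("left_temporal", "occipital", "right_temporal")
EXCLUDED = "excluded"


class MontageError(ValueError):
    """Invalid montage definition or invalid analysis target."""


@dataclass(frozen=True)
class ChannelDef:
    """A long (25-40 mm) source-detector channel."""

    id: int
    source_label: str
    detector_label: str
    roi: str
    distance_mm: float

    @property
    def distance_cm(self) -> float:
        return self.distance_mm / 10.0


@dataclass(frozen=True)
class ShortChannelDef:
    """An 8-mm short channel co-located with one source optode."""

    id: int
    source_label: str
    distance_mm: float = 8.0

    @property
    def distance_cm(self) -> float:
        return self.distance_mm / 10.0


@dataclass(frozen=True)
class Montage:
    channels: tuple[ChannelDef, ...]
    short_channels: tuple[ShortChannelDef, ...]
    limited_subset: dict[str, int]  # roi -> short-channel id
    layout_2d: dict[str, tuple[float, float]] = field(default_factory=dict)
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)

    def __post_init__(self) -> None:
        _validate(self)

    # -- lookups -------------------------------------------------------
    def channel(self, channel_id: int) -> ChannelDef:
        for ch in self.channels:
            if ch.id == channel_id:
                return ch
        raise MontageError(f"no channel with id {channel_id}")

    def short_channel(self, sc_id: int) -> ShortChannelDef:
        for sc in self.short_channels:
            if sc.id == sc_id:
                return sc
        raise MontageError(f"no short channel with id {sc_id}")

    def sc_by_source(self, source_label: str) -> ShortChannelDef:
        for sc in self.short_channels:
            if sc.source_label == source_label:
                return sc
        raise MontageError(f"no short channel at source {source_label!r}")

    @property
    def analyzed_channels(self) -> tuple[ChannelDef, ...]:
        return tuple(ch for ch in self.channels if ch.roi != EXCLUDED)

    @property
    def sources(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ch in self.channels:
            if ch.source_label not in seen:
                seen.append(ch.source_label)
        return tuple(seen)


def _validate(m: Montage) -> None:
    ids = [ch.id for ch in m.channels]
    if len(set(ids)) != len(ids):
        raise MontageError("channel ids must be unique")
    analyzed = [ch for ch in m.channels if ch.roi != EXCLUDED]
    if len(analyzed) != 15:
        raise MontageError(f"expected 15 analyzed channels, got {len(analyzed)}")
    excluded = [ch for ch in m.channels if ch.roi == EXCLUDED]
    if [ch.id for ch in excluded] != [16]:
        raise MontageError("exactly channel 16 must carry roi='excluded'")
    for ch in analyzed:
        if not 25.0 <= ch.distance_mm <= 40.0:
            raise MontageError(f"channel {ch.id}: distance {ch.distance_mm} mm outside 25-40 mm")
        if ch.roi not in ROIS:
            raise MontageError(f"channel {ch.id}: unknown roi {ch.roi!r}")
    counts = {roi: sum(ch.roi == roi for ch in analyzed) for roi in ROIS}
    if counts != {"left_temporal": 4, "occipital": 7, "right_temporal": 4}:
        raise MontageError(f"unexpected ROI channel counts: {counts}")
    sc_sources = [sc.source_label for sc in m.short_channels]
    if len(set(sc_sources)) != len(sc_sources):
        raise MontageError("one short channel per source")
    for sc in m.short_channels:
        if sc.distance_mm != 8.0:
            raise MontageError("short channels are 8 mm by definition")
    for ch in m.channels:
        if ch.source_label not in sc_sources:
            raise MontageError(f"source {ch.source_label!r} lacks a short channel")
    if set(m.limited_subset) != set(ROIS) or len(set(m.limited_subset.values())) != 3:
        raise MontageError("limited_subset must map each ROI to a distinct SC")
    for sc_id in m.limited_subset.values():
        m.short_channel(sc_id)


def build_standard_montage() -> Montage:
    """Load the bundled standard montage (15 analyzed channels + 8 SCs)."""
    with resources.files("shortsep.data").joinpath("montage_standard.json").open() as fh:
        raw = json.load(fh)
    channels = tuple(
        ChannelDef(c["id"], c["source"], c["detector"], c["roi"], c["distance_mm"])
        for c in raw["channels"]
    )
    short_channels = tuple(
        ShortChannelDef(s["id"], s["source"], s["distance_mm"]) for s in raw["short_channels"]
    )
    by_source = {sc.source_label: sc.id for sc in short_channels}
    limited = {roi: by_source[src] for roi, src in raw["limited_subset"].items()}
    layout = {k: tuple(v) for k, v in raw.get("layout_2d", {}).items()}
    return Montage(channels, short_channels, limited, layout, tuple(raw["wavelengths_nm"]))


def nearest_sc(channel: ChannelDef, scope: str, montage: Montage) -> ShortChannelDef:
    """Short channel used by the spatial-specific ("nearest") strategy.

    ``scope='full'``: the SC physically attached to the channel's own source.
    ``scope='limited'``: the single representative SC chosen for the channel's
    lobe (C5 left temporal, POz occipital, CP6 right temporal).
    """
    if channel.roi == EXCLUDED:
        raise MontageError(f"channel {channel.id} is excluded from analysis")
    if scope == "full":
        return montage.sc_by_source(channel.source_label)
    if scope == "limited":
        return montage.short_channel(montage.limited_subset[channel.roi])
    raise MontageError(f"unknown scope {scope!r} (expected 'limited' or 'full')")


def roi_channels(montage: Montage, roi: str) -> list[ChannelDef]:
    """Channels belonging to ``roi`` (or 'excluded'), sorted by id."""
    if roi not in ROIS and roi != EXCLUDED:
        raise MontageError(f"unknown roi {roi!r}")
    return sorted((ch for ch in montage.channels if ch.roi == roi), key=lambda c: c.id)


def scope_sc_ids(montage: Montage, scope: str) -> list[int]:
    """SC ids available under a scope: the 3-SC limited subset or all 8."""
    if scope == "limited":
        return sorted(montage.limited_subset.values())
    if scope == "full":
        return sorted(sc.id for sc in montage.short_channels)
    raise MontageError(f"unknown scope {scope!r}")
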