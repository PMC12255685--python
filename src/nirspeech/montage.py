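"""Optode montage description.

The montage is a lightweight fixture: channel identities, source-detector
distances and coarse region labels.  No 3-D geometry is modelled — region
labels stand in for anatomical specificity and drive the simulator's
condition -> response mapping.  The default montage mirrors the acquisition
geometry of a dual-wavelength continuous-wave system targeting temporal,
somatosensory, frontal and parietal cortex: 49 long channels with
source-detector separations between 2.1 and 4.3 cm plus 8 short (0.8 cm)
channels that see only scalp hemodynamics.

Exactly six long channels (three left-temporal, three right-temporal) are
designated "auditory" ground-truth channels so that data-driven ROI
recovery has a known answer on simulated cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

REGIONS = (
    "left-temporal",
    "right-temporal",
    "left-somatosensory",
    "frontal",
    "parietal",
    "other",
)

SHORT_DISTANCE_CM = 0.8
LONG_DISTANCE_RANGE_CM = (2.1, 4.3)


@dataclass(frozen=True)
class Channel:
    source: str
    detector: str
    distance: float  # cm
    is_short: bool
    region: str

    @property
    def name(self) -> str:
        return f"{self.source}_{self.detector}"


@dataclass
class Montage:
    """A set of fNIRS channels with their sources and detectors."""

    sources: list[str]
    detectors: list[str]
    channels: list[Channel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        src, det = set(self.sources), set(self.detectors)
        for ch in self.channels:
            if ch.source not in src:
                raise ValueError(f"channel {ch.name}: unknown source {ch.source}")
            if ch.detector not in det:
                raise ValueError(f"channel {ch.name}: unknown detector {ch.detector}")
            if ch.region not in REGIONS:
                raise ValueError(f"channel {ch.name}: unknown region {ch.region!r}")
            if ch.is_short:
                if abs(ch.distance - SHORT_DISTANCE_CM) > 1e-9:
                    raise ValueError(
                        f"short channel {ch.name} must sit at {SHORT_DISTANCE_CM} cm"
                    )
            else:
                lo, hi = LONG_DISTANCE_RANGE_CM
                if not lo <= ch.distance <= hi:
                    raise ValueError(
                        f"long channel {ch.name}: distance {ch.distance} outside [{lo}, {hi}] cm"
                    )

    @property
    def long_channels(self) -> list[Channel]:
        return [c for c in self.channels if not c.is_short]

    @property
    def short_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.is_short]

    @property
    def auditory_channels(self) -> list[Channel]:
        """The designated true-auditory channels (temporal region labels)."""
        return [c for c in self.long_channels if c.region.endswith("temporal")]

    def channel_names(self, short: bool | None = None) -> list[str]:
        if short is None:
            return [c.name for c in self.channels]
        return [c.name for c in (self.short_channels if short else self.long_channels)]


def default_montage() -> Montage:
    """Build the default 49-long + 8-short channel montage.

    Region allocation (long channels): 3 left-temporal, 3 right-temporal
    (the designated auditory set), 6 left-somatosensory, 8 frontal,
    8 parietal, 21 other.  Distances cycle deterministically through the
    permitted 2.1-4.3 cm range.
    """
    sources = [f"S{i}" for i in range(1, 17)]
    detectors = [f"D{i}" for i in range(1, 25)] + [f"SD{i}" for i in range(1, 9)]

    region_plan = (
        ["left-temporal"] * 3
        + ["right-temporal"] * 3
        + ["left-somatosensory"] * 6
        + ["frontal"] * 8
        + ["parietal"] * 8
        + ["other"] * 21
    )
    assert len(region_plan) == 49

    channels: list[Channel] = []
    # deterministic distance cycle spanning the montage's 2.1-4.3 cm spread
    dist_cycle = [2.1, 2.5, 3.0, 3.3, 3.6, 4.0, 4.3]
    for i, region in enumerate(region_plan):
        src = sources[i % 16]
        det = detectors[(i * 7 + i // 16) % 24]
        channels.append(
            Channel(src, det, dist_cycle[i % len(dist_cycle)], False, region)
        )
    # de-duplicate accidental source-detector collisions by nudging detector
    seen: set[str] = set()
    for i, ch in enumerate(channels):
        j = 0
        cur = ch
        while cur.name in seen:
            j += 1
            cur = Channel(
                ch.source, detectors[(i * 7 + i // 16 + j) % 24],
                ch.distance, False, ch.region,
            )
        channels[i] = cur
        seen.add(cur.name)

    for i in range(8):
        src = sources[2 * i % 16]
        channels.append(
            Channel(src, f"SD{i + 1}", SHORT_DISTANCE_CM, True, "other")
        )

    return Montage(sources=sources, detectors=detectors, channels=channels)
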