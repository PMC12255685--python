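"""Plain-text serialization for recordings, events, configs and results.

Recordings are written as long-format CSV (time, channel, wavelength,
intensity) plus an events CSV (onset, duration, condition) and a montage
CSV — a documented fallback for environments without an HDF5/SNIRF stack.
Ground-truth configurations round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import Channel, Montage
from .simulate import (
    EventSchedule, GroundTruth, MotionParams, NoiseParams, RawRecording, Trial,
)


def write_events_csv(events: EventSchedule, path) -> None:
    pd.DataFrame(
        [{"onset": t.onset, "duration": t.duration, "condition": t.condition}
         for t in events.trials]
    ).to_csv(path, index=False)


def read_events_csv(path) -> EventSchedule:
    df = pd.read_csv(path)
    return EventSchedule(
        [Trial(r.condition, float(r.onset), float(r.duration))
         for r in df.itertuples()]
    )


def write_montage_csv(montage: Montage, path) -> None:
    pd.DataFrame(
        [{"source": c.source, "detector": c.detector, "distance": c.distance,
          "is_short": c.is_short, "region": c.region}
         for c in montage.channels]
    ).to_csv(path, index=False)


def read_montage_csv(path) -> Montage:
    df = pd.read_csv(path)
    channels = [
        Channel(r.source, r.detector, float(r.distance), bool(r.is_short), r.region)
        for r in df.itertuples()
    ]
    return Montage(
        sources=sorted({c.source for c in channels}),
        detectors=sorted({c.detector for c in channels}),
        channels=channels,
    )


def write_recording(rec: RawRecording, directory) -> Path:
    """Write one participant's recording as CSV files under ``directory``."""
    d = Path(directory) / rec.participant
    d.mkdir(parents=True, exist_ok=True)
    names = rec.channel_names
    frames = []
    times = rec.times
    for i, name in enumerate(names):
        for w, wl in enumerate(rec.wavelengths):
            frames.append(pd.DataFrame({
                "time": times, "channel": name, "wavelength": wl,
                "intensity": rec.intensity[i, w],
            }))
    pd.concat(frames, ignore_index=True).to_csv(d / "intensity.csv", index=False)
    write_events_csv(rec.events, d / "events.csv")
    write_montage_csv(rec.montage, d / "montage.csv")
    meta = {"participant": rec.participant, "sample_rate": rec.sample_rate,
            "wavelengths": list(rec.wavelengths)}
    (d / "meta.yaml").write_text(yaml.safe_dump(meta))
    return d


def read_recording(directory) -> RawRecording:
    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    montage = read_montage_csv(d / "montage.csv")
    events = read_events_csv(d / "events.csv")
    df = pd.read_csv(d / "intensity.csv")
    names = montage.channel_names()
    wls = [int(w) for w in meta["wavelengths"]]
    n = df["time"].nunique()
    intensity = np.empty((len(names), 2, n))
    grouped = {k: g["intensity"].to_numpy() for k, g in df.groupby(["channel", "wavelength"])}
    for i, name in enumerate(names):
        for w, wl in enumerate(wls):
            intensity[i, w] = grouped[(name, wl)]
    return RawRecording(
        participant=str(meta["participant"]), montage=montage,
        sample_rate=float(meta["sample_rate"]), wavelengths=tuple(wls),
        intensity=intensity, events=events,
    )


def ground_truth_to_yaml(truth: GroundTruth, path) -> None:
    doc = {
        "amplitudes": [
            {"condition": c, "region": r, "amplitude": a}
            for (c, r), a in truth.amplitude_by_condition_region.items()
        ],
        "hbr_ratio": truth.hbr_ratio,
        "noise": asdict(truth.noise),
        "scalp_gain": truth.scalp_gain,
        "scalp_amp": truth.scalp_amp,
        "motion": asdict(truth.motion),
        "seed": truth.seed,
    }
    Path(path).write_text(yaml.safe_dump(doc))


def ground_truth_from_yaml(path) -> GroundTruth:
    doc = yaml.safe_load(Path(path).read_text())
    amps = {
        (a["condition"], a["region"]): float(a["amplitude"])
        for a in doc.get("amplitudes", [])
    }
    kwargs = {}
    if amps:
        kwargs["amplitude_by_condition_region"] = amps
    if "noise" in doc:
        kwargs["noise"] = NoiseParams(**doc["noise"])
    if "motion" in doc:
        kwargs["motion"] = MotionParams(**doc["motion"])
    for key in ("hbr_ratio", "scalp_gain", "scalp_amp", "seed"):
        if key in doc:
            kwargs[key] = doc[key]
    return GroundTruth(**kwargs)
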