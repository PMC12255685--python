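"""Data-driven region-of-interest consensus.

For a chosen condition (auditory speech-in-quiet by default) each
participant's ten highest-amplitude channels are identified, separately
for waveform mean amplitudes and GLM betas; per channel the number of
participants listing it is counted; the ROI is the intersection of the
two methods' top-count channel sets.  The same procedure applied to the
tactile condition yields a somatosensory ROI on simulated data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import json
import pandas as pd


@dataclass
class ROIDefinition:
    channels: list[str]
    counts_waveform: dict[str, int]
    counts_beta: dict[str, int]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ROI must be non-empty")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "channels": self.channels,
                    "counts_waveform": self.counts_waveform,
                    "counts_beta": self.counts_beta,
                    "parameters": self.parameters,
                },
                fh, indent=2,
            )


def top_channels_per_participant(
    amplitudes: pd.DataFrame,
    condition: str,
    method: str,
    k: int = 10,
) -> dict[str, list[str]]:
    """Per participant, the k channels with the largest amplitude.

    Ties at rank k are resolved by channel-id order (stable, deterministic);
    participants with fewer than k retained channels contribute all of them
    with a warning.
    """
    sub = amplitudes[
        (amplitudes["condition"] == condition) & (amplitudes["method"] == method)
    ]
    if sub.empty:
        raise ValueError(f"no amplitudes for condition={condition!r}, method={method!r}")
    out: dict[str, list[str]] = {}
    for pid, grp in sub.groupby("participant"):
        grp = grp.sort_values(["amplitude", "unit"], ascending=[False, True],
                              kind="mergesort")
        units = grp["unit"].tolist()
        if len(units) < k:
            warnings.warn(f"participant {pid}: only {len(units)} retained channels (< {k})")
        out[str(pid)] = units[:k]
    return out


def frequency_counts(top_lists: dict[str, list[str]],
                     universe: list[str] | None = None) -> dict[str, int]:
    """Number of participants listing each channel in their top set."""
    counts: dict[str, int] = {c: 0 for c in (universe or [])}
    for chans in top_lists.values():
        for c in chans:
            counts[c] = counts.get(c, 0) + 1
    return counts


def consensus_roi(
    counts_waveform: dict[str, int],
    counts_beta: dict[str, int],
    m: int = 6,
) -> ROIDefinition:
    """Intersect the two methods' top-count channel sets.

    From each method's counts the channels holding the ``m`` largest counts
    are retained (ties at the m-th count included); the ROI is their
    intersection, ordered by combined count then channel id.
    """
    def retained(counts: dict[str, int]) -> set[str]:
        nonzero = {c: n for c, n in counts.items() if n > 0}
        if not nonzero:
            return set()
        ordered = sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ordered) <= m:
            return set(c for c, _ in ordered)
        cut = ordered[m - 1][1]  # include ties at the m-th count
        return {c for c, n in ordered if n >= cut}

    inter = retained(counts_waveform) & retained(counts_beta)
    if not inter:
        raise ValueError(
            "empty ROI: the two methods' top-count sets do not intersect; "
            "consider a larger retention depth m"
        )
    channels = sorted(
        inter,
        key=lambda c: (-(counts_waveform.get(c, 0) + counts_beta.get(c, 0)), c),
    )
    return ROIDefinition(
        channels=channels,
        counts_waveform=dict(counts_waveform),
        counts_beta=dict(counts_beta),
        parameters={"m": m},
    )


def derive_roi(
    amplitudes: pd.DataFrame,
    condition: str = "speech_quiet",
    k: int = 10,
    m: int = 6,
) -> ROIDefinition:
    """Full consensus procedure from a two-method amplitude table."""
    universe = sorted(amplitudes["unit"].unique())
    tops_w = top_channels_per_participant(amplitudes, condition, "waveform", k)
    tops_b = top_channels_per_participant(amplitudes, condition, "beta", k)
    cw = frequency_counts(tops_w, universe)
    cb = frequency_counts(tops_b, universe)
    roi = consensus_roi(cw, cb, m)
    roi.parameters.update({"condition": condition, "k": k})
    return roi


def roi_response(amplitudes: pd.DataFrame, roi: ROIDefinition) -> pd.DataFrame:
    """Equal-weight average of ROI channel amplitudes per cell.

    Returns records at ROI granularity (unit = "ROI"); participants missing
    some ROI channels average over those present, with a warning; a
    participant with no retained ROI channel yields no record.
    """
    sub = amplitudes[amplitudes["unit"].isin(roi.channels)]
    rows = []
    n_roi = len(roi.channels)
    for (pid, cond, method), grp in sub.groupby(
        ["participant", "condition", "method"]
    ):
        if len(grp) < n_roi:
            warnings.warn(
                f"participant {pid}: {len(grp)}/{n_roi} ROI channels for "
                f"{cond}/{method}; averaging the available ones"
            )
        rows.append({
            "participant": pid, "unit": "ROI", "condition": cond,
            "method": method, "amplitude": float(grp["amplitude"].mean()),
        })
    return pd.DataFrame(rows,
                        columns=["participant", "unit", "condition", "method", "amplitude"])
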