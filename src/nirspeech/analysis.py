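"""End-to-end cohort analysis: preprocess -> features -> ROI -> group stats.

Glue that strings the pipeline stages together in their canonical order,
for use from scripts, the CLI, and simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .features import extract_amplitudes
from .groupstats import (
    AdditivityTest, AudioTactileContrast, ConditionActivationModel,
    ContrastResult, GroupModelResult,
)
from .preprocess import ChannelQualityReport, preprocess
from .roi import ROIDefinition, derive_roi, roi_response
from .simulate import RawRecording


@dataclass
class CohortAnalysis:
    """Results of the full pipeline on a cohort of raw recordings."""

    amplitudes: pd.DataFrame  # channel-level, both methods
    roi: ROIDefinition
    roi_amplitudes: pd.DataFrame
    activation: GroupModelResult
    contrast: dict[str, ContrastResult]
    additivity: dict[str, ContrastResult] | None
    qc_reports: dict[str, ChannelQualityReport] = field(default_factory=dict)

    def summary(self) -> str:
        parts = [f"ROI channels: {', '.join(self.roi.channels)}",
                 self.activation.summary()]
        for method, c in self.contrast.items():
            parts.append(c.summary())
        if self.additivity:
            for method, c in self.additivity.items():
                parts.append(c.summary())
        return "\n\n".join(parts)


def cohort_amplitudes(
    cohort: list[RawRecording],
    drift_cutoff: float = 0.01,
    **preprocess_kwargs,
) -> tuple[pd.DataFrame, dict[str, ChannelQualityReport]]:
    """Preprocess every participant and extract both feature methods."""
    tables, reports = [], {}
    for rec in cohort:
        hemo, report = preprocess(rec, **preprocess_kwargs)
        reports[rec.participant] = report
        tables.append(
            extract_amplitudes(hemo, rec.participant, drift_cutoff=drift_cutoff)
        )
    return pd.concat(tables, ignore_index=True), reports


def analyze_cohort(
    cohort: list[RawRecording],
    roi_condition: str = "speech_quiet",
    k: int = 10,
    m: int = 6,
    run_additivity: bool = True,
    drift_cutoff: float = 0.01,
    **preprocess_kwargs,
) -> CohortAnalysis:
    """Run the complete analysis and return all stage outputs."""
    amplitudes, reports = cohort_amplitudes(
        cohort, drift_cutoff=drift_cutoff, **preprocess_kwargs
    )
    roi = derive_roi(amplitudes, condition=roi_condition, k=k, m=m)
    roi_amps = roi_response(amplitudes, roi)
    activation = ConditionActivationModel(roi_amps, granularity="roi").fit()
    contrast = AudioTactileContrast(roi_amps).fit()
    additivity = AdditivityTest(roi_amps).fit() if run_additivity else None
    return CohortAnalysis(
        amplitudes=amplitudes, roi=roi, roi_amplitudes=roi_amps,
        activation=activation, contrast=contrast, additivity=additivity,
        qc_reports=reports,
    )
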