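"""Group-level inference on amplitude tables.

Three linear-mixed-model analyses, each with a participant random
intercept, fitted by REML (statsmodels MixedLM) and reported per feature
method (beta / waveform) separately:

* condition activations — one fixed effect per condition (x channel at
  channel granularity) with suppressed intercept; Benjamini-Hochberg FDR
  at 0.05 across all tested cells within a model;
* audio-tactile contrast — audio-tactile speech-in-noise vs auditory
  speech-in-noise (reference), coefficient = multisensory gain, plus
  per-participant gains;
* additivity test — audio-tactile vs the summed unisensory auxiliary
  condition (auditory speech-in-noise + tactile), classifying the effect
  as sub-additive / additive / super-additive.

Coefficient p-values use a normal reference on z = estimate / SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

FDR_Q = 0.05


def benjamini_hochberg(pvalues, q: float = FDR_Q):
    """Step-up FDR control: (adjusted p-values, rejection flags).

    Thin wrapper over the standard implementation; rejection set is the
    largest k with p_(k) <= k q / n, adjusted p-values by the monotone
    step-up transform.
    """
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _fit_mixedlm(endog, exog, groups, names):
    """REML fit with documented boundary handling for singular variance."""
    model = MixedLM(endog, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except Exception:
            fit = model.fit(reml=True, method="powell")
    params = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse_fe)
    return fit, pd.DataFrame({"term": names, "estimate": params, "se": se})


# --------------------------------------------------------------------------
# condition activations
# --------------------------------------------------------------------------

@dataclass
class GroupModelResult:
    """Per-cell estimates of a condition-activation mixed model."""

    table: pd.DataFrame  # method, unit, condition, estimate, se, z, p, p_fdr, significant
    granularity: str
    n_participants: int
    fdr_q: float = FDR_Q

    def significant(self, method: str | None = None) -> pd.DataFrame:
        t = self.table if method is None else self.table[self.table["method"] == method]
        return t[t["significant"]]

    def summary(self) -> str:
        head = (
            f"Condition activation LMM ({self.granularity} granularity, "
            f"{self.n_participants} participants, random participant intercept, "
            f"BH-FDR q={self.fdr_q})"
        )
        return head + "\n" + self.table.to_string(
            index=False, float_format=lambda v: f"{v: .4g}"
        )


class ConditionActivationModel:
    """HbO response ~ -1 + condition(:unit) + (1 | participant).

    ``granularity`` is "channel" (one cell per condition x channel) or
    "roi" (the table already holds ROI-averaged amplitudes; one cell per
    condition).  Separate mixed models are fitted per feature method, and
    BH-FDR is applied within each model across its full set of cells.
    """

    def __init__(self, amplitudes: pd.DataFrame, granularity: str = "roi"):
        if granularity not in ("roi", "channel"):
            raise ValueError("granularity must be 'roi' or 'channel'")
        self.amplitudes = amplitudes
        self.granularity = granularity

    def fit(self, fdr_q: float = FDR_Q) -> GroupModelResult:
        frames = []
        n_part = self.amplitudes["participant"].nunique()
        if n_part < 2:
            raise ValueError("group model needs >= 2 participants")
        for method, sub in self.amplitudes.groupby("method"):
            if self.granularity == "channel":
                cells = sub["condition"].astype(str) + ":" + sub["unit"].astype(str)
            else:
                cells = sub["condition"].astype(str)
            dummies = pd.get_dummies(cells, dtype=float)  # suppressed intercept
            fit, tab = _fit_mixedlm(
                sub["amplitude"].to_numpy(), dummies.to_numpy(),
                sub["participant"].to_numpy(), list(dummies.columns),
            )
            tab["method"] = method
            if self.granularity == "channel":
                parts = tab["term"].str.split(":", n=1, expand=True)
                tab["condition"], tab["unit"] = parts[0], parts[1]
            else:
                tab["condition"] = tab["term"]
                tab["unit"] = "ROI"
            tab["z"] = tab["estimate"] / tab["se"]
            tab["p"] = 2 * norm.sf(np.abs(tab["z"]))
            tab["p_fdr"], tab["significant"] = benjamini_hochberg(tab["p"], fdr_q)
            frames.append(tab[["method", "unit", "condition", "estimate",
                               "se", "z", "p", "p_fdr", "significant"]])
        return GroupModelResult(pd.concat(frames, ignore_index=True),
                                self.granularity, n_part, fdr_q)


# --------------------------------------------------------------------------
# contrasts
# --------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """A two-condition mixed-model contrast for one feature method."""

    method: str
    reference: str
    comparison: str
    reference_estimate: float
    difference: float
    se: float
    z: float
    p: float
    per_participant: pd.DataFrame | None = None
    direction: str | None = None  # additivity label

    @property
    def percent_change(self) -> float:
        return 100.0 * self.difference / self.reference_estimate

    def summary(self) -> str:
        lines = [
            f"{self.comparison} vs {self.reference} ({self.method})",
            f"  reference estimate: {self.reference_estimate: .3f} umol/l",
            f"  difference: {self.difference: .3f} umol/l "
            f"(SE {self.se:.3f}, z={self.z:.2f}, p={self.p:.3g})",
            f"  percent change: {self.percent_change: .1f}%",
        ]
        if self.direction is not None:
            lines.append(f"  classification: {self.direction}")
        return "\n".join(lines)


def _two_condition_lmm(sub: pd.DataFrame, reference: str, comparison: str):
    """Intercept + indicator(comparison) mixed model; returns fit pieces."""
    present = set(sub["condition"])
    if reference not in present or comparison not in present:
        raise ValueError(f"need both {reference!r} and {comparison!r} in the table")
    X = np.column_stack([
        np.ones(len(sub)),
        (sub["condition"] == comparison).to_numpy(float),
    ])
    fit, tab = _fit_mixedlm(
        sub["amplitude"].to_numpy(), X, sub["participant"].to_numpy(),
        ["intercept", comparison],
    )
    return tab


class AudioTactileContrast:
    """Multisensory gain: audio-tactile vs auditory speech-in-noise.

    Delta HbO ~ condition + (1 | participant) on ROI amplitudes, with
    auditory speech-in-noise as the reference level; the condition
    coefficient estimates the audio-tactile gain.  Fitted separately per
    feature method.
    """

    def __init__(
        self,
        roi_amplitudes: pd.DataFrame,
        reference: str = "speech_noise",
        comparison: str = "audiotactile_noise",
    ):
        self.amplitudes = roi_amplitudes
        self.reference = reference
        self.comparison = comparison

    def fit(self) -> dict[str, ContrastResult]:
        out = {}
        for method, sub in self.amplitudes.groupby("method"):
            sub = sub[sub["condition"].isin([self.reference, self.comparison])]
            tab = _two_condition_lmm(sub, self.reference, self.comparison)
            ref_est = float(tab.loc[tab["term"] == "intercept", "estimate"].iloc[0])
            d = float(tab.loc[tab["term"] == self.comparison, "estimate"].iloc[0])
            se = float(tab.loc[tab["term"] == self.comparison, "se"].iloc[0])
            z = d / se
            wide = sub.pivot_table(index="participant", columns="condition",
                                   values="amplitude")
            gains = (wide[self.comparison] - wide[self.reference]).dropna()
            out[str(method)] = ContrastResult(
                method=str(method), reference=self.reference,
                comparison=self.comparison, reference_estimate=ref_est,
                difference=d, se=se, z=z, p=2 * norm.sf(abs(z)),
                per_participant=gains.rename("gain").reset_index(),
            )
        return out


class AdditivityTest:
    """Bimodal response vs the sum of the unisensory responses.

    Per participant an auxiliary amplitude auditory + tactile is formed;
    a two-condition mixed model contrasts audio-tactile speech-in-noise
    against it.  Classification at ``alpha``: super-additive if the
    audio-tactile response significantly exceeds the sum, sub-additive if
    significantly below, additive otherwise.
    """

    def __init__(
        self,
        roi_amplitudes: pd.DataFrame,
        auditory: str = "speech_noise",
        tactile: str = "tactile",
        bimodal: str = "audiotactile_noise",
        alpha: float = 0.05,
    ):
        self.amplitudes = roi_amplitudes
        self.auditory, self.tactile, self.bimodal = auditory, tactile, bimodal
        self.alpha = alpha

    def fit(self) -> dict[str, ContrastResult]:
        out = {}
        for method, sub in self.amplitudes.groupby("method"):
            wide = sub.pivot_table(index="participant", columns="condition",
                                   values="amplitude")
            needed = [self.auditory, self.tactile, self.bimodal]
            missing = [c for c in needed if c not in wide.columns]
            if missing:
                raise ValueError(f"conditions missing from table: {missing}")
            wide = wide.dropna(subset=needed)
            long = pd.concat([
                pd.DataFrame({
                    "participant": wide.index,
                    "condition": self.bimodal,
                    "amplitude": wide[self.bimodal].to_numpy(),
                }),
                pd.DataFrame({
                    "participant": wide.index,
                    "condition": "unisensory_sum",
                    "amplitude": (wide[self.auditory] + wide[self.tactile]).to_numpy(),
                }),
            ], ignore_index=True)
            tab = _two_condition_lmm(long, "unisensory_sum", self.bimodal)
            ref = float(tab.loc[tab["term"] == "intercept", "estimate"].iloc[0])
            d = float(tab.loc[tab["term"] == self.bimodal, "estimate"].iloc[0])
            se = float(tab.loc[tab["term"] == self.bimodal, "se"].iloc[0])
            z = d / se if se > 0 else 0.0
            p = 2 * norm.sf(abs(z))
            if p < self.alpha:
                direction = "super-additive" if d > 0 else "sub-additive"
            else:
                direction = "additive"
            out[str(method)] = ContrastResult(
                method=str(method), reference="unisensory_sum",
                comparison=self.bimodal, reference_estimate=ref,
                difference=d, se=se, z=z, p=p, direction=direction,
            )
        return out
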