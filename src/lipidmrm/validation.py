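"""Method validation: detection limits, linearity, recovery and CV.

Limits follow the blank-based convention:

    LoB = mean(blank) + 1.645 * SD(blank)
    LoD = mean(blank) + 3     * SD(blank)
    LoQ = mean(blank) + 10    * SD(blank)

with the sample (n-1) standard deviation throughout. The LoD/LoQ
*concentrations* are read off a serial-dilution series as the lowest
calibrator whose mean signal strictly exceeds the corresponding threshold,
and linearity (R^2) is an ordinary least-squares fit of mean raw signal
against concentration over the range from the LoQ concentration to the top
calibrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CalibrationSeries",
    "DilutionLimits",
    "ValidationReport",
    "limits_from_blank",
    "limits_from_dilution",
    "recovery",
    "cv_report",
]


@dataclass(frozen=True)
class CalibrationSeries:
    """Serial-dilution calibration data for one analyte.

    ``concentrations`` are strictly decreasing (serial dilution order);
    ``areas[i]`` holds the replicate raw areas at ``concentrations[i]``.
    """

    analyte_id: str
    concentrations: tuple[float, ...]  # mol/L, strictly decreasing
    areas: tuple[tuple[float, ...], ...]
    blank_areas: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations)
        if c.size == 0 or np.any(np.diff(c) >= 0):
            raise ValueError("concentrations must be strictly decreasing")
        if len(self.areas) != c.size:
            raise ValueError("one replicate tuple per concentration required")
        if len(self.blank_areas) < 3:
            raise ValueError("need >= 3 blank replicates")


def limits_from_blank(
    blank_areas: np.ndarray | list[float],
) -> tuple[float, float, float]:
    """(LoB, LoD threshold, LoQ threshold) in signal units from blanks."""
    blanks = np.asarray(blank_areas, dtype=float)
    if blanks.size < 2:
        raise ValueError("need >= 2 blank replicates to estimate the SD")
    mean = float(blanks.mean())
    sd = float(blanks.std(ddof=1))
    return mean + 1.645 * sd, mean + 3.0 * sd, mean + 10.0 * sd


@dataclass(frozen=True)
class DilutionLimits:
    """Dilution-series readout: concentrations at the method limits."""

    lod_conc: float | None  # None -> no calibrator exceeded the threshold
    loq_conc: float | None
    r_squared: float | None
    linear_range: tuple[float, float] | None
    above_top_calibrator: bool = False


def limits_from_dilution(
    series: CalibrationSeries,
    lod_threshold: float,
    loq_threshold: float,
    use_replicate_means: bool = True,
) -> DilutionLimits:
    """LoD/LoQ concentrations and linearity from a serial-dilution series.

    The LoD (LoQ) concentration is the lowest calibrator whose mean signal
    strictly exceeds the LoD (LoQ) threshold. R^2 comes from OLS of signal
    vs concentration over [LoQ conc, top calibrator]; with
    ``use_replicate_means`` (default) the fit uses replicate means,
    otherwise all replicate points.
    """
    conc = np.asarray(series.concentrations)
    means = np.array([np.mean(a) for a in series.areas])
    above_lod = means > lod_threshold
    above_loq = means > loq_threshold
    if not above_lod.any():
        return DilutionLimits(None, None, None, None, above_top_calibrator=True)
    lod_conc = float(conc[above_lod].min())
    if not above_loq.any():
        return DilutionLimits(lod_conc, None, None, None, above_top_calibrator=True)
    loq_conc = float(conc[above_loq].min())
    in_range = conc >= loq_conc
    if use_replicate_means:
        x = conc[in_range]
        y = means[in_range]
    else:
        x = np.concatenate([
            np.full(len(series.areas[i]), conc[i])
            for i in np.flatnonzero(in_range)
        ])
        y = np.concatenate([
            np.asarray(series.areas[i], dtype=float)
            for i in np.flatnonzero(in_range)
        ])
    if x.size < 2:
        r2 = None
    else:
        fit = sps.linregress(x, y)
        r2 = float(fit.rvalue**2)
    return DilutionLimits(
        lod_conc, loq_conc, r2, (loq_conc, float(conc.max())), False
    )


def recovery(
    pre_spike_areas: np.ndarray | list[float],
    post_spike_areas: np.ndarray | list[float],
) -> tuple[float, float]:
    """Extraction recovery and its precision.

    Relative recovery (%) = mean(pre-extraction spike) / mean(post-extraction
    spike) x 100; %RSD = SD / mean of the pre-spike signal x 100 (n-1 SD).
    """
    pre = np.asarray(pre_spike_areas, dtype=float)
    post = np.asarray(post_spike_areas, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("need >= 1 replicate in each condition")
    if post.mean() == 0:
        raise ValueError("post-extraction spike mean is zero")
    rec = 100.0 * pre.mean() / post.mean()
    rsd = 100.0 * pre.std(ddof=1) / pre.mean() if pre.size > 1 else 0.0
    return float(rec), float(rsd)


def cv_report(
    areas,  # pandas DataFrame: replicates x species
    class_labels,  # mapping or Series: species -> lipid class
) -> "pd.Series":
    """Per-species CV% after within-class sum normalization.

    Within each replicate, every species' area is divided by the total of
    its lipid class in that replicate; CV% = SD / mean x 100 (n-1 SD) on
    the normalized values. A zero class total in any replicate raises.
    """
    import pandas as pd

    df = pd.DataFrame(areas)
    if df.shape[0] < 2:
        raise ValueError("need >= 2 replicates")
    classes = pd.Series(class_labels)
    missing = [c for c in df.columns if c not in classes.index]
    if missing:
        raise ValueError(f"species without class labels: {missing[:3]}")
    normalized = df.copy().astype(float)
    sub = classes.loc[list(df.columns)]
    for cls in sub.unique():
        cols = list(sub.index[sub == cls])
        totals = df[cols].sum(axis=1)
        if (totals == 0).any():
            raise ValueError(f"class {cls} has zero total in some replicate")
        normalized[cols] = df[cols].div(totals, axis=0)
    return 100.0 * normalized.std(ddof=1) / normalized.mean()


@dataclass(frozen=True)
class ValidationReport:
    """Per-analyte validation summary."""

    analyte_id: str
    lob: float
    lod_threshold: float
    loq_threshold: float
    lod_conc: float | None
    loq_conc: float | None
    r_squared: float | None
    recovery_percent: float | None = None
    rsd_percent: float | None = None

    def __post_init__(self) -> None:
        if not self.lob <= self.lod_threshold <= self.loq_threshold:
            raise ValueError("thresholds must satisfy LoB <= LoD <= LoQ")
        if (
            self.lod_conc is not None
            and self.loq_conc is not None
            and self.lod_conc > self.loq_conc
        ):
            raise ValueError("LoD concentration cannot exceed LoQ concentration")


def validate_series(series: CalibrationSeries) -> ValidationReport:
    """Full blank + dilution workup for one analyte."""
    lob, lod_t, loq_t = limits_from_blank(series.blank_areas)
    dil = limits_from_dilution(series, lod_t, loq_t)
    return ValidationReport(
        series.analyte_id, lob, lod_t, loq_t,
        dil.lod_conc, dil.loq_conc, dil.r_squared,
    )
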