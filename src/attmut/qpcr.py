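"""Excision-frequency quantification from qPCR Cq tables.

Strategy: a dilution series of genomic DNA from a 100%-excision lineage is
the standard for both targets — the rejoined attachment site (attB) and a
nearby single-copy genomic control locus. Each target's standards give a
log-linear standard curve Cq = intercept + slope·log10(relative quantity);
a sample's relative quantity on each target is read off its own curve, and
the excision frequency is quantity(attB) / quantity(control). Because both
curves are anchored to the same 100%-excision DNA, the undiluted standard
self-normalises to frequency 1, and any constant per-target Cq offset
cancels.

Growth phases are compared with a paired (dependent) two-sided t-test on
per-replicate frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InputError, ParameterError

ATTB = "attB"
CONTROL = "control"
STANDARD_PHASE = "standard"

#: Cq column sentinel for wells that never crossed threshold.
UNDETERMINED = "Undetermined"

PLATE_COLUMNS = ["sample", "target", "phase", "replicate", "dilution", "cq"]


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares fit of Cq against log10 relative quantity."""

    slope: float  # cycles per log10 quantity; negative for a valid series
    intercept: float  # Cq of the undiluted (quantity 1) standard
    efficiency: float  # 10^(-1/slope) - 1
    r2: float

    def quantity(self, cq: float) -> float:
        """Relative quantity (undiluted standard = 1) for an observed Cq."""
        return float(10.0 ** ((cq - self.intercept) / self.slope))


@dataclass(frozen=True)
class PhaseSummary:
    frequencies: list[float]
    below_detection: int
    mean: float
    se: float


@dataclass(frozen=True)
class ExcisionFrequencyResult:
    per_replicate: pd.DataFrame  # phase, replicate, quantity_attB, quantity_control, frequency
    summaries: dict[str, PhaseSummary]
    curves: dict[str, StandardCurve]


@dataclass(frozen=True)
class PhaseComparison:
    t: float
    df: int
    p_value: float
    ratio: float  # stationary mean / exponential mean


def fit_standard_curve(standards) -> StandardCurve:
    """Fit a standard curve from (dilution factor, Cq) pairs.

    Dilution factor d means relative quantity 1/d (d = 1 is the undiluted
    100%-excision standard). Requires at least 3 distinct dilutions; a flat
    or rising Cq series cannot be a dilution series and is a fit error.
    """
    pairs = [(float(d), float(c)) for d, c in standards]
    if any(d <= 0 for d, _ in pairs):
        raise ParameterError("dilution factors must be positive")
    if len({d for d, _ in pairs}) < 3:
        raise FitError("need at least 3 distinct dilutions")
    x = np.array([-math.log10(d) for d, _ in pairs])  # log10 quantity
    y = np.array([c for _, c in pairs])
    if np.allclose(y, y[0]):
        raise FitError("Cq does not vary across dilutions")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise FitError("standard curve slope must be negative")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r2=float(fit.rvalue**2),
    )


def _check_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise InputError(f"plate is missing columns: {missing}")
    df = plate.copy()
    df["cq"] = pd.to_numeric(
        df["cq"].replace(UNDETERMINED, np.nan), errors="coerce"
    )
    return df


def excision_frequency(
    plate: pd.DataFrame,
    attB_target: str = ATTB,
    control_target: str = CONTROL,
) -> ExcisionFrequencyResult:
    """Per-replicate, mean and SE excision frequencies per growth phase.

    Technical replicate wells sharing (phase, replicate, target) are
    averaged first; the SE is across biological replicates. A replicate
    whose attB Cq is undetermined is reported below detection (NaN
    frequency) and excluded from the mean.
    """
    df = _check_plate(plate)
    std = df[df["phase"] == STANDARD_PHASE]
    if std.empty:
        raise InputError("plate contains no standards")

    curves: dict[str, StandardCurve] = {}
    for target in (attB_target, control_target):
        rows = std[(std["target"] == target) & std["cq"].notna()]
        if rows.empty:
            raise InputError(f"no standards for target {target!r}")
        curves[target] = fit_standard_curve(
            zip(rows["dilution"].astype(float), rows["cq"].astype(float))
        )

    samples = df[df["phase"] != STANDARD_PHASE]
    out_rows = []
    summaries: dict[str, PhaseSummary] = {}
    for phase, grp in samples.groupby("phase", sort=True):
        freqs, n_below = [], 0
        for rep, wells in grp.groupby("replicate", sort=True):
            cq_b = wells.loc[wells["target"] == attB_target, "cq"].mean()
            cq_c = wells.loc[wells["target"] == control_target, "cq"].mean()
            if pd.isna(cq_c):
                raise InputError(
                    f"control Cq undetermined for {phase} replicate {rep}"
                )
            q_c = curves[control_target].quantity(cq_c)
            if pd.isna(cq_b):
                n_below += 1
                out_rows.append((phase, rep, np.nan, q_c, np.nan, True))
                continue
            q_b = curves[attB_target].quantity(cq_b)
            freq = q_b / q_c
            freqs.append(freq)
            out_rows.append((phase, rep, q_b, q_c, freq, False))
        arr = np.asarray(freqs)
        mean = float(arr.mean()) if arr.size else math.nan
        se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
        summaries[str(phase)] = PhaseSummary(
            frequencies=[float(f) for f in freqs],
            below_detection=n_below,
            mean=mean,
            se=se,
        )

    per_rep = pd.DataFrame(
        out_rows,
        columns=[
            "phase", "replicate", "quantity_attB", "quantity_control",
            "frequency", "below_detection",
        ],
    )
    return ExcisionFrequencyResult(
        per_replicate=per_rep, summaries=summaries, curves=curves
    )


def phase_comparison(exponential, stationary) -> PhaseComparison:
    """Paired two-sided t-test of excision frequency between growth phases.

    Arrays are paired by biological replicate and must have equal length
    >= 2. Zero-variance differences are handled explicitly: identical
    arrays give t = 0, p = 1; a constant nonzero shift gives a signed
    infinity with p = 0. Also reports the stationary/exponential ratio of
    phase means.
    """
    x = np.asarray(exponential, float)
    y = np.asarray(stationary, float)
    if x.shape != y.shape:
        raise InputError("phase arrays must be paired (equal length)")
    if x.size < 2:
        raise InputError("need at least 2 replicate pairs")
    diffs = x - y
    ratio = float(y.mean() / x.mean()) if x.mean() != 0 else math.nan
    df = x.size - 1
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs.mean(), 0.0):
            return PhaseComparison(t=0.0, df=df, p_value=1.0, ratio=ratio)
        t = math.inf if diffs.mean() > 0 else -math.inf
        return PhaseComparison(t=t, df=df, p_value=0.0, ratio=ratio)
    res = stats.ttest_rel(x, y)
    return PhaseComparison(
        t=float(res.statistic), df=df, p_value=float(res.pvalue), ratio=ratio
    )
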