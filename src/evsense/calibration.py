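"""Log-linear immunosensor calibration, LOD/LOQ, and quantification.

Both detectors respond linearly in the decadic logarithm of the
extracellular-vesicle particle concentration over the validated range:

    signal = slope * log10(C) + intercept

The limit of detection follows the blank-replicate convention: the
critical signal is the blank mean plus three blank standard deviations
(five replicates by default), inverted through the calibration to a
concentration; the limit of quantification is 3.3x the LOD.  Reported
LOD/LOQ values are rounded to two significant figures (half-up).

Quantification inverts a measured signal through the calibration and
multiplies by the dilution factor; validity is judged at the measured
(post-dilution) concentration, which must lie strictly inside
(1e4, 1e7) particles/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import linregress

__all__ = [
    "CalibrationModel",
    "BlankSet",
    "QuantResult",
    "ReferenceValue",
    "SamplePanelResult",
    "AgreementStats",
    "RetentionResult",
    "fit_calibration",
    "compute_lod",
    "compute_loq",
    "invert_concentration",
    "rsd_percent",
    "dilution_validity",
    "signal_retention",
    "method_agreement",
    "quantify_panel",
    "round_to_2sf",
    "VALID_WINDOW",
]

#: Measured-state concentration window (particles/mL) where results are
#: reliable; boundary values are invalid.
VALID_WINDOW = (1e4, 1e7)


def round_to_2sf(x: float) -> float:
    """Round to two significant figures, half-up (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    q = Decimal(x).scaleb(-exp + 1).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    return float(q.scaleb(exp - 1))


@dataclass
class CalibrationModel:
    """Log-linear signal-to-concentration map for one channel."""

    channel: str
    signal_kind: str  # spr_ratio | qcmd_freq_step
    slope: float  # signal units per decade of particles/mL
    intercept: float  # signal units
    r_squared: float
    range_low: float  # particles/mL
    range_high: float  # particles/mL
    blank_mean: float = float("nan")
    blank_sd: float = float("nan")
    lod: float = float("nan")  # particles/mL, unrounded
    loq: float = float("nan")  # particles/mL, unrounded (= 3.3*lod)
    valid: bool = True

    def predict(self, concentration: float | np.ndarray) -> float | np.ndarray:
        """Expected signal at a particle concentration (particles/mL)."""
        c = np.asarray(concentration, dtype=float)
        if np.any(c <= 0):
            raise ValueError("concentration must be positive")
        out = self.slope * np.log10(c) + self.intercept
        return float(out) if np.ndim(concentration) == 0 else out


@dataclass
class BlankSet:
    """Replicate blank (buffer-only) signals for one channel."""

    values: np.ndarray
    channel: str = ""
    signal_kind: str = "qcmd_freq_step"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 2:
            raise ValueError("at least two blank replicates are required")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


@dataclass
class QuantResult:
    """Per-sample, per-channel concentration estimate."""

    sample_id: str
    channel: str
    signal: float
    dilution_factor: float
    concentration: float  # particles/mL, dilution-corrected
    sd: float = float("nan")
    valid: bool = True


@dataclass(frozen=True)
class ReferenceValue:
    """Reference-method (NTA-style) concentration with its SD."""

    concentration: float
    sd: float = float("nan")


@dataclass
class SamplePanelResult:
    """Quantification results for a sample panel plus reference values."""

    results: list[QuantResult]
    references: dict[str, ReferenceValue]

    def __post_init__(self) -> None:
        missing = sorted({r.sample_id for r in self.results} - set(self.references))
        if missing:
            raise ValueError(f"samples missing a reference value: {missing}")


@dataclass
class AgreementStats:
    """Agreement of panel estimates with the reference method."""

    per_channel_bias: dict[str, float]  # mean relative difference vs reference
    overall_mare: float  # mean absolute relative difference
    flagged: list[tuple[str, str]]  # (sample_id, channel) beyond the limit


@dataclass(frozen=True)
class RetentionResult:
    """Signal retention after sensor regeneration."""

    percent: float
    passed: bool


def fit_calibration(
    concentrations,
    signals,
    channel: str = "",
    signal_kind: str = "qcmd_freq_step",
) -> CalibrationModel:
    """OLS of signal on log10(concentration in particles/mL)."""
    c = np.asarray(concentrations, dtype=float)
    s = np.asarray(signals, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(c)) < 3:
        raise ValueError("at least 3 distinct concentrations are required")
    if len(c) != len(s):
        raise ValueError("concentrations and signals must have equal length")
    fit = linregress(np.log10(c), s)
    return CalibrationModel(
        channel=channel,
        signal_kind=signal_kind,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        range_low=float(c.min()),
        range_high=float(c.max()),
        valid=bool(fit.slope != 0.0),
    )


def compute_lod(blanks: BlankSet, model: CalibrationModel) -> float:
    """LOD from blank replicates: invert blank_mean + 3*SD through the model.

    The signal convention is that the calibration slope is positive
    (signal magnitude grows with concentration), so the critical signal
    maps to a unique concentration.
    """
    if model.slope <= 0:
        raise ValueError(
            "LOD conversion requires a positive calibration slope "
            "(signal increasing with concentration)"
        )
    critical = blanks.mean + 3.0 * blanks.sd
    return 10.0 ** ((critical - model.intercept) / model.slope)


def compute_loq(lod: float, rounded: bool = False) -> float:
    """LOQ = 3.3 x LOD; ``rounded`` applies the 2-significant-figure report rule."""
    if lod <= 0:
        raise ValueError("lod must be positive")
    loq = 3.3 * lod
    return round_to_2sf(loq) if rounded else loq


def calibrate_with_blanks(
    concentrations, signals, blanks: BlankSet, channel: str = "",
    signal_kind: str = "qcmd_freq_step",
) -> CalibrationModel:
    """Full calibration: OLS fit plus blank statistics and LOD/LOQ."""
    model = fit_calibration(concentrations, signals, channel, signal_kind)
    lod = compute_lod(blanks, model)
    return replace(
        model,
        blank_mean=blanks.mean,
        blank_sd=blanks.sd,
        lod=lod,
        loq=compute_loq(lod),
    )


def invert_concentration(
    signal: float, model: CalibrationModel, dilution_factor: float = 1.0
) -> float:
    """C = 10^((signal - intercept)/slope) * dilution_factor (particles/mL)."""
    if model.slope == 0:
        raise ValueError("calibration slope is zero; model not invertible")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return 10.0 ** ((signal - model.intercept) / model.slope) * dilution_factor


def rsd_percent(values) -> float:
    """Relative standard deviation, 100 * sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("at least two values are required")
    mean = float(np.mean(v))
    if mean == 0:
        raise ValueError("mean is zero; RSD undefined")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def dilution_validity(measured_concentration: float) -> bool:
    """True iff the measured-state concentration is strictly inside VALID_WINDOW.

    Boundary values are invalid; a small relative guard keeps values that
    equal a boundary up to floating-point round-off on the invalid side.
    """
    if measured_concentration < 0:
        raise ValueError("concentration must be non-negative")
    lo, hi = VALID_WINDOW
    guard = 1e-12
    return lo * (1 + guard) < measured_concentration < hi * (1 - guard)


def signal_retention(
    initial_signal: float, current_signal: float, threshold: float = 90.0
) -> RetentionResult:
    """Percent of the initial signal retained; QC passes at >= threshold."""
    if initial_signal == 0:
        raise ValueError("initial signal must be non-zero")
    pct = 100.0 * current_signal / initial_signal
    return RetentionResult(percent=pct, passed=pct >= threshold)


def quantify_panel(
    rows,
    models: dict[str, CalibrationModel],
    references: dict[str, ReferenceValue] | None = None,
) -> SamplePanelResult:
    """Invert panel signals to concentrations, aggregating replicates.

    ``rows`` is an iterable of dicts with keys ``sample_id``, ``channel``,
    ``signal``, ``dilution_factor`` and optionally
    ``reference_concentration``/``reference_sd``.  Replicate rows of the
    same (sample, channel) are aggregated to a mean concentration and a
    replicate SD.  Validity is judged per replicate at the measured
    (pre-dilution-correction) concentration.
    """
    groups: dict[tuple[str, str], list[dict]] = {}
    refs: dict[str, ReferenceValue] = dict(references or {})
    for row in rows:
        key = (str(row["sample_id"]), str(row["channel"]))
        groups.setdefault(key, []).append(row)
        if "reference_concentration" in row and key[0] not in refs:
            refs[key[0]] = ReferenceValue(
                concentration=float(row["reference_concentration"]),
                sd=float(row.get("reference_sd", float("nan"))),
            )
    results = []
    for (sample_id, channel), rws in sorted(groups.items()):
        if channel not in models:
            raise KeyError(f"no calibration model for channel {channel!r}")
        model = models[channel]
        concs, valid = [], True
        for r in rws:
            dil = float(r["dilution_factor"])
            c = invert_concentration(float(r["signal"]), model, dil)
            concs.append(c)
            valid = valid and dilution_validity(c / dil)
        concs = np.asarray(concs)
        results.append(
            QuantResult(
                sample_id=sample_id,
                channel=channel,
                signal=float(np.mean([float(r["signal"]) for r in rws])),
                dilution_factor=float(rws[0]["dilution_factor"]),
                concentration=float(np.mean(concs)),
                sd=float(np.std(concs, ddof=1)) if len(concs) > 1 else float("nan"),
                valid=valid,
            )
        )
    return SamplePanelResult(results=results, references=refs)


def method_agreement(
    panel: SamplePanelResult, flag_limit: float = 0.50
) -> AgreementStats:
    """Agreement of estimates with the reference method.

    Per-channel bias is the mean relative difference (estimate - ref)/ref;
    the overall statistic is the mean absolute relative difference; a
    (sample, channel) pair is flagged when its absolute relative
    difference exceeds ``flag_limit``.
    """
    if len({r.sample_id for r in panel.results}) < 2:
        raise ValueError("at least two samples with references are required")
    rel_by_channel: dict[str, list[float]] = {}
    all_abs, flagged = [], []
    for r in panel.results:
        ref = panel.references[r.sample_id].concentration
        rel = (r.concentration - ref) / ref
        rel_by_channel.setdefault(r.channel, []).append(rel)
        all_abs.append(abs(rel))
        if abs(rel) > flag_limit:
            flagged.append((r.sample_id, r.channel))
    bias = {ch: float(np.mean(v)) for ch, v in sorted(rel_by_channel.items())}
    return AgreementStats(
        per_channel_bias=bias,
        overall_mare=float(np.mean(all_abs)),
        flagged=flagged,
    )
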