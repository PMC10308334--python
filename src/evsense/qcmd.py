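"""QCM-D trace analysis: layer steps, Sauerbrey surface concentrations,
antibody packing geometry, and dissipation-vs-frequency rigidity.

A QCM-D staircase experiment deposits successive layers on a gold
crystal (cysteamine, antibody, extracellular vesicles); each deposition
lowers the overtone-normalized resonance frequency by an amount
proportional to the coupled areal mass (Sauerbrey regime).  The surface
concentration of a layer of molar mass M follows from the frequency
step: Gamma = |df| * C_f / M with C_f the crystal's mass sensitivity
(ng cm^-2 Hz^-1).  The slope of dissipation change versus frequency
change over a deposition stage diagnoses layer rigidity: small |dD/df|
means a rigid film, larger values a more viscoelastic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .kinetics import AVOGADRO

__all__ = [
    "StageAnnotation",
    "QcmdTrace",
    "LayerStep",
    "MolecularSpec",
    "IgGGeometry",
    "SlopeFit",
    "PackingDensities",
    "MASS_SENSITIVITY_5MHZ",
    "CYSTEAMINE",
    "IGG_ANTIBODY",
    "extract_steps",
    "sauerbrey_gamma",
    "dry_mass_correction",
    "orientation_packing",
    "footprint_gamma",
    "dd_df_slope",
    "two_segment_dd_df",
]

#: Mass sensitivity of a 5 MHz quartz crystal (ng cm^-2 Hz^-1).
MASS_SENSITIVITY_5MHZ = 17.7

STAGE_NAMES = ("buffer", "csh", "activation", "antibody", "ev", "regeneration")


@dataclass(frozen=True)
class StageAnnotation:
    """One annotated stage of a staircase experiment (index span, end-exclusive)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.name not in STAGE_NAMES:
            raise ValueError(f"unknown stage name {self.name!r}; expected one of {STAGE_NAMES}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("stage span must satisfy 0 <= start < end")


@dataclass
class QcmdTrace:
    """Multi-overtone frequency/dissipation time series with stage annotations.

    ``delta_f`` maps odd harmonic number to the overtone-normalized
    frequency-shift series (Hz); ``delta_d`` maps it to the dissipation
    series in 1e-6 units.
    """

    time: np.ndarray
    delta_f: dict[int, np.ndarray]
    delta_d: dict[int, np.ndarray]
    stages: list[StageAnnotation]
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.delta_f:
            raise ValueError("at least one overtone is required")
        if set(self.delta_f) != set(self.delta_d):
            raise ValueError("delta_f and delta_d must cover the same overtones")
        n = len(self.time)
        for ot in self.delta_f:
            self.delta_f[ot] = np.asarray(self.delta_f[ot], dtype=float)
            self.delta_d[ot] = np.asarray(self.delta_d[ot], dtype=float)
            if len(self.delta_f[ot]) != n or len(self.delta_d[ot]) != n:
                raise ValueError("all series must share the time grid length")
        spans = sorted(self.stages, key=lambda a: a.start)
        for a, b in zip(spans, spans[1:]):
            if a.end > b.start:
                raise ValueError(f"stage spans overlap: {a.name} and {b.name}")
        if any(a.end > n for a in self.stages):
            raise ValueError("stage span exceeds trace length")
        self.stages = spans

    @property
    def overtones(self) -> list[int]:
        return sorted(self.delta_f)

    def stage(self, name: str) -> StageAnnotation:
        for a in self.stages:
            if a.name == name:
                return a
        raise KeyError(f"no stage named {name!r}")


@dataclass
class LayerStep:
    """Frequency/dissipation step of one deposition stage (plateau medians)."""

    stage: str
    delta_f_step: float  # Hz; negative = mass addition
    delta_d_step: float  # 1e-6 units
    overtone: int
    plateau: tuple[int, int]  # absolute index span of the trailing plateau
    quality_warning: bool = False


@dataclass(frozen=True)
class MolecularSpec:
    """Adsorbate description for surface-concentration bookkeeping."""

    name: str
    molar_mass: float  # g/mol
    hydration_excess: float = 0.30  # wet mass exceeds dry by this fraction

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if not (0 <= self.hydration_excess < 5):
            raise ValueError("hydration_excess must be in [0, 5)")


#: Cysteamine free base — the species actually chemisorbed on gold.
CYSTEAMINE = MolecularSpec("cysteamine", molar_mass=77.15, hydration_excess=0.0)

#: Generic IgG-class antibody (approximate molar mass 150 kDa).
IGG_ANTIBODY = MolecularSpec("IgG", molar_mass=150_000.0, hydration_excess=0.30)


@dataclass(frozen=True)
class IgGGeometry:
    """IgG dimensions (nm) for close-packed 2D footprint estimates.

    Fab arms ~6.5 x 3.5 nm and the Fc stem ~5 x 3.5 nm; an effective
    molecular length of 10.5 nm is used for the tilted and horizontal
    footprints (see docs/methods.md for the packing model).
    """

    fab_length: float = 6.5
    fab_width: float = 3.5
    fc_length: float = 5.0
    fc_width: float = 3.5
    effective_length: float = 10.5

    @property
    def footprints_nm2(self) -> dict[str, float]:
        return {
            "vertical": self.fab_length * self.fab_width,
            "tilted": self.effective_length * self.fab_width,
            "horizontal": self.effective_length * self.fab_length,
        }


@dataclass
class SlopeFit:
    """ΔD-vs-Δf regression, optionally with a continuous breakpoint."""

    slope: float  # 1e-6 dissipation units per Hz
    intercept: float
    r_squared: float
    breakpoint: float | None = None  # Hz
    slope2: float | None = None
    sse: float = float("nan")
    no_breakpoint: bool = False
    fallback_single: bool = False


@dataclass(frozen=True)
class PackingDensities:
    """Close-packed surface concentrations per orientation (mol cm^-2)."""

    vertical: float
    tilted: float
    horizontal: float


# ---------------------------------------------------------------------------
# step extraction


def _window_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    denom = float(tc @ tc)
    if denom == 0:
        return 0.0
    return float(tc @ (y - y.mean()) / denom)


def _trailing_plateau(
    t: np.ndarray, y: np.ndarray, window: int, slope_threshold: float
) -> tuple[int, int] | None:
    """Trailing index span where every covering window's |slope| <= threshold."""
    n = len(y)
    if n < window:
        return None
    if abs(_window_slope(t[n - window :], y[n - window :])) > slope_threshold:
        return None
    j = n - window
    while j > 0:
        if abs(_window_slope(t[j - 1 : j - 1 + window], y[j - 1 : j - 1 + window])) <= slope_threshold:
            j -= 1
        else:
            break
    return (j, n)


def extract_steps(
    trace: QcmdTrace,
    overtone: int = 3,
    window: int = 30,
    slope_threshold: float = 0.01,
) -> list[LayerStep]:
    """Per-stage frequency/dissipation steps from trailing-plateau medians.

    For each annotated stage the trailing plateau is the longest end
    segment over which a moving ``window``-sample slope stays below
    ``slope_threshold`` (Hz/s); the step of stage k is the difference of
    the plateau medians of stages k and k-1.  A stage without a
    qualifying plateau contributes its trailing ``window`` samples and is
    flagged with a quality warning.  Steps are offset-invariant and sum
    to the final plateau's offset from the baseline plateau.
    """
    if len(trace.stages) < 2:
        raise ValueError("need at least two annotated stages")
    if overtone not in trace.delta_f:
        raise KeyError(f"overtone {overtone} not in trace")
    f = trace.delta_f[overtone]
    d = trace.delta_d[overtone]
    t = trace.time

    medians: list[tuple[str, float, float, tuple[int, int], bool]] = []
    for st in trace.stages:
        seg_t, seg_f = t[st.start : st.end], f[st.start : st.end]
        span = _trailing_plateau(seg_t, seg_f, window, slope_threshold)
        warn = span is None
        if span is None:
            lo = max(0, (st.end - st.start) - window)
            span = (lo, st.end - st.start)
        abs_span = (st.start + span[0], st.start + span[1])
        f_med = float(np.median(f[abs_span[0] : abs_span[1]]))
        d_med = float(np.median(d[abs_span[0] : abs_span[1]]))
        medians.append((st.name, f_med, d_med, abs_span, warn))

    steps = []
    for prev, cur in zip(medians, medians[1:]):
        steps.append(
            LayerStep(
                stage=cur[0],
                delta_f_step=cur[1] - prev[1],
                delta_d_step=cur[2] - prev[2],
                overtone=overtone,
                plateau=cur[3],
                quality_warning=cur[4] or prev[4],
            )
        )
    return steps


# ---------------------------------------------------------------------------
# surface-concentration calculators


def sauerbrey_gamma(
    delta_f_step: float,
    spec: MolecularSpec,
    mass_sensitivity: float = MASS_SENSITIVITY_5MHZ,
) -> float:
    """Surface concentration Gamma = |df| * C_f / M in mol cm^-2.

    ``mass_sensitivity`` is in ng cm^-2 Hz^-1, so the areal mass
    |df|*C_f is in ng cm^-2 and is converted to g before dividing by the
    molar mass.
    """
    if mass_sensitivity <= 0:
        raise ValueError("mass_sensitivity must be positive")
    areal_mass_ng = abs(delta_f_step) * mass_sensitivity
    return areal_mass_ng * 1e-9 / spec.molar_mass


def dry_mass_correction(wet_mass: float, hydration_excess: float = 0.30) -> float:
    """Strip the hydration shell: dry = wet / (1 + hydration_excess).

    QCM-D senses the hydrated ("wet") layer mass, typically ~30% above
    the bare ("dry") protein mass.
    """
    if wet_mass < 0:
        raise ValueError("wet_mass must be non-negative")
    if hydration_excess <= -1:
        raise ValueError("hydration_excess must exceed -1")
    return wet_mass / (1.0 + hydration_excess)


def footprint_gamma(area_nm2: float) -> float:
    """Close-packed surface concentration 1/(N_A * A) in mol cm^-2 (A in nm^2)."""
    if area_nm2 <= 0:
        raise ValueError("footprint area must be positive")
    return 1.0 / (AVOGADRO * area_nm2 * 1e-14)


def orientation_packing(geometry: IgGGeometry = IgGGeometry()) -> PackingDensities:
    """Theoretical close-packed antibody surface concentrations (mol cm^-2).

    An upright molecule occupies the Fab-arm cross-section, a tilted one
    lies on its effective length x thickness, a flat one on its
    effective length x Fab length; Gamma = 1/(N_A*A) decreases strictly
    as the footprint grows.
    """
    fp = geometry.footprints_nm2
    return PackingDensities(
        vertical=footprint_gamma(fp["vertical"]),
        tilted=footprint_gamma(fp["tilted"]),
        horizontal=footprint_gamma(fp["horizontal"]),
    )


# ---------------------------------------------------------------------------
# dissipation-vs-frequency diagnostics


def dd_df_slope(trace: QcmdTrace, stage: str, overtone: int = 3) -> SlopeFit:
    """OLS of ΔD (1e-6 units) on Δf (Hz) over one stage span."""
    st = trace.stage(stage)
    if st.end - st.start < 10:
        raise ValueError("stage span must contain at least 10 samples")
    x = trace.delta_f[overtone][st.start : st.end]
    y = trace.delta_d[overtone][st.start : st.end]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in delta_f: slope undefined")
    fit = linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    return SlopeFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        sse=float(resid @ resid),
    )


def _hinge_fit(x: np.ndarray, y: np.ndarray, b: float) -> tuple[np.ndarray, float]:
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - b, 0.0)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def two_segment_dd_df(
    delta_f: np.ndarray,
    delta_d: np.ndarray,
    min_segment: int = 10,
) -> SlopeFit:
    """Continuous two-segment (broken-stick) fit of ΔD on Δf.

    The breakpoint is chosen by exhaustive search over sample abscissae
    with at least ``min_segment`` points on each side, minimizing total
    squared error.  Because the single straight line is nested in every
    candidate model, the two-segment SSE never exceeds the single-line
    SSE.  With fewer than ``2*min_segment`` points the function falls
    back to a single-line fit and flags it.
    """
    x = np.asarray(delta_f, dtype=float)
    y = np.asarray(delta_d, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in delta_f: slope undefined")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    n = len(xs)

    line = linregress(xs, ys)
    line_resid = ys - (line.slope * xs + line.intercept)
    line_sse = float(line_resid @ line_resid)

    if n < 2 * min_segment:
        return SlopeFit(
            slope=float(line.slope),
            intercept=float(line.intercept),
            r_squared=float(line.rvalue**2),
            sse=line_sse,
            fallback_single=True,
            no_breakpoint=True,
        )

    best = None
    for i in range(min_segment, n - min_segment + 1):
        b = xs[i - 1]
        if b >= xs[-1] or b <= xs[0]:
            continue
        coef, sse = _hinge_fit(xs, ys, b)
        if best is None or sse < best[1]:
            best = (coef, sse, b)
    coef, sse, b = best
    slope1, slope2 = float(coef[1]), float(coef[1] + coef[2])
    sst = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    no_bp = abs(slope2 - slope1) <= 1e-6 * max(1.0, abs(slope1))
    return SlopeFit(
        slope=slope1,
        intercept=float(coef[0]),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        breakpoint=float(b),
        slope2=slope2,
        sse=min(sse, line_sse),
        no_breakpoint=no_bp,
    )
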