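"""Synthetic instrument-data generator for the SPR/QCM-D pipeline.

No raw instrument traces are publicly deposited for this assay, so every
pipeline input is emulated here with the statistical structure the
analysis assumes: two-state kinetic sensorgrams at the study's four
EV concentrations, staircase QCM-D traces obeying the published
log-linear frequency-step relations, blank replicate sets for LOD
estimation, and quantification panels with reference (NTA-style) values.

All generators are deterministic given (config, seed): randomness flows
through :func:`numpy.random.default_rng` seeded from a SeedSequence
keyed per product so that, e.g., sensorgrams and blanks drawn from the
same master seed are independent but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import zlib

import numpy as np

from .calibration import BlankSet, CalibrationModel, ReferenceValue
from .kinetics import (
    InjectionProtocol,
    Sensorgram,
    TwoStateRateSet,
    particles_to_molar,
    simulate_two_state,
)
from .qcmd import QcmdTrace, StageAnnotation

__all__ = [
    "CHANNELS",
    "PUBLISHED_RATES",
    "QCMD_CALIBRATIONS",
    "SPR_CALIBRATIONS",
    "ANTIBODY_TOTAL_SHIFTS_HZ",
    "GeneratorConfig",
    "gen_sensorgram_set",
    "gen_qcmd_trace",
    "gen_blankset",
    "gen_sample_panel",
]

CHANNELS = ("anti-CD9", "anti-CD63", "anti-CD81")

#: Two-state rate constants per antibody channel (study values); the
#: saturation response rmax is not published and defaults to 100 RU.
PUBLISHED_RATES: dict[str, TwoStateRateSet] = {
    "anti-CD9": TwoStateRateSet(
        ka1=1.67e2, kd1=6.66e-4, ka2=7.46e-2, kd2=1.87e-6, rmax=100.0, channel="anti-CD9"
    ),
    "anti-CD63": TwoStateRateSet(
        ka1=3.48e3, kd1=9.41e-1, ka2=6.81e-2, kd2=1.11e-5, rmax=100.0, channel="anti-CD63"
    ),
    "anti-CD81": TwoStateRateSet(
        ka1=1.76e2, kd1=1.43e-2, ka2=1.67e-1, kd2=1.06e-2, rmax=100.0, channel="anti-CD81"
    ),
}

#: Published QCM-D calibrations: |EV-stage frequency step| (Hz) =
#: slope*log10(C_EVs) + intercept, with the study's R^2.
QCMD_CALIBRATIONS: dict[str, tuple[float, float, float]] = {
    "anti-CD9": (1.75, -6.03, 0.9991),
    "anti-CD63": (2.02, -6.50, 0.9993),
    "anti-CD81": (1.30, -4.07, 0.9895),
}

#: SPR calibrations (EV-response/antibody-capture-response ratio per
#: decade).  SYNTHETIC placeholders: the study shows these only
#: graphically, so the coefficients here are generator parameters and
#: are never compared against published values.
SPR_CALIBRATIONS: dict[str, tuple[float, float]] = {
    "anti-CD9": (0.25, -1.0),
    "anti-CD63": (0.25, -1.0),
    "anti-CD81": (0.25, -1.0),
}

#: Total antibody-stage frequency levels (Hz), inclusive of the -12 Hz
#: cysteamine offset.
ANTIBODY_TOTAL_SHIFTS_HZ: dict[str, float] = {
    "anti-CD9": -27.0,
    "anti-CD63": -37.5,
    "anti-CD81": -30.3,
}

#: Default antibody-stage dD/df slopes (1e-6 per Hz), within the
#: observed rigidity interval [-0.043, -0.029].
ANTIBODY_DD_DF_SLOPES: dict[str, float] = {
    "anti-CD9": -0.032,
    "anti-CD63": -0.029,
    "anti-CD81": -0.043,
}

#: The study's four calibration concentrations (particles/mL).
STUDY_CONCENTRATIONS = (6.1e4, 6.1e5, 6.1e6, 6.1e7)


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions the generators emulate. The seed is mandatory.

    Noise defaults: SPR additive SD is 1% of the maximum response of
    each sensorgram; QCM-D frequency noise SD 0.2 Hz and dissipation
    noise SD 0.05e-6; drift defaults to 0.  Blank SDs set LOD-scale
    behaviour; panel noise is a multiplicative CV on the effective
    captured concentration (replicate-to-replicate capture variability).
    """

    seed: int
    concentrations: tuple[float, ...] = STUDY_CONCENTRATIONS  # particles/mL
    spr_noise_sd_frac: float = 0.01  # additive SD as fraction of max response
    spr_noise_cv: float = 0.0  # multiplicative CV on the response
    qcmd_freq_noise_sd: float = 0.2  # Hz
    qcmd_diss_noise_sd: float = 0.05  # 1e-6 units
    qcmd_drift_hz_per_s: float = 0.0
    stage_duration_s: float = 600.0
    stage_tau_s: float = 60.0
    sampling_interval_s: float = 1.0
    spr_blank_mean: float = 0.0
    spr_blank_sd: float = 0.03  # ratio units
    qcmd_blank_mean: float = 0.0
    qcmd_blank_sd: float = 0.2  # Hz
    panel_conc_cv: float = 0.10  # CV of effective captured concentration
    panel_reference_cv: float = 0.05  # CV of the reference method
    panel_dilution: float = 1e5
    panel_replicates: int = 3
    rates: dict = field(default_factory=lambda: dict(PUBLISHED_RATES))
    qcmd_calibrations: dict = field(default_factory=lambda: dict(QCMD_CALIBRATIONS))
    spr_calibrations: dict = field(default_factory=lambda: dict(SPR_CALIBRATIONS))

    def __post_init__(self) -> None:
        for name in (
            "spr_noise_sd_frac", "spr_noise_cv", "qcmd_freq_noise_sd",
            "qcmd_diss_noise_sd", "spr_blank_sd", "qcmd_blank_sd",
            "panel_conc_cv", "panel_reference_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


_STREAMS = {"spr": 1, "qcmd": 2, "blank": 3, "panel": 4}


def _stable_key(s: str) -> int:
    """Process-independent integer key for a string (crc32)."""
    return zlib.crc32(s.encode("utf-8")) % 2**31


def _rng(config: GeneratorConfig, stream: str, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAMS[stream], *map(int, key)])
    )


def qcmd_model(config: GeneratorConfig, channel: str) -> CalibrationModel:
    """The generating QCM-D calibration model for a channel."""
    slope, intercept, r2 = config.qcmd_calibrations[channel]
    return CalibrationModel(
        channel=channel, signal_kind="qcmd_freq_step", slope=slope,
        intercept=intercept, r_squared=r2,
        range_low=min(config.concentrations), range_high=max(config.concentrations),
    )


def spr_model(config: GeneratorConfig, channel: str) -> CalibrationModel:
    """The generating (synthetic-coefficient) SPR calibration model."""
    slope, intercept = config.spr_calibrations[channel]
    return CalibrationModel(
        channel=channel, signal_kind="spr_ratio", slope=slope,
        intercept=intercept, r_squared=float("nan"),
        range_low=min(config.concentrations), range_high=max(config.concentrations),
    )


def gen_sensorgram_set(
    config: GeneratorConfig,
    channel: str,
    protocol: InjectionProtocol | None = None,
) -> list[Sensorgram]:
    """Two-state sensorgrams at each configured concentration, plus noise.

    Concentrations (particles/mL) are converted to molar before
    simulation.  Noise is additive Gaussian with SD
    ``spr_noise_sd_frac * max|R|`` per sensorgram, then multiplicative
    Gaussian with CV ``spr_noise_cv``.  Equal seeds give bit-identical
    output.
    """
    if channel not in config.rates:
        raise KeyError(f"no rate set configured for channel {channel!r}")
    rates = config.rates[channel]
    out = []
    for i, c_particles in enumerate(config.concentrations):
        rng = _rng(config, "spr", _stable_key(channel), i)
        molar = particles_to_molar(c_particles)
        proto = (
            replace(protocol, analyte_concentration=molar)
            if protocol is not None
            else InjectionProtocol(
                analyte_concentration=molar,
                sampling_interval=config.sampling_interval_s,
            )
        )
        s = simulate_two_state(rates, proto)
        resp = s.response.copy()
        if config.spr_noise_sd_frac > 0:
            sd = config.spr_noise_sd_frac * float(np.max(np.abs(resp)))
            resp = resp + rng.normal(0.0, sd, len(resp))
        if config.spr_noise_cv > 0:
            resp = resp * (1.0 + rng.normal(0.0, config.spr_noise_cv, len(resp)))
        out.append(
            Sensorgram(s.time, resp, s.phase, s.concentration, channel,
                       extras={"c_particles_per_ml": c_particles})
        )
    return out


def gen_qcmd_trace(
    config: GeneratorConfig,
    channel: str,
    ev_concentration: float,
    two_segment: bool = False,
    overtones: tuple[int, ...] = (3,),
) -> QcmdTrace:
    """Staircase QCM-D trace: buffer, cysteamine, antibody, EV stages.

    Frequency levels: 0 (buffer), -12 Hz (cysteamine), the channel's
    total antibody level, then an EV step whose magnitude follows the
    channel's log-linear calibration.  Each stage approaches its plateau
    exponentially (time constant ``stage_tau_s``).  Dissipation is
    co-generated from per-stage dD/df slopes; ``two_segment=True``
    switches the EV stage to a broken-stick dD/df relation (slopes
    -0.02 then -0.06 beyond 60% of the step), as seen at the highest EV
    concentration where vesicle crowding softens the layer.
    """
    if ev_concentration <= 0:
        raise ValueError("ev_concentration must be positive")
    if channel not in config.qcmd_calibrations:
        raise KeyError(f"no QCM-D calibration configured for channel {channel!r}")
    slope, intercept, _ = config.qcmd_calibrations[channel]
    ev_step = slope * np.log10(ev_concentration) + intercept
    if ev_step <= 0:
        raise ValueError("concentration below the calibration's positive-signal domain")

    level_csh = -12.0
    level_ab = ANTIBODY_TOTAL_SHIFTS_HZ[channel]
    level_ev = level_ab - ev_step
    levels = [0.0, level_csh, level_ab, level_ev]
    names = ["buffer", "csh", "antibody", "ev"]
    dd_slopes = {
        "csh": -0.005,
        "antibody": ANTIBODY_DD_DF_SLOPES[channel],
        "ev": -0.035,
    }

    n_stage = int(round(config.stage_duration_s / config.sampling_interval_s))
    t = np.arange(4 * n_stage) * config.sampling_interval_s
    f = np.empty(4 * n_stage)
    d = np.empty(4 * n_stage)
    stages = []
    f_prev, d_prev = 0.0, 0.0
    for k, (name, level) in enumerate(zip(names, levels)):
        lo, hi = k * n_stage, (k + 1) * n_stage
        tt = np.arange(n_stage) * config.sampling_interval_s
        seg_f = level + (f_prev - level) * np.exp(-tt / config.stage_tau_s)
        rel = seg_f - f_prev  # 0 -> (level - f_prev), monotone
        if name == "buffer":
            seg_d = np.full(n_stage, d_prev)
        elif name == "ev" and two_segment:
            step = level - f_prev  # negative
            bp = 0.6 * step
            s1, s2 = -0.02, -0.06
            seg_d = d_prev + np.where(
                rel >= bp, s1 * rel, s1 * bp + s2 * (rel - bp)
            )
        else:
            seg_d = d_prev + dd_slopes[name] * rel
        f[lo:hi] = seg_f
        d[lo:hi] = seg_d
        stages.append(StageAnnotation(name, lo, hi))
        f_prev, d_prev = seg_f[-1], seg_d[-1]

    delta_f, delta_d = {}, {}
    for j, ot in enumerate(overtones):
        rng = _rng(config, "qcmd", _stable_key(channel), int(round(ev_concentration)) % 2**31, ot)
        fo = f + config.qcmd_drift_hz_per_s * t
        if config.qcmd_freq_noise_sd > 0:
            fo = fo + rng.normal(0.0, config.qcmd_freq_noise_sd, len(t))
        do = d.copy()
        if config.qcmd_diss_noise_sd > 0:
            do = do + rng.normal(0.0, config.qcmd_diss_noise_sd, len(t))
        delta_f[ot], delta_d[ot] = fo, do
    return QcmdTrace(time=t, delta_f=delta_f, delta_d=delta_d, stages=stages,
                     extras={"channel": channel, "ev_concentration": ev_concentration})


def gen_blankset(
    config: GeneratorConfig,
    n: int = 5,
    channel: str = "anti-CD9",
    signal_kind: str = "qcmd_freq_step",
) -> BlankSet:
    """n independent blank draws from the configured blank noise model."""
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = _rng(config, "blank", _stable_key(channel), _stable_key(signal_kind), n)
    if signal_kind == "spr_ratio":
        mean, sd = config.spr_blank_mean, config.spr_blank_sd
    else:
        mean, sd = config.qcmd_blank_mean, config.qcmd_blank_sd
    return BlankSet(values=mean + sd * rng.standard_normal(n),
                    channel=channel, signal_kind=signal_kind)


def gen_sample_panel(
    config: GeneratorConfig,
    true_concentrations: dict[str, float],
    channels: tuple[str, ...] = CHANNELS,
    signal_kind: str = "qcmd_freq_step",
) -> tuple[list[dict], dict[str, ReferenceValue], dict[str, float]]:
    """Quantification panel rows plus reference values and hidden truth.

    For each sample and channel, ``panel_replicates`` replicate signals
    are produced by passing the diluted truth through the channel's
    calibration after multiplying by a lognormal-free multiplicative
    (1 + CV*eps) capture-efficiency factor.  Reference values emulate an
    NTA measurement of the same truth with CV ``panel_reference_cv``.

    Returns (rows, references, truth); rows carry a ``replicate`` column
    beyond the standard panel schema.
    """
    if any(v <= 0 for v in true_concentrations.values()):
        raise ValueError("true concentrations must be positive")
    rows: list[dict] = []
    references: dict[str, ReferenceValue] = {}
    for si, (sample_id, truth) in enumerate(sorted(true_concentrations.items())):
        rng_ref = _rng(config, "panel", 0, si)
        ref_draws = truth * (1.0 + config.panel_reference_cv
                             * rng_ref.standard_normal(max(config.panel_replicates, 2)))
        references[sample_id] = ReferenceValue(
            concentration=float(np.mean(ref_draws)),
            sd=float(np.std(ref_draws, ddof=1)),
        )
        for ci, channel in enumerate(channels):
            model = (spr_model(config, channel) if signal_kind == "spr_ratio"
                     else qcmd_model(config, channel))
            rng = _rng(config, "panel", 1, si, ci)
            for rep in range(config.panel_replicates):
                eff = truth / config.panel_dilution
                if config.panel_conc_cv > 0:
                    eff = eff * (1.0 + config.panel_conc_cv * rng.standard_normal())
                eff = max(eff, 1e-300)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "channel": channel,
                        "signal": float(model.predict(eff)),
                        "dilution_factor": config.panel_dilution,
                        "reference_concentration": references[sample_id].concentration,
                        "reference_sd": references[sample_id].sd,
                        "replicate": rep,
                    }
                )
    return rows, references, dict(true_concentrations)
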