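"""End-to-end orchestration: synthesize or load inputs, run every
analysis stage, and emit a single machine-readable JSON report.

The report is a pure function of the configuration (including the seed):
rerunning with the same config reproduces it bit-identically.  Progress
is logged to stderr with ISO timestamps; timestamps never enter the
report itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import calibration as cal
from . import kinetics, qcmd, synthetic_data as synth
from .qcmd import extract_steps, dd_df_slope, sauerbrey_gamma, orientation_packing

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("evsense")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full synthetic-data pipeline run."""

    seed: int
    channels: tuple[str, ...] = synth.CHANNELS
    stages: tuple[str, ...] = ("kinetics", "qcmd", "calibration", "quantify")
    concentrations: tuple[float, ...] = synth.STUDY_CONCENTRATIONS
    panel_truths: dict = field(
        default_factory=lambda: {"sample-1": 3.6e9, "sample-2": 2.4e9}
    )
    signal_kind: str = "qcmd_freq_step"
    fit_fix_rmax: bool = True
    qc_retention_threshold: float = 90.0
    generator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        for key in ("channels", "stages", "concentrations"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def generator_config(self) -> synth.GeneratorConfig:
        return synth.GeneratorConfig(
            seed=self.seed,
            concentrations=self.concentrations,
            **self.generator_overrides,
        )

    def canonical_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)

        return json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=default
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage_kinetics(config: PipelineConfig, gconfig) -> dict:
    out = {}
    for channel in config.channels:
        sensorgrams = synth.gen_sensorgram_set(gconfig, channel)
        fix = {"rmax": gconfig.rates[channel].rmax} if config.fit_fix_rmax else None
        fit = kinetics.fit_two_state(sensorgrams, fix=fix)
        consts = fit.constants
        out[channel] = {
            "rates": {
                n: getattr(fit.rates, n) for n in ("ka1", "kd1", "ka2", "kd2", "rmax")
            },
            "stderr": fit.stderr,
            "KD1_M": consts.KD1,
            "KD2": consts.KD2,
            "KD_total_M": consts.KD_total,
            "rss": fit.rss,
            "converged": fit.converged,
            "n_sensorgrams": fit.n_sensorgrams,
        }
    return out


def _stage_qcmd(config: PipelineConfig, gconfig) -> dict:
    out = {}
    packing = orientation_packing()
    for channel in config.channels:
        trace = synth.gen_qcmd_trace(gconfig, channel, max(config.concentrations))
        steps = {s.stage: s for s in extract_steps(trace)}
        csh_gamma = sauerbrey_gamma(steps["csh"].delta_f_step, qcmd.CYSTEAMINE)
        ab_slope = dd_df_slope(trace, "antibody")
        out[channel] = {
            "steps_hz": {name: s.delta_f_step for name, s in steps.items()},
            "csh_gamma_nmol_cm2": csh_gamma * 1e9,
            "antibody_dd_df_slope": ab_slope.slope,
            "antibody_dd_df_r2": ab_slope.r_squared,
        }
    out["packing_pmol_cm2"] = {
        "vertical": packing.vertical * 1e12,
        "tilted": packing.tilted * 1e12,
        "horizontal": packing.horizontal * 1e12,
    }
    return out


def _stage_calibration(config: PipelineConfig, gconfig) -> dict:
    out = {}
    concs = np.asarray(config.concentrations)
    for channel in config.channels:
        if config.signal_kind == "spr_ratio":
            model0 = synth.spr_model(gconfig, channel)
        else:
            model0 = synth.qcmd_model(gconfig, channel)
        signals = model0.predict(concs)
        blanks = synth.gen_blankset(gconfig, n=5, channel=channel,
                                    signal_kind=config.signal_kind)
        model = cal.calibrate_with_blanks(
            concs, signals, blanks, channel=channel, signal_kind=config.signal_kind
        )
        out[channel] = {
            "slope": model.slope,
            "intercept": model.intercept,
            "r_squared": model.r_squared,
            "blank_mean": model.blank_mean,
            "blank_sd": model.blank_sd,
            "lod_particles_per_ml": model.lod,
            "loq_particles_per_ml": model.loq,
            "lod_reported": cal.round_to_2sf(model.lod),
            "loq_reported": cal.round_to_2sf(model.loq),
        }
    return out


def _stage_quantify(config: PipelineConfig, gconfig, calibrations: dict) -> dict:
    rows, references, truth = synth.gen_sample_panel(
        gconfig, config.panel_truths, channels=config.channels,
        signal_kind=config.signal_kind,
    )
    models = {}
    for channel in config.channels:
        c = calibrations[channel]
        models[channel] = cal.CalibrationModel(
            channel=channel, signal_kind=config.signal_kind,
            slope=c["slope"], intercept=c["intercept"], r_squared=c["r_squared"],
            range_low=min(config.concentrations),
            range_high=max(config.concentrations),
        )
    panel = cal.quantify_panel(rows, models, references)
    agreement = cal.method_agreement(panel)
    return {
        "samples": [
            {
                "sample_id": r.sample_id,
                "channel": r.channel,
                "concentration_particles_per_ml": r.concentration,
                "sd": r.sd,
                "valid": r.valid,
                "reference": panel.references[r.sample_id].concentration,
            }
            for r in panel.results
        ],
        "per_channel_bias": agreement.per_channel_bias,
        "overall_mare": agreement.overall_mare,
        "flagged": agreement.flagged,
        "truth": truth,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the configured stages and return (and optionally write) the report."""
    logging.basicConfig(
        stream=sys.stderr,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    gconfig = config.generator_config()
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "stages": {},
    }
    calibrations = None
    for stage in config.stages:
        logger.info("stage %s: start", stage)
        try:
            if stage == "kinetics":
                report["stages"]["kinetics"] = _stage_kinetics(config, gconfig)
            elif stage == "qcmd":
                report["stages"]["qcmd"] = _stage_qcmd(config, gconfig)
            elif stage == "calibration":
                calibrations = _stage_calibration(config, gconfig)
                report["stages"]["calibration"] = calibrations
            elif stage == "quantify":
                if calibrations is None:
                    calibrations = _stage_calibration(config, gconfig)
                    report["stages"]["calibration"] = calibrations
                for channel in config.channels:
                    if channel not in calibrations:
                        raise PipelineError(
                            f"stage quantify: missing calibration for channel {channel!r}"
                        )
                report["stages"]["quantify"] = _stage_quantify(
                    config, gconfig, calibrations
                )
            else:
                raise PipelineError(f"unknown stage {stage!r}")
        except PipelineError:
            raise
        except Exception as exc:
            if outdir is not None:
                _write_report(report | {"failed_stage": stage}, outdir)
            raise PipelineError(f"stage {stage}: {exc}") from exc
        logger.info("stage %s: done", stage)
    if outdir is not None:
        _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
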