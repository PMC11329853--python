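"""End-to-end orchestration: simulate -> decode -> QC -> kinematics ->
align -> validate, as a configured, logged, reproducible run."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import alignment, kinematics, sensor, synthetic, validity
from .errors import ConfigurationError, FormatError, MTValidateError, ParameterError
from .protocol import DEFAULT_FLIP_SET, Movement

__all__ = ["HampelConfig", "RunConfig", "RunResult", "load_config", "run_pipeline"]

log = logging.getLogger("mtvalidate")


class HampelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    window_halfwidth: int = 5
    n_mad: float = 3.0


class RunConfig(BaseModel):
    """Validated configuration of a full pipeline run.

    Either ``data_dir`` points at an existing dataset (a directory with a
    ``manifest.json``) or ``simulate`` holds a scenario to generate first.
    Unknown keys are rejected.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    out_dir: str = "mtvalidate_out"
    data_dir: str | None = None
    simulate: synthetic.ScenarioConfig | None = None
    seed: int | None = None
    threshold_sd: float = 10.0
    hampel: HampelConfig = Field(default_factory=HampelConfig)
    flip_set: tuple[Movement, ...] = tuple(sorted(DEFAULT_FLIP_SET))
    baseline_r0_window_s: float = 0.5
    zero_shift_window_s: float = 0.25
    target_rate_hz: float | None = None
    max_gap_frames: int = 10
    demean: bool = False
    gauge_factor: float | None = None
    write_heatmap: bool = True

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.data_dir is None and self.simulate is None:
            raise ConfigurationError("either data_dir or simulate must be given")
        if self.threshold_sd <= 0:
            raise ParameterError("threshold_sd must be > 0")
        return self

    def effective_scenario(self) -> synthetic.ScenarioConfig | None:
        """Scenario with the run-level seed override applied."""
        if self.simulate is None:
            return None
        if self.seed is None:
            return self.simulate
        return self.simulate.model_copy(update={"seed": self.seed})


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    from pydantic import ValidationError

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as e:
        raise ConfigurationError(f"{path}: {e}") from e


@dataclass
class RunResult:
    """Artifacts of one pipeline run."""

    report: dict
    trials: pd.DataFrame
    summary: pd.DataFrame
    qc: sensor.QCReport


def _load_manifest(data_dir: Path) -> dict:
    path = data_dir / "manifest.json"
    if not path.exists():
        raise FormatError(f"no manifest.json under {data_dir}")
    return json.loads(path.read_text())


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all pipeline stages in order and write the run artifacts.

    Outputs under ``out_dir``: ``trial_correlations.csv`` (per-trial
    zero-lag coefficients), ``validity_summary.csv`` (median/range per
    movement x sensor), ``run_report.json`` (per-stage counts, QC report,
    effective configuration) and optionally ``validity_heatmap.png``.
    Identical configuration and seed yield identical artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        # -- stage 1: obtain dataset ---------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            scenario = config.effective_scenario()
            data_dir = Path(config.data_dir) if config.data_dir else out / "dataset"
            log.info("simulating scenario: %d participants -> %s",
                     scenario.n_participants, data_dir)
            manifest = synthetic.generate_scenario(scenario, data_dir)
        else:
            stage = "load"
            data_dir = Path(config.data_dir)
            manifest = _load_manifest(data_dir)

        flip_set = frozenset(Movement(m) for m in config.flip_set)
        ref_map = validity.DEFAULT_SENSOR_REFERENCE_MAP

        # -- stage 2: decode + filter sensor streams -----------------------
        stage = "decode"
        streams: list[sensor.ResistanceSeries] = []
        stream_meta: dict[str, dict] = {}
        for part in manifest["participants"]:
            for trial in part["trials"]:
                for sid_str, rel in trial["sensor_logs"].items():
                    rs = sensor.decode_log(
                        data_dir / rel, participant_id=part["id"],
                        movement=Movement(trial["movement"]))
                    rs, _mask = sensor.hampel_filter_series(
                        rs, config.hampel.window_halfwidth, config.hampel.n_mad)
                    streams.append(rs)
                    stream_meta[rs.trial_id + f":{rs.sensor_id}"] = trial
        n_decoded = len(streams)
        log.info("decoded and filtered %d sensor streams", n_decoded)

        # -- stage 3: stream QC --------------------------------------------
        stage = "qc"
        qc = sensor.flag_failed_streams(streams, threshold_sd=config.threshold_sd)
        flagged = qc.flagged_keys()
        log.info("QC flagged %d/%d streams (threshold %.1f SD)",
                 qc.n_flagged, qc.n_streams, config.threshold_sd)

        # -- stage 4: kinematics -------------------------------------------
        stage = "kinematics"
        angle_cache: dict[str, kinematics.KinematicAngleSeries] = {}
        trial_info: dict[str, dict] = {}
        for part in manifest["participants"]:
            for trial in part["trials"]:
                seq = kinematics.read_marker_tsv(
                    data_dir / trial["marker_file"],
                    required_labels=kinematics.SpineModelDefinition().required_markers)
                seq = kinematics.interpolate_gaps(seq, config.max_gap_frames)
                angle_cache[trial["trial_id"]] = kinematics.compute_lumbar_angles(seq)
                trial_info[trial["trial_id"]] = {**trial, "participant": part["id"]}
        log.info("computed lumbar angles for %d trials", len(angle_cache))

        # -- stage 5: align, normalize, correlate --------------------------
        stage = "align"
        results: list[validity.TrialResult] = []
        n_excluded_qc = 0
        for rs in streams:
            trial = trial_info[rs.trial_id]
            mv = Movement(trial["movement"])
            key = (rs.participant_id, mv, rs.sensor_id, rs.trial_id)
            if key in flagged:
                n_excluded_qc += 1
                results.append(validity.TrialResult(
                    rs.participant_id, mv, rs.sensor_id, ref_map[rs.sensor_id],
                    float("nan"), None, False))
                continue
            strain = sensor.compute_strain(
                rs, baseline_window_s=config.baseline_r0_window_s,
                gauge_factor=config.gauge_factor)
            kas = angle_cache[rs.trial_id]
            ref_name = ref_map[rs.sensor_id]
            angle_1d, meta = kinematics.primary_angle(kas, mv, ref_name)
            ts, es, ta, an = alignment.align_and_trim(
                strain.t, strain.eps,
                datetime.fromisoformat(trial["sensor_start"]),
                kas.t, angle_1d,
                datetime.fromisoformat(trial["mocap_start"]))
            t_c, eps_c, ang_c = alignment.resample_to_common_base(
                ts, es, ta, an, target_rate_hz=config.target_rate_hz)
            pair = alignment.AlignedPair(
                t=t_c, eps=eps_c, angle=ang_c, movement=mv,
                sensor_id=rs.sensor_id, reference_angle_name=ref_name,
                participant_id=rs.participant_id, trial_id=rs.trial_id,
                meta=meta)
            pair = alignment.normalize_pair(
                pair, flip_set=flip_set,
                baseline_window_s=config.zero_shift_window_s)
            results.append(validity.evaluate_trial(pair, ref_map,
                                                   demean=config.demean))

        # -- stage 6: aggregate + write ------------------------------------
        stage = "aggregate"
        trials_df = validity.results_to_frame(results)
        summary_df = validity.aggregate(trials_df)
        trials_df.to_csv(out / "trial_correlations.csv", index=False,
                         float_format="%.6f")
        summary_df.to_csv(out / "validity_summary.csv", index=False,
                          float_format="%.6f")
        n_degenerate = int(trials_df["degenerate"].sum())
        report = {
            "stages": {
                "streams_decoded": n_decoded,
                "streams_flagged": qc.n_flagged,
                "streams_excluded_qc": n_excluded_qc,
                "trials_with_kinematics": len(angle_cache),
                "pairs_correlated": int(trials_df["r0"].notna().sum()),
                "pairs_degenerate": n_degenerate,
                "removal_fraction": qc.removal_fraction,
            },
            "qc": qc.to_dict(),
            "config": json.loads(config.model_dump_json()),
        }
        (out / "run_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        if config.write_heatmap:
            stage = "plot"
            import matplotlib.pyplot as plt
            fig = validity.plot_validity_heatmap(
                trials_df, out / "validity_heatmap.png")
            plt.close(fig)
        log.info("run complete: %d pairs correlated, summary in %s",
                 report["stages"]["pairs_correlated"], out)
        return RunResult(report=report, trials=trials_df, summary=summary_df, qc=qc)
    except MTValidateError as e:
        raise type(e)(f"pipeline stage '{stage}' failed: {e}") from e
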