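"""End-to-end orchestration: simulate -> condition -> gate -> sync ->
pair -> grouped-CV train -> agreement.

A single serializable :class:`PipelineConfig` is the only source of
parameters; every run emits a :class:`RunManifest` with a config hash,
stage timings and record counts, so identical configs are auditable as
identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .agreement import AgreementReport, bland_altman, fda_check
from .model import CVPlan, HeldOutPredictions, ModelReport, make_folds, train_bp_model
from .preprocess import FilterSpec, WindowSpec
from .quality import ExclusionRule
from .simulate import SimulationConfig, simulate_cohort
from .sync import build_paired_database

__all__ = ["PipelineConfig", "RunManifest", "StageFailure", "run_end_to_end",
           "estimate_bp_stream", "PipelineResult"]

log = logging.getLogger("neobp")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: BaseException, manifest: "RunManifest"):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class PipelineConfig:
    n_patients: int = 24
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    exclusion: ExclusionRule = field(default_factory=ExclusionRule)
    cv_folds: int = 10
    hidden: tuple[int, ...] = (64, 32)
    max_iter: int = 150
    alpha: float = 0.05
    sim_seed: int = 42
    fold_seed: int = 7
    train_seed: int = 7
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, typ in (("simulation", SimulationConfig), ("filter", FilterSpec),
                         ("window", WindowSpec), ("exclusion", ExclusionRule)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        if "hidden" in kwargs:
            kwargs["hidden"] = tuple(kwargs["hidden"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    config_hash: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    completed: list[str] = field(default_factory=list)

    def check_conservation(self) -> None:
        c = self.counts
        if "paired_windows" in c and "candidate_windows" in c:
            assert c["paired_windows"] <= c["candidate_windows"]
        if "evaluated_points" in c and "paired_windows" in c:
            assert c["evaluated_points"] <= c["paired_windows"]


@dataclass
class PipelineResult:
    manifest: RunManifest
    report_per_individual: AgreementReport
    report_pooled: AgreementReport
    model_report: ModelReport
    held_out: HeldOutPredictions
    plan: CVPlan
    models: dict = field(default_factory=dict)  # fold -> fitted regressor


def estimate_bp_stream(sensors, meta, model, window: Optional[WindowSpec] = None,
                       fspec: Optional[FilterSpec] = None, q_min: float = 2.5):
    """Deployment-style inference on a 4-channel sensor stream alone.

    No arterial reference is available here, so gating uses the quality
    score only. Each hop yields ``(time_s, BPTriplet or None)``; gated
    windows produce ``None`` (a gap), never an interpolated value.
    Estimates are invariant to any affine recalibration of the raw
    sensor stream.
    """
    from .model import featurize
    from .preprocess import bandpass_filter, detect_hfov, normalize_window, notch_filter
    from .preprocess import TooShortError
    from .quality import NoUsableChannelError, select_best_channel
    from .beats import segment_beats

    window = window or WindowSpec()
    fspec = fspec or FilterSpec()
    fs = sensors[0].fs_hz
    filt = [bandpass_filter(s, fspec) for s in sensors]
    freqs = []
    for s in filt:
        try:
            f_v = detect_hfov(s)
        except TooShortError:
            f_v = None
        if f_v is not None:
            freqs.append(f_v)
    if len(freqs) >= 2:
        f_v = float(np.median(freqs))
        filt = [notch_filter(s, f_v) for s in filt]
    L = window.length_samples(fs)
    out = []
    for w0 in window.starts(len(filt[0].samples), fs):
        w0 = int(w0)
        t = w0 / fs
        try:
            ch, score = select_best_channel(
                [s.samples[w0:w0 + L] for s in filt], fs)
        except NoUsableChannelError:
            out.append((t, None))
            continue
        chan = filt[ch].samples
        seg = chan[w0:w0 + L]
        sb = segment_beats(seg - seg.mean(), fs)
        if not sb or w0 + sb[0].start + L > len(chan) or score.q <= q_min:
            out.append((t, None))
            continue
        crop = normalize_window(chan[w0 + sb[0].start:w0 + sb[0].start + L])
        x = featurize(crop, meta.age_days, meta.weight_kg, fs=fs)
        out.append((t, model.predict_triplet(x)))
    return out


def run_end_to_end(config: PipelineConfig) -> PipelineResult:
    """Run the full pipeline on a freshly simulated cohort.

    Identical configs (including seeds) give identical manifest counts;
    agreement numbers are deterministic up to the regressor's documented
    floating-point ordering.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = RunManifest(config_hash=config.config_hash())

    def stage(name):
        class _T:
            def __enter__(self_t):
                self_t.t = time.perf_counter()
                log.info("stage %s ...", name)
            def __exit__(self_t, exc_type, exc, tb):
                manifest.stage_seconds[name] = time.perf_counter() - self_t.t
                if exc is None:
                    manifest.completed.append(name)
        return _T()

    try:
        with stage("simulate"):
            cohort = simulate_cohort(config.n_patients, config.simulation,
                                     seed=config.sim_seed)
            n_win = sum(len(config.window.starts(len(ds.sensors[0].samples),
                                                 ds.config.fs_hz))
                        for ds in cohort)
            manifest.counts["patients"] = len(cohort)
            manifest.counts["candidate_windows"] = int(n_win)
    except Exception as e:  # noqa: BLE001
        raise StageFailure("simulate", e, manifest) from e

    try:
        with stage("pair"):
            db, excl_log, sync_info = build_paired_database(
                cohort, window=config.window, rule=config.exclusion,
                fspec=config.filter, seed=config.sim_seed,
                sync_seed=config.sim_seed)
            manifest.counts["paired_windows"] = len(db)
            manifest.counts["excluded_windows"] = sum(
                1 for e in excl_log if e.decision == "drop")
            manifest.counts["patients_paired"] = len(
                {w.patient_id for w in db})
    except Exception as e:  # noqa: BLE001
        raise StageFailure("pair", e, manifest) from e

    try:
        with stage("train"):
            pids = sorted({w.patient_id for w in db})
            plan = make_folds(pids, k=config.cv_folds, seed=config.fold_seed)
            models, model_report, held = train_bp_model(
                db, plan, seed=config.train_seed, hidden=config.hidden,
                max_iter=config.max_iter)
            manifest.counts["evaluated_points"] = len(held.pred)
    except Exception as e:  # noqa: BLE001
        raise StageFailure("train", e, manifest) from e

    try:
        with stage("agreement"):
            rep_ind = bland_altman(held.pred, held.true, held.patient_ids,
                                   mode="per_individual")
            rep_pool = bland_altman(held.pred, held.true, mode="pooled")
    except Exception as e:  # noqa: BLE001
        raise StageFailure("agreement", e, manifest) from e

    manifest.check_conservation()
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=1))
        summary = {
            "per_individual": {k: asdict(v) for k, v in rep_ind.components.items()},
            "pooled": {k: asdict(v) for k, v in rep_pool.components.items()},
            "fda_per_individual": fda_check(rep_ind),
            "config_hash": manifest.config_hash,
        }
        (out / "agreement.json").write_text(json.dumps(summary, indent=1))
        from .io import write_exclusion_log
        write_exclusion_log(excl_log, out / "exclusions.csv")
    return PipelineResult(manifest=manifest, report_per_individual=rep_ind,
                          report_pooled=rep_pool, model_report=model_report,
                          held_out=held, plan=plan, models=models)
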