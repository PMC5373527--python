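"""End-to-end orchestration: simulate/load -> preprocess -> features -> CV.

A run is described by a :class:`PipelineConfig` and produces a
self-describing run directory: resolved config snapshot, log, feature CSVs,
CV report JSONs, confusion CSVs, and a method-comparison table when more
than one feature method is requested. Identical config (including seed)
reproduces identical outputs.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, evaluate, formats, preprocess
from .containers import EventList, FeatureMatrix, Recording
from .features_baseline import (DEFAULT_POWER_BAND, FilterBankSpec,
                                extract_bandpower)
from .features_td import extract_td_features
from .sim import SimConfig, generate_recording

logger = logging.getLogger(__name__)

METHODS = ("td", "csp", "fbcsp", "bandpower")


@dataclass
class PipelineConfig:
    """All stage parameters for one run; defaults mirror the simulated recording protocol."""

    source: str = "simulate"                  # "simulate" | "edf"
    edf_paths: list[str] = field(default_factory=list)
    events_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    resample_fs: float = 250.0
    band: tuple[float, float] = (6.0, 35.0)
    epoch_window: tuple[float, float] = (1.0, 3.0)
    analysis_window_s: float = 1.0
    ar_order: int = 4
    power_band: tuple[float, float] = DEFAULT_POWER_BAND
    filter_bank: list[tuple[float, float]] | None = None
    methods: tuple[str, ...] = ("td",)
    c_grid: tuple[float, ...] = classify.DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = classify.DEFAULT_GAMMA_GRID
    reps: int = 10
    folds: int = 10
    inner_folds: int = 10
    group_trials: bool = True
    standardize: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.source not in ("simulate", "edf"):
            raise ValueError("source must be 'simulate' or 'edf'")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.source == "edf":
            missing = [p for p in self.edf_paths if not Path(p).exists()]
            if missing or not self.edf_paths:
                raise ValueError(f"missing EDF inputs: {missing}")
            if not self.events_path or not Path(self.events_path).exists():
                raise ValueError("events_path required for edf source")
        self.sim.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = dict(d["sim"])
            if "rest_range_s" in sim:
                sim["rest_range_s"] = tuple(sim["rest_range_s"])
            if "bands" in sim:
                sim["bands"] = {k: tuple(v) for k, v in sim["bands"].items()}
            d["sim"] = SimConfig(**sim)
        for key in ("band", "epoch_window", "power_band", "methods",
                    "c_grid", "gamma_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("filter_bank"):
            d["filter_bank"] = [tuple(b) for b in d["filter_bank"]]
        return cls(**d)


def _load_input(cfg: PipelineConfig) -> tuple[Recording, EventList]:
    if cfg.source == "simulate":
        return generate_recording(cfg.sim)
    parts = [formats.read_edf(p) for p in cfg.edf_paths]
    data = np.concatenate([p.data for p in parts], axis=1)
    rec = Recording(data, parts[0].fs, parts[0].channel_labels)
    return rec, formats.read_events_csv(cfg.events_path)


def build_extractor(cfg: PipelineConfig, epochs, method: str):
    """Fold extractor for one feature method (CSP-family refits per fold)."""
    if method == "td":
        segs = preprocess.segment_windows(epochs, cfg.analysis_window_s)
        return classify.PrecomputedExtractor(extract_td_features(segs, cfg.ar_order))
    if method == "bandpower":
        return classify.PrecomputedExtractor(extract_bandpower(epochs, cfg.power_band))
    bank = FilterBankSpec(cfg.filter_bank) if cfg.filter_bank else None
    return classify.CSPRefitExtractor(epochs, method=method, filter_bank=bank)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write a self-describing run directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("mibci")
    root.addHandler(handler)
    try:
        config.to_yaml(out / "config.yaml")
        logger.info("loading input (%s)", config.source)
        rec, events = _load_input(config)
        in_fs = rec.fs
        logger.info("preprocessing: resample %g Hz, band %s", config.resample_fs,
                    config.band)
        rec = preprocess.resample(rec, config.resample_fs)
        rec = preprocess.bandpass(rec, *config.band)
        onsets = np.round(events.onsets * config.resample_fs / in_fs)
        events = EventList(onsets.astype(np.int64), events.labels)
        epochs = preprocess.extract_epochs(rec, events, *config.epoch_window)
        reports: dict[str, classify.CVReport] = {}
        for method in config.methods:
            logger.info("method %s: extracting and cross-validating", method)
            extractor = build_extractor(config, epochs, method)
            if isinstance(extractor, classify.PrecomputedExtractor):
                extractor.fm.to_csv(out / f"features_{method}.csv")
            report = classify.cross_validate_10x10(
                extractor, c_grid=config.c_grid, gamma_grid=config.gamma_grid,
                reps=config.reps, folds=config.folds,
                inner_folds=config.inner_folds, seed=config.seed,
                standardize=config.standardize,
                group_trials=config.group_trials)
            report.to_json(out / f"cv_report_{method}.json")
            cm = evaluate.ConfusionMatrix(report.class_list,
                                          report.confusion_counts)
            cm.to_frame().to_csv(out / f"confusion_{method}.csv")
            reports[method] = report
            logger.info("method %s: %.1f +/- %.1f %%", method,
                        report.mean_accuracy, report.sd_accuracy)
        if len(reports) > 1:
            comp = evaluate.compare_methods(reports, seed=config.seed)
            comp.summary.to_csv(out / "comparison_summary.csv", index=False)
            comp.pairwise.to_csv(out / "comparison_pairwise.csv", index=False)
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
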