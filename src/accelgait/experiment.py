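"""End-to-end experiments: simulate -> filter -> window -> train -> evaluate.

An :class:`ExperimentConfig` fixes every stage (cohort, filter, windowing,
scenario, network and all seeds) so a run is exactly reproducible.  Two
presets are provided: :func:`paper_config`, the full study protocol
(10 participants x 5 speeds x 3 x 60 s trials, 50 epochs, batch 512), and
:func:`scaled_config`, a desk-scale version (4 participants, 2 speeds x
2 trials x 30 s, 20 epochs) sized to run in minutes on one CPU while
preserving the intra-vs-inter comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .simulate import (SynthConfig, generate_population, simulate_trial,
                       write_trial)
from .preprocess import (FilterSpec, filter_trial, make_windows,
                         concat_windows, split_intra, split_loso)
from .model import CnnSpec, train
from .evaluation import EvalReport, evaluate


def _plain(obj):
    """Recursively turn tuples into lists so YAML stays tag-free."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    cnn: CnnSpec = field(default_factory=CnnSpec)
    window_ms: float = 600.0
    scenario: str = "intra"            # "intra" | "loso"
    train_fraction: float = 0.8        # intra only
    train_sample_stride: int = 1       # thin training windows by this factor
    split_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.scenario not in ("intra", "loso"):
            raise ValueError("scenario must be 'intra' or 'loso'")
        # Input dropout is an inter-participant regulariser only.
        self.cnn = replace(self.cnn, use_dropout=(self.scenario == "loso"))

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = _plain(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update(overrides)
        synth = doc.pop("synth", {})
        if "calibration_targets" in synth:
            synth["calibration_targets"] = {
                k: tuple(v) for k, v in synth["calibration_targets"].items()}
        if "speeds" in synth:
            synth["speeds"] = tuple(synth["speeds"])
        filt = doc.pop("filter", {})
        cnn = doc.pop("cnn", {})
        return cls(synth=SynthConfig(**synth), filter=FilterSpec(**filt),
                   cnn=CnnSpec.from_dict(cnn) if cnn else CnnSpec(), **doc)


def paper_config(seed: int = 0) -> ExperimentConfig:
    """The full study protocol (hours of CPU; use for real runs only)."""
    return ExperimentConfig(
        synth=SynthConfig(population_seed=seed),
        cnn=CnnSpec(seed=seed),
        split_seed=seed,
    )


def scaled_config(seed: int = 0, scenario: str = "intra",
                  noise_sd: float = 0.0) -> ExperimentConfig:
    """Desk-scale preset: 4 participants, 2 speeds x 2 trials x 30 s.

    Trains for 20 epochs with batch 128; training windows are thinned
    (every 2nd window intra, every 3rd for the larger LOSO training sets),
    which costs little information because single-sample-stride windows
    overlap by 59/60 samples.  Evaluation always uses every test window.
    """
    return ExperimentConfig(
        synth=SynthConfig(
            n_participants=4, speeds=(9.0, 11.0), trials_per_speed=2,
            trial_duration=30.0, population_seed=seed, noise_sd=noise_sd),
        cnn=CnnSpec(batch_size=128, epochs=20, seed=seed),
        scenario=scenario,
        train_sample_stride=2 if scenario == "intra" else 3,
        split_seed=seed,
    )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    report: EvalReport
    histories: dict[str, list[float]]
    trials: list = field(default_factory=list)


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


def simulate_dataset(config: ExperimentConfig) -> list:
    """Generate and low-pass filter every trial of the configured cohort."""
    with _stage("simulate"):
        profiles = generate_population(config.synth)
        trials = []
        for profile in profiles:
            for speed in config.synth.speeds:
                for k in range(config.synth.trials_per_speed):
                    trials.append(simulate_trial(
                        profile, speed,
                        duration=config.synth.trial_duration,
                        sample_rate=config.synth.sample_rate,
                        trial_index=k))
    with _stage("filter"):
        spec = replace(config.filter, sample_rate=config.synth.sample_rate)
        return [filter_trial(trial, spec) for trial in trials]


def run_experiment(config: ExperimentConfig, verbose: bool = False,
                   keep_trials: bool = False) -> ExperimentResult:
    """Run the configured experiment and return its evaluation report.

    One model is trained per fold (per participant for the intra scenario,
    per left-out participant for LOSO); fold reports are merged so the
    final report has one row per participant either way.  If
    ``config.output_dir`` is set, the report (text + JSON) and per-fold
    model checkpoints are written there.
    """
    import os

    trials = simulate_dataset(config)
    by_id = {trial.trial_id: trial for trial in trials}

    with _stage("window"):
        windows = {tid: make_windows(trial, window_ms=config.window_ms)
                   for tid, trial in by_id.items()}

    with _stage("split"):
        if config.scenario == "intra":
            plan = split_intra(trials, train_fraction=config.train_fraction,
                               seed=config.split_seed)
        else:
            plan = split_loso(trials)

    import pandas as pd

    histories: dict[str, list[float]] = {}
    fold_reports = []
    for i, fold in enumerate(plan.folds):
        with _stage(f"train fold {fold.label}"):
            train_ds = concat_windows([windows[tid] for tid in fold.train_trials])
            spec = replace(config.cnn, seed=config.cnn.seed + i)
            estimator = train(train_ds, spec,
                              sample_stride=config.train_sample_stride,
                              verbose=verbose)
            histories[fold.label] = estimator.history
        with _stage(f"evaluate fold {fold.label}"):
            test_trials = [by_id[tid] for tid in fold.test_trials]
            fold_reports.append(evaluate(
                estimator, test_trials,
                stance_fraction=config.synth.stance_fraction,
                window_ms=config.window_ms))
        if config.output_dir:
            os.makedirs(config.output_dir, exist_ok=True)
            estimator.save(os.path.join(
                config.output_dir, f"model_{config.scenario}_{fold.label}"))

    with _stage("report"):
        per_participant = pd.concat([r.per_participant for r in fold_reports])
        summary = pd.DataFrame({"mean": per_participant.mean(axis=0),
                                "sd": per_participant.std(axis=0, ddof=0)})
        events_pp = pd.concat(
            [r.events_per_participant for r in fold_reports
             if len(r.events_per_participant)])
        grouped = events_pp.groupby(level="event", sort=False)
        from .simulate import EVENT_NAMES

        events_summary = pd.DataFrame({
            "reference_mean": grouped["reference_mean"].mean(),
            "reference_sd": grouped["reference_mean"].std(ddof=0),
            "estimated_mean": grouped["estimated_mean"].mean(),
            "estimated_sd": grouped["estimated_mean"].std(ddof=0),
            "mae": grouped["mae"].mean(),
            "mae_sd": grouped["mae"].std(ddof=0),
            "mean_difference": grouped["mean_difference"].mean(),
        }).reindex(list(EVENT_NAMES))
        report = EvalReport(
            scenario=config.scenario, per_participant=per_participant,
            summary=summary, events_per_participant=events_pp,
            events_summary=events_summary)

    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        report.to_json(os.path.join(config.output_dir,
                                    f"report_{config.scenario}.json"))
        with open(os.path.join(config.output_dir,
                               f"report_{config.scenario}.txt"), "w") as fh:
            fh.write(report.to_text() + "\n")

    return ExperimentResult(config=config, report=report, histories=histories,
                            trials=trials if keep_trials else [])


def make_fixtures(out_dir, seed: int = 0) -> list[str]:
    """Write a deterministic miniature dataset (2 participants, 10 s, 10 km/h).

    Used by the test suite and the examples; regenerating with the same seed
    is byte-identical.  Returns the CSV paths written.
    """
    cfg = SynthConfig(n_participants=2, speeds=(10.0,), trials_per_speed=1,
                      trial_duration=10.0, population_seed=seed, noise_sd=0.3)
    paths = []
    for profile in generate_population(cfg):
        trial = simulate_trial(profile, 10.0, duration=cfg.trial_duration,
                               sample_rate=cfg.sample_rate)
        csv_path, _ = write_trial(trial, out_dir)
        paths.append(csv_path)
    return paths
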