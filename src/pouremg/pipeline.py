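"""End-to-end pipeline: generate -> preprocess -> featurize -> train ->
evaluate, with a manifest for reproducibility, plus the multi-setting
comparison (features-only vs raw vs raw+features at each granularity).

One global seed fans out deterministically to the per-stage seeds, so a
config+seed pair pins every random choice in the run: synthesis noise,
data splits, weight initialisation and shuffling.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .convmixer import (
    ConvMixerNet,
    FeatureDenseNet,
    ModelConfig,
    predict,
    save_model,
    train_model,
)
from .evaluation import evaluate, export_report, plot_confusion, run_baselines
from .features import FeatureParams, feature_frame, feature_matrix
from .granular_labels import Level, N_CLASSES, granulate
from .signal_io import (
    FilterSpec,
    bandpass_filter,
    notch_filter,
    read_session,
    save_windows,
    segment_windows,
    window_samples,
    write_session,
)
from .synthetic_emg import DEFAULT_SAMPLING_RATE, SynthParams, make_protocol, synthesize_session

__all__ = ["PipelineConfig", "run_pipeline", "compare_settings", "stratified_split"]

logger = logging.getLogger(__name__)

SETTING_MODES = ("features-only", "raw", "raw+features")

# stage-seed offsets (global seed + offset, kept well below 2**31)
_SEED_SYNTH, _SEED_SPLIT, _SEED_MODEL, _SEED_BASELINE = 0, 101, 202, 303


@dataclass
class PipelineConfig:
    """Everything a run needs; serialisable to/from YAML (schema v1)."""

    seed: int = 0
    repetitions: int = 3
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    active_s: float = 5.0
    rest_s: float = 5.0
    level: str = "granular1"
    window_ms: float = 250.0
    step_ms: float = 50.0
    zc_threshold: float = 0.01
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    filters: dict = field(default_factory=dict)  # FilterSpec overrides
    synth: dict = field(default_factory=dict)  # SynthParams overrides
    # ModelConfig overrides; 10 epochs is the desk-scale default — the
    # synthetic task converges in a handful of epochs
    model: dict = field(default_factory=lambda: {"epochs": 10})
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not self.window_ms > self.step_ms > 0:
            raise ValueError(
                f"need window_ms > step_ms > 0, got {self.window_ms}, {self.step_ms}"
            )
        Level(self.level)
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        fr = self.split_fractions
        if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9 or min(fr) <= 0:
            raise ValueError("split_fractions must be 3 positive values summing to 1")
        self.filter_spec = FilterSpec(**self.filters)
        self.filter_spec.validate(self.sampling_rate)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(d["split_fractions"])
        return d

    def synth_params(self) -> SynthParams:
        return SynthParams(seed=self.seed + _SEED_SYNTH, **self.synth)

    def model_config(self, n_classes: int, **overrides) -> ModelConfig:
        kwargs = dict(self.model)
        kwargs.update(overrides)
        kwargs.setdefault("seed", self.seed + _SEED_MODEL)
        return ModelConfig(n_classes=n_classes, **kwargs)


def stratified_split(y, fractions, seed: int):
    """Stratified-by-window train/val/test index split."""
    from sklearn.model_selection import train_test_split

    y = np.asarray(y)
    idx = np.arange(len(y))
    f_train, f_val, f_test = fractions
    train_idx, rest_idx = train_test_split(
        idx, test_size=f_val + f_test, random_state=seed, stratify=y
    )
    val_idx, test_idx = train_test_split(
        rest_idx,
        test_size=f_test / (f_val + f_test),
        random_state=seed + 1,
        stratify=y[rest_idx],
    )
    return train_idx, val_idx, test_idx


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _prepare_data(config: PipelineConfig, out: Path, session=None) -> dict:
    """Stages 1-3: synthesis (unless a session is supplied), filtering,
    segmentation, feature extraction.  Returns in-memory arrays plus the
    list of files written."""
    files = []
    if session is None:
        plan = make_protocol(
            config.repetitions,
            config.sampling_rate,
            config.active_s,
            config.rest_s,
            seed=config.seed + _SEED_SYNTH,
        )
        session = synthesize_session(plan, config.synth_params())
        write_session(session, out / "signal.csv", out / "annotations.csv")
        files += [out / "signal.csv", out / "annotations.csv"]
        logger.info("synthesized %d trials (%.1f s)", len(plan.trials), plan.total_duration_s)

    filtered = bandpass_filter(notch_filter(session, config.filter_spec), config.filter_spec)
    windows = segment_windows(filtered, config.window_ms, config.step_ms)
    if not windows:
        raise RuntimeError("preprocess produced no windows")
    save_windows(windows, out / "windows.h5", out / "windows.labels.csv")
    files += [out / "windows.h5", out / "windows.labels.csv"]

    fparams = FeatureParams(zc_threshold=config.zc_threshold)
    feature_frame(windows, fparams).to_csv(out / "features.csv", index=False)
    files.append(out / "features.csv")
    feats = feature_matrix(windows, fparams)

    x = np.stack([w.samples for w in windows])
    level = Level(config.level)
    y = np.array([granulate(w.label, level) for w in windows])
    logger.info("segmented %d windows of %d samples", len(windows), x.shape[2])
    return {"x": x, "features": feats, "y": y, "windows": windows, "files": files}


def run_pipeline(config: PipelineConfig, out_dir, session=None) -> Path:
    """Execute every stage, persist all artifacts and a checksum manifest.

    Returns the run directory, containing signal/annotation CSVs,
    windows.h5, features.csv, ckpt.npz, train.log, report.json (fine and
    coarsened metrics) and manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate/preprocess/featurize"
    try:
        data = _prepare_data(config, out, session=session)
        x, feats, y = data["x"], data["features"], data["y"]
        level = Level(config.level)

        stage = "split"
        tr, va, te = stratified_split(y, config.split_fractions, config.seed + _SEED_SPLIT)

        stage = "train"
        mconfig = config.model_config(N_CLASSES[level])
        report = train_model(
            x[tr],
            y[tr],
            mconfig,
            features=feats[tr],
            val_windows=x[va],
            val_labels=y[va],
            val_features=feats[va],
            log_path=out / "train.log",
        )
        save_model(report.model, out / "ckpt.npz")

        stage = "evaluate"
        fine, coarse = evaluate(
            report.model, x[te], y[te], level, features=feats[te], report_coarsened=True
        )
        export_report(fine, out, "report_fine")
        export_report(coarse, out, "report_coarse")
        plot_confusion(fine.confusion, out / "confusion_fine.png")
        payload = {
            "level": level.value,
            "fine": fine.to_dict(),
            "coarse": coarse.to_dict(),
            "final_val_accuracy": report.final_val_accuracy,
            "epoch_loss": report.epoch_loss,
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2))

        stage = "manifest"
        outputs = data["files"] + [
            out / "ckpt.npz",
            out / "train.log",
            out / "report.json",
            out / "report_fine.json",
            out / "report_coarse.json",
        ]
        manifest = {
            "pouremg_version": __version__,
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
            "stage_inputs": {
                "train": ["windows.h5", "features.csv"],
                "evaluate": ["windows.h5", "features.csv", "ckpt.npz"],
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return out


def compare_settings(
    config: PipelineConfig,
    settings: list[tuple[str, str]] | None = None,
    out_dir=None,
    session=None,
) -> pd.DataFrame:
    """Train/evaluate each (input mode, level) setting on identical data,
    splits and seeds; returns a table of 4-class (coarsened) accuracies
    with one row per model and one column per setting.

    Modes: ``features-only`` (SVM / random forest / LDA baselines plus a
    small dense head over the 16 features; raw windows never reach these
    models), ``raw`` (ConvMixer on windows alone), ``raw+features``
    (ConvMixer with late feature fusion).  Scoring at the coarse level
    makes settings with different native class counts comparable.
    """
    if not settings:
        raise ValueError("settings must be non-empty")
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    data = _prepare_data(config, out if out is not None else _tmpdir(), session=session)
    x, feats = data["x"], data["features"]

    results: dict[str, dict[str, float]] = {}
    errors: dict[str, str] = {}
    for mode, level_name in settings:
        if mode not in SETTING_MODES:
            raise ValueError(f"unknown mode {mode!r}")
        level = Level(level_name)
        col = f"{mode}@{level.value}"
        try:
            y = np.array([granulate(w.label, level) for w in data["windows"]])
            tr, va, te = stratified_split(y, config.split_fractions, config.seed + _SEED_SPLIT)
            k = N_CLASSES[level]
            if mode == "features-only":
                base = run_baselines(
                    feats, y, level, seed=config.seed + _SEED_BASELINE, train_idx=tr, test_idx=te
                )
                for name, rep in base.items():
                    cm_coarse = _coarse_accuracy_from_argmax(rep, level)
                    results.setdefault(name, {})[col] = cm_coarse
                mconfig = config.model_config(k, fusion_mode="none")
                rep = train_model(None, y[tr], mconfig, features=feats[tr], model_class=FeatureDenseNet)
                _, coarse = evaluate(
                    rep.model, None, y[te], level, features=feats[te], report_coarsened=True
                )
                results.setdefault("dense_head", {})[col] = coarse.accuracy
            else:
                fusion = "late_concat" if mode == "raw+features" else "none"
                mconfig = config.model_config(k, fusion_mode=fusion)
                rep = train_model(
                    x[tr],
                    y[tr],
                    mconfig,
                    features=feats[tr] if fusion == "late_concat" else None,
                )
                _, coarse = evaluate(
                    rep.model,
                    x[te],
                    y[te],
                    level,
                    features=feats[te] if fusion == "late_concat" else None,
                    report_coarsened=True,
                )
                results.setdefault("convmixer", {})[col] = coarse.accuracy
        except Exception as exc:  # keep evaluating the other settings
            errors[col] = str(exc)
            logger.error("setting %s failed: %s", col, exc)
    table = pd.DataFrame(results).T
    table.index.name = "model"
    if out is not None:
        table.to_csv(out / "comparison.csv")
        if errors:
            (out / "comparison_errors.json").write_text(json.dumps(errors, indent=2))
    return table


def _coarse_accuracy_from_argmax(report, level: Level) -> float:
    """Coarsened accuracy for a hard-label report (baselines expose no
    probabilities by default): map the confusion matrix through the
    granule membership matrix."""
    from .evaluation import coarsen_confusion, metrics as _metrics

    if level is Level.COARSE:
        return report.accuracy
    cm = coarsen_confusion(report.confusion, level, Level.COARSE)
    return _metrics(cm).accuracy


def _tmpdir() -> Path:
    import tempfile

    return Path(tempfile.mkdtemp(prefix="pouremg_"))


def load_session_dir(in_dir) -> "RecordingSession":  # noqa: F821
    """Read signal.csv + annotations.csv from a directory."""
    in_dir = Path(in_dir)
    return read_session(in_dir / "signal.csv", in_dir / "annotations.csv")
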