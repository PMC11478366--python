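"""End-to-end study orchestration on synthetic data.

``run_study`` chains simulate → featurize → train (three classical + four
recurrent methods) → evaluate under the six split plans → resource profile
and quantization, and emits a manifest sufficient to re-run bit-identically.
Stage outputs are content-addressed by a hash of the controlling part of the
config, so a re-run with ``resume=True`` reuses finished stages.

At the full default dimensions the complete cross (including leave-one-out
retraining of every recurrent variant) is a long computation; the
``ratios``/``leave_one_out``/``methods`` knobs of :class:`RunConfig` scale
it down.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classic import (
    FeatureScaler,
    LabeledPointSet,
    forest_classify,
    forest_train,
    forest_vote_fractions,
    knn_classify_batch,
    svm_classify,
    svm_train,
)
from .config import RunConfig, TrainingConfig
from .core import CLASS_FALLING, CLASS_STANDING, PointfallError, SubjectTrack
from .evaluate import EvaluationReport, SplitPlan, evaluate, make_splits, mean_report
from .features import FEATURE_NAMES, featurize_track
from .io import write_track
from .recurrent import (
    RecurrentModelSpec,
    TrainedModel,
    make_windows,
    predict,
    predict_proba,
    train,
)
from .resources import FixedPointFormat, count_flops, quantize_model, quantized_predict

__all__ = [
    "FeatureDataset",
    "StudyManifest",
    "featurize_dataset",
    "run_protocol",
    "run_study",
    "CLASSICAL_METHODS",
    "RECURRENT_METHODS",
]

CLASSICAL_METHODS = ("knn", "forest", "svm")
RECURRENT_METHODS = ("lstm", "bilstm", "projected_lstm", "gru")


@dataclass
class FeatureDataset:
    """Featurized study dataset in both frame and window representations."""

    frames_X: np.ndarray  # (N, 7)
    frames_y: np.ndarray  # class codes
    frames_track: np.ndarray  # experiment id per frame
    windows_X: np.ndarray  # (M, T, 7)
    windows_y: np.ndarray
    windows_track: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frames_y)

    @property
    def n_windows(self) -> int:
        return len(self.windows_y)


def featurize_dataset(
    tracks: Sequence[SubjectTrack],
    confidence: float = 0.95,
    window_length: int = 20,
    stride: int = 1,
) -> FeatureDataset:
    """Extract per-frame ellipsoid features and sliding windows for a dataset."""
    fX, fy, ft, wX, wy, wt = [], [], [], [], [], []
    for tr in tracks:
        df = featurize_track(tr, confidence=confidence)
        F = df[list(FEATURE_NAMES)].to_numpy()
        y = df["label"].to_numpy()
        fX.append(F)
        fy.append(y)
        ft.extend([tr.subject_id] * len(df))
        X, labels = make_windows(F, y, window_length=window_length, stride=stride)
        wX.append(X)
        wy.append(labels)
        wt.extend([tr.subject_id] * len(labels))
    return FeatureDataset(
        frames_X=np.concatenate(fX),
        frames_y=np.concatenate(fy),
        frames_track=np.asarray(ft),
        windows_X=np.concatenate(wX),
        windows_y=np.concatenate(wy),
        windows_track=np.asarray(wt),
    )


# ---------------------------------------------------------------------------
# method adapters (uniform fit/predict/proba over frames or windows)


class _Method:
    name: str
    representation: str  # "frames" | "windows"

    def fit(self, X, y):  # pragma: no cover - interface
        raise NotImplementedError

    def predict(self, X):
        raise NotImplementedError

    def proba(self, X):
        return None


class _KNN(_Method):
    representation = "frames"

    def __init__(self, k: int = 5):
        self.name = "knn"
        self.k = k

    def fit(self, X, y):
        self.scaler = FeatureScaler.fit(X)
        self.train_set = LabeledPointSet(self.scaler.transform(X), y)

    def predict(self, X):
        return self.train_set.labels[
            np.zeros(0, dtype=int)
        ] if len(X) == 0 else knn_classify_batch(self.train_set, self.scaler.transform(X), self.k)


class _Forest(_Method):
    representation = "frames"

    def __init__(self, n_trees: int = 50, seed: int = 0):
        self.name = "forest"
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y):
        self.scaler = FeatureScaler.fit(X)
        self.forest = forest_train(
            LabeledPointSet(self.scaler.transform(X), y), n_trees=self.n_trees, seed=self.seed
        )

    def predict(self, X):
        return forest_classify(self.forest, self.scaler.transform(X))

    def proba(self, X):
        frac = forest_vote_fractions(self.forest, self.scaler.transform(X))
        if frac.shape[1] < 4:  # pad to class codes 0..3 before dropping code 0
            frac = np.pad(frac, ((0, 0), (0, 4 - frac.shape[1])))
        return frac[:, [1, 2, 3]]


class _SVM(_Method):
    """Binary standing-vs-falling separator (the two-class protocol)."""

    representation = "frames"

    def __init__(self, classes=(CLASS_STANDING, CLASS_FALLING), C_reg: float = 10.0):
        self.name = "svm"
        self.classes = classes

    def fit(self, X, y):
        self.scaler = FeatureScaler.fit(X)
        self.sep = svm_train(LabeledPointSet(self.scaler.transform(X), y), classes=self.classes)

    def predict(self, X):
        return svm_classify(self.sep, self.scaler.transform(X))


class _Recurrent(_Method):
    representation = "windows"

    def __init__(self, variant: str, config: RunConfig):
        self.name = variant
        self.spec = RecurrentModelSpec(
            variant=variant,
            fc1_dim=config.dims.fc1_dim,
            hidden=config.dims.hidden,
            projection=config.dims.projection,
            window_length=config.window_length,
            stride=config.window_stride,
        )
        self.training = dataclasses.replace(config.training)

    def fit(self, X, y):
        self.model = train(X, y, self.spec, self.training)

    def predict(self, X):
        return predict(self.model, X)

    def proba(self, X):
        return predict_proba(self.model, X)


def _make_method(name: str, config: RunConfig) -> _Method:
    if name == "knn":
        return _KNN()
    if name == "forest":
        return _Forest(seed=config.seed)
    if name == "svm":
        return _SVM()
    if name in RECURRENT_METHODS:
        return _Recurrent(name, config)
    raise PointfallError(f"unknown method {name!r}")


def _subset_for_svm(X, y):
    mask = np.isin(y, (CLASS_STANDING, CLASS_FALLING))
    return X[mask], y[mask]


def run_protocol(
    dataset: FeatureDataset,
    methods: Sequence[str],
    plans: Sequence[SplitPlan],
    config: Optional[RunConfig] = None,
) -> dict[tuple[str, str], EvaluationReport]:
    """Full cross of methods × split plans, one report each.

    Leave-one-out reports are fold means (fold count = number of
    experiments).  The SVM runs on its binary standing/falling subset; the
    other methods use all three classes.
    """
    config = config or RunConfig()
    reports: dict[tuple[str, str], EvaluationReport] = {}
    for name in methods:
        method = _make_method(name, config)
        if method.representation == "frames":
            X, y, grp = dataset.frames_X, dataset.frames_y, dataset.frames_track
        else:
            X, y, grp = dataset.windows_X, dataset.windows_y, dataset.windows_track
        if name == "svm":
            keep = np.isin(y, (CLASS_STANDING, CLASS_FALLING))
            X, y, grp = X[keep], y[keep], grp[keep]
        for plan in plans:
            folds = make_splits(len(y), plan, labels=y, groups=grp)
            fold_reports = []
            for train_idx, test_idx in folds:
                m = _make_method(name, config)
                m.fit(X[train_idx], y[train_idx])
                preds = m.predict(X[test_idx])
                scores = m.proba(X[test_idx])
                fold_reports.append(evaluate(preds, y[test_idx], scores=scores))
            rep = fold_reports[0] if len(fold_reports) == 1 else mean_report(fold_reports)
            reports[(name, plan.name)] = rep
    return reports


# ---------------------------------------------------------------------------
# study driver


@dataclass
class StudyManifest:
    config: dict
    seed: int
    version: str
    artifacts: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _stage_key(name: str, payload: dict) -> str:
    blob = json.dumps({"stage": name, **payload}, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def run_study(config: RunConfig, out_dir: Optional[Path] = None, resume: bool = False) -> StudyManifest:
    """Reproduce the whole study on synthetic data.

    Stages: simulate the 26-track dataset, featurize, evaluate every method
    under every configured split plan, train + profile + quantize the
    recurrent reference models.  Aborts with the failing stage name on error.
    """
    from .simulate import generate_study_dataset

    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = StudyManifest(config=config.to_dict(), seed=config.seed, version=__version__)
    t0 = time.time()

    def stage(name, payload, fn):
        key = _stage_key(name, payload)
        stage_dir = out / f"{name}-{key}"
        marker = stage_dir / "DONE"
        if resume and marker.exists():
            manifest.stages[name] = {"key": key, "reused": True}
            return stage_dir
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            fn(stage_dir)
        except Exception as exc:
            manifest.stages[name] = {"key": key, "failed": str(exc)}
            manifest.save(out / "manifest.partial.json")
            raise PointfallError(f"stage {name!r} failed: {exc}") from exc
        marker.write_text("ok")
        manifest.stages[name] = {"key": key, "reused": False}
        return stage_dir

    # 1. simulate
    tracks_holder: dict = {}

    def do_simulate(d: Path):
        tracks = generate_study_dataset(config.seed, config.n_fall_tracks, config.n_sit_tracks)
        for tr in tracks:
            write_track(tr, d / f"{tr.subject_id}.jsonl")
        tracks_holder["tracks"] = tracks

    sim_dir = stage("simulate", {"seed": config.seed, "n_fall": config.n_fall_tracks,
                                 "n_sit": config.n_sit_tracks}, do_simulate)
    if "tracks" not in tracks_holder:  # resumed: reload
        from .io import read_track

        tracks_holder["tracks"] = [read_track(p) for p in sorted(sim_dir.glob("*.jsonl"))]
    tracks = tracks_holder["tracks"]
    manifest.artifacts["tracks"] = str(sim_dir)

    # 2. featurize
    feat_holder: dict = {}

    def do_featurize(d: Path):
        ds = featurize_dataset(
            tracks, confidence=config.confidence,
            window_length=config.window_length, stride=config.window_stride,
        )
        df = pd.DataFrame(ds.frames_X, columns=list(FEATURE_NAMES))
        df["label"] = ds.frames_y
        df["track"] = ds.frames_track
        df.to_csv(d / "features.csv", index=False)
        feat_holder["ds"] = ds

    feat_dir = stage(
        "featurize",
        {"seed": config.seed, "confidence": config.confidence, "window": config.window_length,
         "stride": config.window_stride},
        do_featurize,
    )
    if "ds" not in feat_holder:
        feat_holder["ds"] = featurize_dataset(
            tracks, confidence=config.confidence,
            window_length=config.window_length, stride=config.window_stride,
        )
    ds = feat_holder["ds"]
    manifest.artifacts["features"] = str(feat_dir / "features.csv")

    # 3. evaluate all methods under all plans
    plans = [SplitPlan("ratio", r, seed=config.seed) for r in config.split_ratios]
    if config.leave_one_out:
        plans.append(SplitPlan("leave_one_out", seed=config.seed))
    methods = [*CLASSICAL_METHODS, *RECURRENT_METHODS]

    def do_evaluate(d: Path):
        reports = run_protocol(ds, methods, plans, config)
        serial = {f"{m}|{p}": r.to_dict() for (m, p), r in reports.items()}
        (d / "reports.json").write_text(json.dumps(serial, indent=2, sort_keys=True))
        rows = [
            {"method": m, "plan": p, "accuracy": r.accuracy, "precision": r.precision,
             "recall": r.recall, "f1": r.f1, "auc": r.auc}
            for (m, p), r in reports.items()
        ]
        pd.DataFrame(rows).to_csv(d / "summary.csv", index=False)

    eval_dir = stage(
        "evaluate",
        {"seed": config.seed, "plans": [p.name for p in plans], "methods": methods,
         "dims": dataclasses.asdict(config.dims), "training": dataclasses.asdict(config.training)},
        do_evaluate,
    )
    manifest.artifacts["reports"] = str(eval_dir / "reports.json")
    manifest.artifacts["summary"] = str(eval_dir / "summary.csv")

    # 4. resource profile + quantization of the recurrent reference models
    def do_profile(d: Path):
        plan = SplitPlan("ratio", 0.8, seed=config.seed)
        (train_idx, test_idx), = make_splits(
            len(ds.windows_y), plan, labels=ds.windows_y, groups=ds.windows_track
        )
        rows = []
        for variant in RECURRENT_METHODS:
            method = _Recurrent(variant, config)
            method.fit(ds.windows_X[train_idx], ds.windows_y[train_idx])
            float_acc = 100.0 * float(
                np.mean(method.predict(ds.windows_X[test_idx]) == ds.windows_y[test_idx])
            )
            prof = count_flops(method.spec, config.window_length)
            row = {"variant": variant, "params": prof.parameter_count,
                   "footprint_bytes": prof.footprint_bytes,
                   "flops_per_window": prof.flops_per_window, "float_accuracy": float_acc}
            for fmt_s in config.quant_formats:
                fmt = FixedPointFormat.from_string(fmt_s)
                q = quantize_model(method.model, fmt)
                qacc = 100.0 * float(
                    np.mean(quantized_predict(q, ds.windows_X[test_idx]) == ds.windows_y[test_idx])
                )
                row[f"acc_{fmt}"] = qacc
            rows.append(row)
        pd.DataFrame(rows).to_csv(d / "resources.csv", index=False)

    prof_dir = stage(
        "profile",
        {"seed": config.seed, "dims": dataclasses.asdict(config.dims),
         "formats": list(config.quant_formats)},
        do_profile,
    )
    manifest.artifacts["resources"] = str(prof_dir / "resources.csv")

    manifest.stages["elapsed_s"] = round(time.time() - t0, 2)
    manifest.save(out / "manifest.json")
    return manifest
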