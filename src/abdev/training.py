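"""Per-platform model training with repeated k-fold cross-validation.

For each assay platform the pipeline is: censor filter (HIC runs recorded
at the 25-min measurement ceiling are dropped) -> response transform
(identity or ordered-quantile) -> VIF pruning + stepwise-AIC variable
selection -> z-scaling -> learner fit. Candidate combinations of
algorithm x variable-set x transform are compared by the mean absolute
error of out-of-fold predictions over a repeated 10-fold cross-validation
(50 repeats by default), the winner is refit on all usable rows, and the
refit model's predictions over the reference panel are stored so new
candidates can later be ranked within that panel.

Every data-dependent step (transform, selection, scaling, hyperparameter
tuning) is refit inside each training fold; nothing leaks from validation
rows.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .config import PLATFORMS, load_platform_defaults
from .errors import DegenerateDataError, SuiteFormatError, TrainingError
from .features import feature_table
from .learners import ALGORITHM_ORDER, fit_learner
from .preprocessing import (FeatureSelection, ScalerParams, TransformSpec,
                            apply_orq, apply_scaler, fit_orq, fit_scaler,
                            identity_transform, invert_orq, select_features)

SUITE_FORMAT_VERSION = 1

#: Minimum usable rows for training a platform (10-fold CV needs depth).
MIN_TRAINING_ROWS = 20

_VARIABLE_ORDER = ("vif_selected", "vif_all")


@dataclass
class PlatformConfig:
    """Modelling choices for one assay platform.

    ``algorithm``/``variables``/``transform`` may each be ``"auto"`` to let
    cross-validated MAE choose among all options.
    """

    platform: str
    algorithm: str = "auto"
    variables: str = "auto"
    transform: str = "auto"
    direction: str = "lower_better"
    threshold: float | str | None = None
    censor_value: float | None = None

    def candidates(self) -> list[tuple[str, str, str]]:
        algos = (ALGORITHM_ORDER if self.algorithm == "auto"
                 else (self.algorithm,))
        varsets = (_VARIABLE_ORDER if self.variables == "auto"
                   else (self.variables,))
        transforms = (("identity", "ordered_quantile")
                      if self.transform == "auto" else (self.transform,))
        return [(a, v, t) for a in algos for v in varsets for t in transforms]

    def to_jsonable(self) -> dict:
        return dict(self.__dict__)


def default_configs(overrides: dict | None = None) -> dict[str, PlatformConfig]:
    """The packaged per-platform defaults, optionally overridden per key."""
    raw = load_platform_defaults()["platforms"]
    out = {}
    for pid, cfg in raw.items():
        merged = dict(cfg)
        if overrides and pid in overrides:
            merged.update(overrides[pid])
        out[pid] = PlatformConfig(platform=pid, **merged)
    return out


@dataclass
class CvSettings:
    folds: int = 10
    repeats: int = 50
    seed: int = 0
    paper_mode: bool = False       # compare MAE on each candidate's native scale


@dataclass
class CvResult:
    """Cross-validation outcome for one candidate."""

    mae: float
    r2: float
    fold_mae: list[float]
    repeats: int
    folds: int
    seed: int
    failed_folds: int = 0

    def to_jsonable(self) -> dict:
        return {"mae": self.mae, "r2": self.r2, "fold_mae": self.fold_mae,
                "repeats": self.repeats, "folds": self.folds,
                "seed": self.seed, "failed_folds": self.failed_folds}


# ---------------------------------------------------------------------------
# folds

def make_folds(n: int, folds: int = 10, repeats: int = 50,
               seed: int = 0) -> np.ndarray:
    """Seeded fold assignments, shape (repeats, n); entry = fold index.

    Each repeat is an independent shuffle partitioned into near-equal
    folds (sizes differ by at most one).
    """
    if n < folds:
        raise ValueError(
            f"cannot make {folds} folds from {n} rows; use fewer folds"
        )
    rng = np.random.default_rng(seed)
    sizes = np.full(folds, n // folds)
    sizes[: n % folds] += 1
    assignments = np.empty((repeats, n), dtype=int)
    template = np.repeat(np.arange(folds), sizes)
    for r in range(repeats):
        perm = rng.permutation(n)
        assignments[r, perm] = template
    return assignments


# ---------------------------------------------------------------------------
# the per-fold pipeline

@dataclass
class FittedPipeline:
    """Transform + selection + scaler + learner fitted on one training set."""

    selection: FeatureSelection
    variables: str
    used_features: list[str]
    scaler: ScalerParams
    transform: TransformSpec
    learner: object
    algorithm: str

    def predict_native(self, X: pd.DataFrame) -> np.ndarray:
        Xs = apply_scaler(self.scaler, X[self.used_features])
        return np.asarray(self.learner.predict(Xs.to_numpy()), dtype=float)

    def predict_raw(self, X: pd.DataFrame) -> np.ndarray:
        return invert_orq(self.transform, self.predict_native(X))


def _fit_pipeline(X: pd.DataFrame, y: np.ndarray, algorithm: str,
                  variables: str, transform: str, grids: dict,
                  vif_threshold: float, seed: int) -> FittedPipeline:
    if transform == "ordered_quantile":
        try:
            tspec = fit_orq(y)
        except DegenerateDataError as exc:
            warnings.warn(f"{exc}; falling back to identity transform",
                          stacklevel=2)
            tspec = identity_transform()
    else:
        tspec = identity_transform()
    z = apply_orq(tspec, y)

    selection = select_features(X, z, vif_threshold=vif_threshold)
    used = (selection.vif_selected if variables == "vif_selected"
            else selection.vif_all)
    if not used:           # stepwise emptied the model; fall back to vif_all
        used = selection.vif_all
    scaler = fit_scaler(X[used])
    used = scaler.features
    Xs = apply_scaler(scaler, X[used])
    learner = fit_learner(algorithm, Xs.to_numpy(), z,
                          (grids or {}).get(algorithm, {}), seed)
    return FittedPipeline(selection=selection, variables=variables,
                          used_features=used, scaler=scaler,
                          transform=tspec, learner=learner,
                          algorithm=algorithm)


# ---------------------------------------------------------------------------
# cross-validation

def cross_validate(config_or_spec, X: pd.DataFrame, y,
                   fold_assignments: np.ndarray, grids: dict | None = None,
                   vif_threshold: float = 10.0, seed: int = 0,
                   paper_mode: bool = False) -> CvResult:
    """Repeated k-fold CV of one (algorithm, variables, transform) spec.

    ``config_or_spec`` is a 3-tuple or a PlatformConfig with concrete (non
    ``auto``) entries. MAE is aggregated over all out-of-fold predictions,
    by default back-transformed to the raw response scale so candidates
    with different response transforms are comparable; ``paper_mode``
    compares on each candidate's native (possibly transformed) scale.
    R2 is the squared Pearson correlation of pooled out-of-fold raw-scale
    predictions against the observed responses.
    """
    if isinstance(config_or_spec, PlatformConfig):
        spec = (config_or_spec.algorithm, config_or_spec.variables,
                config_or_spec.transform)
    else:
        spec = tuple(config_or_spec)
    algorithm, variables, transform = spec
    if "auto" in spec:
        raise ValueError("cross_validate needs a concrete candidate spec")

    y = np.asarray(y, dtype=float)
    repeats, n = fold_assignments.shape
    folds = int(fold_assignments.max()) + 1
    abs_errors: list[np.ndarray] = []
    fold_mae: list[float] = []
    oof_pred = np.empty((repeats, n))
    failed = 0
    total = repeats * folds
    for r in range(repeats):
        assign = fold_assignments[r]
        for f in range(folds):
            val = assign == f
            tr = ~val
            pipe = _fit_pipeline(X.iloc[tr], y[tr], algorithm, variables,
                                 transform, grids, vif_threshold,
                                 seed + 7919 * r + f)
            pred_raw = pipe.predict_raw(X.iloc[val])
            if not np.all(np.isfinite(pred_raw)):
                failed += 1
                oof_pred[r, val] = np.nan
                continue
            oof_pred[r, val] = pred_raw
            if paper_mode:
                err = np.abs(pipe.predict_native(X.iloc[val])
                             - apply_orq(pipe.transform, y[val]))
            else:
                err = np.abs(pred_raw - y[val])
            abs_errors.append(err)
            fold_mae.append(float(err.mean()))
    if failed > 0.05 * total:
        raise TrainingError(
            f"{failed}/{total} folds produced non-finite predictions for "
            f"candidate {spec}"
        )
    all_err = np.concatenate(abs_errors)
    pooled_pred = oof_pred.ravel()
    pooled_obs = np.tile(y, repeats)
    ok = np.isfinite(pooled_pred)
    if pooled_pred[ok].std() <= 1e-12 or pooled_obs[ok].std() <= 1e-12:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(pooled_pred[ok], pooled_obs[ok])[0, 1] ** 2)
    return CvResult(mae=float(all_err.mean()), r2=r2, fold_mae=fold_mae,
                    repeats=repeats, folds=folds, seed=seed,
                    failed_folds=failed)


def select_model(results: list[tuple[tuple[str, str, str], CvResult]]
                 ) -> tuple[tuple[str, str, str], CvResult]:
    """Pick the candidate with minimal MAE.

    Ties (to 1e-12) break toward the simpler model: elastic_net < svm_rbf <
    random_forest, then vif_selected < vif_all, then identity transform.
    """
    if not results:
        raise TrainingError("no successful cross-validation candidates")

    def key(item):
        (algo, varset, transform), cv = item
        return (
            round(cv.mae / 1e-12) * 1e-12,
            ALGORITHM_ORDER.index(algo),
            _VARIABLE_ORDER.index(varset),
            0 if transform == "identity" else 1,
        )

    return min(results, key=key)


# ---------------------------------------------------------------------------
# trained models and suites

@dataclass
class TrainedModel:
    """One platform's fitted predictor plus its reference-panel context."""

    config: PlatformConfig
    pipeline: FittedPipeline
    cv: CvResult
    reference_ids: list[str]
    reference_values: np.ndarray        # observed responses, model scale
    reference_raw: np.ndarray           # observed responses, raw scale
    training_predictions: np.ndarray    # refit predictions, model scale
    resolved_threshold: float | None = None
    candidate_log: list = field(default_factory=list)

    @property
    def platform(self) -> str:
        return self.config.platform

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Model-scale predictions for a feature matrix."""
        return self.pipeline.predict_native(features)

    def predict_raw(self, features: pd.DataFrame) -> np.ndarray:
        """Raw assay-scale predictions (transform inverted)."""
        return self.pipeline.predict_raw(features)


@dataclass
class ModelSuite:
    """Trained models for the platforms with sufficient data."""

    models: dict[str, TrainedModel]
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Per-platform table: algorithm, variables, transform, MAE, R2."""
        rows = []
        for pid in PLATFORMS:
            if pid not in self.models:
                continue
            m = self.models[pid]
            a, v, t = (m.pipeline.algorithm, m.pipeline.variables,
                       m.pipeline.transform.kind)
            rows.append({"platform": pid, "algorithm": a, "variables": v,
                         "transformation": t, "mae": m.cv.mae, "r2": m.cv.r2})
        return pd.DataFrame(rows)


def _usable_rows(dataset, platform: str, censor_value: float | None):
    y = dataset.measurements[platform].dropna()
    if censor_value is not None:
        y = y[y < censor_value]
    return y


def resolve_threshold(config: PlatformConfig, raw_values: np.ndarray
                       ) -> float | None:
    """Numeric thresholds pass through; ``worst_10pct`` resolves to the

    boundary value separating the worst 10% of the reference panel."""
    if config.threshold is None:
        return None
    if isinstance(config.threshold, (int, float)):
        return float(config.threshold)
    if config.threshold != "worst_10pct":
        raise ValueError(f"unknown threshold rule {config.threshold!r}")
    n = len(raw_values)
    k = max(1, int(np.ceil(0.1 * n)))
    srt = np.sort(raw_values)
    if config.direction == "higher_better":    # worst = smallest
        return float(srt[k - 1])
    return float(srt[n - k])                   # worst = largest


def train_platform(dataset, platform: str,
                   config: PlatformConfig | None = None,
                   cv: CvSettings | None = None,
                   feature_matrix: pd.DataFrame | None = None,
                   grids: dict | None = None,
                   vif_threshold: float | None = None) -> TrainedModel:
    """Train one platform model end to end."""
    cv = cv or CvSettings()
    defaults = load_platform_defaults()
    grids = grids if grids is not None else defaults["learners"]
    vif_threshold = (vif_threshold if vif_threshold is not None
                     else defaults["vif_threshold"])
    if config is None:
        config = default_configs()[platform]
    if platform not in dataset.measurements.columns:
        raise TrainingError(f"{platform}: no measurement column")

    y = _usable_rows(dataset, platform, config.censor_value)
    if len(y) < MIN_TRAINING_ROWS:
        raise TrainingError(
            f"{platform}: only {len(y)} usable rows "
            f"(< {MIN_TRAINING_ROWS} required)"
        )
    if feature_matrix is None:
        feature_matrix = feature_table(dataset.records)
    X = feature_matrix.loc[y.index]
    yv = y.to_numpy(dtype=float)

    folds = make_folds(len(yv), folds=cv.folds, repeats=cv.repeats,
                       seed=cv.seed)
    results, failures = [], []
    for spec in config.candidates():
        try:
            res = cross_validate(spec, X, yv, folds, grids=grids,
                                 vif_threshold=vif_threshold, seed=cv.seed,
                                 paper_mode=cv.paper_mode)
            results.append((spec, res))
        except TrainingError as exc:
            failures.append((spec, str(exc)))
    if not results:
        raise TrainingError(
            f"{platform}: all candidates failed: {failures}"
        )
    (algo, varset, transform), best_cv = select_model(results)

    pipe = _fit_pipeline(X, yv, algo, varset, transform, grids,
                         vif_threshold, cv.seed)
    ref_model_scale = apply_orq(pipe.transform, yv)
    preds = pipe.predict_native(X)
    return TrainedModel(
        config=config,
        pipeline=pipe,
        cv=best_cv,
        reference_ids=list(y.index),
        reference_values=ref_model_scale,
        reference_raw=yv,
        training_predictions=preds,
        resolved_threshold=resolve_threshold(config, yv),
        candidate_log=[(spec, res.mae) for spec, res in results],
    )


def train_all(dataset, configs: dict[str, PlatformConfig] | None = None,
              cv: CvSettings | None = None,
              grids: dict | None = None) -> ModelSuite:
    """Train every platform present in the dataset; refusals are collected,

    not fatal."""
    cv = cv or CvSettings()
    if configs is None:
        configs = default_configs()
    features = feature_table(dataset.records)
    models, skipped = {}, {}
    for pid in PLATFORMS:
        if pid not in dataset.measurements.columns:
            skipped[pid] = "no measurement column"
            continue
        try:
            models[pid] = train_platform(
                dataset, pid, config=configs.get(pid), cv=cv,
                feature_matrix=features, grids=grids,
            )
        except TrainingError as exc:
            skipped[pid] = str(exc)
    config_blob = json.dumps(
        {pid: c.to_jsonable() for pid, c in sorted(configs.items())},
        sort_keys=True,
    )
    provenance = {
        "seed": cv.seed,
        "folds": cv.folds,
        "repeats": cv.repeats,
        "config_hash": hashlib.sha256(config_blob.encode()).hexdigest()[:12],
        "abdev_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "skipped": dict(skipped),
    }
    return ModelSuite(models=models, skipped=skipped, provenance=provenance)


# ---------------------------------------------------------------------------
# persistence

def save_suite(suite: ModelSuite, path: str | Path) -> None:
    """Persist a suite: JSON metadata + an adjacent joblib blob holding the

    fitted learner states (forests are not JSON-representable). Linear
    model coefficients are additionally inlined in the JSON for
    inspection."""
    path = Path(path)
    doc = {
        "format_version": SUITE_FORMAT_VERSION,
        "provenance": suite.provenance,
        "skipped": suite.skipped,
        "models": {},
    }
    learners = {}
    for pid, m in suite.models.items():
        pipe = m.pipeline
        entry = {
            "config": m.config.to_jsonable(),
            "algorithm": pipe.algorithm,
            "variables": pipe.variables,
            "used_features": pipe.used_features,
            "selection": {
                "vif_all": pipe.selection.vif_all,
                "vif_selected": pipe.selection.vif_selected,
                "removal_log": pipe.selection.removal_log,
                "aic_log": pipe.selection.aic_log,
            },
            "scaler": {
                "center": pipe.scaler.center.to_dict(),
                "spread": pipe.scaler.spread.to_dict(),
            },
            "transform": pipe.transform.to_jsonable(),
            "cv": m.cv.to_jsonable(),
            "reference_ids": m.reference_ids,
            "reference_values": np.asarray(m.reference_values).tolist(),
            "reference_raw": np.asarray(m.reference_raw).tolist(),
            "training_predictions":
                np.asarray(m.training_predictions).tolist(),
            "resolved_threshold": m.resolved_threshold,
            "candidate_log": [[list(s), mae] for s, mae in m.candidate_log],
        }
        if hasattr(pipe.learner, "coef_"):
            entry["coefficients"] = {
                "intercept": float(np.atleast_1d(pipe.learner.intercept_)[0]),
                "coef": dict(zip(pipe.used_features,
                                 np.asarray(pipe.learner.coef_).tolist())),
            }
        doc["models"][pid] = entry
        learners[pid] = pipe.learner
    path.write_text(json.dumps(doc, indent=1))
    joblib.dump(learners, _learner_blob_path(path))


def _learner_blob_path(path: Path) -> Path:
    return path.with_name(path.name + ".learners")


def load_suite(path: str | Path) -> ModelSuite:
    """Load a persisted suite; predictions are bit-identical to the saved

    suite's."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SuiteFormatError(f"{path}: not a valid suite file: {exc}")
    version = doc.get("format_version")
    if version != SUITE_FORMAT_VERSION:
        raise SuiteFormatError(
            f"{path}: format version {version} unsupported "
            f"(this build reads version {SUITE_FORMAT_VERSION})"
        )
    learners = joblib.load(_learner_blob_path(path))
    models = {}
    for pid, entry in doc["models"].items():
        sel = FeatureSelection(
            vif_all=entry["selection"]["vif_all"],
            vif_selected=entry["selection"]["vif_selected"],
            removal_log=[tuple(x) for x in entry["selection"]["removal_log"]],
            aic_log=[tuple(x) for x in entry["selection"]["aic_log"]],
        )
        used = entry["used_features"]
        scaler = ScalerParams(
            center=pd.Series(entry["scaler"]["center"]).loc[used],
            spread=pd.Series(entry["scaler"]["spread"]).loc[used],
        )
        pipe = FittedPipeline(
            selection=sel,
            variables=entry["variables"],
            used_features=used,
            scaler=scaler,
            transform=TransformSpec.from_jsonable(entry["transform"]),
            learner=learners[pid],
            algorithm=entry["algorithm"],
        )
        cv = CvResult(**entry["cv"])
        models[pid] = TrainedModel(
            config=PlatformConfig(**entry["config"]),
            pipeline=pipe,
            cv=cv,
            reference_ids=entry["reference_ids"],
            reference_values=np.asarray(entry["reference_values"]),
            reference_raw=np.asarray(entry["reference_raw"]),
            training_predictions=np.asarray(entry["training_predictions"]),
            resolved_threshold=entry["resolved_threshold"],
            candidate_log=[(tuple(s), mae)
                           for s, mae in entry["candidate_log"]],
        )
    return ModelSuite(models=models, skipped=doc.get("skipped", {}),
                      provenance=doc.get("provenance", {}))
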