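"""Condition construction, nested cross-validation, transfer and continuous
evaluation, chance bounds and significance testing.

Two cross-validation modes are supported: subject-dependent
leave-one-trial-out with an inner 10-fold loop for parameter selection and
fusion-weight estimation, and subject-independent leave-one-subject-out
where one held-out training subject serves as the evaluation data for
parameter selection and fusion weights before the model is refit on all
training subjects.  No information ever flows from an outer test trial or
subject into any fitted quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    FEATURE_TYPES,
    FusionWeights,
    ShrinkageLda,
    estimate_fusion_weights,
    fuse_predict,
    make_classifier,
)
from .epochs import TrialSet, segment_windows
from .events import LABELS
from .features import (
    FeatureStandardizer,
    PowFeatureParams,
    SlopeFeatureParams,
    continuous_fnirs_feature,
    erp_feature,
    pow_feature,
    select_slope_params,
    slope_feature,
    slope_grid,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- conditions


@dataclass(frozen=True)
class ConditionSpec:
    """A binary classification condition: two disjoint label sets."""

    name: str
    class1: tuple[str, ...]
    class2: tuple[str, ...]

    def __post_init__(self) -> None:
        s1, s2 = set(self.class1), set(self.class2)
        if s1 & s2:
            raise ValueError("condition label sets overlap")
        if not s1 or not s2:
            raise ValueError("both classes need at least one label")
        unknown = (s1 | s2) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}")

    def side_of(self, label: str) -> int | None:
        """0 for class 1, 1 for class 2, None if the label is outside."""
        if label in self.class1:
            return 0
        if label in self.class2:
            return 1
        return None


#: the five standard evaluation conditions
CONDITIONS: dict[str, ConditionSpec] = {
    "AUD_vs_VIS": ConditionSpec("AUD_vs_VIS", ("AUD",), ("VIS",)),
    "AUD_vs_IDLE": ConditionSpec("AUD_vs_IDLE", ("AUD",), ("IDLE",)),
    "VIS_vs_IDLE": ConditionSpec("VIS_vs_IDLE", ("VIS",), ("IDLE",)),
    "allAUD_vs_nonAUD": ConditionSpec("allAUD_vs_nonAUD", ("AUD", "MIX"), ("VIS", "IDLE")),
    "allVIS_vs_nonVIS": ConditionSpec("allVIS_vs_nonVIS", ("VIS", "MIX"), ("AUD", "IDLE")),
}


def build_condition(trials: TrialSet, spec: ConditionSpec
                    ) -> tuple[TrialSet, np.ndarray]:
    """Restrict to the condition's labels and return (subset, binary y).

    y is 0 for class 1 and 1 for class 2; original labels stay available in
    the subset's `meta` for confusion reporting.
    """
    labels = trials.labels
    sides = np.array([-1 if (s := spec.side_of(l)) is None else s for l in labels])
    keep = sides >= 0
    for ci, cls in ((0, spec.class1), (1, spec.class2)):
        if not (sides == ci).any():
            raise ValueError(f"condition {spec.name}: class {cls} has no trials")
    return trials.select(keep), sides[keep]


@dataclass(frozen=True)
class CvPlan:
    """Cross-validation plan: outer mode, inner fold count, seed."""

    mode: str = "loto"  # "loto" (subject-dependent) | "loso" (subject-independent)
    inner_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("loto", "loso"):
            raise ValueError("mode must be 'loto' or 'loso'")


@dataclass(frozen=True)
class ClassifierConfig:
    shrinkage: float = 0.5
    svm_C: float = 1.0


# ------------------------------------------------------------ feature cache


class FeatureCache:
    """Precomputed per-trial feature matrices for one binary condition.

    HbO/HbR slope features are precomputed for every grid point so the
    nested grid search reduces to row slicing; POW and ERP have fixed
    parameters.
    """

    def __init__(
        self,
        trials: TrialSet,
        y: np.ndarray,
        grid: list[SlopeFeatureParams] | None = None,
        pow_params: PowFeatureParams = PowFeatureParams(),
        feature_types: tuple[str, ...] = FEATURE_TYPES,
    ):
        self.y = np.asarray(y, int)
        self.original_labels = trials.labels.copy()
        self.subject_ids = np.repeat(trials.subject_id, len(trials))
        self.feature_types = feature_types
        self.grid = grid if grid is not None else slope_grid()
        self._mats: dict = {}
        if "HbO" in feature_types or "HbR" in feature_types:
            hbo = trials.blocks["hbo"].post_onset()
            hbr = trials.blocks["hbr"].post_onset()
            for p in self.grid:
                self._mats[("HbO", p)] = slope_feature(hbo, p)
                self._mats[("HbR", p)] = slope_feature(hbr, p)
        if "POW" in feature_types:
            psd = pow_feature(trials.blocks["pow"].post_onset(), fs=256.0,
                              params=pow_params)
            self._mats[("POW", None)] = psd.reshape(len(trials), -1)
        if "ERP" in feature_types:
            erp = erp_feature(trials.blocks["erp"].post_onset())
            self._mats[("ERP", None)] = erp.reshape(len(trials), -1)

    def matrix(self, ft: str, params: SlopeFeatureParams | None = None) -> np.ndarray:
        key = (ft, params if ft in ("HbO", "HbR") else None)
        return self._mats[key]

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def concat(cls, caches: list["FeatureCache"]) -> "FeatureCache":
        out = object.__new__(cls)
        out.y = np.concatenate([c.y for c in caches])
        out.original_labels = np.concatenate([c.original_labels for c in caches])
        out.subject_ids = np.concatenate([c.subject_ids for c in caches])
        out.feature_types = caches[0].feature_types
        out.grid = caches[0].grid
        keys = caches[0]._mats.keys()
        out._mats = {k: np.vstack([c._mats[k] for c in caches]) for k in keys}
        return out


class WindowFeatureCache(FeatureCache):
    """Feature cache over continuous-segment windows.

    fNIRS features are the window mean minus the elapsed-data mean on the
    1 Hz haemoglobin series; POW is Welch band power on the EEG window.
    ERP features are undefined without a stimulus onset and are rejected.
    """

    def __init__(
        self,
        subject_id: str,
        hemo,  # HemoglobinSeries
        eeg: np.ndarray,
        eeg_fs: float,
        segments: pd.DataFrame,  # onset_s, duration_s, label
        spec: ConditionSpec,
        w_len: float,
        pow_params: PowFeatureParams = PowFeatureParams(),
        feature_types: tuple[str, ...] = ("HbO", "HbR", "POW"),
    ):
        if "ERP" in feature_types:
            raise ValueError("ERP features require stimulus onsets; "
                             "not available in continuous mode")
        self.feature_types = feature_types
        self.grid = None
        rows_y, rows_lab, feats = [], [], {ft: [] for ft in feature_types}
        for _, seg in segments.iterrows():
            side = spec.side_of(seg["label"])
            if side is None:
                continue
            ws = segment_windows(seg["duration_s"], w_len, seg["label"])
            t0 = float(seg["onset_s"])
            hbo_seg = hemo.hbo[:, int(round(t0 * hemo.fs)):
                               int(round((t0 + seg["duration_s"]) * hemo.fs))]
            hbr_seg = hemo.hbr[:, int(round(t0 * hemo.fs)):
                               int(round((t0 + seg["duration_s"]) * hemo.fs))]
            e0 = int(round(t0 * eeg_fs))
            eeg_seg = eeg[:, e0: e0 + int(round(seg["duration_s"] * eeg_fs))]
            for start, stop in zip(ws.starts, ws.stops):
                rows_y.append(side)
                rows_lab.append(seg["label"])
                if "HbO" in feature_types or "HbR" in feature_types:
                    i0 = int(np.ceil(start * hemo.fs - 1e-9))
                    i1 = int(np.ceil(stop * hemo.fs - 1e-9))
                    i1 = min(i1, hbo_seg.shape[1])
                    if i1 <= i0:  # truncated window without a 1 Hz sample
                        i0 = min(int(np.floor(start * hemo.fs)), hbo_seg.shape[1] - 1)
                        i1 = i0 + 1
                    feats["HbO"].append(continuous_fnirs_feature(
                        hbo_seg[:, i0:i1], hbo_seg[:, :i0]))
                    feats["HbR"].append(continuous_fnirs_feature(
                        hbr_seg[:, i0:i1], hbr_seg[:, :i0]))
                if "POW" in feature_types:
                    j0 = int(round(start * eeg_fs))
                    j1 = min(int(round(stop * eeg_fs)), eeg_seg.shape[1])
                    psd = pow_feature(eeg_seg[None, :, j0:j1], fs=eeg_fs,
                                      params=pow_params)
                    feats["POW"].append(psd.reshape(-1))
        self.y = np.asarray(rows_y, int)
        self.original_labels = np.asarray(rows_lab)
        self.subject_ids = np.repeat(subject_id, len(self.y))
        self._mats = {(ft, None): np.vstack(feats[ft]) for ft in feature_types}

    def matrix(self, ft, params=None):
        return self._mats[(ft, None)]


# ----------------------------------------------------------- fitted models


@dataclass
class FittedCondition:
    """A fully fitted condition model: per-type standardizers + classifiers,
    selected slope parameters, and fusion weights."""

    feature_types: tuple[str, ...]
    slope_params: dict
    standardizers: dict
    classifiers: dict
    weights: FusionWeights
    eval_accuracies: dict

    def component_proba(self, cache: FeatureCache, idx) -> np.ndarray:
        cols = []
        for ft in self.feature_types:
            X = cache.matrix(ft, self.slope_params.get(ft))[idx]
            cols.append(self.classifiers[ft].predict_proba(
                self.standardizers[ft].transform(X)))
        return np.stack(cols, axis=1)

    def predict_index(self, cache: FeatureCache, idx) -> dict[str, np.ndarray]:
        """Class-index predictions per feature type and for META."""
        probs = self.component_proba(cache, idx)
        out = {ft: (probs[:, m, 1] > probs[:, m, 0]).astype(int)
               for m, ft in enumerate(self.feature_types)}
        out["META"], _ = fuse_predict(probs, self.weights)
        return out

    # --------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Serialize to an .npz array bundle plus a JSON provenance sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        arrays: dict = {}
        meta: dict = {"feature_types": list(self.feature_types),
                      "weights": list(self.weights.as_array()),
                      "eval_accuracies": {k: float(v) for k, v
                                          in self.eval_accuracies.items()},
                      "slope_params": {ft: [p.t_opt, p.w] for ft, p
                                       in self.slope_params.items()},
                      "classifier_kinds": {}}
        for ft in self.feature_types:
            nz = self.standardizers[ft]
            arrays[f"{ft}_mean"] = nz.mean_
            arrays[f"{ft}_scale"] = nz.scale_
            arrays[f"{ft}_degenerate"] = nz.degenerate_mask_
            clf = self.classifiers[ft]
            if isinstance(clf, ShrinkageLda):
                meta["classifier_kinds"][ft] = "shrinkage-lda"
                arrays[f"{ft}_coef"] = clf.coef_
                arrays[f"{ft}_intercept"] = np.array([clf.intercept_])
                arrays[f"{ft}_classes"] = clf.classes_
            else:
                meta["classifier_kinds"][ft] = "linear-svm"
                arrays[f"{ft}_support"] = clf.svc_.support_vectors_
                arrays[f"{ft}_dual"] = clf.svc_.dual_coef_
                arrays[f"{ft}_svc_intercept"] = clf.svc_.intercept_
                arrays[f"{ft}_calib"] = np.array([clf.calib_slope_,
                                                  clf.calib_intercept_])
                arrays[f"{ft}_classes"] = clf.classes_
        np.savez(path, **arrays)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "FittedCondition":
        """Inverse of `save` (SVM models reload their linear equivalent)."""
        import json
        from pathlib import Path

        path = Path(path)
        with np.load(path, allow_pickle=False) as bundle:
            arrays = {k: bundle[k] for k in bundle.files}
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        fts = tuple(meta["feature_types"])
        standardizers, classifiers = {}, {}
        for ft in fts:
            nz = FeatureStandardizer()
            nz.mean_ = arrays[f"{ft}_mean"]
            nz.scale_ = arrays[f"{ft}_scale"]
            nz.degenerate_mask_ = arrays[f"{ft}_degenerate"]
            standardizers[ft] = nz
            kind = meta["classifier_kinds"][ft]
            if kind == "shrinkage-lda":
                clf = ShrinkageLda()
                clf.coef_ = arrays[f"{ft}_coef"]
                clf.intercept_ = float(arrays[f"{ft}_intercept"][0])
                clf.classes_ = arrays[f"{ft}_classes"]
            else:
                clf = _LoadedLinearSvm(
                    coef=arrays[f"{ft}_dual"] @ arrays[f"{ft}_support"],
                    intercept=float(arrays[f"{ft}_svc_intercept"][0]),
                    calib=arrays[f"{ft}_calib"],
                    classes=arrays[f"{ft}_classes"])
            classifiers[ft] = clf
        slope_params = {ft: SlopeFeatureParams(*v)
                        for ft, v in meta["slope_params"].items()}
        weights = FusionWeights(tuple(meta["weights"]), fts)
        return cls(fts, slope_params, standardizers, classifiers, weights,
                   meta["eval_accuracies"])


class _LoadedLinearSvm:
    """Deserialized linear SVM: decision function + monotone calibration."""

    def __init__(self, coef, intercept, calib, classes):
        self.coef_ = np.asarray(coef).ravel()
        self.intercept_ = intercept
        self.calib_slope_, self.calib_intercept_ = calib
        self.classes_ = classes

    def decision_function(self, X):
        return np.atleast_2d(X) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        from scipy.special import expit

        p1 = expit(self.calib_slope_ * self.decision_function(X)
                   + self.calib_intercept_)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def _split_accuracy(X, y, splits, factory) -> float:
    accs = []
    for tr, ev in splits:
        if len(np.unique(y[tr])) < 2:
            continue  # degenerate split on very small training sets
        nz = FeatureStandardizer().fit(X[tr])
        clf = factory().fit(nz.transform(X[tr]), y[tr])
        accs.append(float((clf.predict(nz.transform(X[ev])) == y[ev]).mean()))
    return float(np.mean(accs)) if accs else 0.5


def fit_condition(
    cache: FeatureCache,
    train_idx: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> FittedCondition:
    """Fit one condition model on `train_idx` rows of `cache`.

    `splits` (relative to `train_idx`) provide the evaluation data used both
    for slope-parameter selection and for the per-classifier accuracies that
    become fusion weights; the final model is refit on all of `train_idx`.
    """
    y = cache.y[train_idx]
    slope_params: dict = {}
    eval_accs: dict = {}
    for ft in cache.feature_types:
        factory = (lambda ft=ft: make_classifier(ft, cfg.shrinkage, cfg.svm_C))
        if ft in ("HbO", "HbR") and cache.grid:
            fbp = {p: cache.matrix(ft, p)[train_idx] for p in cache.grid}
            p_best, acc = select_slope_params(fbp, y, splits, factory)
            slope_params[ft] = p_best
            eval_accs[ft] = acc
        else:
            eval_accs[ft] = _split_accuracy(
                cache.matrix(ft, None)[train_idx], y, splits, factory)
    weights = estimate_fusion_weights(
        [eval_accs[ft] for ft in cache.feature_types],
        feature_types=cache.feature_types)
    standardizers, classifiers = {}, {}
    for ft in cache.feature_types:
        X = cache.matrix(ft, slope_params.get(ft))[train_idx]
        nz = FeatureStandardizer().fit(X)
        standardizers[ft] = nz
        classifiers[ft] = make_classifier(ft, cfg.shrinkage, cfg.svm_C).fit(
            nz.transform(X), y)
    return FittedCondition(cache.feature_types, slope_params, standardizers,
                           classifiers, weights, eval_accs)


def _inner_splits(y: np.ndarray, n_folds: int, rng: np.random.Generator
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled, class-stratified k-fold splits of range(len(y)).

    Each class's members are dealt round-robin to the folds, so fold sizes
    follow the ceil-then-floor pattern (59 trials in 10 folds -> nine
    6-trial evaluation folds and one of 5, i.e. 53 training trials in a
    6-trial fold) while both classes stay represented in every training set.
    """
    y = np.asarray(y)
    n_train = len(y)
    if n_train < n_folds:
        logger.warning("reducing inner folds from %d to %d", n_folds, n_train)
        n_folds = n_train
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    pos = 0
    for cls in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == cls))
        for idx in members:
            folds[pos % n_folds].append(int(idx))
            pos += 1
    all_idx = np.arange(n_train)
    return [(np.setdiff1d(all_idx, f), np.sort(f)) for f in folds if f]


# ------------------------------------------------------------- CV drivers


@dataclass
class ConditionResult:
    """Evaluation outcome for one condition in one CV mode."""

    condition: str
    mode: str
    accuracy: dict  # feature type / "META" -> overall accuracy
    per_subject: pd.DataFrame  # columns: subject, feature_type, accuracy, n
    label_correct: pd.DataFrame  # META correctness per original label
    fold_params: list = field(default_factory=list)
    fold_weights: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(condition=self.condition, mode=self.mode, feature_type=ft,
                     accuracy=acc) for ft, acc in self.accuracy.items()]
        return pd.DataFrame(rows)


def _collect_result(condition, mode, cache, pred_rows, fold_params, fold_weights
                    ) -> ConditionResult:
    """Assemble a ConditionResult from per-trial prediction records."""
    df = pd.DataFrame(pred_rows)
    feature_cols = [c for c in df.columns
                    if c not in ("subject", "true", "label")]
    accuracy = {ft: float((df[ft] == df["true"]).mean()) for ft in feature_cols}
    per_subject = (
        df.melt(id_vars=["subject", "true", "label"], var_name="feature_type",
                value_name="pred")
        .assign(correct=lambda d: d["pred"] == d["true"])
        .groupby(["subject", "feature_type"])
        .agg(accuracy=("correct", "mean"), n=("correct", "size"))
        .reset_index()
    )
    label_correct = (
        df.assign(correct=lambda d: d["META"] == d["true"])
        .groupby("label")
        .agg(rate=("correct", "mean"), n=("correct", "size"))
        .reset_index()
    )
    return ConditionResult(condition, mode, accuracy, per_subject, label_correct,
                           fold_params, fold_weights)


def run_subject_dependent_cv(
    trials: TrialSet,
    spec: ConditionSpec,
    plan: CvPlan = CvPlan("loto"),
    cfg: ClassifierConfig = ClassifierConfig(),
    grid: list[SlopeFeatureParams] | None = None,
    pow_params: PowFeatureParams = PowFeatureParams(),
    feature_types: tuple[str, ...] = FEATURE_TYPES,
) -> ConditionResult:
    """Leave-one-trial-out with a nested inner CV per outer fold.

    60 condition trials give 60 outer folds; each outer training set of 59
    is split into 10 inner folds (nine of 6 evaluation trials, one of 5) for
    parameter selection and fusion-weight estimation.
    """
    sub, y = build_condition(trials, spec)
    if min(np.bincount(y)) < 2:
        raise ValueError("need >= 2 trials per class")
    cache = FeatureCache(sub, y, grid=grid, pow_params=pow_params,
                         feature_types=feature_types)
    n = len(cache)
    rows, fold_params, fold_weights = [], [], []
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        rng = np.random.default_rng([plan.seed, i])
        splits = _inner_splits(cache.y[train_idx], plan.inner_folds, rng)
        model = fit_condition(cache, train_idx, splits, cfg)
        preds = model.predict_index(cache, np.array([i]))
        rows.append({"subject": sub.subject_id, "true": int(y[i]),
                     "label": cache.original_labels[i],
                     **{ft: int(p[0]) for ft, p in preds.items()}})
        fold_params.append(model.slope_params)
        fold_weights.append(model.weights)
    return _collect_result(spec.name, "subject-dependent", cache, rows,
                           fold_params, fold_weights)


def loso_folds(n_subjects: int, seed: int):
    """Outer LOSO folds with a deterministic evaluation subject per fold.

    Yields (test_subject, train_subjects, eval_subject) index triples; the
    evaluation subject is drawn from the training subjects and is used for
    parameter selection and fusion weights only.  With a single training
    subject (2-subject cohort) there is nothing to hold out and
    eval_subject is None; drivers then fall back to inner k-fold splits.
    """
    for s in range(n_subjects):
        train = [t for t in range(n_subjects) if t != s]
        rng = np.random.default_rng([seed, s])
        eval_subject = (train[int(rng.integers(len(train)))]
                        if len(train) > 1 else None)
        yield s, train, eval_subject


def _fit_loso_fold(caches, train_subjects, eval_subject, plan, cfg,
                   fold: int) -> FittedCondition:
    """Stack the training subjects' caches and fit one LOSO fold's model."""
    stacked = FeatureCache.concat([caches[t] for t in train_subjects])
    if eval_subject is None:
        rng = np.random.default_rng([plan.seed, 10_000 + fold])
        splits = _inner_splits(stacked.y, plan.inner_folds, rng)
    else:
        sizes = np.array([len(caches[t]) for t in train_subjects])
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        pos = train_subjects.index(eval_subject)
        ev_idx = np.arange(offsets[pos], offsets[pos + 1])
        tr_idx = np.setdiff1d(np.arange(len(stacked)), ev_idx)
        splits = [(tr_idx, ev_idx)]
    return fit_condition(stacked, np.arange(len(stacked)), splits, cfg)


def run_subject_independent_cv(
    cohort_trials: list[TrialSet],
    spec: ConditionSpec,
    plan: CvPlan = CvPlan("loso"),
    cfg: ClassifierConfig = ClassifierConfig(),
    grid: list[SlopeFeatureParams] | None = None,
    pow_params: PowFeatureParams = PowFeatureParams(),
    feature_types: tuple[str, ...] = FEATURE_TYPES,
) -> ConditionResult:
    """Leave-one-subject-out: 12 subjects with 60 condition trials each give
    660 training and 60 test trials per fold."""
    if len(cohort_trials) < 2:
        raise ValueError("subject-independent CV needs >= 2 subjects")
    caches = []
    for ts in cohort_trials:
        sub, y = build_condition(ts, spec)
        caches.append(FeatureCache(sub, y, grid=grid, pow_params=pow_params,
                                   feature_types=feature_types))
    rows, fold_params, fold_weights = [], [], []
    for s, train_subjects, eval_subject in loso_folds(len(caches), plan.seed):
        model = _fit_loso_fold(caches, train_subjects, eval_subject, plan, cfg, s)
        test = caches[s]
        preds = model.predict_index(test, np.arange(len(test)))
        for j in range(len(test)):
            rows.append({"subject": test.subject_ids[j], "true": int(test.y[j]),
                         "label": test.original_labels[j],
                         **{ft: int(p[j]) for ft, p in preds.items()}})
        fold_params.append(model.slope_params)
        fold_weights.append(model.weights)
    return _collect_result(spec.name, "subject-independent", caches[0], rows,
                           fold_params, fold_weights)


# ------------------------------------------------------- transfer (Table 4)


def cross_evaluate(
    model,
    cache: FeatureCache,
    expected: dict[str, int],
) -> pd.DataFrame:
    """Evaluate a fitted condition model on trials from outside its training
    label set.

    `expected` maps each original label to the class index (0/1) a perfectly
    modality-specific detector would assign.  Returns per-label and
    per-feature-type fractions of trials assigned the expected class.
    """
    missing = sorted(set(cache.original_labels) - set(expected))
    if missing:
        raise ValueError(f"no expected-class mapping for labels {missing}")
    preds = model.predict_index(cache, np.arange(len(cache)))
    want = np.array([expected[l] for l in cache.original_labels])
    rows = []
    for ft, p in preds.items():
        for lab in np.unique(cache.original_labels):
            m = cache.original_labels == lab
            rows.append(dict(feature_type=ft, label=lab,
                             rate=float((p[m] == want[m]).mean()),
                             n=int(m.sum())))
    return pd.DataFrame(rows)


def run_cross_evaluation(
    cohort_trials: list[TrialSet],
    train_spec: ConditionSpec,
    expected: dict[str, int],
    plan: CvPlan = CvPlan("loso"),
    cfg: ClassifierConfig = ClassifierConfig(),
    grid: list[SlopeFeatureParams] | None = None,
    feature_types: tuple[str, ...] = FEATURE_TYPES,
) -> pd.DataFrame:
    """LOSO transfer evaluation: train on `train_spec`, evaluate each fold's
    model on the test subject's trials with labels in `expected`."""
    if len(cohort_trials) < 2:
        raise ValueError("needs >= 2 subjects")
    train_caches, out_caches = [], []
    eval_labels = tuple(expected)
    for ts in cohort_trials:
        sub, y = build_condition(ts, train_spec)
        train_caches.append(FeatureCache(sub, y, grid=grid,
                                         feature_types=feature_types))
        keep = np.isin(ts.labels, eval_labels)
        out = ts.select(keep)
        out_caches.append(FeatureCache(out, np.zeros(len(out), int), grid=grid,
                                       feature_types=feature_types))
    frames = []
    for s, train_subjects, eval_subject in loso_folds(len(train_caches), plan.seed):
        model = _fit_loso_fold(train_caches, train_subjects, eval_subject,
                               plan, cfg, s)
        frames.append(cross_evaluate(model, out_caches[s], expected))
    all_rows = pd.concat(frames)
    return (all_rows.groupby(["feature_type", "label"])
            .apply(lambda d: np.average(d["rate"], weights=d["n"]),
                   include_groups=False)
            .rename("rate").reset_index())


# --------------------------------------------------- continuous evaluation


def run_continuous_evaluation(
    subjects: list[dict],
    spec: ConditionSpec,
    w_lens: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0),
    plan: CvPlan = CvPlan("loso"),
    cfg: ClassifierConfig = ClassifierConfig(),
    pow_params: PowFeatureParams = PowFeatureParams(),
    feature_types: tuple[str, ...] = ("HbO", "HbR", "POW"),
) -> pd.DataFrame:
    """Windowed decoding of the block-1 continuous clips, LOSO only.

    `subjects` holds dicts with keys subject_id, hemo (HemoglobinSeries),
    eeg (cleaned voltages), eeg_fs, segments (continuous-segment table).
    Returns accuracy per window length and feature type (and META).
    """
    if "ERP" in feature_types:
        raise ValueError("ERP features are restricted to stimulus onsets; "
                         "exclude them from continuous evaluation")
    if len(subjects) < 2:
        raise ValueError("needs >= 2 subjects")
    rows = []
    for w_len in w_lens:
        min_dur = min(min(s["segments"]["duration_s"]) for s in subjects)
        if w_len / 2 > min_dur:
            logger.warning("skipping w_len=%s s (segments too short)", w_len)
            continue
        caches = [
            WindowFeatureCache(s["subject_id"], s["hemo"], s["eeg"], s["eeg_fs"],
                               s["segments"], spec, w_len, pow_params,
                               feature_types)
            for s in subjects
        ]
        preds_all = {ft: [] for ft in (*feature_types, "META")}
        truth_all = []
        for s, train_subjects, eval_subject in loso_folds(len(caches), plan.seed):
            model = _fit_loso_fold(caches, train_subjects, eval_subject,
                                   plan, cfg, s)
            test = caches[s]
            preds = model.predict_index(test, np.arange(len(test)))
            for ft, p in preds.items():
                preds_all[ft].append(p)
            truth_all.append(test.y)
        truth = np.concatenate(truth_all)
        for ft, chunks in preds_all.items():
            acc = float((np.concatenate(chunks) == truth).mean())
            rows.append(dict(condition=spec.name, w_len=w_len, feature_type=ft,
                             accuracy=acc, n_windows=len(truth)))
    return pd.DataFrame(rows)


# ---------------------------------------------------- bounds & significance


def chance_upper_bound(n_trials: int, alpha: float = 0.01,
                       method: str = "normal") -> float:
    """Upper limit (in %) of the two-sided (1 - alpha) interval around 50 %
    accuracy for `n_trials` Bernoulli trials.

    The default normal approximation gives 52.4 % at n = 2880 and 53.4 % at
    n = 1440; ``method="adjusted-wald"`` applies the adjusted-Wald shrinkage
    of the effective trial count.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    z = stats.norm.ppf(1 - alpha / 2)
    if method == "normal":
        half = z * np.sqrt(0.25 / n_trials)
    elif method == "adjusted-wald":
        half = z * np.sqrt(0.25 / (n_trials + z**2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(100.0 * (0.5 + half))


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvals, float), method="holm")[1]


def compare_accuracies(
    pairs: dict[str, tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired one-sided t-tests (first > second) with Holm correction.

    `pairs` maps a condition name to (meta_accuracies, reference_accuracies)
    per subject.  All-zero difference vectors yield p = 1 (exact tie).
    """
    names, pvals, tstats = [], [], []
    for name, (a, b) in pairs.items():
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.shape != b.shape or len(a) < 2:
            raise ValueError(f"{name}: paired vectors of equal length >= 2 required")
        d = a - b
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        elif np.allclose(d, d[0]):
            # constant non-zero difference: zero variance, direction decides
            t, p = (np.inf, 0.0) if d[0] > 0 else (-np.inf, 1.0)
        else:
            t, p = stats.ttest_rel(a, b, alternative="greater")
        names.append(name)
        tstats.append(float(t))
        pvals.append(float(p))
    adj = holm_adjust(pvals)
    return pd.DataFrame({
        "condition": names, "t": tstats, "p": pvals,
        "p_holm": adj, "significant": adj < alpha,
    })


# --------------------------------------------- general-activity stub (75 %)


def general_activity_accuracy(labels, spec: ConditionSpec,
                              active_labels=("AUD", "VIS", "MIX")) -> float:
    """Accuracy of a detector that keys purely on general activity.

    The stub assigns every trial containing any stimulus activity to the
    condition side holding activity labels (and rest to the other); on a
    balanced modality-detection condition such as allVIS vs. nonVIS this
    yields exactly 75 %: VIS, MIX and IDLE are classified correctly, AUD is
    not.
    """
    labels = np.asarray(labels)
    sides = np.array([spec.side_of(l) for l in labels])
    if (sides == None).any():  # noqa: E711 - object comparison on purpose
        raise ValueError("labels outside the condition")
    # the stub's "activity" side: the class containing more active labels
    act1 = sum(l in active_labels for l in spec.class1) / len(spec.class1)
    act2 = sum(l in active_labels for l in spec.class2) / len(spec.class2)
    activity_side = 0 if act1 >= act2 else 1
    pred = np.where(np.isin(labels, active_labels), activity_side,
                    1 - activity_side)
    return float((pred == sides.astype(int)).mean())
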