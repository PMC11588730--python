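"""Repeated three-class random-forest pipeline over laterality features.

Each repetition draws a fresh stratified 70/30 split, filters the 4 x
n_rois laterality features with a decision tree (features with positive
impurity importance survive), recalibrates class weights against group
imbalance, grid-searches a random forest by stratified cross-validated
accuracy on the training set, and scores the held-out subjects with macro
one-vs-rest metrics (ACC, PRE, SPE, SEN, F1, ROC).  The whole sequence is
repeated (100 times by default) and aggregated as mean with normal-
approximation 95% confidence intervals.  Per-repetition selected features,
importances, and fitted bundles are retained for feature scoring and for
external validation against an independent control cohort.

Short time series can be segmented into k contiguous equal blocks treated
as pseudo-subjects to enlarge the sample; a leakage guard (on by default)
keeps all segments of one original subject on the same side of every
split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from hemilat.config import PipelineConfig
from hemilat.io import GROUPS, METRIC_NAMES, RoiTimeSeries
from hemilat.laterality import FAMILIES, LateralityProfile

PATIENT_GROUPS = ("RLS", "NRLS")


class FeatureSelectionError(RuntimeError):
    """No feature earned positive importance; the cohort or effect is too small."""


@dataclass
class FeatureMatrix:
    """Subjects x (4 x n_rois) laterality features with provenance."""

    x: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    origin: np.ndarray  # original subject of each row (== subject_id if unsegmented)
    provenance: tuple[tuple[str, int], ...]  # column -> (family, roi_id)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if np.isnan(self.x).any():
            raise ValueError("feature matrix contains NaN")
        if self.x.shape[1] != len(self.provenance):
            raise ValueError("provenance length must match feature count")

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def n_features(self) -> int:
        return self.x.shape[1]

    def family_subset(self, families: str | Sequence[str]) -> "FeatureMatrix":
        """Restrict to one or more index families (for single-family runs)."""
        if isinstance(families, str):
            families = (families,)
        keep = [i for i, (fam, _) in enumerate(self.provenance) if fam in families]
        if not keep:
            raise ValueError(f"no features for families {families}")
        return FeatureMatrix(
            x=self.x[:, keep],
            labels=self.labels,
            subject_ids=self.subject_ids,
            origin=self.origin,
            provenance=tuple(self.provenance[i] for i in keep),
        )

    def rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            x=self.x[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            origin=self.origin[idx],
            provenance=self.provenance,
        )


def profiles_to_features(profiles: Sequence[LateralityProfile]) -> FeatureMatrix:
    """Stack per-subject profiles into the fixed-order feature matrix."""
    if not profiles:
        raise ValueError("no profiles given")
    n_rois = profiles[0].n_rois
    prov = tuple((fam, roi + 1) for fam in FAMILIES for roi in range(n_rois))
    x = np.stack([p.feature_vector() for p in profiles])
    sids = np.array([p.subject_id for p in profiles])
    origin = np.array([p.subject_id.split("__seg")[0] for p in profiles])
    return FeatureMatrix(
        x=x,
        labels=np.array([p.group for p in profiles]),
        subject_ids=sids,
        origin=origin,
        provenance=prov,
    )


def segment_subjects(cohort: Sequence[RoiTimeSeries], k: int) -> list[RoiTimeSeries]:
    """Cut each subject's series into ``k`` contiguous equal blocks.

    Blocks have ``floor(T / k)`` timepoints (remainder dropped from the
    end); each becomes a pseudo-subject ``<id>__seg<j>`` inheriting the
    label, so downstream splits can group them by original subject.
    """
    if k < 1:
        raise ValueError("segmentation k must be >= 1")
    if k == 1:
        return list(cohort)
    out = []
    for ts in cohort:
        block = ts.n_timepoints // k
        if block < 30:
            warnings.warn(
                f"{ts.subject_id}: segments of {block} timepoints (< 30) are noisy",
                stacklevel=2,
            )
        for j in range(k):
            out.append(
                RoiTimeSeries(
                    subject_id=f"{ts.subject_id}__seg{j + 1}",
                    group=ts.group,
                    data=ts.data[j * block : (j + 1) * block],
                    tr_seconds=ts.tr_seconds,
                )
            )
    return out


def stratified_split(
    labels: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
    origin: np.ndarray | None = None,
    leakage_guard: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class 70/30 (rounded) partition into train/test row indices.

    With the leakage guard on, splitting operates on original subjects, so
    all segments of one subject land on the same side.
    """
    labels = np.asarray(labels)
    if origin is None or not leakage_guard:
        units = np.arange(labels.size)
        unit_labels = labels
        expand = {u: [u] for u in units}
    else:
        origin = np.asarray(origin)
        seen: dict = {}
        for i, o in enumerate(origin):
            seen.setdefault(o, []).append(i)
        units = np.arange(len(seen))
        keys = list(seen)
        unit_labels = np.array([labels[seen[k][0]] for k in keys])
        expand = {u: seen[keys[u]] for u in units}
    train_u, test_u = [], []
    for cls in np.unique(unit_labels):
        members = units[unit_labels == cls]
        if members.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 units; cannot split")
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_u.extend(perm[:n_train])
        test_u.extend(perm[n_train:])
    train = np.sort(np.concatenate([expand[u] for u in train_u]))
    test = np.sort(np.concatenate([expand[u] for u in test_u]))
    return train, test


def select_features_tree(
    x: np.ndarray,
    y: np.ndarray,
    seed: int,
    max_features: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Decision-tree feature filter.

    Fits one multiclass tree on all features and keeps those with positive
    impurity-based importance (optionally capped at the ``max_features``
    highest).  Returns (selected indices, their importances).
    """
    tree = DecisionTreeClassifier(random_state=seed)
    tree.fit(x, y)
    imp = tree.feature_importances_
    sel = np.nonzero(imp > 0)[0]
    if sel.size == 0:
        raise FeatureSelectionError(
            "decision tree found no informative feature; "
            "increase the cohort size or effect magnitude"
        )
    if max_features is not None and sel.size > max_features:
        order = np.argsort(imp[sel])[::-1][:max_features]
        sel = np.sort(sel[order])
    return sel, imp[sel]


def derive_class_weights(
    y: np.ndarray, method: str = "balanced", seed: int = 0
) -> dict[str, float]:
    """Class weights against group imbalance.

    ``balanced`` gives ``n / (n_classes * n_c)``.  ``logistic`` refines the
    balanced weights with one pass of a multinomial logistic model: each
    class's weight is divided by its training recall (poorly recalled
    classes are up-weighted) and the result renormalized to mean 1.
    """
    y = np.asarray(y)
    classes = [g for g in GROUPS if g in y]
    if len(classes) < len(GROUPS):
        missing = set(GROUPS) - set(classes)
        raise ValueError(f"missing class(es) {sorted(missing)} in training labels")
    n = y.size
    counts = {c: int((y == c).sum()) for c in classes}
    weights = {c: n / (len(classes) * counts[c]) for c in classes}
    if method == "logistic":
        raise ValueError("logistic recalibration needs features; use recalibrate_weights")
    return weights


def recalibrate_weights(
    x: np.ndarray, y: np.ndarray, weights: dict[str, float], seed: int = 0
) -> dict[str, float]:
    """One-pass multinomial-logistic refinement of class weights."""
    clf = LogisticRegression(max_iter=200, class_weight=dict(weights), random_state=seed)
    clf.fit(x, y)
    pred = clf.predict(x)
    refined = {}
    for c, w in weights.items():
        mask = y == c
        recall = float((pred[mask] == c).mean()) if mask.any() else 1.0
        refined[c] = w / max(recall, 1e-3)
    mean_w = float(np.mean(list(refined.values())))
    return {c: w / mean_w for c, w in refined.items()}


@dataclass
class TrainedBundle:
    """One repetition's fitted pipeline state."""

    selected: np.ndarray
    importances: np.ndarray  # aligned with ``selected``
    class_weights: dict[str, float]
    rf_params: dict
    forest: RandomForestClassifier
    split_seed: int

    def predict_frame(self, x_full: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xs = x_full[:, self.selected]
        return self.forest.predict(xs), self.forest.predict_proba(xs)


def grid_search_rf(
    x: np.ndarray,
    y: np.ndarray,
    class_weights: dict[str, float],
    grid: Sequence[dict],
    seed: int,
    cv_folds: int = 3,
) -> tuple[RandomForestClassifier, dict]:
    """Pick forest hyperparameters by stratified CV accuracy on the train set.

    Ties go to the first configuration in grid order; the winning forest is
    refit on the full training set with the class weights.  Folds are
    reduced (with a warning) when the smallest class cannot fill them.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    y = np.asarray(y)
    min_class = min(int((y == c).sum()) for c in np.unique(y))
    folds = min(cv_folds, min_class)
    if folds < cv_folds:
        warnings.warn(f"reducing CV folds to {folds} (smallest class has {min_class})", stacklevel=2)
    best_params, best_acc = None, -1.0
    if folds >= 2 and len(grid) > 1:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(skf.split(x, y))
        for params in grid:
            accs = []
            for tr, va in splits:
                rf = RandomForestClassifier(
                    random_state=seed, class_weight=dict(class_weights), **params
                )
                rf.fit(x[tr], y[tr])
                accs.append(float((rf.predict(x[va]) == y[va]).mean()))
            acc = float(np.mean(accs))
            if acc > best_acc + 1e-12:
                best_acc, best_params = acc, params
    else:
        best_params = grid[0]
    forest = RandomForestClassifier(
        random_state=seed, class_weight=dict(class_weights), **best_params
    )
    forest.fit(x, y)
    return forest, dict(best_params)


@dataclass
class MetricsRecord:
    """Macro one-vs-rest metric suite for one test evaluation."""

    acc: float
    pre: float
    spe: float
    sen: float
    f1: float
    roc: float
    confusion: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(
            zip(METRIC_NAMES, (self.acc, self.pre, self.spe, self.sen, self.f1, self.roc))
        )


def _macro_metrics(y_true: np.ndarray, y_pred: np.ndarray, proba: np.ndarray, classes) -> MetricsRecord:
    k = len(classes)
    conf = np.zeros((k, k), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1
    total = conf.sum()
    acc = float(np.trace(conf) / total)
    pre, spe, sen, f1, roc = [], [], [], [], []
    for i, c in enumerate(classes):
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        tn = total - tp - fp - fn
        present = conf[i, :].sum() > 0
        pre.append(tp / (tp + fp) if tp + fp > 0 else (np.nan if not present else 0.0))
        sen.append(tp / (tp + fn) if present else np.nan)
        spe.append(tn / (tn + fp) if tn + fp > 0 else np.nan)
        prec_i, rec_i = pre[-1], sen[-1]
        if np.isnan(prec_i) or np.isnan(rec_i) or prec_i + rec_i == 0:
            f1.append(0.0 if present else np.nan)
        else:
            f1.append(2 * prec_i * rec_i / (prec_i + rec_i))
        binary = (y_true == c).astype(int)
        if 0 < binary.sum() < binary.size:
            roc.append(float(roc_auc_score(binary, proba[:, i])))
        else:
            roc.append(np.nan)
    if np.isnan(pre + spe + sen + f1 + roc).any():
        warnings.warn("a test class is absent; undefined terms excluded from macro averages",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return MetricsRecord(
            acc=acc,
            pre=float(np.nanmean(pre)),
            spe=float(np.nanmean(spe)),
            sen=float(np.nanmean(sen)),
            f1=float(np.nanmean(f1)),
            roc=float(np.nanmean(roc)),
            confusion=conf,
        )


def evaluate(bundle: TrainedBundle, x_full: np.ndarray, y: np.ndarray) -> MetricsRecord:
    """Score a fitted bundle on test features (full-width matrix)."""
    if x_full.shape[0] == 0:
        raise ValueError("empty test set")
    y = np.asarray(y)
    pred, proba = bundle.predict_frame(x_full)
    classes = list(bundle.forest.classes_)
    return _macro_metrics(y, pred, proba, classes)


@dataclass
class RunReport:
    """Aggregated result of the repeated pipeline."""

    records: list[MetricsRecord]
    bundles: list[TrainedBundle]
    test_indices: list[np.ndarray]
    importances: np.ndarray  # (n_repetitions, n_features), zero where unselected
    provenance: tuple[tuple[str, int], ...]
    seed: int
    n_skipped: int = 0

    def per_repetition_frame(self) -> pd.DataFrame:
        rows = [{"repetition": i + 1, **r.as_dict()} for i, r in enumerate(self.records)]
        return pd.DataFrame(rows, columns=["repetition", *METRIC_NAMES])

    def aggregate_frame(self) -> pd.DataFrame:
        """Mean with normal-approximation 95% CI per metric (width 0 for n=1)."""
        df = self.per_repetition_frame()[list(METRIC_NAMES)]
        n = len(df)
        mean = df.mean()
        half = 1.96 * df.std(ddof=1) / np.sqrt(n) if n > 1 else pd.Series(0.0, index=mean.index)
        return pd.DataFrame(
            {
                "metric": METRIC_NAMES,
                "mean": mean.to_numpy(),
                "ci_low": (mean - half.fillna(0.0)).to_numpy(),
                "ci_high": (mean + half.fillna(0.0)).to_numpy(),
            }
        )

    def mean_metric(self, name: str = "ACC") -> float:
        return float(self.per_repetition_frame()[name].mean())

    def accuracies(self) -> np.ndarray:
        return np.array([r.acc for r in self.records])


def _rep_seeds(root_seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def repeat_harness(features: FeatureMatrix, config: PipelineConfig) -> RunReport:
    """Run split / selection / weighting / grid search / evaluation repeatedly.

    All randomness flows from ``config.rng_seed`` expanded into one child
    stream per repetition, so identical inputs and config replay exactly.
    Repetitions whose feature selection fails are skipped and counted.
    """
    seeds = _rep_seeds(config.rng_seed, config.n_repetitions)
    records, bundles, test_sets = [], [], []
    imps = []
    n_skipped = 0
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        try:
            train, test = stratified_split(
                features.labels,
                config.train_fraction,
                rng,
                origin=features.origin,
                leakage_guard=config.leakage_guard,
            )
            sel, sel_imp = select_features_tree(
                features.x[train], features.labels[train], seed=rep_seed,
                max_features=config.max_features,
            )
            weights = derive_class_weights(features.labels[train])
            if config.class_weighting == "logistic":
                weights = recalibrate_weights(
                    features.x[train][:, sel], features.labels[train], weights, seed=rep_seed
                )
            forest, params = grid_search_rf(
                features.x[train][:, sel],
                features.labels[train],
                weights,
                config.rf_grid,
                seed=rep_seed,
                cv_folds=config.rf_cv_folds,
            )
            bundle = TrainedBundle(
                selected=sel,
                importances=forest.feature_importances_,
                class_weights=weights,
                rf_params=params,
                forest=forest,
                split_seed=rep_seed,
            )
            records.append(evaluate(bundle, features.x[test], features.labels[test]))
        except FeatureSelectionError:
            n_skipped += 1
            continue
        bundles.append(bundle)
        test_sets.append(test)
        row = np.zeros(features.n_features)
        row[sel] = forest.feature_importances_
        imps.append(row)
    importances = np.stack(imps) if imps else np.zeros((0, features.n_features))
    return RunReport(
        records=records,
        bundles=bundles,
        test_indices=test_sets,
        importances=importances,
        provenance=features.provenance,
        seed=config.rng_seed,
        n_skipped=n_skipped,
    )


def external_validation(
    report: RunReport,
    features: FeatureMatrix,
    new_controls: FeatureMatrix,
    config: PipelineConfig,
    control_fraction: float = 0.3,
) -> RunReport:
    """Score each repetition's trained bundle on an independent composite set.

    The composite test set pairs the repetition's held-out patients with a
    comparable fresh fraction of a new control cohort that took no part in
    any fitting stage.  Feature layout must match the training cohort's.
    """
    if new_controls.provenance != features.provenance:
        raise ValueError("validation cohort features misaligned with training features")
    seeds = _rep_seeds(report.seed + 1, len(report.bundles))
    records = []
    for bundle, test, s in zip(report.bundles, report.test_indices, seeds):
        rng = np.random.default_rng(s)
        patient_rows = test[np.isin(features.labels[test], PATIENT_GROUPS)]
        n_ctrl = max(1, int(round(control_fraction * new_controls.n_subjects)))
        ctrl_rows = rng.permutation(new_controls.n_subjects)[:n_ctrl]
        x = np.vstack([features.x[patient_rows], new_controls.x[ctrl_rows]])
        y = np.concatenate([features.labels[patient_rows], new_controls.labels[ctrl_rows]])
        records.append(evaluate(bundle, x, y))
    return RunReport(
        records=records,
        bundles=report.bundles,
        test_indices=report.test_indices,
        importances=report.importances,
        provenance=report.provenance,
        seed=report.seed,
        n_skipped=report.n_skipped,
    )
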