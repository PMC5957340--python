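"""Classification evaluation on entropy-derived features.

Feature vectors per subject are the entropy at scale 1 (the
single-scale measure) and at the "optimal" scale — the scale with the
largest direction-free AUC separation between the two groups.  Three
standard classifiers (SVM with RBF kernel, random forest, 3-nearest
neighbours) are evaluated under two resampling schemes: ten independent
repetitions of stratified 10-fold cross-validation (10x10 FCV, CA
averaged over repetitions) and leave-one-out cross-validation (LOOCV).
Classification accuracy is CA = (TP + TN) / (TP + TN + FP + FN) * 100.

Scale selection is performed on the full dataset before cross-validation
(as the feature definition implies); a nested mode that reselects the
scale inside each training fold is available to avoid the selection
leak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .groupstats import auc
from .symbolic import EntropyProfile

__all__ = [
    "FeatureTable",
    "ClassificationResult",
    "select_optimal_scale",
    "build_feature_table",
    "classification_accuracy",
    "evaluate",
    "evaluate_profiles",
    "CLASSIFIERS",
    "SCHEMES",
]

CLASSIFIERS = ("svm_rbf", "rf", "knn3")
SCHEMES = ("ten_by_ten_fcv", "loocv")
_N_FOLDS = 10
_N_REPETITIONS = 10


def _make_classifier(name: str, seed: int):
    if name == "svm_rbf":
        return SVC(kernel="rbf")
    if name == "rf":
        return RandomForestClassifier(random_state=seed)
    if name == "knn3":
        return KNeighborsClassifier(n_neighbors=3)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def select_optimal_scale(
    profiles_by_group: Mapping[str, Sequence[EntropyProfile]],
) -> int:
    """Scale with maximum AUC separation between two groups.

    Separation is direction-free, max(AUC, 1 - AUC), so a scale where
    the group ordering is inverted still counts as separating.  Ties go
    to the smallest scale; scales where either group has no defined
    value are skipped.
    """
    if len(profiles_by_group) != 2:
        raise ValueError("optimal-scale selection requires exactly two groups")
    (name_a, profs_a), (name_b, profs_b) = profiles_by_group.items()
    scales = sorted(
        set(int(s) for p in [*profs_a, *profs_b] for s in p.scales)
    )
    best_scale, best_sep = None, -np.inf
    for scale in scales:
        vals = []
        for profs in (profs_a, profs_b):
            group_vals = []
            for prof in profs:
                try:
                    v = prof.value_at(scale)
                except KeyError:
                    continue
                if np.isfinite(v):
                    group_vals.append(v)
            vals.append(group_vals)
        if not vals[0] or not vals[1]:
            continue  # scale undefined for a whole group
        a = auc(vals[0], vals[1])
        sep = max(a, 1.0 - a)
        if sep > best_sep:
            best_scale, best_sep = scale, sep
    if best_scale is None:
        raise ValueError("no scale has defined values in both groups")
    return best_scale


@dataclass
class FeatureTable:
    """Per-subject feature frame plus scale-selection metadata.

    ``frame`` columns: subject_id, label, then one column per feature
    (e.g. mncse_s1, mncse_s4, mse_s1, mse_s4).  Subjects with an
    undefined entropy at a selected scale are excluded and listed in
    ``excluded``.
    """

    frame: pd.DataFrame
    optimal_scales: dict[str, int]
    excluded: list[str]

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("subject_id", "label")]


def build_feature_table(
    profiles_by_group: Mapping[str, Sequence[EntropyProfile]],
) -> FeatureTable:
    """Entropy at scale 1 and at the optimal scale, per method, per subject.

    ``profiles_by_group`` maps a group label to that group's profiles;
    profiles of different methods (MNCSE, MSE) belonging to the same
    subject must share ``source_id``.  The optimal scale is chosen per
    method from the full dataset.
    """
    methods = sorted(
        {p.method for profs in profiles_by_group.values() for p in profs}
    )
    optimal = {
        method: select_optimal_scale(
            {
                name: [p for p in profs if p.method == method]
                for name, profs in profiles_by_group.items()
            }
        )
        for method in methods
    }
    rows: dict[str, dict[str, object]] = {}
    for name, profs in profiles_by_group.items():
        for prof in profs:
            if prof.source_id is None:
                raise ValueError("profiles need source_id to become features")
            row = rows.setdefault(
                prof.source_id, {"subject_id": prof.source_id, "label": name}
            )
            if row["label"] != name:
                raise ValueError(
                    f"subject {prof.source_id!r} appears in two groups"
                )
            prefix = prof.method.lower()
            for scale in {1, optimal[prof.method]}:
                try:
                    row[f"{prefix}_s{scale}"] = prof.value_at(scale)
                except KeyError:
                    row[f"{prefix}_s{scale}"] = np.nan
    frame = pd.DataFrame(list(rows.values()))
    feature_cols = [c for c in frame.columns if c not in ("subject_id", "label")]
    complete = frame[feature_cols].notna().all(axis=1)
    excluded = frame.loc[~complete, "subject_id"].tolist()
    return FeatureTable(
        frame=frame[complete].reset_index(drop=True),
        optimal_scales=optimal,
        excluded=excluded,
    )


def classification_accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """Percent of correct decisions, (TP + TN) / total * 100."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return 100.0 * (tp + tn) / total


@dataclass
class ClassificationResult:
    """Confusion counts and CA for one classifier under one scheme.

    For 10x10 FCV the counts are summed over the ten repetitions
    (each repetition tests every subject exactly once, so dividing by
    ``n_repetitions`` recovers per-repetition totals, and the Eq-style
    CA on the summed counts equals the mean of per-repetition CAs).
    """

    classifier: str
    scheme: str
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float  # percent
    n_repetitions: int
    seed: int
    pos_label: str


def _confusion(y_true, y_pred, pos_label) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == pos_label
    pos_p = y_pred == pos_label
    tp = int((pos_t & pos_p).sum())
    tn = int((~pos_t & ~pos_p).sum())
    fp = int((~pos_t & pos_p).sum())
    fn = int((pos_t & ~pos_p).sum())
    return tp, tn, fp, fn


def evaluate(
    features: FeatureTable | pd.DataFrame,
    classifier: str = "knn3",
    scheme: str = "loocv",
    seed: int = 0,
    pos_label: str | None = None,
) -> ClassificationResult:
    """Cross-validated classification accuracy on a feature table.

    ``scheme`` is ``"ten_by_ten_fcv"`` (ten independent seeded
    stratified 10-fold partitions; CA averaged over repetitions) or
    ``"loocv"``.  ``pos_label`` names the class counted as "positive"
    (TP); by default the lexicographically smaller label.  Identical
    seeds yield identical partitions and results.
    """
    frame = features.frame if isinstance(features, FeatureTable) else features
    if "label" not in frame.columns:
        raise ValueError("feature table needs a 'label' column")
    feature_cols = [c for c in frame.columns if c not in ("subject_id", "label")]
    if not feature_cols:
        raise ValueError("feature table has no feature columns")
    X = frame[feature_cols].to_numpy(dtype=float)
    y = frame["label"].to_numpy()
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 classes, got {labels.size}")
    if pos_label is None:
        pos_label = str(sorted(labels)[0])
    elif pos_label not in labels:
        raise ValueError(f"pos_label {pos_label!r} not among labels {labels}")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")

    base = _make_classifier(classifier, seed)

    if scheme == "ten_by_ten_fcv":
        class_counts = pd.Series(y).value_counts()
        if class_counts.min() < _N_FOLDS:
            raise ValueError(
                f"class {class_counts.idxmin()!r} has "
                f"{class_counts.min()} subjects < {_N_FOLDS} folds; "
                "use scheme='loocv' for samples this small"
            )
        totals = np.zeros(4, dtype=int)
        rep_cas = []
        for rep in range(_N_REPETITIONS):
            skf = StratifiedKFold(
                n_splits=_N_FOLDS, shuffle=True, random_state=seed + rep
            )
            y_pred = np.empty_like(y)
            for train, test in skf.split(X, y):
                model = clone(base)
                model.fit(X[train], y[train])
                y_pred[test] = model.predict(X[test])
            counts = _confusion(y, y_pred, pos_label)
            totals += counts
            rep_cas.append(classification_accuracy(*counts))
        return ClassificationResult(
            classifier=classifier,
            scheme=scheme,
            tp=int(totals[0]),
            tn=int(totals[1]),
            fp=int(totals[2]),
            fn=int(totals[3]),
            accuracy=float(np.mean(rep_cas)),
            n_repetitions=_N_REPETITIONS,
            seed=seed,
            pos_label=pos_label,
        )

    # LOOCV: deterministic given deterministic classifiers
    y_pred = np.empty_like(y)
    for train, test in LeaveOneOut().split(X):
        model = clone(base)
        model.fit(X[train], y[train])
        y_pred[test] = model.predict(X[test])
    tp, tn, fp, fn = _confusion(y, y_pred, pos_label)
    return ClassificationResult(
        classifier=classifier,
        scheme=scheme,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=classification_accuracy(tp, tn, fp, fn),
        n_repetitions=1,
        seed=seed,
        pos_label=pos_label,
    )


def evaluate_profiles(
    profiles_by_group: Mapping[str, Sequence[EntropyProfile]],
    classifier: str = "knn3",
    scheme: str = "loocv",
    seed: int = 0,
    pos_label: str | None = None,
    nested: bool = False,
) -> ClassificationResult:
    """Evaluate classifiers directly from entropy profiles.

    With ``nested=False`` (the evaluated protocol) the optimal scale is
    chosen once on the full dataset; this leaks selection information
    into the cross-validation, so ``nested=True`` reselects the scale
    inside each training split instead.  Nested mode restricts
    candidate scales to those defined for every subject so that test
    features always exist.
    """
    if not nested:
        return evaluate(
            build_feature_table(profiles_by_group),
            classifier=classifier,
            scheme=scheme,
            seed=seed,
            pos_label=pos_label,
        )

    # assemble per-subject value matrices per method over fully-defined scales
    methods = sorted(
        {p.method for profs in profiles_by_group.values() for p in profs}
    )
    subjects: list[str] = []
    labels: list[str] = []
    per_method: dict[str, list[EntropyProfile]] = {m: [] for m in methods}
    for name, profs in profiles_by_group.items():
        by_id: dict[str, dict[str, EntropyProfile]] = {}
        for p in profs:
            if p.source_id is None:
                raise ValueError("profiles need source_id to become features")
            by_id.setdefault(p.source_id, {})[p.method] = p
        for sid, meth_map in by_id.items():
            if set(meth_map) != set(methods):
                continue  # subject lacks one method entirely
            subjects.append(sid)
            labels.append(name)
            for m in methods:
                per_method[m].append(meth_map[m])
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("nested evaluation requires exactly 2 classes")
    mats: dict[str, np.ndarray] = {}
    scale_axis: dict[str, np.ndarray] = {}
    for m in methods:
        common = sorted(
            set.intersection(*(set(map(int, p.scales)) for p in per_method[m]))
        )
        mat = np.array(
            [[p.value_at(s) for s in common] for p in per_method[m]]
        )
        keep = np.isfinite(mat).all(axis=0)
        if 1 not in np.asarray(common)[keep]:
            raise ValueError(f"scale 1 undefined for some subject ({m})")
        mats[m] = mat[:, keep]
        scale_axis[m] = np.asarray(common)[keep]

    def fold_features(train_idx: np.ndarray) -> np.ndarray:
        cols = []
        for m in methods:
            mat, ax = mats[m], scale_axis[m]
            pos_mask = y[train_idx] == y[train_idx][0]
            best_scale, best_sep = ax[0], -np.inf
            for k, s in enumerate(ax):
                a = auc(
                    mat[train_idx][pos_mask, k], mat[train_idx][~pos_mask, k]
                )
                sep = max(a, 1.0 - a)
                if sep > best_sep:
                    best_scale, best_sep = s, sep
            for s in sorted({1, int(best_scale)}):
                cols.append(mat[:, np.flatnonzero(ax == s)[0]])
        return np.column_stack(cols)

    if pos_label is None:
        pos_label = str(sorted(np.unique(y))[0])
    base = _make_classifier(classifier, seed)

    def run_split(splitter) -> tuple[np.ndarray, np.ndarray]:
        y_pred = np.empty_like(y)
        for train, test in splitter:
            Xf = fold_features(train)
            model = clone(base)
            model.fit(Xf[train], y[train])
            y_pred[test] = model.predict(Xf[test])
        return y, y_pred

    if scheme == "loocv":
        dummy_X = np.zeros((y.size, 1))
        y_true, y_pred = run_split(LeaveOneOut().split(dummy_X))
        tp, tn, fp, fn = _confusion(y_true, y_pred, pos_label)
        return ClassificationResult(
            classifier=classifier, scheme=scheme, tp=tp, tn=tn, fp=fp, fn=fn,
            accuracy=classification_accuracy(tp, tn, fp, fn),
            n_repetitions=1, seed=seed, pos_label=pos_label,
        )
    if scheme != "ten_by_ten_fcv":
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    dummy_X = np.zeros((y.size, 1))
    totals = np.zeros(4, dtype=int)
    rep_cas = []
    for rep in range(_N_REPETITIONS):
        skf = StratifiedKFold(
            n_splits=_N_FOLDS, shuffle=True, random_state=seed + rep
        )
        y_true, y_pred = run_split(skf.split(dummy_X, y))
        counts = _confusion(y_true, y_pred, pos_label)
        totals += counts
        rep_cas.append(classification_accuracy(*counts))
    return ClassificationResult(
        classifier=classifier, scheme=scheme,
        tp=int(totals[0]), tn=int(totals[1]),
        fp=int(totals[2]), fn=int(totals[3]),
        accuracy=float(np.mean(rep_cas)),
        n_repetitions=_N_REPETITIONS, seed=seed, pos_label=pos_label,
    )
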