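"""Language-type decoding from ROI-component load features.

Each subject contributes one sample per reading condition; a sample's
features are the per-ROI sums of that subject's Fisher-z map inside a
group-level component mask, for each of the three linguistic components
(30 ROIs x 3 components = 90 features in the full design).  Labels are
ordinal-coded (Chinese word = 1, English word = 2, Chinese pinyin = 3)
and fit with support vector regression; predictions are snapped to the
nearest valid label.

Leakage is controlled by the fold-specific mask contract: each
leave-one-subject-out fold derives its group masks from the training
subjects only, and the held-out subject's features are extracted with
that same training-derived mask.

Feature importance uses absence-incurred rMSE (the error of the model
refit without the feature), followed by iterative elimination in
ascending importance and knee-point selection on the negative-rMSE curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .group import one_sample_t_map
from .rdm import COMPONENTS, CONDITIONS, CONDITION_LABELS
from .searchlight import RepresentationMap

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Samples x features design for the language-type decoder."""

    X: np.ndarray
    y: np.ndarray
    subjects: list[str]
    feature_names: list[str]
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.subjects), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")

    def subset(self, keep: np.ndarray) -> "FeatureMatrix":
        keep = np.asarray(keep)
        return FeatureMatrix(
            self.X[keep], self.y[keep],
            [self.subjects[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.subjects[i] for i in keep],
            self.feature_names,
            [self.conditions[i] for i in np.flatnonzero(keep)] if (keep.dtype == bool and self.conditions)
            else ([self.conditions[i] for i in keep] if self.conditions else []),
        )


@dataclass
class RfeResult:
    absence_rmse: dict[str, float]
    ranking: list[str]
    neg_rmse_curve: list[float]
    remaining_counts: list[int]
    knee: int
    selected_features: list[str]
    no_informative_knee: bool
    full_rmse: float
    initially_eliminated: list[str]


def component_group_masks(
    rep_maps: dict[tuple[str, str, str], RepresentationMap],
    train_subjects: list[str],
    alpha: float = 0.05,
    cluster_min: int = 10,
    connectivity: int = 18,
) -> dict[str, np.ndarray]:
    """Group-level activation mask per component from training subjects only.

    Per component, the one-sample t significance masks of the three
    conditions are combined by union (how conditions combine into the
    per-component mask is an assumption of this implementation).
    """
    masks = {}
    for comp in COMPONENTS:
        union = None
        for cond in CONDITIONS:
            zs = [rep_maps[(s, cond, comp)].z for s in train_subjects
                  if (s, cond, comp) in rep_maps]
            if not zs:
                continue
            gm = one_sample_t_map(zs, alpha=alpha, cluster_min=cluster_min,
                                  connectivity=connectivity)
            union = gm.sig_mask if union is None else (union | gm.sig_mask)
        masks[comp] = union if union is not None else None
    return masks


def build_features(
    rep_maps: dict[tuple[str, str, str], RepresentationMap],
    atlas: np.ndarray,
    fold_train_subjects: list[str],
    subjects: list[str] | None = None,
    alpha: float = 0.05,
    cluster_min: int = 10,
    connectivity: int = 18,
) -> FeatureMatrix:
    """ROI x component load features under a training-derived group mask.

    Features for every listed subject (including held-out ones) are sums
    of that subject's z map inside ROI ∩ component mask — the mask itself
    never sees non-training data.
    """
    atlas = np.asarray(atlas)
    rois = [int(r) for r in np.unique(atlas) if r != 0]
    if subjects is None:
        subjects = sorted({s for s, _, _ in rep_maps})
    masks = component_group_masks(rep_maps, fold_train_subjects, alpha,
                                  cluster_min, connectivity)
    names = [f"roi{r:02d}_{comp}" for r in rois for comp in COMPONENTS]
    rows, y, subj_col, cond_col = [], [], [], []
    for s in subjects:
        for cond in CONDITIONS:
            feats = []
            for r in rois:
                roi_vox = atlas == r
                for comp in COMPONENTS:
                    cmask = masks[comp]
                    if cmask is None or not (roi_vox & cmask).any():
                        feats.append(0.0)
                        continue
                    z = rep_maps[(s, cond, comp)].z
                    vals = z[roi_vox & cmask]
                    feats.append(float(np.nansum(vals)))
            rows.append(feats)
            y.append(CONDITION_LABELS[cond])
            subj_col.append(s)
            cond_col.append(cond)
    return FeatureMatrix(np.array(rows), np.array(y, dtype=float),
                         subj_col, names, cond_col)


def _fit_predict(X_tr, y_tr, X_te) -> np.ndarray:
    scaler = StandardScaler().fit(X_tr)
    model = SVR(kernel="linear", C=1.0, epsilon=0.1)
    model.fit(scaler.transform(X_tr), y_tr)
    return model.predict(scaler.transform(X_te))


def _snap(pred: np.ndarray, valid_labels: np.ndarray) -> np.ndarray:
    # nearest valid label; ties break toward the lower label
    d = np.abs(pred[:, None] - valid_labels[None, :])
    return valid_labels[np.argmin(d, axis=1)]


def loso_svr(
    features: FeatureMatrix,
    pair: tuple[str, str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Leave-one-subject-out SVR decoding accuracy.

    With ``pair`` given, training and testing are restricted to the two
    conditions' samples (binary framing with a midpoint threshold,
    equivalent to nearest-label snapping on two labels).
    """
    if pair is not None:
        labels = np.array(sorted(CONDITION_LABELS[c] for c in pair), dtype=float)
        keep = np.isin(features.y, labels)
        features = features.subset(keep)
    else:
        labels = np.array(sorted(set(features.y)), dtype=float)
    subjects = sorted(set(features.subjects))
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects for leave-one-subject-out")
    subj_arr = np.array(features.subjects)
    rows = []
    for held in subjects:
        test = subj_arr == held
        train = ~test
        y_tr = features.y[train]
        if len(set(y_tr)) < 2:
            raise ValueError("single-class training fold")
        pred = _fit_predict(features.X[train], y_tr, features.X[test])
        snapped = _snap(pred, labels)
        for i, idx in enumerate(np.flatnonzero(test)):
            rows.append(
                {
                    "subject": held,
                    "true_label": features.y[idx],
                    "raw_prediction": float(pred[i]),
                    "predicted_label": float(snapped[i]),
                    "correct": bool(snapped[i] == features.y[idx]),
                }
            )
    preds = pd.DataFrame(rows)
    return float(preds["correct"].mean()), preds


def loso_classify_with_fold_masks(
    rep_maps: dict[tuple[str, str, str], RepresentationMap],
    atlas: np.ndarray,
    pair: tuple[str, str] | None = None,
    alpha: float = 0.05,
    cluster_min: int = 10,
    connectivity: int = 18,
) -> tuple[float, pd.DataFrame]:
    """Full leakage-safe LOSO run: fold-specific masks, then SVR.

    For each fold the group component masks are rebuilt from the training
    subjects, features for both sides are extracted under that mask, and
    the held-out subject's samples are scored.
    """
    subjects = sorted({s for s, _, _ in rep_maps})
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects for leave-one-subject-out")
    if pair is not None:
        conds = sorted(pair, key=lambda c: CONDITION_LABELS[c])
        labels = np.array([CONDITION_LABELS[c] for c in conds], dtype=float)
    else:
        conds = list(CONDITIONS)
        labels = np.array(sorted(CONDITION_LABELS.values()), dtype=float)
    rows = []
    for held in subjects:
        train_subjects = [s for s in subjects if s != held]
        fm = build_features(rep_maps, atlas, train_subjects,
                            subjects=train_subjects + [held],
                            alpha=alpha, cluster_min=cluster_min,
                            connectivity=connectivity)
        keep_cond = np.isin(fm.conditions, conds)
        fm = fm.subset(keep_cond)
        subj_arr = np.array(fm.subjects)
        train = subj_arr != held
        pred = _fit_predict(fm.X[train], fm.y[train], fm.X[~train])
        snapped = _snap(pred, labels)
        truth = fm.y[~train]
        for i in range(len(pred)):
            rows.append(
                {
                    "subject": held,
                    "true_label": truth[i],
                    "raw_prediction": float(pred[i]),
                    "predicted_label": float(snapped[i]),
                    "correct": bool(snapped[i] == truth[i]),
                }
            )
    preds = pd.DataFrame(rows)
    return float(preds["correct"].mean()), preds


def _loo_rmse(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-sample-out root-mean-squared error of the SVR."""
    n = X.shape[0]
    err = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        pred = _fit_predict(X[tr], y[tr], X[~tr])
        err[i] = pred[0] - y[i]
    return float(np.sqrt(np.mean(err**2)))


def find_knee(x: np.ndarray, y: np.ndarray, flat_tol: float = 1e-3) -> tuple[int | None, float]:
    """Knee of a curve: point of maximum perpendicular distance from the
    chord joining the endpoints.  Returns (index, distance); index is None
    when the curve is flat/linear within ``flat_tol`` of the y range."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        return None, 0.0
    y_range = np.ptp(y)
    if y_range < flat_tol:
        return None, 0.0
    xs = (x - x.min()) / max(np.ptp(x), 1e-12)
    ys = (y - y.min()) / y_range
    p0 = np.array([xs[0], ys[0]])
    p1 = np.array([xs[-1], ys[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.column_stack([xs, ys]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    idx = int(np.argmax(dist))
    if dist[idx] < flat_tol:
        return None, float(dist[idx])
    return idx, float(dist[idx])


def rfe_rank_and_select(features: FeatureMatrix, flat_tol: float = 1e-3) -> RfeResult:
    """Absence-rMSE recursive feature elimination with knee selection.

    Importance of a feature is the leave-one-sample-out rMSE of the model
    refit *without* it (higher = more important).  Features whose absence
    lowers the error below the full model's are flagged for initial
    elimination; all features are then removed one by one in ascending
    importance, the negative rMSE recorded at each remaining-feature
    count, and the knee of that curve selects how many (and which)
    features to keep.  Ties in importance break by feature name.
    """
    X, y = features.X, features.y
    names = features.feature_names
    nfeat = len(names)
    full_rmse = _loo_rmse(X, y)
    if not np.isfinite(full_rmse):
        raise ValueError("non-finite rMSE for the full model")
    absence = {}
    for j, name in enumerate(names):
        cols = np.arange(nfeat) != j
        r = _loo_rmse(X[:, cols], y)
        if not np.isfinite(r):
            raise ValueError(f"non-finite absence rMSE for feature {name!r}")
        absence[name] = r
    # descending importance; ties broken by name for determinism
    ranking = sorted(names, key=lambda nm: (-absence[nm], nm))
    initially_eliminated = [nm for nm in ranking if absence[nm] < full_rmse]
    # eliminate in ascending importance, scoring each remaining-feature count
    order = ranking[::-1]
    curve = [-full_rmse]
    counts = [nfeat]
    active = list(names)
    for nm in order[:-1]:
        active.remove(nm)
        cols = [names.index(a) for a in active]
        curve.append(-_loo_rmse(X[:, cols], y))
        counts.append(len(active))
    idx, _ = find_knee(np.array(counts, dtype=float), np.array(curve), flat_tol)
    if idx is None:
        log.warning("rfe: negative-rMSE curve has no informative knee; keeping all features")
        knee = nfeat
        no_knee = True
    else:
        knee = counts[idx]
        no_knee = False
    selected = ranking[:knee]
    return RfeResult(
        absence_rmse=absence,
        ranking=ranking,
        neg_rmse_curve=curve,
        remaining_counts=counts,
        knee=knee,
        selected_features=selected,
        no_informative_knee=no_knee,
        full_rmse=full_rmse,
        initially_eliminated=initially_eliminated,
    )
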