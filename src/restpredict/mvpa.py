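"""Leave-one-out MVPA: group classification and symptom-severity prediction.

Two model classes follow the familiar fit-then-results pattern:

* :class:`GroupClassifier` — survivor-vs-control linear SVM on hybrid
  ALFF + FC features, evaluated by leave-one-out cross-validation (LOOCV).
* :class:`SymptomPredictor` — linear support-vector regression of SAS/SDS
  scores, with per-fold transfer to the held-out subject's Time-2 session
  and prediction of the score *change* via the model's linear part.

In every fold the held-out subject is excluded from univariate ranking,
bootstrapped sparse selection, and training; selected ALFF features come
first in the concatenated feature vector, selected FC features second.
Features are z-scored with training-fold statistics before the SVM/SVR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.svm import SVC, SVR

from .sparsesel import rank_by_correlation, rank_by_ttest, sparse_select

SURVIVOR, CONTROL = 1, -1


def child_seed(master: int, *keys: int) -> int:
    """Deterministic sub-seed (< 2**31) derived from a master seed and keys."""
    ss = np.random.SeedSequence([int(master), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))


def train_linear_classifier(X: np.ndarray, y: np.ndarray, C: float = 1.0):
    """Maximum-margin linear classifier (hinge loss, L2 penalty).

    Returns ``(w, b)`` with decision rule ``sign(w @ x + b)``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = SVC(kernel="linear", C=C)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def train_linear_svr(X: np.ndarray, y: np.ndarray, C: float = 1.0, epsilon: float = 0.1):
    """Linear epsilon-insensitive support-vector regression; returns (w, b)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    reg = SVR(kernel="linear", C=C, epsilon=epsilon)
    reg.fit(X, np.asarray(y, dtype=float))
    return reg.coef_.ravel().copy(), float(reg.intercept_[0])


@dataclass
class FoldResult:
    """Per-fold bookkeeping of one LOOCV iteration."""

    held_out_id: str
    selected_alff: np.ndarray
    selected_fc: np.ndarray
    model_weights: np.ndarray  # [ALFF weights, FC weights] in selection order
    prediction: float
    actual: float
    prediction_t2: float | None = None
    actual_t2: float | None = None
    prediction_change: float | None = None
    actual_change: float | None = None


@dataclass(frozen=True)
class _Scaler:
    mean: np.ndarray
    sd: np.ndarray

    @staticmethod
    def fit(X: np.ndarray) -> "_Scaler":
        sd = X.std(axis=0)
        return _Scaler(X.mean(axis=0), np.where(sd > 0, sd, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _select_fold_features(alff_tr, fc_tr, y_tr, *, task, modality, init_alff,
                          n_alff, n_fc, l_frac, l0, seed):
    """Training-data-only feature selection for one fold.

    ALFF features are pre-reduced univariately (two-sample t for
    classification, Pearson r for prediction) before the bootstrapped L1
    selector; FC features go to the selector directly.
    """
    sel_alff = np.empty(0, dtype=int)
    sel_fc = np.empty(0, dtype=int)
    if modality in ("hybrid", "alff") and n_alff > 0:
        rank = rank_by_ttest if task == "classify" else rank_by_correlation
        init = rank(alff_tr, y_tr, min(init_alff, alff_tr.shape[1]))
        k = min(n_alff, init.size)
        sub = sparse_select(alff_tr[:, init], y_tr, L_frac=l_frac, l0=l0, k=k,
                            seed=child_seed(seed, 0))
        sel_alff = init[sub.selected]
    if modality in ("hybrid", "fc") and n_fc > 0:
        sub = sparse_select(fc_tr, y_tr, L_frac=l_frac, l0=l0,
                            k=min(n_fc, fc_tr.shape[1]), seed=child_seed(seed, 1))
        sel_fc = sub.selected
    return sel_alff, sel_fc


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResults:
    """LOOCV classification outcome."""

    accuracy: float
    sensitivity: float
    specificity: float
    n: int
    predictions: pd.DataFrame
    fold_results: list[FoldResult] = field(repr=False, default_factory=list)
    modality: str = "hybrid"

    def summary(self) -> str:
        lines = [
            "LOOCV group classification (linear SVM)",
            "=" * 43,
            f"modality            : {self.modality}",
            f"subjects            : {self.n}",
            f"accuracy            : {100 * self.accuracy:6.2f} %",
            f"sensitivity (surv.) : {100 * self.sensitivity:6.2f} %",
            f"specificity (ctrl.) : {100 * self.specificity:6.2f} %",
        ]
        return "\n".join(lines)


class GroupClassifier:
    """Survivor-vs-control LOOCV classifier on ALFF + FC features.

    Parameters
    ----------
    alff_features : ndarray (N, V)
        Normalised per-voxel ALFF values, one row per subject.
    fc_features : ndarray (N, E)
        Upper-triangle FC vectors.
    labels : ndarray (N,)
        +1 for survivors, -1 for controls.
    modality : {"hybrid", "alff", "fc"}
        Which feature block(s) enter the classifier.
    init_alff, n_alff, n_fc : int
        Univariate pre-reduction size and per-modality sparse-selection
        counts (hybrid feature vector has ``n_alff + n_fc`` entries).
    l_frac, l0 : bootstrapped-L1 parameters (rows per repeat, repeats).
    C : SVM regularisation constant.
    """

    def __init__(self, alff_features, fc_features, labels, subject_ids=None, *,
                 modality="hybrid", init_alff=4000, n_alff=500, n_fc=500,
                 l_frac=0.3, l0=200, C=1.0, seed=0):
        self.alff = np.asarray(alff_features, dtype=float)
        self.fc = np.asarray(fc_features, dtype=float)
        self.y = np.asarray(labels)
        n = self.y.size
        if self.alff.shape[0] != n or self.fc.shape[0] != n:
            raise ValueError("feature matrices and labels disagree on subject count")
        if modality not in ("hybrid", "alff", "fc"):
            raise ValueError(f"unknown modality {modality!r}")
        self.subject_ids = (np.asarray(subject_ids) if subject_ids is not None
                            else np.array([f"sub-{i:03d}" for i in range(n)]))
        self.modality = modality
        self.params = dict(init_alff=init_alff, n_alff=n_alff, n_fc=n_fc,
                           l_frac=l_frac, l0=l0, C=C)
        self.seed = seed

    def fit(self, labels=None, seed=None) -> ClassificationResults:
        """Run the full LOOCV; ``labels`` may override (e.g. permutations)."""
        y = self.y if labels is None else np.asarray(labels)
        seed = self.seed if seed is None else seed
        p = self.params
        n = y.size
        if min((y > 0).sum(), (y < 0).sum()) < 2:
            raise ValueError("need at least 2 subjects per class")
        folds: list[FoldResult] = []
        for i in range(n):
            tr = np.arange(n) != i
            n_alff = p["n_alff"] if self.modality in ("hybrid", "alff") else 0
            n_fc = p["n_fc"] if self.modality in ("hybrid", "fc") else 0
            sel_a, sel_f = _select_fold_features(
                self.alff[tr], self.fc[tr], y[tr], task="classify",
                modality=self.modality, init_alff=p["init_alff"],
                n_alff=n_alff, n_fc=n_fc, l_frac=p["l_frac"], l0=p["l0"],
                seed=child_seed(seed, i))
            X_tr = np.column_stack([self.alff[tr][:, sel_a], self.fc[tr][:, sel_f]])
            x_te = np.concatenate([self.alff[i, sel_a], self.fc[i, sel_f]])
            scaler = _Scaler.fit(X_tr)
            w, b = train_linear_classifier(scaler.transform(X_tr), y[tr], C=p["C"])
            pred = SURVIVOR if w @ scaler.transform(x_te) + b >= 0 else CONTROL
            folds.append(FoldResult(str(self.subject_ids[i]), sel_a, sel_f, w,
                                    float(pred), float(y[i])))
        pred = np.array([f.prediction for f in folds])
        actual = np.array([f.actual for f in folds])
        surv, ctrl = actual == SURVIVOR, actual == CONTROL
        table = pd.DataFrame({"subject": self.subject_ids, "actual": actual,
                              "predicted": pred})
        return ClassificationResults(
            accuracy=float((pred == actual).mean()),
            sensitivity=float((pred[surv] == SURVIVOR).mean()) if surv.any() else np.nan,
            specificity=float((pred[ctrl] == CONTROL).mean()) if ctrl.any() else np.nan,
            n=n, predictions=table, fold_results=folds, modality=self.modality)

    def dimension_sweep(self, dims) -> pd.DataFrame:
        """Accuracy as a function of the per-modality feature count."""
        rows = []
        for d in dims:
            saved = dict(self.params)
            self.params["n_alff"] = self.params["n_fc"] = int(d)
            try:
                res = self.fit()
                rows.append({"n_features": int(d), "accuracy": res.accuracy})
            finally:
                self.params = saved
        return pd.DataFrame(rows)


def loocv_classify(alff_features, fc_features, labels, subject_ids=None, **params):
    """Functional driver: returns ``(ClassificationResults, fold results)``."""
    res = GroupClassifier(alff_features, fc_features, labels, subject_ids, **params).fit()
    return res, res.fold_results


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _safe_r(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return np.nan
    return float(scipy.stats.pearsonr(a, b)[0])


@dataclass
class PredictionResults:
    """LOOCV symptom-prediction outcome (Time 1, Time 2, change)."""

    score_name: str
    r_t1: float
    mse_t1: float
    r_t2: float
    mse_t2: float
    r_change: float
    mse_change: float
    predictions: pd.DataFrame
    fold_results: list[FoldResult] = field(repr=False, default_factory=list)

    def summary(self) -> str:
        lines = [
            f"LOOCV symptom prediction (linear SVR) — {self.score_name.upper()}",
            "=" * 52,
            f"{'':14s}{'r':>8s}{'MSE':>12s}{'n':>6s}",
            f"{'Time 1':14s}{self.r_t1:8.3f}{self.mse_t1:12.2f}"
            f"{self.predictions['pred_t1'].notna().sum():6d}",
            f"{'Time 2':14s}{self.r_t2:8.3f}{self.mse_t2:12.2f}"
            f"{self.predictions['pred_t2'].notna().sum():6d}",
            f"{'Change (1-2)':14s}{self.r_change:8.3f}{self.mse_change:12.2f}"
            f"{self.predictions['pred_change'].notna().sum():6d}",
        ]
        return "\n".join(lines)

    def plot_predictions(self, ax=None):
        """Predicted-vs-actual scatter at Time 1 (and Time 2 if present)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.predictions
        ax.scatter(t["actual_t1"], t["pred_t1"], label="Time 1", s=20)
        if t["pred_t2"].notna().any():
            ax.scatter(t["actual_t2"], t["pred_t2"], label="Time 2", s=20, marker="s")
        lims = [np.nanmin(t[["actual_t1", "pred_t1"]].values),
                np.nanmax(t[["actual_t1", "pred_t1"]].values)]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel(f"actual {self.score_name.upper()}")
        ax.set_ylabel(f"predicted {self.score_name.upper()}")
        ax.legend()
        return ax


class SymptomPredictor:
    """LOOCV symptom-severity predictor on survivors' ALFF + FC features.

    Parameters
    ----------
    alff_t1, fc_t1 : ndarray (N, V) / (N, E)
        Time-1 feature matrices, one row per survivor.
    scores_t1 : ndarray (N,)
        SAS or SDS scores at Time 1.
    t2_index : ndarray of int, optional
        Row indices of the survivors who also have a Time-2 session.
    alff_t2, fc_t2, scores_t2 : matching Time-2 data, aligned with
        ``t2_index``.
    """

    def __init__(self, alff_t1, fc_t1, scores_t1, subject_ids=None, *,
                 t2_index=None, alff_t2=None, fc_t2=None, scores_t2=None,
                 score_name="sas", modality="hybrid", init_alff=4000,
                 n_alff=500, n_fc=500, l_frac=0.3, l0=200, C=1.0,
                 epsilon=0.1, seed=0):
        self.alff = np.asarray(alff_t1, dtype=float)
        self.fc = np.asarray(fc_t1, dtype=float)
        self.y = np.asarray(scores_t1, dtype=float)
        if np.isnan(self.y).any():
            raise ValueError("missing Time-1 scores")
        n = self.y.size
        self.subject_ids = (np.asarray(subject_ids) if subject_ids is not None
                            else np.array([f"surv-{i:03d}" for i in range(n)]))
        self.t2_index = (np.asarray(t2_index, dtype=int) if t2_index is not None
                         else np.empty(0, dtype=int))
        self.alff_t2 = np.asarray(alff_t2, dtype=float) if alff_t2 is not None else None
        self.fc_t2 = np.asarray(fc_t2, dtype=float) if fc_t2 is not None else None
        self.scores_t2 = np.asarray(scores_t2, dtype=float) if scores_t2 is not None else None
        self.score_name = score_name
        self.modality = modality
        self.params = dict(init_alff=init_alff, n_alff=n_alff, n_fc=n_fc,
                           l_frac=l_frac, l0=l0, C=C, epsilon=epsilon)
        self.seed = seed

    def fit(self, scores=None, seed=None) -> PredictionResults:
        """Run the LOOCV; ``scores`` may override Time-1 targets (permutations)."""
        y = self.y if scores is None else np.asarray(scores, dtype=float)
        seed = self.seed if seed is None else seed
        p = self.params
        n = y.size
        t2_lookup = {int(idx): j for j, idx in enumerate(self.t2_index)}
        folds: list[FoldResult] = []
        for i in range(n):
            tr = np.arange(n) != i
            n_alff = p["n_alff"] if self.modality in ("hybrid", "alff") else 0
            n_fc = p["n_fc"] if self.modality in ("hybrid", "fc") else 0
            sel_a, sel_f = _select_fold_features(
                self.alff[tr], self.fc[tr], y[tr], task="predict",
                modality=self.modality, init_alff=p["init_alff"],
                n_alff=n_alff, n_fc=n_fc, l_frac=p["l_frac"], l0=p["l0"],
                seed=child_seed(seed, i))
            X_tr = np.column_stack([self.alff[tr][:, sel_a], self.fc[tr][:, sel_f]])
            scaler = _Scaler.fit(X_tr)
            w, b = train_linear_svr(scaler.transform(X_tr), y[tr],
                                    C=p["C"], epsilon=p["epsilon"])
            x1 = np.concatenate([self.alff[i, sel_a], self.fc[i, sel_f]])
            pred1 = float(w @ scaler.transform(x1) + b)
            fold = FoldResult(str(self.subject_ids[i]), sel_a, sel_f, w,
                              pred1, float(y[i]))
            if i in t2_lookup:
                j = t2_lookup[i]
                x2 = np.concatenate([self.alff_t2[j, sel_a], self.fc_t2[j, sel_f]])
                fold.prediction_t2 = float(w @ scaler.transform(x2) + b)
                fold.actual_t2 = float(self.scores_t2[j])
                # linear model applied to the feature-difference vector;
                # equals pred(T1) - pred(T2) because the affine parts cancel
                fold.prediction_change = float((w / scaler.sd) @ (x1 - x2))
                fold.actual_change = float(y[i]) - fold.actual_t2
            folds.append(fold)
        return self._summarise(folds)

    def _summarise(self, folds: list[FoldResult]) -> PredictionResults:
        table = pd.DataFrame({
            "subject": [f.held_out_id for f in folds],
            "actual_t1": [f.actual for f in folds],
            "pred_t1": [f.prediction for f in folds],
            "actual_t2": [f.actual_t2 for f in folds],
            "pred_t2": [f.prediction_t2 for f in folds],
            "actual_change": [f.actual_change for f in folds],
            "pred_change": [f.prediction_change for f in folds],
        })
        have2 = table["pred_t2"].notna()

        def mse(a, b):
            return float(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2))

        r2 = m2 = rc = mc = np.nan
        if have2.any():
            sub = table[have2]
            r2 = _safe_r(sub["pred_t2"], sub["actual_t2"])
            m2 = mse(sub["pred_t2"], sub["actual_t2"])
            rc = _safe_r(sub["pred_change"], sub["actual_change"])
            mc = mse(sub["pred_change"], sub["actual_change"])
        return PredictionResults(
            score_name=self.score_name,
            r_t1=_safe_r(table["pred_t1"], table["actual_t1"]),
            mse_t1=mse(table["pred_t1"], table["actual_t1"]),
            r_t2=r2, mse_t2=m2, r_change=rc, mse_change=mc,
            predictions=table, fold_results=folds)


def loocv_predict(alff_t1, fc_t1, scores_t1, subject_ids=None, **kwargs):
    """Functional driver: returns ``(PredictionResults, fold results)``."""
    res = SymptomPredictor(alff_t1, fc_t1, scores_t1, subject_ids, **kwargs).fit()
    return res, res.fold_results
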