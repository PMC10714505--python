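"""Cross-validated presence/absence classification over frequentmer features.

The workflow per fold: derive a frequentmer catalog from the training
split only (leakage-free), build binary presence feature matrices for
train and test samples, fit a model, and score the held-out samples.
Feature columns follow a fixed, reproducible order — the control
frequentmer block then the patient block, each ascending by encoded
value — so coefficients are comparable across runs.

Models mirror the reference configuration: an L2-penalised logistic
regression with inverse regularisation strength C=0.01 and an iteration
cap of 2000, and a gradient-boosted tree ensemble (XGBoost) with
max_depth=11, gamma=0.3, eta=0.2, alpha=6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .core import FrequentmerCatalog
from .io_manifest import Cohort, SampleManifest
from .kmer import KmerSet


@dataclass
class FoldAssignment:
    n_folds: int
    seed: int
    assignment: dict[str, int]  # sample_id -> test-fold index

    def test_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f != fold]


def make_folds(
    manifests: list[SampleManifest], n_folds: int = 10, seed: int = 0
) -> FoldAssignment:
    """Stratified fold assignment: each sample lands in exactly one test
    fold and the patient fraction per fold stays within one sample of
    the global fraction.  Deterministic given the seed."""
    ids = [m.sample_id for m in manifests]
    y = np.array([m.cohort == Cohort.patient for m in manifests], dtype=int)
    for label, name in ((1, "patient"), (0, "control")):
        if (y == label).sum() < n_folds:
            raise ValueError(
                f"{name} cohort has {(y == label).sum()} samples, fewer than "
                f"{n_folds} folds"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_tr, te) in enumerate(skf.split(np.zeros(len(ids)), y)):
        for i in te:
            assignment[ids[i]] = fold
    return FoldAssignment(n_folds, seed, assignment)


@dataclass
class FeatureMatrix:
    fold_id: int
    feature_kmers: np.ndarray     # control block then patient block, each ascending
    n_control_features: int       # size of the leading control block
    X: np.ndarray                 # samples x features, uint8 in {0,1}
    y: np.ndarray                 # 1 = patient
    sample_ids: list[str]

    @property
    def feature_side(self) -> np.ndarray:
        """'control' / 'patient' per feature column."""
        side = np.full(len(self.feature_kmers), "patient", dtype=object)
        side[: self.n_control_features] = "control"
        return side

    def subset(self, column_idx: np.ndarray) -> "FeatureMatrix":
        column_idx = np.asarray(column_idx)
        return FeatureMatrix(
            self.fold_id,
            self.feature_kmers[column_idx],
            int((column_idx < self.n_control_features).sum()),
            self.X[:, column_idx],
            self.y,
            self.sample_ids,
        )


def build_features(
    catalog: FrequentmerCatalog,
    ksets: dict[str, KmerSet],
    manifests: list[SampleManifest],
    sample_ids: list[str],
) -> FeatureMatrix:
    """Binary presence matrix: X[i, j] = 1 iff feature k-mer j is in
    sample i's retained k-mer set."""
    if catalog.n_total == 0:
        raise ValueError(
            "empty frequentmer catalog: no features; lower the recurrency threshold r"
        )
    cohort_of = {m.sample_id: m.cohort for m in manifests}
    feats = catalog.feature_order()
    X = np.zeros((len(sample_ids), len(feats)), dtype=np.uint8)
    for i, sid in enumerate(sample_ids):
        km = ksets[sid].kmers
        if len(km):
            pos = np.searchsorted(km, feats)
            pos = np.clip(pos, 0, len(km) - 1)
            X[i] = (km[pos] == feats).astype(np.uint8)
    y = np.array([cohort_of[s] == Cohort.patient for s in sample_ids], dtype=int)
    return FeatureMatrix(
        catalog.fold_id, feats, len(catalog.control_fms), X, y, list(sample_ids)
    )


@dataclass
class PCAReport:
    explained_variance_ratio: np.ndarray  # up to 90 components
    coords3: np.ndarray                   # first 3 PC coordinates per sample
    n_components: int


def run_pca(X: np.ndarray, n_components: int = 90) -> PCAReport:
    """Column-mean-centred PCA (no unit-variance scaling) of the binary
    feature matrix; reports explained-variance ratios for up to
    ``n_components`` components and the first three coordinates."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    n_comp = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    coords3 = coords[:, : min(3, n_comp)]
    return PCAReport(pca.explained_variance_ratio_, coords3, n_comp)


@dataclass
class ModelResult:
    fold_id: int
    model_kind: str               # "logistic" | "boosted"
    test_sample_ids: list[str]
    scores: np.ndarray            # predicted patient probability on the test split
    y_true: np.ndarray
    auc: float
    confusion: dict[str, int]     # tn/fp/fn/tp at the 0.5 threshold
    coefficients: np.ndarray | None = None  # logistic only, one per feature


def _confusion(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5):
    pred = (scores >= threshold).astype(int)
    return {
        "tn": int(((pred == 0) & (y_true == 0)).sum()),
        "fp": int(((pred == 1) & (y_true == 0)).sum()),
        "fn": int(((pred == 0) & (y_true == 1)).sum()),
        "tp": int(((pred == 1) & (y_true == 1)).sum()),
    }


def _auc_or_nan(y_true, scores) -> float:
    if len(np.unique(y_true)) < 2:
        return float("nan")
    return float(roc_auc_score(y_true, scores))


def fit_logistic(train: FeatureMatrix, test: FeatureMatrix) -> ModelResult:
    """L2 logistic regression (C=0.01, max_iter=2000), deterministic."""
    if len(np.unique(train.y)) < 2:
        raise ValueError("training labels contain a single class")
    # ridge (L2) penalty is sklearn's default; stating it explicitly is
    # deprecated from 1.8 on
    clf = LogisticRegression(C=0.01, max_iter=2000, solver="lbfgs")
    clf.fit(train.X, train.y)
    scores = clf.predict_proba(test.X)[:, 1]
    return ModelResult(
        fold_id=train.fold_id,
        model_kind="logistic",
        test_sample_ids=test.sample_ids,
        scores=scores,
        y_true=test.y,
        auc=_auc_or_nan(test.y, scores),
        confusion=_confusion(test.y, scores),
        coefficients=clf.coef_.ravel().copy(),
    )


def fit_boosted(train: FeatureMatrix, test: FeatureMatrix, seed: int = 0) -> ModelResult:
    """Gradient-boosted trees with the reference hyperparameters."""
    from xgboost import XGBClassifier

    if len(np.unique(train.y)) < 2:
        raise ValueError("training labels contain a single class")
    clf = XGBClassifier(
        max_depth=11,
        gamma=0.3,
        learning_rate=0.2,
        reg_alpha=6,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
    )
    clf.fit(train.X, train.y)
    scores = clf.predict_proba(test.X)[:, 1].astype(float)
    return ModelResult(
        fold_id=train.fold_id,
        model_kind="boosted",
        test_sample_ids=test.sample_ids,
        scores=scores,
        y_true=test.y,
        auc=_auc_or_nan(test.y, scores),
        confusion=_confusion(test.y, scores),
    )


@dataclass
class RankedFeatures:
    fold_id: int
    order: np.ndarray             # column indices, |coef| descending
    kmers: np.ndarray             # feature k-mers in ranked order
    coefficients: np.ndarray      # signed coefficients in ranked order
    side: np.ndarray              # 'control'/'patient' in ranked order

    def side_counts_at(self, n: int) -> dict[str, int]:
        top = self.side[:n]
        return {
            "patient": int((top == "patient").sum()),
            "control": int((top == "control").sum()),
        }

    def coefficient_histogram(self, bins: int = 30) -> pd.DataFrame:
        """Signed-coefficient histograms split by frequentmer side."""
        lo, hi = self.coefficients.min(), self.coefficients.max()
        edges = np.linspace(lo, hi, bins + 1) if hi > lo else np.array([lo - 0.5, lo + 0.5])
        rows = []
        for side in ("control", "patient"):
            counts, _ = np.histogram(self.coefficients[self.side == side], bins=edges)
            for b, c in enumerate(counts):
                rows.append(
                    {"side": side, "bin_low": edges[b], "bin_high": edges[b + 1], "count": int(c)}
                )
        return pd.DataFrame(rows)


def coefficient_report(result: ModelResult, fm: FeatureMatrix) -> RankedFeatures:
    """Rank features by absolute logistic coefficient, descending; ties
    broken by encoded k-mer ascending."""
    if result.coefficients is None:
        raise ValueError("coefficient report requires a logistic ModelResult")
    coefs = result.coefficients
    order = np.lexsort((fm.feature_kmers, -np.abs(coefs)))
    return RankedFeatures(
        fold_id=result.fold_id,
        order=order,
        kmers=fm.feature_kmers[order],
        coefficients=coefs[order],
        side=fm.feature_side[order],
    )


DEFAULT_TOPN_GRID = (25, 50, 100, 200, 300, 400, 500, 750, 1000)


def topn_retrain(
    train: FeatureMatrix,
    test: FeatureMatrix,
    ranked: RankedFeatures,
    grid=DEFAULT_TOPN_GRID,
) -> pd.DataFrame:
    """Refit the logistic model on the top-N features of the SAME split
    for each N in the grid; N values exceeding the feature count are
    skipped with a warning.  Ranking comes from the training fit only."""
    rows = []
    n_features = train.X.shape[1]
    for n in grid:
        if n > n_features:
            warnings.warn(f"top-N value {n} exceeds feature count {n_features}; skipped",
                          stacklevel=2)
            continue
        cols = np.sort(ranked.order[:n])
        res = fit_logistic(train.subset(cols), test.subset(cols))
        rows.append({"n": n, "fold_id": train.fold_id, "auc": res.auc})
    return pd.DataFrame(rows)


@dataclass
class SummaryReport:
    pooled_auc: float
    fold_aucs: list[float]
    mean_auc: float
    auc_ci95: tuple[float, float]     # mean +/- 1.96 sd/sqrt(n_folds)
    confusion_pct: dict[str, float]   # pooled percentages at 0.5
    mean_roc: pd.DataFrame            # fpr grid, mean tpr, per-fold band
    n_folds_used: int
    excluded_folds: list[int] = field(default_factory=list)


def evaluate(results: list[ModelResult]) -> SummaryReport:
    """Pooled and per-fold ROC/AUC with a mean ROC curve interpolated on
    a common FPR grid; single-class test folds are excluded from the
    per-fold AUC with a warning but still pooled."""
    if not results:
        raise ValueError("no fold results to evaluate")
    fold_aucs, excluded = [], []
    grid = np.linspace(0, 1, 101)
    tprs = []
    all_scores = np.concatenate([r.scores for r in results])
    all_y = np.concatenate([r.y_true for r in results])
    for r in results:
        if len(np.unique(r.y_true)) < 2:
            warnings.warn(
                f"fold {r.fold_id}: single-class test split, excluded from AUC",
                stacklevel=2,
            )
            excluded.append(r.fold_id)
            continue
        fold_aucs.append(float(roc_auc_score(r.y_true, r.scores)))
        fpr, tpr, _ = roc_curve(r.y_true, r.scores)
        tprs.append(np.interp(grid, fpr, tpr))
    pooled = _auc_or_nan(all_y, all_scores)
    mean_auc = float(np.mean(fold_aucs)) if fold_aucs else float("nan")
    sd = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
    half = 1.96 * sd / np.sqrt(len(fold_aucs)) if fold_aucs else float("nan")
    conf = _confusion(all_y, all_scores)
    total = sum(conf.values())
    conf_pct = {key: 100.0 * v / total for key, v in conf.items()}
    mean_tpr = np.mean(tprs, axis=0) if tprs else np.full_like(grid, np.nan)
    sd_tpr = np.std(tprs, axis=0) if tprs else np.full_like(grid, np.nan)
    roc_df = pd.DataFrame({"fpr": grid, "mean_tpr": mean_tpr, "sd_tpr": sd_tpr})
    return SummaryReport(
        pooled_auc=pooled,
        fold_aucs=fold_aucs,
        mean_auc=mean_auc,
        auc_ci95=(mean_auc - half, mean_auc + half),
        confusion_pct=conf_pct,
        mean_roc=roc_df,
        n_folds_used=len(fold_aucs),
        excluded_folds=excluded,
    )
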