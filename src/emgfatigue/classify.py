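"""Fatigue classification (SVM / KNN / ANN) and its evaluation protocols.

The unit of classification is one analysis window; its feature vector
concatenates the nine features of every selected source component
(raw signal plus retained IMFs).  Two cross-validation schemes:

* ``stratified-window`` — stratified k-fold over windows.  Windows from
  the same trial land in both train and test folds, so trial
  autocorrelation inflates accuracy; this mirrors the common (and
  optimistic) evaluation in the sEMG fatigue literature.
* ``grouped-by-subject`` — folds partition subjects, so a subject never
  appears in both train and test.  The honest generalisation estimate.

Feature standardisation (and NaN imputation) is fitted on the train fold
only.  The t-SNE representation is *transductive*: the embedding is
computed on all windows before splitting, so test rows influence the
coordinates — retained because it matches how t-SNE-then-classify is
typically practised, but flagged in every report as ``leakage_caveat``.

Accuracy is (TP + TN) / (TP + TN + FP + FN) with "difficult" as the
positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.impute import SimpleImputer
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from emgfatigue.emd import DecompParams, decompose
from emgfatigue.features import FEATURE_COLUMNS, WindowConfig, extract_feature_table
from emgfatigue.tsne import tsne_embed

CLASSIFIER_KINDS = ("svm", "knn", "ann")
POSITIVE_LABEL = "difficult"
SCHEMES = ("stratified-window", "grouped-by-subject")


def accuracy_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("no evaluated samples")
    return (tp + tn) / total


def fit_classifier(
    train_rows: np.ndarray,
    labels: np.ndarray,
    kind: str = "svm",
    hyperparams: dict | None = None,
    seed: int = 0,
) -> Pipeline:
    """Train one classifier on standardized features.

    The returned sklearn pipeline imputes NaNs (median) and z-scores with
    statistics from the training rows only, then fits the classifier:
    RBF-SVM (C=10), 5-NN (distance tie-break via distance weighting), or a
    one-hidden-layer (32 unit) perceptron with early stopping.
    """
    hyperparams = dict(hyperparams or {})
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")
    if kind == "svm":
        clf = SVC(C=hyperparams.pop("C", 10.0), kernel="rbf", gamma="scale", **hyperparams)
    elif kind == "knn":
        clf = KNeighborsClassifier(
            n_neighbors=hyperparams.pop("n_neighbors", 5), weights="distance", **hyperparams
        )
    elif kind == "ann":
        clf = MLPClassifier(
            hidden_layer_sizes=hyperparams.pop("hidden_layer_sizes", (32,)),
            early_stopping=True,
            max_iter=hyperparams.pop("max_iter", 1000),
            learning_rate_init=hyperparams.pop("learning_rate_init", 0.01),
            random_state=seed,
            **hyperparams,
        )
    else:
        raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
    model = Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", clf),
        ]
    )
    model.fit(np.asarray(train_rows, dtype=float), np.asarray(labels))
    return model


@dataclass
class EvalReport:
    """Fold-wise confusion counts and accuracies for one evaluation."""

    scheme: str
    classifier: str
    representation: str
    folds: list[dict] = field(default_factory=list)
    fold_assignment: dict = field(default_factory=dict)
    seed: int = 0
    config: dict = field(default_factory=dict)
    leakage_caveat: str | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f["accuracy"] for f in self.folds]))

    @property
    def pooled_counts(self) -> dict:
        keys = ("tp", "tn", "fp", "fn")
        return {k: int(sum(f[k] for f in self.folds)) for k in keys}

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "classifier": self.classifier,
            "representation": self.representation,
            "seed": self.seed,
            "mean_accuracy": self.mean_accuracy,
            "pooled_counts": self.pooled_counts,
            "folds": self.folds,
            "fold_assignment": {str(k): v for k, v in self.fold_assignment.items()},
            "config": self.config,
            "leakage_caveat": self.leakage_caveat,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def pivot_features(
    table: pd.DataFrame, sources: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Widen the long feature table to one row per window.

    Returns ``(X, y, groups, index)`` where X concatenates the feature
    columns of every selected source, y is the window label, groups the
    subject id, and index the per-row keys.
    """
    if sources is not None:
        table = table[table["source"].isin(sources)]
        if table.empty:
            raise ValueError(f"no rows for sources {sources}")
    wide = table.pivot_table(
        index=["subject_id", "trial_id", "channel_id", "window", "label"],
        columns="source",
        values=FEATURE_COLUMNS,
        sort=True,
    )
    wide.columns = [f"{src}_{feat}" for feat, src in wide.columns]
    wide = wide.sort_index(axis=1).reset_index()
    y = wide.pop("label").to_numpy()
    groups = wide["subject_id"].to_numpy()
    index = wide[["subject_id", "trial_id", "channel_id", "window"]]
    x = wide.drop(columns=["subject_id", "trial_id", "channel_id", "window"]).to_numpy(float)
    return x, y, groups, index


def _tsne_representation(x: np.ndarray, seed: int, **tsne_kwargs) -> np.ndarray:
    # impute before embedding; the embedding itself z-scores columns
    col_median = np.nanmedian(x, axis=0)
    x = np.where(np.isnan(x), col_median, x)
    n_iter = tsne_kwargs.pop("n_iter", 600)
    return tsne_embed(x, dims=3, seed=seed, n_iter=n_iter, **tsne_kwargs).coords


def cross_validate(
    table: pd.DataFrame,
    scheme: str = "stratified-window",
    k_folds: int = 5,
    kind: str = "svm",
    seed: int = 0,
    sources: list[str] | None = None,
    representation: str = "features",
    hyperparams: dict | None = None,
    tsne_kwargs: dict | None = None,
) -> EvalReport:
    """Fold-wise evaluation of one classifier on one representation."""
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    x, y, groups, index = pivot_features(table, sources)
    caveat = None
    if representation == "tsne":
        x = _tsne_representation(x, seed=seed, **(tsne_kwargs or {}))
        caveat = (
            "t-SNE is transductive: the 3-D coordinates were computed on all "
            "windows before splitting, so test rows influenced the embedding."
        )
    elif representation != "features":
        raise ValueError("representation must be 'features' or 'tsne'")

    if scheme == "stratified-window":
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        split = splitter.split(x, y)
    else:
        n_groups = len(np.unique(groups))
        if n_groups < k_folds:
            raise ValueError(f"{n_groups} subjects cannot fill {k_folds} grouped folds")
        splitter = GroupKFold(n_splits=k_folds)
        split = splitter.split(x, y, groups)

    report = EvalReport(
        scheme=scheme,
        classifier=kind,
        representation=representation,
        seed=seed,
        config={"k_folds": k_folds, "sources": sources, "n_windows": int(len(y))},
        leakage_caveat=caveat,
    )
    classes = [l for l in np.unique(y) if l != POSITIVE_LABEL] + [POSITIVE_LABEL]
    for fold_id, (train, test) in enumerate(split):
        model = fit_classifier(x[train], y[train], kind, hyperparams, seed=seed + fold_id)
        pred = model.predict(x[test])
        cm = confusion_matrix(y[test], pred, labels=classes)
        tn, fp, fn, tp = cm.ravel()
        report.folds.append(
            {
                "fold": fold_id,
                "tp": int(tp),
                "tn": int(tn),
                "fp": int(fp),
                "fn": int(fn),
                "accuracy": accuracy_from_counts(int(tp), int(tn), int(fp), int(fn)),
            }
        )
        for row in test:
            report.fold_assignment[tuple(index.iloc[row])] = fold_id
    return report


def imf_sweep(
    table: pd.DataFrame,
    max_k: int,
    kind: str = "svm",
    scheme: str = "stratified-window",
    k_folds: int = 5,
    seed: int = 0,
    include_tsne: bool = True,
    tsne_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Accuracy as a function of the number of retained IMFs.

    For each k the classifier sees the raw-signal features plus those of
    IMFs 1..k; optionally also on the 3-D t-SNE reduction of the same
    feature set.  Returns a tidy frame with columns
    ``n_imfs, accuracy_features, accuracy_tsne, spearman-ready``.
    """
    rows = []
    for k in range(1, max_k + 1):
        sources = ["raw"] + [f"imf{i}" for i in range(1, k + 1)]
        rep = cross_validate(
            table, scheme=scheme, k_folds=k_folds, kind=kind, seed=seed, sources=sources
        )
        entry = {"n_imfs": k, "accuracy_features": rep.mean_accuracy}
        if include_tsne:
            rep_t = cross_validate(
                table,
                scheme=scheme,
                k_folds=k_folds,
                kind=kind,
                seed=seed,
                sources=sources,
                representation="tsne",
                tsne_kwargs=tsne_kwargs,
            )
            entry["accuracy_tsne"] = rep_t.mean_accuracy
        rows.append(entry)
    return pd.DataFrame(rows)


def sweep_spearman(curve: pd.DataFrame, column: str = "accuracy_features") -> float:
    """Spearman correlation between IMF count and accuracy along the sweep."""
    rho = spearmanr(curve["n_imfs"], curve[column]).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def method_comparison(
    records,
    variants: tuple[str, ...] = ("EMD", "EEMD", "CEEMD", "CEEMDAN", "ICEEMDAN"),
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS,
    decomp_params: DecompParams | None = None,
    window_config: WindowConfig = WindowConfig(),
    k_keep: int | None = None,
    scheme: str = "stratified-window",
    k_folds: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], EvalReport]]:
    """Decomposition-method x classifier accuracy matrix under one CV protocol.

    Returns the accuracy matrix (variants as rows, classifiers as columns)
    and the underlying per-cell reports.
    """
    from dataclasses import replace

    base = decomp_params or DecompParams(ensemble_size=30, seed=seed)
    matrix = pd.DataFrame(index=list(variants), columns=list(classifiers), dtype=float)
    reports: dict[tuple[str, str], EvalReport] = {}
    for variant in variants:
        params = replace(base, variant=variant)
        imf_sets = {r.key: decompose(r.samples, params) for r in records}
        table = extract_feature_table(records, window_config, imf_sets, k_keep=k_keep)
        for kind in classifiers:
            rep = cross_validate(
                table, scheme=scheme, k_folds=k_folds, kind=kind, seed=seed
            )
            matrix.loc[variant, kind] = rep.mean_accuracy
            reports[(variant, kind)] = rep
    return matrix, reports


def ranking_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Long-form accuracy ranking, best first."""
    long = matrix.stack().rename("accuracy").reset_index()
    long.columns = ["method", "classifier", "accuracy"]
    return long.sort_values("accuracy", ascending=False, ignore_index=True)
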