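"""Random-forest validation of viral signatures.

Per-dataset discriminative power is measured by five repeats of stratified
fivefold cross-validation of a random forest on signature-vOTU abundances
(AUC of out-of-fold case probabilities). Feature importance is the mean
decrease in accuracy (MDA) under feature permutation on held-out folds,
averaged over all 25 folds. Cross-population transfer is assessed by
training on one dataset and scoring another, and by leave-one-dataset-out
(LODO) analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ._rng import child_rng, child_seed

__all__ = [
    "DatasetBundle",
    "CvReport",
    "auc",
    "cv_auc",
    "top_union",
    "cross_dataset",
    "lodo",
]

#: random-forest defaults mirroring the canonical R implementation
RF_DEFAULTS = dict(n_estimators=500, max_features="sqrt")

CASE_LABEL = "case"


@dataclass
class DatasetBundle:
    """One dataset: samples x feature abundances plus case/control labels."""

    dataset_id: str
    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if self.features.isna().any().any():
            raise ValueError(f"{self.dataset_id}: missing values in feature matrix")
        present = set(self.labels.unique())
        if not {"case", "control"} <= present:
            raise ValueError(f"{self.dataset_id}: both labels must be present, got {present}")
        if not self.features.index.equals(self.labels.index):
            self.labels = self.labels.loc[self.features.index]


@dataclass
class CvReport:
    dataset_id: str
    fold_aucs: np.ndarray  # shape (n_repeats, n_folds)
    feature_ranking: list[str]
    mda: pd.Series = field(repr=False, default=None)

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())


def auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Probability a random case outscores a random control (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == "case"]
    neg = scores[labels == "control"]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (pos.size * neg.size))


def _fit_rf(x: np.ndarray, y: np.ndarray, seed: int, **rf_params) -> RandomForestClassifier:
    params = {**RF_DEFAULTS, **rf_params}
    model = RandomForestClassifier(random_state=seed & 0x7FFFFFFF, **params)
    model.fit(x, y)
    return model


def _case_proba(model: RandomForestClassifier, x: np.ndarray) -> np.ndarray:
    idx = list(model.classes_).index("case")
    return model.predict_proba(x)[:, idx]


def _mda(
    model: RandomForestClassifier,
    x_test: np.ndarray,
    y_test: np.ndarray,
    rng: np.random.Generator,
    n_repeats: int,
) -> np.ndarray:
    """Mean decrease in accuracy under feature permutation on held-out data.

    All features of one repeat are permuted into a single stacked matrix so
    the forest is traversed once per repeat rather than once per feature.
    """
    n, p = x_test.shape
    baseline = (model.predict(x_test) == y_test).mean()
    stacked = np.tile(x_test, (n_repeats * p, 1))
    for r in range(n_repeats):
        for j in range(p):
            block = (r * p + j) * n
            stacked[block : block + n, j] = x_test[rng.permutation(n), j]
    pred = model.predict(stacked) == np.tile(y_test, n_repeats * p)
    acc = pred.reshape(n_repeats, p, n).mean(axis=2)
    return baseline - acc.mean(axis=0)


def cv_auc(
    bundle: DatasetBundle,
    n_repeats: int = 5,
    n_folds: int = 5,
    seed: int = 0,
    mda_repeats: int = 5,
    **rf_params,
) -> CvReport:
    """Repeated stratified cross-validated AUC with MDA feature ranking.

    Per repeat, samples are split into stratified folds from a seeded
    stream; a forest trained on the training folds scores the held-out
    fold. MDA per fold is the accuracy drop under feature permutation on
    that held-out fold, averaged across all repeats x folds to rank
    features (ties broken by feature id).
    """
    x = bundle.features.to_numpy(dtype=float)
    y = bundle.labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if counts.min() < n_folds:
        raise ValueError(
            f"{bundle.dataset_id}: smallest class ({counts.min()}) cannot fill {n_folds} folds"
        )
    fold_aucs = np.zeros((n_repeats, n_folds))
    importances = np.zeros(x.shape[1])
    for rep in range(n_repeats):
        rep_seed = child_seed(seed, "cv", bundle.dataset_id, rep) & 0x7FFFFFFF
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        for fold, (train, test) in enumerate(skf.split(x, y)):
            fit_seed = child_seed(seed, "rf", bundle.dataset_id, rep, fold)
            model = _fit_rf(x[train], y[train], fit_seed, **rf_params)
            fold_aucs[rep, fold] = auc(_case_proba(model, x[test]), y[test])
            importances += _mda(
                model,
                x[test],
                y[test],
                child_rng(seed, "mda", bundle.dataset_id, rep, fold),
                mda_repeats,
            )
    importances /= n_repeats * n_folds
    mda = pd.Series(importances, index=bundle.features.columns, name="mda")
    ranking = sorted(mda.index, key=lambda f: (-mda[f], f))
    return CvReport(
        dataset_id=bundle.dataset_id,
        fold_aucs=fold_aucs,
        feature_ranking=ranking,
        mda=mda,
    )


def top_union(rankings: Mapping[str, Sequence[str]], k: int = 5) -> list[str]:
    """Union of each dataset's top-k features, sorted for determinism."""
    if k < 1:
        raise ValueError("k must be at least 1")
    selected: set[str] = set()
    for dataset_id, ranking in rankings.items():
        if len(ranking) == 0:
            raise ValueError(f"empty ranking for {dataset_id!r}")
        selected.update(list(ranking)[:k])
    return sorted(selected)


def _check_features(bundles: Sequence[DatasetBundle], features: Sequence[str]) -> None:
    for b in bundles:
        missing = sorted(set(features) - set(b.features.columns))
        if missing:
            raise ValueError(f"{b.dataset_id}: features missing from bundle: {missing}")


def cross_dataset(
    bundles: Sequence[DatasetBundle],
    features: Sequence[str],
    seed: int = 0,
    diagonal: Mapping[str, float] | None = None,
    **rf_params,
) -> pd.DataFrame:
    """Train-on-one / test-on-another AUC matrix over the given features.

    Off-diagonal (i, j): forest trained on the full dataset i, scored on
    dataset j. Diagonal: the dataset's own cross-validated mean AUC
    (pass precomputed values via ``diagonal`` to avoid refitting).
    """
    if len(bundles) < 2:
        raise ValueError("cross-dataset analysis needs at least 2 bundles")
    _check_features(bundles, features)
    ids = [b.dataset_id for b in bundles]
    out = pd.DataFrame(np.nan, index=ids, columns=ids)
    models = {}
    for b in bundles:
        sub = DatasetBundle(b.dataset_id, b.features[list(features)], b.labels)
        models[b.dataset_id] = _fit_rf(
            sub.features.to_numpy(dtype=float),
            sub.labels.to_numpy(),
            child_seed(seed, "xds", b.dataset_id),
            **rf_params,
        )
        if diagonal is not None and b.dataset_id in diagonal:
            out.loc[b.dataset_id, b.dataset_id] = diagonal[b.dataset_id]
        else:
            out.loc[b.dataset_id, b.dataset_id] = cv_auc(
                sub, seed=seed, **rf_params
            ).mean_auc
    for bi in bundles:
        for bj in bundles:
            if bi.dataset_id == bj.dataset_id:
                continue
            scores = _case_proba(
                models[bi.dataset_id], bj.features[list(features)].to_numpy(dtype=float)
            )
            out.loc[bi.dataset_id, bj.dataset_id] = auc(scores, bj.labels.to_numpy())
    return out


def lodo(
    bundles: Sequence[DatasetBundle],
    features: Sequence[str],
    seed: int = 0,
    **rf_params,
) -> pd.Series:
    """Leave-one-dataset-out AUC: train on all other bundles, score the rest."""
    if len(bundles) < 3:
        raise ValueError("LODO needs at least 3 bundles")
    _check_features(bundles, features)
    aucs = {}
    for held in bundles:
        train = [b for b in bundles if b.dataset_id != held.dataset_id]
        x = np.vstack([b.features[list(features)].to_numpy(dtype=float) for b in train])
        y = np.concatenate([b.labels.to_numpy() for b in train])
        model = _fit_rf(x, y, child_seed(seed, "lodo", held.dataset_id), **rf_params)
        scores = _case_proba(model, held.features[list(features)].to_numpy(dtype=float))
        aucs[held.dataset_id] = auc(scores, held.labels.to_numpy())
    return pd.Series(aucs, name="lodo_auc")
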