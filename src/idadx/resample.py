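"""Training-fold resampling: exact-balance SMOTE, ensemble noise filter, combos.

Four strategies are available inside cross-validation, applied to the
training part of a fold only:

* ``none``     — identity.
* ``ef``       — ensemble filter: drop instances misclassified out-of-fold by
                 *all* m heterogeneous base learners (consensus label-noise rule).
* ``smote``    — synthetic minority oversampling to exact class balance:
                 n_syn = n_neg - n_pos synthetic points, each a random convex
                 combination x_i + (x_hat - x_i)·λ of a minority instance and
                 one of its k nearest minority neighbors, λ ~ U[0, 1].
* ``ef_smote`` — filter first, then oversample the filtered set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .datasets import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = ["ResamplingPlan", "STRATEGIES", "smote", "ensemble_filter", "apply_strategy"]

STRATEGIES = ("none", "ef", "smote", "ef_smote")


@dataclass(frozen=True)
class ResamplingPlan:
    strategy: str = "none"
    smote_k: int = 5
    ef_m: int = 3
    ef_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.ef_m < 2:
            raise ValueError("ef_m must be >= 2 (consensus needs at least two learners)")


def smote(ds: LabeledDataset, k: int = 5, seed: int = 0, _lam: float | None = None) -> LabeledDataset:
    """Oversample the minority class to exact balance.

    Generates n_neg - n_pos synthetic minority rows; each picks a minority
    donor uniformly (with replacement), one of the donor's k nearest minority
    neighbors (Euclidean, ties to lower index), and an independent λ ~ U[0,1].
    Already-balanced input is returned unchanged.  ``_lam`` pins λ to a fixed
    value (diagnostic use only).
    """
    counts = ds.class_counts()
    minority = ds.minority_label()
    n_pos, n_neg = counts[minority], counts[not minority]
    n_syn = n_neg - n_pos
    if n_syn == 0:
        return ds
    if n_pos < 2:
        raise ValueError("minority class needs at least 2 instances for SMOTE")
    k_eff = min(k, n_pos - 1)
    if k_eff < k:
        logger.info("smote: k clipped from %d to %d (minority size %d)", k, k_eff, n_pos)

    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(ds.labels == minority)
    M = ds.features[min_idx]
    D = cdist(M, M)
    np.fill_diagonal(D, np.inf)
    nn = np.argsort(D, axis=1, kind="stable")[:, :k_eff]

    donors = rng.integers(0, n_pos, size=n_syn)
    picks = rng.integers(0, k_eff, size=n_syn)
    lam = np.full(n_syn, _lam) if _lam is not None else rng.random(n_syn)
    xi = M[donors]
    xhat = M[nn[donors, picks]]
    synth = xi + (xhat - xi) * lam[:, None]

    X = np.vstack([ds.features, synth])
    y = np.concatenate([ds.labels, np.full(n_syn, minority, dtype=bool)])
    return replace(ds, features=X, labels=y, name=f"{ds.name}+smote")


def _base_learners(m: int, seed: int):
    roster = [
        ("tree", DecisionTreeClassifier(random_state=seed)),
        ("knn", KNeighborsClassifier(n_neighbors=5)),
        ("lda", LinearDiscriminantAnalysis()),
        ("nb", GaussianNB()),
        ("logreg", LogisticRegression(max_iter=1000, random_state=seed)),
    ]
    if m > len(roster):
        raise ValueError(f"ef_m at most {len(roster)} heterogeneous learners supported")
    return roster[:m]


def ensemble_filter(ds: LabeledDataset, m: int = 3, folds: int = 5, seed: int = 0) -> np.ndarray:
    """Consensus label-noise detection.

    A shared stratified k-fold partition; each of m heterogeneous base
    learners is trained out-of-fold and predicts every held-out instance, so
    every instance is tested exactly m times.  Indices misclassified by all
    m learners are returned (sorted).  Degenerate partitions (a training
    part with one class) trigger a refold with a new seed, up to 10 tries.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = ds.class_counts()
    if min(counts.values()) < 2:
        raise ValueError("both classes need at least 2 instances")
    folds = min(folds, min(counts.values()))

    y = ds.labels.astype(int)
    X = ds.features
    for attempt in range(10):
        s = seed + attempt
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=s)
        splits = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            break
        logger.info("ensemble_filter: degenerate partition, refolding (attempt %d)", attempt + 1)
    else:
        raise RuntimeError("could not build a partition with both classes in every training part")

    wrong = np.zeros(ds.n, dtype=int)
    for _name, learner in _base_learners(m, seed):
        for tr, te in splits:
            learner.fit(X[tr], y[tr])
            pred = learner.predict(X[te])
            wrong[te] += (pred != y[te]).astype(int)
    return np.flatnonzero(wrong == m)


def apply_strategy(ds: LabeledDataset, plan: ResamplingPlan) -> LabeledDataset:
    """Apply the plan to a training fold (never to evaluation data)."""
    if plan.strategy == "none":
        return ds
    if plan.strategy == "smote":
        return smote(ds, k=plan.smote_k, seed=plan.seed)

    noisy = ensemble_filter(ds, m=plan.ef_m, folds=plan.ef_folds, seed=plan.seed)
    keep = np.setdiff1d(np.arange(ds.n), noisy)
    filtered = ds.subset(keep, name=f"{ds.name}+ef")
    counts = filtered.class_counts()
    if min(counts.values()) == 0:
        raise RuntimeError(
            "ensemble filter removed an entire class; use a smaller ef_m or disable EF"
        )
    if noisy.size:
        removed = {
            True: int(ds.labels[noisy].sum()),
            False: int((~ds.labels[noisy]).sum()),
        }
        logger.info("ensemble filter removed %d instance(s) per class: %s", noisy.size, removed)
    if plan.strategy == "ef":
        return filtered
    return smote(filtered, k=plan.smote_k, seed=plan.seed)  # ef_smote
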