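"""All-relevant feature screening with shadow features (Boruta).

Each original column is duplicated and permuted within itself ("shadow"
features), destroying its relation to the response while preserving its
marginal distribution.  A random forest is fit on originals + shadows; a real
feature scores a *hit* when its importance exceeds the best shadow importance
(shadowMax).  Hits accumulated over repeated runs are tested against the
coin-flip null Binomial(runs, 1/2): significantly more hits than chance
confirms the feature, significantly fewer rejects it, anything else stays
tentative.  The loop stops early once every feature is decided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .datasets import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = ["BorutaResult", "add_shadow_features", "boruta"]

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass(frozen=True)
class BorutaResult:
    decisions: dict[str, str]  # feature -> confirmed / rejected / tentative
    hits: dict[str, int]
    importance_history: list[dict]  # per run: feature importances + "shadowMax"
    runs_executed: int
    alpha: float

    def selected(self, keep_tentative: bool = True) -> list[str]:
        """Features to carry forward; tentative ones kept by default."""
        allow = {CONFIRMED, TENTATIVE} if keep_tentative else {CONFIRMED}
        return [f for f, d in self.decisions.items() if d in allow]


def add_shadow_features(X: np.ndarray, rng_seed: int) -> np.ndarray:
    """Append max(p, 5) shadow columns, each a permutation of an original column.

    With fewer than 5 originals, columns are recycled so at least 5 shadows
    exist.  Original columns are untouched; output is [X | shadows].
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(rng_seed)
    n_shadow = max(p, 5)
    shadows = np.empty((n, n_shadow))
    for s in range(n_shadow):
        shadows[:, s] = rng.permutation(X[:, s % p])
    return np.hstack([X, shadows])


def _importances(model, X, y, kind: str, rng_seed: int) -> np.ndarray:
    if kind == "impurity":
        return model.feature_importances_
    if kind == "permutation":
        r = permutation_importance(model, X, y, n_repeats=5, random_state=rng_seed, n_jobs=1)
        return r.importances_mean
    raise ValueError(f"unknown importance kind {kind!r}")


def boruta(
    ds: LabeledDataset,
    runs: int = 100,
    alpha: float = 0.01,
    rng_seed: int = 0,
    n_estimators: int = 500,
    max_depth: int | None = None,
    importance: str = "impurity",
) -> BorutaResult:
    """Shadow-feature significance screening of every feature.

    A two-sided view of the hit count against Binomial(r, 0.5) with a
    Bonferroni correction across the p features decides each feature as soon
    as the evidence allows; undecided features at exhaustion are tentative.
    """
    if runs < 10:
        raise ValueError("runs must be >= 10")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    counts = ds.class_counts()
    if min(counts.values()) == 0:
        raise ValueError("labels contain a single class; screening is undefined")

    p = ds.p
    names = list(ds.feature_names)
    y = ds.labels.astype(int)
    rng = np.random.default_rng(rng_seed)
    hits = dict.fromkeys(names, 0)
    decisions = dict.fromkeys(names, TENTATIVE)
    history: list[dict] = []
    corrected = alpha / p

    r = 0
    for r in range(1, runs + 1):
        seed = int(rng.integers(2**31))
        Xaug = add_shadow_features(ds.features, rng_seed=seed)
        forest = RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth,
            random_state=seed, n_jobs=1,
        )
        forest.fit(Xaug, y)
        imp = _importances(forest, Xaug, y, importance, seed)
        shadow_max = float(imp[p:].max())
        record = {names[i]: float(imp[i]) for i in range(p)}
        record["shadowMax"] = shadow_max
        history.append(record)

        for i, f in enumerate(names):
            if decisions[f] != TENTATIVE:
                continue
            if imp[i] > shadow_max:
                hits[f] += 1
            if binomtest(hits[f], r, 0.5, alternative="greater").pvalue < corrected:
                decisions[f] = CONFIRMED
            elif binomtest(hits[f], r, 0.5, alternative="less").pvalue < corrected:
                decisions[f] = REJECTED
        if all(d != TENTATIVE for d in decisions.values()):
            logger.info("all features decided after %d run(s)", r)
            break

    return BorutaResult(
        decisions=decisions, hits=hits, importance_history=history,
        runs_executed=r, alpha=alpha,
    )
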