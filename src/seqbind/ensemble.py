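"""Balanced-subset random-forest ensemble and multi-window combination.

Binding residues are rare (~4% of instances under the vdW contact rule), so
a single classifier trained on the raw data collapses to the majority
class.  Instead the negative pool is split into disjoint subsets; each
subset is paired with *all* positives to form a balanced training set, one
random forest is trained per set, and the ensemble's score for a residue is
the fraction of forests voting "binding".  A vote threshold v turns scores
into calls (v = ceil(n/2) is majority voting, v = n unanimity).

Predictions obtained with different sliding-window lengths are merged by

    combined = mean(scores) - std(scores)        (population std)

which penalizes disagreement between window sizes: the combined score can
only reach the mean when every window agrees.
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

DEFAULT_N_SUBSETS = 15


def _derive_seed(base_seed: int, tag: str) -> int:
    """Stable per-component seed below 2**31."""
    return zlib.crc32(f"{tag}:{base_seed}".encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# domain types


@dataclass
class BalancedSplit:
    """One balanced training subset: all positives + disjoint negatives."""

    index: int
    positive_ids: np.ndarray
    negative_ids: np.ndarray

    def __post_init__(self):
        self.positive_ids = np.asarray(self.positive_ids, dtype=int)
        self.negative_ids = np.asarray(self.negative_ids, dtype=int)

    @property
    def instance_ids(self) -> np.ndarray:
        return np.concatenate([self.positive_ids, self.negative_ids])


@dataclass
class ForestConfig:
    """Random-forest hyperparameters shared by all ensemble members.

    ``max_features`` defaults to int(log2(J) + 1) where J is the feature
    count (Breiman's classical default for the per-split feature draw).
    """

    n_trees: int = 500
    max_features: int | None = None
    seed: int = 0
    max_depth: int | None = None
    min_samples_leaf: int = 1

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("need at least one tree")

    def resolved_max_features(self, n_features: int) -> int:
        if self.max_features is not None:
            if not 1 <= self.max_features <= n_features:
                raise ValueError(
                    f"max_features {self.max_features} outside [1, {n_features}]"
                )
            return self.max_features
        return max(1, min(n_features, int(math.log2(n_features) + 1)))


@dataclass
class EnsembleModel:
    """Trained member forests plus the splits and config that produced them."""

    forests: list[RandomForestClassifier]
    splits: list[BalancedSplit]
    config: ForestConfig
    fingerprint: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.forests) != len(self.splits):
            raise ValueError("classifier count must equal split count")

    @property
    def n_subsets(self) -> int:
        return len(self.forests)


# ---------------------------------------------------------------------------
# splits


def make_balanced_splits(
    labels: np.ndarray,
    n_subsets: int = DEFAULT_N_SUBSETS,
    strategy: str = "matched",
    seed: int = 0,
) -> list[BalancedSplit]:
    """Split the negative pool into ``n_subsets`` disjoint groups.

    strategy="matched": each subset draws exactly N_pos negatives; leftover
    negatives are discarded (with a warning), preserving exact balance.
    strategy="partition": all negatives are divided into near-equal parts,
    so subsets may be larger than the positive set but no negative is wasted.
    Positives are shared by every split.
    """
    labels = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) < 1:
        raise ValueError("need at least one positive instance")
    if len(neg) < n_subsets:
        raise ValueError(f"need at least {n_subsets} negatives, have {len(neg)}")
    if strategy not in ("matched", "partition"):
        raise ValueError(f"unknown strategy {strategy!r}")

    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(neg)
    if strategy == "matched":
        per = len(pos)
        if n_subsets * per > len(neg):
            raise ValueError(
                f"matched strategy needs {n_subsets}x{per} negatives, have {len(neg)}"
            )
        parts = [shuffled[i * per : (i + 1) * per] for i in range(n_subsets)]
        leftover = len(neg) - n_subsets * per
        if leftover:
            warnings.warn(
                f"matched strategy leaves {leftover} of {len(neg)} negatives unused"
            )
    else:
        parts = np.array_split(shuffled, n_subsets)
    return [
        BalancedSplit(index=i, positive_ids=pos.copy(), negative_ids=np.sort(part))
        for i, part in enumerate(parts)
    ]


def check_splits(splits: Sequence[BalancedSplit]) -> None:
    """Assert the split invariants: shared positives, disjoint negatives."""
    ref = splits[0].positive_ids
    seen: set[int] = set()
    for s in splits:
        if not np.array_equal(np.sort(s.positive_ids), np.sort(ref)):
            raise ValueError(f"split {s.index}: positive set differs")
        ids = set(s.negative_ids.tolist())
        if ids & seen:
            raise ValueError(f"split {s.index}: negatives overlap a previous split")
        seen |= ids


# ---------------------------------------------------------------------------
# training and voting


def train_ensemble(
    features,
    labels: np.ndarray,
    splits: Sequence[BalancedSplit],
    config: ForestConfig | None = None,
    fingerprint: str | None = None,
) -> EnsembleModel:
    """Train one forest per balanced split.

    ``features`` may be a FeatureMatrix (its fingerprint is recorded) or a
    plain array.  Training is deterministic given the config seed.
    """
    if config is None:
        config = ForestConfig()
    X, fp = _as_array(features, fingerprint)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {y.shape[0]} labels")
    check_splits(splits)

    forests = []
    for split in splits:
        ids = split.instance_ids
        y_sub = y[ids]
        if len(np.unique(y_sub)) < 2:
            raise ValueError(f"split {split.index} contains a single class only")
        clf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.resolved_max_features(X.shape[1]),
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            random_state=_derive_seed(config.seed, f"forest-{split.index}"),
            n_jobs=1,
        )
        clf.fit(X[ids], y_sub)
        forests.append(clf)
    return EnsembleModel(
        forests=forests,
        splits=list(splits),
        config=config,
        fingerprint=fp,
        meta={"n_features": int(X.shape[1])},
    )


def _as_array(features, fingerprint: str | None):
    fp = fingerprint
    if hasattr(features, "values") and hasattr(features, "fingerprint"):
        if fp is None:
            fp = features.fingerprint
        X = np.asarray(features.values, dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    return X, fp


def ensemble_votes(model: EnsembleModel, features, fingerprint: str | None = None) -> np.ndarray:
    """Number of member forests voting class 1, per instance."""
    X, fp = _as_array(features, fingerprint)
    if model.fingerprint is not None and fp is not None and model.fingerprint != fp:
        raise ValueError(
            f"feature-layout fingerprint mismatch: model {model.fingerprint}, input {fp}"
        )
    votes = np.zeros(X.shape[0], dtype=int)
    for clf in model.forests:
        votes += clf.predict(X).astype(int)
    return votes


def ensemble_scores(model: EnsembleModel, features, fingerprint: str | None = None) -> np.ndarray:
    """Fraction of member forests voting positive, in [0, 1]."""
    return ensemble_votes(model, features, fingerprint) / model.n_subsets


def vote_threshold_predict(votes: np.ndarray, v: int, n_subsets: int | None = None) -> np.ndarray:
    """Binary call: 1 iff at least ``v`` forests voted positive."""
    votes = np.asarray(votes, dtype=int)
    n = n_subsets if n_subsets is not None else int(votes.max(initial=1))
    if not 1 <= v <= n:
        raise ValueError(f"vote threshold {v} outside [1, {n}]")
    return (votes >= v).astype(int)


def majority_threshold(n_subsets: int) -> int:
    return math.ceil(n_subsets / 2)


# ---------------------------------------------------------------------------
# window combination


def combine_windows(window_scores: Sequence[np.ndarray], ddof: int = 0) -> np.ndarray:
    """Combine per-window scores: mean minus (population) standard deviation.

    The combination never exceeds the plain mean and equals it exactly when
    all windows agree, so inconsistent window lengths are penalized.
    """
    if len(window_scores) < 1:
        raise ValueError("need at least one window prediction")
    arrs = [np.asarray(s, dtype=float) for s in window_scores]
    L = arrs[0].shape[0]
    for a in arrs:
        if a.shape != (L,):
            raise ValueError("window predictions must all have the same length")
    stack = np.stack(arrs)
    return stack.mean(axis=0) - stack.std(axis=0, ddof=ddof)


def binarize_combined(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary call from combined scores: 1 iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("combined scores must be finite")
    return (scores >= threshold).astype(int)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: EnsembleModel, model_dir) -> None:
    d = Path(model_dir)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "fingerprint": model.fingerprint,
        "config": {
            "n_trees": model.config.n_trees,
            "max_features": model.config.max_features,
            "seed": model.config.seed,
            "max_depth": model.config.max_depth,
            "min_samples_leaf": model.config.min_samples_leaf,
        },
        "splits": [
            {
                "index": s.index,
                "positive_ids": s.positive_ids.tolist(),
                "negative_ids": s.negative_ids.tolist(),
            }
            for s in model.splits
        ],
        "meta": model.meta,
    }
    (d / "model.json").write_text(json.dumps(meta, indent=1))
    for i, clf in enumerate(model.forests):
        joblib.dump(clf, d / f"forest_{i:02d}.joblib")


def load_model(model_dir) -> EnsembleModel:
    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    splits = [
        BalancedSplit(
            index=s["index"],
            positive_ids=np.array(s["positive_ids"], dtype=int),
            negative_ids=np.array(s["negative_ids"], dtype=int),
        )
        for s in meta["splits"]
    ]
    forests = [joblib.load(d / f"forest_{i:02d}.joblib") for i in range(len(splits))]
    return EnsembleModel(
        forests=forests,
        splits=splits,
        config=ForestConfig(**meta["config"]),
        fingerprint=meta["fingerprint"],
        meta=meta.get("meta", {}),
    )
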