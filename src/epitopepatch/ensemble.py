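"""Balanced bootstrap-and-vote random-forest ensemble.

Epitope instance sets are heavily imbalanced (far more non-epitope surface
residues than epitope residues).  Instead of reweighting, the negative set
A- is subsampled n_sub times to the size of the positive set A+; each
balanced subset (subsample ∪ A+) trains one random forest, and a new
instance is classified by counting positive votes across the n_sub forests.
The default decision cutoff is half the sub-classifiers (ties at exactly
half count as positive); sweeping the cutoff yields the ROC curve.

Forest defaults follow the classic small-forest setup: 10 trees,
floor(log2(m)) + 1 candidate features per split, unlimited depth.  All
randomness (subsampling and tree growing) derives from one master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

PERSISTENCE_VERSION = 1


@dataclass
class RFParams:
    """Random-forest hyper-parameters for every sub-classifier."""

    n_trees: int = 10
    max_features: int | str | None = "log2plus1"  # floor(log2(m)) + 1
    max_depth: int | None = None

    def resolve_max_features(self, n_features: int) -> int | str | None:
        if self.max_features == "log2plus1":
            return min(int(np.log2(n_features)) + 1, n_features)
        return self.max_features


@dataclass
class TrainingSet:
    """Positive (epitope) and negative (non-epitope) patch vectors."""

    positives: np.ndarray  # (n_pos, n_features)
    negatives: np.ndarray  # (n_neg, n_features)

    def __post_init__(self):
        self.positives = np.atleast_2d(np.asarray(self.positives, dtype=float))
        self.negatives = np.atleast_2d(np.asarray(self.negatives, dtype=float))
        if self.positives.shape[1] != self.negatives.shape[1]:
            raise ValueError("positive and negative vectors differ in length")
        if len(self.negatives) < len(self.positives):
            logger.warning("fewer negatives (%d) than positives (%d): the class "
                           "balance assumption is inverted",
                           len(self.negatives), len(self.positives))


def default_n_sub(n_neg: int, n_pos: int) -> int:
    """Default number of sub-classifiers: round(|A-| / |A+|), at least 1."""
    return max(1, int(round(n_neg / n_pos)))


def make_balanced_subsets(training: TrainingSet, n_sub: int | None = None,
                          seed: int = 0) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Build ``n_sub`` balanced training sets.

    Each subset pairs the full positive set with ``|A+|`` negatives sampled
    without replacement (within the subset; subsets are drawn independently
    and may overlap).  Returns (X, y, negative_indices) triples; the indices
    make the sampling auditable and persistable.

    If there are fewer negatives than positives, a single unbalanced set
    with all instances is returned with a warning.
    """
    n_pos, n_neg = len(training.positives), len(training.negatives)
    if n_pos < 1:
        raise ValueError("at least one positive instance is required")
    rng = np.random.default_rng(seed)
    if n_neg < n_pos:
        logger.warning("negatives (%d) < positives (%d): falling back to one "
                       "unbalanced training set", n_neg, n_pos)
        idx = np.arange(n_neg)
        X = np.vstack([training.positives, training.negatives])
        y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
        return [(X, y, idx)]
    if n_sub is None:
        n_sub = default_n_sub(n_neg, n_pos)
    subsets = []
    for _ in range(n_sub):
        idx = np.sort(rng.choice(n_neg, size=n_pos, replace=False))
        X = np.vstack([training.positives, training.negatives[idx]])
        y = np.concatenate([np.ones(n_pos), np.zeros(n_pos)])
        subsets.append((X, y, idx))
    return subsets


@dataclass
class VoteEnsemble:
    """Trained sub-classifiers combined by voting."""

    forests: list[RandomForestClassifier]
    rf_params: RFParams
    subset_indices: list[np.ndarray]
    seeds: list[int]
    n_features: int

    @property
    def n_sub(self) -> int:
        return len(self.forests)

    @property
    def default_cutoff(self) -> float:
        return self.n_sub / 2.0

    def predict_votes(self, X: np.ndarray) -> np.ndarray:
        """Positive-vote count in [0, n_sub] for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(f"feature length {X.shape[1]} != training length "
                             f"{self.n_features}")
        votes = np.zeros(len(X), dtype=int)
        for forest in self.forests:
            votes += forest.predict(X).astype(int)
        return votes

    def decide(self, votes: np.ndarray, cutoff: float | None = None) -> np.ndarray:
        """Positive call iff votes >= cutoff (default: half the sub-classifiers)."""
        votes = np.asarray(votes)
        if np.any((votes < 0) | (votes > self.n_sub)):
            raise ValueError("votes outside [0, n_sub]")
        if cutoff is None:
            cutoff = self.default_cutoff
        return votes >= cutoff


def train_ensemble(subsets: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                   rf_params: RFParams | None = None,
                   seed: int = 0) -> VoteEnsemble:
    """Train one random forest per balanced subset.

    Per-forest seeds are spawned deterministically from the master ``seed``
    so (data, seed, params) fully determine every vote.
    """
    if not subsets:
        raise ValueError("no training subsets")
    params = rf_params or RFParams()
    n_features = subsets[0][0].shape[1]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(subsets))]
    forests = []
    for (X, y, _), sub_seed in zip(subsets, child_seeds):
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate single-class training subset")
        forest = RandomForestClassifier(
            n_estimators=params.n_trees,
            max_features=params.resolve_max_features(n_features),
            max_depth=params.max_depth,
            random_state=sub_seed,
        )
        forest.fit(X, y)
        forests.append(forest)
    return VoteEnsemble(forests=forests, rf_params=params,
                        subset_indices=[idx for _, _, idx in subsets],
                        seeds=child_seeds, n_features=n_features)


def save_ensemble(ensemble: VoteEnsemble, path) -> None:
    """Persist the ensemble (params, seeds, subset indices, forests)."""
    joblib.dump({
        "version": PERSISTENCE_VERSION,
        "rf_params": asdict(ensemble.rf_params),
        "seeds": ensemble.seeds,
        "subset_indices": ensemble.subset_indices,
        "n_features": ensemble.n_features,
        "forests": ensemble.forests,
    }, path)


def load_ensemble(path) -> VoteEnsemble:
    payload = joblib.load(path)
    if payload.get("version") != PERSISTENCE_VERSION:
        raise ValueError(f"unsupported model archive version {payload.get('version')!r}")
    return VoteEnsemble(forests=payload["forests"],
                        rf_params=RFParams(**payload["rf_params"]),
                        subset_indices=payload["subset_indices"],
                        seeds=payload["seeds"],
                        n_features=payload["n_features"])
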