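"""Evaluation: confusion metrics, vote-cutoff ROC/AUC, per-structure
leave-one-out cross-validation, and class-contrast distance statistics.

Cross-validation partitions by *structure*: each fold trains on all
structures but one and tests on the held-out structure, so no residue of a
test antigen ever reaches training.  The headline number is the unweighted
mean of per-structure AUCs; a pooled-residue AUC is reported alongside.

The distance statistics contrast epitope and non-epitope patches: mean
adjacent distance per central amino-acid type, and mean distance of the
kth-nearest neighbour per k, each compared with a paired t-test (closed
form, pairing over amino-acid types and over k respectively).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from epitopepatch.ensemble import (RFParams, TrainingSet, VoteEnsemble,
                                   make_balanced_subsets, train_ensemble)
from epitopepatch.patches import ResiduePatch
from epitopepatch.pipeline import FeaturizedStructure, RunConfig
from epitopepatch.structure import ResidueId

logger = logging.getLogger(__name__)


def confusion_metrics(TP: int, TN: int, FP: int, FN: int) -> dict[str, float]:
    """SN, SP, ACC, precision, recall and F from a confusion table.

    SN = TP/(TP+FN); SP = TN/(TN+FP); ACC = (TP+TN)/total;
    precision = TP/(TP+FP); recall = SN; F = 2·precision·recall /
    (precision+recall).  A metric whose denominator is zero is reported as
    NaN (undefined), never silently as 0.
    """
    if min(TP, TN, FP, FN) < 0:
        raise ValueError("confusion counts must be non-negative")

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    sn = ratio(TP, TP + FN)
    sp = ratio(TN, TN + FP)
    acc = ratio(TP + TN, TP + TN + FP + FN)
    precision = ratio(TP, TP + FP)
    recall = sn
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        f = math.nan
    else:
        f = 2 * precision * recall / (precision + recall)
    return {"SN": sn, "SP": sp, "ACC": acc, "precision": precision,
            "recall": recall, "F": f}


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    TP = int(np.count_nonzero(y_true & y_pred))
    TN = int(np.count_nonzero(~y_true & ~y_pred))
    FP = int(np.count_nonzero(~y_true & y_pred))
    FN = int(np.count_nonzero(y_true & ~y_pred))
    return TP, TN, FP, FN


def roc_auc(votes: np.ndarray, labels: np.ndarray,
            n_sub: int) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC from a vote-cutoff sweep.

    One (FPR, TPR) = (1-SP, SN) point per integer cutoff in {0, ..,
    n_sub+1}; cutoff 0 calls everything positive and n_sub+1 nothing, so
    the curve spans (1,1)–(0,0).  AUC integrates the sorted points by the
    trapezoidal rule, which credits vote ties with half weight.
    """
    votes = np.asarray(votes)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    points = []
    for cutoff in range(0, n_sub + 2):
        pred = votes >= cutoff
        TP, TN, FP, FN = confusion_counts(labels, pred)
        points.append((FP / n_neg, TP / n_pos))
    xy = sorted(points)
    xs = np.array([p[0] for p in xy])
    ys = np.array([p[1] for p in xy])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def paired_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test from its closed form.

    t = mean(d) / (sd(d)/sqrt(k)) with d = a - b and k pairs; p from the
    t distribution with k-1 degrees of freedom.  All-zero differences give
    (0, 1); zero spread with a non-zero mean gives (±inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired t-test needs two equal-length 1-D arrays, k >= 2")
    d = a - b
    k = len(d)
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(k))
    p = 2.0 * float(sps.t.sf(abs(t), df=k - 1))
    return float(t), p


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

@dataclass
class StructureResult:
    structure_id: str
    TP: int
    TN: int
    FP: int
    FN: int
    metrics: dict[str, float]
    auc: float | None            # None when the test structure is single-class
    votes: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)
    residue_ids: list[ResidueId] = field(repr=False, default_factory=list)


@dataclass
class EvaluationResult:
    per_structure: list[StructureResult]
    mean_auc: float              # unweighted mean of per-structure AUCs
    pooled_auc: float            # AUC over all residues pooled
    mean_metrics: dict[str, float]
    n_sub: int


def _train_fold(X_train: np.ndarray, y_train: np.ndarray,
                config: RunConfig, fold_seed: int) -> VoteEnsemble:
    training = TrainingSet(positives=X_train[y_train > 0.5],
                           negatives=X_train[y_train <= 0.5])
    subsets = make_balanced_subsets(training, n_sub=config.n_sub, seed=fold_seed)
    params = RFParams(n_trees=config.n_trees, max_depth=config.max_depth)
    return train_ensemble(subsets, rf_params=params, seed=fold_seed)


def loocv(items: list[FeaturizedStructure], config: RunConfig | None = None,
          seed: int | None = None) -> EvaluationResult:
    """Per-structure leave-one-out cross-validation.

    For each of the n structures an ensemble is trained on the other n-1
    and evaluated on the held-out one: confusion metrics at the default
    vote cutoff (half the sub-classifiers) and AUC from the cutoff sweep.
    Structures whose test labels are single-class are skipped for AUC with
    a warning but still contribute confusion counts.
    """
    cfg = config or RunConfig()
    if seed is None:
        seed = cfg.seed
    labelled = [it for it in items if it.y is not None and len(it.y)]
    if len(labelled) < 2:
        raise ValueError("LOOCV needs at least 2 labelled structures")
    fold_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                  for s in np.random.SeedSequence(seed).spawn(len(labelled))]

    per_structure: list[StructureResult] = []
    all_votes, all_labels, all_fracs = [], [], []
    n_sub_seen = []
    for i, held_out in enumerate(labelled):
        train_items = [it for j, it in enumerate(labelled) if j != i]
        X_train = np.vstack([it.X for it in train_items])
        y_train = np.concatenate([it.y for it in train_items])
        ensemble = _train_fold(X_train, y_train, cfg, fold_seeds[i])
        votes = ensemble.predict_votes(held_out.X)
        cutoff = cfg.vote_cutoff if cfg.vote_cutoff is not None else ensemble.default_cutoff
        pred = ensemble.decide(votes, cutoff)
        TP, TN, FP, FN = confusion_counts(held_out.y, pred)
        metrics = confusion_metrics(TP, TN, FP, FN)
        y = held_out.y.astype(bool)
        if y.any() and (~y).any():
            _, auc = roc_auc(votes, held_out.y, ensemble.n_sub)
        else:
            auc = None
            logger.warning("%s: single-class labels, structure skipped for AUC",
                           held_out.structure_id)
        per_structure.append(StructureResult(
            structure_id=held_out.structure_id, TP=TP, TN=TN, FP=FP, FN=FN,
            metrics=metrics, auc=auc, votes=votes, labels=held_out.y,
            residue_ids=held_out.residue_ids))
        # pooled ROC uses the vote fraction so folds with different n_sub
        # share a common score scale
        all_votes.append(votes)
        all_fracs.append(votes / ensemble.n_sub)
        all_labels.append(held_out.y)
        n_sub_seen.append(ensemble.n_sub)

    aucs = [r.auc for r in per_structure if r.auc is not None]
    if not aucs:
        raise ValueError("no structure had both classes; cannot compute mean AUC")
    mean_auc = float(np.mean(aucs))
    pooled_auc = _pooled_auc(np.concatenate(all_fracs), np.concatenate(all_labels))

    mean_metrics = {}
    for key in ("SN", "SP", "ACC", "precision", "recall", "F"):
        vals = [r.metrics[key] for r in per_structure if not math.isnan(r.metrics[key])]
        mean_metrics[key] = float(np.mean(vals)) if vals else math.nan
    return EvaluationResult(per_structure=per_structure, mean_auc=mean_auc,
                            pooled_auc=pooled_auc, mean_metrics=mean_metrics,
                            n_sub=int(round(float(np.mean(n_sub_seen)))))


def _pooled_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC with half credit for ties."""
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return math.nan
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# distance statistics (class contrast of patch geometry)
# ---------------------------------------------------------------------------

@dataclass
class DistanceProfile:
    """Epitope vs non-epitope contrast of patch distance geometry."""

    by_aa: dict[str, tuple[float, float]]        # aa -> (mean_epi, mean_non)
    by_k: dict[int, tuple[float, float]]         # k -> (mean_epi, mean_non)
    aa_t: float
    aa_p: float
    k_t: float
    k_p: float
    excluded_aa: list[str]                       # types present in one class only


def patch_distance_statistics(patches: list[ResiduePatch],
                              labels: dict[ResidueId, bool],
                              central_types: dict[ResidueId, str]) -> DistanceProfile:
    """Compare patch distance geometry between epitope and non-epitope patches.

    Two views: the mean adjacent distance grouped by the central residue's
    amino-acid type, and the mean distance of the kth-nearest neighbour for
    each rank k = 1..n-1.  Each view is tested with a paired t-test (pairs
    = amino-acid types, and pairs = ranks k).  Types observed in only one
    class are excluded from the pairing and reported.
    """
    if not patches:
        raise ValueError("no patches")
    sizes = {p.size for p in patches}
    if len(sizes) != 1:
        raise ValueError(f"patch sizes differ: {sorted(sizes)}")
    n = sizes.pop()

    mean_by_class_aa: dict[tuple[bool, str], list[float]] = {}
    dists_by_class_k: dict[bool, list[np.ndarray]] = {True: [], False: []}
    for p in patches:
        lab = bool(labels[p.central])
        aa = central_types[p.central]
        mean_by_class_aa.setdefault((lab, aa), []).append(float(p.distances.mean()))
        dists_by_class_k[lab].append(p.distances)
    if not dists_by_class_k[True] or not dists_by_class_k[False]:
        raise ValueError("both epitope and non-epitope patches are required")

    aa_types = sorted({aa for _, aa in mean_by_class_aa})
    by_aa: dict[str, tuple[float, float]] = {}
    excluded = []
    for aa in aa_types:
        epi = mean_by_class_aa.get((True, aa))
        non = mean_by_class_aa.get((False, aa))
        if epi is None or non is None:
            excluded.append(aa)
            continue
        by_aa[aa] = (float(np.mean(epi)), float(np.mean(non)))
    if len(by_aa) >= 2:
        aa_t, aa_p = paired_t_test(np.array([v[0] for v in by_aa.values()]),
                                   np.array([v[1] for v in by_aa.values()]))
    else:
        aa_t, aa_p = math.nan, math.nan

    epi_mat = np.vstack(dists_by_class_k[True])
    non_mat = np.vstack(dists_by_class_k[False])
    epi_k = epi_mat.mean(axis=0)
    non_k = non_mat.mean(axis=0)
    by_k = {k + 1: (float(epi_k[k]), float(non_k[k])) for k in range(n - 1)}
    k_t, k_p = paired_t_test(epi_k, non_k)

    return DistanceProfile(by_aa=by_aa, by_k=by_k, aa_t=aa_t, aa_p=aa_p,
                           k_t=k_t, k_p=k_p, excluded_aa=excluded)
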