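"""Ensemble random-forest QSAR classifier with applicability-domain control.

The classifier is an ensemble of random forests (default 100 members),
each trained on an independent random 90% sample of the training rows;
a compound is predicted active iff strictly more than 50% of the members
vote active.  Hyperparameters (tree count, 100-1000 in steps of 100, and
the feature-block combination among physchem / Morgan / residue-contact
blocks) are selected by seeded stratified 10-fold cross-validation
accuracy; on the RIPK1 set the published optimum is 700 trees on
physicochemical descriptors + residue contacts (89.9 +/- 2.7% CV
accuracy).

Prediction reliability is controlled by a reliability-density
neighborhood (RDN) applicability domain: a kernel-weighted sum of local
cross-validated correctness in fingerprint-similarity space.  Tightening
the reliability cutoff trades coverage for precision among accepted
predicted actives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from plifscreen.curation import ACTIVE, INACTIVE

FEATURE_BLOCKS = ("physchem", "morgan", "residue_contacts")


def split_train_test(records, test_fraction: float = 0.3, seed: int = 0):
    """Random, seed-reproducible train/test split of a DataFrame or array.

    The test set holds ``floor(n * test_fraction)`` rows (so 624 rows at
    0.3 split 437/187); train and test are disjoint and exhaustive.
    Raises when a label column is present and either class is missing
    from the training part.
    """
    if not 0 <= test_fraction < 1:
        raise ValueError(f"test_fraction must be in [0, 1), got {test_fraction}")
    n = len(records)
    n_test = int(math.floor(n * test_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    if isinstance(records, pd.DataFrame):
        train, test = records.iloc[train_idx], records.iloc[test_idx]
        if "label" in records.columns and n_test > 0:
            present = set(train["label"])
            if not {ACTIVE, INACTIVE} <= present:
                raise ValueError(f"class absent from training split: have {present}")
    else:
        arr = np.asarray(records)
        train, test = arr[train_idx], arr[test_idx]
    return train, test


class EnsembleForestClassifier(ClassifierMixin, BaseEstimator):
    """Bagged ensemble of random forests with majority-vote prediction.

    Each of the ``n_members`` forests is trained on an independent random
    sample of ``bag_fraction`` of the training rows (without replacement
    by default); the predicted class is active iff strictly more than
    half of the members vote active — an exact 50% tie is inactive.

    Parameters
    ----------
    n_members : number of forests in the ensemble (default 100).
    n_trees : trees per forest (default 700, the published optimum).
    bag_fraction : fraction of training rows per member (default 0.9).
    with_replacement : sample member bags with replacement (default off).
    pos_label : the label counted as "active" in vote fractions.
    random_state : seed pinning member bags and within-forest randomness.

    Attributes
    ----------
    members_ : the trained forests.
    classes_ : sorted class labels.
    """

    def __init__(
        self,
        n_members: int = 100,
        n_trees: int = 700,
        bag_fraction: float = 0.9,
        with_replacement: bool = False,
        pos_label=ACTIVE,
        random_state: int | None = None,
    ):
        self.n_members = n_members
        self.n_trees = n_trees
        self.bag_fraction = bag_fraction
        self.with_replacement = with_replacement
        self.pos_label = pos_label
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"expected a binary problem, got classes {self.classes_}")
        n = X.shape[0]
        bag_size = int(round(self.bag_fraction * n))
        for cls in self.classes_:
            if (y == cls).sum() < 2:
                raise ValueError(f"fewer than 2 training rows for class {cls!r}")
        if bag_size < 4:
            raise ValueError(
                f"bag of {bag_size} rows is too small to train a member forest"
            )
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.members_ = []
        for _ in range(self.n_members):
            idx = rng.choice(n, size=bag_size, replace=self.with_replacement)
            if len(np.unique(y[idx])) < 2:
                # resample until the bag holds both classes (rare at 90%)
                for _retry in range(100):
                    idx = rng.choice(n, size=bag_size, replace=self.with_replacement)
                    if len(np.unique(y[idx])) == 2:
                        break
                else:
                    raise ValueError("could not draw a bag containing both classes")
            member_seed = int(rng.integers(0, 2**31 - 1))
            forest = RandomForestClassifier(
                n_estimators=self.n_trees, random_state=member_seed, n_jobs=1
            )
            forest.fit(X[idx], y[idx])
            self.members_.append(forest)
        return self

    def vote_fraction_active(self, X) -> np.ndarray:
        """Fraction of members voting for the positive class, per row."""
        check_is_fitted(self, "members_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature count mismatch: fitted with {self.n_features_in_}, got {X.shape[1]}"
            )
        votes = np.zeros(X.shape[0])
        for forest in self.members_:
            votes += forest.predict(X) == self.pos_label
        return votes / len(self.members_)

    def predict_proba(self, X) -> np.ndarray:
        frac = self.vote_fraction_active(X)
        proba = np.empty((len(frac), 2))
        pos_col = int(np.where(self.classes_ == self.pos_label)[0][0])
        proba[:, pos_col] = frac
        proba[:, 1 - pos_col] = 1 - frac
        return proba

    def predict(self, X) -> np.ndarray:
        frac = self.vote_fraction_active(X)
        neg_label = self.classes_[self.classes_ != self.pos_label][0]
        return np.where(frac > 0.5, self.pos_label, neg_label)


def predict_majority(model: EnsembleForestClassifier, X, compound_ids=None) -> pd.DataFrame:
    """Majority-vote prediction records for a feature matrix.

    Columns: ``compound_id, vote_fraction_active, predicted_label``.
    Active iff vote fraction strictly exceeds 0.5.
    """
    frac = model.vote_fraction_active(X)
    neg_label = model.classes_[model.classes_ != model.pos_label][0]
    labels = np.where(frac > 0.5, model.pos_label, neg_label)
    if compound_ids is None:
        compound_ids = np.arange(len(frac))
    return pd.DataFrame(
        {
            "compound_id": np.asarray(compound_ids),
            "vote_fraction_active": frac,
            "predicted_label": labels,
        }
    )


@dataclass
class PerformanceMetrics:
    """Confusion counts plus precision and accuracy.

    ``precision_active`` = true actives / predicted actives, and
    symmetrically for inactives; either is None (undefined) when nothing
    is predicted in that class.
    """

    true_actives: int
    true_inactives: int
    predicted_actives: int
    predicted_inactives: int
    precision_active: float | None
    precision_inactive: float | None
    accuracy: float


def evaluate(predicted_labels, true_labels) -> PerformanceMetrics:
    """Precision-for-actives, precision-for-inactives and overall accuracy."""
    pred = np.asarray(predicted_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("predictions and labels are not aligned")
    pred_a = pred == ACTIVE
    pred_i = pred == INACTIVE
    true_a = int(np.sum(pred_a & (true == ACTIVE)))
    true_i = int(np.sum(pred_i & (true == INACTIVE)))
    n_pred_a = int(pred_a.sum())
    n_pred_i = int(pred_i.sum())
    return PerformanceMetrics(
        true_actives=true_a,
        true_inactives=true_i,
        predicted_actives=n_pred_a,
        predicted_inactives=n_pred_i,
        precision_active=true_a / n_pred_a if n_pred_a else None,
        precision_inactive=true_i / n_pred_i if n_pred_i else None,
        accuracy=(true_a + true_i) / len(pred) if len(pred) else float("nan"),
    )


@dataclass
class OptimizationResult:
    """Winning hyperparameters plus the full cross-validation table."""

    n_trees: int
    blocks: tuple
    cv_mean: float
    cv_sd: float
    table: pd.DataFrame


def block_combinations(blocks: Sequence[str] = FEATURE_BLOCKS) -> list[tuple]:
    """All non-empty combinations of the feature blocks (7 for 3 blocks)."""
    out = []
    for size in range(1, len(blocks) + 1):
        out.extend(combinations(blocks, size))
    return out


def optimize_hyperparameters(
    feature_blocks: Mapping[str, np.ndarray],
    y,
    trees_grid: Iterable[int] = tuple(range(100, 1001, 100)),
    blocks: Sequence[tuple] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> OptimizationResult:
    """Grid search over tree counts and feature-block combinations.

    Every (trees, block-combination) pair — 70 configurations on the
    full default grid — is scored by seeded stratified ``cv_folds``-fold
    cross-validation accuracy of a single random forest; the argmax is
    returned, with ties broken toward fewer trees, then fewer feature
    columns.  Folds are stratified so each holds both classes.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    combos = list(blocks) if blocks is not None else block_combinations(
        tuple(feature_blocks.keys())
    )
    trees_grid = list(trees_grid)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    rows = []
    for combo in combos:
        X = np.hstack([np.asarray(feature_blocks[b], dtype=float) for b in combo])
        for n_trees in trees_grid:
            accs = []
            for fold_seed, (tr, te) in enumerate(folds):
                forest = RandomForestClassifier(
                    n_estimators=n_trees, random_state=seed + fold_seed, n_jobs=1
                )
                forest.fit(X[tr], y[tr])
                accs.append(float(np.mean(forest.predict(X[te]) == y[te])))
            rows.append(
                {
                    "blocks": combo,
                    "n_trees": n_trees,
                    "n_features": X.shape[1],
                    "cv_mean": float(np.mean(accs)),
                    "cv_sd": float(np.std(accs, ddof=1)),
                }
            )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["cv_mean", "n_trees", "n_features"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    return OptimizationResult(
        n_trees=int(best["n_trees"]),
        blocks=tuple(best["blocks"]),
        cv_mean=float(best["cv_mean"]),
        cv_sd=float(best["cv_sd"]),
        table=table,
    )


def cross_validated_correctness(
    X, y, cv_folds: int = 10, seed: int = 0, n_trees: int = 100
) -> np.ndarray:
    """Per-row out-of-fold prediction correctness (bool) from stratified CV.

    This is the training-set correctness signal that the RDN
    applicability domain aggregates locally.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    correct = np.zeros(len(y), dtype=bool)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for fold_seed, (tr, te) in enumerate(skf.split(X, y)):
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + fold_seed, n_jobs=1
        )
        forest.fit(X[tr], y[tr])
        correct[te] = forest.predict(X[te]) == y[te]
    return correct


def _tanimoto_matrix(queries: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between binary row vectors."""
    q = queries.astype(bool)
    r = refs.astype(bool)
    inter = q.astype(np.int32) @ r.astype(np.int32).T
    qs = q.sum(axis=1)[:, None]
    rs = r.sum(axis=1)[None, :]
    union = qs + rs - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


class RDNReliability(BaseEstimator):
    """Reliability-density neighborhood applicability domain.

    The reliability of a query is the kernel-weighted mass of *correct*
    cross-validated training predictions in its fingerprint
    neighborhood:

        r(q) = sum_i correct_i * exp(-d(q, i)^2 / (2 * bandwidth^2))

    with d = 1 - Tanimoto similarity on a binary fingerprint block.
    Dense, well-predicted neighborhoods give high reliability; sparse or
    error-prone regions give low reliability.  The score is a sum, not
    an average, so adding a nearby correctly-predicted training compound
    can never lower it, and a query with no kernel support scores 0.

    Parameters
    ----------
    bandwidth : Gaussian kernel bandwidth on Tanimoto distance
        (default 0.25 — contributions decay sharply past ~0.5 distance).
    """

    def __init__(self, bandwidth: float = 0.25):
        self.bandwidth = bandwidth

    def fit(self, X, correct):
        """Store training fingerprints and their out-of-fold correctness."""
        X = np.asarray(X)
        correct = np.asarray(correct, dtype=bool)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if X.shape[0] != correct.shape[0]:
            raise ValueError("fingerprints and correctness flags are not aligned")
        self.X_ = X
        self.correct_ = correct
        return self

    def score_samples(self, Q) -> np.ndarray:
        """Reliability score for each query row (higher = more reliable)."""
        check_is_fitted(self, "X_")
        Q = np.asarray(Q)
        sim = _tanimoto_matrix(Q, self.X_)
        dist = 1.0 - sim
        kernel = np.exp(-(dist**2) / (2.0 * self.bandwidth**2))
        return kernel @ self.correct_.astype(float)


def ad_curve(predictions: pd.DataFrame, true_labels, cutoffs) -> pd.DataFrame:
    """Precision/coverage trade-off along an applicability-domain cutoff grid.

    ``predictions`` must carry ``predicted_label`` and ``reliability``
    columns.  At each cutoff, predictions with reliability >= cutoff are
    accepted; the table reports precision among accepted predicted
    actives (NaN when none) and the accepted fraction (coverage).
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("empty cutoff grid")
    if "reliability" not in predictions.columns:
        raise ValueError("predictions lack a reliability column")
    true = np.asarray(true_labels)
    rel = predictions["reliability"].to_numpy()
    pred = predictions["predicted_label"].to_numpy()
    rows = []
    for cut in cutoffs:
        accepted = rel >= cut
        pred_a = accepted & (pred == ACTIVE)
        n_pred_a = int(pred_a.sum())
        precision = float((true[pred_a] == ACTIVE).mean()) if n_pred_a else np.nan
        rows.append(
            {
                "cutoff": cut,
                "precision_active": precision,
                "coverage": float(accepted.mean()),
                "n_accepted": int(accepted.sum()),
                "n_predicted_active": n_pred_a,
            }
        )
    return pd.DataFrame(rows)
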