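"""Repeated k-fold cross-validation of the composite scores.

The union of the positive and negative sets is randomly partitioned into k
near-equal folds (unstratified by default, matching a plain random split).
Each fold serves once as the test set: weights are fitted on the other
k - 1 folds by simplex AUC maximization and AUC plus threshold-maximized
MCC are evaluated on the held-out fold.  The partitioning is repeated for
M independent realisations, giving k*M fold results per score; defaults
are k = 5, M = 25.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import SCORE_TERMS, WEIGHT_SYMBOLS
from .metrics import auc, ks_normality, max_mcc
from .model import CompositeScoreClassifier

logger = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05


@dataclasses.dataclass
class CVConfig:
    """Cross-validation settings (defaults k=5, M=25)."""

    k: int = 5
    M: int = 25
    seed: int = 0
    score: str = "s4"
    stratified: bool = False
    optimizer: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.score not in SCORE_TERMS:
            raise ValueError(f"unknown score {self.score!r}")


def kfold_partition(ids: Sequence, k: int, seed: int, labels=None, stratified: bool = False):
    """Random partition of ``ids`` into k disjoint folds of near-equal size.

    Sizes differ by at most 1; deterministic under ``seed``.  With
    ``stratified=True`` the class proportions of ``labels`` are preserved
    per fold (off by default: the plain split randomizes the class mix).
    """
    ids = np.asarray(ids)
    if k > ids.size:
        raise ValueError(f"k={k} exceeds number of items {ids.size}")
    rng = np.random.default_rng(seed)
    if not stratified:
        perm = rng.permutation(ids.size)
        return [ids[chunk] for chunk in np.array_split(perm, k)]
    if labels is None:
        raise ValueError("stratified partition requires labels")
    labels = np.asarray(labels)
    folds: list[list] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = members[rng.permutation(members.size)]
        for j, idx in enumerate(members):
            folds[(j + offset) % k].append(idx)
        offset += members.size % k
    return [ids[np.array(sorted(f), dtype=int)] for f in folds]


def _summary_stat(values: np.ndarray) -> tuple[float, float, bool]:
    """(location, sd, is_normal): mean when the KS flag accepts normality,
    median otherwise (the sd is reported either way)."""
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    try:
        normal = ks_normality(values) > NORMALITY_ALPHA
    except ValueError:
        normal = True  # too few / constant values: mean by convention
    loc = float(np.mean(values)) if normal else float(np.median(values))
    return loc, sd, normal


def cross_validate(
    features: pd.DataFrame,
    labels,
    config: CVConfig,
) -> tuple[pd.DataFrame, dict]:
    """Repeated k-fold CV of one composite score.

    Returns ``(folds, summary)``: one row per (realisation, fold) with the
    fitted weights and train/test metrics, and a summary dict with
    location +/- sd for test AUC, test MCC and each weight (mean when a KS
    flag accepts normality, median otherwise).  Folds whose training or
    test part contains a single class are skipped with a warning.
    """
    y = np.asarray(labels).astype(int).ravel()
    n = len(features)
    if y.shape[0] != n:
        raise ValueError("features and labels have different lengths")
    free, _ = SCORE_TERMS[config.score]
    ss = np.random.SeedSequence(config.seed)
    part_seeds = ss.spawn(config.M)
    rows = []
    for r, child in enumerate(part_seeds):
        child_seeds = child.generate_state(2)
        folds = kfold_partition(
            np.arange(n), config.k, int(child_seeds[0] % (2**31)),
            labels=y, stratified=config.stratified,
        )
        for j, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
                msg = f"realisation {r} fold {j}: single-class fold skipped"
                warnings.warn(msg, stacklevel=2)
                logger.warning(msg)
                continue
            est = CompositeScoreClassifier(
                score=config.score,
                random_state=int(child_seeds[1] % (2**31)) + j,
                **config.optimizer,
            )
            est.fit(features.iloc[train_idx], y[train_idx])
            s_test = est.decision_function(features.iloc[test_idx])
            test_auc = auc(s_test, y[test_idx])
            test_mcc, _ = max_mcc(s_test, y[test_idx])
            row = {"realisation": r, "fold": j}
            for t in free:
                row[WEIGHT_SYMBOLS[t]] = est.weights_[t]
            row.update(
                train_auc=est.train_auc_, test_auc=test_auc, test_mcc=test_mcc
            )
            rows.append(row)
    folds_df = pd.DataFrame(rows)
    summary: dict = {
        "score": config.score,
        "k": config.k,
        "M": config.M,
        "n_folds": len(folds_df),
    }
    if len(folds_df):
        for col in ["test_auc", "test_mcc", "train_auc"] + [WEIGHT_SYMBOLS[t] for t in free]:
            loc, sd, normal = _summary_stat(folds_df[col].to_numpy())
            summary[col] = {"value": loc, "sd": sd, "normal": normal}
    return folds_df, summary


def evaluate_fixed_score(
    scores, labels, folds: Sequence[np.ndarray]
) -> pd.DataFrame:
    """Per-fold test AUC/MCC of a pre-trained score (no fitting).

    Used to benchmark an externally trained predictor (e.g. the pi-pi
    score alone) on the same test folds as the cross-validated scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    rows = []
    for j, idx in enumerate(folds):
        idx = np.asarray(idx, dtype=int)
        if len(np.unique(y[idx])) < 2:
            warnings.warn(f"fold {j}: single-class fold skipped", stacklevel=2)
            continue
        fold_auc = auc(s[idx], y[idx])
        fold_mcc, _ = max_mcc(s[idx], y[idx])
        rows.append({"fold": j, "test_auc": fold_auc, "test_mcc": fold_mcc})
    return pd.DataFrame(rows)


def evaluate_fixed_score_cv(
    scores, labels, k: int = 5, M: int = 25, seed: int = 0
) -> pd.DataFrame:
    """Fixed-score evaluation over the same repeated partitions as
    :func:`cross_validate` (same seed derivation)."""
    n = np.asarray(scores).shape[0]
    ss = np.random.SeedSequence(seed)
    rows = []
    for r, child in enumerate(ss.spawn(M)):
        child_seeds = child.generate_state(2)
        folds = kfold_partition(np.arange(n), k, int(child_seeds[0] % (2**31)))
        df = evaluate_fixed_score(scores, labels, folds)
        df.insert(0, "realisation", r)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
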