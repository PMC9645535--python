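"""Cross-validation bookkeeping.

The reference protocol is 3-fold cross-validation over 75 cases with a
50:25 train:test split per fold: the cases are partitioned into three
disjoint test sets of 25, and each fold trains on the remaining 50.  Test
cases are always pre-augmentation originals; augmented copies inherit their
parent's fold assignment, so a fold trained with 10:1 offline augmentation
sees ``50 * (10 + 1) = 550`` training sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Fold", "make_folds", "augmented_training_size"]


@dataclass(frozen=True)
class Fold:
    index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"fold": self.index, "train_ids": list(self.train_ids),
                "test_ids": list(self.test_ids)}


def make_folds(case_ids: list[str], k: int = 3, n_train: int = 50,
               n_test: int = 25, seed: int = 0) -> list[Fold]:
    """Partition ``case_ids`` into ``k`` folds with disjoint test sets.

    Requires ``k * n_test <= len(case_ids)`` and
    ``n_train + n_test <= len(case_ids)``; each case appears in at most one
    test set, and every fold's train/test sets are disjoint.
    """
    ids = list(case_ids)
    n = len(ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k * n_test > n:
        raise ValueError(f"{k} disjoint test sets of {n_test} need >= "
                         f"{k * n_test} cases, got {n}")
    if n_train + n_test > n:
        raise ValueError("n_train + n_test exceeds the cohort size")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    folds = []
    for f in range(k):
        test = order[f * n_test:(f + 1) * n_test]
        rest = [c for c in order if c not in test]
        folds.append(Fold(f, tuple(rest[:n_train]), tuple(test)))
    return folds


def augmented_training_size(n_train: int, ratio: int) -> int:
    """Training sets per fold after ``ratio``:1 offline augmentation with
    originals retained (50 cases at 10:1 -> 550)."""
    return n_train * (ratio + 1)


def assign_augmented(fold: Fold, augmented_ids: dict[str, str]) -> Fold:
    """Extend a fold's training set with augmented copies of its training
    cases (``augmented_ids`` maps augmented id -> parent id).  Copies of
    test cases are never added: testing uses pre-augmentation originals."""
    train = set(fold.train_ids)
    extra = tuple(aid for aid, parent in augmented_ids.items()
                  if parent in train)
    return Fold(fold.index, fold.train_ids + extra, fold.test_ids)
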