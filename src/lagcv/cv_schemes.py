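"""Chronological split, the three fold plans, and CV error.

Three ways of cross-validating the training region of a daily time series:

* ``five_fold`` — days are randomly shuffled and dealt into k validation
  sets (the classic scheme, which ignores seriality);
* ``lobo`` — Leave-One-Block-Out: the region is cut into k contiguous
  blocks; each block in turn validates a model trained on all the others,
  earlier *and* later;
* ``tb`` — Temporal-Block (forward chaining): only blocks strictly before
  the validation block may train, so no future information ever predicts
  the past.  The default geometry cuts k+1 blocks so that exactly k
  validation errors exist; fold i trains on blocks 1..i and validates on
  block i+1, making the first fold's training set the smallest.

The CV error of a plan is the arithmetic mean of the per-fold validation
mean squared errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Fold:
    train: np.ndarray
    val: np.ndarray


@dataclass(frozen=True)
class FoldPlan:
    """Ordered (train, validation) index pairs over the training region."""

    scheme: str
    folds: tuple[Fold, ...]
    indices: np.ndarray  # the full training region the plan covers

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class CVResult:
    scheme: str
    hyperparameters: tuple[int, ...]
    fold_mses: tuple[float, ...]
    cv_error: float
    seed: int | None = None


def chronological_split(n: int, train_fraction: float = 0.70) -> tuple[np.ndarray, np.ndarray]:
    """First floor(n * fraction) days train; the contiguous remainder tests."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if n < 10:
        raise ValueError("need at least 10 days to split")
    n_train = int(np.floor(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("degenerate split: train and test must both be non-empty")
    idx = np.arange(n)
    return idx[:n_train], idx[n_train:]


def _blocks(indices: np.ndarray, n_blocks: int) -> list[np.ndarray]:
    """Contiguous blocks, sizes differing by <= 1, earlier blocks larger."""
    return [b for b in np.array_split(indices, n_blocks)]


def five_fold_folds(train_indices: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Randomly shuffled k-fold plan (day-level shuffling, seeded)."""
    train_indices = np.asarray(train_indices)
    _check_k(train_indices, k)
    if k < 2:
        raise ValueError("five_fold needs k >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(train_indices)
    val_sets = [np.sort(v) for v in np.array_split(perm, k)]
    folds = tuple(
        Fold(
            train=np.sort(np.concatenate([v for j, v in enumerate(val_sets) if j != i])),
            val=val_sets[i],
        )
        for i in range(k)
    )
    return FoldPlan(scheme="five_fold", folds=folds, indices=np.sort(train_indices))


def lobo_folds(train_indices: np.ndarray, k: int = 5) -> FoldPlan:
    """Leave-One-Block-Out: each contiguous block validates, the rest train."""
    train_indices = np.asarray(train_indices)
    _check_k(train_indices, k)
    if k < 2:
        raise ValueError("lobo needs k >= 2 (k = 1 would leave an empty training set)")
    blocks = _blocks(train_indices, k)
    folds = tuple(
        Fold(
            train=np.concatenate([b for j, b in enumerate(blocks) if j != i]),
            val=blocks[i],
        )
        for i in range(k)
    )
    return FoldPlan(scheme="lobo", folds=folds, indices=train_indices)


def tb_folds(train_indices: np.ndarray, k: int = 5, mode: str = "expanding") -> FoldPlan:
    """Temporal-Block plan with strict temporal precedence in every fold.

    ``mode="expanding"`` (default): k+1 blocks, fold i trains on blocks
    1..i and validates on block i+1 — k folds, training sets strictly
    growing.  ``mode="drop-first"``: k blocks, k-1 folds (the first block
    never validates).
    """
    train_indices = np.asarray(train_indices)
    if mode not in ("expanding", "drop-first"):
        raise ValueError("mode must be 'expanding' or 'drop-first'")
    n_blocks = k + 1 if mode == "expanding" else k
    if len(train_indices) < n_blocks:
        raise ValueError(f"need at least {n_blocks} days for {n_blocks} non-empty blocks")
    blocks = _blocks(train_indices, n_blocks)
    folds = tuple(
        Fold(train=np.concatenate(blocks[: i + 1]), val=blocks[i + 1])
        for i in range(n_blocks - 1)
    )
    return FoldPlan(scheme="tb", folds=folds, indices=train_indices)


def cv_error(fold_mses) -> float:
    """Arithmetic mean of the per-fold validation MSEs."""
    arr = np.asarray(list(fold_mses), dtype=float)
    if arr.size == 0:
        raise ValueError("no fold MSEs")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("fold MSEs must be finite and non-negative")
    return float(arr.mean())


def make_plan(
    scheme: str, train_indices: np.ndarray, k: int = 5, seed: int = 0, tb_mode: str = "expanding"
) -> FoldPlan:
    """Dispatch to the named scheme."""
    if scheme == "five_fold":
        return five_fold_folds(train_indices, k=k, seed=seed)
    if scheme == "lobo":
        return lobo_folds(train_indices, k=k)
    if scheme == "tb":
        return tb_folds(train_indices, k=k, mode=tb_mode)
    raise ValueError(f"unknown scheme {scheme!r}")


def run_cv(X, y, plan: FoldPlan, spec, continuous=None) -> CVResult:
    """Score one hyperparameter setting under a fold plan.

    For each fold the network is trained on the fold's training rows (input
    scaling statistics come from those rows only) and evaluated on the
    validation rows; the CV error is the mean of the fold MSEs.  Fold
    indices address rows of ``X`` positionally.
    """
    from . import ann_model  # local import: ann_model does not import us

    y = np.asarray(y, dtype=float)
    mses = []
    for i, fold in enumerate(plan.folds):
        fold_spec = spec.replace(seed=spec.seed + i)
        net = ann_model.train(
            _take(X, fold.train), y[fold.train], fold_spec, continuous=continuous
        )
        pred = net.predict(_take(X, fold.val))
        mses.append(ann_model.mse(pred, y[fold.val]))
    return CVResult(
        scheme=plan.scheme,
        hyperparameters=tuple(spec.hidden_layout),
        fold_mses=tuple(mses),
        cv_error=cv_error(mses),
        seed=spec.seed,
    )


def _take(X, rows):
    return X.iloc[rows] if hasattr(X, "iloc") else np.asarray(X)[rows]


def _check_k(indices: np.ndarray, k: int) -> None:
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(indices):
        raise ValueError(f"k={k} exceeds the {len(indices)} training days")
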