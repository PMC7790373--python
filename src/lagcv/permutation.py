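"""Permutation null, permutation ratio (PR) and its contribution complement.

Shuffling the outcome over the training region breaks every association
between mortality and the predictors while preserving the outcome's
marginal distribution; re-running the identical CV procedure on the
shuffled outcome yields the CV error a model can reach when there is
nothing to learn (essentially the outcome variance).  The permutation
ratio

    PR = min(1, CV_error(observed) / CV_error(permuted))

plays the role of 1 - R^2: values near 1 mean the model adds nothing,
and (1 - PR) * 100 is read as the percentage of prediction accuracy the
trained model contributes.

Only the outcome vector is permuted; the feature matrix (including lagged
mortality columns) is left fixed.  This is the minimal exchange that
breaks the outcome-predictor association — rebuilding lag features from a
shuffled series would also destroy the predictors' internal time
structure and change the null being tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cv_schemes import FoldPlan, run_cv


@dataclass(frozen=True)
class PRResult:
    cv_error_observed: float
    cv_error_permuted: float
    pr: float
    contribution_percent: float
    n_permutations: int
    seed: int | None = None


def permute_outcome(y, seed: int = 0) -> np.ndarray:
    """A uniformly random, seeded permutation of y (multiset preserved)."""
    y = np.asarray(y)
    if y.size < 2:
        raise ValueError("need at least two outcomes to permute")
    rng = np.random.default_rng(seed)
    return y[rng.permutation(y.size)]


def permuted_cv_error(
    X,
    y,
    plan: FoldPlan,
    spec,
    n_permutations: int = 1,
    seed: int = 0,
    continuous=None,
) -> float:
    """Mean CV error over permutation replicates of the training outcomes.

    Each replicate shuffles y across the whole training region once (same
    fold plan, same network spec as the observed run) — one realization per
    replicate, replicate seeds derived from ``seed``.  A single replicate
    matches how one permuted grid cell is produced; >= 20 replicates give
    stable PRs.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(y, dtype=float)
    region = plan.indices
    errors = []
    for r in range(n_permutations):
        y_perm = y.copy()
        y_perm[region] = permute_outcome(y[region], seed=seed + r)
        errors.append(run_cv(X, y_perm, plan, spec, continuous=continuous).cv_error)
    return float(np.mean(errors))


def permutation_ratio(cv_observed: float, cv_permuted: float) -> float:
    """min(1, observed / permuted); both errors must be positive."""
    if cv_observed <= 0 or cv_permuted <= 0:
        raise ValueError("CV errors must be positive")
    return min(1.0, cv_observed / cv_permuted)


def contribution(pr: float) -> float:
    """(1 - PR) * 100, the model's contribution to prediction accuracy, %."""
    if not 0 < pr <= 1:
        raise ValueError("PR must lie in (0, 1]")
    return (1.0 - pr) * 100.0


def pr_result(
    X, y, plan: FoldPlan, spec, n_permutations: int = 1, seed: int = 0, continuous=None
) -> PRResult:
    """Observed CV error, permuted CV error and the PR in one pass."""
    observed = run_cv(X, y, plan, spec, continuous=continuous).cv_error
    permuted = permuted_cv_error(
        X, y, plan, spec, n_permutations=n_permutations, seed=seed, continuous=continuous
    )
    pr = permutation_ratio(observed, permuted)
    return PRResult(
        cv_error_observed=observed,
        cv_error_permuted=permuted,
        pr=pr,
        contribution_percent=contribution(pr),
        n_permutations=n_permutations,
        seed=seed,
    )
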