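"""Artificial-masking evaluation of completion accuracy.

Recovery accuracy is scored the way tensor-completion benchmarks do: hide a
fraction of the *observed* entries (artificial missing values), refit on the
remainder, and compare imputed against held-out true values with the relative
standard error

    RSE = ||x_hat - x||_2 / ||x||_2     over the held-out index set,

which is 0 at perfect recovery and 1 for an all-zero imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .completion import TensorCompletionModel
from .errors import DataError, NumericError
from .tensor_data import ExpressionTensor, WeightMask

__all__ = [
    "MaskingExperiment",
    "make_artificial_missing",
    "rse",
    "missing_ratio",
    "grid_search_rank",
]


@dataclass
class MaskingExperiment:
    """A train/held-out split of the observed entries of a mask."""

    artificial_rate: float
    heldout_index: np.ndarray  # (n_heldout, ndim) integer coordinates
    train_mask: WeightMask
    seed: int


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def make_artificial_missing(mask: WeightMask | np.ndarray, rate: float, seed: int) -> MaskingExperiment:
    """Sample held-out entries uniformly without replacement from observed ones.

    The held-out count is ``rate`` times the observed count, rounded half away
    from zero.  The training mask is the input mask with held-out entries
    flipped to 0.
    """
    values = mask.values if isinstance(mask, WeightMask) else np.asarray(mask, dtype=float)
    if not 0 < rate < 1:
        raise DataError(f"rate must be in (0,1), got {rate}")
    observed = np.argwhere(values == 1)
    if observed.shape[0] == 0:
        raise DataError("mask has no observed entries")
    n_held = _round_half_away(rate * observed.shape[0])
    if n_held == 0:
        raise DataError(f"rate {rate} yields zero held-out entries of {observed.shape[0]} observed")
    rng = np.random.default_rng(seed)
    picks = rng.choice(observed.shape[0], size=n_held, replace=False)
    heldout = observed[np.sort(picks)]
    train = values.copy()
    train[tuple(heldout.T)] = 0.0
    return MaskingExperiment(rate, heldout, WeightMask(train), seed)


def rse(original, imputed, heldout_index: np.ndarray) -> float:
    """Relative L2 error between true and imputed values on the held-out set."""
    x = original.values if isinstance(original, ExpressionTensor) else np.asarray(original, dtype=float)
    xh = imputed.values if isinstance(imputed, ExpressionTensor) else np.asarray(imputed, dtype=float)
    heldout_index = np.asarray(heldout_index)
    if heldout_index.shape[0] == 0:
        raise DataError("empty held-out index")
    idx = tuple(heldout_index.T)
    truth = x[idx]
    pred = xh[idx]
    denom = float(np.sqrt(np.sum(truth * truth)))
    if denom == 0.0:
        raise NumericError("all held-out originals are zero: RSE undefined")
    return float(np.sqrt(np.sum((pred - truth) ** 2))) / denom


def missing_ratio(mask: WeightMask | np.ndarray) -> float:
    """Fraction of tensor entries that are missing (mask 0)."""
    values = mask.values if isinstance(mask, WeightMask) else np.asarray(mask, dtype=float)
    if values.size == 0:
        raise DataError("empty mask")
    return float((values == 0).sum() / values.size)


def grid_search_rank(
    tensor,
    mask: WeightMask | np.ndarray,
    method: str,
    candidate_ranks: Sequence,
    validation_rate: float = 0.1,
    seed: int = 0,
    max_iterations: int = 100,
):
    """Pick the rank with the lowest internal validation RSE.

    For every candidate, an internal validation set is masked at
    ``validation_rate`` (same split for all candidates), the model is fitted
    on the remainder, and the candidate with minimal validation RSE wins.
    Ties go to the smaller rank (smaller CP rank, or lexicographically
    smaller TT-rank sequence).
    """
    candidates = list(candidate_ranks)
    if not candidates:
        raise DataError("no candidate ranks")
    split = make_artificial_missing(mask, validation_rate, seed)
    data = tensor.values if isinstance(tensor, ExpressionTensor) else np.asarray(tensor, dtype=float)

    def size_key(r):
        return (r,) if np.isscalar(r) else tuple(r)

    best = None
    for cand in candidates:
        try:
            model = TensorCompletionModel(data, split.train_mask, method=method, rank=cand)
            res = model.fit(max_iterations=max_iterations, seed=seed)
        except Exception as exc:
            raise type(exc)(f"candidate rank {cand}: {exc}") from exc
        score = rse(data, res.impute(), split.heldout_index)
        key = (score, size_key(cand))
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1]
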