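"""Synthetic horizontally partitioned logistic datasets.

Generates the kind of data the secure pipeline is evaluated on: n records
with binary covariates, a trailing intercept column of ones, and outcomes
drawn from the logistic model at a chosen true coefficient vector.  The
reference evaluation shape is 60 records with 3 binary features (plus
intercept), split across 2-4 parties; the defaults reproduce it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .pipeline import PartyDataset

log = logging.getLogger(__name__)

DEFAULT_BETA = (1.0, 0.5, -0.5, 0.0)


@dataclass
class SimSpec:
    """Simulation specification.

    ``beta_true`` has one entry per binary feature plus a final intercept
    coefficient.  ``split`` gives per-party record counts (contiguous
    blocks); by default the records are divided as evenly as possible
    among ``h`` parties.
    """

    n: int = 60
    m_features: int = 3
    beta_true: Sequence[float] = DEFAULT_BETA
    feature_prob: float = 0.5
    h: int = 2
    split: Optional[Sequence[int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m_features < 1:
            raise ValueError("n and m_features must be positive")
        if not 0.0 < self.feature_prob < 1.0:
            raise ValueError("feature_prob must lie in (0, 1)")
        if len(self.beta_true) != self.m_features + 1:
            raise ValueError("beta_true must have m_features + 1 entries")
        if self.split is None:
            base, extra = divmod(self.n, self.h)
            self.split = tuple(base + (1 if i < extra else 0)
                               for i in range(self.h))
        self.split = tuple(int(s) for s in self.split)
        if sum(self.split) != self.n or any(s < 1 for s in self.split):
            raise ValueError("split must be positive and sum to n")


def generate(spec: SimSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Draw the pooled design and outcomes.

    Covariates are iid Bernoulli(feature_prob), the last column is the
    intercept, and y_i ~ Bernoulli(logistic(beta_true' x_i)).  A design
    with a constant covariate column cannot identify that coefficient, so
    such draws are rejected and regenerated from a derived sub-seed (with
    a warning); deterministic for a given seed either way.
    """
    beta = np.asarray(spec.beta_true, dtype=float)
    for attempt in range(64):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=spec.seed, spawn_key=(attempt,)))
        X = np.empty((spec.n, spec.m_features + 1))
        X[:, :-1] = (rng.random((spec.n, spec.m_features))
                     < spec.feature_prob).astype(float)
        X[:, -1] = 1.0
        degenerate = [j for j in range(spec.m_features)
                      if len(np.unique(X[:, j])) < 2]
        if degenerate:
            msg = (f"degenerate draw (constant feature column(s) "
                   f"{degenerate}); regenerating with sub-seed {attempt + 1}")
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        p = 1.0 / (1.0 + np.exp(-X @ beta))
        y = (rng.random(spec.n) < p).astype(float)
        return X, y
    raise RuntimeError("could not draw a non-degenerate design")


def partition(X: np.ndarray, y: np.ndarray,
              split: Sequence[int]) -> List[PartyDataset]:
    """Slice pooled data into contiguous per-party blocks."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if sum(split) != X.shape[0] or X.shape[0] != y.size:
        raise ValueError(f"split {tuple(split)} does not sum to n={X.shape[0]}")
    parties = []
    start = 0
    for s in split:
        parties.append(PartyDataset(X[start:start + s], y[start:start + s]))
        start += s
    return parties


def simulate_parties(spec: SimSpec) -> List[PartyDataset]:
    """Convenience: generate then partition per the spec."""
    X, y = generate(spec)
    return partition(X, y, spec.split)
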