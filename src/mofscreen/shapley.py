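"""Shapley-value feature attribution for model predictions.

Implements the interventional (background-conditioned) Shapley value: the
value of a coalition S is the model output with features in S taken from
the instance and the rest from a background sample, averaged over the
background rows.  Exact coalition enumeration is used for small feature
counts; otherwise a seeded permutation-sampling estimator.  The efficiency
axiom (base value + sum of attributions = prediction) holds exactly for
the exact method and by telescoping for the sampled one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np

__all__ = ["ShapleyExplanation", "shapley_explain"]

#: Exact enumeration is refused above this many features (2^d blow-up).
EXACT_HARD_LIMIT = 30
#: Default switch point between exact enumeration and permutation sampling.
EXACT_DEFAULT_LIMIT = 12


@dataclass
class ShapleyExplanation:
    attributions: np.ndarray
    base_value: float
    prediction: float
    method: str  # "exact" or "sampled(n_permutations=..., seed=...)"
    standard_errors: np.ndarray | None = None

    @property
    def efficiency_gap(self) -> float:
        return float(abs(self.base_value + self.attributions.sum() - self.prediction))


def shapley_explain(
    f: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    method: str = "auto",
    n_permutations: int = 2000,
    seed: int = 0,
) -> ShapleyExplanation:
    """Attribute ``f``'s output at ``x`` to its features.

    Parameters
    ----------
    f
        Vectorized model: maps an (n, d) array to n scalar outputs.
    x
        The instance to explain, shape (d,).
    background
        Non-empty (m, d) background sample defining "feature missing".
    method
        "exact", "sampled", or "auto" (exact iff d <= 12).
    """
    x = np.asarray(x, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    if background.ndim == 1:
        background = background.reshape(1, -1)
    if background.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    d = x.size
    if method == "auto":
        method = "exact" if d <= EXACT_DEFAULT_LIMIT else "sampled"
    if method == "exact":
        if d > EXACT_HARD_LIMIT:
            raise ValueError(
                f"exact enumeration over 2^{d} coalitions exceeds the combinatorial limit"
            )
        return _exact(f, x, background)
    if method == "sampled":
        return _sampled(f, x, background, n_permutations, seed)
    raise ValueError(f"unknown method {method!r}")


def _coalition_value(f, x, background, mask: np.ndarray) -> float:
    z = background.copy()
    z[:, mask] = x[mask]
    return float(np.mean(f(z)))


def _exact(f, x, background) -> ShapleyExplanation:
    d = x.size
    # cache v(S) for every coalition
    values: dict[int, float] = {}
    for size in range(d + 1):
        for subset in combinations(range(d), size):
            mask = np.zeros(d, dtype=bool)
            mask[list(subset)] = True
            values[frozenset(subset)] = _coalition_value(f, x, background, mask)
    phi = np.zeros(d)
    fact = math.factorial
    for i in range(d):
        others = [j for j in range(d) if j != i]
        for size in range(d):
            w = fact(size) * fact(d - size - 1) / fact(d)
            for subset in combinations(others, size):
                s = frozenset(subset)
                phi[i] += w * (values[s | {i}] - values[s])
    base = values[frozenset()]
    pred = values[frozenset(range(d))]
    return ShapleyExplanation(
        attributions=phi, base_value=base, prediction=pred, method="exact"
    )


def _sampled(f, x, background, n_permutations: int, seed: int) -> ShapleyExplanation:
    d = x.size
    m = background.shape[0]
    rng = np.random.default_rng(seed)
    contrib = np.zeros((n_permutations, d))
    base_samples = np.empty(n_permutations)
    pred = float(np.mean(f(x.reshape(1, -1))))
    for t in range(n_permutations):
        perm = rng.permutation(d)
        b = background[rng.integers(m)]
        # batch the d+1 states of this permutation into one model call
        states = np.tile(b, (d + 1, 1))
        z = b.copy()
        for step, i in enumerate(perm, start=1):
            z[i] = x[i]
            states[step] = z
        outs = np.asarray(f(states), dtype=float).ravel()
        base_samples[t] = outs[0]
        contrib[t, perm] = np.diff(outs)
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / math.sqrt(n_permutations)
    base = float(base_samples.mean())
    return ShapleyExplanation(
        attributions=phi,
        base_value=base,
        prediction=pred,
        method=f"sampled(n_permutations={n_permutations}, seed={seed})",
        standard_errors=se,
    )
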