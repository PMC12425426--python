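"""Adaptive synthetic (ADASYN) oversampling of minority classes.

ADASYN allocates the synthetic-sample budget adaptively: each minority point
x_i is weighted by r_i, the fraction of its K nearest neighbours (searched
among *all* points) that belong to other classes, so synthesis concentrates
near the class border where the minority class is hardest to learn. Each
synthetic point is a convex combination s = x_i + lambda * (x_z - x_i) of
its parent x_i and a same-class neighbour x_z, with lambda ~ Uniform[0, 1].

For more than two classes every minority class is oversampled one-vs-rest
against the pooled remainder; the largest class is left untouched. The
implementation is written from first principles (neighbour queries go
through sklearn's NearestNeighbors); it is intended to run inside each
training fold, after standardisation, so test rows are never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = ["AdasynConfig", "AdasynOversampler", "adasyn_oversample",
           "per_class_budgets", "largest_remainder_round"]


@dataclass
class AdasynConfig:
    """K nearest neighbours, balance level beta in [0, 1] (1 = fully
    balanced), distance metric, and the RNG seed."""

    k: int = 5
    beta: float = 1.0
    metric: str = "euclidean"
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")


def largest_remainder_round(weights: np.ndarray, total: int) -> np.ndarray:
    """Non-negative integers proportional to ``weights`` summing to ``total``.

    Floors the ideal real-valued allocation and hands the remaining units to
    the largest fractional parts (ties broken by index for determinism), so
    two equal weights receive budgets differing by at most one and the
    allocation is monotone in the weights.
    """
    weights = np.asarray(weights, dtype=float)
    if total == 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    ideal = weights / weights.sum() * total
    base = np.floor(ideal).astype(int)
    short = total - base.sum()
    if short > 0:
        frac = ideal - base
        order = np.lexsort((np.arange(len(frac)), -frac))
        base[order[:short]] += 1
    return base


class AdasynOversampler(BaseEstimator):
    """sklearn-style resampler implementing the adaptive synthetic scheme.

    Parameters mirror :class:`AdasynConfig`. After :meth:`fit_resample` the
    attributes ``synthetic_mask_`` (True for generated rows) and
    ``synthetic_provenance_`` (parent index, partner index, lambda per
    synthetic row, indices into the input X) are available.
    """

    def __init__(self, k: int = 5, beta: float = 1.0,
                 metric: str = "euclidean", seed: int = 0) -> None:
        self.k = k
        self.beta = beta
        self.metric = metric
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _border_weights(self, X: np.ndarray, minority_idx: np.ndarray,
                        is_other: np.ndarray) -> np.ndarray:
        """r_i = (# other-class points among the K nearest of x_i) / K."""
        k = min(self.k, len(X) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1, metric=self.metric).fit(X)
        _, idx = nn.kneighbors(X[minority_idx])
        r = np.empty(len(minority_idx))
        for row, (i, neigh) in enumerate(zip(minority_idx, idx)):
            neigh = neigh[neigh != i][:k]
            r[row] = is_other[neigh].mean()
        return r

    def _budgets_for_class(
        self, X: np.ndarray, y: np.ndarray, cls, m_majority: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(minority indices, per-point synthesis counts) for one class.

        The budget G = (m_majority - m_minority) * beta brings the class up
        to the largest class's size at beta = 1; border weights r_i count
        neighbours of *any* other class (one-vs-rest pooling).
        """
        minority_idx = np.flatnonzero(y == cls)
        m_minority = len(minority_idx)
        g_total = int(round((m_majority - m_minority) * self.beta))
        if g_total <= 0:
            return minority_idx, np.zeros(m_minority, dtype=int)
        if m_minority < 2:
            raise ValueError(
                f"minority class {cls!r} has fewer than 2 members; "
                "no synthesis partner exists"
            )
        r = self._border_weights(X, minority_idx, is_other=(y != cls))
        if r.sum() == 0.0:
            warnings.warn(
                f"class {cls!r}: no borderline minority points (all r_i = 0); "
                "falling back to uniform per-point budgets", stacklevel=2,
            )
            r = np.ones_like(r)
        return minority_idx, largest_remainder_round(r, g_total)

    # -- public API --------------------------------------------------------

    def per_class_budgets(self, X, y) -> dict:
        """Per-point synthesis counts for every class needing oversampling."""
        AdasynConfig(self.k, self.beta, self.metric, self.seed).validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        largest = classes[np.argmax(counts)]
        m_majority = int(counts.max())
        out = {}
        for cls in classes:
            if cls == largest:
                continue
            idx, budgets = self._budgets_for_class(X, y, cls, m_majority)
            out[cls] = {"indices": idx, "budgets": budgets}
        return out

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X_resampled, y_resampled)``: originals first, unchanged,
        followed by the synthetic rows."""
        AdasynConfig(self.k, self.beta, self.metric, self.seed).validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        budgets = self.per_class_budgets(X, y)

        new_rows: list[np.ndarray] = []
        new_labels: list = []
        provenance: list[tuple[int, int, float]] = []
        for cls in sorted(budgets, key=str):
            idx = budgets[cls]["indices"]
            counts = budgets[cls]["budgets"]
            if counts.sum() == 0:
                continue
            k = min(self.k, len(idx) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1, metric=self.metric)
            nn.fit(X[idx])
            _, neigh = nn.kneighbors(X[idx])
            for row, (i, g) in enumerate(zip(idx, counts)):
                partners = idx[neigh[row][neigh[row] != row][:k]]
                for _ in range(int(g)):
                    z = partners[rng.integers(len(partners))]
                    lam = rng.uniform()
                    new_rows.append(X[i] + lam * (X[z] - X[i]))
                    new_labels.append(cls)
                    provenance.append((int(i), int(z), float(lam)))

        n_orig = len(X)
        if new_rows:
            X_out = np.vstack([X, np.asarray(new_rows)])
            y_out = np.concatenate([y, np.asarray(new_labels, dtype=y.dtype)])
        else:
            X_out, y_out = X.copy(), y.copy()
        self.synthetic_mask_ = np.concatenate(
            [np.zeros(n_orig, dtype=bool), np.ones(len(new_rows), dtype=bool)]
        )
        self.synthetic_provenance_ = provenance
        return X_out, y_out


def adasyn_oversample(X, y, cfg: AdasynConfig | None = None):
    """Functional wrapper: returns ``(X', y', synthetic_mask)``."""
    cfg = cfg or AdasynConfig()
    sampler = AdasynOversampler(k=cfg.k, beta=cfg.beta, metric=cfg.metric,
                                seed=cfg.seed)
    X_out, y_out = sampler.fit_resample(X, y)
    return X_out, y_out, sampler.synthetic_mask_


def per_class_budgets(X, y, cfg: AdasynConfig | None = None) -> dict:
    cfg = cfg or AdasynConfig()
    sampler = AdasynOversampler(k=cfg.k, beta=cfg.beta, metric=cfg.metric,
                                seed=cfg.seed)
    return sampler.per_class_budgets(X, y)
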