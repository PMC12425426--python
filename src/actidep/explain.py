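"""Model-agnostic attribution: coalitional Shapley values and LIME surrogates.

The Shapley value of feature i for model f at instance x is

    phi_i = sum over S subset of N\\{i} of
            |S|! (|N| - |S| - 1)! / |N|!  *  [v(S + i) - v(S)]

with the value function v(S) = the model's expected output when features in
S take their values from x and the remaining features are replaced by
baseline values — here averaged over a background sample of training rows
(a single baseline vector is a background of size one). The exact computation
enumerates every coalition and is feasible up to ``p_limit`` features; a
permutation-sampling estimator covers larger p, with efficiency restored by
an additive renormalisation that is flagged in the output.

LIME fits a proximity-weighted ridge surrogate over a binary quartile-bin
representation of perturbed samples around x, yielding signed threshold
rules such as ``0.74 < autocorr <= 0.78``.

Global importance is the mean absolute attribution across a set of
explanations; rankings from different models are compared within each
model's own scale (rank correlation and top-k overlap), never across raw
magnitudes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.linear_model import Ridge

__all__ = [
    "BackgroundReference",
    "ShapleyExplanation",
    "LimeExplanation",
    "ImportanceRanking",
    "exact_shapley",
    "sampled_shapley",
    "lime_explain",
    "global_importance",
    "compare_model_explanations",
    "ExactShapleyExplainer",
    "PermutationShapleyExplainer",
    "LimeTabularExplainer",
]

ModelFn = Callable[[np.ndarray], np.ndarray]


@dataclass
class BackgroundReference:
    """Replacement source for out-of-coalition features.

    ``rows`` is an (n, p) array of training rows (n = 1 reproduces a single
    fixed baseline vector). Feature order must match the model's input.
    """

    rows: np.ndarray
    feature_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.size == 0:
            raise ValueError("background must be non-empty")

    @property
    def n_features(self) -> int:
        return self.rows.shape[1]

    @classmethod
    def subsample(cls, X: np.ndarray, size: int = 50, seed: int = 0,
                  feature_names: Optional[list[str]] = None
                  ) -> "BackgroundReference":
        X = np.asarray(X, dtype=float)
        if len(X) <= size:
            return cls(X, feature_names)
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(X), size=size, replace=False)
        return cls(X[idx], feature_names)


@dataclass
class ShapleyExplanation:
    instance_id: str
    phi: np.ndarray
    base_value: float
    fx: float
    feature_names: Optional[list[str]] = None
    class_index: Optional[int] = None
    renormalized: bool = False

    def to_dict(self) -> dict:
        names = self.feature_names or [f"f{i}" for i in range(len(self.phi))]
        return {
            "instance_id": self.instance_id,
            "phi": dict(zip(names, map(float, self.phi))),
            "base_value": self.base_value,
            "fx": self.fx,
            "class_index": self.class_index,
            "renormalized": self.renormalized,
        }


def _masked_values(
    model_fn: ModelFn, x: np.ndarray, background: BackgroundReference,
    masks: np.ndarray, chunk: int = 262144,
) -> np.ndarray:
    """v(S) for each boolean coalition mask: mean over background rows of
    the model applied to x with out-of-S features replaced."""
    n_bg = len(background.rows)
    p = background.n_features
    out = np.empty(len(masks))
    rows_per_mask = n_bg
    masks_per_chunk = max(1, chunk // rows_per_mask)
    for start in range(0, len(masks), masks_per_chunk):
        batch = masks[start:start + masks_per_chunk]
        # impose x on in-coalition features, background elsewhere
        data = np.where(batch[:, None, :], x[None, None, :],
                        background.rows[None, :, :])
        preds = np.asarray(model_fn(data.reshape(-1, p)), dtype=float)
        out[start:start + len(batch)] = preds.reshape(len(batch), n_bg).mean(axis=1)
    return out


def exact_shapley(
    model_fn: ModelFn,
    x: np.ndarray,
    background: BackgroundReference | np.ndarray,
    p_limit: int = 16,
    instance_id: str = "instance",
    feature_names: Optional[list[str]] = None,
    class_index: Optional[int] = None,
) -> ShapleyExplanation:
    """Exact Shapley attribution by full coalition enumeration.

    Evaluates v on all 2^p coalitions (batched through the model) and
    combines marginal contributions with the coalitional weights
    |S|!(p-|S|-1)!/p!. Raises for p > ``p_limit`` — use
    :func:`sampled_shapley` instead.
    """
    if not isinstance(background, BackgroundReference):
        background = BackgroundReference(background, feature_names)
    x = np.asarray(x, dtype=float).ravel()
    p = len(x)
    if p != background.n_features:
        raise ValueError("instance and background dimensions differ")
    if p > p_limit:
        raise ValueError(
            f"p={p} exceeds p_limit={p_limit}; use sampled_shapley for "
            "larger feature sets"
        )
    masks = np.zeros((2**p, p), dtype=bool)
    for s, subset in enumerate(itertools.product([False, True], repeat=p)):
        masks[s] = subset
    v = _masked_values(model_fn, x, background, masks)
    # index coalitions by bitmask for O(1) lookup of v(S) and v(S + i)
    bit = 2 ** np.arange(p)[::-1]
    code = masks @ bit
    v_by_code = np.empty(2**p)
    v_by_code[code] = v

    fact = [math.factorial(i) for i in range(p + 1)]
    phi = np.zeros(p)
    sizes = masks.sum(axis=1)
    for i in range(p):
        without_i = ~masks[:, i]
        s_masks = masks[without_i]
        s_codes = code[without_i]
        s_sizes = sizes[without_i]
        w = np.array(
            [fact[s] * fact[p - s - 1] / fact[p] for s in s_sizes]
        )
        phi[i] = float(np.sum(w * (v_by_code[s_codes + bit[i]] - v_by_code[s_codes])))
    base = float(v_by_code[0])
    fx = float(v_by_code[2**p - 1])
    return ShapleyExplanation(
        instance_id=instance_id, phi=phi, base_value=base, fx=fx,
        feature_names=feature_names or background.feature_names,
        class_index=class_index,
    )


def sampled_shapley(
    model_fn: ModelFn,
    x: np.ndarray,
    background: BackgroundReference | np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
    instance_id: str = "instance",
    feature_names: Optional[list[str]] = None,
    class_index: Optional[int] = None,
) -> ShapleyExplanation:
    """Permutation-sampling Shapley estimate (unbiased before adjustment).

    For each random feature ordering, features are inserted one by one and
    their marginal value-function gains accumulated. The final attributions
    are additively renormalised so the efficiency identity
    ``sum(phi) = f(x) - v(empty)`` holds exactly; the adjustment is flagged
    via ``renormalized=True``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if not isinstance(background, BackgroundReference):
        background = BackgroundReference(background, feature_names)
    x = np.asarray(x, dtype=float).ravel()
    p = len(x)
    rng = np.random.default_rng(seed)
    n_bg = len(background.rows)

    # one prefix-coalition mask per (permutation, step): step j imposes the
    # first j features of the permutation; step 0 is the empty coalition
    perms = np.array([rng.permutation(p) for _ in range(n_permutations)])
    masks = np.zeros((n_permutations, p + 1, p), dtype=bool)
    for r in range(n_permutations):
        for j in range(p):
            masks[r, j + 1] = masks[r, j]
            masks[r, j + 1, perms[r, j]] = True
    v = _masked_values(model_fn, x, background, masks.reshape(-1, p))
    v = v.reshape(n_permutations, p + 1)

    phi = np.zeros(p)
    gains = np.diff(v, axis=1)  # marginal gain at each insertion step
    for r in range(n_permutations):
        phi[perms[r]] += gains[r]
    phi /= n_permutations

    base = float(v[:, 0].mean())
    fx = float(v[:, -1].mean())
    residual = (fx - base) - phi.sum()
    phi += residual / p
    return ShapleyExplanation(
        instance_id=instance_id, phi=phi, base_value=base, fx=fx,
        feature_names=feature_names or background.feature_names,
        class_index=class_index, renormalized=True,
    )


# ---------------------------------------------------------------------------
# LIME: proximity-weighted ridge surrogate over quartile-bin indicators


@dataclass
class LimeExplanation:
    instance_id: str
    rules: list[tuple[str, float]]
    intercept: float
    r_squared: float
    kernel_width: float
    n_samples: int
    seed: int
    excluded_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "rules": [{"rule": r, "weight": w} for r, w in self.rules],
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "kernel_width": self.kernel_width,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "excluded_features": self.excluded_features,
        }


def _quartile_edges(training: np.ndarray) -> np.ndarray:
    """(5, p) array of min/q25/q50/q75/max per feature."""
    return np.quantile(training, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)


def _bin_of(value: float, edges: np.ndarray) -> int:
    """Quartile bin 0..3 of a scalar given its feature's 5 edges."""
    inner = edges[1:4]
    return int(np.searchsorted(inner, value, side="left"))


def _rule_string(name: str, b: int, edges: np.ndarray) -> str:
    q1, q2, q3 = edges[1], edges[2], edges[3]
    if b == 0:
        return f"{name} <= {q1:.4g}"
    if b == 1:
        return f"{q1:.4g} < {name} <= {q2:.4g}"
    if b == 2:
        return f"{q2:.4g} < {name} <= {q3:.4g}"
    return f"{name} > {q3:.4g}"


def lime_explain(
    model_fn: ModelFn,
    x: np.ndarray,
    training: np.ndarray,
    feature_names: Optional[list[str]] = None,
    n_samples: int = 5000,
    kernel_width: Optional[float] = None,
    top_k: int = 10,
    seed: int = 0,
    instance_id: str = "instance",
) -> LimeExplanation:
    """Local threshold-rule surrogate around one instance.

    Features are discretised into quartile bins of the training data; each
    perturbed sample draws a bin per feature uniformly and a value uniformly
    within that bin, and is represented by the binary indicator "falls in
    the same bin as x". Samples are weighted by exp(-d^2 / w^2) with d the
    Euclidean distance in indicator space and w = 0.75 * sqrt(p) by default;
    a ridge regression on the indicators yields signed rule weights and the
    weighted R^2 of the local fit. Features with degenerate spread (all
    quartiles equal) are excluded with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    training = np.atleast_2d(np.asarray(training, dtype=float))
    p = len(x)
    names = feature_names or [f"f{i}" for i in range(p)]
    if kernel_width is None:
        kernel_width = 0.75 * math.sqrt(p)
    rng = np.random.default_rng(seed)

    edges = _quartile_edges(training)
    degenerate = [j for j in range(p) if edges[1, j] == edges[3, j]]
    if degenerate:
        warnings.warn(
            "degenerate spread, excluded from rules: "
            + ", ".join(names[j] for j in degenerate),
            stacklevel=2,
        )
    usable = [j for j in range(p) if j not in degenerate]

    x_bins = np.array([_bin_of(x[j], edges[:, j]) for j in range(p)])
    bins = rng.integers(0, 4, size=(n_samples, p))
    lo = edges[bins, np.arange(p)]
    hi = edges[bins + 1, np.arange(p)]
    values = lo + rng.uniform(size=(n_samples, p)) * (hi - lo)
    # first sample is the instance itself, as in standard LIME
    values[0] = x
    bins[0] = x_bins

    z = (bins == x_bins[None, :]).astype(float)
    dist = np.sqrt(((1.0 - z) ** 2).sum(axis=1))
    sample_weight = np.exp(-(dist**2) / kernel_width**2)
    f = np.asarray(model_fn(values), dtype=float)

    design = z[:, usable]
    ridge = Ridge(alpha=1.0)
    ridge.fit(design, f, sample_weight=sample_weight)
    r2 = float(ridge.score(design, f, sample_weight=sample_weight))

    coefs = ridge.coef_
    order = np.argsort(-np.abs(coefs), kind="stable")[:top_k]
    rules = [
        (_rule_string(names[usable[o]], x_bins[usable[o]], edges[:, usable[o]]),
         float(coefs[o]))
        for o in order
    ]
    return LimeExplanation(
        instance_id=instance_id, rules=rules,
        intercept=float(ridge.intercept_), r_squared=r2,
        kernel_width=float(kernel_width), n_samples=n_samples, seed=seed,
        excluded_features=[names[j] for j in degenerate],
    )


# ---------------------------------------------------------------------------
# Global importance and cross-model comparison


@dataclass
class ImportanceRanking:
    """Features ordered by mean absolute attribution, for one model."""

    feature_names: list[str]
    importance: np.ndarray
    model_tag: str = ""

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        order = np.argsort(-self.importance, kind="stable")
        self.feature_names = [self.feature_names[i] for i in order]
        self.importance = self.importance[order]

    def rank_of(self, feature: str) -> int:
        """1-based rank of a feature in the ordering."""
        return self.feature_names.index(feature) + 1

    def top(self, k: int) -> list[str]:
        return self.feature_names[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_names, "mean_abs_attribution":
             self.importance, "model": self.model_tag}
        )


def global_importance(
    explanations: Sequence[ShapleyExplanation], model_tag: str = ""
) -> ImportanceRanking:
    """Mean |phi| per feature across explanations (classes pooled)."""
    if not explanations:
        raise ValueError("need at least one explanation")
    names = explanations[0].feature_names
    for e in explanations:
        if e.feature_names != names or len(e.phi) != len(explanations[0].phi):
            raise ValueError("explanations have inconsistent feature sets")
    mat = np.abs(np.vstack([e.phi for e in explanations]))
    names = names or [f"f{i}" for i in range(mat.shape[1])]
    return ImportanceRanking(
        feature_names=list(names), importance=mat.mean(axis=0),
        model_tag=model_tag,
    )


def compare_model_explanations(
    rank_a: ImportanceRanking, rank_b: ImportanceRanking, top_k: int = 3
) -> dict:
    """Rank agreement between two models' importance orderings.

    Works on ranks within each model's own attribution scale (the raw
    magnitudes of different architectures are not comparable). Reports the
    Spearman rank correlation, top-k overlap and per-feature rank deltas.
    """
    if set(rank_a.feature_names) != set(rank_b.feature_names):
        raise ValueError("rankings cover different feature sets")
    features = sorted(rank_a.feature_names)
    ra = np.array([rank_a.rank_of(f) for f in features], dtype=float)
    rb = np.array([rank_b.rank_of(f) for f in features], dtype=float)
    rho = float(sp_stats.spearmanr(ra, rb).statistic)
    overlap = len(set(rank_a.top(top_k)) & set(rank_b.top(top_k)))
    return {
        "spearman_rho": rho,
        "top_k": top_k,
        "top_k_overlap": overlap,
        "rank_deltas": {
            f: int(rank_a.rank_of(f) - rank_b.rank_of(f)) for f in features
        },
        "models": (rank_a.model_tag, rank_b.model_tag),
    }


# ---------------------------------------------------------------------------
# sklearn-style explainer classes (thin stateful wrappers)


class _BaseExplainer:
    def get_params(self, deep: bool = True) -> dict:
        return {k: v for k, v in self.__dict__.items()
                if not k.endswith("_")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


class ExactShapleyExplainer(_BaseExplainer):
    """Exact coalitional Shapley explainer bound to a background sample."""

    def __init__(self, model_fn: ModelFn, p_limit: int = 16) -> None:
        self.model_fn = model_fn
        self.p_limit = p_limit

    def fit(self, background: np.ndarray,
            feature_names: Optional[list[str]] = None
            ) -> "ExactShapleyExplainer":
        self.background_ = BackgroundReference(background, feature_names)
        return self

    def explain(self, x: np.ndarray, instance_id: str = "instance",
                class_index: Optional[int] = None) -> ShapleyExplanation:
        return exact_shapley(
            self.model_fn, x, self.background_, p_limit=self.p_limit,
            instance_id=instance_id, class_index=class_index,
        )


class PermutationShapleyExplainer(_BaseExplainer):
    """Permutation-sampling Shapley explainer for larger feature sets."""

    def __init__(self, model_fn: ModelFn, n_permutations: int = 200,
                 seed: int = 0) -> None:
        self.model_fn = model_fn
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, background: np.ndarray,
            feature_names: Optional[list[str]] = None
            ) -> "PermutationShapleyExplainer":
        self.background_ = BackgroundReference(background, feature_names)
        return self

    def explain(self, x: np.ndarray, instance_id: str = "instance",
                class_index: Optional[int] = None) -> ShapleyExplanation:
        return sampled_shapley(
            self.model_fn, x, self.background_,
            n_permutations=self.n_permutations, seed=self.seed,
            instance_id=instance_id, class_index=class_index,
        )


class LimeTabularExplainer(_BaseExplainer):
    """LIME threshold-rule explainer bound to a training summary."""

    def __init__(self, model_fn: ModelFn, n_samples: int = 5000,
                 kernel_width: Optional[float] = None, top_k: int = 10,
                 seed: int = 0) -> None:
        self.model_fn = model_fn
        self.n_samples = n_samples
        self.kernel_width = kernel_width
        self.top_k = top_k
        self.seed = seed

    def fit(self, training: np.ndarray,
            feature_names: Optional[list[str]] = None
            ) -> "LimeTabularExplainer":
        self.training_ = np.atleast_2d(np.asarray(training, dtype=float))
        self.feature_names_ = feature_names
        return self

    def explain(self, x: np.ndarray, instance_id: str = "instance"
                ) -> LimeExplanation:
        return lime_explain(
            self.model_fn, x, self.training_,
            feature_names=self.feature_names_, n_samples=self.n_samples,
            kernel_width=self.kernel_width, top_k=self.top_k,
            seed=self.seed, instance_id=instance_id,
        )
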