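"""Mixed voting: individual weights, group weights, and their convex blend.

All ensemble weights live on the n-simplex (nonnegative, summing to 1).  Three
mechanisms are provided:

* **Individual voting** — each base model in turn is designated primary and a
  weight vector is fitted from a primary-heavy prior by multiplicative,
  accuracy-proportional updates; the n fitted vectors are combined with
  exponential-accuracy coefficients  alpha_i = exp(A_i) / sum_j exp(A_j).
* **Group voting** — random simplex starting points are evolved by the same
  accuracy-proportional update each epoch and the trajectory point with the
  highest validation accuracy is selected.
* **Mixed voting** — W = beta1 * W_group + (1 - beta1) * W_individual, with
  beta1 = 0.2 by default.

Validation accuracies A_i are taken as fractions in [0, 1]; a ``temperature``
parameter sharpens or flattens the exponential coefficients for users who
want winner-take-all behavior.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "WeightVector",
    "AccuracyVector",
    "accuracy_coefficients",
    "combine_individual",
    "fit_individual_weight_set",
    "group_update",
    "group_select",
    "generate_group_candidates",
    "mixed_combine",
]

_SIMPLEX_ATOL = 1e-9


@dataclasses.dataclass(frozen=True)
class WeightVector:
    """A point on the n-simplex: nonnegative entries summing to 1."""

    w: np.ndarray

    def __init__(self, w: Sequence[float] | np.ndarray):
        arr = np.asarray(w, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError(f"weights must be a nonempty 1-D vector, got shape {arr.shape}")
        if np.any(arr < -_SIMPLEX_ATOL):
            raise ValueError(f"weights must be nonnegative, got {arr}")
        s = arr.sum()
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError(f"weights must sum to 1, got sum {s}")
        arr = np.clip(arr, 0.0, None)
        object.__setattr__(self, "w", arr / arr.sum())

    def __len__(self) -> int:
        return self.w.size

    def __getitem__(self, i: int) -> float:
        return float(self.w[i])


@dataclasses.dataclass(frozen=True)
class AccuracyVector:
    """Per-model validation accuracies on a declared scale."""

    a: np.ndarray
    scale: str = "fraction"

    def __init__(self, a: Sequence[float] | np.ndarray, scale: str = "fraction"):
        arr = np.asarray(a, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("accuracies must be a nonempty 1-D vector")
        if scale not in ("fraction", "percent"):
            raise ValueError(f"scale must be 'fraction' or 'percent', got {scale!r}")
        hi = 1.0 if scale == "fraction" else 100.0
        if np.any(arr < 0) or np.any(arr > hi):
            raise ValueError(f"accuracies out of range for scale {scale!r}: {arr}")
        object.__setattr__(self, "a", arr)
        object.__setattr__(self, "scale", scale)

    def as_fraction(self) -> np.ndarray:
        return self.a / 100.0 if self.scale == "percent" else self.a.copy()


def accuracy_coefficients(acc: AccuracyVector, temperature: float = 1.0) -> np.ndarray:
    """Exponential-accuracy coefficients alpha_i = exp(A_i/T) / sum_j exp(A_j/T).

    Accuracies are converted to fractions first, so equal accuracies give the
    uniform vector and the mapping is strictly monotone in A_i.  Computed with
    max-subtraction for numerical stability.
    """
    a = acc.as_fraction() / float(temperature)
    z = a - a.max()
    e = np.exp(z)
    return e / e.sum()


def combine_individual(
    weight_sets: Sequence[WeightVector], alphas: Sequence[float] | np.ndarray
) -> WeightVector:
    """Convex combination of the n per-primary weight sets: W_i = sum_k alpha_k W_k."""
    alphas = np.asarray(alphas, dtype=float)
    if len(weight_sets) != alphas.size:
        raise ValueError(
            f"{len(weight_sets)} weight sets but {alphas.size} mixing coefficients"
        )
    n = len(weight_sets[0])
    if any(len(ws) != n for ws in weight_sets):
        raise ValueError("all weight sets must have equal length")
    stacked = np.stack([ws.w for ws in weight_sets])  # (n_sets, n)
    return WeightVector(alphas @ stacked)


def primary_prior(n: int, primary_index: int, primary_mass: float = 0.55) -> WeightVector:
    """Primary-heavy starting point: ``primary_mass`` on the primary model,
    the rest shared equally (0.55 / 0.15 x 3 for n = 4)."""
    if not 0 <= primary_index < n:
        raise ValueError(f"primary_index {primary_index} out of range for n={n}")
    w = np.full(n, (1.0 - primary_mass) / (n - 1)) if n > 1 else np.array([1.0])
    if n > 1:
        w[primary_index] = primary_mass
    return WeightVector(w)


def _multiplicative_update(w: np.ndarray, a: np.ndarray) -> np.ndarray:
    wa = w * a
    s = wa.sum()
    if s <= 0:
        raise ValueError("accuracy-weighted mass is zero; cannot update weights")
    return wa / s


def fit_individual_weight_set(
    primary_index: int,
    accuracies_per_epoch: Iterable[AccuracyVector],
    primary_mass: float = 0.55,
    scorer: Callable[[WeightVector], float] | None = None,
) -> WeightVector:
    """Fit one per-primary weight set W_k.

    Starts from the primary-heavy prior and applies, for each epoch's accuracy
    vector, the multiplicative update w_j <- w_j a_j / sum_m w_m a_m.  With a
    ``scorer`` (weights -> ensemble validation accuracy) the best vector along
    the trajectory (prior included) is returned, earliest epoch winning ties;
    without one, the final vector is returned.
    """
    epochs = list(accuracies_per_epoch)
    if not epochs:
        raise ValueError("need at least one epoch of accuracies")
    n = epochs[0].a.size
    w = primary_prior(n, primary_index, primary_mass).w
    trajectory = [w.copy()]
    for acc in epochs:
        a = acc.as_fraction()
        if a.size != n:
            raise ValueError("accuracy vectors must have constant length")
        if np.all(a == 0):
            raise ValueError("all-zero accuracy vector")
        w = _multiplicative_update(w, a)
        trajectory.append(w.copy())
    if scorer is None:
        return WeightVector(trajectory[-1])
    scores = [scorer(WeightVector(t)) for t in trajectory]
    return WeightVector(trajectory[int(np.argmax(scores))])


def group_update(w: WeightVector, acc: AccuracyVector) -> WeightVector:
    """Accuracy-proportional multiplicative update of a group candidate.

    w*_i is proportional to w_i * a_i / sum_j a_j, renormalized to the simplex
    (renormalization leaves the later argmax selection unchanged).  Invariant
    under rescaling all accuracies by a positive constant.
    """
    a = acc.as_fraction()
    if a.size != len(w):
        raise ValueError(f"length mismatch: {len(w)} weights vs {a.size} accuracies")
    if a.sum() <= 0:
        raise ValueError("accuracies sum to zero")
    return WeightVector(_multiplicative_update(w.w, a / a.sum()))


def group_select(
    candidates: Sequence[WeightVector],
    validation_scorer: Callable[[WeightVector], float],
) -> WeightVector:
    """Select the candidate with the highest validation accuracy.

    Ties are broken by the lowest candidate index.
    """
    if not candidates:
        raise ValueError("no group-weight candidates to select from")
    scores = [validation_scorer(c) for c in candidates]
    return candidates[int(np.argmax(scores))]


def generate_group_candidates(
    n: int,
    accuracies_per_epoch: Sequence[AccuracyVector],
    restarts: int = 32,
    seed: int = 0,
) -> list[WeightVector]:
    """Random-restart candidate pool for the group search.

    Draws ``restarts`` flat-Dirichlet points on the n-simplex and evolves each
    through the per-epoch accuracy updates; every trajectory point (including
    the starting draws) is a candidate.
    """
    rng = np.random.default_rng(seed)
    candidates: list[WeightVector] = []
    for _ in range(restarts):
        w = WeightVector(rng.dirichlet(np.ones(n)))
        candidates.append(w)
        for acc in accuracies_per_epoch:
            w = group_update(w, acc)
            candidates.append(w)
    return candidates


def mixed_combine(w_group: WeightVector, w_individual: WeightVector, beta1: float) -> WeightVector:
    """Mixed voting: W = beta1 * W_g + (1 - beta1) * W_i."""
    if not 0.0 <= beta1 <= 1.0:
        raise ValueError(f"beta1 must be in [0, 1], got {beta1}")
    if len(w_group) != len(w_individual):
        raise ValueError("weight vectors must have equal length")
    return WeightVector(beta1 * w_group.w + (1.0 - beta1) * w_individual.w)
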