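"""Forward-algorithm hidden Markov model over weekly PRO states.

The hidden state y_t is the week's ordinal PRO state; the observation x_t
is the week's 105-slot tracker feature vector.  Emissions are obtained by
Bayes-inverting the per-week classifier's posterior,

    P(x_t | y_t)  ∝  S(y_t | x_t) / P(y_t),

dropping the constant P(x_t), which cancels because each filtered belief
is renormalized.  Transitions are estimated by counting week-to-week state
transitions in the training sequences and row-normalizing (with optional
add-alpha smoothing and an optional Gaussian kernel over ordinal state
distance).  The forward recursion is

    b_1(y)  ∝  e_1(y) · P(y),        b_t(y)  ∝  e_t(y) · Σ_s T[s, y] b_{t-1}(s),

with the argmax of b_t as the week's state classification.  Weeks without
an observation (a dropped week inside a retained patient) propagate the
belief through the transition matrix with no emission — a pure prediction
step.  Only filtering is implemented; no smoothing or Viterbi decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .binning import BinningScheme, ProDefinition

__all__ = [
    "TransitionMatrix",
    "class_prior",
    "estimate_transitions",
    "emission_score",
    "forward_filter",
    "severe_probability",
]


@dataclass
class TransitionMatrix:
    """Row-stochastic week-to-week transition probabilities plus the raw
    transition counts they were estimated from."""

    probs: np.ndarray
    counts: np.ndarray
    alpha: float = 1.0
    kernel_bandwidth: float | None = None

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    def __post_init__(self) -> None:
        P = np.asarray(self.probs, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition matrix must be square")
        if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must be non-negative and sum to 1")
        self.probs = P


def _gaussian_kernel_smooth(counts: np.ndarray, bandwidth: float) -> np.ndarray:
    """Spread each row's counts over ordinal state distance with a Gaussian
    kernel — neighboring severity states share statistical strength."""
    S = counts.shape[1]
    d = np.arange(S)[:, None] - np.arange(S)[None, :]
    K = np.exp(-0.5 * (d / bandwidth) ** 2)
    K /= K.sum(axis=1, keepdims=True)
    return counts @ K


def estimate_transitions(
    sequences: Iterable[Sequence[int | None]],
    n_states: int,
    alpha: float = 1.0,
    kernel_bandwidth: float | None = None,
) -> TransitionMatrix:
    """Count consecutive (y_{t-1}, y_t) pairs and normalize rows.

    ``None`` entries mark weeks without a usable state (dropped week or
    unanswered survey); they break the chain, so no pair is counted across
    them.  ``alpha`` is added to every cell before normalization; rows with
    zero total mass fall back to uniform.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states for a transition matrix")
    counts = np.zeros((n_states, n_states))
    for seq in sequences:
        prev: int | None = None
        for s in seq:
            if s is not None and not (0 <= s < n_states):
                raise ValueError(f"state {s} outside 0..{n_states - 1}")
            if prev is not None and s is not None:
                counts[prev, s] += 1
            prev = s
    work = counts.copy()
    if kernel_bandwidth is not None:
        work = _gaussian_kernel_smooth(work, kernel_bandwidth)
    work = work + alpha
    totals = work.sum(axis=1, keepdims=True)
    probs = np.where(totals > 0, work / np.where(totals == 0, 1, totals), 1.0 / n_states)
    return TransitionMatrix(
        probs=probs, counts=counts, alpha=alpha, kernel_bandwidth=kernel_bandwidth
    )


def class_prior(
    states: Iterable[int], n_states: int, floor: float = 1e-6
) -> np.ndarray:
    """Training-frequency prior P(y), floored so no state has zero mass."""
    arr = np.asarray(list(states), dtype=int)
    counts = np.bincount(arr, minlength=n_states).astype(float)
    p = counts / counts.sum() if counts.sum() > 0 else np.full(n_states, 1.0 / n_states)
    p = np.maximum(p, floor)
    return p / p.sum()


def emission_score(
    posterior: np.ndarray, prior: np.ndarray, floor: float = 1e-12
) -> np.ndarray:
    """Unnormalized emission vector: posterior / prior (Bayes inversion).

    Both vectors are floored at ``floor`` before the division so a class
    absent from a training split cannot produce a zero or infinite score.
    The dropped constant P(x_t) is irrelevant: beliefs are renormalized.
    """
    posterior = np.asarray(posterior, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if posterior.shape != prior.shape:
        raise ValueError(
            f"posterior ({posterior.shape}) and prior ({prior.shape}) dimensions differ"
        )
    return np.maximum(posterior, floor) / np.maximum(prior, floor)


@dataclass
class FilteredBelief:
    """Per-week filtered state distributions S(y_t | x_1..x_t)."""

    beliefs: np.ndarray  # (n_weeks, n_states)

    @property
    def predictions(self) -> np.ndarray:
        """Argmax state per week (ties toward the lower index)."""
        return np.argmax(self.beliefs, axis=1)

    def __len__(self) -> int:
        return len(self.beliefs)


def forward_filter(
    posteriors: Sequence[np.ndarray | None],
    transitions: TransitionMatrix,
    prior: np.ndarray,
    emission_floor: float = 1e-12,
) -> FilteredBelief:
    """Run the forward recursion over one patient's ordered weeks.

    ``posteriors`` holds the classifier's posterior vector per week, or
    ``None`` for weeks with no usable observation (prediction step only).
    Week 1's belief is emission ⊙ prior (or the prior itself if week 1 is
    unobserved); each belief is renormalized to sum to 1.
    """
    prior = np.asarray(prior, dtype=float)
    S = transitions.n_states
    if prior.shape != (S,):
        raise ValueError("prior dimension does not match the transition matrix")
    if len(posteriors) == 0:
        raise ValueError("need at least one week to filter")

    beliefs = np.empty((len(posteriors), S))
    for t, post in enumerate(posteriors):
        pred = prior if t == 0 else transitions.probs.T @ beliefs[t - 1]
        if post is None:
            b = pred
        else:
            e = emission_score(np.asarray(post, dtype=float), prior, emission_floor)
            b = e * pred
        total = b.sum()
        if total <= 0 or not np.isfinite(total):
            raise ValueError(f"belief vanished at week {t + 1}")
        beliefs[t] = b / total
    return FilteredBelief(beliefs)


def severe_probability(
    belief: np.ndarray,
    scheme: BinningScheme,
    severe_override: dict[int, bool] | None = None,
) -> float:
    """Probability mass on the severe side of the threshold.

    Sums the belief (or a classifier posterior — the baseline is scored the
    same way) over states whose labels binarize as severe; a merged bin
    straddling the threshold has no intrinsic side and must be assigned via
    ``severe_override`` (state index -> bool).
    """
    belief = np.asarray(belief, dtype=float)
    sides = scheme.severe_states()
    if belief.shape != (len(sides),):
        raise ValueError("belief dimension does not match the scheme")
    mask = np.zeros(len(sides), dtype=bool)
    for i, side in enumerate(sides):
        if side is None:
            if severe_override is None or i not in severe_override:
                raise ValueError(
                    f"state {i} merges bins across the severity threshold; "
                    "an explicit severe-side assignment is required"
                )
            side = severe_override[i]
        mask[i] = side
    return float(belief[mask].sum())
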