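"""Ordinal state binning of weekly PRO scores.

PROMIS t-scores (population mean 50, SD 10) are discretized into 8 ordinal
states: six width-5 (0.5 SD) bins centred on the instrument's clinical
severity threshold — three below it and three above, the threshold owning
the left edge of its own bin — plus two open-ended catch-all tails.  Each
state is labelled by the left edge of its interval, e.g. threshold 60 gives
labels 40, 45, 50, 55, 60, 65, 70, 75 where 40 absorbs everything below 40
and 75 everything at 75 or above.  Sparse bins (fewer than ``min_count``
training observations) are merged toward the threshold to avoid classes a
forest cannot learn.

Severity direction differs by instrument family: for *symptom* scores
(pain interference, fatigue, sleep disturbance) high is bad (severe at
>= 60); for *function* scores (physical function, social activity) low is
bad (severe at <= 40); the Godin leisure-time exercise index classifies a
respondent as inactive below 24.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ProDefinition",
    "BinningScheme",
    "PRO_DEFINITIONS",
    "make_scheme",
    "assign_state",
    "merge_sparse_bins",
    "binarize",
]

Kind = Literal["symptom", "function", "exercise"]

_KIND_THRESHOLD = {"symptom": 60.0, "function": 40.0, "exercise": 24.0}
_KIND_DIRECTION = {"symptom": "above", "function": "below", "exercise": "below"}


@dataclass(frozen=True)
class ProDefinition:
    """A patient-reported outcome instrument and its severity convention.

    ``severe_direction`` says on which side of ``threshold`` the *severe*
    (or, for exercise, *inactive*) scores lie.  The threshold itself is
    severe for symptom (>= 60) and function (<= 40) scores but *active*
    (normal) for the Godin exercise score (severe strictly below 24).
    """

    name: str
    kind: Kind
    threshold: float = None  # type: ignore[assignment]
    severe_direction: str = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in _KIND_THRESHOLD:
            raise ValueError(f"unknown PRO kind {self.kind!r}")
        if self.threshold is None:
            object.__setattr__(self, "threshold", _KIND_THRESHOLD[self.kind])
        if self.severe_direction is None:
            object.__setattr__(self, "severe_direction", _KIND_DIRECTION[self.kind])
        expected = (_KIND_THRESHOLD[self.kind], _KIND_DIRECTION[self.kind])
        if (self.threshold, self.severe_direction) != expected:
            raise ValueError(
                f"PRO {self.name!r} of kind {self.kind!r} must use "
                f"threshold={expected[0]} severe_direction={expected[1]!r}"
            )


#: The six weekly instruments of the study cohort.
PRO_DEFINITIONS: dict[str, ProDefinition] = {
    "pain_interference": ProDefinition("pain_interference", "symptom"),
    "fatigue": ProDefinition("fatigue", "symptom"),
    "sleep_disturbance": ProDefinition("sleep_disturbance", "symptom"),
    "physical_function": ProDefinition("physical_function", "function"),
    "social_activity": ProDefinition("social_activity", "function"),
    "exercise": ProDefinition("exercise", "exercise"),
}


def binarize(score: float, pro: ProDefinition) -> bool:
    """True iff ``score`` is on the severe (or inactive) side of the threshold.

    Symptom: severe at score >= threshold.  Function: severe at
    score <= threshold.  Exercise: inactive strictly below the threshold
    (a Godin score of 24 counts as active).
    """
    if not math.isfinite(score):
        raise ValueError(f"non-finite score {score!r} for PRO {pro.name!r}")
    if pro.kind == "symptom":
        return score >= pro.threshold
    if pro.kind == "function":
        return score <= pro.threshold
    return score < pro.threshold  # exercise


@dataclass
class BinningScheme:
    """Ordered partition of the score line into ordinal states.

    ``members`` holds, per state, the tuple of original (pre-merge) width-5
    labels the state covers; ``edges`` are the S-1 interior breakpoints, so
    state(s) = number of edges <= s.  ``labels`` are the representative
    labels (first member of each state).
    """

    pro: ProDefinition
    members: list[tuple[float, ...]]
    edges: list[float]
    min_count: int = 40
    merge_log: list[dict] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.members)

    @property
    def labels(self) -> list[float]:
        return [m[0] for m in self.members]

    @property
    def original_labels(self) -> list[float]:
        return [lab for m in self.members for lab in m]

    def intervals(self) -> list[tuple[float, float]]:
        """Half-open [lo, hi) intervals, with infinite tails."""
        bounds = [-math.inf, *self.edges, math.inf]
        return list(zip(bounds[:-1], bounds[1:]))

    def label_interval(self, label: float) -> tuple[float, float]:
        """Width-5 generative interval of one original label (tails truncated)."""
        return (label, label + 5.0)

    def threshold_state(self) -> int:
        for i, m in enumerate(self.members):
            if self.pro.threshold in m:
                return i
        raise ValueError("threshold label not present in scheme")

    def severe_states(self) -> list[bool | None]:
        """Per-state severity; None marks a merged bin straddling the threshold."""
        out: list[bool | None] = []
        for m in self.members:
            sides = {binarize(lab, self.pro) for lab in m}
            out.append(sides.pop() if len(sides) == 1 else None)
        return out

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pro": {"name": self.pro.name, "kind": self.pro.kind},
            "members": [list(m) for m in self.members],
            "edges": list(self.edges),
            "min_count": self.min_count,
            "merge_log": self.merge_log,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        pro = ProDefinition(d["pro"]["name"], d["pro"]["kind"])
        return cls(
            pro=pro,
            members=[tuple(m) for m in d["members"]],
            edges=list(d["edges"]),
            min_count=d.get("min_count", 40),
            merge_log=list(d.get("merge_log", [])),
        )

    @classmethod
    def from_json(cls, s: str) -> "BinningScheme":
        return cls.from_dict(json.loads(s))


def make_scheme(pro: ProDefinition, min_count: int = 40) -> BinningScheme:
    """Build the unmerged 8-state scheme anchored at the PRO's threshold.

    Labels run from threshold-20 to threshold+15 in steps of 5; the lowest
    and highest bins are catch-alls for the open tails.
    """
    labels = [pro.threshold - 20.0 + 5.0 * k for k in range(8)]
    edges = labels[1:]
    return BinningScheme(
        pro=pro,
        members=[(lab,) for lab in labels],
        edges=edges,
        min_count=min_count,
    )


def assign_state(score, scheme: BinningScheme):
    """Map score(s) to ordinal state index 0..S-1 (vectorized).

    Intervals are half-open [lo, hi): a score exactly on an edge belongs to
    the higher state, so threshold-valued scores land in the threshold bin.
    """
    arr = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("cannot assign a state to a non-finite score")
    idx = np.searchsorted(np.asarray(scheme.edges), arr, side="right")
    if np.ndim(score) == 0:
        return int(idx)
    return idx.astype(int)


def merge_sparse_bins(
    scheme: BinningScheme,
    counts: Sequence[int],
    direction: Literal["toward_threshold", "larger_neighbor"] = "toward_threshold",
) -> BinningScheme:
    """Merge bins with fewer than ``min_count`` training observations.

    Iteratively the sparsest under-populated bin (ties: lowest index) is
    merged into an adjacent neighbor — by default the one on the threshold
    side, protecting the clinically meaningful boundary; the threshold bin
    itself merges into whichever neighbor has the larger count (ties: lower
    index).  Stops when every bin reaches ``min_count`` or one bin remains.
    ``counts`` must come from the training partition only.
    """
    counts = [int(c) for c in counts]
    if len(counts) != scheme.n_states:
        raise ValueError("counts length must equal the number of states")
    members = [tuple(m) for m in scheme.members]
    edges = list(scheme.edges)
    log: list[dict] = list(scheme.merge_log)

    def neighbor_of(i: int) -> int:
        thr = next(k for k, m in enumerate(members) if scheme.pro.threshold in m)
        if direction == "toward_threshold" and i != thr:
            return i + 1 if i < thr else i - 1
        # threshold bin (or larger-neighbor policy): pick the fuller side
        cands = [j for j in (i - 1, i + 1) if 0 <= j < len(members)]
        return max(cands, key=lambda j: (counts[j], -j))

    while len(members) > 1:
        sparse = [i for i, c in enumerate(counts) if c < scheme.min_count]
        if not sparse:
            break
        i = min(sparse, key=lambda k: (counts[k], k))
        j = neighbor_of(i)
        lo, hi = min(i, j), max(i, j)
        log.append(
            {"merged": list(members[i]), "into": list(members[j]), "count": counts[i]}
        )
        members[lo : hi + 1] = [members[lo] + members[hi]]
        counts[lo : hi + 1] = [counts[lo] + counts[hi]]
        del edges[lo]  # interior edge between lo and hi disappears

    return replace(scheme, members=members, edges=edges, merge_log=log)


def state_counts(scores: Iterable[float], scheme: BinningScheme) -> np.ndarray:
    """Histogram of scores over the scheme's states."""
    idx = assign_state(np.asarray(list(scores), dtype=float), scheme)
    return np.bincount(idx, minlength=scheme.n_states)
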