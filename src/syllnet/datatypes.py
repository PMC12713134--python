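"""Core in-memory containers shared across the package.

A *syllable* is a sub-second stereotyped behavioral module (e.g. "scrunch",
"rear up") emitted by a motion-sequencing pipeline as an integer label.  A
recording session yields an ordered sequence of such labels; consecutive
emissions never repeat because a syllable label only changes at a behavioral
boundary.  Everything downstream (alternation statistics, transition
matrices, behavior networks) consumes these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SyllableSequence",
    "LabelMap",
    "TransitionMatrix",
    "TransitionRecord",
]


@dataclass
class SyllableSequence:
    """One animal-session's ordered integer syllable emissions.

    Parameters
    ----------
    animal_id : str
        Unique identifier of the animal-session.
    group : str
        Experimental group (e.g. ``"naive"`` or ``"epileptic"``).
    timepoint : str
        Session timepoint label (e.g. ``"12w"`` for weeks post insult).
    emissions : array-like of int
        Syllable ids ``S_1 .. S_T`` in emission order.  Ids are 0-based
        nonnegative integers and consecutive ids must differ (no immediate
        self-repeat).
    validate : bool
        Check the invariants on construction (default True).
    """

    animal_id: str
    group: str
    timepoint: str
    emissions: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.emissions)
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            flt = np.asarray(arr, dtype=float)
            if not np.all(flt == np.floor(flt)):
                raise ValueError("syllable ids must be integers")
            arr = flt.astype(np.int64)
        self.emissions = arr.astype(np.int64, copy=False)
        if self.validate:
            if self.emissions.size < 1:
                raise ValueError("sequence length < 1")
            if self.emissions.min(initial=0) < 0:
                raise ValueError("syllable ids must be nonnegative")
            if self.emissions.size > 1 and np.any(
                self.emissions[:-1] == self.emissions[1:]
            ):
                t = int(np.argmax(self.emissions[:-1] == self.emissions[1:]))
                raise ValueError(
                    f"immediate self-repeat at positions {t},{t + 1} "
                    f"(syllable {self.emissions[t]})"
                )

    @property
    def T(self) -> int:
        """Number of emissions."""
        return int(self.emissions.size)

    def __len__(self) -> int:
        return self.T


class TransitionRecord(NamedTuple):
    """One long-format row: incoming syllable, outgoing syllable, count."""

    incoming: int
    outgoing: int
    frequency: int


@dataclass
class TransitionMatrix:
    """n x n counts of ``S_t -> S_{t+1}`` transitions.

    Rows index the incoming syllable, columns the outgoing syllable, in the
    order given by ``syllable_ids``.  Counts are raw (non-normalized) so the
    grand total equals ``T - 1`` for an unfiltered source sequence.
    """

    syllable_ids: list[int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.syllable_ids = [int(i) for i in self.syllable_ids]
        if len(set(self.syllable_ids)) != len(self.syllable_ids):
            raise ValueError("duplicate syllable ids")
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if c.shape[0] != len(self.syllable_ids):
            raise ValueError("counts shape does not match syllable_ids")
        if c.size and not np.issubdtype(c.dtype, np.integer):
            flt = np.asarray(c, dtype=float)
            if not np.all(flt == np.floor(flt)):
                raise ValueError("counts must be integers")
            c = flt.astype(np.int64)
        if c.size and c.min() < 0:
            raise ValueError("counts must be nonnegative")
        self.counts = c.astype(np.int64, copy=False)

    @property
    def n(self) -> int:
        return len(self.syllable_ids)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.syllable_ids, columns=self.syllable_ids
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return self.syllable_ids == other.syllable_ids and np.array_equal(
            self.counts, other.counts
        )


UNLABELED = "unlabeled"


@dataclass
class LabelMap:
    """Syllable id -> (behavior name, racing flag) lookup.

    Unknown ids resolve to ``"unlabeled"`` with ``is_racing=False`` so that a
    partial map never breaks an analysis; "racing" marks syllables whose
    behavior is fast circular locomotion, a phenotype of chronic epilepsy.
    """

    names: dict[int, str] = field(default_factory=dict)
    racing: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = {int(k): str(v) for k, v in self.names.items()}
        self.racing = {int(k): bool(v) for k, v in self.racing.items()}

    def name(self, syllable_id: int) -> str:
        return self.names.get(int(syllable_id), UNLABELED)

    def is_racing(self, syllable_id: int) -> bool:
        return self.racing.get(int(syllable_id), False)

    @property
    def racing_ids(self) -> list[int]:
        return sorted(i for i, r in self.racing.items() if r)

    @property
    def ids(self) -> list[int]:
        return sorted(set(self.names) | set(self.racing))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabelMap":
        required = {"syllable_id", "behavior_name", "is_racing"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"label map missing columns: {sorted(missing)}")
        ids = df["syllable_id"].astype(int)
        if ids.duplicated().any():
            raise ValueError("duplicate syllable_id in label map")
        return cls(
            names=dict(zip(ids, df["behavior_name"].astype(str))),
            racing=dict(zip(ids, df["is_racing"].astype(bool))),
        )

    def to_frame(self) -> pd.DataFrame:
        ids = self.ids
        return pd.DataFrame(
            {
                "syllable_id": ids,
                "behavior_name": [self.name(i) for i in ids],
                "is_racing": [self.is_racing(i) for i in ids],
            }
        )
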