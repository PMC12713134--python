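"""Repetitive-alternation statistics and perseveration bouts.

A sliding three-syllable window ``S_t, S_{t+1}, S_{t+2}`` is *non-repetitive*
when the first and third syllables differ and *repetitive* when they are
identical (A -> B -> A).  The binary indicator sequence

    b_t = 1 if S_t != S_{t+2} else 0,   t = 1 .. T-2

summarizes the alternation structure of a session.  The fraction of
non-repetitive alternations f = mean(b) measures behavioral flexibility, and
maximal constant runs of b quantify bouts: runs of 0s are perseverative
(repetition) bouts, runs of 1s are flexible stretches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import SyllableSequence

__all__ = [
    "classify_triplets",
    "nonrepetitive_fraction",
    "run_lengths",
    "AlternationProfile",
    "CumulativeDistribution",
    "cumulative_distribution",
    "average_distributions",
    "profiles_table",
    "runs_table",
]


def _emissions(seq) -> np.ndarray:
    if isinstance(seq, SyllableSequence):
        return seq.emissions
    return np.asarray(seq, dtype=np.int64)


def classify_triplets(seq: SyllableSequence | Sequence[int]) -> np.ndarray:
    """Binary indicators b_1..b_{T-2}: 1 iff the triplet is non-repetitive.

    ``(5, 6, 9)`` yields ``[1]`` (5 != 9); ``(12, 1, 12)`` yields ``[0]``.
    """
    s = _emissions(seq)
    if s.size < 3:
        raise ValueError("alternation analysis needs at least 3 emissions")
    return (s[:-2] != s[2:]).astype(np.int8)


def nonrepetitive_fraction(b: Sequence[int]) -> float:
    """f = mean of the indicator sequence, in [0, 1]."""
    arr = np.asarray(b)
    if arr.size == 0:
        raise ValueError("empty indicator sequence")
    return float(arr.mean())


def run_lengths(b: Sequence[int]) -> tuple[list[int], list[int]]:
    """Maximal constant blocks of b, split by value.

    Returns ``(repetitive_runs, nonrepetitive_runs)``: lengths of maximal
    0-blocks (perseveration bouts) and 1-blocks, each in order of occurrence.
    Interleaving the two lists in recorded order reconstructs b.
    """
    arr = np.asarray(b)
    if arr.size == 0:
        raise ValueError("empty indicator sequence")
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    rep: list[int] = []
    nonrep: list[int] = []
    for s, e in zip(starts, ends):
        (nonrep if arr[s] else rep).append(int(e - s))
    return rep, nonrep


@dataclass
class AlternationProfile:
    """Per-animal alternation summary: indicators, fraction, bout lengths."""

    animal_id: str
    group: str
    timepoint: str
    b: np.ndarray
    f: float
    repetitive_runs: list[int]
    nonrepetitive_runs: list[int]

    @classmethod
    def from_sequence(cls, seq: SyllableSequence) -> "AlternationProfile":
        b = classify_triplets(seq)
        rep, nonrep = run_lengths(b)
        return cls(
            animal_id=seq.animal_id,
            group=seq.group,
            timepoint=seq.timepoint,
            b=b,
            f=nonrepetitive_fraction(b),
            repetitive_runs=rep,
            nonrepetitive_runs=nonrep,
        )

    @property
    def percent_repetitive(self) -> float:
        return 100.0 * (1.0 - self.f)


@dataclass
class CumulativeDistribution:
    """Empirical CDF in relative-frequency percent, evaluated at `values`."""

    values: np.ndarray
    cum_percent: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cum_percent = np.asarray(self.cum_percent, dtype=float)
        if self.values.shape != self.cum_percent.shape:
            raise ValueError("values and cum_percent must have equal length")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("values must be strictly increasing")
        if np.any(np.diff(self.cum_percent) < 0):
            raise ValueError("cum_percent must be nondecreasing")

    def at(self, x: float) -> float:
        """Step-CDF value (percent) at x: percent of observations <= x."""
        idx = np.searchsorted(self.values, x, side="right") - 1
        return 0.0 if idx < 0 else float(self.cum_percent[idx])


def cumulative_distribution(values: Iterable[float]) -> CumulativeDistribution:
    """Per-animal empirical CDF in percent over the observed values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    uniq, counts = np.unique(arr, return_counts=True)
    pct = 100.0 * np.cumsum(counts) / arr.size
    return CumulativeDistribution(values=uniq, cum_percent=pct)


def average_distributions(
    dists: Sequence[CumulativeDistribution],
) -> CumulativeDistribution:
    """Average step CDFs pointwise on the union grid of observed values.

    This is the "average cumulative frequency distribution" overlaid in bold
    on per-animal curves: each animal's step function is evaluated at every
    value any animal observed, then averaged.
    """
    if len(dists) == 0:
        raise ValueError("no distributions to average")
    grid = np.unique(np.concatenate([d.values for d in dists]))
    mean = np.mean([[d.at(x) for x in grid] for d in dists], axis=0)
    return CumulativeDistribution(values=grid, cum_percent=mean)


def profiles_table(seqs: Iterable[SyllableSequence]) -> pd.DataFrame:
    """Tidy per-animal table: T, f, percent repetitive."""
    rows = []
    for seq in seqs:
        p = AlternationProfile.from_sequence(seq)
        rows.append(
            {
                "animal_id": p.animal_id,
                "group": p.group,
                "timepoint": p.timepoint,
                "T": seq.T,
                "f": p.f,
                "percent_repetitive": p.percent_repetitive,
            }
        )
    return pd.DataFrame(rows)


def runs_table(seqs: Iterable[SyllableSequence]) -> pd.DataFrame:
    """Long bout table: one row per run (animal_id, group, timepoint, run_type, length)."""
    rows = []
    for seq in seqs:
        p = AlternationProfile.from_sequence(seq)
        for L in p.repetitive_runs:
            rows.append((p.animal_id, p.group, p.timepoint, "repetitive", L))
        for L in p.nonrepetitive_runs:
            rows.append((p.animal_id, p.group, p.timepoint, "nonrepetitive", L))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "timepoint", "run_type", "length"]
    )
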