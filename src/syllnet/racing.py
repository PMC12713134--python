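"""Syllable-usage normalization, racing classification, and binarization.

"Racing" syllables are those labeled as fast circular locomotion (e.g. "edge
racing"), a marker phenotype of chronic epilepsy.  Usage is normalized per
animal (emission counts divided by total emissions); racing usage is then
binarized at a threshold — by default 0.025, the highest normalized racing
usage seen in aged control animals — to build a racing-by-animal presence
heatmap.
"""

from __future__ import annotations

import warnings
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import LabelMap, SyllableSequence

__all__ = [
    "RACING_THRESHOLD",
    "usage_from_sequence",
    "usage_table",
    "binarize_racing",
    "racing_heatmap",
    "racing_usage_total",
    "nonracing_usage_total",
    "behavior_word_counts",
]

#: Default binarization threshold on normalized racing usage.
RACING_THRESHOLD = 0.025


def usage_from_sequence(
    seq: SyllableSequence, durations: Sequence[float] | None = None
) -> pd.Series:
    """Normalized per-syllable usage of one animal (fractions summing to 1).

    Usage is occurrence-based: emission counts divided by the number of
    emissions.  Pass per-emission ``durations`` (e.g. frame counts) to weight
    by time spent instead.
    """
    if seq.T < 1:
        raise ValueError("empty sequence")
    if durations is None:
        ids, counts = np.unique(seq.emissions, return_counts=True)
        frac = counts / seq.T
    else:
        dur = np.asarray(durations, dtype=float)
        if dur.shape != seq.emissions.shape:
            raise ValueError("durations must match emissions length")
        if dur.min(initial=0) < 0 or dur.sum() <= 0:
            raise ValueError("durations must be nonnegative with positive total")
        ids = np.unique(seq.emissions)
        frac = np.array(
            [dur[seq.emissions == i].sum() for i in ids]
        ) / dur.sum()
    return pd.Series(frac, index=ids.astype(int), name=seq.animal_id)


def usage_table(seqs: Iterable[SyllableSequence]) -> pd.DataFrame:
    """Animals x syllables usage matrix (absent syllables are 0)."""
    series = [usage_from_sequence(s) for s in seqs]
    df = pd.DataFrame(series).fillna(0.0)
    return df[sorted(df.columns)]


def _as_series(usage: pd.Series | Mapping[int, float]) -> pd.Series:
    if isinstance(usage, pd.Series):
        return usage
    return pd.Series(dict(usage))


def binarize_racing(
    usage: pd.Series | Mapping[int, float],
    labels: LabelMap,
    threshold: float = RACING_THRESHOLD,
) -> pd.Series:
    """Presence indicator per racing syllable: 1 iff usage strictly exceeds
    the threshold.

    The comparison is strict because the threshold is defined as the highest
    racing usage of the reference control animals, which must themselves
    binarize to all zeros.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    u = _as_series(usage)
    racing_ids = labels.racing_ids
    if not racing_ids:
        warnings.warn("label map contains no racing syllables", stacklevel=2)
        return pd.Series(dtype=int, name=u.name)
    vals = u.reindex(racing_ids).fillna(0.0)
    return (vals > threshold).astype(int).rename(u.name)


def racing_heatmap(
    seqs: Iterable[SyllableSequence],
    labels: LabelMap,
    threshold: float = RACING_THRESHOLD,
) -> pd.DataFrame:
    """Binary racing-syllable x animal matrix (rows: racing ids, cols: animals)."""
    cols = {}
    for seq in seqs:
        cols[seq.animal_id] = binarize_racing(
            usage_from_sequence(seq), labels, threshold
        )
    return pd.DataFrame(cols)


def racing_usage_total(
    usage: pd.Series | Mapping[int, float], labels: LabelMap
) -> float:
    """Summed normalized usage over racing-flagged syllables."""
    u = _as_series(usage)
    return float(sum(v for i, v in u.items() if labels.is_racing(i)))


def nonracing_usage_total(
    usage: pd.Series | Mapping[int, float], labels: LabelMap
) -> float:
    """Summed normalized usage over non-racing syllables (complement of racing)."""
    u = _as_series(usage)
    return float(sum(v for i, v in u.items() if not labels.is_racing(i)))


def behavior_word_counts(
    node_ids: Iterable[int], labels: LabelMap
) -> dict[str, int]:
    """Multiplicity of each behavior name among the given nodes.

    This is the count table behind a word cloud: a behavior repeated twice in
    the node list gets count 2.  Ids missing from the label map count under
    "unlabeled".
    """
    return dict(Counter(labels.name(i) for i in node_ids))
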