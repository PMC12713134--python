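"""Synthetic cohorts of behavioral syllable sequences.

The generator emulates the output of a motion-sequencing pipeline for a
longitudinal two-group study (control vs. chronically epileptic animals):
integer-labeled emission sequences with no immediate self-repeats,
group-specific vocabulary (disease-specific syllables), a tunable tendency to
return to the syllable emitted two steps earlier (perseveration), inflated
usage of "racing" syllables at chronic timepoints, and shortened sequences
(sedentary phenotype) at the latest timepoint.

Generative rule for one sequence of target length T over vocabulary V with
return bias rho and base distribution pi (uniform by default, racing ids'
mass multiplied by a boost and renormalized):

* S_1 ~ pi; S_2 ~ pi restricted to V \\ {S_1};
* for t >= 3: with probability rho emit S_{t-2} (always a legal draw since
  S_{t-2} != S_{t-1}; if ever equal the rule falls through); otherwise emit a
  draw from pi restricted to V \\ {S_{t-1}}.

With a uniform base over n syllables this gives the exact repetitive-triplet
fraction ``P(S_t == S_{t+2}) = rho + (1 - rho) / (n - 1)``, which anchors the
analytic recovery checks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .datatypes import LabelMap, SyllableSequence

__all__ = [
    "CohortConfig",
    "simulate_sequence",
    "simulate_cohort",
    "default_label_map",
    "GROUPS",
    "TIMEPOINTS",
    "CHRONIC_TIMEPOINTS",
    "CONTROL_GROUP",
]

#: Study design emulated by default: two groups, three timepoints
#: (weeks post status epilepticus).
GROUPS: tuple[str, ...] = ("naive", "epileptic")
TIMEPOINTS: tuple[str, ...] = ("1.5w", "12w", "20w")
CHRONIC_TIMEPOINTS: tuple[str, ...] = ("12w", "20w")
LATEST_TIMEPOINT: str = "20w"
CONTROL_GROUP: str = "naive"


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study's structure: a vocabulary of 37
    syllables of which 7 (ids 30-36) occur only in the diseased group, four
    of those flagged as racing; roughly 1,500 emissions per 20-minute
    session; 15 animals per group per timepoint.

    Parameters
    ----------
    n_syllables : int
        Vocabulary size ``n``.
    seq_length : int
        Target emissions per animal ``T``.
    n_animals_per_group : int
        Animals per group per timepoint.
    return_bias : float
        Probability ``rho`` in [0, 1] that the next emission returns to the
        syllable two steps back, for the diseased group.
    baseline_return_bias : float
        ``rho`` for the control group (and any group not receiving the
        elevated bias); must not exceed ``return_bias`` for the directional
        contrasts to hold.
    group_specific_ids : frozenset of int
        Syllables with nonzero probability only in the diseased group (at
        chronic timepoints).
    racing_ids : frozenset of int
        Syllables flagged as racing.
    racing_boost : float
        Nonnegative multiplier on racing syllables' base mass, applied to the
        diseased group at chronic timepoints.
    length_factor : float
        Multiplier in (0, 1] on ``T`` for the diseased group at the latest
        (sedentary) timepoint.
    base_concentration : float or None
        If set, base syllable weights are drawn once per config from a
        Gamma(concentration, 1) kernel instead of being uniform; off by
        default so the analytic triplet fractions hold exactly.
    seed : int
        Master seed; per-animal streams are derived deterministically.
    """

    n_syllables: int = 37
    seq_length: int = 1500
    n_animals_per_group: int = 15
    return_bias: float = 0.30
    baseline_return_bias: float = 0.05
    group_specific_ids: frozenset[int] = frozenset(range(30, 37))
    racing_ids: frozenset[int] = frozenset(range(30, 34))
    racing_boost: float = 3.0
    length_factor: float = 0.7
    base_concentration: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_syllables < 2:
            raise ValueError("n_syllables must be >= 2")
        if self.seq_length < 3:
            raise ValueError("seq_length must be >= 3")
        if self.n_animals_per_group < 1:
            raise ValueError("n_animals_per_group must be >= 1")
        for name in ("return_bias", "baseline_return_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        universe = set(range(self.n_syllables))
        object.__setattr__(
            self, "group_specific_ids", frozenset(int(i) for i in self.group_specific_ids)
        )
        object.__setattr__(
            self, "racing_ids", frozenset(int(i) for i in self.racing_ids)
        )
        if not self.group_specific_ids <= universe:
            raise ValueError("group_specific_ids outside [0, n_syllables)")
        if not self.racing_ids <= universe:
            raise ValueError("racing_ids outside [0, n_syllables)")
        if self.racing_boost < 0:
            raise ValueError("racing_boost must be nonnegative")
        if not 0.0 < self.length_factor <= 1.0:
            raise ValueError("length_factor must lie in (0, 1]")
        if self.length_factor * self.seq_length < 3:
            raise ValueError(
                "length_factor * seq_length must be >= 3 "
                "(alternation analysis needs at least 3 emissions)"
            )
        if len(universe - self.group_specific_ids) < 2:
            raise ValueError("control vocabulary must keep >= 2 syllables")


def _group_conditions(
    config: CohortConfig, group: str, timepoint: str
) -> tuple[np.ndarray, float, float, int]:
    """Effective (vocabulary, return bias, racing boost, length) for a cell.

    The control group never uses the group-specific syllables and keeps the
    baseline return bias; the diseased group carries the elevated return bias
    throughout, gains the specific vocabulary and the racing boost at chronic
    timepoints, and shortens at the latest timepoint.
    """
    universe = np.arange(config.n_syllables)
    diseased = group != CONTROL_GROUP
    chronic = timepoint in CHRONIC_TIMEPOINTS
    if diseased and chronic:
        vocab = universe
    else:
        vocab = np.array(
            sorted(set(range(config.n_syllables)) - config.group_specific_ids)
        )
    rho = config.return_bias if diseased else config.baseline_return_bias
    boost = config.racing_boost if (diseased and chronic) else 1.0
    T = config.seq_length
    if diseased and timepoint == LATEST_TIMEPOINT:
        T = max(3, int(round(config.length_factor * config.seq_length)))
    return vocab, rho, boost, T


def _base_weights(config: CohortConfig, vocab: np.ndarray, boost: float) -> np.ndarray:
    if config.base_concentration is None:
        w = np.ones(vocab.size)
    else:
        # One fixed non-uniform kernel per config, shared by every animal.
        kernel_rng = np.random.default_rng(config.seed)
        full = kernel_rng.gamma(config.base_concentration, 1.0, config.n_syllables)
        w = full[vocab].astype(float)
    racing = np.isin(vocab, sorted(config.racing_ids))
    w = w.copy()
    w[racing] *= boost
    total = w.sum()
    if total <= 0:
        raise ValueError("base distribution has zero total mass")
    return w / total


def _draw(rng: np.random.Generator, vocab: np.ndarray, cumw: np.ndarray,
          forbid: int | None) -> int:
    # Rejection sampling == drawing from the base restricted to vocab \ {forbid}.
    while True:
        s = int(vocab[np.searchsorted(cumw, rng.random(), side="right")])
        if s != forbid:
            return s


def simulate_sequence(
    config: CohortConfig,
    group: str,
    seed: int,
    timepoint: str = "12w",
    animal_id: str | None = None,
) -> SyllableSequence:
    """Simulate one animal-session under the group/timepoint conditions.

    The same ``(config, group, timepoint, seed)`` always yields an identical
    sequence.

    Raises
    ------
    ValueError
        If the group's effective vocabulary has fewer than two syllables
        (no legal non-repeating draw exists).
    """
    vocab, rho, boost, T = _group_conditions(config, group, timepoint)
    if vocab.size < 2:
        raise ValueError("vocabulary must contain >= 2 syllables")
    weights = _base_weights(config, vocab, boost)
    cumw = np.cumsum(weights)
    cumw[-1] = 1.0  # guard against rounding at the top end
    rng = np.random.default_rng(seed)

    out = np.empty(T, dtype=np.int64)
    out[0] = _draw(rng, vocab, cumw, forbid=None)
    out[1] = _draw(rng, vocab, cumw, forbid=out[0])
    for t in range(2, T):
        if rho > 0 and rng.random() < rho and out[t - 2] != out[t - 1]:
            out[t] = out[t - 2]
        else:
            out[t] = _draw(rng, vocab, cumw, forbid=out[t - 1])
    return SyllableSequence(
        animal_id=animal_id or f"{group}-{timepoint}-s{seed}",
        group=group,
        timepoint=timepoint,
        emissions=out,
    )


def animal_seed(config_seed: int, group: str, timepoint: str, index: int) -> int:
    """Deterministic per-animal seed: master seed + stable key hash, < 2**31."""
    key = f"{group}|{timepoint}|{index}".encode()
    return int((config_seed + zlib.crc32(key)) % (2**31))


def simulate_cohort(
    config: CohortConfig,
    groups: Sequence[str] = GROUPS,
    timepoints: Sequence[str] = TIMEPOINTS,
) -> list[SyllableSequence]:
    """Simulate the full cohort: every group x timepoint x animal.

    Animals are mutually independent (distinct derived seeds) and the whole
    cohort is reproducible from ``config.seed`` alone.
    """
    cohort: list[SyllableSequence] = []
    for group in groups:
        for tp in timepoints:
            for i in range(config.n_animals_per_group):
                s = animal_seed(config.seed, group, tp, i)
                cohort.append(
                    simulate_sequence(
                        config,
                        group,
                        seed=s,
                        timepoint=tp,
                        animal_id=f"{group}_{tp}_{i:02d}",
                    )
                )
    return cohort


def default_label_map(config: CohortConfig) -> LabelMap:
    """Behavior names for a synthetic vocabulary.

    Racing ids get racing-flavored names so word-count tables are readable;
    everything else gets a generic name.
    """
    names: dict[int, str] = {}
    racing: dict[int, bool] = {}
    racing_names = ("edge racing", "racing", "wild running", "dash")
    for i in range(config.n_syllables):
        if i in config.racing_ids:
            names[i] = racing_names[sorted(config.racing_ids).index(i) % len(racing_names)]
            racing[i] = True
        elif i in config.group_specific_ids:
            names[i] = f"specific behavior {i}"
            racing[i] = False
        else:
            names[i] = f"behavior {i}"
            racing[i] = False
    return LabelMap(names=names, racing=racing)
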