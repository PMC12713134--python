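"""Readers and writers for the on-disk formats.

Everything is plain UTF-8, comma-delimited CSV with a mandatory header row,
except networks, which can also be exported as GraphML.  Syllable ids are
0-based integers everywhere; behavior names live only in the label map.

Formats
-------
sequence        one row per emission: ``frame_index, syllable_id``
manifest        one row per animal: ``animal_id, group, timepoint, file, seed``
label map       ``syllable_id, behavior_name, is_racing``
wide matrix     square table, incoming syllable down the side, outgoing
                syllable along the top, empty corner header
long matrix     ``incoming, outgoing, frequency`` with zero rows omitted
edge table      ``source, target, weight`` (importable into Cytoscape)
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import LabelMap, SyllableSequence, TransitionMatrix, TransitionRecord

__all__ = [
    "read_sequence",
    "write_sequence",
    "read_manifest",
    "write_cohort",
    "read_cohort",
    "read_label_map",
    "write_label_map",
    "read_wide_matrix",
    "write_wide_matrix",
    "matrix_to_long",
    "long_to_matrix",
    "read_long_matrix",
    "write_long_matrix",
    "export_network",
    "read_graphml",
]


# ---------------------------------------------------------------- sequences

def write_sequence(seq: SyllableSequence, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {"frame_index": np.arange(seq.T), "syllable_id": seq.emissions}
    )
    df.to_csv(path, index=False)


def read_sequence(
    path: str | os.PathLike,
    animal_id: str | None = None,
    group: str = "",
    timepoint: str = "",
) -> SyllableSequence:
    """Read one animal's emission CSV.

    Metadata not stored in the per-animal file (group, timepoint) may be
    supplied by the caller, typically from a cohort manifest.
    """
    df = pd.read_csv(path)
    if "syllable_id" not in df.columns:
        raise ValueError(f"{path}: missing 'syllable_id' column")
    col = df["syllable_id"]
    if len(col) == 0:
        raise ValueError(f"{path}: sequence length < 1")
    numeric = pd.to_numeric(col, errors="coerce")
    bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0)))
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ValueError(
            f"{path}: non-integer syllable id {col.iloc[row]!r} at row {row}"
        )
    return SyllableSequence(
        animal_id=animal_id or Path(path).stem,
        group=group,
        timepoint=timepoint,
        emissions=numeric.astype(np.int64).to_numpy(),
    )


MANIFEST_COLUMNS = ["animal_id", "group", "timepoint", "file", "seed"]


def write_cohort(
    cohort: Iterable[SyllableSequence],
    out_dir: str | os.PathLike,
    seeds: dict[str, int] | None = None,
) -> Path:
    """Write one CSV per animal plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for seq in cohort:
        fname = f"{seq.animal_id}.csv"
        write_sequence(seq, out / fname)
        rows.append(
            {
                "animal_id": seq.animal_id,
                "group": seq.group,
                "timepoint": seq.timepoint,
                "file": fname,
                "seed": (seeds or {}).get(seq.animal_id, ""),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str, "group": str, "timepoint": str})
    missing = set(MANIFEST_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def read_cohort(manifest_path: str | os.PathLike) -> list[SyllableSequence]:
    """Load every animal listed in a cohort manifest."""
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    return [
        read_sequence(
            base / row.file,
            animal_id=row.animal_id,
            group=row.group,
            timepoint=row.timepoint,
        )
        for row in manifest.itertuples()
    ]


# ---------------------------------------------------------------- label maps

def read_label_map(path: str | os.PathLike) -> LabelMap:
    return LabelMap.from_frame(pd.read_csv(path))


def write_label_map(labels: LabelMap, path: str | os.PathLike) -> None:
    labels.to_frame().to_csv(path, index=False)


# ------------------------------------------------------- transition matrices

def write_wide_matrix(m: TransitionMatrix, path: str | os.PathLike) -> None:
    """Write the square incoming x outgoing count table (empty corner cell)."""
    df = m.to_frame()
    df.index.name = None
    df.to_csv(path, index=True, index_label="")


def read_wide_matrix(path: str | os.PathLike) -> TransitionMatrix:
    df = pd.read_csv(path, index_col=0)
    rows = [int(i) for i in df.index]
    cols = [int(c) for c in df.columns]
    if rows != cols:
        raise ValueError(f"{path}: row labels do not match column labels")
    vals = df.to_numpy()
    if vals.size and np.nanmin(vals) < 0:
        raise ValueError(f"{path}: counts must be nonnegative")
    return TransitionMatrix(syllable_ids=rows, counts=vals)


def matrix_to_long(m: TransitionMatrix) -> list[TransitionRecord]:
    """Long format: one record per nonzero cell, zero cells omitted."""
    rec = []
    ids = m.syllable_ids
    rows, cols = np.nonzero(m.counts)
    for r, c in zip(rows, cols):
        rec.append(TransitionRecord(ids[r], ids[c], int(m.counts[r, c])))
    return rec


def long_to_matrix(
    records: Iterable[TransitionRecord | tuple],
    syllable_ids: Sequence[int],
) -> TransitionMatrix:
    """Rebuild the wide matrix over an explicit id universe."""
    ids = [int(i) for i in syllable_ids]
    pos = {s: k for k, s in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)), dtype=np.int64)
    for inc, out, freq in records:
        if inc not in pos or out not in pos:
            raise ValueError(f"record ({inc}->{out}) outside the id universe")
        counts[pos[inc], pos[out]] += int(freq)
    return TransitionMatrix(syllable_ids=ids, counts=counts)


LONG_COLUMNS = ["incoming", "outgoing", "frequency"]


def write_long_matrix(m: TransitionMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(matrix_to_long(m), columns=LONG_COLUMNS).to_csv(path, index=False)


def read_long_matrix(
    path: str | os.PathLike, syllable_ids: Sequence[int] | None = None
) -> TransitionMatrix:
    df = pd.read_csv(path)
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: long matrix missing columns {sorted(missing)}")
    records = [
        TransitionRecord(int(r.incoming), int(r.outgoing), int(r.frequency))
        for r in df.itertuples()
    ]
    if syllable_ids is None:
        syllable_ids = sorted({r.incoming for r in records} | {r.outgoing for r in records})
    return long_to_matrix(records, syllable_ids)


# ------------------------------------------------------------------ networks

def export_network(
    net: nx.DiGraph | nx.MultiDiGraph,
    path: str | os.PathLike,
    format: str = "graphml",
) -> None:
    """Write a behavior network as GraphML or as a Cytoscape edge table.

    GraphML keeps node ids, any ``behavior`` node attribute, and edge
    weights; the edge table is ``source, target, weight`` CSV.
    """
    if format == "graphml":
        nx.write_graphml(net, path, named_key_ids=True)
    elif format == "edge-table":
        rows = [
            {"source": u, "target": v, "weight": d.get("weight", 1)}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_graphml(path: str | os.PathLike) -> nx.DiGraph | nx.MultiDiGraph:
    g = nx.read_graphml(path, node_type=int)
    # GraphML stores weights as typed attributes; coerce to int when exact.
    for _, _, d in g.edges(data=True):
        if "weight" in d and float(d["weight"]).is_integer():
            d["weight"] = int(d["weight"])
    return g
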