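"""Reading and writing ESM report files and network outputs.

Two on-disk report layouts are supported:

* **wide** — one row per answered prompt: ``participant_id,timestamp,
  [gender,]<one 0/1 column per emotion>``.
* **long** — one row per (prompt, emotion) pair: ``participant_id,timestamp,
  emotion,present``; emotions absent from a prompt are imputed as 0, so a
  file that lists only endorsed emotions is equivalent to the wide form.

All CSVs are comma-separated UTF-8 with dot decimal separators; timestamps
are ISO-8601 in the participant's local clock time (no timezone conversion
is attempted, since hour-of-day analyses are in local time). Networks go out
as an edge-list CSV or as GraphML (nodes carry valence and optional
frequency, edges carry the signed weight); both round-trip exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ReportDataset
from .network import WeightMatrix
from .taxonomy import EmotionTaxonomy, default_taxonomy, validate_emotion_names

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _read_csv(path: PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"empty input file: {path}")
    return df


def load_reports(
    path: PathLike,
    schema: str = "wide",
    taxonomy: Optional[EmotionTaxonomy] = None,
    errors: str = "raise",
) -> ReportDataset:
    """Load an ESM report CSV into a validated :class:`ReportDataset`.

    Parameters
    ----------
    path
        CSV file.
    schema
        ``"wide"`` or ``"long"`` (see module docstring).
    taxonomy
        Defaults to the 18-emotion taxonomy.
    errors
        ``"raise"`` (default): any row with an unparseable timestamp or a
        non-binary indicator aborts the load with an error naming the row
        and column. ``"drop"``: such rows are rejected and logged one by
        one, and the remainder is returned.
    """
    if schema not in ("wide", "long"):
        raise ValueError(f"schema must be 'wide' or 'long', got {schema!r}")
    if errors not in ("raise", "drop"):
        raise ValueError(f"errors must be 'raise' or 'drop', got {errors!r}")
    taxonomy = taxonomy or default_taxonomy()
    df = _read_csv(path)
    if schema == "long":
        df = _pivot_long(df, taxonomy)
    missing = [c for c in ("participant_id", "timestamp") if c not in df.columns]
    missing += [e for e in taxonomy if e not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    bad_rows: set[int] = set()
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    for idx in df.index[ts.isna()]:
        msg = f"row {idx}: unparseable timestamp {df.loc[idx, 'timestamp']!r}"
        if errors == "raise":
            raise ValueError(msg)
        logger.error(msg)
        bad_rows.add(idx)
    for emo in taxonomy:
        vals = pd.to_numeric(df[emo], errors="coerce")
        ok = vals.isin((0, 1))
        for idx in df.index[~ok]:
            msg = f"row {idx}, column {emo!r}: indicator {df.loc[idx, emo]!r} is not 0/1"
            if errors == "raise":
                raise ValueError(msg)
            logger.error(msg)
            bad_rows.add(idx)
    if bad_rows:
        df = df.drop(index=sorted(bad_rows))
        if len(df) == 0:
            raise ValueError("no valid reports left after dropping bad rows")
    df = df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    return ReportDataset(df, taxonomy)


def _pivot_long(df: pd.DataFrame, taxonomy: EmotionTaxonomy) -> pd.DataFrame:
    required = ["participant_id", "timestamp", "emotion", "present"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    validate_emotion_names(df["emotion"].unique(), taxonomy)
    wide = (
        df.pivot_table(
            index=["participant_id", "timestamp"],
            columns="emotion",
            values="present",
            aggfunc="max",
            fill_value=0,
        )
        .reindex(columns=list(taxonomy), fill_value=0)
        .reset_index()
    )
    wide.columns.name = None
    return wide


def write_reports(dataset: ReportDataset, path: PathLike, schema: str = "wide") -> None:
    """Write a dataset back to CSV (wide or long), ISO timestamps to seconds."""
    df = dataset.df.copy()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    if schema == "wide":
        df.to_csv(path, index=False)
    elif schema == "long":
        long = df.melt(
            id_vars=["participant_id", "timestamp"],
            value_vars=list(dataset.taxonomy),
            var_name="emotion",
            value_name="present",
        )
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"schema must be 'wide' or 'long', got {schema!r}")


def write_network(
    W: WeightMatrix,
    path: PathLike,
    format: str = "edge_list_csv",
    frequency: Optional[pd.Series] = None,
) -> None:
    """Write the emotion network to disk.

    ``edge_list_csv`` emits one row per unordered pair (emotion_a, emotion_b,
    weight) — 153 rows for 18 emotions. ``graphml`` emits a GraphML graph
    whose nodes carry ``valence`` (and ``frequency`` if given) attributes and
    whose edges carry ``weight``; reading it back reproduces the matrix
    exactly (weights are serialized at full double precision).
    """
    if format == "edge_list_csv":
        # default float formatting is the shortest round-trippable repr
        W.edge_list().to_csv(path, index=False)
    elif format == "graphml":
        G = nx.Graph()
        for e in W.taxonomy:
            attrs = {"valence": W.taxonomy.valence[e]}
            if frequency is not None and e in frequency.index:
                attrs["frequency"] = float(frequency[e])
            G.add_node(e, **attrs)
        for _, row in W.edge_list().iterrows():
            G.add_edge(row["emotion_a"], row["emotion_b"], weight=float(row["weight"]))
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"format must be 'edge_list_csv' or 'graphml', got {format!r}")


def read_network(
    path: PathLike,
    format: str = "edge_list_csv",
    taxonomy: Optional[EmotionTaxonomy] = None,
) -> WeightMatrix:
    """Read a network written by :func:`write_network` back into a matrix."""
    taxonomy = taxonomy or default_taxonomy()
    k = len(taxonomy)
    W = np.zeros((k, k))
    if format == "edge_list_csv":
        edges = pd.read_csv(path, float_precision="round_trip")
        it = edges[["emotion_a", "emotion_b", "weight"]].itertuples(index=False)
    elif format == "graphml":
        G = nx.read_graphml(path)
        it = ((a, b, d["weight"]) for a, b, d in G.edges(data=True))
    else:
        raise ValueError(f"format must be 'edge_list_csv' or 'graphml', got {format!r}")
    for a, b, w in it:
        i, j = taxonomy.index(a), taxonomy.index(b)
        W[i, j] = W[j, i] = float(w)
    return WeightMatrix(W, taxonomy)
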