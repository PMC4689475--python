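"""In-memory containers for experience-sampling (ESM) emotion reports.

A *report* is one answered prompt: a participant id, a timestamp in the
participant's local clock time, and a binary indicator per emotion in the
taxonomy (the all-zero vector is legal and means "no emotion right now").
The dataset wraps a pandas DataFrame so that the usual split/apply/combine
machinery stays available, while validation and taxonomy alignment are
enforced at construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

from .taxonomy import EmotionTaxonomy, default_taxonomy

META_COLUMNS = ("participant_id", "timestamp", "gender")
GENDER_LEVELS = ("female", "male", "unknown")


class EmotionReport(NamedTuple):
    """One answered prompt."""

    participant_id: str
    timestamp: pd.Timestamp
    indicators: np.ndarray  # 0/1, aligned to taxonomy order
    gender: str = "unknown"


@dataclass
class ReportDataset:
    """A validated collection of emotion reports.

    Parameters
    ----------
    df
        One row per report. Required columns: ``participant_id``,
        ``timestamp`` (datetime-like, local clock time), one 0/1 column per
        emotion in ``taxonomy``; optional ``gender`` in
        {female, male, unknown}.
    taxonomy
        The emotion taxonomy the indicator columns are aligned to.
    """

    df: pd.DataFrame
    taxonomy: EmotionTaxonomy = field(default_factory=default_taxonomy)

    def __post_init__(self) -> None:
        df = self.df
        if len(df) == 0:
            raise ValueError("a ReportDataset needs at least one report")
        missing = [c for c in ("participant_id", "timestamp") if c not in df.columns]
        missing += [e for e in self.taxonomy if e not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {missing}")
        df = df.copy()
        df["participant_id"] = df["participant_id"].astype(str)
        if (df["participant_id"].str.len() == 0).any():
            raise ValueError("participant ids must be non-empty")
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        if "gender" not in df.columns:
            df["gender"] = "unknown"
        df["gender"] = df["gender"].fillna("unknown").astype(str)
        bad_gender = set(df["gender"]) - set(GENDER_LEVELS)
        if bad_gender:
            raise ValueError(f"gender values must be in {GENDER_LEVELS}, got {bad_gender}")
        ind = df[list(self.taxonomy)].to_numpy()
        if not np.isin(ind, (0, 1)).all():
            raise ValueError("emotion indicators must be 0 or 1")
        df[list(self.taxonomy)] = ind.astype(np.int8)
        dup = df.duplicated(subset=["participant_id", "timestamp"]).sum()
        if dup:
            # The app allows snoozed/delayed prompts, so duplicates are kept.
            warnings.warn(
                f"{dup} duplicate (participant, timestamp) report(s) kept",
                stacklevel=2,
            )
        ordered = ["participant_id", "timestamp", "gender"] + list(self.taxonomy)
        extra = [c for c in df.columns if c not in ordered]
        self.df = df[ordered + extra].reset_index(drop=True)

    # -- accessors ----------------------------------------------------------

    @property
    def n_reports(self) -> int:
        return len(self.df)

    @property
    def n_participants(self) -> int:
        return self.df["participant_id"].nunique()

    @property
    def indicators(self) -> np.ndarray:
        """(n_reports, n_emotions) int array in canonical taxonomy order."""
        return self.df[list(self.taxonomy)].to_numpy()

    @property
    def participant_ids(self) -> pd.Series:
        return self.df["participant_id"]

    @property
    def timestamps(self) -> pd.Series:
        return self.df["timestamp"]

    def reports(self) -> Iterator[EmotionReport]:
        ind = self.indicators
        for i, row in enumerate(self.df.itertuples(index=False)):
            yield EmotionReport(row.participant_id, row.timestamp, ind[i], row.gender)

    def subset(self, mask: np.ndarray | pd.Series) -> "ReportDataset":
        """Dataset restricted to the reports where ``mask`` is True."""
        return ReportDataset(self.df.loc[np.asarray(mask)], self.taxonomy)

    def by_group(self, column: str) -> dict[str, "ReportDataset"]:
        """Split into one dataset per level of ``column`` (e.g. gender)."""
        if column not in self.df.columns:
            raise KeyError(f"no such column: {column}")
        out: dict[str, ReportDataset] = {}
        for level, sub in self.df.groupby(column, observed=True):
            out[str(level)] = ReportDataset(sub, self.taxonomy)
        return out

    def __len__(self) -> int:
        return self.n_reports


def dataset_from_arrays(
    indicators: np.ndarray,
    participant_ids: Optional[np.ndarray] = None,
    timestamps: Optional[pd.Series] = None,
    gender: Optional[np.ndarray] = None,
    taxonomy: Optional[EmotionTaxonomy] = None,
) -> ReportDataset:
    """Assemble a dataset from raw arrays, filling in trivial metadata.

    Useful in tests and for wrapping a bare (n_reports, 18) indicator matrix:
    missing participant ids become one id per report (no nesting), missing
    timestamps an hourly sequence.
    """
    taxonomy = taxonomy or default_taxonomy()
    indicators = np.asarray(indicators)
    n = indicators.shape[0]
    if indicators.ndim != 2 or indicators.shape[1] != len(taxonomy):
        raise ValueError(
            f"indicator matrix must be (n_reports, {len(taxonomy)}), "
            f"got {indicators.shape}"
        )
    if participant_ids is None:
        participant_ids = np.array([f"p{i}" for i in range(n)])
    if timestamps is None:
        timestamps = pd.date_range("2013-02-01 09:00", periods=n, freq="h")
    df = pd.DataFrame(indicators, columns=list(taxonomy))
    df.insert(0, "participant_id", participant_ids)
    df.insert(1, "timestamp", timestamps)
    if gender is not None:
        df["gender"] = gender
    return ReportDataset(df, taxonomy)
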