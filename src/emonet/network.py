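"""Signed co-occurrence network of emotions and its centrality structure.

Emotions are nodes of a weighted undirected graph; the edge weight between
two emotions is the phi coefficient (Pearson correlation of the two binary
indicator vectors pooled over all reports). A positive edge means the two
emotions tend to be reported together; a negative edge means reporting one
makes reporting the other less likely.

Degree centrality (DC) of an emotion is the sum of the absolute weights of
its 17 edges; for an 18-emotion taxonomy it is bounded by 17, attained only
when every edge is a perfect correlation or a perfect inhibition.

The connector / provincial / distal typology operationalizes the idea that
an emotion can couple to both valences (connector), to its own valence only
(provincial), or to hardly anything (distal). An edge is called *strong*
when |weight| >= tau (default 0.1). The classification is an explicit
threshold rule, not a reproduction of any visual judgement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datasets import ReportDataset, dataset_from_arrays
from .taxonomy import EmotionTaxonomy, default_taxonomy

logger = logging.getLogger(__name__)

TYPOLOGY_LABELS = ("connector", "provincial", "distal")


@dataclass
class WeightMatrix:
    """Symmetric signed edge-weight matrix of the emotion network.

    ``W[a, b]`` is the phi correlation of emotions a and b; the diagonal is 0
    by convention (no self-edges). Pairs whose correlation is undefined
    because an indicator is constant are stored as 0 and flagged in ``mask``.
    """

    W: np.ndarray
    taxonomy: EmotionTaxonomy = field(default_factory=default_taxonomy)
    n_reports: int = 0
    mask: Optional[np.ndarray] = None  # True where phi was undefined

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        k = len(self.taxonomy)
        if W.shape != (k, k):
            raise ValueError(f"weight matrix must be {k}x{k}, got {W.shape}")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(W).max() > 1 + 1e-9:
            raise ValueError("edge weights must lie in [-1, 1]")
        np.fill_diagonal(W, 0.0)
        self.W = W
        if self.mask is None:
            self.mask = np.zeros((k, k), dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        names = list(self.taxonomy)
        return pd.DataFrame(self.W, index=names, columns=names)

    def edge_list(self) -> pd.DataFrame:
        """All unordered pairs (k*(k-1)/2 rows) as a tidy edge table."""
        names = list(self.taxonomy)
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append((names[i], names[j], self.W[i, j]))
        return pd.DataFrame(rows, columns=["emotion_a", "emotion_b", "weight"])


def phi_matrix(
    dataset: Union[ReportDataset, np.ndarray],
    taxonomy: Optional[EmotionTaxonomy] = None,
    person_centered: bool = False,
) -> WeightMatrix:
    """Phi-coefficient matrix of the binary emotion indicators.

    Pools all reports (between- plus within-person covariation), matching how
    the network weights are defined for the full sample. With
    ``person_centered=True`` each participant's mean indicator vector is
    subtracted first, leaving within-person covariation only — a sensitivity
    variant, not the default definition.
    """
    if isinstance(dataset, ReportDataset):
        taxonomy = dataset.taxonomy
        X = dataset.indicators.astype(float)
        groups = dataset.participant_ids.to_numpy()
    else:
        taxonomy = taxonomy or default_taxonomy()
        X = np.asarray(dataset, dtype=float)
        groups = None
        if person_centered:
            raise ValueError("person_centered requires a ReportDataset")
    n, k = X.shape
    if n < 2:
        raise ValueError("phi matrix needs at least 2 reports")
    if person_centered:
        means = pd.DataFrame(X).groupby(groups).transform("mean").to_numpy()
        X = X - means
    sd = X.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.corrcoef(X, rowvar=False)
    mask = np.zeros((k, k), dtype=bool)
    mask[constant, :] = True
    mask[:, constant] = True
    np.fill_diagonal(mask, False)
    W = np.where(np.isnan(W), 0.0, W)
    W[mask] = 0.0
    np.fill_diagonal(W, 0.0)
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    if mask.any():
        names = [taxonomy.emotions[i] for i in np.flatnonzero(constant)]
        logger.warning("constant indicator(s) %s: phi undefined, stored as 0", names)
    return WeightMatrix(W, taxonomy, n_reports=n, mask=mask)


def degree_centrality(W: WeightMatrix) -> pd.Series:
    """DC per emotion: sum of |edge weight| over the other emotions."""
    dc = np.abs(W.W).sum(axis=1)
    return pd.Series(dc, index=list(W.taxonomy), name="degree_centrality")


@dataclass
class Typology:
    """Connector/provincial/distal label per emotion, with the tau used."""

    labels: Mapping[str, str]
    tau: float

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.labels), name="typology")


def classify_typology(
    W: WeightMatrix,
    taxonomy: Optional[EmotionTaxonomy] = None,
    tau: float = 0.1,
) -> Typology:
    """Label each emotion connector, provincial or distal.

    An edge is strong iff |weight| >= tau. An emotion is a *connector* if it
    has strong edges to both valences, *provincial* if it has strong
    same-valence edges only, and *distal* if it has no strong same-valence
    edge. An emotion whose only strong edges are to the opposite valence is
    filed as distal (and logged): it lacks the same-valence core that defines
    the other two types.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    taxonomy = taxonomy or W.taxonomy
    strong = np.abs(W.W) >= tau
    np.fill_diagonal(strong, False)
    same = np.array(
        [[taxonomy.same_valence(a, b) for b in taxonomy] for a in taxonomy]
    )
    labels: dict[str, str] = {}
    for i, e in enumerate(taxonomy):
        has_same = bool((strong[i] & same[i]).any())
        has_opp = bool((strong[i] & ~same[i]).any())
        if has_same and has_opp:
            labels[e] = "connector"
        elif has_same:
            labels[e] = "provincial"
        else:
            if has_opp:
                logger.info(
                    "%s has only opposite-valence strong edges; filed as distal", e
                )
            labels[e] = "distal"
    return Typology(labels, tau)


def compare_centrality(
    dc_a: Union[pd.Series, Sequence[float]],
    dc_b: Union[pd.Series, Sequence[float]],
) -> dict:
    """Paired t-test of two centrality profiles over the same emotions.

    Differences are taken a - b, so a positive t means profile ``a`` is the
    more interconnected one. Returns t, df, p (two-sided) and Cohen's d for
    paired samples (mean difference / SD of differences).
    """
    a = pd.Series(dc_a).astype(float)
    b = pd.Series(dc_b).astype(float)
    if isinstance(dc_a, pd.Series) and isinstance(dc_b, pd.Series):
        if list(a.index) != list(b.index):
            b = b.reindex(a.index)
            if b.isna().any():
                raise ValueError("profiles must cover the same emotions")
    if len(a) != len(b):
        raise ValueError("profiles must have equal length")
    diff = a.to_numpy() - b.to_numpy()
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return {"t": 0.0, "df": n - 1, "p": 1.0, "cohens_d": 0.0, "degenerate": False}
        warnings.warn("zero SD of differences: t statistic unbounded", stacklevel=2)
        return {
            "t": np.inf * np.sign(diff.mean()),
            "df": n - 1,
            "p": 0.0,
            "cohens_d": np.inf * np.sign(diff.mean()),
            "degenerate": True,
        }
    res = stats.ttest_rel(a.to_numpy(), b.to_numpy())
    d = diff.mean() / sd
    return {
        "t": float(res.statistic),
        "df": int(n - 1),
        "p": float(res.pvalue),
        "cohens_d": float(d),
        "degenerate": False,
    }


def frequency_centrality_correlation(
    freq: Union[pd.Series, Sequence[float]],
    dc: Union[pd.Series, Sequence[float]],
) -> dict:
    """Pearson r between per-emotion frequency and DC, with a Fisher-z CI.

    With only 18 emotions the interval is wide; the Fisher z transform gives
    the standard 95% CI, r in [tanh(z - 1.96/sqrt(n-3)), tanh(z + 1.96/sqrt(n-3))].
    """
    f = pd.Series(freq).astype(float)
    c = pd.Series(dc).astype(float)
    if isinstance(freq, pd.Series) and isinstance(dc, pd.Series):
        c = c.reindex(f.index)
        if c.isna().any():
            raise ValueError("frequency and centrality must cover the same emotions")
    if len(f) != len(c):
        raise ValueError("inputs must have equal length")
    n = len(f)
    if f.std(ddof=0) == 0 or c.std(ddof=0) == 0:
        warnings.warn("constant input: correlation undefined", stacklevel=2)
        return {"r": np.nan, "ci_low": np.nan, "ci_high": np.nan, "n": n}
    r = float(np.corrcoef(f, c)[0, 1])
    if abs(r) >= 1.0:
        return {"r": r, "ci_low": r, "ci_high": r, "n": n}
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return {"r": r, "ci_low": float(lo), "ci_high": float(hi), "n": n}


def cooccurrence_table(dataset: ReportDataset) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise co-endorsement counts and opposite-valence co-occurrence rates.

    Returns
    -------
    counts
        k x k DataFrame; entry (a, b) is the number of reports endorsing both
        a and b (the diagonal holds each emotion's endorsement count).
    mixed_rate
        Per emotion, the proportion of its endorsements in which at least one
        opposite-valence emotion was endorsed in the same report; NaN for an
        emotion that was never endorsed.
    """
    X = dataset.indicators.astype(np.int64)
    names = list(dataset.taxonomy)
    counts = pd.DataFrame(X.T @ X, index=names, columns=names)
    pos_mask = dataset.taxonomy.positive_mask()
    any_pos = X[:, pos_mask].any(axis=1)
    any_neg = X[:, ~pos_mask].any(axis=1)
    rates = {}
    for i, e in enumerate(names):
        endorsed = X[:, i] == 1
        total = int(endorsed.sum())
        if total == 0:
            rates[e] = np.nan
            continue
        opp = any_neg if pos_mask[i] else any_pos
        rates[e] = float((endorsed & opp).sum() / total)
    return counts, pd.Series(rates, name="opposite_valence_cooccurrence_rate")


class EmotionNetwork(BaseEstimator):
    """Estimator for the signed emotion network and its centrality typology.

    Follows the scikit-learn convention: ``fit`` ingests either a
    ``ReportDataset`` or a plain (n_reports, n_emotions) binary matrix and
    exposes the results as fitted attributes.

    Parameters
    ----------
    tau : float, default 0.1
        Absolute edge-weight threshold above which an edge counts as strong
        for the connector/provincial/distal classification.
    taxonomy : EmotionTaxonomy, optional
        Defaults to the 18-emotion mDES taxonomy (or the dataset's own).
    person_centered : bool, default False
        Subtract participant means before correlating (within-person
        sensitivity variant).

    Attributes
    ----------
    weights_ : WeightMatrix
        The signed phi-correlation network.
    degree_centrality_ : pd.Series
        DC per emotion.
    typology_ : pd.Series
        Connector/provincial/distal label per emotion.
    mask_ : np.ndarray
        True for pairs whose phi was undefined (constant indicator).
    n_reports_ : int
    """

    def __init__(
        self,
        tau: float = 0.1,
        taxonomy: Optional[EmotionTaxonomy] = None,
        person_centered: bool = False,
    ):
        self.tau = tau
        self.taxonomy = taxonomy
        self.person_centered = person_centered

    def fit(self, X: Union[ReportDataset, np.ndarray], y=None) -> "EmotionNetwork":
        if not isinstance(X, ReportDataset):
            X = dataset_from_arrays(np.asarray(X), taxonomy=self.taxonomy)
        self.weights_ = phi_matrix(X, person_centered=self.person_centered)
        self.mask_ = self.weights_.mask
        self.n_reports_ = self.weights_.n_reports
        self.degree_centrality_ = degree_centrality(self.weights_)
        self.typology_ = classify_typology(
            self.weights_, X.taxonomy, tau=self.tau
        ).to_series()
        return self

    def summary(self) -> pd.DataFrame:
        """Per-emotion DC and typology as one table."""
        return pd.DataFrame(
            {
                "degree_centrality": self.degree_centrality_,
                "typology": self.typology_,
            }
        )
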