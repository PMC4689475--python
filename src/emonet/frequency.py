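"""Frequency of emotions: multilevel point estimates, CIs, temporal profiles.

Every frequency here is "percentage of reports" for a binary per-report
outcome: a single emotion's indicator, a report category, or "any emotion".
Reports are nested in participants, so the model-based estimates use a
linear-probability model with a compound-symmetry (exchangeable)
within-participant covariance, fitted as a GEE with exchangeable working
correlation — its point estimate is the random-intercept GLS mean and its
sandwich CI is cluster-robust, which is exactly the fallback needed when
the within-participant correlation is estimated at zero.

Report categories partition prompts into ``positive_only`` (>=1 positive, no
negative emotion endorsed), ``negative_only`` (the mirror image), ``mixed``
(at least one of each valence simultaneously) and ``none`` (the all-zero
report). By construction the four pooled category frequencies sum to 100%
and "any emotion" equals 100% minus "none".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

from .datasets import ReportDataset
from .taxonomy import EmotionTaxonomy

CATEGORIES = ("positive_only", "negative_only", "mixed", "none")
Z95 = 1.959963984540054


def categorize_report(indicators: Sequence[int], taxonomy: EmotionTaxonomy) -> str:
    """Category of a single report's indicator vector."""
    v = np.asarray(indicators)
    if v.shape != (len(taxonomy),):
        raise ValueError(
            f"indicator vector must have length {len(taxonomy)}, got {v.shape}"
        )
    pos = taxonomy.positive_mask()
    has_pos, has_neg = bool(v[pos].any()), bool(v[~pos].any())
    if has_pos and has_neg:
        return "mixed"
    if has_pos:
        return "positive_only"
    if has_neg:
        return "negative_only"
    return "none"


def categorize_reports(dataset: ReportDataset) -> pd.Series:
    """Category per report (vectorized), aligned to the dataset rows."""
    X = dataset.indicators
    pos = dataset.taxonomy.positive_mask()
    has_pos = X[:, pos].any(axis=1)
    has_neg = X[:, ~pos].any(axis=1)
    out = np.where(
        has_pos & has_neg,
        "mixed",
        np.where(has_pos, "positive_only", np.where(has_neg, "negative_only", "none")),
    )
    return pd.Series(out, index=dataset.df.index, name="category")


def _outcome_vector(dataset: ReportDataset, target: str) -> np.ndarray:
    """Binary per-report outcome for an emotion, category, or 'any'."""
    if target == "any":
        return dataset.indicators.any(axis=1).astype(float)
    if target in dataset.taxonomy:
        return dataset.indicators[:, dataset.taxonomy.index(target)].astype(float)
    if target in CATEGORIES:
        return (categorize_reports(dataset) == target).to_numpy(dtype=float)
    raise ValueError(f"unknown target {target!r}")


@dataclass
class FrequencyEstimate:
    """Point estimate (percentage of reports) with a 95% CI."""

    target: str
    estimate: float  # percent
    ci_low: float
    ci_high: float
    n_reports: int
    n_participants: int
    pooled: float = np.nan  # pooled proportion, percent
    ci_method: str = "exchangeable"

    def __post_init__(self) -> None:
        self.ci_low = float(np.clip(self.ci_low, 0.0, 100.0))
        self.ci_high = float(np.clip(self.ci_high, 0.0, 100.0))
        if not self.ci_low <= self.estimate + 1e-9 or not self.estimate <= self.ci_high + 1e-9:
            raise ValueError(
                f"CI must bracket the estimate: {self.ci_low}, {self.estimate}, {self.ci_high}"
            )


def _cluster_robust_pooled(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Pooled proportion and its cluster-robust SE (both on the 0-1 scale)."""
    n = len(y)
    p = y.mean()
    resid = pd.Series(y - p).groupby(groups).sum().to_numpy()
    se = np.sqrt((resid**2).sum()) / n
    return float(p), float(se)


def estimate_frequency(
    dataset: ReportDataset,
    target: str,
    method: str = "exchangeable",
    link: str = "identity",
) -> FrequencyEstimate:
    """Estimate how often ``target`` occurs, as a percentage of reports.

    Parameters
    ----------
    dataset
        Reports nested in participants.
    target
        An emotion name, a category (``positive_only``, ``negative_only``,
        ``mixed``, ``none``) or ``"any"``.
    method
        ``"exchangeable"`` (default): compound-symmetry multilevel model via
        GEE with exchangeable working correlation; ``"pooled"``: pooled
        proportion with a cluster-robust Wald CI.
    link
        ``"identity"`` (linear-probability, symmetric CI on the percentage
        scale) or ``"logit"`` (CI computed on the logit scale and mapped
        back).

    Notes
    -----
    Degenerate cases: a constant outcome returns a zero-width CI; a single
    participant cannot support a between-participant variance component, so
    the estimate is the pooled proportion with a Wilson binomial CI, flagged
    in ``ci_method``.
    """
    if method not in ("exchangeable", "pooled"):
        raise ValueError(f"method must be 'exchangeable' or 'pooled', got {method!r}")
    if link not in ("identity", "logit"):
        raise ValueError(f"link must be 'identity' or 'logit', got {link!r}")
    y = _outcome_vector(dataset, target)
    groups = dataset.participant_ids.to_numpy()
    n, n_part = len(y), dataset.n_participants
    pooled_pct = 100.0 * float(y.mean())

    def make(est, lo, hi, how):
        return FrequencyEstimate(
            target, est, lo, hi, n, n_part, pooled=pooled_pct, ci_method=how
        )

    if y.min() == y.max():  # constant outcome: no sampling variability to model
        return make(pooled_pct, pooled_pct, pooled_pct, "degenerate")
    if n_part < 2:
        lo, hi = sm.stats.proportion_confint(int(y.sum()), n, method="wilson")
        warnings.warn(
            "single participant: model-based CI unavailable, using binomial CI",
            stacklevel=2,
        )
        return make(pooled_pct, 100 * lo, 100 * hi, "binomial")

    if method == "pooled":
        p, se = _cluster_robust_pooled(y, groups)
        return make(100 * p, 100 * (p - Z95 * se), 100 * (p + Z95 * se), "cluster_robust")

    exog = np.ones((n, 1))
    cov = sm.cov_struct.Exchangeable()
    family = sm.families.Gaussian() if link == "identity" else sm.families.Binomial()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GEE(y, exog, groups=groups, family=family, cov_struct=cov).fit()
        beta, se = float(res.params[0]), float(res.bse[0])
        if not np.isfinite(beta) or not np.isfinite(se):
            raise ValueError("non-finite GEE result")
    except Exception:
        p, se = _cluster_robust_pooled(y, groups)
        return make(100 * p, 100 * (p - Z95 * se), 100 * (p + Z95 * se), "cluster_robust")
    how = "exchangeable"
    if cov.dep_params <= 0:
        # working correlation at/below zero: estimate collapses to the pooled
        # proportion; the sandwich CI is already the cluster-robust one
        how = "cluster_robust"
    if link == "identity":
        est, lo, hi = beta, beta - Z95 * se, beta + Z95 * se
    else:
        est = expit(beta)
        lo, hi = expit(beta - Z95 * se), expit(beta + Z95 * se)
    return make(100 * est, 100 * lo, 100 * hi, how)


class FrequencyEstimator(BaseEstimator):
    """Estimator producing the full frequency table of a report dataset.

    One row per emotion (sorted by descending frequency), per category
    (positive_only, negative_only, mixed) and for "any emotion" — 22 rows
    for the 18-emotion taxonomy. Both the model-based estimate and the
    pooled proportion are reported.

    Parameters
    ----------
    method : {"exchangeable", "pooled"}, default "exchangeable"
    link : {"identity", "logit"}, default "identity"

    Attributes
    ----------
    table_ : pd.DataFrame
        Columns: target, kind, estimate_pct, ci_low, ci_high, pooled_pct,
        n_reports, n_participants, ci_method.
    estimates_ : dict[str, FrequencyEstimate]
    """

    def __init__(self, method: str = "exchangeable", link: str = "identity"):
        self.method = method
        self.link = link

    def fit(self, X: ReportDataset, y=None) -> "FrequencyEstimator":
        targets = list(X.taxonomy) + ["positive_only", "negative_only", "mixed", "any"]
        self.estimates_ = {
            t: estimate_frequency(X, t, method=self.method, link=self.link)
            for t in targets
        }
        rows = []
        for t, e in self.estimates_.items():
            kind = (
                "emotion"
                if t in X.taxonomy
                else ("any" if t == "any" else "category")
            )
            rows.append(
                {
                    "target": t,
                    "kind": kind,
                    "estimate_pct": e.estimate,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "pooled_pct": e.pooled,
                    "n_reports": e.n_reports,
                    "n_participants": e.n_participants,
                    "ci_method": e.ci_method,
                }
            )
        df = pd.DataFrame(rows)
        order = {"emotion": 0, "category": 1, "any": 2}
        df["_k"] = df["kind"].map(order)
        df = (
            df.sort_values(["_k", "estimate_pct"], ascending=[True, False], kind="stable")
            .drop(columns="_k")
            .reset_index(drop=True)
        )
        # categories keep their canonical order rather than frequency order
        cat = df[df.kind == "category"].set_index("target")
        cat = cat.loc[["positive_only", "negative_only", "mixed"]].reset_index()
        df = pd.concat(
            [df[df.kind == "emotion"], cat, df[df.kind == "any"]], ignore_index=True
        )
        self.table_ = df
        return self


def frequency_table(
    dataset: ReportDataset, method: str = "exchangeable", link: str = "identity"
) -> pd.DataFrame:
    """Frequency table (18 emotions + 3 categories + any = 22 rows)."""
    return FrequencyEstimator(method=method, link=link).fit(dataset).table_


def positive_negative_ratio(dataset: ReportDataset, method: str = "pooled") -> float:
    """How many times more often positive-only than negative-only reports occur.

    Returns ``NaN`` with a warning when no report is negative-only.
    """
    pos = estimate_frequency(dataset, "positive_only", method=method).estimate
    neg = estimate_frequency(dataset, "negative_only", method=method).estimate
    if neg == 0:
        warnings.warn("no negative-only reports: ratio undefined", stacklevel=2)
        return float("nan")
    return pos / neg


@dataclass
class TemporalProfile:
    """Pooled frequency of a target by hour of day or ISO weekday."""

    target: str
    by: str  # "hour" or "weekday"
    values: dict[int, float] = field(default_factory=dict)  # bin -> proportion
    n: dict[int, int] = field(default_factory=dict)  # bin -> report count

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.target).sort_index()

    @property
    def bins(self) -> tuple[int, ...]:
        return tuple(sorted(self.values))


def temporal_profile(
    dataset: ReportDataset,
    target: str,
    by: str = "hour",
    hour_range: tuple[int, int] = (6, 22),
    min_reports: int = 1000,
) -> TemporalProfile:
    """Pooled frequency of ``target`` per hour of day or per weekday.

    Hour bins are the floor of the local clock hour; bins outside
    ``hour_range`` (inclusive) are excluded, as are bins with fewer than
    ``min_reports`` reports — sparse night-time bins would otherwise yield
    unstable frequencies. Weekdays are ISO (Monday=1..Sunday=7) and are not
    range-filtered.
    """
    if by not in ("hour", "weekday"):
        raise ValueError(f"by must be 'hour' or 'weekday', got {by!r}")
    y = _outcome_vector(dataset, target)
    ts = dataset.timestamps
    bins = ts.dt.hour if by == "hour" else ts.dt.dayofweek + 1
    grouped = pd.DataFrame({"bin": bins.to_numpy(), "y": y}).groupby("bin")["y"]
    values, counts = {}, {}
    for b, series in grouped:
        b = int(b)
        if by == "hour" and not hour_range[0] <= b <= hour_range[1]:
            continue
        if len(series) < min_reports:
            continue
        values[b] = float(series.mean())
        counts[b] = int(len(series))
    if not values:
        warnings.warn(
            f"no {by} bins left for {target!r} after filtering", stacklevel=2
        )
    return TemporalProfile(target, by, values, counts)


def fluctuation_magnitude(
    profiles: Mapping[str, TemporalProfile],
    emotion_set: Optional[Sequence[str]] = None,
) -> float:
    """Mean across emotions of the SD of hourly frequencies.

    For each emotion in ``emotion_set`` (default: all profiled), take the
    sample standard deviation (n-1 denominator) of its per-bin frequencies;
    return the mean of those SDs. All profiles must cover the same bins and
    at least two of them.
    """
    emotions = list(emotion_set) if emotion_set is not None else list(profiles)
    if not emotions:
        raise ValueError("empty emotion set")
    ref_bins = profiles[emotions[0]].bins
    if len(ref_bins) < 2:
        raise ValueError("need at least 2 bins to measure fluctuation")
    sds = []
    for e in emotions:
        prof = profiles[e]
        if prof.bins != ref_bins:
            raise ValueError(
                f"profile for {e!r} covers bins {prof.bins}, expected {ref_bins}"
            )
        vals = np.array([prof.values[b] for b in ref_bins])
        sds.append(vals.std(ddof=1))
    return float(np.mean(sds))
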