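"""End-to-end analysis pipeline: data in, reproducible report bundle out.

One config drives the whole analysis — load a report CSV (or generate a
synthetic dataset), estimate the frequency table, build temporal profiles,
fit the signed network with centrality and typology, and compare group
networks — writing every product plus a manifest that suffices to re-run
the identical analysis. All randomness flows from the single seed, so an
identical config yields a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .datasets import ReportDataset
from .frequency import (
    CATEGORIES,
    FrequencyEstimator,
    fluctuation_magnitude,
    positive_negative_ratio,
    temporal_profile,
)
from .io import load_reports, write_network
from .network import (
    EmotionNetwork,
    compare_centrality,
    frequency_centrality_correlation,
)
from .simulate import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Configuration of one full pipeline run.

    Exactly one of ``input_csv`` / ``synthetic`` must be given.
    """

    input_csv: Optional[str] = None
    schema_: str = Field(default="wide", alias="schema")
    synthetic: Optional[SyntheticConfig] = None
    out_dir: str = "emonet_out"
    tau: float = Field(default=0.1, gt=0)
    hour_range: tuple[int, int] = (6, 22)
    min_reports: int = Field(default=1000, ge=1)
    group_col: Optional[str] = "gender"
    method: str = "exchangeable"
    seed: Optional[int] = None  # overrides synthetic.seed when given

    model_config = {"populate_by_name": True}

    @model_validator(mode="after")
    def _one_input(self) -> "PipelineConfig":
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csv / synthetic must be set")
        return self

    def config_hash(self) -> str:
        """Hash of the analysis-defining fields (output location excluded)."""
        payload = self.model_dump(by_alias=True, exclude={"out_dir"})
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_or_generate(config: PipelineConfig) -> ReportDataset:
    if config.input_csv is not None:
        return load_reports(config.input_csv, schema=config.schema_)
    syn = config.synthetic
    if config.seed is not None:
        syn = syn.model_copy(update={"seed": config.seed})
    return generate_dataset(syn)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory products (dataset, tables, network)
    and the paths written. Raises on any stage failure, with the stage name
    in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_warnings: list[str] = []
    paths: dict[str, str] = {}
    t0 = time.time()

    def stage(name: str):
        logger.info("stage %-12s t=%.1fs", name, time.time() - t0)

    stage("load")
    dataset = _load_or_generate(config)

    stage("frequencies")
    est = FrequencyEstimator(method=config.method).fit(dataset)
    freq = est.table_
    paths["frequencies"] = str(out / "frequencies.csv")
    freq.to_csv(paths["frequencies"], index=False, float_format="%.6g")

    stage("profiles")
    targets = list(dataset.taxonomy) + list(CATEGORIES) + ["any"]
    prof_rows = []
    profiles_hour = {}
    for by in ("hour", "weekday"):
        for t in targets:
            import warnings as _w

            with _w.catch_warnings(record=True) as caught:
                _w.simplefilter("always")
                prof = temporal_profile(
                    dataset,
                    t,
                    by=by,
                    hour_range=config.hour_range,
                    min_reports=config.min_reports,
                )
            for c in caught:
                run_warnings.append(str(c.message))
            if by == "hour":
                profiles_hour[t] = prof
            for b in prof.bins:
                prof_rows.append(
                    {"target": t, "by": by, "bin": b,
                     "frequency": prof.values[b], "n": prof.n[b]}
                )
    profiles = pd.DataFrame(
        prof_rows, columns=["target", "by", "bin", "frequency", "n"]
    )
    paths["profiles"] = str(out / "temporal_profiles.csv")
    profiles.to_csv(paths["profiles"], index=False, float_format="%.6g")

    fluct: dict[str, float] = {}
    pos_profiles = {e: profiles_hour[e] for e in dataset.taxonomy.positive}
    if all(len(p.bins) >= 2 for p in pos_profiles.values()):
        fluct["mean_sd_positive"] = fluctuation_magnitude(
            profiles_hour, dataset.taxonomy.positive
        )
        fluct["mean_sd_negative"] = fluctuation_magnitude(
            profiles_hour, dataset.taxonomy.negative
        )
    else:
        run_warnings.append("too few hour bins for fluctuation magnitude")

    stage("network")
    net = EmotionNetwork(tau=config.tau).fit(dataset)
    pooled_freq = freq.set_index("target")["pooled_pct"]
    paths["edges"] = str(out / "edges.csv")
    write_network(net.weights_, paths["edges"], format="edge_list_csv")
    paths["graphml"] = str(out / "network.graphml")
    write_network(
        net.weights_, paths["graphml"], format="graphml", frequency=pooled_freq
    )
    centrality = net.summary().rename_axis("emotion").reset_index()
    paths["centrality"] = str(out / "centrality.csv")
    centrality.to_csv(paths["centrality"], index=False, float_format="%.6g")
    if net.mask_.any():
        masked = sorted(
            {list(dataset.taxonomy)[i] for i in net.mask_.any(axis=1).nonzero()[0]}
        )
        run_warnings.append(f"phi undefined (constant indicator) for: {masked}")

    stage("compare")
    comparison = None
    col = config.group_col
    if col:
        if col not in dataset.df.columns or dataset.df[col].nunique() < 2:
            run_warnings.append(
                f"group comparison skipped: column {col!r} missing or single-level"
            )
        else:
            groups = dataset.by_group(col)
            levels = sorted(groups, key=lambda g: -groups[g].n_reports)[:2]
            levels = sorted(levels)
            nets = {g: EmotionNetwork(tau=config.tau).fit(groups[g]) for g in levels}
            comparison = compare_centrality(
                nets[levels[0]].degree_centrality_, nets[levels[1]].degree_centrality_
            )
            comparison = {"group_a": levels[0], "group_b": levels[1], **comparison}
            paths["comparison"] = str(out / "comparison.json")
            Path(paths["comparison"]).write_text(json.dumps(comparison, indent=2))

    stage("summary")
    emo_freq = freq[freq.kind == "emotion"].set_index("target")["estimate_pct"]
    fc = frequency_centrality_correlation(
        emo_freq.reindex(list(dataset.taxonomy)), net.degree_centrality_
    )
    headline = {t: float(freq.set_index("target").loc[t, "estimate_pct"])
                for t in ("any", "positive_only", "negative_only", "mixed")}
    summary = {
        "n_reports": dataset.n_reports,
        "n_participants": dataset.n_participants,
        "headline_pct": headline,
        "positive_negative_ratio": positive_negative_ratio(dataset),
        "fluctuation": fluct,
        "frequency_centrality_r": fc,
        "typology_counts": net.typology_.value_counts().to_dict(),
    }
    paths["summary"] = str(out / "summary.json")
    Path(paths["summary"]).write_text(json.dumps(summary, indent=2))

    manifest = {
        "emonet_version": __version__,
        "library_versions": _library_versions(),
        "config": json.loads(config.model_dump_json(by_alias=True)),
        "config_hash": config.config_hash(),
        "seed": config.seed if config.seed is not None
        else (config.synthetic.seed if config.synthetic else None),
        "warnings": run_warnings,
        "outputs": paths,
    }
    paths["manifest"] = str(out / "manifest.json")
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2))
    stage("done")

    return {
        "dataset": dataset,
        "frequencies": freq,
        "profiles": profiles,
        "network": net,
        "comparison": comparison,
        "summary": summary,
        "paths": paths,
    }


def _library_versions() -> dict[str, str]:
    import numpy
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
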