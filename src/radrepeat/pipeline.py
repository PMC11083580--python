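"""End-to-end orchestration: simulate/load -> transform -> fit -> summarise
-> group -> report, as one seeded, logged, reproducible run."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import grouping as grp
from . import reporting
from .cohort import CohortSpec, generate_cohort, validate_measurement_table
from .features import (
    FeatureRegistry,
    Transform,
    TransformDomainError,
    apply_transform,
)
from .model import (
    ConvergenceError,
    ModelConfig,
    destandardise,
    fit_with_retries,
    initial_values,
    standardise,
)
from .stats import RepeatabilitySummary, summarise_feature

logger = logging.getLogger("radrepeat")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "transform_table"]


@dataclass
class RunConfig:
    """One pipeline run.

    Exactly one input source: ``synthetic`` (a list of cohort specs, one per
    feature) or ``csv_path`` (a long-format measurement table).  Transforms
    come from ``registry`` when a feature is registered there, otherwise
    ``default_transform`` applies; measurements already on their model scale
    should use ``identity``.
    """

    synthetic: list[CohortSpec] | None = None
    csv_path: str | Path | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    registry: FeatureRegistry | None = None
    default_transform: Transform = Transform.LOG
    features: list[str] | None = None
    cluster_threshold: float = grp.DEFAULT_THRESHOLD
    reference_feature: str | None = None
    output_dir: str | Path = "radrepeat_output"
    render_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.csv_path is None):
            raise ValueError("exactly one input source (synthetic or csv_path)")


@dataclass
class PipelineResult:
    table: pd.DataFrame
    transformed: pd.DataFrame
    summaries: dict[str, RepeatabilitySummary]
    groups: grp.FeatureGroups | None
    overview: pd.DataFrame | None
    failures: dict[str, str]
    manifest: list[str]
    convergence: dict[str, int]

    @property
    def exit_code(self) -> int:
        return 1 if self.failures else 0


def _feature_transform(config: RunConfig, feature: str) -> Transform:
    if config.registry is not None and feature in config.registry:
        return config.registry.transform(feature)
    return Transform(config.default_transform)


def transform_table(
    config: RunConfig, table: pd.DataFrame, features: list[str]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Apply each feature's transform to every measurement.

    Returns the transformed table and a map of features excluded because a
    value fell outside the transform domain (flagged, never silent)."""
    failures: dict[str, str] = {}
    parts = []
    for feature in features:
        rule = _feature_transform(config, feature)
        sub = table[table["feature_name"] == feature].copy()
        try:
            sub["value"] = [apply_transform(v, rule) for v in sub["value"]]
        except TransformDomainError as exc:
            failures[feature] = f"transform: {exc}"
            continue
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True) if parts else table.iloc[0:0].copy()
    return out, failures


def _load_table(config: RunConfig) -> pd.DataFrame:
    if config.synthetic is not None:
        tables = [generate_cohort(spec) for spec in config.synthetic]
        table = pd.concat(tables, ignore_index=True)
    else:
        path = Path(config.csv_path)
        if not path.exists():
            raise FileNotFoundError(path)
        table = pd.read_csv(path)
    validate_measurement_table(table)
    return table


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis for every requested feature.

    Per-feature failures (transform domain, degenerate data, non-convergence
    after the retry budget) are collected and reported in the run log; they
    never abort the remaining features.  Everything is a pure function of the
    config (including its seed).
    """
    table = _load_table(config)
    features = config.features or sorted(table["feature_name"].unique())
    missing = [f for f in features if f not in set(table["feature_name"])]
    if missing:
        raise ValueError(f"unknown feature names: {missing}")

    transformed, failures = transform_table(config, table, features)

    summaries: dict[str, RepeatabilitySummary] = {}
    convergence: dict[str, int] = {}
    for k, feature in enumerate(f for f in features if f not in failures):
        mconf = replace(
            config.model,
            seed=int(np.random.SeedSequence(config.seed, spawn_key=(k,))
                     .generate_state(1)[0] % (2**31)),
        )
        try:
            data = standardise(transformed, feature)
            init = initial_values(data)
            samples, report = fit_with_retries(data, init, mconf)
            convergence[feature] = report.retries_used
            samples = destandardise(samples, data)
            summaries[feature] = summarise_feature(
                samples, feature=feature,
                transform=_feature_transform(config, feature),
            )
        except (ValueError, ZeroDivisionError, ConvergenceError) as exc:
            failures[feature] = f"{type(exc).__name__}: {exc}"
            logger.warning("feature %s failed: %s", feature, exc)

    groups = None
    if len(summaries) >= 2:
        try:
            dist = grp.spearman_distance(transformed, sorted(summaries))
            groups = grp.cluster_features(dist, threshold=config.cluster_threshold)
            groups = grp.select_representatives(groups, summaries)
        except ValueError as exc:
            logger.warning("feature grouping skipped: %s", exc)

    overview = None
    if config.reference_feature is not None and summaries:
        overview = reporting.icc_overview(summaries, config.reference_feature)

    ba_features = (
        [g.representative for g in groups.groups] if groups is not None
        else sorted(summaries)
    )
    bland_altman = [
        reporting.bland_altman_table(transformed, f, summaries[f])
        for f in ba_features
    ]

    manifest = reporting.write_reports(
        config.output_dir,
        summaries=summaries,
        groups=groups,
        bland_altman=bland_altman,
        overview=overview,
        config_echo={
            "seed": config.seed,
            "features": features,
            "cluster_threshold": config.cluster_threshold,
            "reference_feature": config.reference_feature,
            "model": vars(config.model),
            "retries_used": convergence,
            "failures": failures,
        },
        failures=failures,
        render_plots=config.render_plots,
    )
    return PipelineResult(
        table=table, transformed=transformed, summaries=summaries,
        groups=groups, overview=overview, failures=failures,
        manifest=manifest, convergence=convergence,
    )
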