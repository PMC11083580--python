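"""Tabular analysis outputs: Bland-Altman records, ICC overview tables and
the report writer.

Bland-Altman analysis is done on the transformed (model) scale; for
log-scale features the repeatability limits are additionally expressed as
percentage bounds by back-transforming +-1.96*sqrt(2)*sigma_r' through the
exponential — the same adjustment used for heteroscedastic (proportional-
error) data in the limits-of-agreement literature.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import LOG_SCALE_TRANSFORMS, Transform
from .stats import RepeatabilitySummary, repeatability_coefficient

logger = logging.getLogger("radrepeat")

__all__ = [
    "BlandAltmanResult",
    "bland_altman_table",
    "icc_overview",
    "write_reports",
]


@dataclass
class BlandAltmanResult:
    """Per-lesion pair means/differences plus repeatability limits.

    ``records`` columns: patient_id, lesion_id, pair_mean, pair_difference
    (repeat2 - repeat1), on the transformed scale.  ``loa_percent`` is the
    (lower, upper) percentage-change bound for log-scale features, else None.
    """

    feature: str
    records: pd.DataFrame
    rc: float
    limit_lower: float
    limit_upper: float
    loa_percent: tuple[float, float] | None
    skipped_lesions: list[str] = field(default_factory=list)


def bland_altman_table(
    table: pd.DataFrame,
    feature: str,
    summary: RepeatabilitySummary,
    transform: Transform | None = None,
) -> BlandAltmanResult:
    """Build the Bland-Altman record set for one feature.

    Differences and means are computed on the transformed scale the model
    saw; limits are +-RC around zero using the posterior-median sigma_r.
    Lesions missing a repeat are skipped with a warning, not dropped
    silently.
    """
    transform = Transform(transform if transform is not None else summary.transform)
    sub = table[table["feature_name"] == feature]
    if sub.empty:
        raise ValueError(f"feature '{feature}' not present in table")
    wide = sub.pivot_table(
        index=["patient_id", "lesion_id"], columns="repeat", values="value",
        sort=False,
    )
    skipped = []
    if 1 not in wide.columns or 2 not in wide.columns:
        raise ValueError(f"feature '{feature}' lacks one of the two repeats")
    incomplete = wide[wide[[1, 2]].isna().any(axis=1)]
    for (_, lid) in incomplete.index:
        skipped.append(lid)
        logger.warning("Bland-Altman: lesion %s skipped (missing repeat)", lid)
    wide = wide.dropna(subset=[1, 2])

    records = pd.DataFrame({
        "patient_id": [p for p, _ in wide.index],
        "lesion_id": [l for _, l in wide.index],
        "pair_mean": (wide[1] + wide[2]).to_numpy(float) / 2.0,
        "pair_difference": (wide[2] - wide[1]).to_numpy(float),
    })
    rc = summary.rc.median
    if transform in LOG_SCALE_TRANSFORMS and summary.loa_lower is not None:
        loa = (summary.loa_lower.median, summary.loa_upper.median)
    else:
        loa = None
    return BlandAltmanResult(
        feature=feature,
        records=records,
        rc=rc,
        limit_lower=-rc,
        limit_upper=rc,
        loa_percent=loa,
        skipped_lesions=skipped,
    )


def icc_overview(
    summaries: dict[str, RepeatabilitySummary],
    reference_feature: str,
    use_interval_overlap: bool = False,
) -> pd.DataFrame:
    """Waterfall-style overview of ICCs against a reference metric.

    Features are sorted by descending median intra-patient ICC, with IQR
    columns; the flags mark features whose ICC is at least the reference's
    ("good repeatability").  By default medians are compared point-wise; with
    ``use_interval_overlap`` a feature also qualifies when its 95% interval
    overlaps the reference median (ICC uncertainty can be large).
    """
    if reference_feature not in summaries:
        raise KeyError(f"reference feature '{reference_feature}' has no summary")
    ref = summaries[reference_feature]
    rows = []
    for name, s in summaries.items():
        if use_interval_overlap:
            intra_ok = s.icc_intra.ci95[1] >= ref.icc_intra.median
            inter_ok = s.icc_inter.ci95[1] >= ref.icc_inter.median
        else:
            intra_ok = s.icc_intra.median >= ref.icc_intra.median
            inter_ok = s.icc_inter.median >= ref.icc_inter.median
        rows.append({
            "feature": name,
            "icc_intra_median": s.icc_intra.median,
            "icc_intra_iqr_lo": s.icc_intra.iqr[0],
            "icc_intra_iqr_hi": s.icc_intra.iqr[1],
            "icc_inter_median": s.icc_inter.median,
            "icc_inter_iqr_lo": s.icc_inter.iqr[0],
            "icc_inter_iqr_hi": s.icc_inter.iqr[1],
            "ge_reference_intra": bool(intra_ok),
            "ge_reference_inter": bool(inter_ok),
        })
    df = pd.DataFrame(rows).sort_values(
        ["icc_intra_median", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


def write_reports(
    directory: str | Path,
    summaries: dict[str, RepeatabilitySummary] | None = None,
    groups=None,
    bland_altman: list[BlandAltmanResult] | None = None,
    overview: pd.DataFrame | None = None,
    config_echo: dict | None = None,
    failures: dict[str, str] | None = None,
    render_plots: bool = False,
) -> list[str]:
    """Write the deterministic report file set; returns the manifest.

    Always writes the config echo and a run log; summaries CSV, groups JSON,
    per-feature Bland-Altman CSVs and the ICC overview are written when
    provided.  Plots (Bland-Altman scatter, ICC waterfall) are optional
    artifacts rendered only on request.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"report directory '{directory}' is not writable: {exc}")

    manifest: list[str] = []

    def _register(path: Path) -> Path:
        manifest.append(path.name)
        return path

    echo = dict(config_echo or {})
    with open(_register(directory / "run_config.json"), "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True, default=str)

    if summaries:
        df = pd.DataFrame([s.row() for s in summaries.values()])
        df.to_csv(_register(directory / "summaries.csv"), index=False)
    if overview is not None:
        overview.to_csv(_register(directory / "icc_overview.csv"), index=False)
    if groups is not None:
        with open(_register(directory / "feature_groups.json"), "w") as fh:
            json.dump(groups.to_dict(), fh, indent=2, sort_keys=True)
    for ba in bland_altman or []:
        out = ba.records.copy()
        out["rc"] = ba.rc
        out["limit_lower"] = ba.limit_lower
        out["limit_upper"] = ba.limit_upper
        if ba.loa_percent is not None:
            out["loa_lower_pct"], out["loa_upper_pct"] = ba.loa_percent
        safe = ba.feature.replace("/", "_")
        out.to_csv(_register(directory / f"bland_altman_{safe}.csv"), index=False)
        if render_plots:
            _render_bland_altman(ba, directory / f"bland_altman_{safe}.png")
            manifest.append(f"bland_altman_{safe}.png")
    if render_plots and overview is not None and len(overview):
        _render_waterfall(overview, directory / "icc_waterfall.png")
        manifest.append("icc_waterfall.png")

    log_lines = [f"files: {len(manifest) + 1}"]
    for name, why in (failures or {}).items():
        log_lines.append(f"FAILED {name}: {why}")
    (_register(directory / "run.log")).write_text("\n".join(log_lines) + "\n")
    return sorted(manifest)


def _render_bland_altman(ba: BlandAltmanResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for pid, grp in ba.records.groupby("patient_id"):
        ax.scatter(grp["pair_mean"], grp["pair_difference"], s=18, label=pid)
    for y, style in [(0.0, ":"), (ba.limit_lower, "--"), (ba.limit_upper, "--")]:
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("pair mean (transformed)")
    ax.set_ylabel("repeat 2 - repeat 1")
    ax.set_title(ba.feature, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _render_waterfall(overview: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(5, 0.25 * len(overview)), 4))
    x = np.arange(len(overview))
    ax.bar(x, overview["icc_intra_median"], color="tab:blue")
    err = np.vstack([
        overview["icc_intra_median"] - overview["icc_intra_iqr_lo"],
        overview["icc_intra_iqr_hi"] - overview["icc_intra_median"],
    ])
    ax.errorbar(x, overview["icc_intra_median"], yerr=err, fmt="none",
                ecolor="k", linewidth=1)
    ax.set_xticks(x)
    ax.set_xticklabels(overview["feature"], rotation=90, fontsize=6)
    ax.set_ylabel("intra-patient ICC (median, IQR)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
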