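"""Redundancy grouping of features by rank correlation.

Features measuring essentially the same lesion property are identified by
hierarchical clustering of the pairwise distance d = 1 - rho^2 (Spearman),
cut at a cophenetic threshold (default 0.51); anticorrelation counts as
redundancy, and the rank-based rho makes monotone transforms (e.g. log)
immaterial.  One representative per group is then chosen as the member with
the highest median intra-patient ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .stats import RepeatabilitySummary

__all__ = [
    "DistanceMatrix",
    "FeatureGroup",
    "FeatureGroups",
    "spearman_distance",
    "cluster_features",
    "select_representatives",
]

DEFAULT_THRESHOLD = 0.51


@dataclass
class DistanceMatrix:
    """Symmetric 1 - rho^2 distance matrix with feature labels; features with
    undefined correlation (constant across lesions) are excluded and listed
    in ``flagged``."""

    values: np.ndarray
    features: list[str]
    flagged: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.features),) * 2:
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.features)


@dataclass
class FeatureGroup:
    members: list[str]
    representative: str | None = None


@dataclass
class FeatureGroups:
    groups: list[FeatureGroup]

    def __len__(self) -> int:
        return len(self.groups)

    def all_members(self) -> list[str]:
        return [m for g in self.groups for m in g.members]

    def to_dict(self) -> dict:
        return {
            "n_groups": len(self.groups),
            "groups": [
                {"members": g.members, "representative": g.representative}
                for g in self.groups
            ],
        }


def spearman_distance(table: pd.DataFrame, features: list[str]) -> DistanceMatrix:
    """Pairwise d = 1 - rho^2 across lesions (pooled over patients).

    The per-lesion value fed to the correlation is the mean of the two
    repeats.  Needs at least 3 lesions with complete values; constant
    features have undefined rho and are flagged and excluded.
    """
    sub = table[table["feature_name"].isin(features)]
    per_lesion = (
        sub.groupby(["patient_id", "lesion_id", "feature_name"], sort=False)["value"]
        .mean()
        .unstack("feature_name")
    )
    missing = [f for f in features if f not in per_lesion.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    per_lesion = per_lesion[features].dropna()
    if len(per_lesion) < 3:
        raise ValueError("Spearman distance needs >= 3 complete lesions")

    flagged = [f for f in features if per_lesion[f].nunique() == 1]
    kept = [f for f in features if f not in flagged]
    x = per_lesion[kept].to_numpy(float)
    if len(kept) == 1:
        rho = np.ones((1, 1))
    elif len(kept) == 2:
        r = float(spearmanr(x[:, 0], x[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(spearmanr(x).statistic)
    d = 1.0 - rho**2
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, features=kept, flagged=flagged)


def cluster_features(
    dist: DistanceMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    linkage_method: str = "average",
) -> FeatureGroups:
    """Agglomerative clustering cut at cophenetic distance = threshold.

    Groups are returned in a deterministic order (members sorted by name,
    groups by first member).
    """
    n = len(dist.features)
    if n == 0:
        return FeatureGroups(groups=[])
    if n == 1:
        return FeatureGroups(groups=[FeatureGroup(members=list(dist.features))])
    z = linkage(squareform(dist.values, checks=False), method=linkage_method)
    labels = fcluster(z, t=threshold, criterion="distance")
    by_label: dict[int, list[str]] = {}
    for feat, lab in zip(dist.features, labels):
        by_label.setdefault(int(lab), []).append(feat)
    groups = [FeatureGroup(members=sorted(m)) for m in by_label.values()]
    groups.sort(key=lambda g: g.members[0])
    return FeatureGroups(groups=groups)


def select_representatives(
    groups: FeatureGroups,
    summaries: dict[str, RepeatabilitySummary],
) -> FeatureGroups:
    """Pick, per group, the member with the maximum median intra-patient ICC
    (ties broken lexicographically by feature name)."""
    out = []
    for g in groups.groups:
        missing = [m for m in g.members if m not in summaries]
        if missing:
            raise KeyError(f"no repeatability summary for {missing}")
        best = min(g.members, key=lambda m: (-summaries[m].icc_intra.median, m))
        out.append(FeatureGroup(members=list(g.members), representative=best))
    return FeatureGroups(groups=out)
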