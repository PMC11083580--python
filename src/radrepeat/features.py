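"""Lesion eligibility, grey-level discretisation, feature registry and
native first-order features.

Texture and shape feature mathematics (GLCM/GLRLM/GLSZM/GLDM/NGTDM, mesh
shape descriptors) are deliberately not implemented natively: those values
come from a pluggable IBSI-conformant extractor satisfying
:class:`FeatureExtractor`.  Only first-order statistics are computed in-house.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Protocol, runtime_checkable

import numpy as np


class Transform(str, Enum):
    """Per-feature variance-stabilising transform applied before modelling."""

    LOG = "log"
    IDENTITY = "identity"
    ONE_MINUS = "one_minus"
    ONE_MINUS_THEN_LOG = "one_minus_then_log"


class FeatureClass(str, Enum):
    FIRSTORDER = "firstorder"
    SHAPE = "shape"
    GLCM = "glcm"
    GLRLM = "glrlm"
    GLSZM = "glszm"
    GLDM = "gldm"
    NGTDM = "ngtdm"


#: Transforms whose output lives on a log scale (limits of agreement apply).
LOG_SCALE_TRANSFORMS = frozenset({Transform.LOG, Transform.ONE_MINUS_THEN_LOG})


class TransformDomainError(ValueError):
    """Operand outside the transform's domain (e.g. log of a non-positive
    value); the lesion-feature pair must be flagged and excluded from the
    log-scale model rather than silently propagated."""


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    feature_class: FeatureClass
    transform: Transform


@dataclass(frozen=True)
class BinningConfig:
    """Fixed-bin-width grey-level discretisation.

    Bin widths chosen so a full-range map yields exactly 30 grey levels:
    100e-6 mm^2/s width covers ADC in [0, 3000e-6); 100/30 % (3.333%,
    stored exactly so the 30th bin closes the range) covers rFF% in
    [0, 100).  The anchor (bin-edge origin) is fixed at 0 because both maps
    are inherently normalised and non-negative, making grey levels
    reproducible across lesions.
    """

    map_kind: str = "ADC"
    bin_width: float = 100.0
    anchor: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @classmethod
    def adc(cls) -> "BinningConfig":
        return cls(map_kind="ADC", bin_width=100.0)

    @classmethod
    def rff(cls) -> "BinningConfig":
        return cls(map_kind="rFF", bin_width=100.0 / 30.0)


@dataclass(frozen=True)
class LesionCandidate:
    """Candidate target lesion with the quantities the eligibility rule needs.

    ``mean_adc`` in 1e-6 mm^2/s, ``mean_rff`` in percent,
    ``unequivocal_change``: >=30% change in size and/or ADC versus prior
    imaging, which rescues high-ADC lesions.
    """

    mean_adc: float
    mean_rff: float
    volume_ml: float
    unequivocal_change: bool = False

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be positive")


def lesion_eligibility(c: LesionCandidate) -> bool:
    """Target-lesion rule: volume >= 1 mL, low fat signal (rFF% < 20),
    and either mean ADC < 1400e-6 mm^2/s or unequivocal interval change."""
    return (
        c.volume_ml >= 1.0
        and c.mean_rff < 20.0
        and (c.mean_adc < 1400.0 or c.unequivocal_change)
    )


def discretise(values: np.ndarray | list, config: BinningConfig) -> np.ndarray:
    """Map intensities to positive integer grey levels with a fixed bin width.

    ``level = floor((x - anchor) / bin_width) + 1``; values below the anchor
    signal a wrong map/config pairing and raise.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretise an empty value list")
    if np.any(x < config.anchor):
        raise ValueError(
            f"value below bin anchor {config.anchor}: check that the "
            f"{config.map_kind} binning config matches the input map"
        )
    return (np.floor((x - config.anchor) / config.bin_width) + 1).astype(int)


def apply_transform(value: float, rule: Transform) -> float:
    """Apply a registry transform to a single feature value.

    log-rules require a strictly positive operand (after any 1-x step);
    violations raise :class:`TransformDomainError` so callers can flag and
    exclude the lesion-feature pair.
    """
    rule = Transform(rule)
    if rule is Transform.IDENTITY:
        return float(value)
    if rule is Transform.ONE_MINUS:
        return float(1.0 - value)
    operand = 1.0 - value if rule is Transform.ONE_MINUS_THEN_LOG else float(value)
    if operand <= 0:
        raise TransformDomainError(
            f"transform {rule.value} requires a positive operand, got {operand!r}"
        )
    return float(np.log(operand))


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

_FIRSTORDER = [
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "Mean", "MeanAbsoluteDeviation", "Median",
    "Minimum", "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
    "Skewness", "StandardDeviation", "TotalEnergy", "Uniformity", "Variance",
]
_SHAPE = [
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
]
_GLCM = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MaximumProbability", "MCC", "SumEntropy",
]
_GLRLM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]
_GLSZM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]
_GLDM = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]
_NGTDM = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

# Features kept on their native (identity) scale: they take zero/negative
# values so a log transform is undefined.  Imc1 is typically <= 0, hence
# identity rather than the 1-x-then-log rule used for Imc2 (range [0,1)).
_IDENTITY = {"firstorder_Skewness", "firstorder_Minimum",
             "glcm_Correlation", "glcm_ClusterShade", "glcm_Imc1"}
_ONE_MINUS = {"glcm_Idn", "glcm_Idmn"}
_ONE_MINUS_THEN_LOG = {"glcm_Imc2"}


class FeatureRegistry:
    """Ordered, unique collection of feature entries keyed by full name
    (``<class>_<Name>``), with per-feature transform rules."""

    def __init__(self, entries: list[RegistryEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("registry feature names must be unique")
        self._entries = {e.name: e for e in entries}

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> RegistryEntry:
        return self._entries[name]

    def names(self) -> list[str]:
        return list(self._entries)

    def transform(self, name: str) -> Transform:
        return self._entries[name].transform

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self:
            counts[e.feature_class.value] = counts.get(e.feature_class.value, 0) + 1
        return counts

    def subset(self, feature_class: FeatureClass) -> list[RegistryEntry]:
        return [e for e in self if e.feature_class is feature_class]

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            e.name: {"class": e.feature_class.value, "transform": e.transform.value}
            for e in self
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureRegistry":
        return cls([
            RegistryEntry(name, FeatureClass(v["class"]), Transform(v["transform"]))
            for name, v in d.items()
        ])

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureRegistry":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _default_transform(full_name: str) -> Transform:
    if full_name in _IDENTITY:
        return Transform.IDENTITY
    if full_name in _ONE_MINUS:
        return Transform.ONE_MINUS
    if full_name in _ONE_MINUS_THEN_LOG:
        return Transform.ONE_MINUS_THEN_LOG
    return Transform.LOG


def build_default_registry() -> FeatureRegistry:
    """The default 106-feature registry: 19 first-order, 14 shape, 22 GLCM,
    16 GLRLM, 16 GLSZM, 14 GLDM and 5 NGTDM features, each with its
    variance-stabilising transform."""
    groups = [
        (FeatureClass.FIRSTORDER, _FIRSTORDER),
        (FeatureClass.SHAPE, _SHAPE),
        (FeatureClass.GLCM, _GLCM),
        (FeatureClass.GLRLM, _GLRLM),
        (FeatureClass.GLSZM, _GLSZM),
        (FeatureClass.GLDM, _GLDM),
        (FeatureClass.NGTDM, _NGTDM),
    ]
    entries = []
    for fclass, names in groups:
        for n in names:
            full = f"{fclass.value}_{n}"
            entries.append(RegistryEntry(full, fclass, _default_transform(full)))
    return FeatureRegistry(entries)


# --------------------------------------------------------------------------
# first-order features
# --------------------------------------------------------------------------

def first_order_features(
    values: np.ndarray | list,
    binning: BinningConfig | None = None,
    voxel_volume_mm3: float = 1.0,
) -> dict[str, float]:
    """Native first-order statistics of the in-mask intensity distribution.

    Skewness uses population (biased) moments; kurtosis is Pearson kurtosis
    (fourth standardised moment, no -3 excess correction), following IBSI
    consensus definitions.  Entropy and Uniformity are computed on fixed-bin
    discretised grey levels (``binning`` defaults to the ADC config).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("first-order features need at least 2 values")
    binning = binning or BinningConfig.adc()

    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance per IBSI
    sd = float(np.sqrt(var))
    centred = x - mean
    if sd > 0:
        skew = float((centred**3).mean() / sd**3)
        kurt = float((centred**4).mean() / var**2)
    else:
        skew, kurt = 0.0, 0.0

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    levels = discretise(x, binning)
    _, counts = np.unique(levels, return_counts=True)
    p = counts / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    return {
        "firstorder_Mean": mean,
        "firstorder_Median": float(p50),
        "firstorder_Minimum": float(x.min()),
        "firstorder_Maximum": float(x.max()),
        "firstorder_Range": float(x.max() - x.min()),
        "firstorder_10Percentile": float(p10),
        "firstorder_90Percentile": float(p90),
        "firstorder_InterquartileRange": float(p75 - p25),
        "firstorder_RootMeanSquared": float(np.sqrt((x**2).mean())),
        "firstorder_Skewness": skew,
        "firstorder_Kurtosis": kurt,
        "firstorder_Variance": var,
        "firstorder_StandardDeviation": sd,
        "firstorder_MeanAbsoluteDeviation": float(np.abs(centred).mean()),
        "firstorder_RobustMeanAbsoluteDeviation": rmad,
        "firstorder_Energy": float((x**2).sum()),
        "firstorder_TotalEnergy": float(voxel_volume_mm3 * (x**2).sum()),
        "firstorder_Entropy": entropy,
        "firstorder_Uniformity": uniformity,
    }


# --------------------------------------------------------------------------
# pluggable extractor
# --------------------------------------------------------------------------

@runtime_checkable
class FeatureExtractor(Protocol):
    """Contract for an external IBSI-conformant feature extractor.

    ``aggregation`` must declare whether texture matrices are aggregated in
    3D or per slice (``"3D"`` / ``"2.5D"`` / ``"2D"``), since published
    values depend on it.
    """

    aggregation: str

    def extract(
        self,
        image: np.ndarray,
        mask: np.ndarray,
        binning: BinningConfig,
        feature_names: list[str],
    ) -> dict[str, float]:
        """Return raw (untransformed) values for the requested features;
        must raise ``KeyError`` for features it cannot compute."""
        ...


class MissingFeatureError(KeyError):
    """The configured extractor does not provide a registered feature."""


class ReferenceFirstOrderExtractor:
    """Reference extractor implementing the first-order class only, through
    an independent scipy/numpy code path.  Used to cross-validate the native
    implementation; it is not an IBSI texture implementation.
    """

    aggregation = "3D"

    def extract(self, image, mask, binning, feature_names):
        from scipy import stats as ss

        x = np.asarray(image)[np.asarray(mask, dtype=bool)].astype(float)
        p = np.percentile
        lv = discretise(x, binning)
        freq = np.bincount(lv)[1:]
        prob = freq[freq > 0] / x.size
        robust = x[(x >= p(x, 10)) & (x <= p(x, 90))]
        table = {
            "firstorder_Mean": np.mean(x),
            "firstorder_Median": np.median(x),
            "firstorder_Minimum": np.min(x),
            "firstorder_Maximum": np.max(x),
            "firstorder_Range": np.ptp(x),
            "firstorder_10Percentile": p(x, 10),
            "firstorder_90Percentile": p(x, 90),
            "firstorder_InterquartileRange": ss.iqr(x),
            "firstorder_RootMeanSquared": np.sqrt(np.mean(np.square(x))),
            "firstorder_Skewness": ss.skew(x, bias=True),
            "firstorder_Kurtosis": ss.kurtosis(x, fisher=False, bias=True),
            "firstorder_Variance": np.var(x),
            "firstorder_StandardDeviation": np.std(x),
            "firstorder_MeanAbsoluteDeviation": np.mean(np.abs(x - np.mean(x))),
            "firstorder_RobustMeanAbsoluteDeviation": np.mean(
                np.abs(robust - np.mean(robust))
            ),
            "firstorder_Energy": np.sum(np.square(x)),
            "firstorder_TotalEnergy": np.sum(np.square(x)),
            "firstorder_Entropy": -np.sum(prob * np.log2(prob)),
            "firstorder_Uniformity": np.sum(np.square(prob)),
        }
        out = {}
        for name in feature_names:
            if name not in table:
                raise KeyError(name)
            out[name] = float(table[name])
        return out


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    registry: FeatureRegistry,
    config: BinningConfig,
    extractor: FeatureExtractor | None = None,
    voxel_volume_mm3: float = 1.0,
    transform: bool = True,
) -> dict[str, float]:
    """Extract all registered features from one lesion.

    First-order values are computed natively; every other registered class is
    delegated to ``extractor``.  With ``transform=True`` (default) each value
    is passed through its registry transform; domain violations raise
    :class:`TransformDomainError`.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("lesion mask is empty")
    x = np.asarray(image, dtype=float)[mask]

    raw = first_order_features(x, config, voxel_volume_mm3)
    raw = {k: v for k, v in raw.items() if k in registry}

    external = [e.name for e in registry if e.feature_class is not FeatureClass.FIRSTORDER]
    if external:
        if extractor is None:
            raise MissingFeatureError(
                f"no extractor configured for non-first-order features: {external[:3]}..."
            )
        try:
            raw.update(extractor.extract(image, mask, config, external))
        except KeyError as exc:
            raise MissingFeatureError(
                f"extractor does not provide registered feature {exc}"
            ) from exc

    if not transform:
        return raw
    return {name: apply_transform(v, registry.transform(name)) for name, v in raw.items()}
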