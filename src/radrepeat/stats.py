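"""Derived repeatability statistics and their posterior summaries.

Each statistic is a deterministic function of the hierarchical model
parameters:

    RC    = 1.96 * sqrt(2) * sigma_r          repeatability coefficient
    ICCd  = sigma_p^2 / (sigma_p^2 + sigma_r^2)   intra-patient ICC
    ICCD  = sigma_0^2 / (sigma_0^2 + sigma_r^2)   inter-patient ICC
    wlCV  = sqrt(mean_j sigma_r^2 / mu_ij^2)      within-lesion CV
    blCV  = sqrt(mean_i sigma_p^2 / mu_i^2)       between-lesion CV
    bCV   = sigma_0 / mu_0                        between-patient CV
    LoA   = (exp(+-1.96 sqrt(2) sigma_r') - 1) * 100%   (log-scale only)

Uncertainty is propagated by computing every statistic per posterior draw
and summarising with the median, interquartile range and central 95%
interval; the per-lesion and per-patient means used in the CVs come from
the same joint draw as the SDs.  The 1.96 multiplier is kept literal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import LOG_SCALE_TRANSFORMS, Transform
from .model import PosteriorSamples

__all__ = [
    "RC_FACTOR",
    "StatisticSummary",
    "RepeatabilitySummary",
    "repeatability_coefficient",
    "icc_intra",
    "icc_inter",
    "cv_statistics",
    "limits_of_agreement",
    "bias_assessment",
    "summarise_feature",
]

RC_FACTOR = 1.96 * math.sqrt(2.0)


def repeatability_coefficient(sigma_r):
    """RC = 1.96*sqrt(2)*sigma_r: the smallest change between two
    measurements deemed significant at p=0.05."""
    s = np.asarray(sigma_r, dtype=float)
    if np.any(s < 0):
        raise ValueError("sigma_r must be non-negative")
    out = RC_FACTOR * s
    return float(out) if out.ndim == 0 else out


def _icc(sig_num, sigma_r):
    a = np.asarray(sig_num, dtype=float) ** 2
    b = np.asarray(sigma_r, dtype=float) ** 2
    denom = a + b
    if np.any(denom == 0):
        raise ValueError("ICC undefined when both SDs are zero")
    out = a / denom
    return float(out) if out.ndim == 0 else out


def icc_intra(sigma_p, sigma_r):
    """Intra-patient ICC: inter-measurement error against intra-patient
    (between-lesion) variation."""
    return _icc(sigma_p, sigma_r)


def icc_inter(sigma_0, sigma_r):
    """Inter-patient ICC: inter-measurement error against inter-patient
    variation."""
    return _icc(sigma_0, sigma_r)


def cv_statistics(sigma_r, sigma_p, sigma_0, mu_ij, mu_i, mu_0):
    """Within-lesion, between-lesion and between-patient coefficients of
    variation for one parameter draw (or point estimate).

    Any zero mean makes the corresponding CV undefined and raises; callers
    should flag the feature rather than report an infinite CV.
    """
    mu_ij = np.asarray(mu_ij, dtype=float)
    mu_i = np.asarray(mu_i, dtype=float)
    if np.any(mu_ij == 0) or np.any(mu_i == 0) or mu_0 == 0:
        raise ZeroDivisionError("CV undefined: a mean parameter is zero")
    wlcv = float(np.sqrt(np.mean(sigma_r**2 / mu_ij**2)))
    blcv = float(np.sqrt(np.mean(sigma_p**2 / mu_i**2)))
    bcv = float(sigma_0 / mu_0)
    return wlcv, blcv, bcv


def limits_of_agreement(sigma_r_logscale, transform: Transform = Transform.LOG):
    """Percentage limits of agreement for log-scale features:
    ``(exp(+-1.96 sqrt(2) sigma_r') - 1) * 100``.

    Only meaningful when the feature's registry transform puts it on a log
    scale; calling it for an identity- or 1-x-transformed feature is a
    contract error.
    """
    if Transform(transform) not in LOG_SCALE_TRANSFORMS:
        raise ValueError(
            "limits of agreement are defined for log-transformed features only"
        )
    s = np.asarray(sigma_r_logscale, dtype=float)
    if np.any(s < 0):
        raise ValueError("sigma_r must be non-negative")
    upper = (np.exp(RC_FACTOR * s) - 1.0) * 100.0
    lower = (np.exp(-RC_FACTOR * s) - 1.0) * 100.0
    if s.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def bias_assessment(epsilon_draws, level: float = 0.95):
    """Central credible interval for the second-repeat bias and whether it
    excludes zero.  Requires >= 100 draws for a stable 95% interval."""
    eps = np.asarray(epsilon_draws, dtype=float).ravel()
    if eps.size < 100:
        raise ValueError("bias assessment needs at least 100 draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(eps, [alpha, 1.0 - alpha])
    significant = bool(lo > 0 or hi < 0)
    return (float(lo), float(hi)), significant


# --------------------------------------------------------------------------
# posterior summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StatisticSummary:
    median: float
    iqr: tuple[float, float]
    ci95: tuple[float, float]

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "StatisticSummary":
        q = np.quantile(draws, [0.025, 0.25, 0.5, 0.75, 0.975])
        return cls(median=float(q[2]), iqr=(float(q[1]), float(q[3])),
                   ci95=(float(q[0]), float(q[4])))


@dataclass
class RepeatabilitySummary:
    """Posterior median/IQR/95% interval for each derived statistic of one
    feature.  ``loa_lower``/``loa_upper`` are ``None`` for features not on a
    log scale (the statistic is not applicable, never silently computed)."""

    feature: str
    transform: Transform
    rc: StatisticSummary
    icc_intra: StatisticSummary
    icc_inter: StatisticSummary
    wlcv: StatisticSummary | None
    blcv: StatisticSummary | None
    bcv: StatisticSummary | None
    loa_lower: StatisticSummary | None
    loa_upper: StatisticSummary | None
    epsilon: StatisticSummary
    bias_interval: tuple[float, float]
    bias_significant: bool
    n_draws: int
    cv_flagged: bool = False  # CVs skipped because a mean draw was zero

    def row(self) -> dict:
        """Flatten to one tidy CSV row."""
        out: dict[str, object] = {"feature": self.feature,
                                  "transform": self.transform.value}
        for name in ("rc", "icc_intra", "icc_inter", "wlcv", "blcv", "bcv",
                     "loa_lower", "loa_upper", "epsilon"):
            s: StatisticSummary | None = getattr(self, name)
            if s is None:
                out[f"{name}_median"] = np.nan
                out[f"{name}_iqr_lo"] = np.nan
                out[f"{name}_iqr_hi"] = np.nan
                out[f"{name}_ci_lo"] = np.nan
                out[f"{name}_ci_hi"] = np.nan
            else:
                out[f"{name}_median"] = s.median
                out[f"{name}_iqr_lo"], out[f"{name}_iqr_hi"] = s.iqr
                out[f"{name}_ci_lo"], out[f"{name}_ci_hi"] = s.ci95
        out["bias_significant"] = self.bias_significant
        out["cv_flagged"] = self.cv_flagged
        return out


def summarise_feature(
    samples: PosteriorSamples,
    feature: str | None = None,
    transform: Transform = Transform.LOG,
    converged: bool = True,
    force: bool = False,
) -> RepeatabilitySummary:
    """Compute every repeatability statistic per posterior draw and
    summarise with median / IQR / central 95% interval.

    ``samples`` should be on the destandardised (original transformed-
    feature) scale so the CVs and limits of agreement are meaningful.
    Refuses non-converged samples unless ``force=True``.
    """
    if not converged and not force:
        raise ValueError("refusing to summarise non-converged samples "
                         "(pass force=True to override)")
    transform = Transform(transform)
    sr = samples.flat("sigma_r")
    sp = samples.flat("sigma_p")
    s0 = samples.flat("sigma0")
    mu0 = samples.flat("mu0")
    mu_i = samples.flat("mu_i")
    mu_ij = samples.flat("mu_ij")
    eps = samples.flat("epsilon")

    rc = repeatability_coefficient(sr)
    iccd = icc_intra(sp, sr)
    iccD = icc_inter(s0, sr)

    cv_flagged = bool(
        np.any(mu_ij == 0) or np.any(mu_i == 0) or np.any(mu0 == 0)
    )
    if cv_flagged:
        wlcv = blcv = bcv = None
    else:
        wlcv_d = np.sqrt(np.mean(sr[:, None] ** 2 / mu_ij**2, axis=1))
        blcv_d = np.sqrt(np.mean(sp[:, None] ** 2 / mu_i**2, axis=1))
        bcv_d = s0 / mu0
        wlcv = StatisticSummary.from_draws(wlcv_d)
        blcv = StatisticSummary.from_draws(blcv_d)
        bcv = StatisticSummary.from_draws(bcv_d)

    if transform in LOG_SCALE_TRANSFORMS:
        lo_d, up_d = limits_of_agreement(sr, transform)
        loa_lower = StatisticSummary.from_draws(lo_d)
        loa_upper = StatisticSummary.from_draws(up_d)
    else:
        loa_lower = loa_upper = None

    bias_ci, bias_sig = bias_assessment(eps)
    return RepeatabilitySummary(
        feature=feature or "feature",
        transform=transform,
        rc=StatisticSummary.from_draws(rc),
        icc_intra=StatisticSummary.from_draws(iccd),
        icc_inter=StatisticSummary.from_draws(iccD),
        wlcv=wlcv, blcv=blcv, bcv=bcv,
        loa_lower=loa_lower, loa_upper=loa_upper,
        epsilon=StatisticSummary.from_draws(eps),
        bias_interval=bias_ci,
        bias_significant=bias_sig,
        n_draws=int(eps.size),
        cv_flagged=cv_flagged,
    )
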