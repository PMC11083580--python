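"""Three-level hierarchical Bayesian repeatability model.

The model for the (transformed) measurement ``x_ijk`` of lesion ``j`` in
patient ``i`` at repeat ``k`` is

    x_ij1 ~ N(mu_ij, sigma_r)        x_ij2 ~ N(mu_ij + epsilon, sigma_r)
    mu_ij ~ N(mu_i, sigma_p)         mu_i  ~ N(mu_0, sigma_0)

with half-Cauchy(0, 5) priors on the three standard deviations and
N(0, 10^2) priors on ``mu_0`` and the second-repeat bias ``epsilon``.
sigma_p and sigma_r are population-wide: with the lesion counts seen in
practice a per-patient sigma_p is not meaningfully estimable, and a single
sigma_p is directly comparable with the measurement error sigma_r.

Posterior sampling uses an exact blocked Gibbs sampler.  All full
conditionals of the location parameters are Gaussian; the half-Cauchy priors
are handled through their inverse-gamma scale-mixture representation
(sigma^2 | a ~ IG(1/2, 1/a), a ~ IG(1/2, 1/scale^2)), which makes every
variance update conjugate as well.  The sampler is therefore deterministic
given a seed, has no tuning phase, and mixes well for this model class.

Data are standardised before sampling by the baseline-1 convention
(subtract the mean and divide by the SD of the first repeat), and draws are
mapped back afterwards with :func:`destandardise`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ModelConfig",
    "StandardisedData",
    "InitialValues",
    "PosteriorSamples",
    "ConvergenceReport",
    "ConvergenceError",
    "standardise",
    "initial_values",
    "check_initials_within_prior",
    "sample_posterior",
    "gelman_rubin",
    "fit_with_retries",
    "destandardise",
]


class ConvergenceError(RuntimeError):
    """Raised when the retry schema exhausts its budget without convergence."""


@dataclass(frozen=True)
class ModelConfig:
    """MCMC configuration.

    ``n_samples`` is the per-chain total including warmup (so the default
    3 chains x (2000 - 500) = 4500 retained draws); set
    ``samples_include_warmup=False`` to read it as post-warmup draws.
    Convergence passes when at least ``rhat_coverage`` of all sampled
    parameters have R-hat <= ``rhat_threshold``; otherwise sampling is
    repeated with fresh deterministic seeds up to ``max_retries`` times.
    """

    n_chains: int = 3
    n_samples: int = 2000
    n_warmup: int = 500
    thinning: int = 1
    samples_include_warmup: bool = True
    rhat_threshold: float = 1.02
    rhat_coverage: float = 0.99
    rhat_method: str = "classic"  # or "rank" (split-chain rank-normalised)
    max_retries: int = 10
    sigma_prior_scale: float = 5.0
    mu_prior_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_samples, self.thinning) < 1 or self.n_warmup < 0:
            raise ValueError("chain/sample/thinning counts must be positive")
        if self.samples_include_warmup and self.n_warmup >= self.n_samples:
            raise ValueError("n_warmup must be smaller than n_samples")
        if self.rhat_threshold <= 1:
            raise ValueError("rhat_threshold must exceed 1")
        if not 0 < self.rhat_coverage <= 1:
            raise ValueError("rhat_coverage must be in (0, 1]")
        if self.max_retries < 0:
            raise ValueError("max_retries must be >= 0")

    @property
    def n_kept(self) -> int:
        """Post-warmup draws retained per chain (before thinning)."""
        if self.samples_include_warmup:
            return self.n_samples - self.n_warmup
        return self.n_samples


@dataclass
class StandardisedData:
    """Per-lesion wide data on the standardised scale.

    ``x1``/``x2`` are the two repeats per lesion, both standardised by the
    baseline-1 mean and SD; ``patient_index[j]`` maps lesion ``j`` to its
    patient.  The stored constants allow exact inversion.
    """

    feature: str
    patient_ids: list[str]
    lesion_ids: list[str]
    patient_index: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    baseline1_mean: float
    baseline1_var: float

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_ids)

    @property
    def lesions_per_patient(self) -> np.ndarray:
        return np.bincount(self.patient_index, minlength=self.n_patients)


@dataclass(frozen=True)
class InitialValues:
    """Moment-based starting point for the sampler (baseline-1 convention)."""

    mu_ij0: np.ndarray
    sigma_r0: float
    mu_i0: np.ndarray
    sigma_p0: float
    mu_00: float
    sigma_00: float
    epsilon_0: float


@dataclass
class PosteriorSamples:
    """Post-warmup MCMC draws, shaped ``(n_chains, n_draws)`` for the five
    global parameters and ``(n_chains, n_draws, ...)`` for the per-patient
    and per-lesion means."""

    mu0: np.ndarray
    sigma0: np.ndarray
    sigma_p: np.ndarray
    sigma_r: np.ndarray
    epsilon: np.ndarray
    mu_i: np.ndarray
    mu_ij: np.ndarray
    patient_ids: list[str]
    lesion_ids: list[str]
    standardised: bool = True

    @property
    def n_chains(self) -> int:
        return self.mu0.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu0.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (n_chains*n_draws, ...)."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def iter_parameters(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield every scalar sampled parameter as (name, (chains, draws))."""
        for name in ("mu0", "sigma0", "sigma_p", "sigma_r", "epsilon"):
            yield name, getattr(self, name)
        for i, pid in enumerate(self.patient_ids):
            yield f"mu_i[{pid}]", self.mu_i[:, :, i]
        for j, lid in enumerate(self.lesion_ids):
            yield f"mu_ij[{lid}]", self.mu_ij[:, :, j]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format (chain, draw, parameter, value) for CSV export."""
        frames = []
        for name, arr in self.iter_parameters():
            c, d = np.meshgrid(
                np.arange(self.n_chains), np.arange(self.n_draws), indexing="ij"
            )
            frames.append(pd.DataFrame({
                "chain": c.ravel(), "draw": d.ravel(),
                "parameter": name, "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    fraction_converged: float
    threshold: float
    coverage_required: float
    retries_used: int = 0
    passed: bool = False

    def worst(self, k: int = 5) -> list[tuple[str, float]]:
        return sorted(self.rhat.items(), key=lambda kv: -kv[1])[:k]


# --------------------------------------------------------------------------
# standardisation and initial values
# --------------------------------------------------------------------------

def standardise(table: pd.DataFrame, feature: str) -> StandardisedData:
    """Standardise both repeats of one feature by the baseline-1 mean and SD.

    ``x' = (x - mean(x1)) / sqrt(var(x1))`` with the unbiased sample
    variance; the constants are stored for later inversion.  Requires at
    least two lesions with both repeats present.
    """
    sub = table[table["feature_name"] == feature]
    if sub.empty:
        raise ValueError(f"feature '{feature}' not present in table")
    wide = sub.pivot_table(
        index=["patient_id", "lesion_id"], columns="repeat", values="value",
        sort=False,
    )
    if 1 not in wide.columns or 2 not in wide.columns:
        raise ValueError(f"feature '{feature}' lacks one of the two repeats")
    wide = wide.dropna(subset=[1, 2])
    if len(wide) < 2:
        raise ValueError("standardisation needs at least two complete lesions")

    x1 = wide[1].to_numpy(dtype=float)
    x2 = wide[2].to_numpy(dtype=float)
    mean1 = float(x1.mean())
    var1 = float(x1.var(ddof=1))
    if var1 <= 0:
        raise ValueError(
            f"feature '{feature}' is degenerate: baseline-1 variance is zero"
        )
    sd1 = np.sqrt(var1)

    patients = [p for p, _ in wide.index]
    uniq = list(dict.fromkeys(patients))
    pat_idx = np.array([uniq.index(p) for p in patients], dtype=int)
    return StandardisedData(
        feature=feature,
        patient_ids=uniq,
        lesion_ids=[l for _, l in wide.index],
        patient_index=pat_idx,
        x1=(x1 - mean1) / sd1,
        x2=(x2 - mean1) / sd1,
        baseline1_mean=mean1,
        baseline1_var=var1,
    )


def initial_values(data: StandardisedData) -> InitialValues:
    """Moment-based initial values.

    mu_ij0 = (x1+x2)/2; sigma_r0 = sqrt(sum (x1-x2)^2 / (2 L));
    mu_i0 = within-patient mean of mu_ij0;
    sigma_p0 = sqrt(sum (mu_ij0-mu_i0)^2 / (L-N));
    mu_00 = mean of mu_i0; sigma_00 = SD of mu_i0 (N-1 denominator);
    epsilon_0 = mean(x2-x1).  When every patient has a single lesion the
    sigma_p0 denominator vanishes; sigma_r0 is used instead (any positive
    starting value is admissible).
    """
    L, N = data.n_lesions, data.n_patients
    if N < 2:
        raise ValueError(
            "initial values need >= 2 patients (between-patient SD undefined)"
        )
    mu_ij0 = 0.5 * (data.x1 + data.x2)
    diff = data.x1 - data.x2
    sigma_r0 = float(np.sqrt((diff**2).sum() / (2 * L)))
    sums = np.bincount(data.patient_index, weights=mu_ij0, minlength=N)
    mi = data.lesions_per_patient
    mu_i0 = sums / mi
    if L > N:
        resid = mu_ij0 - mu_i0[data.patient_index]
        sigma_p0 = float(np.sqrt((resid**2).sum() / (L - N)))
    else:
        sigma_p0 = sigma_r0  # one lesion per patient: fall back
    mu_00 = float(mu_i0.mean())
    sigma_00 = float(np.sqrt(((mu_i0 - mu_00) ** 2).sum() / (N - 1)))
    epsilon_0 = float((data.x2 - data.x1).mean())
    return InitialValues(mu_ij0, sigma_r0, mu_i0, sigma_p0, mu_00, sigma_00, epsilon_0)


def check_initials_within_prior(init: InitialValues, config: ModelConfig) -> None:
    """Validate that every initial value lies inside the central 99.9% mass
    of its prior, so the priors genuinely cover the data range."""
    from scipy import stats

    z = stats.norm.ppf(0.9995) * config.mu_prior_sd
    sigma_hi = stats.halfcauchy.ppf(0.999, scale=config.sigma_prior_scale)
    problems = []
    for name, val in [("mu_00", init.mu_00), ("epsilon_0", init.epsilon_0)]:
        if abs(val) > z:
            problems.append(f"{name}={val:.3g} outside +/-{z:.3g}")
    for name, val in [("sigma_r0", init.sigma_r0), ("sigma_p0", init.sigma_p0),
                      ("sigma_00", init.sigma_00)]:
        if val > sigma_hi:
            problems.append(f"{name}={val:.3g} above {sigma_hi:.3g}")
    if problems:
        raise ValueError(
            "initial values outside the central 99.9% prior mass: "
            + "; ".join(problems)
        )


# --------------------------------------------------------------------------
# Gibbs sampler
# --------------------------------------------------------------------------

_SIGMA_FLOOR = 1e-3  # starting value floor; degenerate zero SDs stall Gibbs


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def _run_chain(
    data: StandardisedData,
    init: InitialValues,
    config: ModelConfig,
    rng: np.random.Generator,
    jitter: bool,
) -> dict[str, np.ndarray]:
    x1, x2 = data.x1, data.x2
    pat = data.patient_index
    L, N = data.n_lesions, data.n_patients
    mi = data.lesions_per_patient.astype(float)
    A2 = config.sigma_prior_scale**2
    mu_prior_prec = 1.0 / config.mu_prior_sd**2

    mu_ij = init.mu_ij0.copy()
    mu_i = init.mu_i0.copy()
    mu0 = init.mu_00
    eps = init.epsilon_0
    s2_r = max(init.sigma_r0, _SIGMA_FLOOR) ** 2
    s2_p = max(init.sigma_p0, _SIGMA_FLOOR) ** 2
    s2_0 = max(init.sigma_00, _SIGMA_FLOOR) ** 2
    if jitter:
        # overdisperse chain starts so the R-hat diagnostic is meaningful
        mu_ij = mu_ij + 0.2 * rng.standard_normal(L)
        mu_i = mu_i + 0.2 * rng.standard_normal(N)
        mu0 += 0.2 * rng.standard_normal()
        eps += 0.2 * rng.standard_normal()
        s2_r *= float(np.exp(0.5 * rng.standard_normal()))
        s2_p *= float(np.exp(0.5 * rng.standard_normal()))
        s2_0 *= float(np.exp(0.5 * rng.standard_normal()))
    a_r = a_p = a_0 = 1.0 / A2

    n_iter = config.n_warmup + config.n_kept * config.thinning
    kept = config.n_kept
    out = {
        "mu0": np.empty(kept), "sigma0": np.empty(kept),
        "sigma_p": np.empty(kept), "sigma_r": np.empty(kept),
        "epsilon": np.empty(kept),
        "mu_i": np.empty((kept, N)), "mu_ij": np.empty((kept, L)),
    }
    k = 0
    for it in range(n_iter):
        # lesion means
        prec = 2.0 / s2_r + 1.0 / s2_p
        mean = ((x1 + x2 - eps) / s2_r + mu_i[pat] / s2_p) / prec
        mu_ij = mean + rng.standard_normal(L) / np.sqrt(prec)
        # patient means
        sums = np.bincount(pat, weights=mu_ij, minlength=N)
        prec_i = mi / s2_p + 1.0 / s2_0
        mean_i = (sums / s2_p + mu0 / s2_0) / prec_i
        mu_i = mean_i + rng.standard_normal(N) / np.sqrt(prec_i)
        # population mean
        prec0 = N / s2_0 + mu_prior_prec
        mu0 = mu_i.sum() / s2_0 / prec0 + rng.standard_normal() / np.sqrt(prec0)
        # second-repeat bias
        prec_e = L / s2_r + mu_prior_prec
        eps = (x2 - mu_ij).sum() / s2_r / prec_e + rng.standard_normal() / np.sqrt(prec_e)
        # variances (half-Cauchy via IG scale mixture)
        ss_r = float(((x1 - mu_ij) ** 2).sum() + ((x2 - mu_ij - eps) ** 2).sum())
        s2_r = _inv_gamma(rng, (2 * L + 1) / 2.0, 1.0 / a_r + ss_r / 2.0)
        a_r = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / s2_r)
        ss_p = float(((mu_ij - mu_i[pat]) ** 2).sum())
        s2_p = _inv_gamma(rng, (L + 1) / 2.0, 1.0 / a_p + ss_p / 2.0)
        a_p = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / s2_p)
        ss_0 = float(((mu_i - mu0) ** 2).sum())
        s2_0 = _inv_gamma(rng, (N + 1) / 2.0, 1.0 / a_0 + ss_0 / 2.0)
        a_0 = _inv_gamma(rng, 1.0, 1.0 / A2 + 1.0 / s2_0)

        post = it - config.n_warmup
        if post >= 0 and post % config.thinning == 0:
            out["mu0"][k] = mu0
            out["sigma0"][k] = np.sqrt(s2_0)
            out["sigma_p"][k] = np.sqrt(s2_p)
            out["sigma_r"][k] = np.sqrt(s2_r)
            out["epsilon"][k] = eps
            out["mu_i"][k] = mu_i
            out["mu_ij"][k] = mu_ij
            k += 1
    return out


def sample_posterior(
    data: StandardisedData,
    init: InitialValues,
    config: ModelConfig,
    attempt: int = 0,
) -> PosteriorSamples:
    """Draw posterior samples with the blocked Gibbs sampler.

    Chain 0 starts at the moment-based initial values; the remaining chains
    are deterministically jittered so between-chain agreement is informative.
    ``attempt`` enters the seed derivation, so each retry explores fresh
    randomness while remaining a pure function of (seed, attempt).
    """
    check_initials_within_prior(init, config)
    chains = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(attempt, c))
        )
        chains.append(_run_chain(data, init, config, rng, jitter=(c > 0 or attempt > 0)))
    stack = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    return PosteriorSamples(
        mu0=stack["mu0"], sigma0=stack["sigma0"], sigma_p=stack["sigma_p"],
        sigma_r=stack["sigma_r"], epsilon=stack["epsilon"],
        mu_i=stack["mu_i"], mu_ij=stack["mu_ij"],
        patient_ids=list(data.patient_ids), lesion_ids=list(data.lesion_ids),
        standardised=True,
    )


# --------------------------------------------------------------------------
# convergence
# --------------------------------------------------------------------------

def _classic_rhat(arr: np.ndarray) -> float:
    """Classic Gelman-Rubin on full post-warmup chains: sqrt of the pooled
    variance estimate over the mean within-chain variance."""
    m, n = arr.shape
    w = float(arr.var(axis=1, ddof=1).mean())
    b_over_n = float(arr.mean(axis=1).var(ddof=1))
    if w <= 0:
        return 1.0
    v_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(v_hat / w))


def gelman_rubin(samples: PosteriorSamples, config: ModelConfig | None = None) -> ConvergenceReport:
    """Per-parameter R-hat over all sampled parameters, and the pass rule
    (fraction with R-hat <= threshold must reach the coverage requirement).

    The default is the classic diagnostic on full post-warmup chains;
    ``rhat_method="rank"`` switches to arviz's split-chain rank-normalised
    variant.
    """
    config = config or ModelConfig()
    if samples.n_chains < 2:
        raise ValueError("R-hat needs at least two chains")
    rhat: dict[str, float] = {}
    if config.rhat_method == "rank":
        import warnings

        import arviz as az

        for name, arr in samples.iter_parameters():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat[name] = float(az.rhat(az.convert_to_dataset(arr))["x"])
    else:
        for name, arr in samples.iter_parameters():
            rhat[name] = _classic_rhat(arr)
    vals = np.array(list(rhat.values()))
    frac = float((vals <= config.rhat_threshold).mean())
    return ConvergenceReport(
        rhat=rhat,
        fraction_converged=frac,
        threshold=config.rhat_threshold,
        coverage_required=config.rhat_coverage,
        passed=frac >= config.rhat_coverage,
    )


def fit_with_retries(
    data: StandardisedData,
    init: InitialValues,
    config: ModelConfig,
) -> tuple[PosteriorSamples, ConvergenceReport]:
    """Sample, check convergence, and re-sample with fresh deterministic
    seeds until the coverage rule passes or ``max_retries`` is exhausted
    (then raise :class:`ConvergenceError` with diagnostics)."""
    report = None
    for attempt in range(config.max_retries + 1):
        samples = sample_posterior(data, init, config, attempt=attempt)
        report = gelman_rubin(samples, config)
        report.retries_used = attempt
        if report.passed:
            return samples, report
    worst = ", ".join(f"{n}={r:.4f}" for n, r in report.worst())
    raise ConvergenceError(
        f"no convergence after {config.max_retries} retries "
        f"({report.fraction_converged:.1%} of parameters with R-hat <= "
        f"{config.rhat_threshold}); worst: {worst}"
    )


# --------------------------------------------------------------------------
# destandardisation
# --------------------------------------------------------------------------

def destandardise(samples: PosteriorSamples, data: StandardisedData) -> PosteriorSamples:
    """Map draws back to the original (transformed-feature) scale.

    Locations (mu0, mu_i, mu_ij) are rescaled and shifted; epsilon, a
    difference, and the three SDs are rescaled only.  Applying this twice is
    an error.
    """
    if not samples.standardised:
        raise ValueError("samples are already on the original scale")
    s = float(np.sqrt(data.baseline1_var))
    m = data.baseline1_mean
    return PosteriorSamples(
        mu0=samples.mu0 * s + m,
        sigma0=samples.sigma0 * s,
        sigma_p=samples.sigma_p * s,
        sigma_r=samples.sigma_r * s,
        epsilon=samples.epsilon * s,
        mu_i=samples.mu_i * s + m,
        mu_ij=samples.mu_ij * s + m,
        patient_ids=samples.patient_ids,
        lesion_ids=samples.lesion_ids,
        standardised=False,
    )
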