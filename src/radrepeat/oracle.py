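"""Closed-form nested variance-components estimator.

A method-of-moments cross-check for the MCMC fit, independent of any
sampling machinery:

    sigma_r^2 = sum (x1-x2)^2 / (2 L)
    sigma_p^2 = pooled within-patient variance of lesion means - sigma_r^2/2
    sigma_0^2 = between-patient variance of patient means
                - sigma_p^2/M - sigma_r^2/(2M)      (balanced design, M = Mi)
    epsilon   = mean(x2 - x1)
    mu_0      = grand mean of patient means

On unbalanced designs the harmonic-mean lesion count replaces M; the
estimator remains consistent but loses a little efficiency.  Negative
variance estimates — a standard method-of-moments pathology — are truncated
at zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import StandardisedData, standardise

__all__ = ["MomentEstimates", "moment_estimates"]


@dataclass(frozen=True)
class MomentEstimates:
    sigma_r_hat: float
    sigma_p_hat: float
    sigma_0_hat: float
    mu_0_hat: float
    epsilon_hat: float
    truncated: tuple[str, ...] = ()

    def row(self, feature: str = "feature") -> dict:
        return {
            "feature": feature, "estimator": "moment",
            "sigma_r": self.sigma_r_hat, "sigma_p": self.sigma_p_hat,
            "sigma_0": self.sigma_0_hat, "mu_0": self.mu_0_hat,
            "epsilon": self.epsilon_hat,
            "truncated": ";".join(self.truncated),
        }


def _from_arrays(x1, x2, pat_idx, n_patients) -> MomentEstimates:
    L = x1.size
    N = n_patients
    if N < 2:
        raise ValueError("moment estimator needs >= 2 patients for sigma_0")
    mi = np.bincount(pat_idx, minlength=N).astype(float)

    diff = x1 - x2
    s2_r = float((diff**2).sum() / (2 * L))
    eps = float((x2 - x1).mean())

    y = 0.5 * (x1 + x2)  # per-lesion means; Var(y|lesion truth) = s2_r/2
    ybar_i = np.bincount(pat_idx, weights=y, minlength=N) / mi

    truncated = []
    if L > N:
        within = float(((y - ybar_i[pat_idx]) ** 2).sum() / (L - N))
        s2_p = within - s2_r / 2.0
    else:
        s2_p = 0.0
        truncated.append("sigma_p:no-replication")
    if s2_p < 0:
        s2_p = 0.0
        truncated.append("sigma_p")

    mu0 = float(ybar_i.mean())
    between = float(((ybar_i - mu0) ** 2).sum() / (N - 1))
    m_eff = float(N / (1.0 / mi).sum())  # harmonic mean; equals M if balanced
    s2_0 = between - s2_p / m_eff - s2_r / (2.0 * m_eff)
    if s2_0 < 0:
        s2_0 = 0.0
        truncated.append("sigma_0")

    return MomentEstimates(
        sigma_r_hat=float(np.sqrt(s2_r)),
        sigma_p_hat=float(np.sqrt(s2_p)),
        sigma_0_hat=float(np.sqrt(s2_0)),
        mu_0_hat=mu0,
        epsilon_hat=eps,
        truncated=tuple(truncated),
    )


def moment_estimates(
    table_or_data: pd.DataFrame | StandardisedData,
    feature: str | None = None,
) -> MomentEstimates:
    """Method-of-moments variance components for one feature.

    Accepts either a long-format measurement table (with ``feature``) or an
    already-prepared :class:`StandardisedData`; in the table case the raw
    (unstandardised) values are used directly.
    """
    if isinstance(table_or_data, StandardisedData):
        d = table_or_data
        return _from_arrays(d.x1, d.x2, d.patient_index, d.n_patients)
    if feature is None:
        raise ValueError("feature name required with a measurement table")
    sub = table_or_data[table_or_data["feature_name"] == feature]
    if sub.empty:
        raise ValueError(f"feature '{feature}' not present in table")
    wide = sub.pivot_table(
        index=["patient_id", "lesion_id"], columns="repeat", values="value",
        sort=False,
    ).dropna(subset=[1, 2])
    patients = [p for p, _ in wide.index]
    uniq = list(dict.fromkeys(patients))
    pat_idx = np.array([uniq.index(p) for p in patients], dtype=int)
    return _from_arrays(
        wide[1].to_numpy(float), wide[2].to_numpy(float), pat_idx, len(uniq)
    )
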