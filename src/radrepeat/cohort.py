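"""Synthetic test-retest cohorts with nested measurement structure.

Generates long-format repeated-measurement tables whose values follow the
three-level hierarchy assumed by the repeatability model: patient means are
drawn around a population mean (inter-patient SD ``sigma0``), lesion means
around their patient mean (intra-patient SD ``sigma_p``), and the two repeat
measurements around the lesion mean (inter-measurement SD ``sigma_r``), with
an optional additive bias ``epsilon`` on the second repeat.  An auxiliary
generator produces small voxel-level lesion images for exercising the feature
front-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "MEASUREMENT_COLUMNS",
    "generate_cohort",
    "generate_lesion_image",
    "save_lesion_image",
    "validate_measurement_table",
]

#: Column schema of the long-format measurement table.
MEASUREMENT_COLUMNS = ("patient_id", "lesion_id", "repeat", "feature_name", "value")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic test-retest cohort.

    Parameters
    ----------
    n_patients:
        Number of patients ``N``.
    lesions_per_patient:
        Lesion count ``M_i`` for each patient; may be ragged (real designs
        are unbalanced, with up to ~10 target lesions per patient).
    mu0:
        Population mean of the measurand (on log scale if ``scale="log"``).
    sigma0, sigma_p, sigma_r:
        Inter-patient, intra-patient (between-lesion) and inter-measurement
        standard deviations.
    epsilon:
        Additive bias applied to the second repeat.  Default 0: test-retest
        studies of this design typically show no significant bias.
    scale:
        ``"linear"`` emits the normal draws directly; ``"log"`` exponentiates
        them, yielding strictly positive log-normal values.
    feature_name:
        Label written into the ``feature_name`` column.
    seed:
        Master seed.  Per-patient substreams are derived deterministically so
        appending a patient never perturbs earlier patients' values.
    """

    n_patients: int
    lesions_per_patient: Sequence[int]
    mu0: float = 0.0
    sigma0: float = 0.0
    sigma_p: float = 0.0
    sigma_r: float = 0.0
    epsilon: float = 0.0
    scale: str = "linear"
    feature_name: str = "feature"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.lesions_per_patient) != self.n_patients:
            raise ValueError(
                f"lesions_per_patient has {len(self.lesions_per_patient)} entries "
                f"for {self.n_patients} patients"
            )
        if any(m < 1 for m in self.lesions_per_patient):
            raise ValueError("every patient needs at least one lesion")
        for name in ("sigma0", "sigma_p", "sigma_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a full cohort from the nested generative model.

    For patient ``i`` with lesions ``j``:  ``mu_i ~ N(mu0, sigma0)``,
    ``mu_ij ~ N(mu_i, sigma_p)``, ``x_ij1 ~ N(mu_ij, sigma_r)`` and
    ``x_ij2 ~ N(mu_ij + epsilon, sigma_r)``.

    Returns a long-format DataFrame with columns
    ``patient_id, lesion_id, repeat, feature_name, value`` containing exactly
    two repeats per (patient, lesion).
    """
    master = np.random.SeedSequence(spec.seed)
    rows: list[tuple] = []
    for i in range(spec.n_patients):
        # independent substream per patient: stable under cohort extension
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(i,)))
        mu_i = spec.mu0 + spec.sigma0 * rng.standard_normal()
        m_i = spec.lesions_per_patient[i]
        mu_ij = mu_i + spec.sigma_p * rng.standard_normal(m_i)
        x1 = mu_ij + spec.sigma_r * rng.standard_normal(m_i)
        x2 = mu_ij + spec.epsilon + spec.sigma_r * rng.standard_normal(m_i)
        if spec.scale == "log":
            x1, x2 = np.exp(x1), np.exp(x2)
        pid = f"P{i + 1:03d}"
        for j in range(m_i):
            lid = f"{pid}-L{j + 1:02d}"
            rows.append((pid, lid, 1, spec.feature_name, float(x1[j])))
            rows.append((pid, lid, 2, spec.feature_name, float(x2[j])))
    del master
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def validate_measurement_table(table: pd.DataFrame) -> None:
    """Check the long-format schema and the two-repeats-per-lesion invariant.

    Raises ``ValueError`` naming the offending column or key on failure.
    """
    for col in MEASUREMENT_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"measurement table is missing column '{col}'")
    bad_rep = set(table["repeat"].unique()) - {1, 2}
    if bad_rep:
        raise ValueError(f"repeat must be 1 or 2, found {sorted(bad_rep)}")
    keys = table[["patient_id", "lesion_id", "repeat", "feature_name"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicated measurement key {dup}")
    counts = table.groupby(
        ["patient_id", "lesion_id", "feature_name"], sort=False
    )["repeat"].count()
    if (counts != 2).any():
        bad = counts[counts != 2].index[0]
        raise ValueError(f"(patient, lesion, feature) {bad} does not have exactly two repeats")


def generate_lesion_image(
    mean: float,
    sd: float,
    volume_ml: float,
    voxel_spacing_mm: tuple[float, float, float],
    smoothness: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesise a 3D parametric map and a lesion mask of given volume.

    The mask is a quasi-spherical blob whose voxel count equals
    ``ceil(volume_ml * 1000 / voxel_volume_mm3)`` exactly.  In-mask voxels are
    log-normal with the requested (linear-scale) target mean and SD; ``sd=0``
    gives a uniform lesion.  ``smoothness`` (mm) applies Gaussian smoothing to
    the in-mask noise to mimic spatial texture correlation.

    Returns ``(image, mask)`` as float and boolean arrays.
    """
    if volume_ml <= 0:
        raise ValueError("volume_ml must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    spacing = np.asarray(voxel_spacing_mm, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("voxel_spacing_mm must be three positive values")

    voxel_vol = float(np.prod(spacing))
    n_target = math.ceil(volume_ml * 1000.0 / voxel_vol)

    # choose a grid comfortably containing an n_target-voxel ball
    radius_vox = (3 * n_target / (4 * math.pi)) ** (1 / 3)
    half = int(math.ceil(radius_vox)) + 3
    shape = (2 * half + 1,) * 3
    centre = np.array([half] * 3, dtype=float)
    idx = np.indices(shape, dtype=float)
    # isotropic distance in index space keeps the voxel count exact
    dist2 = sum((idx[a] - centre[a]) ** 2 for a in range(3))
    order = np.argsort(dist2, axis=None, kind="stable")
    mask = np.zeros(shape, dtype=bool)
    mask.flat[order[:n_target]] = True

    rng = np.random.default_rng(seed)
    image = np.zeros(shape, dtype=float)
    if sd == 0:
        image[mask] = mean
    else:
        # log-normal with target linear-scale mean/sd
        cv2 = (sd / mean) ** 2
        log_sd = math.sqrt(math.log1p(cv2))
        log_mu = math.log(mean) - 0.5 * log_sd**2
        noise = rng.standard_normal(shape)
        if smoothness > 0:
            from scipy.ndimage import gaussian_filter

            sig = smoothness / spacing
            noise = gaussian_filter(noise, sigma=sig)
            noise /= max(noise[mask].std(), 1e-12)
            noise -= noise[mask].mean()
        image[mask] = np.exp(log_mu + log_sd * noise[mask])
    return image, mask


def save_lesion_image(
    image: np.ndarray,
    mask: np.ndarray,
    voxel_spacing_mm: tuple[float, float, float],
    image_path: str | Path,
    mask_path: str | Path,
) -> None:
    """Write image and mask as NIfTI with a diagonal affine from the spacing."""
    import nibabel as nib

    affine = np.diag(list(voxel_spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(image.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(mask_path))
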