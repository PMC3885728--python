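"""Synthetic phantoms and longitudinal treatment studies.

Two generators stand in for the animal experiments:

* :func:`make_phantom` builds a mouse-torso-like optical volume (a capsule:
  finite cylinder with hemispherical caps) with homogeneous background optical
  properties and a spherical fluorescent inclusion playing the role of an
  orthotopic liver tumor.
* :func:`simulate_study` draws a two-arm longitudinal study (control vs
  treated) with exponential tumor growth, multiplicative log-normal animal
  heterogeneity and measurement noise, caliper diameters tied to intensity
  through a fixed monotone map, and body weight carrying no group effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "OpticalVolume",
    "SourceVolume",
    "make_phantom",
    "simulate_study",
    "validate_study",
    "STUDY_COLUMNS",
]

#: canonical column order of a study table
STUDY_COLUMNS = ["animal_id", "group", "day", "intensity", "a_mm", "b_mm", "weight_g"]

# Study-generator defaults. The control growth rate (per day) sits where the
# two arms, under the default noise levels, separate statistically around the
# second imaging time point (day 8) rather than immediately; the baseline
# intensity puts the day-12 control group mean in the 10^6-10^7 photons/cm^2/s
# range typical of luciferase xenograft imaging.
DEFAULT_GROWTH_RATE_CONTROL = 0.13
DEFAULT_TREATED_FRACTION = 0.6
DEFAULT_S0_MEAN = 1.6e6
DEFAULT_ANIMAL_CV = 0.3
DEFAULT_MEASUREMENT_CV = 0.15
DEFAULT_DAYS = (0, 4, 8, 12)

# Caliper map: expected caliper volume tracks expected intensity through
# V = V0 * (S / S0)**eta.  eta < 1 encodes that caliper volume responds less
# dramatically than viable-cell light output; V0 is the enrollment volume
# (treatment begins once tumors reach ~100 mm^3).
CALIPER_V0_MM3 = 100.0
CALIPER_ETA = 0.5
CALIPER_ASPECT = 1.3  # longer/shorter diameter ratio
# caliper noise: diameters are read more repeatably than photon counts
CALIPER_CV_FRACTION = 1.0 / 3.0  # of measurement_cv

BODY_WEIGHT_MEAN_G = 20.0
BODY_WEIGHT_CV = 0.05
BODY_WEIGHT_DAY_SD_G = 0.3


@dataclass
class OpticalVolume:
    """Voxelized optical-property map defining the photon-transport medium.

    Parameters
    ----------
    voxel_size : float
        Isotropic voxel edge length in mm.
    mu_a : ndarray
        Absorption coefficient per voxel, 1/mm.
    mu_s_prime : ndarray
        Reduced scattering coefficient per voxel, 1/mm.
    mask : ndarray of bool
        True inside the tissue domain. Must be a single connected component.
    """

    voxel_size: float
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.mu_s_prime = np.asarray(self.mu_s_prime, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not (self.mu_a.shape == self.mu_s_prime.shape == self.mask.shape):
            raise ValueError("mu_a, mu_s_prime and mask must share a shape")
        if self.mask.ndim != 3:
            raise ValueError("volumes must be 3-D")
        if not self.mask.any():
            raise ValueError("tissue mask is empty")
        if np.any(self.mu_a[self.mask] <= 0) or np.any(self.mu_s_prime[self.mask] <= 0):
            raise ValueError("optical coefficients must be > 0 on masked voxels")
        _, n_components = ndimage.label(self.mask)
        if n_components != 1:
            raise ValueError(f"tissue mask has {n_components} connected components, expected 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(self.voxel_size ** 3)

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, shape (nvox, 3).

        Voxel ``(i, j, k)`` is centered at ``(i + 0.5, j + 0.5, k + 0.5) * h``.
        """
        idx = np.indices(self.shape).reshape(3, -1).T
        return (idx + 0.5) * self.voxel_size


@dataclass
class SourceVolume:
    """Voxelized fluorophore yield density (the unknown of the inverse problem).

    ``yield_`` is a density in arbitrary units per mm^3, zero outside the
    tissue mask; ``truth_power`` integrates it over the volume. The truth
    fields are populated only for synthetic phantoms.
    """

    voxel_size: float
    yield_: np.ndarray
    truth_centroid: np.ndarray | None = None
    truth_power: float | None = None

    def __post_init__(self) -> None:
        self.yield_ = np.asarray(self.yield_, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.yield_.ndim != 3:
            raise ValueError("yield must be 3-D")
        if np.any(self.yield_ < 0):
            raise ValueError("fluorophore yield must be >= 0 everywhere")
        if self.truth_centroid is not None:
            self.truth_centroid = np.asarray(self.truth_centroid, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.yield_.shape)  # type: ignore[return-value]

    def total_power(self) -> float:
        """Integrated yield: sum of density times voxel volume."""
        return float(self.yield_.sum() * self.voxel_size ** 3)

    def centroid_mm(self) -> np.ndarray | None:
        """Yield-weighted centroid in mm, or None for an all-zero volume."""
        total = self.yield_.sum()
        if total == 0:
            return None
        idx = np.indices(self.shape).reshape(3, -1)
        w = self.yield_.ravel()
        return ((idx * w).sum(axis=1) / total + 0.5) * self.voxel_size


def _capsule_mask(shape: tuple[int, int, int], voxel_size: float, radius_mm: float | None) -> np.ndarray:
    """Boolean capsule (cylinder with hemispherical caps) along the z axis."""
    nx, ny, nz = shape
    h = voxel_size
    cx, cy = nx * h / 2.0, ny * h / 2.0
    if radius_mm is None:
        radius_mm = 0.85 * min(nx, ny) * h / 2.0
    z_lo = radius_mm
    z_hi = nz * h - radius_mm
    if z_hi <= z_lo:
        raise ValueError("volume too short along z for hemispherical caps")
    centers = (np.indices(shape).astype(float) + 0.5) * h
    x, y, z = centers
    # distance to the capsule's axis segment [(cx,cy,z_lo), (cx,cy,z_hi)]
    zc = np.clip(z, z_lo, z_hi)
    dist = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - zc) ** 2)
    return dist <= radius_mm


def make_phantom(
    shape: tuple[int, int, int] = (40, 40, 60),
    voxel_size: float = 0.5,
    background_mu_a: float = 0.02,
    background_mu_s_prime: float = 1.0,
    tumor_center: tuple[float, float, float] | None = None,
    tumor_radius: float = 2.0,
    tumor_yield: float = 1.0,
    seed: int | None = None,
    torso_radius_mm: float | None = None,
    tumor_mu_a_contrast: float = 1.0,
) -> tuple[OpticalVolume, SourceVolume]:
    """Build a torso-proxy optical phantom with a spherical fluorescent tumor.

    Parameters
    ----------
    shape : (nx, ny, nz)
        Voxel grid dimensions.
    voxel_size : float
        Isotropic voxel size, mm.
    background_mu_a, background_mu_s_prime : float
        Homogeneous background absorption / reduced scattering, 1/mm.
        Defaults are typical soft-tissue values near 500-525 nm.
    tumor_center : mm triple, optional
        Sphere center in world coordinates; defaults to an off-axis point in
        the upper half of the torso (a liver-lobe proxy).
    tumor_radius : float
        Sphere radius, mm; must cover at least one voxel center.
    tumor_yield : float
        Fluorophore yield density inside the sphere (a.u. / mm^3).
    seed : int, optional
        Accepted for interface symmetry; the phantom itself is deterministic.
    torso_radius_mm : float, optional
        Capsule radius; default 85% of the half-width of the grid.
    tumor_mu_a_contrast : float
        Multiplicative absorption contrast of tumor voxels (1.0 = pure
        emission contrast, no optical contrast).

    Returns
    -------
    (OpticalVolume, SourceVolume)
        The source volume records ``truth_centroid`` and ``truth_power``.
    """
    if background_mu_a <= 0 or background_mu_s_prime <= 0:
        raise ValueError("optical coefficients must be > 0")
    if tumor_yield < 0:
        raise ValueError("tumor_yield must be >= 0")
    shape = tuple(int(s) for s in shape)  # type: ignore[assignment]
    mask = _capsule_mask(shape, voxel_size, torso_radius_mm)

    h = voxel_size
    if tumor_center is None:
        nx, ny, nz = shape
        tumor_center = (nx * h / 2.0 + nx * h * 0.12, ny * h / 2.0, nz * h * 0.62)
    center = np.asarray(tumor_center, dtype=float)
    if tumor_radius < voxel_size:
        raise ValueError("tumor_radius must be at least one voxel")

    centers = (np.indices(shape).astype(float) + 0.5) * h
    dist = np.sqrt(((centers - center.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
    sphere = dist <= tumor_radius
    if not sphere.any():
        raise ValueError("tumor sphere covers no voxel centers")
    if np.any(sphere & ~mask):
        raise ValueError("tumor sphere extends outside the tissue mask")

    mu_a = np.full(shape, background_mu_a)
    if tumor_mu_a_contrast != 1.0:
        mu_a[sphere] *= tumor_mu_a_contrast
    mu_s = np.full(shape, background_mu_s_prime)
    vol = OpticalVolume(voxel_size=voxel_size, mu_a=mu_a, mu_s_prime=mu_s, mask=mask)

    yield_ = np.where(sphere, float(tumor_yield), 0.0)
    power = float(yield_.sum() * h ** 3)
    src = SourceVolume(
        voxel_size=voxel_size,
        yield_=yield_,
        truth_centroid=center,
        truth_power=power,
    )
    return vol, src


def simulate_study(
    n_per_group: int = 12,
    days: tuple[int, ...] = DEFAULT_DAYS,
    s0_mean: float = DEFAULT_S0_MEAN,
    growth_rate_control: float = DEFAULT_GROWTH_RATE_CONTROL,
    growth_rate_treated: float | None = None,
    animal_cv: float = DEFAULT_ANIMAL_CV,
    measurement_cv: float = DEFAULT_MEASUREMENT_CV,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a two-arm longitudinal imaging study.

    Each animal ``i`` in group ``g`` has a log-normal baseline
    ``S0_i`` (mean ``s0_mean``, coefficient of variation ``animal_cv``) and
    expected intensity ``S0_i * exp(rate_g * day)``; the observed intensity is
    multiplied by log-normal measurement noise with CV ``measurement_cv``.
    Caliper diameters are generated so that the caliper volume 0.5*a*b^2
    tracks intensity through a fixed monotone (power-law) map, and body weight
    carries no group effect.

    Returns a DataFrame with columns
    ``animal_id, group, day, intensity, a_mm, b_mm, weight_g``;
    one row per animal per day.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (between-group ANOVA undefined)")
    days = tuple(int(d) for d in days)
    if list(days) != sorted(days) or len(set(days)) != len(days):
        raise ValueError("days must be strictly ascending")
    if days[0] != 0:
        raise ValueError("first measurement day must be 0")
    if animal_cv < 0 or measurement_cv < 0:
        raise ValueError("CVs must be >= 0")
    if s0_mean <= 0:
        raise ValueError("s0_mean must be > 0")
    if growth_rate_treated is None:
        growth_rate_treated = DEFAULT_TREATED_FRACTION * growth_rate_control

    rng = np.random.default_rng(seed)
    rates = {"control": growth_rate_control, "treated": growth_rate_treated}

    # mean-preserving log-normal: E[exp(mu + s Z)] = exp(mu + s^2/2)
    s_animal = np.sqrt(np.log1p(animal_cv ** 2))
    s_meas = np.sqrt(np.log1p(measurement_cv ** 2))
    s_cal = np.sqrt(np.log1p((CALIPER_CV_FRACTION * measurement_cv) ** 2))

    rows = []
    animal_counter = 0
    for group in ("control", "treated"):
        rate = rates[group]
        s0 = s0_mean * np.exp(s_animal * rng.standard_normal(n_per_group) - s_animal ** 2 / 2)
        weight0 = BODY_WEIGHT_MEAN_G * (
            1 + BODY_WEIGHT_CV * rng.standard_normal(n_per_group)
        )
        for i in range(n_per_group):
            animal_counter += 1
            aid = f"M{animal_counter:03d}"
            for day in days:
                expected = s0[i] * np.exp(rate * day)
                noise = np.exp(s_meas * rng.standard_normal() - s_meas ** 2 / 2)
                intensity = expected * noise
                # caliper volume through the fixed monotone map of expected
                # intensity, with its own (small) measurement noise
                v_expected = CALIPER_V0_MM3 * (expected / s0_mean) ** CALIPER_ETA
                b = (v_expected / (0.5 * CALIPER_ASPECT)) ** (1.0 / 3.0)
                b *= np.exp(s_cal * rng.standard_normal() - s_cal ** 2 / 2)
                a = CALIPER_ASPECT * b
                weight = weight0[i] + BODY_WEIGHT_DAY_SD_G * rng.standard_normal()
                rows.append((aid, group, day, intensity, a, b, weight))

    df = pd.DataFrame(rows, columns=STUDY_COLUMNS)
    validate_study(df)
    return df


def validate_study(df: pd.DataFrame) -> None:
    """Check study-table invariants; raise ValueError on violation."""
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study table missing columns: {sorted(missing)}")
    if not set(df["group"]) <= {"control", "treated"}:
        raise ValueError("group must be 'control' or 'treated'")
    if (df["intensity"] <= 0).any():
        raise ValueError("intensities must be strictly positive")
    counts = df.groupby("group")["animal_id"].nunique()
    if counts.nunique() > 1:
        raise ValueError(f"group sizes differ: {counts.to_dict()}")
    per_animal_days = df.groupby("animal_id")["day"].apply(lambda s: tuple(sorted(s)))
    if per_animal_days.nunique() > 1:
        raise ValueError("animals do not share a common set of measurement days")
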