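"""Steady-state diffusion-approximation photon transport and Born sensitivity.

The forward model solves

    -div(D grad Phi) + mu_a Phi = q,      D = 1 / (3 (mu_a + mu_s'))

by a 7-point finite-difference discretization on the voxel grid, with a Robin
(partial-current) boundary condition  Phi + 2 A_n D dPhi/dn = 0  on the tissue
surface, A_n accounting for internal reflection at the tissue/air refractive
mismatch. The discretized operator is symmetric positive definite, so emission
Green's functions are obtained by adjoint (here: plain) solves, and
reciprocity holds to solver tolerance.

Fluorescence acquisition is transillumination: per projection angle the
excitation laser enters on one side of the torso and detectors sample the
fluence on the opposite side. The Born-type sensitivity (system) matrix has
rows  A[(s,d), j] = G_em(r_d, r_j) * Phi_ex,s(r_j)  over masked voxels j, so
that A applied to a fluorophore yield density reproduces the noise-free
simulated measurements exactly on a common grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .phantom import OpticalVolume, SourceVolume

__all__ = [
    "AcquisitionGeometry",
    "MeasurementSet",
    "SystemMatrix",
    "DiffusionSolver",
    "solve_diffusion",
    "build_system_matrix",
    "simulate_measurements",
    "robin_coefficient",
]

#: measurement-table column order
MEASUREMENT_COLUMNS = ["angle_deg", "excitation_id", "detector_id", "value", "sigma"]


def robin_coefficient(n_tissue: float = 1.37) -> float:
    """Internal-reflection boundary coefficient A_n for refractive index n.

    Uses the Egan-Hilgeman polynomial fit for the effective reflection
    coefficient; A_n = (1 + R_eff) / (1 - R_eff). n = 1.37 (soft tissue vs
    air) gives A_n ~ 3.0.
    """
    r_eff = -1.440 / n_tissue ** 2 + 0.710 / n_tissue + 0.668 + 0.0636 * n_tissue
    return (1.0 + r_eff) / (1.0 - r_eff)


class DiffusionSolver:
    """Factorized finite-difference diffusion operator for one OpticalVolume.

    Assembles the SPD system over masked voxels once and keeps an LU
    factorization, so repeated solves (per excitation position, per detector
    adjoint) cost one back-substitution each.
    """

    def __init__(self, volume: OpticalVolume, n_tissue: float = 1.37):
        self.volume = volume
        self.n_tissue = n_tissue
        self.mask_flat = volume.mask.ravel()
        self.masked_indices = np.flatnonzero(self.mask_flat)
        self.n_unknowns = self.masked_indices.size
        if self.n_unknowns == 0:
            raise ValueError("empty tissue mask: diffusion system is singular")
        self._index_of = -np.ones(self.mask_flat.size, dtype=np.int64)
        self._index_of[self.masked_indices] = np.arange(self.n_unknowns)
        self._matrix = self._assemble()
        try:
            self._lu = splu(self._matrix.tocsc())
        except RuntimeError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                f"diffusion system factorization failed ({exc}); "
                "check optical coefficients and mask"
            ) from exc
        self._surface_tree: cKDTree | None = None
        self._surface_flat: np.ndarray | None = None

    _cache: "dict[tuple, DiffusionSolver]" = {}

    @classmethod
    def cached(cls, volume: OpticalVolume, n_tissue: float = 1.37) -> "DiffusionSolver":
        """Reuse the factorized operator for an identical volume.

        The sparse factorization dominates the cost of repeated forward
        simulations on one phantom; solvers are keyed by the volume content
        (a few entries are kept, LRU-style).
        """
        import hashlib

        h = hashlib.sha1()
        h.update(volume.mu_a.tobytes())
        h.update(volume.mu_s_prime.tobytes())
        h.update(volume.mask.tobytes())
        key = (h.hexdigest(), float(volume.voxel_size), float(n_tissue))
        solver = cls._cache.pop(key, None)
        if solver is None:
            solver = cls(volume, n_tissue=n_tissue)
        cls._cache[key] = solver
        while len(cls._cache) > 3:
            cls._cache.pop(next(iter(cls._cache)))
        return solver

    def _assemble(self) -> sparse.coo_matrix:
        vol = self.volume
        h = vol.voxel_size
        shape = vol.mask.shape
        mask = vol.mask
        D = 1.0 / (3.0 * (vol.mu_a + vol.mu_s_prime))
        a_n = robin_coefficient(self.n_tissue)

        diag = vol.mu_a.copy()
        diag[~mask] = 0.0
        rows, cols, vals = [], [], []

        flat_idx = np.arange(mask.size).reshape(shape)
        for axis in range(3):
            # interior faces between two masked voxels: harmonic-mean D
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            m_lo = mask[tuple(sl_lo)]
            m_hi = mask[tuple(sl_hi)]
            both = m_lo & m_hi
            d_lo = D[tuple(sl_lo)][both]
            d_hi = D[tuple(sl_hi)][both]
            d_face = 2.0 * d_lo * d_hi / (d_lo + d_hi)
            w = d_face / h ** 2
            i_lo = self._index_of[flat_idx[tuple(sl_lo)][both]]
            i_hi = self._index_of[flat_idx[tuple(sl_hi)][both]]
            rows.extend([i_lo, i_hi])
            cols.extend([i_hi, i_lo])
            vals.extend([-w, -w])
            # accumulate diagonal couplings
            diag_add = np.zeros(mask.size)
            np.add.at(diag_add, flat_idx[tuple(sl_lo)][both].ravel(), w)
            np.add.at(diag_add, flat_idx[tuple(sl_hi)][both].ravel(), w)
            diag += diag_add.reshape(shape)

            # boundary faces: masked voxel facing an unmasked voxel or the
            # grid edge gets a Robin partial-current term
            for lo_side in (True, False):
                if lo_side:
                    inner, outer = tuple(sl_hi), tuple(sl_lo)
                else:
                    inner, outer = tuple(sl_lo), tuple(sl_hi)
                facing_out = mask[inner] & ~mask[outer]
                if facing_out.any():
                    d_in = D[inner][facing_out]
                    flux = 1.0 / (h * (2.0 * a_n + h / (2.0 * d_in)))
                    diag_add = np.zeros(mask.size)
                    np.add.at(diag_add, flat_idx[inner][facing_out].ravel(), flux)
                    diag += diag_add.reshape(shape)
                # voxels on the grid edge itself
                edge = [slice(None)] * 3
                edge[axis] = slice(-1, None) if not lo_side else slice(0, 1)
                edge_mask = mask[tuple(edge)]
                if edge_mask.any():
                    d_in = D[tuple(edge)][edge_mask]
                    flux = 1.0 / (h * (2.0 * a_n + h / (2.0 * d_in)))
                    diag_add = np.zeros(mask.size)
                    np.add.at(diag_add, flat_idx[tuple(edge)][edge_mask].ravel(), flux)
                    diag += diag_add.reshape(shape)

        i_diag = np.arange(self.n_unknowns)
        rows.append(i_diag)
        cols.append(i_diag)
        vals.append(diag.ravel()[self.masked_indices])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return sparse.coo_matrix((vals, (rows, cols)), shape=(self.n_unknowns,) * 2)

    # -- solves ---------------------------------------------------------

    def solve_masked(self, q_masked: np.ndarray) -> np.ndarray:
        """Solve for fluence given a source density vector on masked voxels."""
        phi = self._lu.solve(np.asarray(q_masked, dtype=float))
        if not np.all(np.isfinite(phi)):
            raise np.linalg.LinAlgError("diffusion solve produced non-finite fluence")
        return phi

    def solve(self, source_field: np.ndarray) -> np.ndarray:
        """Solve for fluence on the full grid given a full-grid source density.

        The source density must vanish outside the tissue mask.
        """
        q = np.asarray(source_field, dtype=float)
        if q.shape != self.volume.mask.shape:
            raise ValueError("source field shape does not match the volume")
        if np.any(q.ravel()[~self.mask_flat] != 0):
            raise ValueError("source density must be zero outside the tissue mask")
        phi = np.zeros(self.volume.mask.shape)
        phi.ravel()[self.masked_indices] = self.solve_masked(q.ravel()[self.masked_indices])
        return phi

    # -- geometry helpers ----------------------------------------------

    def surface_voxels(self) -> np.ndarray:
        """Flat indices of masked voxels with at least one unmasked/outside face."""
        mask = self.volume.mask
        padded = np.pad(mask, 1, constant_values=False)
        interior = np.ones_like(mask)
        for axis in range(3):
            lo = np.roll(padded, 1, axis=axis)[1:-1, 1:-1, 1:-1]
            hi = np.roll(padded, -1, axis=axis)[1:-1, 1:-1, 1:-1]
            interior &= lo & hi
        surface = mask & ~interior
        return np.flatnonzero(surface.ravel())

    def _ensure_surface_tree(self) -> None:
        if self._surface_tree is None:
            self._surface_flat = self.surface_voxels()
            coords = np.array(np.unravel_index(self._surface_flat, self.volume.mask.shape)).T
            centers = (coords + 0.5) * self.volume.voxel_size
            self._surface_tree = cKDTree(centers)

    def nearest_surface_voxel(self, point_mm) -> int:
        """Flat index of the surface voxel nearest a world point (mm)."""
        self._ensure_surface_tree()
        dist, idx = self._surface_tree.query(np.asarray(point_mm, dtype=float))
        if dist > 2.0 * self.volume.voxel_size:
            raise ValueError(
                f"point {tuple(point_mm)} is {dist:.2f} mm from the tissue "
                "surface (> 2 voxels): not a valid surface position"
            )
        return int(self._surface_flat[idx])

    def nearest_masked_voxel(self, point_mm) -> int:
        """Flat index of the masked voxel nearest a world point (mm)."""
        coords = np.array(np.unravel_index(self.masked_indices, self.volume.mask.shape)).T
        centers = (coords + 0.5) * self.volume.voxel_size
        d2 = ((centers - np.asarray(point_mm, dtype=float)) ** 2).sum(axis=1)
        return int(self.masked_indices[np.argmin(d2)])

    def point_source_density(self, point_mm, power: float = 1.0) -> np.ndarray:
        """Full-grid source density for a point source of total power `power`."""
        flat = self.nearest_masked_voxel(point_mm)
        q = np.zeros(self.volume.mask.size)
        q[flat] = power / self.volume.voxel_volume
        return q.reshape(self.volume.mask.shape)


def solve_diffusion(volume: OpticalVolume, source_field: np.ndarray) -> np.ndarray:
    """One-shot diffusion solve; see :class:`DiffusionSolver` for repeated use."""
    return DiffusionSolver(volume).solve(source_field)


# ---------------------------------------------------------------------------
# acquisition geometry
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionGeometry:
    """Transillumination acquisition geometry.

    Positions are world coordinates in mm, per projection angle (rotation
    about the long z axis, right-handed, 0 deg = illumination from +x).
    Excitation positions sit on the illuminated surface; detector positions
    on the opposite surface.
    """

    projection_angles: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    excitation_positions: dict = field(default_factory=dict)
    detector_positions: dict = field(default_factory=dict)
    excitation_wavelength_nm: float = 488.0
    emission_wavelength_nm: float = 525.0
    source_power_mw: float = 20.0

    def n_rows(self) -> int:
        return sum(
            len(self.excitation_positions[a]) * len(self.detector_positions[a])
            for a in self.projection_angles
        )

    def validate_on(self, volume: OpticalVolume) -> None:
        """Check that all positions sit on the tissue surface and detectors
        face the excitation side (transillumination)."""
        solver = DiffusionSolver.cached(volume)
        nx, ny, _ = volume.shape
        h = volume.voxel_size
        axis_xy = np.array([nx * h / 2.0, ny * h / 2.0])
        for ang in self.projection_angles:
            u = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
            for p in self.excitation_positions[ang]:
                solver.nearest_surface_voxel(p)
                if np.dot(np.asarray(p)[:2] - axis_xy, u) <= 0:
                    raise ValueError(f"excitation {p} not on the illuminated (+{ang} deg) side")
            for p in self.detector_positions[ang]:
                solver.nearest_surface_voxel(p)
                if np.dot(np.asarray(p)[:2] - axis_xy, u) >= 0:
                    raise ValueError(f"detector {p} not opposite the {ang} deg illumination")

    @classmethod
    def auto(
        cls,
        volume: OpticalVolume,
        angles: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0),
        n_detectors_transverse: int = 5,
        n_detectors_axial: int = 9,
        transverse_halfangle_deg: float = 40.0,
        axial_span_frac: float = 0.6,
        torso_radius_mm: float | None = None,
        **kwargs,
    ) -> "AcquisitionGeometry":
        """Place one excitation point per angle and a detector grid opposite.

        The torso proxy is a capsule about the grid's z axis; excitation
        enters at mid-height on the illuminated side, and detectors sample an
        arc (+-`transverse_halfangle_deg`) by axial grid on the far side.
        """
        nx, ny, nz = volume.shape
        h = volume.voxel_size
        cx, cy = nx * h / 2.0, ny * h / 2.0
        if torso_radius_mm is None:
            torso_radius_mm = 0.85 * min(nx, ny) * h / 2.0
        r = torso_radius_mm
        z_mid = nz * h / 2.0
        z_span = axial_span_frac * nz * h
        z_vals = z_mid + np.linspace(-z_span / 2, z_span / 2, n_detectors_axial)
        phis = np.deg2rad(
            np.linspace(-transverse_halfangle_deg, transverse_halfangle_deg, n_detectors_transverse)
        )
        exc, det = {}, {}
        for ang in angles:
            th = np.deg2rad(ang)
            exc[ang] = [np.array([cx + r * np.cos(th), cy + r * np.sin(th), z_mid])]
            pts = []
            for z in z_vals:
                for phi in phis:
                    a = th + np.pi + phi
                    pts.append(np.array([cx + r * np.cos(a), cy + r * np.sin(a), z]))
            det[ang] = pts
        return cls(
            projection_angles=tuple(angles),
            excitation_positions=exc,
            detector_positions=det,
            **kwargs,
        )


@dataclass
class MeasurementSet:
    """Boundary fluorescence measurements.

    ``table`` has columns angle_deg, excitation_id, detector_id, value, sigma
    in canonical (angle, excitation, detector) order.
    """

    table: pd.DataFrame
    geometry: AcquisitionGeometry | None = None

    def __post_init__(self) -> None:
        missing = set(MEASUREMENT_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"measurement table missing columns: {sorted(missing)}")
        key = ["angle_deg", "excitation_id", "detector_id"]
        if self.table.duplicated(subset=key).any():
            raise ValueError("duplicated (angle, excitation, detector) measurement keys")
        self.table = (
            self.table.sort_values(key).reset_index(drop=True)[MEASUREMENT_COLUMNS]
        )

    @property
    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SystemMatrix:
    """Born sensitivity operator from yield density to boundary measurements.

    ``matrix`` has one row per (angle, excitation, detector) in canonical
    order and one column per masked voxel of the reconstruction grid;
    ``voxel_indices`` maps columns to flat voxel indices.
    """

    matrix: np.ndarray
    voxel_indices: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_size: float
    row_index: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("system matrix contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def apply(self, source: SourceVolume) -> np.ndarray:
        """Forward-project a SourceVolume through the Born operator."""
        if source.shape != self.grid_shape:
            raise ValueError("source grid does not match the system-matrix grid")
        return self.matrix @ source.yield_.ravel()[self.voxel_indices]

    def solution_to_volume(self, x: np.ndarray, clamp_negative: bool = True) -> SourceVolume:
        """Map a coefficient vector back to a SourceVolume (zeros off-mask)."""
        y = np.zeros(int(np.prod(self.grid_shape)))
        xv = np.asarray(x, dtype=float)
        if clamp_negative:
            xv = np.maximum(xv, 0.0)
        y[self.voxel_indices] = xv
        return SourceVolume(voxel_size=self.voxel_size, yield_=y.reshape(self.grid_shape))


def _excitation_fields(solver: DiffusionSolver, geometry: AcquisitionGeometry):
    """Excitation fluence per (angle, excitation id), sources stepped one
    transport mean free path inside the surface."""
    vol = solver.volume
    nx, ny, _ = vol.shape
    h = vol.voxel_size
    cx, cy = nx * h / 2.0, ny * h / 2.0
    fields = {}
    for ang in geometry.projection_angles:
        th = np.deg2rad(ang)
        u = np.array([np.cos(th), np.sin(th), 0.0])
        for s_id, p in enumerate(geometry.excitation_positions[ang]):
            p = np.asarray(p, dtype=float)
            entry_flat = solver.nearest_surface_voxel(p)
            coord = np.array(np.unravel_index(entry_flat, vol.shape))
            entry_mm = (coord + 0.5) * h
            mus = vol.mu_s_prime.ravel()[entry_flat]
            inside = entry_mm - u / mus  # one transport mean free path inward
            q = solver.point_source_density(inside, power=geometry.source_power_mw)
            fields[(ang, s_id)] = solver.solve(q)
    return fields


def build_system_matrix(
    volume: OpticalVolume,
    geometry: AcquisitionGeometry,
    normalized: bool = False,
    solver: DiffusionSolver | None = None,
) -> SystemMatrix:
    """Assemble the Born sensitivity matrix for a volume and geometry.

    Row (angle, s, d), column j:  G_em(r_d, r_j) * Phi_ex,s(r_j),  with the
    emission Green's function from one adjoint solve per detector (the
    discrete operator is symmetric). With ``normalized=True`` each row is
    divided by the excitation signal at its detector (normalized Born).
    """
    if solver is None:
        solver = DiffusionSolver.cached(volume)
    exc_fields = _excitation_fields(solver, geometry)

    # adjoint Green's functions, one per distinct detector voxel
    det_voxel: dict[tuple[float, int], int] = {}
    green: dict[int, np.ndarray] = {}
    for ang in geometry.projection_angles:
        for d_id, p in enumerate(geometry.detector_positions[ang]):
            flat = solver.nearest_surface_voxel(p)
            det_voxel[(ang, d_id)] = flat
            if flat not in green:
                e = np.zeros(solver.n_unknowns)
                e[solver._index_of[flat]] = 1.0
                green[flat] = solver.solve_masked(e)

    masked = solver.masked_indices
    rows = []
    index_rows = []
    for ang in geometry.projection_angles:
        for s_id in range(len(geometry.excitation_positions[ang])):
            phi_ex = exc_fields[(ang, s_id)].ravel()[masked]
            for d_id in range(len(geometry.detector_positions[ang])):
                g = green[det_voxel[(ang, d_id)]]
                row = g * phi_ex
                if normalized:
                    ex_at_det = exc_fields[(ang, s_id)].ravel()[det_voxel[(ang, d_id)]]
                    if ex_at_det <= 0:
                        raise ValueError("zero excitation signal at detector; cannot normalize")
                    row = row / ex_at_det
                rows.append(row)
                index_rows.append((ang, s_id, d_id))
    matrix = np.array(rows)
    row_index = pd.DataFrame(index_rows, columns=["angle_deg", "excitation_id", "detector_id"])
    return SystemMatrix(
        matrix=matrix,
        voxel_indices=masked,
        grid_shape=volume.shape,
        voxel_size=volume.voxel_size,
        row_index=row_index,
        normalized=normalized,
    )


def simulate_measurements(
    volume: OpticalVolume,
    source: SourceVolume,
    geometry: AcquisitionGeometry,
    snr_db: float | None = None,
    seed: int | None = None,
    solver: DiffusionSolver | None = None,
) -> MeasurementSet:
    """Simulate boundary fluorescence measurements for a fluorophore source.

    Noise-free values come from two diffusion solves per excitation
    (excitation fluence, then emission fluence with source density
    yield * Phi_ex). With ``snr_db`` set, additive Gaussian noise is applied
    at that signal-to-noise ratio (sigma = rms(values) * 10^(-SNR/20)) and
    recorded per row.
    """
    if source.shape != volume.shape or source.voxel_size != volume.voxel_size:
        raise ValueError("source grid does not match the optical volume grid")
    if solver is None:
        solver = DiffusionSolver.cached(volume)
    exc_fields = _excitation_fields(solver, geometry)

    rows = []
    for ang in geometry.projection_angles:
        for s_id in range(len(geometry.excitation_positions[ang])):
            phi_ex = exc_fields[(ang, s_id)]
            q_em = source.yield_ * phi_ex
            q_em[~volume.mask] = 0.0
            phi_em = solver.solve(q_em)
            for d_id, p in enumerate(geometry.detector_positions[ang]):
                flat = solver.nearest_surface_voxel(p)
                rows.append((ang, s_id, d_id, phi_em.ravel()[flat], 0.0))
    table = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)

    if snr_db is not None and np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        rms = float(np.sqrt(np.mean(table["value"] ** 2)))
        sigma = rms * 10.0 ** (-snr_db / 20.0)
        table["value"] = table["value"] + sigma * rng.standard_normal(len(table))
        table["sigma"] = sigma
    return MeasurementSet(table=table, geometry=geometry)
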