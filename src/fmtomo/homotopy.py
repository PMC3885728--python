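"""Homotopy (LASSO-path) sparse reconstruction with adaptive regularization.

Solves  min_x 0.5 ||b - A x||^2 + lam ||x||_1  by tracking the piecewise-linear
solution path from lam = ||A^T b||_inf downward. Each iteration performs the
six steps of the active-set homotopy method:

1. compute the residual-correlation vector  c = A^T (b - A x);
2. update the supporting (active) set I of unknowns whose correlations sit
   at the current regularization level lam;
3. obtain the direction d restricted to I from the Gram system
   (A_I^T A_I) d_I = sign(c_I);
4. compute the two candidate step sizes: the smallest positive step gamma+
   at which an inactive correlation catches up with lam, and the smallest
   positive step gamma- at which an active unknown crosses zero;
5. append the entrant to I or remove the leaver, depending on which step
   is smaller;
6. update the unknowns x_I <- x_I + gamma d_I and lam <- lam - gamma.

Because lam is lowered along the path rather than fixed a priori, the
reconstruction does not depend on an initial estimate of the regularization
parameter; stopping rules (relative residual, active-set cap, lam floor) pick
the reported point on the path.

The module-level functions implement the individual steps; the
:class:`HomotopyLasso` estimator composes them behind the scikit-learn
``fit``/``predict`` interface, and :func:`reconstruct` binds the solver to
the tomographic forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .phantom import OpticalVolume, SourceVolume
from .forward import (
    AcquisitionGeometry,
    MeasurementSet,
    SystemMatrix,
    build_system_matrix,
)

__all__ = [
    "HomotopyState",
    "HomotopyLasso",
    "residual_correlations",
    "update_support",
    "active_direction",
    "step_sizes",
    "homotopy_solve",
    "reconstruct",
    "coarsen_volume",
    "StalledPathError",
    "DegenerateDirectionError",
]


class StalledPathError(RuntimeError):
    """Neither an entrant nor a leaver exists while lam is above its floor."""

    def __init__(self, message: str, state: "HomotopyState | None" = None):
        super().__init__(message)
        self.state = state


class DegenerateDirectionError(np.linalg.LinAlgError):
    """The Gram matrix on the active set is rank deficient.

    Remediation: drop the most recent entrant (done automatically once by
    the path driver) or raise the correlation tolerance.
    """

    def __init__(self, message: str, state: "HomotopyState | None" = None):
        super().__init__(message)
        self.state = state


@dataclass
class HomotopyState:
    """Mutable state of the homotopy path.

    Attributes
    ----------
    x : ndarray
        Current unknowns; zero off the active set.
    active : list of int
        Supporting set I, in order of entry.
    c : ndarray
        Residual-correlation vector A^T (b - A x).
    lam : float
        Current regularization parameter (non-increasing along the path).
    d : ndarray
        Current direction (nonzero only on I).
    step_history : list
        Per-iteration records (lam, gamma, event, index, residual, n_active).
    path_lambdas, path_coefs : list
        Snapshots of (lam, x) at every breakpoint, including the start.
    """

    x: np.ndarray
    active: list = field(default_factory=list)
    c: np.ndarray | None = None
    lam: float = 0.0
    d: np.ndarray | None = None
    step_history: list = field(default_factory=list)
    path_lambdas: list = field(default_factory=list)
    path_coefs: list = field(default_factory=list)
    iteration: int = 0
    stop_reason: str | None = None

    def trace(self) -> list[dict]:
        """JSON-serializable per-iteration trace."""
        return [
            {
                "iteration": i,
                "lam": float(rec[0]),
                "gamma": float(rec[1]),
                "event": rec[2],
                "index": None if rec[3] is None else int(rec[3]),
                "residual_norm": float(rec[4]),
                "n_active": int(rec[5]),
            }
            for i, rec in enumerate(self.step_history)
        ]


def residual_correlations(A: np.ndarray, b: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Step 1: residual-correlation vector c = A^T (b - A x)."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.asarray(x, dtype=float)
    if A.ndim != 2 or b.shape != (A.shape[0],) or x.shape != (A.shape[1],):
        raise ValueError(
            f"dimension mismatch: A {A.shape}, b {b.shape}, x {x.shape}"
        )
    return A.T @ (b - A @ x)


def update_support(c: np.ndarray, lam: float, tol: float = 1e-10) -> np.ndarray:
    """Step 2: supporting set I = indices with |c_i| >= lam - tol.

    At initialization (x = 0, lam = ||c||_inf) this selects the maximally
    correlated column(s); ties within tol are all admitted.
    """
    if lam <= 0:
        raise ValueError("update_support requires lam > 0")
    I = np.flatnonzero(np.abs(c) >= lam - tol)
    if I.size == 0:
        raise RuntimeError(
            "empty supporting set at lam <= lam_max: path invariant violated"
        )
    return I


def active_direction(A: np.ndarray, c: np.ndarray, I) -> np.ndarray:
    """Step 3: direction d with (A_I^T A_I) d_I = sign(c_I), zero off I."""
    I = np.asarray(I, dtype=int)
    A_I = A[:, I]
    gram = A_I.T @ A_I
    rhs = np.sign(c[I])
    try:
        d_I = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDirectionError(
            f"rank-deficient Gram matrix on active set of size {I.size}; "
            "consider dropping the most recent entrant"
        ) from exc
    if not np.all(np.isfinite(d_I)):
        raise DegenerateDirectionError("non-finite direction from Gram solve")
    d = np.zeros(A.shape[1])
    d[I] = d_I
    return d


def step_sizes(
    A: np.ndarray,
    c: np.ndarray,
    x: np.ndarray,
    d: np.ndarray,
    I,
    lam: float,
    tol: float = 1e-10,
):
    """Step 4: candidate steps to the next path breakpoint.

    Returns ``(gamma_plus, join_index, gamma_minus, remove_index)``:
    the smallest positive value among (lam - c_i)/(1 - a_i^T A_I d_I) and
    (lam + c_i)/(1 + a_i^T A_I d_I) over inactive i (the entrant), and the
    smallest positive -x_i/d_i over active i (the leaver). Either is +inf
    when no positive argument exists.
    """
    I = np.asarray(I, dtype=int)
    n = A.shape[1]
    inactive = np.setdiff1d(np.arange(n), I, assume_unique=False)

    gamma_plus = np.inf
    join_index = None
    if inactive.size:
        v = A[:, inactive].T @ (A[:, I] @ d[I])  # a_i^T A_I d_I
        ci = c[inactive]
        with np.errstate(divide="ignore", invalid="ignore"):
            cand1 = (lam - ci) / (1.0 - v)
            cand2 = (lam + ci) / (1.0 + v)
        cands = np.concatenate([cand1, cand2])
        idxs = np.concatenate([inactive, inactive])
        pos = cands > tol
        if pos.any():
            k = np.argmin(cands[pos])
            gamma_plus = float(cands[pos][k])
            join_index = int(idxs[pos][k])

    gamma_minus = np.inf
    remove_index = None
    if I.size:
        with np.errstate(divide="ignore", invalid="ignore"):
            cand = -x[I] / d[I]
        pos = cand > tol
        if pos.any():
            k = np.argmin(cand[pos])
            gamma_minus = float(cand[pos][k])
            remove_index = int(I[pos][k])

    return gamma_plus, join_index, gamma_minus, remove_index


def homotopy_solve(
    A: np.ndarray,
    b: np.ndarray,
    lam_min: float | None = None,
    residual_tol: float = 0.05,
    max_active: int | None = None,
    max_iter: int | None = None,
    tol: float = 1e-10,
    record_path: bool = True,
) -> tuple[np.ndarray, HomotopyState]:
    """Run the six-step homotopy path from x = 0, lam = ||A^T b||_inf.

    Stops at the first satisfied criterion: relative residual
    ||b - Ax|| / ||b|| <= ``residual_tol``; active-set size reaching
    ``max_active`` (default 5% of the unknowns, at least 1); lam reaching
    ``lam_min`` (default 1e-6 lam_max); or ``max_iter`` iterations (default
    10 * max_active).

    Returns the final coefficient vector and the full :class:`HomotopyState`.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(A)) or not np.all(np.isfinite(b)):
        raise ValueError("A and b must be finite")
    m, n = A.shape
    if b.shape != (m,):
        raise ValueError(f"b has shape {b.shape}, expected ({m},)")
    if max_active is None:
        max_active = max(1, int(np.ceil(0.05 * n)))
    if max_iter is None:
        max_iter = 10 * max_active

    x = np.zeros(n)
    state = HomotopyState(x=x)
    c = residual_correlations(A, b, x)
    lam_max = float(np.max(np.abs(c))) if n else 0.0
    if lam_min is None:
        lam_min = 1e-6 * lam_max
    state.c = c
    state.lam = lam_max

    b_norm = float(np.linalg.norm(b))
    if b_norm == 0.0 or lam_max == 0.0:
        state.stop_reason = "zero_signal"
        if record_path:
            state.path_lambdas.append(state.lam)
            state.path_coefs.append(x.copy())
        return x, state

    active = list(np.atleast_1d(update_support(c, lam_max, tol)))
    if record_path:
        state.path_lambdas.append(lam_max)
        state.path_coefs.append(x.copy())

    dropped_recent = False
    while True:
        state.iteration += 1
        if state.iteration > max_iter:
            state.stop_reason = "max_iter"
            break
        I = np.array(active, dtype=int)
        try:
            d = active_direction(A, c, I)
        except DegenerateDirectionError:
            if not dropped_recent and len(active) > 1:
                # remediation: drop the most recent entrant once and retry
                active.pop()
                dropped_recent = True
                state.iteration -= 1
                continue
            raise DegenerateDirectionError(
                "Gram matrix remained rank deficient after dropping the most "
                "recent entrant",
                state,
            )
        dropped_recent = False
        state.d = d

        g_plus, j_join, g_minus, j_rm = step_sizes(A, c, x, d, I, state.lam, tol)
        lam_gap = state.lam - lam_min
        if not np.isfinite(g_plus) and not np.isfinite(g_minus):
            if lam_gap > tol:
                # no event left: the path runs linearly down to lam_min
                gamma, event, idx = lam_gap, "cap", None
            else:
                raise StalledPathError(
                    f"no positive step available at lam={state.lam:.3e} > "
                    f"lam_min={lam_min:.3e}",
                    state,
                )
        else:
            # Step 5: removal wins ties (within tol) to avoid a singular Gram
            if g_minus <= g_plus + tol:
                gamma, event, idx = g_minus, "remove", j_rm
            else:
                gamma, event, idx = g_plus, "add", j_join
            if gamma >= lam_gap:
                gamma, event, idx = lam_gap, "cap", None

        # Step 6: update unknowns and regularization parameter
        x[I] += gamma * d[I]
        state.lam -= gamma
        if event == "remove":
            x[idx] = 0.0
            active.remove(idx)
        elif event == "add":
            active.append(idx)

        c = residual_correlations(A, b, x)
        state.c = c
        residual = float(np.linalg.norm(b - A @ x))
        state.step_history.append(
            (state.lam, gamma, event, idx, residual, len(active))
        )
        if record_path:
            state.path_lambdas.append(state.lam)
            state.path_coefs.append(x.copy())

        if residual / b_norm <= residual_tol:
            state.stop_reason = "residual_tol"
            break
        if state.lam <= lam_min + tol:
            state.stop_reason = "lam_min"
            break
        if len(active) >= max_active and event == "add":
            state.stop_reason = "max_active"
            break
        if event == "cap":
            state.stop_reason = "lam_min"
            break

    state.active = list(active)
    state.x = x
    return x, state


class HomotopyLasso(BaseEstimator, RegressorMixin):
    """L1-regularized least squares solved along the homotopy path.

    Scikit-learn-compatible estimator around :func:`homotopy_solve`. The
    path starts at lam = ||X^T y||_inf and descends until a stopping rule
    fires; the fitted coefficients are the path solution at the stopping
    point.

    Parameters
    ----------
    lam_min : float, optional
        Floor on the regularization parameter (default 1e-6 of the starting
        value).
    residual_tol : float
        Stop when ||y - X coef|| / ||y|| falls below this (default 0.05).
    max_active : int, optional
        Cap on the active-set size (default 5% of the number of features).
    max_iter : int, optional
        Iteration cap (default 10 * max_active).
    tol : float
        Numerical tolerance on correlation comparisons (default 1e-10).
    record_path : bool
        Keep (lam, coef) snapshots at every breakpoint in ``path_lambdas_``
        / ``path_coefs_``.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Path solution at the stopping point.
    lambda_ : float
        Regularization parameter at the stopping point.
    active_set_ : list of int
        Supporting set at the stopping point.
    n_iter_ : int
        Number of path iterations taken.
    state_ : HomotopyState
        Full solver state and per-iteration trace.
    """

    def __init__(
        self,
        lam_min: float | None = None,
        residual_tol: float = 0.05,
        max_active: int | None = None,
        max_iter: int | None = None,
        tol: float = 1e-10,
        record_path: bool = True,
    ):
        self.lam_min = lam_min
        self.residual_tol = residual_tol
        self.max_active = max_active
        self.max_iter = max_iter
        self.tol = tol
        self.record_path = record_path

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        coef, state = homotopy_solve(
            X,
            y,
            lam_min=self.lam_min,
            residual_tol=self.residual_tol,
            max_active=self.max_active,
            max_iter=self.max_iter,
            tol=self.tol,
            record_path=self.record_path,
        )
        self.coef_ = coef
        self.state_ = state
        self.lambda_ = state.lam
        self.active_set_ = list(state.active)
        self.n_iter_ = state.iteration
        self.path_lambdas_ = list(state.path_lambdas)
        self.path_coefs_ = list(state.path_coefs)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_


def coarsen_volume(volume: OpticalVolume, factor: int) -> OpticalVolume:
    """Down-sample an OpticalVolume by an integer factor per axis.

    The coarse mask marks blocks containing any masked fine voxel; optical
    coefficients are averaged over the masked fine voxels of each block
    (background values fill fully-unmasked blocks, which stay outside the
    mask anyway). Grid dimensions must be divisible by the factor.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return volume
    shape = volume.shape
    if any(s % factor for s in shape):
        raise ValueError(f"grid {shape} not divisible by coarsening factor {factor}")
    new_shape = tuple(s // factor for s in shape)

    def blocks(arr):
        return arr.reshape(
            new_shape[0], factor, new_shape[1], factor, new_shape[2], factor
        ).transpose(0, 2, 4, 1, 3, 5).reshape(*new_shape, -1)

    mask_b = blocks(volume.mask)
    coarse_mask = mask_b.any(axis=-1)
    counts = mask_b.sum(axis=-1)
    safe = np.maximum(counts, 1)
    mu_a = blocks(volume.mu_a * volume.mask).sum(axis=-1) / safe
    mu_s = blocks(volume.mu_s_prime * volume.mask).sum(axis=-1) / safe
    # fill unmasked blocks with the median masked value to keep coefficients
    # positive everywhere (they never enter the solve)
    fill_a = np.median(mu_a[coarse_mask])
    fill_s = np.median(mu_s[coarse_mask])
    mu_a[~coarse_mask] = fill_a
    mu_s[~coarse_mask] = fill_s
    return OpticalVolume(
        voxel_size=volume.voxel_size * factor,
        mu_a=mu_a,
        mu_s_prime=mu_s,
        mask=coarse_mask,
    )


def reconstruct(
    volume: OpticalVolume,
    geometry: AcquisitionGeometry,
    measurements: MeasurementSet,
    recon_grid_factor: int = 2,
    lam_min: float | None = None,
    residual_tol: float = 0.05,
    max_active: int | None = None,
    max_iter: int | None = None,
    tol: float = 1e-10,
    normalized: bool = False,
    nonneg_clamp: bool = True,
    system_matrix: SystemMatrix | None = None,
) -> tuple[SourceVolume, HomotopyState]:
    """Reconstruct a fluorophore distribution from boundary measurements.

    Builds the Born sensitivity matrix on a grid coarsened by
    ``recon_grid_factor`` (an inverse-crime guard when the measurements were
    simulated on the fine grid), runs the homotopy path, and maps the
    solution back to a SourceVolume. Negative coefficients are clamped to
    zero at the reporting stage when ``nonneg_clamp`` is set; the solver
    itself is the signed path.
    """
    if system_matrix is None:
        coarse = coarsen_volume(volume, recon_grid_factor)
        system_matrix = build_system_matrix(coarse, geometry, normalized=normalized)

    # align measurement rows with system-matrix rows by their acquisition keys
    key = ["angle_deg", "excitation_id", "detector_id"]
    sm_index = system_matrix.row_index.reset_index(names="sm_row")
    merged = measurements.table.merge(sm_index, on=key, how="inner", validate="1:1")
    if len(merged) != len(measurements.table) or len(merged) != len(sm_index):
        raise ValueError("measurements do not match the acquisition geometry rows")
    A = system_matrix.matrix[merged["sm_row"].to_numpy()]
    b = merged["value"].to_numpy()

    est = HomotopyLasso(
        lam_min=lam_min,
        residual_tol=residual_tol,
        max_active=max_active,
        max_iter=max_iter,
        tol=tol,
    ).fit(A, b)
    recon = system_matrix.solution_to_volume(est.coef_, clamp_negative=nonneg_clamp)
    return recon, est.state_
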