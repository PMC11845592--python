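"""T2 relaxometry: rigid resampling of multi-echo stacks and per-voxel
three-parameter mono-exponential fitting.

The signal model is ``S(TE) = alpha * exp(-TE / T2) + C`` fitted by
Levenberg-Marquardt least squares.  :func:`fit_t2_voxel` is the scalar
contract (scipy LM); :func:`t2_map` runs a vectorized batch LM with the
analytic Jacobian over all in-mask voxels, which is what makes whole-knee
maps affordable — the two routes agree to solver tolerance and are
cross-checked in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .volumes import EchoSeries, GridSpec, LabelVolume

__all__ = ["RigidTransform", "T2FitResult", "rigid_resample", "fit_t2_voxel", "t2_map"]

log = logging.getLogger(__name__)

T2_BOUNDS_MS = (1e-3, 2000.0)  # fits outside this range are flagged, not clamped


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R @ x + t (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal (tol 1e-8)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1), not a reflection")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float, translation=(0, 0, 0)):
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3], m[:3, 3] = self.rotation, self.translation
        return m

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"matrix": self.matrix.tolist()}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "RigidTransform":
        with open(path) as fh:
            m = np.asarray(json.load(fh)["matrix"], dtype=float)
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class T2FitResult:
    """Per-voxel mono-exponential fit over a mask (ParameterMap)."""

    alpha: np.ndarray
    t2: np.ndarray
    offset: np.ndarray
    converged: np.ndarray
    residual_norm: np.ndarray
    mask: np.ndarray
    grid: GridSpec

    @property
    def nonconverged_fraction(self) -> float:
        n = int(self.mask.sum())
        return 0.0 if n == 0 else 1.0 - float(self.converged[self.mask].sum()) / n


def rigid_resample(
    series: EchoSeries, transform: RigidTransform, target_grid: GridSpec
) -> EchoSeries:
    """Resample every echo onto ``target_grid`` with one shared transform.

    ``transform`` maps source-frame coordinates into the target frame (it
    would be estimated once from the first echo and applied to all).
    Interpolation is cubic; target voxels that map outside the source
    volume are flagged invalid rather than extrapolated.
    """
    inv = transform.inverse()
    ax = target_grid.world_coords()
    Xt = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    Xs = inv.apply(Xt)
    idx = series.grid.world_to_index(Xs)  # fractional source indices (N, 3)
    shape = np.asarray(series.grid.shape)
    inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    if not inside.any():
        raise ValueError("target grid does not overlap the source volume")
    coords = idx.T.reshape(3, *target_grid.shape)
    out = np.empty((series.n_echoes, *target_grid.shape))
    for e in range(series.n_echoes):
        out[e] = ndimage.map_coordinates(
            series.signals[e], coords, order=3, mode="constant", cval=0.0
        )
    valid = inside.reshape(target_grid.shape)
    if series.valid is not None:  # propagate invalidity through chained resampling
        src_valid = ndimage.map_coordinates(
            series.valid.astype(np.float32), coords, order=1, mode="constant", cval=0.0
        )
        valid = valid & (src_valid > 0.999)
    out[:, ~valid] = 0.0  # never NaN: it would poison later spline prefilters
    return EchoSeries(
        signals=out, echo_times=series.echo_times, grid=target_grid, valid=valid
    )


def _default_init(signal: np.ndarray, te: np.ndarray):
    """alpha0 = S(first) - S(last), C0 = S(last), T2_0 from the two-point slope."""
    c0 = signal[..., -1]
    a0 = signal[..., 0] - c0
    with np.errstate(divide="ignore", invalid="ignore"):
        num = signal[..., 0] - c0
        den = signal[..., 1] - c0
        ratio = np.where((num > 0) & (den > 0), num / den, np.nan)
        t20 = (te[1] - te[0]) / np.log(ratio)
    t20 = np.where(np.isfinite(t20) & (t20 > 0), t20, 30.0)
    return a0, t20, c0


def fit_t2_voxel(signal, te, init=None):
    """Levenberg-Marquardt fit of S(TE) = alpha exp(-TE/T2) + C at one voxel.

    Returns ``(alpha, t2, c, converged, residual_norm)``.  Degenerate input
    (constant signal, T2 unidentifiable) is reported as non-converged with
    NaN parameters — never silently clamped.
    """
    signal = np.asarray(signal, dtype=float)
    te = np.asarray(te, dtype=float)
    if signal.size < 3 or te.size != signal.size:
        raise ValueError("need >= 3 echoes with matching echo times")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    if np.ptp(signal) == 0:
        return np.nan, np.nan, float(signal[0]), False, 0.0
    if init is None:
        init = _default_init(signal, te)
    p0 = np.asarray(init, dtype=float)

    def resid(p):
        return p[0] * np.exp(-te / p[1]) + p[2] - signal

    def jac(p):
        e = np.exp(-te / p[1])
        return np.column_stack([e, p[0] * te / p[1] ** 2 * e, np.ones_like(te)])

    try:
        sol = optimize.least_squares(resid, p0, jac=jac, method="lm", xtol=1e-14)
    except Exception:
        sol = None
    ok = sol is not None and sol.success and T2_BOUNDS_MS[0] < sol.x[1] <= T2_BOUNDS_MS[1]
    if not ok:  # bounded fallback before declaring failure
        sol = optimize.least_squares(
            resid,
            np.clip(p0, [-np.inf, T2_BOUNDS_MS[0], -np.inf], [np.inf, T2_BOUNDS_MS[1], np.inf]),
            jac=jac,
            method="trf",
            bounds=([-np.inf, T2_BOUNDS_MS[0], -np.inf], [np.inf, T2_BOUNDS_MS[1], np.inf]),
            xtol=1e-14,
        )
        ok = sol.success and T2_BOUNDS_MS[0] < sol.x[1] < T2_BOUNDS_MS[1]
    a, t2, c = sol.x
    return float(a), float(t2), float(c), bool(ok), float(np.linalg.norm(resid(sol.x)))


def fit_t2_batch(signals: np.ndarray, te: np.ndarray, max_iter: int = 80):
    """Vectorized Levenberg-Marquardt over (N, E) signal rows.

    Same model, initialization and bounds policy as :func:`fit_t2_voxel`,
    with per-row damping.  Returns arrays (alpha, t2, c, converged, rnorm).
    """
    sig = np.asarray(signals, dtype=float)
    te = np.asarray(te, dtype=float)
    n = sig.shape[0]
    a, t2, c = _default_init(sig, te)
    a, t2, c = a.astype(float), t2.astype(float), np.asarray(c, dtype=float).copy()
    degenerate = np.ptp(sig, axis=1) == 0
    lam = np.full(n, 1e-3)
    scale = np.maximum(np.ptp(sig, axis=1), 1e-12)

    def cost(a, t2, c):
        r = a[:, None] * np.exp(-te[None, :] / t2[:, None]) + c[:, None] - sig
        return r, np.einsum("ne,ne->n", r, r)

    r, f = cost(a, t2, c)
    active = ~degenerate
    for _ in range(max_iter):
        if not active.any():
            break
        e = np.exp(-te[None, :] / t2[:, None])
        J = np.stack([e, a[:, None] * te[None, :] / t2[:, None] ** 2 * e,
                      np.ones_like(e)], axis=-1)  # (N, E, 3)
        A = np.einsum("nei,nej->nij", J, J)
        g = np.einsum("nei,ne->ni", J, r)
        D = np.maximum(np.einsum("nii->ni", A), 1e-12)  # Marquardt diag scaling
        M = A.copy()
        M[:, [0, 1, 2], [0, 1, 2]] += lam[:, None] * D
        try:
            step = -np.linalg.solve(M, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            M = M + 1e-9 * np.eye(3)[None]
            step = -np.linalg.solve(M, g[..., None])[..., 0]
        a_n = a + np.where(active, step[:, 0], 0.0)
        t2_n = np.clip(t2 + np.where(active, step[:, 1], 0.0), 1e-6, 1e6)
        c_n = c + np.where(active, step[:, 2], 0.0)
        r_n, f_n = cost(a_n, t2_n, c_n)
        better = active & (f_n < f)
        a = np.where(better, a_n, a)
        t2 = np.where(better, t2_n, t2)
        c = np.where(better, c_n, c)
        r = np.where(better[:, None], r_n, r)
        f = np.where(better, f_n, f)
        lam = np.where(better, lam * 0.3, np.where(active, lam * 4.0, lam))
        gnorm = np.linalg.norm(g, axis=1)
        stepnorm = np.linalg.norm(step, axis=1)
        active = active & (gnorm > 1e-12 * scale**2) & (stepnorm > 1e-13) & (lam < 1e10)
    converged = (
        ~degenerate
        & (np.linalg.norm(np.einsum("nei,ne->ni",
            np.stack([np.exp(-te[None, :] / t2[:, None]),
                      a[:, None] * te[None, :] / t2[:, None] ** 2
                      * np.exp(-te[None, :] / t2[:, None]),
                      np.ones((n, te.size))], axis=-1), r), axis=1)
           <= 1e-6 * scale**2 + 1e-10)
        & (t2 > T2_BOUNDS_MS[0]) & (t2 <= T2_BOUNDS_MS[1])
    )
    a = np.where(degenerate, np.nan, a)
    t2 = np.where(degenerate, np.nan, t2)
    rnorm = np.sqrt(f)
    return a, t2, c, converged, rnorm


def t2_map(series: EchoSeries, mask: LabelVolume, tissue) -> T2FitResult:
    """Fit every in-mask voxel of a multi-echo stack.

    Out-of-mask voxels are left undefined (NaN).  The non-converged
    fraction is logged; non-converged voxels keep their flag so downstream
    averages can exclude them.
    """
    if mask.grid != series.grid:
        raise ValueError("mask and echo series are on different grids")
    m = mask.mask(tissue)
    if series.valid is not None:
        m = m & series.valid
    if not m.any():
        raise ValueError(f"mask for tissue {tissue!r} is empty")
    sig = series.signals[:, m].T  # (N, E)
    a, t2, c, conv, rnorm = fit_t2_batch(sig, series.echo_times)
    shape = series.grid.shape

    def full(values, fill=np.nan):
        out = np.full(shape, fill, dtype=float)
        out[m] = values
        return out

    conv_vol = np.zeros(shape, dtype=bool)
    conv_vol[m] = conv
    res = T2FitResult(
        alpha=full(a),
        t2=full(t2),
        offset=full(c),
        converged=conv_vol,
        residual_norm=full(rnorm, 0.0),
        mask=m,
        grid=series.grid,
    )
    log.info(
        "t2_map(%s): %d voxels, %.2f%% non-converged",
        tissue, int(m.sum()), 100 * res.nonconverged_fraction,
    )
    return res
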