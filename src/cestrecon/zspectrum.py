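"""Multi-pool Z-spectrum models, pixel-wise fitting, and MTR-asymmetry analysis.

The Z-spectrum Z(x, ω) describes the attenuation of the water signal as a
function of the RF saturation offset frequency ω (Hz).  The combined
Lorentzian–Gaussian (LG) model uses a Lorentzian line for direct water
saturation at the water resonance ω1 and Gaussian lines for the CEST pools
at their known centers ωi:

    Z(ω) = 1 − a / ((ω − ω1)² + Γ)  −  Σᵢ bᵢ · exp(−(ω − ωi)² / σᵢ²)

with a, Γ in Hz², bᵢ dimensionless and σᵢ in Hz.  The all-Lorentzian (LL)
variant replaces each Gaussian pool term with bᵢ / ((ω − ωi)² + σᵢ), pool
widths then being Hz² like the water term.  Pool terms are *subtracted*
(they are saturation dips); ``pool_sign=+1`` restores an additive sign for
sensitivity checks.

Pool centers ω1 and ωi are assumed known from the experimental setup and
are never fitted.  Fitting is bounded nonlinear least squares over
{a, Γ, bᵢ, σᵢ}, internally parametrized by dip *depths* (a/Γ, and bᵢ/σᵢ for
LL pools) so that all amplitudes share the dimensionless bound [0, 1.5].
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyGrid",
    "Pool",
    "ZSpectrumParams",
    "ZSpectrumSamples",
    "FitDiagnostics",
    "FitComparison",
    "ZParamsMap",
    "eval_zmodel",
    "fit_zspectrum",
    "fit_zspectrum_map",
    "compare_fits",
    "mtr_asymmetry",
    "mtr_asymmetry_map",
]

DIP = -1.0      # pool terms subtracted from 1 (saturation dips); default
PRINTED = +1.0  # literal additive pool sign

#: Fraction of max(s0) below which a pixel counts as background.
BACKGROUND_FRACTION = 0.05


# ---------------------------------------------------------------------------
# Frequency grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FrequencyGrid:
    """Saturation offset-frequency schedule.

    Parameters
    ----------
    offsets
        Offset frequencies in Hz, unique, in acquisition order.
    ref_index
        Index of the unsaturated reference offset ω0.
    water_offset
        Water resonance ω1 in Hz (0 in all cases considered here).
    pool_offsets
        Known CEST pool centers ωi in Hz, i ≥ 2.
    """

    offsets: np.ndarray
    ref_index: int
    water_offset: float = 0.0
    pool_offsets: tuple[float, ...] = ()

    def __post_init__(self):
        offs = np.asarray(self.offsets, dtype=float)
        if offs.ndim != 1 or offs.size < 2:
            raise ValueError("offsets must be a 1-D array with at least 2 entries")
        if np.unique(offs).size != offs.size:
            raise ValueError("offsets must be unique")
        if not (0 <= self.ref_index < offs.size):
            raise ValueError(f"ref_index {self.ref_index} out of range")
        if not (offs.min() < self.water_offset < offs.max()):
            raise ValueError("grid must span both sides of the water offset")
        object.__setattr__(self, "offsets", offs)
        object.__setattr__(self, "pool_offsets", tuple(float(p) for p in self.pool_offsets))

    @property
    def n_offsets(self) -> int:
        return self.offsets.size

    @property
    def ref_offset(self) -> float:
        return float(self.offsets[self.ref_index])

    @property
    def step(self) -> float:
        """Representative grid spacing (median |Δω| of the sorted offsets)."""
        return float(np.median(np.diff(np.sort(self.offsets))))

    @property
    def span(self) -> float:
        return float(self.offsets.max() - self.offsets.min())

    def contains(self, omega: float, tol: float = 1e-6) -> bool:
        return bool(np.any(np.abs(self.offsets - omega) <= tol))

    def index_of(self, omega: float, tol: float = 1e-6) -> int:
        """Index of a grid offset; raises with the nearest offsets if absent."""
        d = np.abs(self.offsets - omega)
        i = int(np.argmin(d))
        if d[i] > tol:
            near = self.offsets[np.argsort(d)[:3]]
            raise KeyError(
                f"offset {omega} Hz not on grid; nearest available: {sorted(near)}"
            )
        return i

    def off_grid_pools(self, tol: float = 1e-6) -> list[float]:
        """Pool centers (or their negations) that do not coincide with a grid offset."""
        flagged = []
        for p in self.pool_offsets:
            if not (self.contains(p, tol) and self.contains(-p, tol)):
                flagged.append(p)
        return flagged

    def subset(self, keep_offsets: Iterable[float]) -> "FrequencyGrid":
        """Restrict to a subset of offsets, preserving order and remapping ref_index."""
        keep = [self.index_of(w) for w in keep_offsets]
        keep = sorted(set(keep))
        if self.ref_index not in keep:
            raise ValueError("subset must retain the reference offset ω0")
        new_ref = keep.index(self.ref_index)
        return FrequencyGrid(self.offsets[keep], new_ref, self.water_offset, self.pool_offsets)


# ---------------------------------------------------------------------------
# Model parameters and evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class Pool:
    """One CEST pool term: center (Hz), amplitude, width (Hz for LG, Hz² for LL)."""

    center: float
    amplitude: float
    width: float


@dataclasses.dataclass(frozen=True)
class ZSpectrumParams:
    """Per-pixel multi-pool Z-spectrum parameters.

    ``water_amplitude`` is the Lorentzian numerator a (Hz²); the water dip
    depth at ω1 is a/Γ.  ``model_kind`` selects LG (Gaussian pools) or LL
    (Lorentzian pools).
    """

    water_amplitude: float
    water_width: float
    pools: tuple[Pool, ...] = ()
    model_kind: str = "LG"
    pool_sign: float = DIP
    water_center: float = 0.0

    def __post_init__(self):
        if self.model_kind not in ("LG", "LL"):
            raise ValueError(f"model_kind must be 'LG' or 'LL', got {self.model_kind!r}")
        if not np.isfinite(self.water_amplitude) or self.water_amplitude < 0:
            raise ValueError("water_amplitude must be finite and >= 0")
        if not self.water_width > 0:
            raise ValueError("water_width must be > 0")
        pools = tuple(p if isinstance(p, Pool) else Pool(*p) for p in self.pools)
        for p in pools:
            if not np.isfinite(p.center):
                raise ValueError("pool centers must be finite")
            if not p.width > 0:
                raise ValueError("pool widths must be > 0")
        object.__setattr__(self, "pools", pools)

    @property
    def centers(self) -> tuple[float, ...]:
        return tuple(p.center for p in self.pools)


@dataclasses.dataclass(frozen=True)
class ZSpectrumSamples:
    """Z-spectrum values sampled on a frequency grid."""

    grid: FrequencyGrid
    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.n_offsets,):
            raise ValueError("values must have one entry per grid offset")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", vals)


def eval_zmodel(params: ZSpectrumParams, omega) -> np.ndarray:
    """Evaluate the multi-pool Z-spectrum model at offset(s) ``omega`` (Hz)."""
    w = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("omega must be finite")
    d2 = (w - params.water_center) ** 2
    z = 1.0 - params.water_amplitude / (d2 + params.water_width)
    for p in params.pools:
        di2 = (w - p.center) ** 2
        if params.model_kind == "LG":
            term = p.amplitude * np.exp(-di2 / p.width**2)
        else:
            term = p.amplitude / (di2 + p.width)
        z = z + params.pool_sign * term
    return z


# ---------------------------------------------------------------------------
# Fit parametrization: x = [depth_w, Γ, depth_1..depth_P, width_1..width_P]
# All depths dimensionless in [0, 1.5]; widths Hz (LG) / Hz² (LL).
# ---------------------------------------------------------------------------

def _fit_bounds(grid_step: float, grid_span: float, npool: int, model_kind: str):
    gam_min = max(1e-8, (0.05 * grid_step) ** 2)
    if model_kind == "LG":
        w_min, w_max = max(1e-8, 0.05 * grid_step), grid_span
    else:
        w_min, w_max = max(1e-8, (0.05 * grid_step) ** 2), grid_span**2
    lb = np.array([0.0, gam_min] + [0.0] * npool + [w_min] * npool)
    ub = np.array([1.5, grid_span**2] + [1.5] * npool + [w_max] * npool)
    return lb, ub


def _pack(params: ZSpectrumParams) -> np.ndarray:
    depths = []
    widths = []
    for p in params.pools:
        if params.model_kind == "LG":
            depths.append(p.amplitude)
        else:
            depths.append(p.amplitude / p.width)
        widths.append(p.width)
    dw = params.water_amplitude / params.water_width
    return np.array([dw, params.water_width] + depths + widths, dtype=float)


def _unpack(x: np.ndarray, centers: Sequence[float], model_kind: str,
            pool_sign: float, water_center: float) -> ZSpectrumParams:
    npool = len(centers)
    dw, gam = x[0], x[1]
    pools = []
    for i in range(npool):
        d, w = x[2 + i], x[2 + npool + i]
        amp = d if model_kind == "LG" else d * w
        pools.append(Pool(float(centers[i]), float(amp), float(w)))
    return ZSpectrumParams(float(dw * gam), float(gam), tuple(pools),
                           model_kind, pool_sign, water_center)


def _zmodel_batched(X: np.ndarray, omega: np.ndarray, centers: Sequence[float],
                    model_kind: str, pool_sign: float, water_center: float,
                    with_jac: bool = True):
    """Vectorized model (and Jacobian) for a batch of parameter vectors.

    X: (M, P) parameter vectors; omega: (N,) offsets.
    Returns Z (M, N) and, if requested, J (M, N, P).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M, P = X.shape
    npool = len(centers)
    om = np.asarray(omega, dtype=float)
    N = om.size
    dw = X[:, 0:1]
    gam = X[:, 1:2]
    d2w = ((om - water_center) ** 2)[None, :]
    den = d2w + gam
    Z = 1.0 - dw * gam / den
    J = np.empty((M, N, P)) if with_jac else None
    if with_jac:
        J[:, :, 0] = -gam / den
        J[:, :, 1] = -dw * d2w / den**2
    for i in range(npool):
        di2 = ((om - centers[i]) ** 2)[None, :]
        d = X[:, 2 + i : 3 + i]
        w = X[:, 2 + npool + i : 3 + npool + i]
        if model_kind == "LG":
            g = np.exp(-di2 / w**2)
            Z += pool_sign * d * g
            if with_jac:
                J[:, :, 2 + i] = pool_sign * g
                J[:, :, 2 + npool + i] = pool_sign * d * g * (2.0 * di2 / w**3)
        else:
            denp = di2 + w
            g = w / denp
            Z += pool_sign * d * g
            if with_jac:
                J[:, :, 2 + i] = pool_sign * g
                J[:, :, 2 + npool + i] = pool_sign * d * di2 / denp**2
    return (Z, J) if with_jac else Z


def _default_init(omega: np.ndarray, values: np.ndarray, centers: Sequence[float],
                  model_kind: str, step: float, water_center: float) -> np.ndarray:
    """Heuristic starting point: water depth from the minimum near ω1, pool
    depths from the residual dip at each center, widths a few grid steps."""
    near = np.abs(omega - water_center) <= 3.0 * step + 1e-9
    if not near.any():
        near = np.abs(omega - water_center) <= np.min(np.abs(omega - water_center)) + 1e-9
    dw0 = float(np.clip(1.0 - values[near].min(), 1e-3, 1.45))
    gam0 = (10.0 * step) ** 2
    depths, widths = [], []
    for c in centers:
        i = int(np.argmin(np.abs(omega - c)))
        water_only = 1.0 - dw0 * gam0 / ((omega[i] - water_center) ** 2 + gam0)
        depths.append(float(np.clip(water_only - values[i], 0.01, 1.4)))
        widths.append(3.0 * step if model_kind == "LG" else (3.0 * step) ** 2)
    return np.array([dw0, gam0] + depths + widths, dtype=float)


@dataclasses.dataclass(frozen=True)
class FitDiagnostics:
    residual_norm: float
    mae: float
    success: bool
    degenerate: bool = False
    nfev: int = 0


def fit_zspectrum(samples: ZSpectrumSamples, centers: Sequence[float],
                  model_kind: str = "LG", init: ZSpectrumParams | None = None,
                  pool_sign: float = DIP) -> tuple[ZSpectrumParams, FitDiagnostics]:
    """Bounded nonlinear least-squares fit of the multi-pool model.

    Pool centers are fixed (known from the experimental setup).  Every sample
    handed in participates in the residual.  Deterministic given ``init``.
    """
    omega = samples.grid.offsets
    y = samples.values
    npool = len(centers)
    if y.size < 2 + 2 * npool:
        raise ValueError(
            f"need at least {2 + 2 * npool} samples to fit {npool} pool(s), got {y.size}"
        )
    step, span = samples.grid.step, samples.grid.span
    wc = samples.grid.water_offset
    lb, ub = _fit_bounds(step, span, npool, model_kind)

    if np.ptp(y) < 1e-12:
        # Flat spectrum: amplitudes at their lower bound, nothing to fit.
        x = np.array([0.0, (10.0 * step) ** 2] + [0.0] * npool
                     + [3.0 * step if model_kind == "LG" else (3.0 * step) ** 2] * npool)
        params = _unpack(x, centers, model_kind, pool_sign, wc)
        resid = eval_zmodel(params, omega) - y
        return params, FitDiagnostics(float(np.linalg.norm(resid)),
                                      float(np.abs(resid).mean()), True, degenerate=True)

    if init is not None:
        x0 = np.clip(_pack(init), lb, ub)
    else:
        x0 = np.clip(_default_init(omega, y, centers, model_kind, step, wc), lb, ub)

    def fun(x):
        z = _zmodel_batched(x[None, :], omega, centers, model_kind, pool_sign, wc,
                            with_jac=False)
        return z[0] - y

    def jac(x):
        _, J = _zmodel_batched(x[None, :], omega, centers, model_kind, pool_sign, wc)
        return J[0]

    res = least_squares(fun, x0, jac=jac, bounds=(lb, ub), method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, x_scale="jac",
                        max_nfev=2000)
    params = _unpack(res.x, centers, model_kind, pool_sign, wc)
    resid = res.fun
    return params, FitDiagnostics(float(np.linalg.norm(resid)),
                                  float(np.abs(resid).mean()),
                                  bool(res.success), nfev=int(res.nfev))


# ---------------------------------------------------------------------------
# Batched pixel-map fitting (vectorized Levenberg–Marquardt)
# ---------------------------------------------------------------------------

def _batched_lm(x0, target, omega, centers, model_kind, pool_sign, water_center,
                lb, ub, max_iter=60, ftol=1e-14, step_cap=1.0):
    """Levenberg–Marquardt over a batch of independent pixels.

    x0: (M, P) starting points; target: (M, N) spectra.  The positive scale
    parameters (Γ and the pool widths, orders of magnitude larger than the
    dimensionless depths) are optimized in log space, which both normalizes
    the Jacobian columns and keeps them positive without projection traps at
    the lower bound; steps are capped at ``step_cap`` per component (log
    units for the scale parameters) and clipped to the bounds.
    """
    P = np.shape(x0)[1]
    npool = len(centers)
    log_idx = np.zeros(P, dtype=bool)
    log_idx[1] = True
    log_idx[2 + npool:] = True

    def to_q(xa):
        q = np.array(xa, dtype=float)
        q[:, log_idx] = np.log(np.maximum(q[:, log_idx], 1e-300))
        return q

    def to_x(qa):
        xa = np.array(qa, dtype=float)
        xa[:, log_idx] = np.exp(xa[:, log_idx])
        return xa

    qlb, qub = to_q(lb[None, :])[0], to_q(ub[None, :])[0]
    q = np.clip(to_q(x0), qlb, qub)
    M = q.shape[0]

    def cost_of(qc, tgt, with_jac=True):
        xc = to_x(qc)
        out = _zmodel_batched(xc, omega, centers, model_kind, pool_sign,
                              water_center, with_jac=with_jac)
        if with_jac:
            Z, J = out
            J = J.copy()
            J[:, :, log_idx] *= xc[:, None, log_idx]  # chain rule d/d(log p)
            r = Z - tgt
            return r, J, 0.5 * np.einsum("mn,mn->m", r, r)
        r = out - tgt
        return 0.5 * np.einsum("mn,mn->m", r, r)

    r, J, cost = cost_of(q, target)
    mu = np.full(M, 1e-3)
    identity = np.eye(P)[None]
    for _ in range(max_iter):
        JTJ = np.einsum("mnp,mnq->mpq", J, J)
        g = np.einsum("mnp,mn->mp", J, r)
        diag = np.einsum("mpp->mp", JTJ)
        damp = _diag_embed(diag) + 1e-10 * identity
        A = JTJ + mu[:, None, None] * damp
        try:
            dq = -np.linalg.solve(A, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            dq = -np.linalg.solve(A + 1e-8 * identity, g[..., None])[..., 0]
        np.clip(dq, -step_cap, step_cap, out=dq)
        q_try = np.clip(q + dq, qlb, qub)
        cost_try = cost_of(q_try, target, with_jac=False)
        improved = cost_try < cost
        if improved.any():
            r_new, J_new, _ = cost_of(q_try[improved], target[improved])
            q[improved] = q_try[improved]
            r[improved] = r_new
            J[improved] = J_new
        rel_drop = np.where(improved, (cost - cost_try) / np.maximum(cost, 1e-300), 1.0)
        cost = np.where(improved, cost_try, cost)
        mu = np.where(improved, mu * 0.3, mu * 4.0)
        np.clip(mu, 1e-12, 1e12, out=mu)
        if np.all((improved & (rel_drop < ftol)) | (~improved & (mu >= 1e12))):
            break
    return to_x(q), cost


def _diag_embed(d):
    M, P = d.shape
    out = np.zeros((M, P, P))
    idx = np.arange(P)
    out[:, idx, idx] = d
    return out


@dataclasses.dataclass
class ZParamsMap:
    """Fitted Z-spectrum parameter maps over an image.

    Arrays are 2-D (a, gamma) or (npool, ny, nx) (pool amplitude/width).
    Unmasked (background) pixels carry zero amplitudes, i.e. Z ≡ 1.
    """

    a: np.ndarray
    gamma: np.ndarray
    pool_amplitude: np.ndarray
    pool_width: np.ndarray
    centers: tuple[float, ...]
    model_kind: str
    pool_sign: float
    water_center: float
    mask: np.ndarray

    def params_at(self, iy: int, ix: int) -> ZSpectrumParams:
        pools = tuple(
            Pool(self.centers[i], float(self.pool_amplitude[i, iy, ix]),
                 float(self.pool_width[i, iy, ix]))
            for i in range(len(self.centers))
        )
        return ZSpectrumParams(float(self.a[iy, ix]), float(self.gamma[iy, ix]),
                               pools, self.model_kind, self.pool_sign, self.water_center)

    def evaluate(self, grid: FrequencyGrid, ref_is_unity: bool = True) -> np.ndarray:
        """Model spectra on a grid, shape (n_offsets, ny, nx).

        With ``ref_is_unity`` the sample at the unsaturated reference offset
        is exactly 1 by definition (no saturation applied there).
        """
        ny, nx = self.a.shape
        npool = len(self.centers)
        X = np.empty((ny * nx, 2 + 2 * npool))
        depth_w = np.where(self.gamma > 0, self.a / np.maximum(self.gamma, 1e-300), 0.0)
        X[:, 0] = depth_w.ravel()
        X[:, 1] = np.maximum(self.gamma, 1e-8).ravel()
        for i in range(npool):
            amp = self.pool_amplitude[i]
            w = np.maximum(self.pool_width[i], 1e-8)
            X[:, 2 + i] = (amp if self.model_kind == "LG" else amp / w).ravel()
            X[:, 2 + npool + i] = w.ravel()
        Z = _zmodel_batched(X, grid.offsets, self.centers, self.model_kind,
                            self.pool_sign, self.water_center, with_jac=False)
        out = Z.reshape(ny, nx, grid.n_offsets).transpose(2, 0, 1)
        if ref_is_unity:
            out[grid.ref_index] = 1.0
        return out


def fit_zspectrum_map(values: np.ndarray, grid: FrequencyGrid,
                      centers: Sequence[float], model_kind: str = "LG",
                      mask: np.ndarray | None = None,
                      init: ZParamsMap | None = None,
                      pool_sign: float = DIP,
                      exclude_ref: bool = True,
                      max_iter: int = 60) -> tuple[ZParamsMap, dict]:
    """Fit the multi-pool model at every masked pixel of a spectrum stack.

    ``values`` has shape (n_offsets, ny, nx).  The unsaturated reference
    sample is excluded from the residual by default (it is 1 by definition
    and carries no saturation information).  Unmasked pixels get zero
    amplitudes (flat spectrum).
    """
    nw, ny, nx = values.shape
    if nw != grid.n_offsets:
        raise ValueError("values first axis must match the grid")
    npool = len(centers)
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    sel = np.ones(nw, dtype=bool)
    if exclude_ref:
        sel[grid.ref_index] = False
    omega = grid.offsets[sel]
    step, span = grid.step, grid.span
    wc = grid.water_offset
    lb, ub = _fit_bounds(step, span, npool, model_kind)

    flat = values[sel][:, mask].T  # (M, N)
    M = flat.shape[0]
    if init is not None:
        npix_params = 2 + 2 * npool
        X0 = np.empty((M, npix_params))
        X0[:, 0] = np.where(init.gamma[mask] > 0,
                            init.a[mask] / np.maximum(init.gamma[mask], 1e-300), 0.0)
        X0[:, 1] = init.gamma[mask]
        for i in range(npool):
            amp = init.pool_amplitude[i][mask]
            w = init.pool_width[i][mask]
            X0[:, 2 + i] = amp if model_kind == "LG" else amp / np.maximum(w, 1e-300)
            X0[:, 2 + npool + i] = w
    else:
        X0 = np.empty((M, 2 + 2 * npool))
        for m in range(M):
            X0[m] = _default_init(omega, flat[m], centers, model_kind, step, wc)
    X, cost = _batched_lm(X0, flat, omega, centers, model_kind, pool_sign, wc,
                          lb, ub, max_iter=max_iter)

    a = np.zeros((ny, nx))
    gamma = np.full((ny, nx), (10.0 * step) ** 2)
    pamp = np.zeros((npool, ny, nx))
    pwid = np.full((npool, ny, nx),
                   3.0 * step if model_kind == "LG" else (3.0 * step) ** 2)
    a[mask] = X[:, 0] * X[:, 1]
    gamma[mask] = X[:, 1]
    for i in range(npool):
        d, w = X[:, 2 + i], X[:, 2 + npool + i]
        pamp[i][mask] = d if model_kind == "LG" else d * w
        pwid[i][mask] = w
    zmap = ZParamsMap(a, gamma, pamp, pwid, tuple(float(c) for c in centers),
                      model_kind, pool_sign, wc, mask.copy())
    diag = {"n_pixels": int(M), "mean_cost": float(cost.mean()) if M else 0.0,
            "max_cost": float(cost.max()) if M else 0.0}
    return zmap, diag


# ---------------------------------------------------------------------------
# LG-vs-LL comparison
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FitComparison:
    mae_lg: float
    mae_ll: float
    reduction_pct: float
    params_lg: ZSpectrumParams
    params_ll: ZSpectrumParams


def compare_fits(samples: ZSpectrumSamples, centers: Sequence[float],
                 reference: ZSpectrumSamples, pool_sign: float = DIP) -> FitComparison:
    """Fit both LG and LL models to ``samples`` and report each prediction's
    mean absolute error against ``reference`` plus the relative reduction of
    the LG error over the LL error."""
    if samples.grid.n_offsets != reference.grid.n_offsets or \
            not np.allclose(samples.grid.offsets, reference.grid.offsets):
        raise ValueError("samples and reference must share the same grid")
    out = {}
    for kind in ("LG", "LL"):
        params, _ = fit_zspectrum(samples, centers, kind, pool_sign=pool_sign)
        pred = eval_zmodel(params, samples.grid.offsets)
        out[kind] = (params, float(np.abs(pred - reference.values).mean()))
    mae_lg, mae_ll = out["LG"][1], out["LL"][1]
    red = 100.0 * (1.0 - mae_lg / mae_ll) if mae_ll > 0 else 0.0
    return FitComparison(mae_lg, mae_ll, red, out["LG"][0], out["LL"][0])


# ---------------------------------------------------------------------------
# MTR asymmetry
# ---------------------------------------------------------------------------

def mtr_asymmetry(s_minus, s_plus, s0):
    """MTRasym(ω) = [Ssat(−ω) − Ssat(ω)] / S0.

    Pixels with non-positive S0 propagate as NaN (masked), not as an error.
    """
    s_minus = np.asarray(s_minus, dtype=float)
    s_plus = np.asarray(s_plus, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s0 > 0, (s_minus - s_plus) / np.where(s0 > 0, s0, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def mtr_asymmetry_map(images, omega: float,
                      mask_threshold: float = BACKGROUND_FRACTION) -> np.ndarray:
    """Pixel-wise MTR asymmetry at ±``omega`` from an image series.

    ``images`` must expose ``data`` (n_offsets, ny, nx) and ``grid``.
    Background pixels (reference signal below ``mask_threshold`` of its
    maximum) are NaN.
    """
    grid = images.grid
    ip = grid.index_of(omega)
    im = grid.index_of(-omega)
    s0 = images.data[grid.ref_index]
    out = mtr_asymmetry(images.data[im], images.data[ip], s0)
    smax = s0.max()
    if smax <= 0:
        return np.full(s0.shape, np.nan)
    out = np.asarray(out)
    out[s0 < mask_threshold * smax] = np.nan
    return out
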