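"""Conventional FFT + pixel-fit reconstruction and joint k-ω ADMM
reconstruction with CGLS image updates, Z-spectrum-constrained fitting,
plug-and-play spatial denoising, a closed-form auxiliary update, and dual
ascent.

The joint model reconstructs amplitude images f(x, ω) at all saturation
offsets simultaneously:

    min_{f,A,Z}  ½ Σ_ω |F A(x,ω) f(x,ω) − g(ω)|² + R[f, λ]
    s.t.         f(x,ω) = f(x,ω0) · Z(x,ω),

with Z constrained to the multi-pool spectral model.  Splitting variables
v (denoised image copy) and T (spectrum copy) turn this into an augmented
Lagrangian solved by ADMM: quadratic CGLS solves for f(·, ω≠ω0) and
f(·, ω0) (the latter couples all offsets), pixel-wise model fitting for Z,
a plug-and-play denoiser for v, a closed-form update for T, and gradient
ascent on the duals y, z, t.  The phase factor A is re-estimated by folding
the phase of each complex f-solve back into A and keeping the magnitude,
so f ≥ 0 by construction.

Updates use freshest available values (Gauss–Seidel ordering); the phase is
re-estimated once per outer iteration by default.  The stopping rule is that
the mean relative changes of f and of the Z-spectrum samples between outer
iterations both fall below ε.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_nl_means, denoise_tv_chambolle, denoise_wavelet

from .phantom import ImageSeries, KSpaceSeries, PhaseSeries, cfft2, icfft2
from .zspectrum import (
    BACKGROUND_FRACTION,
    DIP,
    FrequencyGrid,
    ZParamsMap,
    fit_zspectrum_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReconConfig",
    "ADMMState",
    "ReconResult",
    "fft_recon",
    "conventional_reconstruct",
    "joint_reconstruct",
    "cgls_solve",
    "update_f",
    "update_f0",
    "update_Z",
    "update_T",
    "update_duals",
    "denoise_v",
    "estimate_lambda",
    "register_denoiser",
    "get_denoiser",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReconConfig:
    """Tunables of the joint reconstruction.

    ``rho`` is the ADMM penalty (affects convergence rate, not the fixed
    point); ``epsilon`` the stopping threshold on the mean relative change
    of f and of the Z samples.  ``lambda_scale`` times the mode of the
    5×5-patch local variance histogram gives the denoiser's noise-variance
    parameter λ — a deliberately conservative estimate to avoid
    over-smoothing.  ``dual_y_form`` selects whether the y-update residual
    uses Z (default) or the splitting variable T; ``pool_sign`` the spectral
    dip sign convention.
    """

    rho: float = 0.5
    epsilon: float = 1e-3
    max_outer_iters: int = 100
    cgls_max_iters: int = 50
    cgls_tol: float = 1e-6
    patch_size: int = 5
    lambda_scale: float = 0.5
    lambda_bins: int = 64
    denoiser: str = "nlm"
    dual_y_form: str = "Z"            # "Z" or "T"
    phase_update: str = "outer"       # "outer" or "never"
    mask_threshold: float = BACKGROUND_FRACTION
    pool_sign: float = DIP
    fit_max_iter: int = 60
    fit_warm_max_iter: int = 15

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError("patch_size must be odd and >= 3")
        if not (0 < self.lambda_scale <= 1):
            raise ValueError("lambda_scale must be in (0, 1]")
        if self.dual_y_form not in ("Z", "T"):
            raise ValueError("dual_y_form must be 'Z' or 'T'")


@dataclasses.dataclass
class ADMMState:
    """All primal and dual variables of the ADMM iteration.

    Arrays are (n_offsets, ny, nx); ``f`` real amplitudes, ``phase`` the
    angle of the unit-modulus factor A, ``v`` the denoised copy, ``T`` the
    auxiliary spectrum samples, ``Zs`` the fitted model samples (exactly 1
    at the reference offset), ``zmap`` the fitted parameter maps, and
    ``y``, ``z``, ``t`` the scaled duals of the three constraints.
    """

    f: np.ndarray
    phase: np.ndarray
    v: np.ndarray
    T: np.ndarray
    Zs: np.ndarray
    zmap: ZParamsMap
    y: np.ndarray
    z: np.ndarray
    t: np.ndarray
    grid: FrequencyGrid
    mask: np.ndarray
    rho: float
    k: int = 0

    @property
    def f0(self) -> np.ndarray:
        return self.f[self.grid.ref_index]

    @property
    def A(self) -> np.ndarray:
        return np.exp(1j * self.phase)


@dataclasses.dataclass
class ReconResult:
    images: ImageSeries
    phase: PhaseSeries
    zparams: ZParamsMap
    history: list[dict]
    converged: bool
    method: str = "joint"


# ---------------------------------------------------------------------------
# Denoiser registry — contract: (2-D image, noise variance λ) → 2-D image,
# pure and deterministic; λ ≤ 0 means "leave the image unchanged".
# ---------------------------------------------------------------------------

_DENOISERS: dict[str, Callable[[np.ndarray, float], np.ndarray]] = {}


def register_denoiser(name: str, fn: Callable[[np.ndarray, float], np.ndarray]) -> None:
    _DENOISERS[name] = fn


def get_denoiser(name: str) -> Callable[[np.ndarray, float], np.ndarray]:
    try:
        return _DENOISERS[name]
    except KeyError:
        raise KeyError(f"unknown denoiser {name!r}; registered: {sorted(_DENOISERS)}")


def _dn_nlm(image, lam):
    if lam <= 0:
        return image
    sigma = float(np.sqrt(lam))
    return denoise_nl_means(image, h=0.8 * sigma, sigma=sigma, patch_size=5,
                            patch_distance=6, fast_mode=True)


def _dn_wavelet(image, lam):
    if lam <= 0:
        return image
    return denoise_wavelet(image, sigma=float(np.sqrt(lam)), rescale_sigma=True)


def _dn_tv(image, lam):
    if lam <= 0:
        return image
    return denoise_tv_chambolle(image, weight=float(np.sqrt(lam)))


def _dn_gaussian(image, lam):
    if lam <= 0:
        return image
    return ndimage.gaussian_filter(image, sigma=1.0)


register_denoiser("nlm", _dn_nlm)
register_denoiser("wavelet", _dn_wavelet)
register_denoiser("tv", _dn_tv)
register_denoiser("gaussian", _dn_gaussian)
register_denoiser("identity", lambda image, lam: image)


def estimate_lambda(image: np.ndarray, patch_size: int = 5,
                    lambda_scale: float = 0.5, bins: int = 64) -> float:
    """Noise-variance parameter λ: ``lambda_scale`` times the histogram mode
    of the local variances of all dense patch_size×patch_size patches."""
    image = np.asarray(image, dtype=float)
    if min(image.shape) <= patch_size:
        raise ValueError("image must be larger than the patch")
    m = ndimage.uniform_filter(image, patch_size)
    m2 = ndimage.uniform_filter(image * image, patch_size)
    h = patch_size // 2
    var = np.clip(m2 - m * m, 0.0, None)[h:-h, h:-h]  # valid patches only
    vmin, vmax = float(var.min()), float(var.max())
    if vmax - vmin < 1e-300:
        return lambda_scale * vmin
    counts, edges = np.histogram(var.ravel(), bins=bins, range=(vmin, vmax))
    i = int(np.argmax(counts))
    mode = 0.5 * (edges[i] + edges[i + 1])
    return float(lambda_scale * mode)


# ---------------------------------------------------------------------------
# CGLS
# ---------------------------------------------------------------------------

def _tdot(a, b) -> float:
    return float(sum(np.vdot(ai, bi).real for ai, bi in zip(a, b)))


def _taxpy(alpha, x, y):
    return tuple(yi + alpha * xi for xi, yi in zip(x, y))


def cgls_solve(forward, adjoint, rhs, init, tol: float = 1e-6,
               max_iters: int = 50) -> tuple[np.ndarray, dict]:
    """Conjugate gradients on the least-squares normal equations.

    ``forward(x)`` returns a tuple of stacked residual blocks, ``adjoint``
    maps such a tuple back to the solution space; they must form an adjoint
    pair.  Stops when the normal-equation residual drops below ``tol``
    relative to its initial value, or immediately if the init is already a
    least-squares solution.
    """
    x = init
    r = tuple(bi - fi for bi, fi in zip(rhs, forward(x)))
    s = adjoint(r)
    gamma = float(np.vdot(s, s).real)
    gamma0 = gamma
    info = {"iters": 0, "relres": 0.0}
    if gamma0 == 0.0:
        return x, info
    p = s
    for it in range(1, max_iters + 1):
        q = forward(p)
        qq = _tdot(q, q)
        if qq == 0.0:
            break
        alpha = gamma / qq
        x = x + alpha * p
        r = _taxpy(-alpha, q, r)
        s = adjoint(r)
        gamma_new = float(np.vdot(s, s).real)
        info["iters"] = it
        info["relres"] = float(np.sqrt(gamma_new / gamma0))
        if info["relres"] <= tol:
            break
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    if info["relres"] > tol and info["iters"] == max_iters:
        logger.warning("CGLS hit iteration cap (relres=%.3g)", info["relres"])
    return x, info


# ---------------------------------------------------------------------------
# Conventional reconstruction
# ---------------------------------------------------------------------------

def fft_recon(ks: KSpaceSeries) -> tuple[ImageSeries, PhaseSeries]:
    """Per-offset inverse DFT; magnitude and phase of the complex images."""
    img = icfft2(ks.data)
    return ImageSeries(np.abs(img), ks.grid), PhaseSeries(np.angle(img), ks.grid)


def conventional_reconstruct(ks: KSpaceSeries, centers: Sequence[float],
                             model_kind: str = "LG",
                             cfg: ReconConfig | None = None) -> ReconResult:
    """The two-step baseline: FFT reconstruction per offset, then pixel-wise
    Z-spectrum fitting of f(x, ω)/f(x, ω0) on non-background pixels."""
    cfg = cfg or ReconConfig()
    images, phase = fft_recon(ks)
    s0 = images.data[ks.grid.ref_index]
    smax = s0.max()
    mask = s0 > cfg.mask_threshold * smax if smax > 0 else np.zeros(s0.shape, bool)
    safe_s0 = np.where(s0 > 0, s0, 1.0)
    zvals = images.data / safe_s0[None]
    zmap, _ = fit_zspectrum_map(zvals, ks.grid, centers, model_kind, mask=mask,
                                pool_sign=cfg.pool_sign, max_iter=cfg.fit_max_iter)
    return ReconResult(images, phase, zmap, [], True, method="conventional")


# ---------------------------------------------------------------------------
# ADMM sub-problem updates
# ---------------------------------------------------------------------------

def _factor_phase(fc: np.ndarray, prev_phase: np.ndarray, enabled: bool):
    """Split a complex solve into magnitude and phase; where the magnitude is
    (numerically) zero the previous phase is retained."""
    mag = np.abs(fc)
    if not enabled:
        return np.real(fc).clip(min=0.0), prev_phase
    tiny = 1e-12 * (mag.max() + 1e-300)
    ang = np.angle(fc)
    new_phase = np.where(mag > tiny, prev_phase + ang, prev_phase)
    return mag, new_phase


def update_f(state: ADMMState, ks: KSpaceSeries, cfg: ReconConfig,
             refresh_phase: bool = True) -> None:
    """CGLS solve of the quadratic sub-problem for f(·, ω) at every ω ≠ ω0:
    data fidelity at ω plus penalties tying f to f0·T and to v."""
    grid = state.grid
    sel = np.arange(grid.n_offsets) != grid.ref_index
    A = state.A[sel]
    g = ks.data[sel]
    rho = state.rho
    sr = np.sqrt(rho)
    b2 = state.f0[None] * state.T[sel] - state.y[sel] / rho
    b3 = state.v[sel] + state.z[sel] / rho

    def forward(x):
        return (cfft2(A * x), sr * x, sr * x)

    def adjoint(r):
        return np.conj(A) * icfft2(r[0]) + sr * (r[1] + r[2])

    rhs = (g, sr * b2.astype(complex), sr * b3.astype(complex))
    x0 = state.f[sel].astype(complex)
    xc, _ = cgls_solve(forward, adjoint, rhs, x0, cfg.cgls_tol, cfg.cgls_max_iters)
    mag, new_phase = _factor_phase(xc, state.phase[sel], refresh_phase)
    state.f[sel] = mag
    state.phase[sel] = new_phase


def update_f0(state: ADMMState, ks: KSpaceSeries, cfg: ReconConfig,
              refresh_phase: bool = True) -> None:
    """CGLS solve for the reference image f(·, ω0), coupling its own data
    fidelity with the T-penalties of all other offsets — the step through
    which information from every frequency flows into the reference."""
    grid = state.grid
    ref = grid.ref_index
    sel = np.arange(grid.n_offsets) != ref
    A0 = state.A[ref]
    g0 = ks.data[ref]
    rho = state.rho
    sr = np.sqrt(rho)
    Tsel = state.T[sel]
    b_t = state.f[sel] + state.y[sel] / rho      # targets of the T rows
    b_v = state.v[ref] + state.z[ref] / rho

    def forward(x):
        return (cfft2(A0 * x), sr * (Tsel * x[None]), sr * x)

    def adjoint(r):
        return (np.conj(A0) * icfft2(r[0])
                + sr * np.sum(Tsel * r[1], axis=0) + sr * r[2])

    rhs = (g0, sr * b_t.astype(complex), sr * b_v.astype(complex))
    x0 = state.f[ref].astype(complex)
    xc, _ = cgls_solve(forward, adjoint, rhs, x0, cfg.cgls_tol, cfg.cgls_max_iters)
    mag, new_phase = _factor_phase(xc, state.phase[ref], refresh_phase)
    state.f[ref] = mag
    state.phase[ref] = new_phase


def update_Z(state: ADMMState, centers: Sequence[float], model_kind: str,
             cfg: ReconConfig) -> None:
    """Spectral-model projection: per pixel, fit the multi-pool model to the
    target samples T + t/ρ (the unconstrained minimizer of the Z
    sub-problem) and evaluate the fit on the grid."""
    target = state.T + state.t / state.rho
    zmap, diag = fit_zspectrum_map(target, state.grid, centers, model_kind,
                                   mask=state.mask, init=state.zmap,
                                   pool_sign=cfg.pool_sign,
                                   max_iter=cfg.fit_warm_max_iter)
    state.zmap = zmap
    state.Zs = zmap.evaluate(state.grid, ref_is_unity=True)


def denoise_v(state: ADMMState, cfg: ReconConfig) -> None:
    """Plug-and-play step: per offset, v = Denoiser(f − z/ρ, λ) with λ
    estimated from that offset's input image."""
    dn = get_denoiser(cfg.denoiser)
    inp = state.f - state.z / state.rho
    for i in range(state.grid.n_offsets):
        lam = estimate_lambda(inp[i], cfg.patch_size, cfg.lambda_scale, cfg.lambda_bins)
        state.v[i] = dn(inp[i], lam)


def update_T(state: ADMMState) -> None:
    """Closed-form minimizer of the T sub-problem:
    T = (ρZ − t + f0·y + ρ·f·f0) / (ρ·f0² + ρ)."""
    rho = state.rho
    f0 = state.f0[None]
    state.T = (rho * state.Zs - state.t + f0 * state.y + rho * state.f * f0) \
        / (rho * f0**2 + rho)


def update_duals(state: ADMMState, cfg: ReconConfig) -> None:
    """Dual ascent: y += ρ(f − f0·Z) (or T per config), z += ρ(v − f),
    t += ρ(T − Z)."""
    spec = state.Zs if cfg.dual_y_form == "Z" else state.T
    state.y = state.y + state.rho * (state.f - state.f0[None] * spec)
    state.z = state.z + state.rho * (state.v - state.f)
    state.t = state.t + state.rho * (state.T - state.Zs)


# ---------------------------------------------------------------------------
# Joint reconstruction driver
# ---------------------------------------------------------------------------

def _fidelity_residual(state: ADMMState, ks: KSpaceSeries) -> float:
    return float(np.linalg.norm(cfft2(state.A * state.f) - ks.data))


def joint_reconstruct(ks: KSpaceSeries, centers: Sequence[float],
                      model_kind: str = "LG",
                      cfg: ReconConfig | None = None) -> ReconResult:
    """Joint k-ω ADMM reconstruction.

    Warm-starts from the conventional reconstruction (f, A from the FFT; Z
    from its pixel-wise fit; v = f, T = Z samples, duals zero), then cycles
    f-updates, Z-fitting, plug-and-play denoising, the closed-form T update
    and dual ascent until the mean relative changes of f and of the Z
    samples both fall below ε.  Aborts with a diagnostic if the data
    fidelity residual grows tenfold over five iterations.
    """
    cfg = cfg or ReconConfig()
    grid = ks.grid
    conv = conventional_reconstruct(ks, centers, model_kind, cfg)
    f = conv.images.data.copy()
    phase = conv.phase.phase.copy()
    mask = conv.zparams.mask
    Zs = conv.zparams.evaluate(grid, ref_is_unity=True)
    state = ADMMState(f=f, phase=phase, v=f.copy(), T=Zs.copy(), Zs=Zs,
                      zmap=conv.zparams, y=np.zeros_like(f), z=np.zeros_like(f),
                      t=np.zeros_like(f), grid=grid, mask=mask, rho=cfg.rho)
    history: list[dict] = []
    converged = False
    refresh = cfg.phase_update == "outer"
    for k in range(1, cfg.max_outer_iters + 1):
        f_old = state.f.copy()
        Z_old = state.Zs.copy()
        update_f(state, ks, cfg, refresh_phase=refresh)
        update_f0(state, ks, cfg, refresh_phase=refresh)
        update_Z(state, centers, model_kind, cfg)
        denoise_v(state, cfg)
        update_T(state)
        update_duals(state, cfg)
        state.k = k
        rel_f = float(np.abs(state.f - f_old).mean() / max(np.abs(f_old).mean(), 1e-300))
        rel_Z = float(np.abs(state.Zs - Z_old).mean() / max(np.abs(Z_old).mean(), 1e-300))
        fid = _fidelity_residual(state, ks)
        cviol = float(np.abs(state.f - state.f0[None] * state.Zs).mean())
        entry = {"iter": k, "rel_change_f": rel_f, "rel_change_Z": rel_Z,
                 "fidelity_residual": fid, "constraint_violation": cviol}
        history.append(entry)
        logger.info("joint iter %d: Δf=%.3e ΔZ=%.3e fid=%.3e cviol=%.3e",
                    k, rel_f, rel_Z, fid, cviol)
        if len(history) > 5 and fid > 10.0 * min(h["fidelity_residual"] for h in history[-6:-1]):
            entry["diverged"] = True
            logger.warning("joint reconstruction aborted: fidelity residual grew 10x")
            break
        if rel_f < cfg.epsilon and rel_Z < cfg.epsilon:
            converged = True
            break
    return ReconResult(ImageSeries(state.f, grid), PhaseSeries(state.phase, grid),
                       state.zmap, history, converged, method="joint")
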