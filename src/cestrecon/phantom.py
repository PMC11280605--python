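"""Synthetic CEST phantoms, forward Z-spectrum image series, Fourier encoding,
noise injection, and offset-frequency subsampling.

The acquisition model per offset ω is

    g(ω) = F [ A(x, ω) · f(x, ω) ] + n,

with f(x, ω) = f(x, ω0) · Z(x, ω) the real amplitude image, A = e^{iφ} a
smoothly varying unit-modulus phase factor, F the centered orthonormal 2-D
DFT, and n complex Gaussian noise whose standard deviation is a stated
fraction of the mean k-space magnitude at the unsaturated reference ω0.

Coordinates are 0-based row-major pixel indices.  Geometry primitives in
phantom specs (disk, rectangle) use fractional coordinates of the image so
presets scale to any matrix size.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import fft as _fft

from .zspectrum import (
    FrequencyGrid,
    Pool,
    ZSpectrumParams,
    eval_zmodel,
)

__all__ = [
    "ImageSeries",
    "PhaseSeries",
    "KSpaceSeries",
    "PhantomScene",
    "preset_spec",
    "build_phantom",
    "grid_from_spec",
    "phase_series",
    "synthesize_series",
    "encode_kspace",
    "add_noise",
    "subsample_offsets",
    "select_offsets",
    "cfft2",
    "icfft2",
]


# ---------------------------------------------------------------------------
# Series containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ImageSeries:
    """Real amplitude images f(x, ω), shape (n_offsets, ny, nx)."""

    data: np.ndarray
    grid: FrequencyGrid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != self.grid.n_offsets:
            raise ValueError("data must be (n_offsets, ny, nx) matching the grid")


@dataclasses.dataclass
class PhaseSeries:
    """Phase angles φ(x, ω) in radians; the phase factor is A = e^{iφ}."""

    phase: np.ndarray
    grid: FrequencyGrid

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 3 or self.phase.shape[0] != self.grid.n_offsets:
            raise ValueError("phase must be (n_offsets, ny, nx) matching the grid")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase must be finite")

    @property
    def factors(self) -> np.ndarray:
        """Unit-modulus complex factors A(x, ω)."""
        return np.exp(1j * self.phase)


@dataclasses.dataclass
class KSpaceSeries:
    """Complex k-space data per offset, shape (n_offsets, ny, nx)."""

    data: np.ndarray
    grid: FrequencyGrid
    noise_level: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3 or self.data.shape[0] != self.grid.n_offsets:
            raise ValueError("data must be (n_offsets, ny, nx) matching the grid")


# ---------------------------------------------------------------------------
# Centered orthonormal 2-D DFT (shared by simulation and reconstruction)
# ---------------------------------------------------------------------------

def cfft2(x: np.ndarray) -> np.ndarray:
    """Centered orthonormal forward 2-D DFT over the last two axes.

    The image origin sits at the array center (fftshift convention) and the
    transform is unitary, so ``icfft2(cfft2(x)) == x`` and energy is
    preserved exactly (Parseval with constant 1)."""
    ax = (-2, -1)
    return _fft.fftshift(_fft.fft2(_fft.ifftshift(x, axes=ax), axes=ax, norm="ortho"), axes=ax)


def icfft2(k: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cfft2`."""
    ax = (-2, -1)
    return _fft.fftshift(_fft.ifft2(_fft.ifftshift(k, axes=ax), axes=ax, norm="ortho"), axes=ax)


# ---------------------------------------------------------------------------
# Phantom scenes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhantomScene:
    """A compartment phantom: geometry, per-compartment pool parameters,
    reference signal, phase model, and evaluation ROIs."""

    shape: tuple[int, int]
    label_map: np.ndarray
    s0_map: np.ndarray
    compartment_params: dict[int, ZSpectrumParams | None]
    phase_map: np.ndarray              # (ny, nx) base phase, radians
    roi_masks: dict[str, np.ndarray]
    background_roi: str = "background"
    phase_alpha: float = 0.0           # per-offset phase variation strength

    def __post_init__(self):
        ny, nx = self.shape
        if ny <= 0 or nx <= 0:
            raise ValueError("shape must be positive")
        self.label_map = np.asarray(self.label_map)
        self.s0_map = np.asarray(self.s0_map, dtype=float)
        self.phase_map = np.asarray(self.phase_map, dtype=float)
        for arr, name in ((self.label_map, "label_map"), (self.s0_map, "s0_map"),
                          (self.phase_map, "phase_map")):
            if arr.shape != (ny, nx):
                raise ValueError(f"{name} shape {arr.shape} != {self.shape}")
        if np.any(self.s0_map < 0):
            raise ValueError("s0_map must be >= 0 everywhere")
        if not np.all(np.isfinite(self.phase_map)):
            raise ValueError("phase_map must be finite")
        missing = set(np.unique(self.label_map)) - set(self.compartment_params)
        if missing:
            raise ValueError(f"label_map labels without compartment params: {sorted(missing)}")
        bg = self.roi_masks.get(self.background_roi)
        if bg is not None:
            for name, m in self.roi_masks.items():
                if name != self.background_roi and np.any(m & bg):
                    raise ValueError(f"ROI {name!r} overlaps the background mask")


def _geometry_mask(shape, geom: Mapping) -> np.ndarray:
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    kind = geom["type"]
    if kind == "background":
        return np.ones(shape, dtype=bool)
    if kind == "disk":
        cy, cx = geom["center"]
        r = geom["radius"] * min(ny, nx)
        return (yy - cy * ny) ** 2 + (xx - cx * nx) ** 2 <= r**2
    if kind == "rectangle":
        y0, x0, y1, x1 = geom["extent"]
        return ((yy >= y0 * ny) & (yy < y1 * ny) & (xx >= x0 * nx) & (xx < x1 * nx))
    raise ValueError(f"unknown geometry type {kind!r}")


def _params_from_spec(p: Mapping | None) -> ZSpectrumParams | None:
    if p is None:
        return None
    gamma = float(p["gamma"])
    if "a" in p:
        a = float(p["a"])
    else:
        a = float(p["depth"]) * gamma
    pools = tuple(Pool(float(q["center"]), float(q["amplitude"]), float(q["width"]))
                  for q in p.get("pools", ()))
    return ZSpectrumParams(a, gamma, pools, p.get("model", "LG"),
                           water_center=float(p.get("water_center", 0.0)))


def _poly2d(shape, coeffs) -> np.ndarray:
    """Low-order 2-D polynomial over normalized coordinates in [-1, 1]."""
    ny, nx = shape
    y = np.linspace(-1.0, 1.0, ny)[:, None]
    x = np.linspace(-1.0, 1.0, nx)[None, :]
    out = np.zeros(shape)
    for i, row in enumerate(coeffs):
        for j, c in enumerate(row):
            if c:
                out += c * (y**i) * (x**j)
    return out


def grid_from_spec(spec: Mapping) -> FrequencyGrid:
    g = spec["grid"]
    if "offsets" in g:
        offsets = np.asarray(g["offsets"], dtype=float)
    else:
        offsets = np.arange(g["start"], g["stop"] + 0.5 * g["step"], g["step"], dtype=float)
        for extra in g.get("extra_offsets", ()):
            offsets = np.union1d(offsets, [float(extra), -float(extra)])
    grid = FrequencyGrid(offsets, 0, float(g.get("water_offset", 0.0)),
                         tuple(g.get("pool_offsets", ())))
    return FrequencyGrid(offsets, grid.index_of(float(g["ref_offset"])),
                         grid.water_offset, grid.pool_offsets)


def build_phantom(spec) -> PhantomScene:
    """Build a :class:`PhantomScene` from a spec dict or YAML file path.

    The spec names the matrix shape, compartments (geometry primitives plus
    per-compartment Z-spectrum parameters and reference signal), the phase
    polynomial, and named ROIs for evaluation.
    """
    if isinstance(spec, (str, bytes)):
        with open(spec) as fh:
            spec = yaml.safe_load(fh)
    shape = tuple(int(s) for s in spec["shape"])
    if len(shape) != 2 or min(shape) <= 0:
        raise ValueError("shape must be two positive integers")
    label_map = np.zeros(shape, dtype=int)
    s0_map = np.zeros(shape)
    compartment_params: dict[int, ZSpectrumParams | None] = {}
    for lab, comp in enumerate(spec["compartments"]):
        m = _geometry_mask(shape, comp["geometry"])
        label_map[m] = lab
        s0_map[m] = float(comp.get("s0", 0.0))
        compartment_params[lab] = _params_from_spec(comp.get("params"))
    phase_spec = spec.get("phase", {})
    phase_map = _poly2d(shape, phase_spec.get("coeffs", [[0.0]]))
    rois = {}
    for roi in spec.get("rois", ()):
        rois[roi["name"]] = _geometry_mask(shape, roi["geometry"])
    background_roi = spec.get("background_roi", "background")
    if background_roi not in rois:
        rois[background_roi] = label_map == 0
    return PhantomScene(shape, label_map, s0_map, compartment_params, phase_map,
                        rois, background_roi, float(phase_spec.get("alpha", 0.0)))


# Water-only compartments share these brain-like line parameters: the water
# dip has depth 0.999 and Lorentzian width parameter 4e4 Hz² (half-width
# 200 Hz), giving Z(0) ≈ 0.001.
_WATER = {"depth": 0.999, "gamma": 4.0e4}


def preset_spec(name: str, shape: tuple[int, int] = (128, 128)) -> dict:
    """Built-in phantom descriptions.

    ``simulated_brain``: two compartments, CEST pool at 450 Hz, offsets
    −1250..1250 Hz step 50 (51 offsets), reference at −1250 Hz, proton
    density 0.85 (T1/T2 = 1200/120 ms carried as metadata only — the forward
    model never uses them).  ``choline``: four vials (10–100 mM-like pool
    amplitudes) plus a water vial in a signal-free background, pool at
    130 Hz.  ``iopamidol``: four inserts with amide pools at 530 and 700 Hz
    in a water background.  Choline/iopamidol pool amplitudes are
    illustrative defaults, overridable in the spec.
    """
    ny, nx = shape
    if name == "simulated_brain":
        return {
            "name": name,
            "shape": [ny, nx],
            "metadata": {"proton_density": 0.85, "t1_ms": 1200.0, "t2_ms": 120.0},
            "grid": {"start": -1250, "stop": 1250, "step": 50,
                     "ref_offset": -1250, "water_offset": 0, "pool_offsets": [450]},
            "phase": {"coeffs": [[0.1, 0.4, 0.15], [0.3, 0.2, 0.0], [0.1, 0.0, 0.0]],
                      "alpha": 0.0},
            "compartments": [
                {"name": "air", "geometry": {"type": "background"}, "s0": 0.0,
                 "params": None},
                {"name": "tissue", "geometry": {"type": "disk", "center": [0.5, 0.5],
                                                "radius": 0.42},
                 "s0": 0.85, "params": {**_WATER, "pools": []}},
                {"name": "cest_roi", "geometry": {"type": "disk", "center": [0.42, 0.58],
                                                  "radius": 0.12},
                 "s0": 0.85,
                 "params": {**_WATER,
                            "pools": [{"center": 450, "amplitude": 0.12, "width": 150}]}},
            ],
            "rois": [
                {"name": "insert", "geometry": {"type": "disk", "center": [0.42, 0.58],
                                                "radius": 0.10}},
                {"name": "tissue", "geometry": {"type": "disk", "center": [0.62, 0.36],
                                                "radius": 0.10}},
                {"name": "background", "geometry": {"type": "rectangle",
                                                    "extent": [0.0, 0.0, 0.06, 1.0]}},
            ],
            "background_roi": "background",
        }
    if name == "choline":
        vials = [(0.30, 0.30, 0.0), (0.30, 0.70, 0.03), (0.70, 0.30, 0.06),
                 (0.70, 0.70, 0.10), (0.50, 0.50, 0.16)]
        comps = [{"name": "fomblin", "geometry": {"type": "background"},
                  "s0": 0.0, "params": None}]
        rois = []
        for i, (cy, cx, amp) in enumerate(vials):
            pools = [] if amp == 0 else [{"center": 130, "amplitude": amp, "width": 60}]
            comps.append({"name": f"vial{i}",
                          "geometry": {"type": "disk", "center": [cy, cx], "radius": 0.11},
                          "s0": 1.0, "params": {"depth": 0.95, "gamma": 1.0e4,
                                                "pools": pools}})
            rois.append({"name": f"vial{i}", "geometry": {"type": "disk",
                                                          "center": [cy, cx], "radius": 0.09}})
        rois.append({"name": "background",
                     "geometry": {"type": "rectangle", "extent": [0.0, 0.0, 0.06, 1.0]}})
        return {"name": name, "shape": [ny, nx],
                "grid": {"start": -650, "stop": 650, "step": 26,
                         "ref_offset": -650, "water_offset": 0, "pool_offsets": [130]},
                "phase": {"coeffs": [[0.05, 0.3, 0.1], [0.25, 0.15, 0.0]], "alpha": 0.0},
                "compartments": comps, "rois": rois, "background_roi": "background"}
    if name == "iopamidol":
        inserts = [(0.30, 0.30, 0.03, 0.02), (0.30, 0.70, 0.05, 0.04),
                   (0.70, 0.30, 0.08, 0.06), (0.70, 0.70, 0.11, 0.09)]
        comps = [
            {"name": "air", "geometry": {"type": "background"}, "s0": 0.0, "params": None},
            {"name": "water", "geometry": {"type": "disk", "center": [0.5, 0.5],
                                           "radius": 0.45},
             "s0": 1.0, "params": {**_WATER, "pools": []}},
        ]
        rois = [{"name": "water", "geometry": {"type": "disk", "center": [0.5, 0.5],
                                               "radius": 0.07}}]
        for i, (cy, cx, b2, b3) in enumerate(inserts):
            comps.append({"name": f"insert{i}",
                          "geometry": {"type": "disk", "center": [cy, cx], "radius": 0.11},
                          "s0": 1.0,
                          "params": {**_WATER,
                                     "pools": [{"center": 530, "amplitude": b2, "width": 120},
                                               {"center": 700, "amplitude": b3, "width": 120}]}})
            rois.append({"name": f"insert{i}",
                         "geometry": {"type": "disk", "center": [cy, cx], "radius": 0.09}})
        rois.append({"name": "background",
                     "geometry": {"type": "rectangle", "extent": [0.0, 0.0, 0.05, 1.0]}})
        return {"name": name, "shape": [ny, nx],
                "grid": {"start": -1250, "stop": 1250, "step": 50,
                         "extra_offsets": [530],
                         "ref_offset": -1250, "water_offset": 0,
                         "pool_offsets": [530, 700]},
                "phase": {"coeffs": [[0.05, 0.3, 0.1], [0.25, 0.15, 0.0]], "alpha": 0.0},
                "compartments": comps, "rois": rois, "background_roi": "background"}
    raise KeyError(f"unknown preset {name!r}; available: simulated_brain, choline, iopamidol")


# ---------------------------------------------------------------------------
# Forward synthesis and encoding
# ---------------------------------------------------------------------------

def phase_series(scene: PhantomScene, grid: FrequencyGrid) -> PhaseSeries:
    """Expand the scene's base phase to a per-offset stack.

    With ``phase_alpha == 0`` the phase is constant across ω; otherwise it is
    scaled linearly with the offset's position in the grid."""
    base = scene.phase_map[None, :, :]
    if scene.phase_alpha == 0.0:
        phase = np.broadcast_to(base, (grid.n_offsets,) + scene.shape).copy()
    else:
        wmax = np.abs(grid.offsets).max()
        scale = 1.0 + scene.phase_alpha * (grid.offsets / wmax)
        phase = base * scale[:, None, None]
    return PhaseSeries(phase, grid)


def synthesize_series(scene: PhantomScene, grid: FrequencyGrid) -> ImageSeries:
    """Forward Z-spectrum image series f(x, ω) = f(x, ω0) · Z(x, ω).

    The sample at the unsaturated reference ω0 equals s0 exactly (no RF
    saturation applied there)."""
    for params in scene.compartment_params.values():
        if params is None:
            continue
        for p in params.pools:
            if not any(abs(p.center - g) < 1e-6 for g in grid.pool_offsets):
                raise ValueError(
                    f"pool center {p.center} Hz not among grid pool offsets {grid.pool_offsets}"
                )
    data = np.zeros((grid.n_offsets,) + scene.shape)
    for lab, params in scene.compartment_params.items():
        m = scene.label_map == lab
        if not m.any():
            continue
        if params is None:
            z = np.ones(grid.n_offsets)
        else:
            z = eval_zmodel(params, grid.offsets)
        z = z.copy()
        z[grid.ref_index] = 1.0
        data[:, m] = z[:, None] * scene.s0_map[m][None, :]
    return ImageSeries(data, grid)


def encode_kspace(images: ImageSeries, phase: PhaseSeries) -> KSpaceSeries:
    """Fourier-encode the phase-modulated image series: g(ω) = F[A·f]."""
    if images.data.shape != phase.phase.shape:
        raise ValueError("images and phase must share shape")
    data = cfft2(phase.factors * images.data)
    return KSpaceSeries(data, images.grid, noise_level=0.0)


def add_noise(ks: KSpaceSeries, level: float, seed: int) -> KSpaceSeries:
    """Add i.i.d. Gaussian noise to real and imaginary parts of every offset.

    The noise standard deviation is ``level`` times the mean k-space
    magnitude at the unsaturated reference offset ω0."""
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if level == 0:
        return KSpaceSeries(ks.data.copy(), ks.grid, 0.0, seed)
    sigma = level * float(np.abs(ks.data[ks.grid.ref_index]).mean())
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, ks.data.shape) + 1j * rng.normal(0.0, sigma, ks.data.shape)
    return KSpaceSeries(ks.data + noise, ks.grid, float(level), int(seed))


def subsample_offsets(ks: KSpaceSeries, keep: Iterable[float]) -> tuple[KSpaceSeries, float]:
    """Restrict an acquisition to a subset of offsets.

    ``keep`` must retain ω0, the water offset, every pool offset and its
    negation.  Returns the restricted series (retained arrays bit-exact) and
    the reduction fraction (n_dropped / n_original)."""
    grid = ks.grid
    keep_set = {grid.index_of(w) for w in keep}
    required = {grid.ref_index, grid.index_of(grid.water_offset)}
    for p in grid.pool_offsets:
        required.add(grid.index_of(p))
        required.add(grid.index_of(-p))
    missing = required - keep_set
    if missing:
        offs = sorted(float(grid.offsets[i]) for i in missing)
        raise ValueError(f"keep drops required offsets (Hz): {offs}")
    idx = sorted(keep_set)
    new_grid = grid.subset(grid.offsets[idx])
    out = KSpaceSeries(ks.data[idx].copy(), new_grid, ks.noise_level, ks.rng_seed)
    frac = (grid.n_offsets - len(idx)) / grid.n_offsets
    return out, float(frac)


def select_offsets(grid: FrequencyGrid, n_keep: int) -> np.ndarray:
    """Deterministically choose ``n_keep`` offsets: all required ones (ω0,
    water, ±pools) first, the rest evenly spaced across the remainder."""
    required = {grid.ref_index, grid.index_of(grid.water_offset)}
    for p in grid.pool_offsets:
        required.add(grid.index_of(p))
        required.add(grid.index_of(-p))
    if n_keep < len(required) or n_keep > grid.n_offsets:
        raise ValueError(f"n_keep must be in [{len(required)}, {grid.n_offsets}]")
    others = [i for i in range(grid.n_offsets) if i not in required]
    n_extra = n_keep - len(required)
    if n_extra and others:
        pick = np.unique(np.round(np.linspace(0, len(others) - 1, n_extra)).astype(int))
        chosen = required | {others[i] for i in pick}
        # rounding collisions: fill from the unchosen others in order
        for i in others:
            if len(chosen) >= n_keep:
                break
            chosen.add(i)
    else:
        chosen = required
    return grid.offsets[sorted(chosen)]
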