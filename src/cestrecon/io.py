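"""HDF5/JSON serialization of k-space series, image stacks, fitted parameter
maps and reconstruction results, plus run manifests.

Layouts
-------
KSpaceSeries      /kspace (complex, offsets × ny × nx), /offsets_hz;
                  attrs ref_index, water_offset_hz, pool_offsets_hz,
                  noise_level, rng_seed.
ImageSeries       /images, /offsets_hz + the same grid attrs.
PhaseSeries       /phase, /offsets_hz + grid attrs.
ZParamsMap        /params/a, /params/gamma, /params/pool{i}/{b,sigma},
                  /params/mask + a JSON sidecar with centers and model_kind.
ReconResult       /recon/magnitude, /recon/phase, /recon/zparams/*,
                  /history (JSON string attr).

All pixel coordinates are 0-based, row-major.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import h5py
import numpy as np

from .phantom import ImageSeries, KSpaceSeries, PhaseSeries
from .recon import ReconResult
from .zspectrum import FrequencyGrid, ZParamsMap

__all__ = [
    "write_kspace", "read_kspace",
    "write_image_series", "read_image_series",
    "write_phase_series", "read_phase_series",
    "write_zparams", "read_zparams",
    "write_recon_result", "read_recon_result",
    "write_rois", "read_rois",
    "write_manifest", "read_manifest",
    "export_nifti",
]

_MISSING_SEED = -1


def _write_grid(h, grid: FrequencyGrid) -> None:
    h.create_dataset("offsets_hz", data=grid.offsets)
    h.attrs["ref_index"] = grid.ref_index
    h.attrs["water_offset_hz"] = grid.water_offset
    h.attrs["pool_offsets_hz"] = np.asarray(grid.pool_offsets, dtype=float)


def _read_grid(h) -> FrequencyGrid:
    return FrequencyGrid(
        np.asarray(h["offsets_hz"]),
        int(h.attrs["ref_index"]),
        float(h.attrs["water_offset_hz"]),
        tuple(float(p) for p in np.atleast_1d(h.attrs["pool_offsets_hz"])),
    )


def write_kspace(path, ks: KSpaceSeries) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("kspace", data=ks.data)
        _write_grid(h, ks.grid)
        h.attrs["noise_level"] = ks.noise_level
        h.attrs["rng_seed"] = _MISSING_SEED if ks.rng_seed is None else int(ks.rng_seed)


def read_kspace(path) -> KSpaceSeries:
    with h5py.File(path, "r") as h:
        seed = int(h.attrs["rng_seed"])
        return KSpaceSeries(np.asarray(h["kspace"]), _read_grid(h),
                            float(h.attrs["noise_level"]),
                            None if seed == _MISSING_SEED else seed)


def write_image_series(path, images: ImageSeries) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("images", data=images.data)
        _write_grid(h, images.grid)


def read_image_series(path) -> ImageSeries:
    with h5py.File(path, "r") as h:
        return ImageSeries(np.asarray(h["images"]), _read_grid(h))


def write_phase_series(path, phase: PhaseSeries) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("phase", data=phase.phase)
        _write_grid(h, phase.grid)


def read_phase_series(path) -> PhaseSeries:
    with h5py.File(path, "r") as h:
        return PhaseSeries(np.asarray(h["phase"]), _read_grid(h))


def _write_zparams_group(h, zmap: ZParamsMap) -> None:
    g = h.create_group("params")
    g.create_dataset("a", data=zmap.a)
    g.create_dataset("gamma", data=zmap.gamma)
    g.create_dataset("mask", data=zmap.mask)
    for i in range(len(zmap.centers)):
        gp = g.create_group(f"pool{i}")
        gp.create_dataset("b", data=zmap.pool_amplitude[i])
        gp.create_dataset("sigma", data=zmap.pool_width[i])


def _read_zparams_group(h, meta: dict) -> ZParamsMap:
    g = h["params"]
    centers = tuple(meta["centers"])
    pamp = np.stack([np.asarray(g[f"pool{i}/b"]) for i in range(len(centers))]) \
        if centers else np.zeros((0,) + g["a"].shape)
    pwid = np.stack([np.asarray(g[f"pool{i}/sigma"]) for i in range(len(centers))]) \
        if centers else np.zeros((0,) + g["a"].shape)
    return ZParamsMap(np.asarray(g["a"]), np.asarray(g["gamma"]), pamp, pwid,
                      centers, meta["model_kind"], meta.get("pool_sign", -1.0),
                      meta.get("water_center", 0.0), np.asarray(g["mask"], dtype=bool))


def _zparams_meta(zmap: ZParamsMap) -> dict:
    return {"centers": list(zmap.centers), "model_kind": zmap.model_kind,
            "pool_sign": zmap.pool_sign, "water_center": zmap.water_center}


def write_zparams(path, zmap: ZParamsMap) -> None:
    """Parameter maps as HDF5 plus a JSON sidecar of fixed centers/model."""
    path = pathlib.Path(path)
    with h5py.File(path, "w") as h:
        _write_zparams_group(h, zmap)
    path.with_suffix(".json").write_text(json.dumps(_zparams_meta(zmap), indent=2))


def read_zparams(path) -> ZParamsMap:
    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with h5py.File(path, "r") as h:
        return _read_zparams_group(h, meta)


def write_recon_result(path, result: ReconResult) -> None:
    with h5py.File(path, "w") as h:
        g = h.create_group("recon")
        g.create_dataset("magnitude", data=result.images.data)
        g.create_dataset("phase", data=result.phase.phase)
        _write_grid(h, result.images.grid)
        _write_zparams_group(g, result.zparams)
        h.attrs["method"] = result.method
        h.attrs["converged"] = bool(result.converged)
        h.attrs["history"] = json.dumps(result.history)
        h.attrs["zparams_meta"] = json.dumps(_zparams_meta(result.zparams))


def read_recon_result(path) -> ReconResult:
    with h5py.File(path, "r") as h:
        grid = _read_grid(h)
        meta = json.loads(h.attrs["zparams_meta"])
        zmap = _read_zparams_group(h["recon"], meta)
        return ReconResult(
            ImageSeries(np.asarray(h["recon/magnitude"]), grid),
            PhaseSeries(np.asarray(h["recon/phase"]), grid),
            zmap,
            json.loads(h.attrs["history"]),
            bool(h.attrs["converged"]),
            str(h.attrs["method"]),
        )


def write_rois(path, rois: dict[str, np.ndarray], background: str) -> None:
    with h5py.File(path, "w") as h:
        h.attrs["background"] = background
        for name, m in rois.items():
            h.create_dataset(name, data=np.asarray(m, dtype=bool))


def read_rois(path) -> tuple[dict[str, np.ndarray], str]:
    with h5py.File(path, "r") as h:
        rois = {name: np.asarray(h[name], dtype=bool) for name in h}
        return rois, str(h.attrs["background"])


def write_manifest(path, config: dict) -> None:
    """JSON run manifest: everything needed to re-run a command bit-identically."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    import cestrecon
    payload = {"format_version": 1, "package_version": cestrecon.__version__, **config}
    pathlib.Path(path).write_text(json.dumps(payload, indent=2, default=_default))


def read_manifest(path) -> dict:
    return json.loads(pathlib.Path(path).read_text())


def export_nifti(path, images: ImageSeries) -> None:
    """Optional NIfTI export of a magnitude stack (offsets as volumes)."""
    import nibabel as nib

    vol = np.moveaxis(images.data, 0, -1)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)), str(path))
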