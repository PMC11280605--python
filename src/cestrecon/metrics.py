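"""Quantitative evaluation: ROI-based SNR in dB, frequency-averaged SNR,
ROI statistics of MTR-asymmetry maps, and uncertainty-reduction summaries.

SNR follows the amplitude convention 20·log10(mean ROI signal / std of the
background noise); a 10·log10 power switch is provided for sensitivity
checks.  ROI statistics are population statistics (ddof = 0).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ROISet",
    "EvalReport",
    "snr_db",
    "averaged_snr",
    "roi_statistics",
    "uncertainty_reduction",
    "contrast_to_noise",
]


@dataclasses.dataclass
class ROISet:
    """Named boolean masks plus a designated background mask for noise
    estimation; the background must be nonempty and disjoint from every
    signal ROI."""

    masks: dict[str, np.ndarray]
    background: str = "background"

    def __post_init__(self):
        if self.background not in self.masks:
            raise ValueError(f"background mask {self.background!r} missing")
        bg = self.masks[self.background]
        if not bg.any():
            raise ValueError("background mask is empty")
        for name, m in self.masks.items():
            if m.shape != bg.shape:
                raise ValueError(f"mask {name!r} shape mismatch")
            if name != self.background and np.any(m & bg):
                raise ValueError(f"ROI {name!r} overlaps the background mask")

    @property
    def signal_names(self) -> list[str]:
        return [n for n in self.masks if n != self.background]

    def background_mask(self) -> np.ndarray:
        return self.masks[self.background]


def snr_db(image: np.ndarray, roi: np.ndarray, background: np.ndarray,
           convention: str = "amplitude") -> float:
    """SNR in dB: the ratio of the mean ROI signal to the standard deviation
    of the background noise.  Returns +inf (with a logged flag) when the
    background is exactly constant."""
    image = np.asarray(image, dtype=float)
    mean_sig = float(image[roi].mean())
    noise = float(image[background].std())
    factor = 20.0 if convention == "amplitude" else 10.0
    if noise == 0.0:
        logger.warning("snr_db: zero background std, returning +inf sentinel")
        return float("inf")
    return factor * float(np.log10(mean_sig / noise))


def averaged_snr(images, roi: np.ndarray, background: np.ndarray,
                 include: Sequence[int] | None = None,
                 convention: str = "amplitude") -> float:
    """Arithmetic mean of per-offset SNRs over the included offset indices
    (all offsets by default)."""
    data = images.data
    idx = range(data.shape[0]) if include is None else list(include)
    idx = list(idx)
    if not idx:
        raise ValueError("offset selection is empty")
    return float(np.mean([snr_db(data[i], roi, background, convention) for i in idx]))


def roi_statistics(map2d: np.ndarray, rois: ROISet,
                   include_background: bool = False) -> dict[str, tuple[float, float]]:
    """Population mean and std of a map within each named ROI.  NaN pixels
    (masked, e.g. background in an MTR-asymmetry map) are ignored."""
    out = {}
    names = list(rois.masks) if include_background else rois.signal_names
    for name in names:
        m = rois.masks[name]
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty")
        vals = np.asarray(map2d, dtype=float)[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out[name] = (float("nan"), float("nan"))
        else:
            out[name] = (float(vals.mean()), float(vals.std()))
    return out


def uncertainty_reduction(std_ref: Mapping[str, float] | Iterable[float],
                          std_new: Mapping[str, float] | Iterable[float]) -> dict:
    """Reduction of MTR-asymmetry uncertainty across ROIs.

    The headline number is 100·(1 − mean(std_new)/mean(std_ref)) with the
    unweighted mean over ROIs as the aggregate; because that aggregation is
    a convention, the per-ROI reductions and their mean are reported too.
    """
    if isinstance(std_ref, Mapping):
        keys = list(std_ref)
        ref = np.array([std_ref[k] for k in keys], dtype=float)
        new = np.array([std_new[k] for k in keys], dtype=float)
    else:
        ref = np.array(list(std_ref), dtype=float)
        new = np.array(list(std_new), dtype=float)
        keys = [str(i) for i in range(ref.size)]
    agg_ref, agg_new = float(ref.mean()), float(new.mean())
    if agg_ref <= 0:
        raise ValueError("reference aggregate std must be > 0")
    per_roi = {k: 100.0 * (1.0 - n / r) if r > 0 else float("nan")
               for k, r, n in zip(keys, ref, new)}
    finite = [v for v in per_roi.values() if np.isfinite(v)]
    return {
        "aggregate_ref": agg_ref,
        "aggregate_new": agg_new,
        "reduction_pct": 100.0 * (1.0 - agg_new / agg_ref),
        "per_roi_reduction_pct": per_roi,
        "mean_per_roi_reduction_pct": float(np.mean(finite)) if finite else float("nan"),
    }


def contrast_to_noise(map2d: np.ndarray, roi: np.ndarray,
                      reference: np.ndarray) -> float:
    """Contrast-to-noise of a map: (mean over ROI − mean over reference
    region) divided by the std within the reference region.  NaNs ignored."""
    m = np.asarray(map2d, dtype=float)
    a = m[roi]
    a = a[np.isfinite(a)]
    b = m[reference]
    b = b[np.isfinite(b)]
    sd = b.std()
    if sd == 0:
        return float("inf")
    return float((a.mean() - b.mean()) / sd)


@dataclasses.dataclass
class EvalReport:
    """Per-offset and averaged SNR plus per-ROI MTR-asymmetry statistics."""

    per_offset_snr_db: dict[str, list[float]]
    averaged_snr_db: dict[str, float]
    mtr_roi_stats: dict[str, dict[str, tuple[float, float]]]
    uncertainty: dict | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        for method, per in self.per_offset_snr_db.items():
            finite = [s for s in per if np.isfinite(s)]
            if finite and method in self.averaged_snr_db:
                if not np.isclose(self.averaged_snr_db[method], np.mean(per)):
                    raise ValueError("averaged SNR must equal the mean of per-offset SNRs")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=float)

    def to_csv(self, path) -> None:
        rows = ["metric,method,key,value"]
        for method, per in self.per_offset_snr_db.items():
            for i, s in enumerate(per):
                rows.append(f"snr_db,{method},{i},{s}")
        for method, s in self.averaged_snr_db.items():
            rows.append(f"averaged_snr_db,{method},,{s}")
        for method, stats in self.mtr_roi_stats.items():
            for name, (mean, std) in stats.items():
                rows.append(f"mtr_mean,{method},{name},{mean}")
                rows.append(f"mtr_std,{method},{name},{std}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")
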