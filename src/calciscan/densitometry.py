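"""Calcite CT-number (CCN) densitometry.

The CCN maps reconstructed grayscale onto a scale where surrounding air
is 0 and standard calcite (density 2.71 g/cm^3) is 1000:

    CCN = 1000 * (mu_sample - mu_air) / (mu_calcite - mu_air)

Because the mapping is affine in the grayscale and both references are
taken from the *same* scan, any per-scan gain/offset drift cancels
exactly — this is the property that makes paired pre/post comparisons
meaningful.  The clinical CT number (Hounsfield units) is provided for
reference:  CT = k * (mu_m - mu_w) / mu_w, water = 0 HU, air = -1000 HU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from calciscan.errors import CalibrationError, SegmentationError, ValidationError
from calciscan.volume import AttenuationVolume

#: scale constant k of the clinical CT-number equation
CT_K = 1000.0
#: CCN of the standard-calcite reference
CCN_CALCITE = 1000.0


def ct_number(mu_m, mu_w, k: float = CT_K):
    """Clinical CT number (HU): ``k * (mu_m - mu_w) / mu_w``."""
    if np.any(np.asarray(mu_w) <= 0):
        raise ValidationError("mu_w must be positive")
    out = k * (np.asarray(mu_m, dtype=np.float64) - mu_w) / mu_w
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class ScanCalibration:
    """Per-scan air and standard-calcite grayscale references."""

    mu_air: float
    mu_calcite: float
    n_air: int
    n_calcite: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_air) or not np.isfinite(self.mu_calcite):
            raise CalibrationError("non-finite calibration means")
        if self.mu_calcite <= self.mu_air:
            raise CalibrationError(
                f"degenerate calibration: mu_calcite={self.mu_calcite} "
                f"<= mu_air={self.mu_air}")


def ccn(mu_sample, cal: ScanCalibration):
    """Map grayscale/attenuation onto the calcite CT-number scale.

    Values are deliberately not clipped: noisy voxels may fall below 0 or
    above 1000, and clipping them would bias paired comparisons.
    """
    out = (CCN_CALCITE * (np.asarray(mu_sample, dtype=np.float64) - cal.mu_air)
           / (cal.mu_calcite - cal.mu_air))
    return float(out) if np.ndim(out) == 0 else out


def _erode(mask: np.ndarray) -> np.ndarray:
    # one-voxel erosion drops partial-volume rims; border_value=1 keeps
    # regions flush with the array edge from being eaten from that side
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    return ndimage.binary_erosion(mask, structure=structure, border_value=1)


def _autodetect_regions(values: np.ndarray,
                        min_voxels: int) -> dict[str, np.ndarray]:
    """Fallback when no labels are present: calcite = brightest large
    connected component above Otsu; air = dominant low histogram mode."""
    finite = values[np.isfinite(values)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise CalibrationError("volume has no contrast; cannot auto-detect")
    thr = threshold_otsu(values)
    lab, n = ndimage.label(values > thr,
                           structure=np.ones((3,) * values.ndim, dtype=bool))
    if n == 0:
        raise CalibrationError("no bright component found for calcite standard")
    means, sizes = [], []
    for i in range(1, n + 1):
        comp = lab == i
        sizes.append(int(comp.sum()))
        means.append(float(values[comp].mean()))
    candidates = [i for i in range(n) if sizes[i] >= min_voxels]
    if not candidates:
        raise CalibrationError("no bright component large enough for calibration")
    best = max(candidates, key=lambda i: means[i])
    calcite = lab == best + 1
    low = values[values <= thr]
    counts, edges = np.histogram(low, bins=50)
    m = int(np.argmax(counts))
    center = 0.5 * (edges[m] + edges[m + 1])
    sigma = 1.4826 * np.median(np.abs(low - np.median(low)))
    half_band = max(5.0 * sigma, edges[m + 1] - edges[m])
    air = np.abs(values - center) <= half_band
    return {"calcite_standard": calcite, "air": air}


def calibrate_scan(volume: AttenuationVolume, *,
                   min_voxels: int = 100) -> ScanCalibration:
    """Estimate per-scan air/calcite reference means.

    Labeled regions are used when present, otherwise auto-detection is
    attempted.  Each region is eroded by one voxel before averaging and
    must retain at least ``min_voxels`` voxels.
    """
    labels = volume.region_labels
    if "calcite_standard" not in labels or "air" not in labels:
        labels = _autodetect_regions(volume.values, min_voxels)
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for name in ("calcite_standard", "air"):
        region = _erode(labels[name].astype(bool))
        n = int(region.sum())
        if n < min_voxels:
            raise CalibrationError(
                f"region {name!r} has {n} voxels after erosion (< {min_voxels})")
        means[name] = float(volume.values[region].mean())
        counts[name] = n
    return ScanCalibration(mu_air=means["air"], mu_calcite=means["calcite_standard"],
                           n_air=counts["air"], n_calcite=counts["calcite_standard"])


def ccn_volume(volume: AttenuationVolume,
               cal: ScanCalibration | None = None) -> AttenuationVolume:
    """Convenience: calibrate (if needed) and map a whole volume to CCN."""
    cal = cal or calibrate_scan(volume)
    return AttenuationVolume(values=ccn(volume.values, cal),
                             voxel_size=volume.voxel_size,
                             region_labels=volume.region_labels)


def segment_shell(ccn_values: np.ndarray, *,
                  exclude: np.ndarray | None = None,
                  min_component: int = 1000,
                  ccn_range: tuple[float, float] = (0.0, 1200.0)) -> np.ndarray:
    """Binary shell mask from a CCN-calibrated volume.

    Otsu threshold computed on CCN values restricted to ``ccn_range``,
    followed by full-connectivity component filtering at
    ``min_component`` voxels.  The standard-calcite region (``exclude``)
    is removed before thresholding.  Pores are left open.
    """
    values = np.asarray(ccn_values, dtype=np.float64)
    candidates = values.copy()
    if exclude is not None:
        candidates[exclude.astype(bool)] = ccn_range[0] - 1
    in_range = candidates[(candidates >= ccn_range[0]) & (candidates <= ccn_range[1])]
    if in_range.size == 0 or np.ptp(in_range) == 0:
        raise SegmentationError("no CCN contrast inside the segmentation range")
    thr = threshold_otsu(in_range)
    fg = (candidates > thr) & (candidates <= ccn_range[1])
    lab, n = ndimage.label(fg, structure=np.ones((3,) * values.ndim, dtype=bool))
    if n == 0:
        raise SegmentationError("no foreground component")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_component) + 1
    if keep.size == 0:
        raise SegmentationError(
            f"no component reaches {min_component} voxels (largest: {int(sizes.max())})")
    return np.isin(lab, keep)


def _palette_lut(palette: str, levels: int = 256) -> np.ndarray:
    import matplotlib

    cmap = matplotlib.colormaps[palette]
    return (cmap(np.linspace(0, 1, levels))[:, :3] * 255 + 0.5).astype(np.uint8)


def density_slices(ccn_values: np.ndarray, *, axis: int = 0,
                   palette: str = "viridis", out_dir=None,
                   ccn_max: float = CCN_CALCITE):
    """Render CCN slices as 8-bit color images (CCN 0..1000 across the palette).

    The mapping is monotone; with ``out_dir`` set, PNGs plus a JSON
    metadata file (palette name, range) are written.  Returns the stack
    of RGB arrays, one per slice along ``axis``.
    """
    values = np.asarray(ccn_values, dtype=np.float64)
    if values.ndim == 2:
        values = values[None, ...]
        axis = 0
    if not 0 <= axis < values.ndim:
        raise ValidationError(f"axis {axis} invalid for {values.ndim}D volume")
    lut = _palette_lut(palette)
    idx = np.clip(values / ccn_max * (len(lut) - 1), 0, len(lut) - 1)
    rgb = lut[np.round(idx).astype(np.intp)]
    rgb = np.moveaxis(rgb, axis, 0)
    if out_dir is not None:
        import json
        from pathlib import Path

        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, img in enumerate(rgb):
            iio.imwrite(out / f"slice_{k:04d}.png", img)
        (out / "palette.json").write_text(json.dumps(
            {"palette": palette, "ccn_min": 0.0, "ccn_max": ccn_max,
             "levels": len(lut), "axis": axis}))
    return rgb


def decode_density_slice(rgb: np.ndarray, *, palette: str = "viridis",
                         ccn_max: float = CCN_CALCITE) -> np.ndarray:
    """Invert the palette mapping: nearest-LUT-color lookup back to CCN."""
    lut = _palette_lut(palette).astype(np.int32)
    px = rgb.reshape(-1, 3).astype(np.int32)
    d2 = ((px[:, None, :] - lut[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return (idx / (len(lut) - 1) * ccn_max).reshape(rgb.shape[:-1])


@dataclass(frozen=True)
class SpecimenDensitySummary:
    """Shell-mask CCN statistics for one specimen."""

    mean_ccn: float
    histogram_counts: tuple[int, ...]
    histogram_edges: tuple[float, ...]
    shell_voxel_count: int
    shell_volume: float  # um^3 (um^2 for 2D slices)


def specimen_summary(ccn_values: np.ndarray, mask: np.ndarray, *,
                     voxel_size: float, bins: int = 50,
                     hist_range: tuple[float, float] = (0.0, 1200.0),
                     statistic: str = "mean") -> SpecimenDensitySummary:
    """Per-specimen CCN summary over the shell mask (default: mean)."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValidationError("empty shell mask")
    vals = np.asarray(ccn_values, dtype=np.float64)[mask]
    reducer = {"mean": np.mean, "median": np.median}.get(statistic)
    if reducer is None:
        raise ValidationError(f"unknown summary statistic {statistic!r}")
    counts, edges = np.histogram(vals, bins=bins, range=hist_range)
    return SpecimenDensitySummary(
        mean_ccn=float(reducer(vals)),
        histogram_counts=tuple(int(c) for c in counts),
        histogram_edges=tuple(float(e) for e in edges),
        shell_voxel_count=int(mask.sum()),
        shell_volume=float(mask.sum()) * voxel_size ** mask.ndim)
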