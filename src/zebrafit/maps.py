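"""Volume-level fitting: parameter maps, weighted maps and scan summaries.

Fitting a scan produces one 3D map per model parameter plus convergence
and residual diagnostics.  For the bicompartmental model the perfusion
fraction additionally weights the compartment maps (f*t2s_p, f*d_star,
(1-f)*t2s_d, (1-f)*adc and their sums), so a scan can be summarised
either per raw compartment or as fraction-weighted quantities.  The
whole-organ value of any map is its arithmetic mean over converged
in-mask voxels; voxels whose fit failed hold NaN and are excluded from
every summary (exclusion counts are kept alongside).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import DegenerateSignalError, SchemeValidationError, SummaryError
from .fitting import FitConfig, GridEvaluator, fit_voxel
from .models import PARAM_NAMES
from .volume import VolumeSeries

__all__ = [
    "ParameterMaps",
    "ScanMetrics",
    "fit_volume",
    "fraction_weighted_maps",
    "whole_placenta_summary",
    "voxel_value_histogram",
    "save_parameter_maps",
    "load_parameter_maps",
    "METRIC_NAMES",
]

log = logging.getLogger(__name__)

#: map name -> reported metric name, per model
_METRIC_OF_MAP = {
    "t2s_adc": {"t2s": "t2s_adc.t2s", "adc": "t2s_adc.adc"},
    "t2s_ivim": {
        "t2s_p": "ivim.t2s_perf",
        "d_star": "ivim.adc_perf",
        "t2s_d": "ivim.t2s_diff",
        "adc": "ivim.adc_diff",
        "f": "ivim.f",
        "t2s_perf_weighted": "ivim.t2s_perf_weighted",
        "adc_perf_weighted": "ivim.adc_perf_weighted",
        "t2s_diff_weighted": "ivim.t2s_diff_weighted",
        "adc_diff_weighted": "ivim.adc_diff_weighted",
        "t2s_combined": "ivim.t2s_combined",
        "adc_combined": "ivim.adc_combined",
    },
}

#: The seven core whole-organ metrics reported for every scan pair of fits.
METRIC_NAMES = (
    "t2s_adc.t2s", "t2s_adc.adc",
    "ivim.t2s_perf", "ivim.adc_perf", "ivim.t2s_diff", "ivim.adc_diff",
    "ivim.f",
)


@dataclass
class ParameterMaps:
    """Fitted 3D parameter maps for one scan and one model.

    ``maps`` holds one (x, y, z) float array per parameter (NaN outside
    the mask and at failed voxels); ``converged`` flags usable voxels;
    ``residual_norm`` stores each voxel's sum of squared residuals.
    """

    model_id: str
    maps: dict
    converged: np.ndarray
    residual_norm: np.ndarray
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def spatial_shape(self) -> tuple:
        return self.mask.shape

    @property
    def n_converged(self) -> int:
        return int((self.converged & self.mask).sum())

    @property
    def n_failed(self) -> int:
        return int((self.mask & ~self.converged).sum())

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]


def fit_volume(series: VolumeSeries, model_id: str,
               config: Optional[FitConfig] = None) -> ParameterMaps:
    """Brute2fine fit of every in-mask voxel.

    Per-voxel failures (degenerate signals, non-convergence) are recorded
    in the ``converged`` map and never abort the remaining voxels.  The
    grid design matrix is built once and shared across voxels.
    """
    if config is None:
        config = FitConfig.default(model_id)
    if not series.mask.any():
        raise SchemeValidationError("mask contains no voxels")
    evaluator = GridEvaluator(model_id, config.grid, series.scheme)
    shape = series.spatial_shape
    names = PARAM_NAMES[model_id]
    maps = {n: np.full(shape, np.nan) for n in names}
    converged = np.zeros(shape, dtype=bool)
    residual = np.full(shape, np.nan)
    n_failed = 0
    for idx in zip(*np.nonzero(series.mask)):
        signal = series.signal[idx]
        try:
            result = fit_voxel(signal, series.scheme, model_id,
                               config=config, evaluator=evaluator)
        except DegenerateSignalError:
            n_failed += 1
            continue
        residual[idx] = result.residual_norm
        if result.params is None:
            n_failed += 1
            continue
        converged[idx] = result.converged
        if not result.converged:
            n_failed += 1
        for n in names:
            maps[n][idx] = getattr(result.params, n)
    if n_failed:
        log.info("fit_volume(%s): %d of %d in-mask voxel(s) did not converge",
                 model_id, n_failed, series.n_mask_voxels)
    # failed voxels keep NaN parameter values so summaries skip them
    for n in names:
        maps[n][~converged] = np.nan
    return ParameterMaps(model_id=model_id, maps=maps, converged=converged,
                         residual_norm=residual, mask=series.mask.copy(),
                         affine=series.affine.copy())


def fraction_weighted_maps(maps: ParameterMaps) -> dict:
    """Fraction-weighted compartment maps from a bicompartmental fit.

    Returns per-voxel ``f*t2s_p`` / ``f*d_star`` (perfusing),
    ``(1-f)*t2s_d`` / ``(1-f)*adc`` (diffusing) and the combined weighted
    sums ``f*t2s_p + (1-f)*t2s_d`` and ``f*d_star + (1-f)*adc``.
    """
    if maps.model_id != "t2s_ivim":
        raise TypeError(
            f"fraction weighting needs t2s_ivim maps, got {maps.model_id!r}"
        )
    f = maps["f"]
    out = {
        "t2s_perf_weighted": f * maps["t2s_p"],
        "adc_perf_weighted": f * maps["d_star"],
        "t2s_diff_weighted": (1.0 - f) * maps["t2s_d"],
        "adc_diff_weighted": (1.0 - f) * maps["adc"],
    }
    out["t2s_combined"] = out["t2s_perf_weighted"] + out["t2s_diff_weighted"]
    out["adc_combined"] = out["adc_perf_weighted"] + out["adc_diff_weighted"]
    return out


@dataclass
class ScanMetrics:
    """Whole-organ metric values for one scan.

    values : metric name -> whole-organ mean over converged in-mask voxels
    n_voxels_used : number of voxels entering each mean
    """

    values: dict
    n_voxels_used: int

    def __post_init__(self) -> None:
        if self.n_voxels_used < 1:
            raise SummaryError("a scan summary needs at least one usable voxel")
        f = self.values.get("ivim.f")
        if f is not None and not 0.0 <= f <= 1.0:
            raise SummaryError(f"mean perfusion fraction {f} outside [0, 1]")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _usable(maps: ParameterMaps) -> np.ndarray:
    return maps.mask & maps.converged


def whole_placenta_summary(maps: ParameterMaps,
                           derived: Optional[dict] = None,
                           statistic: str = "mean") -> ScanMetrics:
    """Whole-organ summary of every raw (and optionally derived) map.

    ``statistic`` is "mean" (default) or "median"; either way only
    converged in-mask voxels contribute.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    usable = _usable(maps)
    n = int(usable.sum())
    if n == 0:
        raise SummaryError("no converged in-mask voxels to summarise")
    reduce = np.mean if statistic == "mean" else np.median
    named = dict(maps.maps)
    if derived:
        named.update(derived)
    metric_of = _METRIC_OF_MAP[maps.model_id]
    values = {}
    for map_name, arr in named.items():
        metric = metric_of.get(map_name)
        if metric is None or map_name == "s0":
            continue
        values[metric] = float(reduce(arr[usable]))
    return ScanMetrics(values=values, n_voxels_used=n)


def voxel_value_histogram(maps: ParameterMaps, metric: str, bins=32,
                          derived: Optional[dict] = None):
    """Histogram of a map's converged in-mask voxel values.

    ``metric`` names either a raw parameter map or a derived map passed
    via ``derived``.  Returns ``(bin_edges, counts)``; counts always sum
    to the number of usable voxels.
    """
    named = dict(maps.maps)
    if derived:
        named.update(derived)
    if metric not in named:
        raise KeyError(f"unknown map {metric!r}; have {sorted(named)}")
    usable = _usable(maps)
    vals = named[metric][usable]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise SummaryError(f"no usable voxels for map {metric!r}")
    counts, edges = np.histogram(vals, bins=bins)
    return edges, counts


def save_parameter_maps(maps: ParameterMaps, out_dir: str | os.PathLike,
                        derived: Optional[dict] = None) -> None:
    """Write one NIfTI per map plus a JSON sidecar describing the set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    named = dict(maps.maps)
    if derived:
        named.update(derived)
    for name, arr in named.items():
        nib.save(nib.Nifti1Image(arr.astype(np.float64), maps.affine),
                 out / f"{name}.nii.gz")
    nib.save(nib.Nifti1Image(maps.converged.astype(np.uint8), maps.affine),
             out / "converged.nii.gz")
    nib.save(nib.Nifti1Image(maps.mask.astype(np.uint8), maps.affine),
             out / "mask.nii.gz")
    nib.save(nib.Nifti1Image(maps.residual_norm.astype(np.float64), maps.affine),
             out / "residual_norm.nii.gz")
    sidecar = {"model_id": maps.model_id, "maps": sorted(named)}
    (out / "maps.json").write_text(json.dumps(sidecar, indent=2))


def load_parameter_maps(maps_dir: str | os.PathLike) -> tuple:
    """Read a map directory written by :func:`save_parameter_maps`.

    Returns ``(ParameterMaps, derived_dict)`` with derived maps separated
    from raw parameter maps.
    """
    d = Path(maps_dir)
    sidecar = json.loads((d / "maps.json").read_text())
    model_id = sidecar["model_id"]
    raw_names = set(PARAM_NAMES[model_id])
    maps, derived = {}, {}
    for name in sidecar["maps"]:
        arr = np.asarray(nib.load(d / f"{name}.nii.gz").dataobj, dtype=float)
        (maps if name in raw_names else derived)[name] = arr
    conv_img = nib.load(d / "converged.nii.gz")
    converged = np.asarray(conv_img.dataobj) != 0
    mask = np.asarray(nib.load(d / "mask.nii.gz").dataobj) != 0
    residual = np.asarray(nib.load(d / "residual_norm.nii.gz").dataobj, dtype=float)
    pm = ParameterMaps(model_id=model_id, maps=maps, converged=converged,
                       residual_norm=residual, mask=mask,
                       affine=np.asarray(conv_img.affine, dtype=float))
    return pm, derived


def metrics_frame(rows: list[dict]) -> pd.DataFrame:
    """Tabulate per-scan metrics dicts (subject_id, ga_weeks, metrics...)."""
    return pd.DataFrame(rows)
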