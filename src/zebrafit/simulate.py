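"""Synthetic data with known ground truth.

Three generators mirror the study design that the statistics modules
expect, so every pipeline stage is testable without clinical data:

* **voxel signals** — forward-model signals under optional Gaussian or
  Rician noise (Rician: magnitude of the noiseless signal plus a complex
  Gaussian perturbation, the standard MR magnitude-noise model);
* **placenta phantoms** — small 3D volumes whose per-voxel ground-truth
  parameters vary as a smooth low-frequency field, optionally modulated
  by lobule-like domains with depressed-T2* rims, under an ellipsoidal
  organ mask;
* **GA-structured cohorts** — whole-organ metric tables for a
  cross-sectional arm (one scan per subject) and a longitudinal arm (two
  scans per subject), with linear gestational-age trajectories, subject
  random intercepts, subject-specific slopes and scan-level noise.

Default cohort geometry follows the study being emulated: 62
cross-sectional subjects with GA ~ 30.72 +/- 4.74 weeks, 17 longitudinal
pairs with first scans at 27.23 +/- 3.00 weeks and a mean inter-scan
interval of 6.87 weeks.  Trajectory slopes default to the published
cross-sectional slopes; absolute levels at the 28-week reference are
conventions (chosen to sit in the published placental range) because no
absolute values are printed for this protocol, and are fully
configurable.  Everything is driven by explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import SimulationSpecError
from .maps import ParameterMaps, ScanMetrics
from .cohort import SubjectObservation, GA_MIN_WEEKS, GA_MAX_WEEKS
from .fitting import FAST_ADC_LOWER_BOUND
from .models import PARAM_NAMES, model_signal, params_type
from .scheme import AcquisitionScheme, default_zebra_scheme
from .volume import VolumeSeries

__all__ = [
    "NoiseSpec",
    "TrajectorySpec",
    "CohortSpec",
    "HeterogeneitySpec",
    "ga_trajectory",
    "simulate_voxel_signal",
    "simulate_phantom",
    "simulate_cohort",
    "default_trajectories",
    "observations_to_frame",
    "DEFAULT_PHANTOM_PARAMS",
]

_NOISE_MODELS = ("none", "gaussian", "rician")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description: model, absolute sigma, seed."""

    model: str = "gaussian"
    sigma: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model not in _NOISE_MODELS:
            raise SimulationSpecError(
                f"unknown noise model {self.model!r}; known: {_NOISE_MODELS}"
            )
        if self.sigma < 0:
            raise SimulationSpecError(f"sigma must be >= 0, got {self.sigma}")


def _apply_noise(signal: np.ndarray, noise: NoiseSpec,
                 rng: np.random.Generator) -> np.ndarray:
    if noise.model == "none" or noise.sigma == 0.0:
        return signal.copy()
    if noise.model == "gaussian":
        return signal + rng.normal(0.0, noise.sigma, size=signal.shape)
    re = signal + rng.normal(0.0, noise.sigma, size=signal.shape)
    im = rng.normal(0.0, noise.sigma, size=signal.shape)
    return np.hypot(re, im)


def simulate_voxel_signal(params, scheme: AcquisitionScheme,
                          noise: NoiseSpec = NoiseSpec(model="none"),
                          model_id: Optional[str] = None) -> np.ndarray:
    """Forward-model signal for one voxel under the given noise model.

    The model is inferred from the parameter type unless ``model_id`` is
    given.  The noise seed fully determines the output.
    """
    if model_id is None:
        model_id = "t2s_adc" if type(params).__name__ == "T2sADCParams" else "t2s_ivim"
    clean = model_signal(model_id, params, scheme)
    rng = np.random.default_rng(noise.seed)
    return _apply_noise(clean, noise, rng)


# ---------------------------------------------------------------------------
# phantoms

#: Nominal mid-gestation placental parameter values used as phantom bases.
DEFAULT_PHANTOM_PARAMS = {
    "t2s_adc": {"s0": 100.0, "t2s": 60.0, "adc": 1.8e-3},
    "t2s_ivim": {"s0": 100.0, "f": 0.30, "d_star": 30e-3, "t2s_p": 85.0,
                 "adc": 1.6e-3, "t2s_d": 95.0},
}

# phantom truth must stay strictly inside the default fitting bounds
_PARAM_LIMITS = {
    "s0": (0.0, math.inf),
    "t2s": (5.0, 500.0),
    "t2s_p": (5.0, 500.0),
    "t2s_d": (5.0, 500.0),
    "adc": (0.0, 3e-3),
    "d_star": (FAST_ADC_LOWER_BOUND, 0.5),
    "f": (0.0, 1.0),
}


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Spatial texture of phantom ground truth.

    smooth_amplitude : fractional amplitude of the low-frequency field
        applied multiplicatively to every varying parameter
    n_modes : number of random-phase cosine modes in the smooth field
    n_lobules : number of lobule seed points (0 disables lobulation)
    lobule_depth : fractional T2* depression at inter-lobule rims
    rim_width : rim thickness in voxels
    vary : parameter names the smooth field modulates
    """

    smooth_amplitude: float = 0.10
    n_modes: int = 3
    n_lobules: int = 0
    lobule_depth: float = 0.2
    rim_width: float = 1.0
    vary: tuple = ("t2s", "adc", "t2s_p", "t2s_d", "d_star", "f")

    def __post_init__(self) -> None:
        if self.smooth_amplitude < 0 or self.lobule_depth < 0:
            raise SimulationSpecError("heterogeneity amplitudes must be >= 0")
        if self.n_lobules < 0 or self.n_modes < 1 or self.rim_width <= 0:
            raise SimulationSpecError("bad heterogeneity spec")


def _smooth_field(shape, rng: np.random.Generator, n_modes: int) -> np.ndarray:
    """Sum of low-frequency cosine modes, normalised to [-1, 1]."""
    grids = np.meshgrid(*[np.linspace(0.0, 1.0, s) for s in shape],
                        indexing="ij")
    out = np.zeros(shape)
    for _ in range(n_modes):
        freq = rng.uniform(0.5, 1.5, size=3)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
        mode = np.ones(shape)
        for g, fr, ph in zip(grids, freq, phase):
            mode = mode * np.cos(2.0 * np.pi * fr * g + ph)
        out += mode
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def _ellipsoid_mask(shape) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    center = [(s - 1) / 2.0 for s in shape]
    semi = [max(s / 2.0, 1.0) for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _lobule_rim(shape, mask, rng: np.random.Generator, n_lobules: int,
                rim_width: float) -> np.ndarray:
    """1 at boundaries between lobule domains, 0 deep inside a lobule."""
    coords = np.argwhere(mask)
    centers = coords[rng.choice(len(coords), size=min(n_lobules, len(coords)),
                                replace=False)]
    grids = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                 indexing="ij"), axis=-1).astype(float)
    d = np.linalg.norm(grids[..., None, :] - centers[None, None, None, :, :],
                       axis=-1)
    d.sort(axis=-1)
    if d.shape[-1] < 2:
        return np.zeros(shape)
    gap = d[..., 1] - d[..., 0]  # small gap = Voronoi boundary
    return np.exp(-((gap / rim_width) ** 2))


def simulate_phantom(shape, model_id: str,
                     heterogeneity: Optional[HeterogeneitySpec] = None,
                     noise: NoiseSpec = NoiseSpec(model="none"),
                     seed: int = 0,
                     base_params: Optional[dict] = None,
                     scheme: Optional[AcquisitionScheme] = None):
    """Simulate a heterogeneous placenta phantom with known truth maps.

    Returns ``(VolumeSeries, ParameterMaps)`` where the parameter maps
    hold the generating per-voxel truth.  ``seed`` drives both the truth
    fields and the measurement noise, so a seed reproduces the phantom
    bit-for-bit.  Heterogeneity that pushes any parameter outside the
    model's fitting bounds raises :class:`SimulationSpecError`.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or shape[0] < 4 or shape[1] < 4 or shape[2] < 2:
        raise SimulationSpecError(f"phantom shape must be >= 4x4x2, got {shape}")
    if model_id not in PARAM_NAMES:
        raise KeyError(f"unknown model id {model_id!r}")
    het = heterogeneity or HeterogeneitySpec()
    scheme = scheme or default_zebra_scheme()
    base = dict(DEFAULT_PHANTOM_PARAMS[model_id])
    if base_params:
        base.update(base_params)
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(shape)

    fields = {}
    for name in PARAM_NAMES[model_id]:
        value = float(base[name])
        arr = np.full(shape, value)
        if name in het.vary and het.smooth_amplitude > 0:
            arr = value * (1.0 + het.smooth_amplitude
                           * _smooth_field(shape, rng, het.n_modes))
        fields[name] = arr
    if het.n_lobules > 0 and het.lobule_depth > 0:
        rim = _lobule_rim(shape, mask, rng, het.n_lobules, het.rim_width)
        for name in ("t2s", "t2s_p", "t2s_d"):
            if name in fields:
                fields[name] = fields[name] * (1.0 - het.lobule_depth * rim)

    for name, arr in fields.items():
        lo, hi = _PARAM_LIMITS[name]
        bad = mask & ((arr < lo) | (arr > hi))
        if bad.any():
            raise SimulationSpecError(
                f"heterogeneity drives {name} outside [{lo}, {hi}] in "
                f"{int(bad.sum())} voxel(s); reduce the amplitude"
            )
    if model_id == "t2s_ivim":
        bad = mask & (fields["d_star"] < fields["adc"])
        if bad.any():
            raise SimulationSpecError(
                "heterogeneity makes d_star < adc; compartments would be "
                "unidentifiable"
            )

    ptype = params_type(model_id)
    signal = np.zeros(shape + (len(scheme),))
    noise_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    for idx in zip(*np.nonzero(mask)):
        params = ptype(**{n: float(fields[n][idx]) for n in PARAM_NAMES[model_id]})
        clean = model_signal(model_id, params, scheme)
        signal[idx] = _apply_noise(clean, noise, noise_rng)

    series = VolumeSeries(signal=signal, mask=mask, scheme=scheme)
    converged = mask.copy()
    truth_maps = {n: np.where(mask, fields[n], np.nan) for n in PARAM_NAMES[model_id]}
    truth = ParameterMaps(model_id=model_id, maps=truth_maps,
                          converged=converged,
                          residual_norm=np.where(mask, 0.0, np.nan),
                          mask=mask)
    return series, truth


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class TrajectorySpec:
    """Linear gestational-age ground truth for one whole-organ metric.

    value(ga) = value_at_ref + slope * (ga - ga_ref), GA in weeks.

    between_subject_sd : SD of the subject random intercept
    within_subject_sd : SD of scan-level measurement noise
    slope_between_subject_sd : SD of subject-specific slopes around
        ``slope`` (controls the ground-truth consistency ratio)
    """

    metric: str
    value_at_ref: float
    slope: float
    ga_ref: float = 28.0
    between_subject_sd: float = 0.0
    within_subject_sd: float = 0.0
    slope_between_subject_sd: float = 0.0

    def __post_init__(self) -> None:
        for sd in (self.between_subject_sd, self.within_subject_sd,
                   self.slope_between_subject_sd):
            if sd < 0:
                raise SimulationSpecError("trajectory SDs must be >= 0")
        for ga in (GA_MIN_WEEKS, GA_MAX_WEEKS):
            v = self.value_at_ref + self.slope * (ga - self.ga_ref)
            if self.metric.endswith(".f"):
                if not 0.0 <= v <= 1.0:
                    raise SimulationSpecError(
                        f"{self.metric}: trajectory leaves [0, 1] at GA {ga}"
                    )
            elif "t2s" in self.metric and v <= 0:
                raise SimulationSpecError(
                    f"{self.metric}: trajectory non-positive at GA {ga}"
                )
            elif "adc" in self.metric and v < 0:
                raise SimulationSpecError(
                    f"{self.metric}: trajectory negative at GA {ga}"
                )


def ga_trajectory(spec: TrajectorySpec, ga_weeks: float) -> float:
    """Ground-truth metric value at ``ga_weeks`` under a linear trend."""
    if not GA_MIN_WEEKS <= ga_weeks <= GA_MAX_WEEKS:
        raise SimulationSpecError(
            f"gestational age {ga_weeks} outside [{GA_MIN_WEEKS}, {GA_MAX_WEEKS}]"
        )
    return spec.value_at_ref + spec.slope * (ga_weeks - spec.ga_ref)


# Cross-sectional slopes follow the published values; residual scatter is
# back-solved from the published R^2 via sigma_res = |slope|*sigma_GA*
# sqrt((1-R^2)/R^2) with sigma_GA = 4.74 weeks, then split into a
# between-subject intercept SD and a smaller scan-level SD.  Slope
# dispersion across subjects follows the published longitudinal SDs.
_DEFAULT_TRAJ = (
    # metric, value@28wk, slope/wk, between_sd, within_sd, slope_sd
    ("t2s_adc.t2s", 90.0, -2.54, 8.68, 2.5, 1.44),
    ("t2s_adc.adc", 1.8e-3, -0.03e-3, 0.187e-3, 0.05e-3, 0.05e-3),
    ("ivim.t2s_perf", 85.0, -2.35, 9.34, 2.5, 1.74),
    ("ivim.adc_perf", 30e-3, -0.03e-3, 0.241e-3, 0.05e-3, 0.08e-3),
    ("ivim.t2s_diff", 95.0, -1.91, 11.29, 2.5, 2.34),
    ("ivim.adc_diff", 1.6e-3, -0.004e-3, 0.0224e-3, 0.004e-3, 0.004e-3),
    ("ivim.f", 0.32, 0.005, 0.031, 0.008, 0.0193),
)


def default_trajectories() -> dict:
    """Default per-metric trajectory calibration (see module docstring)."""
    return {
        m: TrajectorySpec(metric=m, value_at_ref=v, slope=s,
                          between_subject_sd=bsd, within_subject_sd=wsd,
                          slope_between_subject_sd=ssd)
        for m, v, s, bsd, wsd, ssd in _DEFAULT_TRAJ
    }


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated cohort.

    The noise spec's model toggles scan-level noise ("none" switches all
    random effects off for exact-recovery checks); its sigma scales every
    metric's within/between SDs (1.0 = as calibrated).
    """

    n_cross: int = 62
    n_long_pairs: int = 17
    ga_mean: float = 30.72
    ga_sd: float = 4.74
    long_ga1_mean: float = 27.23
    long_ga1_sd: float = 3.00
    interval_mean: float = 6.87
    interval_sd: float = 1.5
    trajectories: dict = field(default_factory=default_trajectories)
    noise: NoiseSpec = NoiseSpec(model="gaussian", sigma=1.0, seed=0)
    n_voxels_nominal: int = 500
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_cross < 0 or self.n_long_pairs < 0:
            raise SimulationSpecError("cohort counts must be >= 0")
        if self.interval_mean <= 0:
            raise SimulationSpecError("inter-scan interval mean must be > 0")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, max_retries: int) -> float:
    if sd == 0:
        if not lo <= mean <= hi:
            raise SimulationSpecError(f"mean {mean} outside [{lo}, {hi}]")
        return mean
    for _ in range(max_retries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise SimulationSpecError(
        f"could not draw a value in [{lo}, {hi}] from N({mean}, {sd}^2) "
        f"after {max_retries} tries"
    )


def _clip_metric(metric: str, value: float) -> float:
    if metric.endswith(".f"):
        return min(max(value, 0.0), 1.0)
    if "t2s" in metric:
        return max(value, 1e-6)
    if "adc" in metric:
        return max(value, 0.0)
    return value


def simulate_cohort(spec: CohortSpec, seed: Optional[int] = None):
    """Draw a cross-sectional and a longitudinal metric-level cohort.

    Returns ``(cross_obs, long_pairs, truth)``: single observations for
    the cross-sectional arm, ordered scan pairs for the longitudinal arm,
    and a truth record holding the generating trajectories, every
    longitudinal subject's true slope per metric, and the drawn GAs and
    intervals.
    """
    if seed is None:
        seed = spec.noise.seed if spec.noise.seed is not None else 0
    rng = np.random.default_rng(seed)
    noise_on = spec.noise.model != "none"
    scale = spec.noise.sigma if noise_on else 0.0
    trajs = spec.trajectories

    def metric_value(traj, ga, subj_offset, subj_slope):
        v = traj.value_at_ref + subj_slope * (ga - traj.ga_ref) + subj_offset
        v += rng.normal(0.0, traj.within_subject_sd * scale) if scale else 0.0
        return _clip_metric(traj.metric, v)

    cross = []
    for i in range(spec.n_cross):
        ga = _truncated_normal(rng, spec.ga_mean, spec.ga_sd,
                               GA_MIN_WEEKS, GA_MAX_WEEKS, spec.max_retries)
        values = {}
        for m, traj in trajs.items():
            offset = rng.normal(0.0, traj.between_subject_sd * scale) if scale else 0.0
            values[m] = metric_value(traj, ga, offset, traj.slope)
        cross.append(SubjectObservation(
            subject_id=f"cs{i:03d}", ga_weeks=ga,
            metrics=ScanMetrics(values=values, n_voxels_used=spec.n_voxels_nominal),
        ))

    long_pairs = []
    true_slopes: dict = {m: [] for m in trajs}
    gas1, intervals = [], []
    for i in range(spec.n_long_pairs):
        for _ in range(spec.max_retries):
            ga1 = _truncated_normal(rng, spec.long_ga1_mean, spec.long_ga1_sd,
                                    GA_MIN_WEEKS, GA_MAX_WEEKS, spec.max_retries)
            dt = rng.normal(spec.interval_mean, spec.interval_sd * (1 if noise_on else 0))
            if dt > 0.5 and ga1 + dt <= GA_MAX_WEEKS:
                break
        else:
            raise SimulationSpecError(
                "could not draw a valid longitudinal scan interval"
            )
        ga2 = ga1 + dt
        gas1.append(ga1)
        intervals.append(dt)
        sid = f"lg{i:03d}"
        subj_offsets = {}
        subj_slopes = {}
        for m, traj in trajs.items():
            subj_offsets[m] = (rng.normal(0.0, traj.between_subject_sd * scale)
                               if scale else 0.0)
            subj_slopes[m] = traj.slope + (
                rng.normal(0.0, traj.slope_between_subject_sd) if noise_on else 0.0
            )
            true_slopes[m].append(subj_slopes[m])
        obs = []
        for ga in (ga1, ga2):
            values = {m: metric_value(trajs[m], ga, subj_offsets[m],
                                      subj_slopes[m]) for m in trajs}
            obs.append(SubjectObservation(
                subject_id=sid, ga_weeks=ga,
                metrics=ScanMetrics(values=values,
                                    n_voxels_used=spec.n_voxels_nominal),
            ))
        long_pairs.append(tuple(obs))

    truth = {
        "seed": seed,
        "trajectories": {m: t for m, t in trajs.items()},
        "true_slopes": {m: list(v) for m, v in true_slopes.items()},
        "ga_first_scan": gas1,
        "intervals": intervals,
    }
    return cross, long_pairs, truth


def observations_to_frame(obs: Sequence[SubjectObservation]) -> pd.DataFrame:
    """Flatten observations to a metrics table (one row per scan)."""
    rows = []
    for o in obs:
        row = {"subject_id": o.subject_id, "ga_weeks": o.ga_weeks,
               "n_voxels_used": o.metrics.n_voxels_used}
        row.update(o.metrics.values)
        rows.append(row)
    return pd.DataFrame(rows)
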