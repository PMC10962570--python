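"""Per-voxel parameter estimation: brute-force grid init + bounded refinement.

The "brute2fine" strategy fits a voxel in two stages:

1. **brute**: evaluate the forward model on a coarse grid over the
   nonlinear parameters; at every grid point the signal scale s0 has a
   closed-form least-squares solution (the model is linear in s0), so s0
   is profiled out analytically rather than gridded.  The best grid point
   seeds stage two.
2. **fine**: bounded nonlinear least squares (trust-region reflective)
   over all parameters including s0, minimising the unweighted Gaussian
   sum of squared residuals.

For the bicompartmental model the pseudo-diffusion coefficient is
restricted from below (``fast_adc_lower_bound``, default 3.0e-3 mm^2/s —
the diffusivity of free water at body temperature) and the tissue ADC
from above by the same value, so the "perfusing" label always belongs to
the faster compartment and label swapping cannot occur.

The whole procedure is deterministic: identical inputs give bit-identical
results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import yaml
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import DegenerateSignalError, SchemeValidationError
from .models import (
    MODEL_IDS,
    PARAM_NAMES,
    model_signal,
    params_type,
)
from .scheme import AcquisitionScheme

__all__ = [
    "GridSpec",
    "FitConfig",
    "FitResult",
    "GridEvaluator",
    "brute_grid_search",
    "refine_fit",
    "fit_voxel",
    "DiffusionRelaxometryFit",
    "FAST_ADC_LOWER_BOUND",
]

#: Default lower bound on the pseudo-diffusion coefficient, mm^2/s
#: (free-water diffusivity at 37 C).
FAST_ADC_LOWER_BOUND = 3.0e-3

# nonlinear (gridded) parameters per model, in vector order after s0
_NONLINEAR = {
    "t2s_adc": ("t2s", "adc"),
    "t2s_ivim": ("f", "d_star", "t2s_p", "adc", "t2s_d"),
}

_T2S_GRID = tuple(np.arange(20.0, 201.0, 20.0))           # ms
_ADC_GRID = tuple(np.arange(0.5e-3, 3.01e-3, 0.5e-3))     # mm^2/s

_DEFAULT_GRIDS = {
    "t2s_adc": {"t2s": _T2S_GRID, "adc": _ADC_GRID},
    "t2s_ivim": {
        "f": (0.1, 0.3, 0.5, 0.7),
        "d_star": (5e-3, 10e-3, 20e-3, 50e-3, 100e-3),
        "t2s_p": _T2S_GRID,
        "adc": _ADC_GRID,
        "t2s_d": _T2S_GRID,
    },
}

_DEFAULT_BOUNDS = {
    "t2s_adc": {"s0": (0.0, np.inf), "t2s": (5.0, 500.0), "adc": (0.0, 3e-3)},
    "t2s_ivim": {
        "s0": (0.0, np.inf),
        "f": (0.0, 1.0),
        "d_star": (FAST_ADC_LOWER_BOUND, 0.5),
        "t2s_p": (5.0, 500.0),
        "adc": (0.0, 3e-3),
        "t2s_d": (5.0, 500.0),
    },
}


@dataclass(frozen=True)
class GridSpec:
    """Ordered value lists for the gridded (nonlinear) parameters.

    ``values`` maps parameter name -> 1D array of candidate values; s0 is
    never gridded (it is profiled out analytically).  For the
    bicompartmental model every ``d_star`` grid value must respect
    ``fast_adc_lower_bound``.
    """

    values: dict
    fast_adc_lower_bound: float = FAST_ADC_LOWER_BOUND

    def __post_init__(self) -> None:
        if self.fast_adc_lower_bound <= 0:
            raise ValueError("fast_adc_lower_bound must be > 0")
        clean = {}
        for name, vals in self.values.items():
            arr = np.atleast_1d(np.asarray(vals, dtype=float))
            if arr.size == 0:
                raise ValueError(f"empty grid for parameter {name!r}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite grid value for parameter {name!r}")
            clean[name] = arr
        object.__setattr__(self, "values", clean)

    @classmethod
    def default(cls, model_id: str,
                fast_adc_lower_bound: float = FAST_ADC_LOWER_BOUND) -> "GridSpec":
        if model_id not in MODEL_IDS:
            raise KeyError(f"unknown model id {model_id!r}; known: {MODEL_IDS}")
        vals = {k: np.asarray(v) for k, v in _DEFAULT_GRIDS[model_id].items()}
        if "d_star" in vals:
            vals["d_star"] = vals["d_star"][vals["d_star"] >= fast_adc_lower_bound]
            if vals["d_star"].size == 0:
                raise ValueError(
                    "fast_adc_lower_bound excludes every default d_star grid value"
                )
        return cls(values=vals, fast_adc_lower_bound=fast_adc_lower_bound)

    @classmethod
    def from_mapping(cls, mapping: dict,
                     fast_adc_lower_bound: float = FAST_ADC_LOWER_BOUND) -> "GridSpec":
        """Build from a config mapping; each entry is either an explicit
        list or ``{"start": a, "stop": b, "step": s}`` (inclusive)."""
        values = {}
        for name, spec in mapping.items():
            if isinstance(spec, dict):
                a, b, s = float(spec["start"]), float(spec["stop"]), float(spec["step"])
                if s <= 0 or b < a:
                    raise ValueError(f"bad range for grid parameter {name!r}")
                values[name] = np.arange(a, b + 0.5 * s, s)
            else:
                values[name] = np.asarray(spec, dtype=float)
        return cls(values=values, fast_adc_lower_bound=fast_adc_lower_bound)


@dataclass(frozen=True)
class FitConfig:
    """Everything that parametrises a brute2fine fit of one model."""

    model_id: str
    grid: GridSpec
    bounds: dict
    ftol: float = 1e-10
    xtol: float = 1e-12
    max_iter: int = 500
    n_starts: int = 3
    fast_adc_lower_bound: float = FAST_ADC_LOWER_BOUND

    @classmethod
    def default(cls, model_id: str, **overrides) -> "FitConfig":
        if model_id not in MODEL_IDS:
            raise KeyError(f"unknown model id {model_id!r}; known: {MODEL_IDS}")
        fast = overrides.pop("fast_adc_lower_bound", FAST_ADC_LOWER_BOUND)
        grid = overrides.pop("grid", None) or GridSpec.default(model_id, fast)
        bounds = dict(_DEFAULT_BOUNDS[model_id])
        bounds.update(overrides.pop("bounds", {}))
        if "d_star" in bounds:
            lo, hi = bounds["d_star"]
            bounds["d_star"] = (max(lo, fast), hi)
        return cls(model_id=model_id, grid=grid, bounds=bounds,
                   fast_adc_lower_bound=fast, **overrides)

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        """Load a fit configuration from a YAML file.

        Recognised keys: ``model`` (required), ``grid`` (mapping),
        ``bounds`` (mapping name -> [lo, hi]), ``ftol``, ``xtol``,
        ``max_iter``, ``n_starts``, ``fast_adc_lower_bound``.
        """
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        model_id = raw.pop("model", None) or raw.pop("model_id", None)
        if model_id is None:
            raise ValueError(f"{path}: config must name a 'model'")
        kwargs = {}
        fast = float(raw.pop("fast_adc_lower_bound", FAST_ADC_LOWER_BOUND))
        if "grid" in raw:
            kwargs["grid"] = GridSpec.from_mapping(raw.pop("grid"), fast)
        if "bounds" in raw:
            kwargs["bounds"] = {
                k: (float(v[0]), float(v[1])) for k, v in raw.pop("bounds").items()
            }
        for key in ("ftol", "xtol"):
            if key in raw:
                kwargs[key] = float(raw.pop(key))
        for key in ("max_iter", "n_starts"):
            if key in raw:
                kwargs[key] = int(raw.pop(key))
        if raw:
            raise ValueError(f"{path}: unrecognised config keys {sorted(raw)}")
        return cls.default(model_id, fast_adc_lower_bound=fast, **kwargs)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-voxel fit.

    ``params`` is None for a degenerate voxel (all-zero / non-finite
    signal); ``residual_norm`` is the sum of squared signal residuals at
    the returned point.
    """

    params: object
    residual_norm: float
    converged: bool
    n_iterations: int
    init_params: object
    model_id: str


def _check_signal(signal: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size != len(scheme):
        raise SchemeValidationError(
            f"signal has {signal.size} measurements, scheme has {len(scheme)}"
        )
    if not np.all(np.isfinite(signal)):
        raise DegenerateSignalError("signal contains non-finite values")
    if not np.any(signal > 0):
        raise DegenerateSignalError("signal has no positive entries")
    return signal


class GridEvaluator:
    """Precomputed unit-s0 model signals on a parameter grid.

    Building the (n_grid_points, n_measurements) design matrix costs far
    more than scoring one voxel against it, so volume fitting constructs
    one evaluator per (model, grid, scheme) and reuses it for every voxel.
    """

    def __init__(self, model_id: str, grid: GridSpec, scheme: AcquisitionScheme):
        if model_id not in MODEL_IDS:
            raise KeyError(f"unknown model id {model_id!r}; known: {MODEL_IDS}")
        names = _NONLINEAR[model_id]
        missing = [n for n in names if n not in grid.values]
        if missing:
            raise ValueError(f"grid is missing parameters {missing} for {model_id}")
        axes = [grid.values[n] for n in names]
        mesh = np.meshgrid(*axes, indexing="ij")
        combos = np.column_stack([m.ravel() for m in mesh])
        if model_id == "t2s_ivim":
            keep = combos[:, names.index("d_star")] >= combos[:, names.index("adc")]
            keep &= combos[:, names.index("d_star")] >= grid.fast_adc_lower_bound
            combos = combos[keep]
            if combos.shape[0] == 0:
                raise ValueError("grid admits no combination with d_star >= adc")
        self.model_id = model_id
        self.param_names = names
        self.combos = combos
        self.scheme = scheme
        self.matrix = self._signals(combos, scheme)
        self._row_sq = np.einsum("ij,ij->i", self.matrix, self.matrix)

    def _signals(self, combos: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
        dte = (scheme.echo_times - scheme.te_min)[None, :]
        b = scheme.b_values[None, :]
        c = {n: combos[:, i][:, None] for i, n in enumerate(self.param_names)}
        if self.model_id == "t2s_adc":
            return np.exp(-dte / c["t2s"] - b * c["adc"])
        fast = np.exp(-b * c["d_star"] - dte / c["t2s_p"])
        slow = np.exp(-b * c["adc"] - dte / c["t2s_d"])
        return c["f"] * fast + (1.0 - c["f"]) * slow

    def rank(self, signal: np.ndarray, k: int = 1):
        """Best ``k`` grid points for ``signal`` with profiled s0.

        Returns a list of parameter objects ordered by ascending residual
        sum of squares.  Ties break toward the lower grid index, so the
        result is deterministic.
        """
        proj = self.matrix @ signal
        s0 = np.maximum(proj, 0.0) / self._row_sq
        # ||y - s0*m||^2 = ||y||^2 - 2*s0*proj + s0^2*||m||^2
        rss = float(signal @ signal) - 2.0 * s0 * proj + s0 * s0 * self._row_sq
        k = min(k, rss.size)
        if k == 1:
            order = np.array([int(np.argmin(rss))])
        else:
            part = np.argpartition(rss, k - 1)[:k]
            order = part[np.argsort(rss[part], kind="stable")]
        ptype = params_type(self.model_id)
        out = []
        for idx in order:
            kwargs = dict(zip(self.param_names, self.combos[idx]))
            out.append(ptype(s0=float(s0[idx]), **{k_: float(v) for k_, v in kwargs.items()}))
        return out


def brute_grid_search(signal, scheme: AcquisitionScheme, model_id: str,
                      grid: Optional[GridSpec] = None,
                      evaluator: Optional[GridEvaluator] = None):
    """Exhaustive grid search for the best initializer.

    Minimises the sum of squared residuals over every grid combination of
    the nonlinear parameters; s0 takes its closed-form least-squares value
    (clipped at 0) at each grid point and is not gridded.
    """
    signal = _check_signal(signal, scheme)
    if evaluator is None:
        evaluator = GridEvaluator(model_id, grid or GridSpec.default(model_id), scheme)
    return evaluator.rank(signal, k=1)[0]


def _vector_signal(model_id: str, x: np.ndarray, scheme: AcquisitionScheme) -> np.ndarray:
    """Forward signal from the raw parameter vector (no dataclass checks,
    safe for intermediate optimizer iterates)."""
    dte = scheme.echo_times - scheme.te_min
    b = scheme.b_values
    if model_id == "t2s_adc":
        s0, t2s, adc = x
        return s0 * np.exp(-dte / t2s - b * adc)
    s0, f, d_star, t2s_p, adc, t2s_d = x
    return s0 * (f * np.exp(-b * d_star - dte / t2s_p)
                 + (1.0 - f) * np.exp(-b * adc - dte / t2s_d))


def _bounds_arrays(model_id: str, bounds: dict):
    names = PARAM_NAMES[model_id]
    lo = np.array([bounds[n][0] for n in names], dtype=float)
    hi = np.array([bounds[n][1] for n in names], dtype=float)
    # t2s values of 0 are not evaluable; keep strictly positive floors
    for i, n in enumerate(names):
        if n.startswith("t2s") and lo[i] <= 0:
            lo[i] = 1e-3
    return lo, hi


def _finalize_params(model_id: str, x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    x = np.clip(x, lo, hi)
    if model_id == "t2s_ivim" and x[4] > x[2]:  # adc > d_star: relabel
        s0, f, d_star, t2s_p, adc, t2s_d = x
        x = np.array([s0, 1.0 - f, adc, t2s_d, d_star, t2s_p])
    return params_type(model_id).from_array(x)


def refine_fit(signal, scheme: AcquisitionScheme, model_id: str, init,
               bounds: Optional[dict] = None, ftol: float = 1e-10,
               xtol: float = 1e-12, max_iter: int = 500) -> FitResult:
    """Bounded nonlinear least-squares refinement from ``init``.

    Never raises on non-convergence (returns ``converged=False`` with the
    last iterate) and never returns a point with a larger residual norm
    than the initializer.
    """
    signal = _check_signal(signal, scheme)
    bounds = bounds if bounds is not None else dict(_DEFAULT_BOUNDS[model_id])
    lo, hi = _bounds_arrays(model_id, bounds)
    x0 = np.clip(init.as_array(), lo, hi)
    init_resid = _vector_signal(model_id, x0, scheme) - signal

    def residuals(x):
        return _vector_signal(model_id, x, scheme) - signal

    if not np.all(np.isfinite(init_resid)):
        raise DegenerateSignalError("objective is non-finite at the initializer")
    try:
        res = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            ftol=ftol, xtol=xtol, gtol=1e-12,
            max_nfev=max_iter * (len(x0) + 1),
        )
        x_best, cost, nfev, status = res.x, 2.0 * res.cost, res.nfev, res.status
    except ValueError as exc:  # non-finite residuals mid-path
        raise DegenerateSignalError(f"optimizer failed: {exc}") from None
    init_norm = float(init_resid @ init_resid)
    if cost > init_norm:
        x_best, cost, status = x0, init_norm, 0
    params = _finalize_params(model_id, x_best, lo, hi)
    return FitResult(
        params=params,
        residual_norm=float(cost),
        converged=bool(status > 0),
        n_iterations=int(nfev),
        init_params=init,
        model_id=model_id,
    )


def fit_voxel(signal, scheme: AcquisitionScheme, model_id: str,
              config: Optional[FitConfig] = None,
              evaluator: Optional[GridEvaluator] = None) -> FitResult:
    """Brute2fine fit of one voxel: grid search, then bounded refinement.

    With ``n_starts > 1`` the refinement is run from the best grid points
    in order and stopped early once a refinement converges with an
    essentially perfect fit; the lowest-residual result wins (ties keep
    the earlier start, so the procedure is deterministic).
    """
    if config is None:
        config = FitConfig.default(model_id)
    if config.model_id != model_id:
        raise TypeError(
            f"config is for model {config.model_id!r}, requested {model_id!r}"
        )
    signal = _check_signal(signal, scheme)
    if evaluator is None:
        evaluator = GridEvaluator(model_id, config.grid, scheme)
    starts = evaluator.rank(signal, k=max(1, config.n_starts))
    sig_sq = float(signal @ signal)
    best: Optional[FitResult] = None
    for start in starts:
        result = refine_fit(
            signal, scheme, model_id, start, bounds=config.bounds,
            ftol=config.ftol, xtol=config.xtol, max_iter=config.max_iter,
        )
        result = dataclasses.replace(result, init_params=starts[0])
        if best is None or result.residual_norm < best.residual_norm:
            best = result
        if best.converged and best.residual_norm <= 1e-16 * sig_sq:
            break
    return best


def _as_scheme(X) -> AcquisitionScheme:
    if isinstance(X, AcquisitionScheme):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 5):
        raise ValueError(
            "X must be an AcquisitionScheme or an array of shape (n, 2) "
            "with columns (b, TE_ms) or (n, 5) with (gx, gy, gz, b, TE_ms)"
        )
    if arr.shape[1] == 5:
        return AcquisitionScheme(b_values=arr[:, 3], directions=arr[:, :3],
                                 echo_times=arr[:, 4])
    dirs = np.tile([0.0, 0.0, 1.0], (arr.shape[0], 1))
    return AcquisitionScheme(b_values=arr[:, 0], directions=dirs,
                             echo_times=arr[:, 1])


class DiffusionRelaxometryFit(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator wrapping the brute2fine voxel fit.

    Parameters
    ----------
    model : {"t2s_adc", "t2s_ivim"}
        Which combined T2*-diffusion signal model to fit.
    grid : GridSpec, optional
        Initialization grid; the model's default grid if None.
    bounds : dict, optional
        Per-parameter (lo, hi) refinement bounds, merged over defaults.
    fast_adc_lower_bound : float
        Lower bound on the pseudo-diffusion coefficient, mm^2/s.
    ftol, max_iter, n_starts
        Refinement stopping tolerance, iteration cap, and number of
        ranked grid starts.

    Attributes
    ----------
    params_ : T2sADCParams or T2sIVIMParams
        Fitted voxel parameters.
    residual_norm_ : float
        Sum of squared signal residuals at the fit.
    converged_ : bool
    n_iter_ : int
    init_params_ : parameters chosen by the grid search
    result_ : FitResult

    Examples
    --------
    >>> from zebrafit import default_zebra_scheme, t2sadc_signal, T2sADCParams
    >>> scheme = default_zebra_scheme()
    >>> y = t2sadc_signal(T2sADCParams(s0=1.0, t2s=60.0, adc=1.8e-3), scheme)
    >>> est = DiffusionRelaxometryFit(model="t2s_adc").fit(scheme, y)
    >>> round(est.params_.t2s, 3)
    60.0
    """

    def __init__(self, model: str = "t2s_adc", grid: Optional[GridSpec] = None,
                 bounds: Optional[dict] = None,
                 fast_adc_lower_bound: float = FAST_ADC_LOWER_BOUND,
                 ftol: float = 1e-10, max_iter: int = 500, n_starts: int = 3):
        self.model = model
        self.grid = grid
        self.bounds = bounds
        self.fast_adc_lower_bound = fast_adc_lower_bound
        self.ftol = ftol
        self.max_iter = max_iter
        self.n_starts = n_starts

    def _config(self) -> FitConfig:
        return FitConfig.default(
            self.model,
            grid=self.grid,
            bounds=self.bounds or {},
            fast_adc_lower_bound=self.fast_adc_lower_bound,
            ftol=self.ftol,
            max_iter=self.max_iter,
            n_starts=self.n_starts,
        )

    def fit(self, X, y) -> "DiffusionRelaxometryFit":
        """Fit the signal model to one voxel.

        X is the acquisition scheme (or a (n, 2)/(n, 5) numeric array);
        y the measured signal vector.
        """
        scheme = _as_scheme(X)
        result = fit_voxel(np.asarray(y, dtype=float), scheme, self.model,
                           config=self._config())
        self.scheme_ = scheme
        self.result_ = result
        self.params_ = result.params
        self.residual_norm_ = result.residual_norm
        self.converged_ = result.converged
        self.n_iter_ = result.n_iterations
        self.init_params_ = result.init_params
        return self

    def predict(self, X) -> np.ndarray:
        """Model signal at the fitted parameters for scheme ``X``."""
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted; call fit first")
        return model_signal(self.model, self.params_, _as_scheme(X))
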