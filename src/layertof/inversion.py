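"""Optical-property estimation by nonlinear least squares.

Three fitters share one machinery:

* :func:`fit_homogeneous_td` — semi-infinite closed-form model fitted to a
  single transient; fast, used to initialize the layered fits.
* :func:`fit_two_layer_td` — the primary path: Levenberg-Marquardt fit of
  the two-layer time-domain model to a single-distance transient with the
  top thickness fixed (known from ultrasound or phantom specification).
* :func:`fit_two_layer_cw` — the continuous-wave comparison baseline: fit
  of the layered steady-state model to multi-distance intensities.

Positivity of the coefficients is enforced by optimizing in log space, so
the Levenberg-Marquardt steps themselves are unconstrained.  The default
loss weights residuals by the per-bin Poisson standard deviation
(``1/sqrt(max(counts, 1))``) for count data and falls back to a scale-free
log-domain loss for model-density transients; a Poisson-deviance loss is
also available.  The default fit window runs from the bin where the rising
edge first exceeds 50% of the peak to the last bin above 0.1% of the peak:
the early cut avoids instrument-response-dominated bins while the deep tail
is kept because it carries the deep-layer information (the Poisson weights
handle its low counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .diffusion_forward import TwoLayerEvaluator, _semi_infinite_td
from .media import DetectionGeometry, TimeGrid, Transient
from .preprocessing import default_fit_window

__all__ = ["FitConfig", "FitResult", "fit_homogeneous_td", "fit_two_layer_td", "fit_two_layer_cw"]

_LOSSES = ("weighted_least_squares_on_counts", "poisson_deviance", "least_squares_on_log")


@dataclass(frozen=True)
class FitConfig:
    """Fit options shared by the TD and CW inversions.

    ``free`` lists the free parameters (subset of mua1, musp1, mua2, musp2,
    amplitude, t0 for the layered TD fit).  Bounds act as a validity box on
    the log-transformed coefficients; the top-layer thickness is never free.
    """

    free: tuple[str, ...] = ("mua1", "musp1", "mua2", "musp2", "amplitude")
    loss: str = "weighted_least_squares_on_counts"
    bounds: dict = field(
        default_factory=lambda: {"mua": (1e-3, 1.0), "musp": (1.0, 30.0)}
    )
    max_iter: int = 200
    tol: float = 1e-10
    fit_window: tuple[float, float] | None = None  # None -> automatic rule
    init: dict | None = None  # explicit initial values, else automatic

    def __post_init__(self) -> None:
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")
        for key, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {key} must satisfy lower < upper")


@dataclass(frozen=True)
class FitResult:
    """Recovered parameters with convergence diagnostics.

    ``covariance`` is the Gauss-Newton proxy ``(J^T J)^-1 * s^2`` from the
    final Jacobian in natural (not log) parameter scale, usable for relative
    identifiability comparisons rather than rigorous confidence intervals.
    """

    estimates: dict
    residual_norm: float
    iterations: int
    converged: bool
    covariance: np.ndarray | None = None
    param_order: tuple[str, ...] = ()
    message: str = ""

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]

    def stderr(self, name: str) -> float:
        if self.covariance is None or name not in self.param_order:
            return float("nan")
        i = self.param_order.index(name)
        return float(np.sqrt(max(self.covariance[i, i], 0.0)))


def _exp_clipped(v: float) -> float:
    """exp on a clipped log-parameter; keeps optimizer excursions finite."""
    return float(np.exp(min(max(v, -60.0), 60.0)))


def _effective_loss(transient: Transient, config: FitConfig) -> str:
    """Poisson count weighting is meaningless for model-density transients;
    fall back to the scale-free log-domain loss there."""
    if transient.kind != "counts" and config.loss == "weighted_least_squares_on_counts":
        return "least_squares_on_log"
    return config.loss


def _bound_penalty(names: tuple[str, ...], p_log: np.ndarray, bounds: dict,
                   alpha: float = 1e4) -> np.ndarray:
    """Soft one-sided penalties keeping the LM iterates inside the validity
    box (the steps themselves stay unconstrained)."""
    pen = np.zeros(2 * len(names))
    for i, (nm, v) in enumerate(zip(names, p_log)):
        key = "mua" if nm.startswith("mua") else "musp" if nm.startswith("musp") else None
        if key and key in bounds:
            lo, hi = np.log(bounds[key][0]), np.log(bounds[key][1])
            pen[2 * i] = alpha * max(0.0, v - hi)
            pen[2 * i + 1] = alpha * max(0.0, lo - v)
    return pen


def _window_mask(transient: Transient, config: FitConfig) -> np.ndarray:
    if config.fit_window is not None:
        lo, hi = config.fit_window
    else:
        lo, hi = default_fit_window(transient.values, transient.t)
    mask = (transient.t >= lo) & (transient.t <= hi)
    if mask.sum() < 5:
        raise ValueError("fit window selects fewer than 5 bins")
    return mask


def _residual_factory(y: np.ndarray, loss: str):
    """Return r(model) for the chosen loss, on window-restricted arrays."""
    if loss == "weighted_least_squares_on_counts":
        w = 1.0 / np.sqrt(np.maximum(y, 1.0))

        def resid(m: np.ndarray) -> np.ndarray:
            return (m - y) * w

    elif loss == "poisson_deviance":

        def resid(m: np.ndarray) -> np.ndarray:
            m = np.maximum(m, 1e-300)
            dev = 2.0 * (m - y + np.where(y > 0, y * np.log(y / m), 0.0))
            return np.sign(m - y) * np.sqrt(np.maximum(dev, 0.0))

    else:  # least_squares_on_log

        def resid(m: np.ndarray) -> np.ndarray:
            return np.log(np.maximum(m, 1e-300)) - np.log(np.maximum(y, 1e-300))

    return resid


def _finalize(
    sol, names: tuple[str, ...], estimates: dict, n_data: int
) -> FitResult:
    converged = bool(sol.status > 0)
    dof = max(n_data - len(names), 1)
    cov = None
    try:
        jtj = sol.jac.T @ sol.jac
        cov_log = np.linalg.inv(jtj) * (2.0 * sol.cost / dof)
        # delta method back to natural scale: d(theta)/d(log theta) = theta
        scale = np.array([estimates[n] for n in names])
        cov = cov_log * np.outer(scale, scale)
    except np.linalg.LinAlgError:
        converged = False
    return FitResult(
        estimates=estimates,
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        iterations=int(sol.nfev),
        converged=converged,
        covariance=cov,
        param_order=names,
        message=str(sol.message),
    )


def _check_bounds(result: FitResult, config: FitConfig) -> FitResult:
    est = result.estimates
    ok = True
    for name, value in est.items():
        key = "mua" if name.startswith("mua") else "musp" if name.startswith("musp") else None
        if key and key in config.bounds:
            lo, hi = config.bounds[key]
            margin = 1e-6 * (hi - lo)
            if not (lo - margin <= value <= hi + margin):
                ok = False
    if not ok:
        return replace(result, converged=False, message=result.message + " [outside bounds]")
    return result


# ---------------------------------------------------------------------------
# homogeneous fit (initialization stage)
# ---------------------------------------------------------------------------

def fit_homogeneous_td(
    transient: Transient,
    geometry: DetectionGeometry,
    n: float = 1.4,
    config: FitConfig | None = None,
    n_ambient: float = 1.0,
) -> FitResult:
    """Fit (mua, musp, amplitude) of a semi-infinite medium to a transient."""
    config = config or FitConfig(free=("mua", "musp", "amplitude"))
    mask = _window_mask(transient, config)
    t = transient.t[mask]
    y = transient.values[mask]
    resid = _residual_factory(y, _effective_loss(transient, config))
    total = transient.values.sum() * transient.grid.dt

    def model(p_log: np.ndarray) -> np.ndarray:
        mua, musp, amp = (_exp_clipped(v) for v in p_log)
        return amp * _semi_infinite_td(t, mua, musp, n, n_ambient, geometry.rho)

    names = ("mua", "musp", "amplitude")
    x0 = np.log([0.1, 10.0, max(total, 1e-12) / 5e-4])
    sol = least_squares(
        lambda p: np.concatenate([resid(model(p)), _bound_penalty(names, p, config.bounds)]),
        x0,
        method="lm",
        xtol=config.tol,
        ftol=config.tol,
        gtol=config.tol,
        max_nfev=config.max_iter * 8,
    )
    mua, musp, amp = np.exp(sol.x)
    result = _finalize(sol, names, {"mua": mua, "musp": musp, "amplitude": amp}, mask.sum())
    return _check_bounds(result, config)


# ---------------------------------------------------------------------------
# two-layer TD fit (primary path)
# ---------------------------------------------------------------------------

def fit_two_layer_td(
    transient: Transient,
    geometry: DetectionGeometry,
    top_thickness: float,
    config: FitConfig | None = None,
    n1: float = 1.4,
    n2: float = 1.4,
    n_ambient: float = 1.0,
    evaluator: TwoLayerEvaluator | None = None,
) -> FitResult:
    """Levenberg-Marquardt fit of the two-layer TD model to one transient.

    The top thickness is a fixed input, never fitted.  Initialization uses a
    homogeneous fit whose (mua, musp) seed both layers unless ``config.init``
    provides explicit values.  A low-sensitivity warning is emitted when the
    late tail (beyond twice the peak time) carries fewer than 100 counts.
    """
    config = config or FitConfig()
    mask = _window_mask(transient, config)
    t_all = transient.t
    y_all = transient.values
    y = y_all[mask]
    resid = _residual_factory(y, _effective_loss(transient, config))

    if transient.kind == "counts":
        t_peak = t_all[int(np.argmax(y_all))]
        if y_all[t_all > 2.0 * t_peak].sum() <= 100:
            warnings.warn(
                "fewer than 100 counts beyond twice the peak time: deep-layer "
                "sensitivity is low",
                stacklevel=2,
            )

    ev = evaluator or TwoLayerEvaluator(
        geometry=geometry,
        grid=transient.grid,
        n1=n1,
        n2=n2,
        n_ambient=n_ambient,
        thickness=top_thickness,
        pad_factor=2,
    )

    if config.init is not None:
        init = dict(config.init)
    else:
        hom = fit_homogeneous_td(transient, geometry, n=n1, config=FitConfig(loss=config.loss))
        init = {
            "mua1": hom["mua"],
            "musp1": hom["musp"],
            "mua2": hom["mua"],
            "musp2": hom["musp"],
            "amplitude": hom["amplitude"],
        }
    lo_a, hi_a = config.bounds.get("mua", (1e-3, 1.0))
    lo_s, hi_s = config.bounds.get("musp", (1.0, 30.0))
    for k in ("mua1", "mua2"):
        init[k] = float(np.clip(init[k], lo_a, hi_a))
    for k in ("musp1", "musp2"):
        init[k] = float(np.clip(init[k], lo_s, hi_s))

    names = tuple(config.free)
    fixed = {k: v for k, v in init.items() if k not in names}

    def unpack(p_log: np.ndarray) -> dict:
        params = dict(fixed)
        params.update({nm: _exp_clipped(v) for nm, v in zip(names, p_log)})
        return params

    def model(p_log: np.ndarray) -> np.ndarray:
        q = unpack(p_log)
        dens = ev.td(q["mua1"], q["musp1"], q["mua2"], q["musp2"])
        return q.get("amplitude", 1.0) * dens[mask]

    x0 = np.log([max(init[nm], 1e-12) for nm in names])
    sol = least_squares(
        lambda p: np.concatenate([resid(model(p)), _bound_penalty(names, p, config.bounds)]),
        x0,
        method="lm",
        xtol=config.tol,
        ftol=config.tol,
        gtol=config.tol,
        max_nfev=config.max_iter * 10,
    )
    est = unpack(sol.x)
    result = _finalize(sol, names, est, int(mask.sum()))
    return _check_bounds(result, config)


# ---------------------------------------------------------------------------
# two-layer CW fit (comparison baseline)
# ---------------------------------------------------------------------------

def fit_two_layer_cw(
    intensities,
    rhos,
    top_thickness: float,
    config: FitConfig | None = None,
    n1: float = 1.4,
    n2: float = 1.4,
    n_ambient: float = 1.0,
    amplitude: float | None = None,
    wavelength: float = 800.0,
) -> FitResult:
    """Fit the layered steady-state model to multi-distance intensities.

    Least squares on log intensities.  By default the overall amplitude is a
    known calibration constant (``amplitude=None`` estimates it from the
    data by profiling, which leaves ``len(rhos) - 1`` informative points);
    four detector distances then just determine the four layer coefficients.
    """
    config = config or FitConfig(free=("mua1", "musp1", "mua2", "musp2"))
    y = np.asarray(intensities, dtype=float)
    rhos = np.asarray(rhos, dtype=float)
    if y.shape != rhos.shape or y.ndim != 1:
        raise ValueError("intensities and rhos must be 1-D arrays of equal length")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")
    names = tuple(nm for nm in config.free if nm != "amplitude")
    profile_amp = amplitude is None
    n_eff = len(rhos) - (1 if profile_amp else 0)
    if n_eff < len(names):
        raise ValueError(
            f"{len(rhos)} distances cannot determine {len(names)} free "
            f"parameters{' plus a profiled amplitude' if profile_amp else ''}"
        )

    evs = [
        TwoLayerEvaluator(
            geometry=DetectionGeometry(rho=r, wavelength=wavelength),
            grid=TimeGrid(0.0, 5.0, 2),
            n1=n1,
            n2=n2,
            n_ambient=n_ambient,
            thickness=top_thickness,
            check=False,
        )
        for r in rhos
    ]
    log_y = np.log(y)

    init = dict(config.init or {"mua1": 0.1, "musp1": 10.0, "mua2": 0.1, "musp2": 10.0})

    def resid(p_log: np.ndarray) -> np.ndarray:
        q = dict(init)
        q.update({nm: _exp_clipped(v) for nm, v in zip(names, p_log)})
        model = np.array([ev.cw(q["mua1"], q["musp1"], q["mua2"], q["musp2"]) for ev in evs])
        log_m = np.log(np.maximum(model, 1e-300))
        if profile_amp:
            offset = np.mean(log_y - log_m)
        else:
            offset = np.log(amplitude)
        return (log_m + offset) - log_y

    x0 = np.log([max(init[nm], 1e-12) for nm in names])
    sol = least_squares(
        lambda p: np.concatenate([resid(p), _bound_penalty(names, p, config.bounds)]),
        x0,
        method="lm",
        xtol=config.tol,
        ftol=config.tol,
        gtol=config.tol,
        max_nfev=config.max_iter * 10,
    )
    est = dict(init)
    est.update({nm: _exp_clipped(v) for nm, v in zip(names, sol.x)})
    result = _finalize(sol, names, est, len(rhos))
    return _check_bounds(result, config)
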