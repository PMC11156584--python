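"""Estimators for photometry traces, histology profiles and calibrations.

The estimators follow scikit-learn conventions: hyperparameters in
``__init__``, data in ``fit``, fitted attributes with trailing underscores,
``get_params``/``set_params`` inherited from ``BaseEstimator``.

* :class:`BaselineCorrector` - cubic-spline baseline removal for the slow
  (~6 %/h) decline of the photometry baseline, excluding bleach/recovery
  windows from the spline fit.
* :class:`FrapEstimator` - diffusion coefficient from a fluorescence
  recovery-after-photobleaching trace (erf-based hemisphere model).
* :class:`ClearanceEstimator` - (D, tau, amplitude) from a dye-arrival
  curve with first-order clearance, plus the percent clearance at the
  fitted curve's peak.
* :class:`GaussianProfileModel` - Gaussian + baseline fit of a histology
  intensity-vs-distance profile.
* :class:`IntensityCalibration` - linear intensity <-> concentration map.

Module-level functions (:func:`fit_frap`, :func:`fit_clearance`, ...) are
thin wrappers over the estimators for script use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import LSQUnivariateSpline
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from . import models
from .models import (
    ClearanceModel,
    DetectionGeometry,
    GaussianSource,
    TransportParams,
)

__all__ = [
    "PhotometryTrace",
    "HistologyProfile",
    "FitResult",
    "BaselineCorrector",
    "FrapEstimator",
    "ClearanceEstimator",
    "GaussianProfileModel",
    "IntensityCalibration",
    "baseline_correct",
    "fit_frap",
    "fit_clearance",
    "fit_gaussian_profile",
    "calibrate_intensity",
    "apply_calibration",
]

_Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class PhotometryTrace:
    """A fluorescence time series with optional per-sample vigilance labels.

    ``time`` in seconds (strictly increasing), ``intensity`` in arbitrary
    units (or concentration units after calibration).  ``sampling_rate`` is
    checked against the median sample interval to within 1 %.
    """

    time: np.ndarray
    intensity: np.ndarray
    sampling_rate: float | None = None
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        median_dt = float(np.median(np.diff(self.time)))
        if self.sampling_rate is None:
            self.sampling_rate = 1.0 / median_dt
        elif abs(self.sampling_rate - 1.0 / median_dt) > 0.01 * self.sampling_rate:
            raise ValueError("sampling_rate inconsistent with median sample interval")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.time.shape:
                raise ValueError("labels must match trace length")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time, "intensity_au": self.intensity})
        if self.labels is not None:
            df["state"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "PhotometryTrace":
        df = pd.read_csv(path)
        for col in ("time_s", "intensity_au"):
            if col not in df.columns:
                raise ValueError(f"trace CSV missing required column '{col}'")
        labels = df["state"].to_numpy() if "state" in df.columns else None
        return cls(time=df["time_s"].to_numpy(), intensity=df["intensity_au"].to_numpy(),
                   labels=labels, meta=meta or {})

    def crop(self, t_start: float, t_stop: float) -> "PhotometryTrace":
        m = (self.time >= t_start) & (self.time <= t_stop)
        return PhotometryTrace(
            time=self.time[m], intensity=self.intensity[m],
            labels=None if self.labels is None else self.labels[m], meta=dict(self.meta),
        )


@dataclass
class HistologyProfile:
    """Mean slice intensity against signed anterior-posterior distance (um)."""

    ap_distance: np.ndarray
    mean_intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ap_distance = np.asarray(self.ap_distance, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if self.ap_distance.shape != self.mean_intensity.shape:
            raise ValueError("distance and intensity must have equal length")
        order = np.argsort(self.ap_distance)
        self.ap_distance = self.ap_distance[order]
        self.mean_intensity = self.mean_intensity[order]
        if np.any(self.mean_intensity < 0):
            raise ValueError("intensities must be >= 0")

    def to_csv(self, path) -> None:
        pd.DataFrame({"ap_distance_um": self.ap_distance,
                      "mean_intensity_au": self.mean_intensity}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HistologyProfile":
        df = pd.read_csv(path)
        for col in ("ap_distance_um", "mean_intensity_au"):
            if col not in df.columns:
                raise ValueError(f"histology CSV missing required column '{col}'")
        return cls(df["ap_distance_um"].to_numpy(), df["mean_intensity_au"].to_numpy())


@dataclass
class FitResult:
    """Named parameter estimates with 95 % intervals and fit diagnostics."""

    estimates: dict
    units: dict
    ci95: dict
    rss: float
    converged: bool
    n_points: int
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be >= 0")
        for name, (lo, hi) in self.ci95.items():
            est = self.estimates[name]
            if not (lo - 1e-12 <= est <= hi + 1e-12):
                raise ValueError(f"ci95 for '{name}' does not bracket the estimate")

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "units": dict(self.units),
            "ci95": {k: [float(lo), float(hi)] for k, (lo, hi) in self.ci95.items()},
            "rss": float(self.rss),
            "converged": bool(self.converged),
            "n_points": int(self.n_points),
            "flags": list(self.flags),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Baseline correction
# ---------------------------------------------------------------------------


class BaselineCorrector(BaseEstimator, TransformerMixin):
    """Cubic-spline baseline fit with bleach/recovery windows masked out.

    The in vivo photometry baseline declines slowly (~6 % per hour) while
    bleach pulses superimpose sharp transients.  The baseline is fitted by a
    least-squares cubic spline on data outside every excluded window
    (``exclude_windows`` plus a post-window guard); correction is either
    ratiometric (``mode="divide"``) or additive (``mode="subtract"``), in
    both cases rescaled so the corrected baseline sits at the mean fitted
    baseline level (a drift-free trace is returned unchanged).

    Parameters
    ----------
    exclude_windows : sequence of (start_s, end_s)
        Bleach/recovery intervals to keep out of the baseline fit.
    guard_s : float
        Extra guard appended after each excluded window (recovery tail).
    knot_spacing_s : float
        Interior-knot spacing of the spline.
    mode : {"divide", "subtract"}
    min_baseline_s : float
        Minimum total baseline coverage required (default 30 min).
    """

    def __init__(self, exclude_windows: Sequence = (), guard_s: float = 900.0,
                 knot_spacing_s: float = 3600.0, mode: str = "divide",
                 min_baseline_s: float = 1800.0):
        self.exclude_windows = exclude_windows
        self.guard_s = guard_s
        self.knot_spacing_s = knot_spacing_s
        self.mode = mode
        self.min_baseline_s = min_baseline_s

    def _mask(self, t: np.ndarray) -> np.ndarray:
        keep = np.ones(t.shape, dtype=bool)
        for start, end in self.exclude_windows:
            keep &= ~((t >= start) & (t <= end + self.guard_s))
        return keep

    def fit(self, trace: PhotometryTrace, y=None) -> "BaselineCorrector":
        if self.mode not in ("divide", "subtract"):
            raise ValueError("mode must be 'divide' or 'subtract'")
        t, yv = trace.time, trace.intensity
        keep = self._mask(t)
        tm, ym = t[keep], yv[keep]
        if tm.size < 8:
            raise ValueError("insufficient baseline data outside excluded windows")
        coverage = tm.size / trace.sampling_rate
        if coverage < self.min_baseline_s:
            raise ValueError(
                f"insufficient baseline coverage: {coverage:.0f} s < {self.min_baseline_s:.0f} s"
            )
        knots = np.arange(tm[0] + self.knot_spacing_s, tm[-1], self.knot_spacing_s)
        # keep only knots satisfying Schoenberg-Whitney (>= 4 points per interval)
        good = []
        prev = tm[0]
        for kn in knots:
            if np.count_nonzero((tm > prev) & (tm < kn)) >= 4:
                good.append(kn)
                prev = kn
        if good and np.count_nonzero(tm > good[-1]) < 4:
            good.pop()
        self.spline_ = LSQUnivariateSpline(tm, ym, t=np.asarray(good), k=3)
        self.n_baseline_points_ = int(tm.size)
        self._fit_times_ = tm
        return self

    def baseline(self, t) -> np.ndarray:
        return self.spline_(np.asarray(t, dtype=float))

    def transform(self, trace: PhotometryTrace) -> PhotometryTrace:
        # scale-preserving: the corrected baseline sits at the mean fitted
        # baseline level rather than at 1 (divide) or 0 (subtract), so a
        # drift-free trace passes through unchanged and units are kept
        b = self.baseline(trace.time)
        level = float(np.mean(self.spline_(self._fit_times_)))
        if self.mode == "divide":
            corrected = trace.intensity / b * level
        else:
            corrected = trace.intensity - b + level
        return PhotometryTrace(time=trace.time.copy(), intensity=corrected,
                               labels=None if trace.labels is None else trace.labels.copy(),
                               meta={**trace.meta, "baseline_corrected": self.mode})

    def correct(self, trace: PhotometryTrace) -> PhotometryTrace:
        return self.fit(trace).transform(trace)


# ---------------------------------------------------------------------------
# Nonlinear least-squares machinery shared by the curve estimators
# ---------------------------------------------------------------------------


def _multistart_least_squares(residual, starts, bounds):
    """Bounded trust-region least squares from several starts; best RSS wins."""
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = optimize.least_squares(residual, x0, bounds=bounds, method="trf",
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all least-squares starts failed")
    return best


def _linearized_se(res) -> np.ndarray:
    """Per-parameter standard errors from the residual Jacobian at the optimum."""
    n, p = res.jac.shape
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    cov = np.linalg.pinv(res.jac.T @ res.jac) * s2
    return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))


def _at_bounds(x, bounds, rel=1e-6) -> bool:
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    span = np.where(np.isfinite(hi - lo), hi - lo, np.abs(x) + 1.0)
    return bool(np.any((x - lo) <= rel * span) or np.any((hi - x) <= rel * span))


# ---------------------------------------------------------------------------
# FRAP (photobleaching recovery) estimator
# ---------------------------------------------------------------------------


class FrapEstimator(BaseEstimator, RegressorMixin):
    """Diffusion coefficient from a fluorescence recovery trace.

    The model is ``I(t) = I_inf - (I_inf - I0) * M(t)/M(0)`` where ``M(t)``
    is the bleached-dye content of a detection hemisphere of radius ``R``
    around a Gaussian bleach of width ``sigma``.  ``D`` is fitted by bounded
    trust-region least squares in ``log10 D`` from ``n_starts`` log-spaced
    starts; ``I0``/``I_inf`` are free parameters by default (this makes the
    estimate invariant to affine transforms of the intensity scale).

    Parameters
    ----------
    sigma_um : float
        Width of the bleached Gaussian (must be supplied; it is not
        identifiable jointly with D from a single recovery curve).
    radius_um : float, optional
        Detection radius R; defaults to ``sigma_um`` (matched optics).
    fit_intensities : bool
        If False, ``i0``/``i_inf`` must be provided and are held fixed.
    i0, i_inf : float, optional
        Post-bleach and equilibrium intensities when held fixed.
    d_bounds : (float, float)
        Bounds on D in um^2/s.
    n_starts : int
        Number of log-spaced D starts.

    Attributes
    ----------
    d_ : float           Fitted diffusion coefficient (um^2/s).
    d_ci95_ : (lo, hi)   Linearized 95 % interval on D.
    i0_, i_inf_ : float  Fitted (or fixed) intensity anchors.
    result_ : FitResult  Full report.
    """

    def __init__(self, sigma_um: float = 150.0, radius_um: float | None = None,
                 fit_intensities: bool = True, i0: float | None = None,
                 i_inf: float | None = None, d_bounds: tuple = (1e-2, 5e3),
                 n_starts: int = 5):
        self.sigma_um = sigma_um
        self.radius_um = radius_um
        self.fit_intensities = fit_intensities
        self.i0 = i0
        self.i_inf = i_inf
        self.d_bounds = d_bounds
        self.n_starts = n_starts

    def _norm_recovery(self, t, d):
        """M(t)/M(0) for diffusion coefficient d."""
        src = GaussianSource(c_peak=1.0, sigma=self.sigma_um)
        geo = DetectionGeometry(radius_r_detect=self.radius_um or self.sigma_um)
        tp = TransportParams(d_tissue=d)
        return models.moles_in_hemisphere(t, src, tp, geo) / models.moles_in_hemisphere(0.0, src, tp, geo)

    def fit(self, t, y) -> "FrapEstimator":
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be equal-length 1-D arrays")
        if np.any(t < 0):
            raise ValueError("recovery times must be >= 0 (relative to bleach end)")

        i0_init = self.i0 if self.i0 is not None else float(y[0])
        tail = y[t >= t[-1] - max(300.0, (t[-1] - t[0]) / 10)]
        iinf_init = self.i_inf if self.i_inf is not None else float(tail.mean())
        if iinf_init <= i0_init:
            iinf_init = i0_init + max(np.ptp(y), 1e-9)

        lo_d, hi_d = np.log10(self.d_bounds[0]), np.log10(self.d_bounds[1])
        span = np.ptp(y) if np.ptp(y) > 0 else 1.0

        if self.fit_intensities:
            def residual(theta):
                logd, i0, iinf = theta
                return (iinf - (iinf - i0) * self._norm_recovery(t, 10.0**logd)) - y
            bounds = ([lo_d, i0_init - 10 * span, i0_init - 10 * span],
                      [hi_d, iinf_init + 10 * span, iinf_init + 10 * span])
            starts = [np.array([ld, i0_init, iinf_init])
                      for ld in np.linspace(max(lo_d, 0.0), min(hi_d, np.log10(2e3)), self.n_starts)]
        else:
            if self.i0 is None or self.i_inf is None:
                raise ValueError("fit_intensities=False requires explicit i0 and i_inf")

            def residual(theta):
                (logd,) = theta
                return (self.i_inf - (self.i_inf - self.i0) * self._norm_recovery(t, 10.0**logd)) - y
            bounds = ([lo_d], [hi_d])
            starts = [np.array([ld])
                      for ld in np.linspace(max(lo_d, 0.0), min(hi_d, np.log10(2e3)), self.n_starts)]

        res = _multistart_least_squares(residual, starts, bounds)
        se = _linearized_se(res)

        logd = res.x[0]
        self.d_ = float(10.0**logd)
        se_d = float(se[0] * self.d_ * np.log(10.0))
        self.d_ci95_ = (self.d_ - _Z95 * se_d, self.d_ + _Z95 * se_d)
        if self.fit_intensities:
            self.i0_, self.i_inf_ = float(res.x[1]), float(res.x[2])
            ci_i0 = (self.i0_ - _Z95 * se[1], self.i0_ + _Z95 * se[1])
            ci_iinf = (self.i_inf_ - _Z95 * se[2], self.i_inf_ + _Z95 * se[2])
        else:
            self.i0_, self.i_inf_ = float(self.i0), float(self.i_inf)
            ci_i0 = (self.i0_, self.i0_)
            ci_iinf = (self.i_inf_, self.i_inf_)

        flags = []
        converged = bool(res.success)
        if _at_bounds(res.x[:1], (bounds[0][:1], bounds[1][:1])):
            converged = False
            flags.append("d_at_bounds")
        self.rss_ = float(2.0 * res.cost)
        self.converged_ = converged
        self.n_points_ = int(t.size)
        self.result_ = FitResult(
            estimates={"d": self.d_, "i0": self.i0_, "i_inf": self.i_inf_},
            units={"d": "um^2/s", "i0": "a.u.", "i_inf": "a.u."},
            ci95={"d": self.d_ci95_, "i0": ci_i0, "i_inf": ci_iinf},
            rss=self.rss_, converged=converged, n_points=self.n_points_, flags=flags,
        )
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.i_inf_ - (self.i_inf_ - self.i0_) * self._norm_recovery(t, self.d_)


# ---------------------------------------------------------------------------
# Clearance (dye arrival) estimator
# ---------------------------------------------------------------------------


def cleared_peak_time(src: GaussianSource, tp: TransportParams, cl: ClearanceModel,
                      distance_r: float) -> float:
    """Peak time of the cleared arrival curve C'(r, t), by 1-D maximization."""
    geo = DetectionGeometry(radius_r_detect=src.sigma, distance_r=distance_r)
    t_diff = models.peak_arrival_time(geo, src, tp)
    if np.isinf(cl.tau):
        return t_diff
    t_hi = max(10.0 * t_diff, 10.0 * cl.tau, 1e4)
    grid = np.linspace(0.0, t_hi, 4001)
    vals = models.clearance_concentration(distance_r, grid, src, tp, cl)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -models.clearance_concentration(distance_r, max(t, 0.0), src, tp, cl),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-6 * max(hi, 1.0)},
    )
    return float(max(res.x, 0.0))


class ClearanceEstimator(BaseEstimator, RegressorMixin):
    """(D, tau, amplitude) from a dye-arrival concentration trace.

    Fits ``C'(r, t) = A (1 - t/(t+tau)) [1 + 2Dt/sigma^2]^(-3/2)
    exp(-r^2/(4Dt + 2 sigma^2))`` by bounded least squares in
    ``(A, log10 D, log10 tau)`` from a grid of starts.  Early times (default
    first 20 min) are masked: the model assumes parenchymal spread only and
    the earliest arrival can be contaminated by ventricular transit.

    With ``fit_tau=False`` the surviving fraction is pinned at 1 (gel /
    no-clearance model, pure Gaussian spread).

    Attributes
    ----------
    d_, tau_, c_peak_ : floats   Fitted parameters (tau_ = inf when fixed).
    peak_time_s_ : float         Peak time of the fitted cleared curve.
    clearance_at_peak_pct_ : float   100 t_pk / (t_pk + tau) at that peak.
    result_ : FitResult
    """

    def __init__(self, distance_r_um: float = 3335.0, sigma_um: float = 250.0,
                 fit_tau: bool = True, early_mask_s: float = 1200.0,
                 d_bounds: tuple = (1e-2, 5e3), tau_bounds: tuple = (60.0, 1e12),
                 n_starts_d: int = 5, n_starts_tau: int = 3):
        self.distance_r_um = distance_r_um
        self.sigma_um = sigma_um
        self.fit_tau = fit_tau
        self.early_mask_s = early_mask_s
        self.d_bounds = d_bounds
        self.tau_bounds = tau_bounds
        self.n_starts_d = n_starts_d
        self.n_starts_tau = n_starts_tau

    def _shape(self, t, d, tau):
        s2 = self.sigma_um**2
        denom = 4.0 * d * t + 2.0 * s2
        surv = 1.0 if np.isinf(tau) else tau / (t + tau)
        return surv * (1.0 + 2.0 * d * t / s2) ** -1.5 * np.exp(-self.distance_r_um**2 / denom)

    def fit(self, t, c) -> "ClearanceEstimator":
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("t and c must be equal-length 1-D arrays")
        mask = t >= self.early_mask_s
        if np.count_nonzero(mask) < 10:
            mask = np.ones_like(t, dtype=bool)
        tm, cm = t[mask], c[mask]

        lo_d, hi_d = np.log10(self.d_bounds[0]), np.log10(self.d_bounds[1])
        lo_tau, hi_tau = np.log10(self.tau_bounds[0]), np.log10(self.tau_bounds[1])
        c_scale = max(float(np.max(np.abs(cm))), 1e-30)

        d_starts = np.linspace(np.log10(5.0), np.log10(2e3), self.n_starts_d)
        starts = []
        if self.fit_tau:
            tau_starts = np.linspace(3.0, 5.0, self.n_starts_tau)  # 1e3..1e5 s

            def residual(theta):
                a, logd, logtau = theta
                return a * self._shape(tm, 10.0**logd, 10.0**logtau) - cm

            bounds = ([0.0, lo_d, lo_tau], [np.inf, hi_d, hi_tau])
            for ld in d_starts:
                for lt in tau_starts:
                    shape_max = max(float(np.max(self._shape(tm, 10.0**ld, 10.0**lt))), 1e-300)
                    starts.append(np.array([c_scale / shape_max, ld, lt]))
        else:
            def residual(theta):
                a, logd = theta
                return a * self._shape(tm, 10.0**logd, np.inf) - cm

            bounds = ([0.0, lo_d], [np.inf, hi_d])
            for ld in d_starts:
                shape_max = max(float(np.max(self._shape(tm, 10.0**ld, np.inf))), 1e-300)
                starts.append(np.array([c_scale / shape_max, ld]))

        res = _multistart_least_squares(residual, starts, bounds)
        se = _linearized_se(res)

        self.c_peak_ = float(res.x[0])
        self.d_ = float(10.0 ** res.x[1])
        se_d = float(se[1] * self.d_ * np.log(10.0))
        self.d_ci95_ = (self.d_ - _Z95 * se_d, self.d_ + _Z95 * se_d)
        flags = []
        if self.fit_tau:
            log_tau = res.x[2]
            self.tau_ = float(10.0**log_tau)
            tau_decades = 2.0 * _Z95 * se[2]
            self.tau_ci95_ = (10.0 ** (log_tau - _Z95 * se[2]), 10.0 ** (log_tau + _Z95 * se[2]))
            if tau_decades > 3.0:
                flags.append("tau_unidentifiable")
        else:
            self.tau_ = np.inf
            self.tau_ci95_ = (np.inf, np.inf)

        converged = bool(res.success)
        if _at_bounds(res.x[1:2], ([lo_d], [hi_d])):
            converged = False
            flags.append("d_at_bounds")

        src = GaussianSource(c_peak=max(self.c_peak_, 1e-300), sigma=self.sigma_um)
        tp = TransportParams(d_tissue=self.d_)
        cl = ClearanceModel(tau=self.tau_)
        self.peak_time_s_ = cleared_peak_time(src, tp, cl, self.distance_r_um)
        self.clearance_at_peak_pct_ = float(models.clearance_percent(self.peak_time_s_, cl))

        self.rss_ = float(2.0 * res.cost)
        self.converged_ = converged
        self.n_points_ = int(tm.size)
        est = {"d": self.d_, "tau": self.tau_, "c_peak": self.c_peak_,
               "peak_time": self.peak_time_s_, "clearance_at_peak": self.clearance_at_peak_pct_}
        ci = {"d": self.d_ci95_, "tau": self.tau_ci95_,
              "c_peak": (self.c_peak_ - _Z95 * se[0], self.c_peak_ + _Z95 * se[0]),
              "peak_time": (self.peak_time_s_, self.peak_time_s_),
              "clearance_at_peak": (self.clearance_at_peak_pct_, self.clearance_at_peak_pct_)}
        self.result_ = FitResult(
            estimates=est,
            units={"d": "um^2/s", "tau": "s", "c_peak": "a.u.",
                   "peak_time": "s", "clearance_at_peak": "%"},
            ci95=ci, rss=self.rss_, converged=converged,
            n_points=self.n_points_, flags=flags,
        )
        return self

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.c_peak_ * self._shape(t, self.d_, self.tau_)


# ---------------------------------------------------------------------------
# Histology Gaussian profile
# ---------------------------------------------------------------------------


class GaussianProfileModel(BaseEstimator, RegressorMixin):
    """Gaussian + constant baseline fit of an intensity-vs-distance profile.

    Fits ``y = baseline + amplitude * exp(-(x - center)^2 / (2 width^2))``
    with all four parameters free; ``width`` is reported as a standard
    deviation in micrometres.
    """

    def __init__(self, min_points: int = 8):
        self.min_points = min_points

    @staticmethod
    def _model(x, amplitude, center, width, baseline):
        return baseline + amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2))

    def fit(self, x, y) -> "GaussianProfileModel":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} distance points")
        center0 = float(x[np.argmax(y)])
        if not (np.any(x < center0) and np.any(x > center0)):
            raise ValueError("profile must span both sides of the peak")
        base0 = float(np.min(y))
        amp0 = float(np.ptp(y)) or 1.0
        width0 = max((x.max() - x.min()) / 6.0, 1e-6)
        try:
            popt, pcov = optimize.curve_fit(
                self._model, x, y, p0=[amp0, center0, width0, base0],
                bounds=([0.0, x.min() - np.ptp(x), 1e-9, -np.inf],
                        [np.inf, x.max() + np.ptp(x), np.inf, np.inf]),
                maxfev=20_000,
            )
            converged = True
        except RuntimeError:
            raise RuntimeError("Gaussian profile fit did not converge")
        self.amplitude_, self.center_um_, self.width_um_, self.baseline_ = map(float, popt)
        self.width_um_ = abs(self.width_um_)
        resid = self._model(x, *popt) - y
        self.rss_ = float(resid @ resid)
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        names = ["amplitude", "center", "width", "baseline"]
        vals = [self.amplitude_, self.center_um_, self.width_um_, self.baseline_]
        self.result_ = FitResult(
            estimates=dict(zip(names, vals)),
            units={"amplitude": "a.u.", "center": "um", "width": "um", "baseline": "a.u."},
            ci95={n: (v - _Z95 * s, v + _Z95 * s) for n, v, s in zip(names, vals, se)},
            rss=self.rss_, converged=converged, n_points=int(x.size),
        )
        return self

    def predict(self, x):
        return self._model(np.asarray(x, dtype=float), self.amplitude_,
                           self.center_um_, self.width_um_, self.baseline_)


# ---------------------------------------------------------------------------
# Intensity calibration
# ---------------------------------------------------------------------------


class IntensityCalibration(BaseEstimator, TransformerMixin):
    """Linear fluorescence-intensity to concentration calibration.

    ``fit(concentration, intensity)`` estimates ``intensity = slope *
    concentration + intercept`` by ordinary least squares; a non-positive
    fitted slope is rejected as an invalid calibration.
    ``to_concentration`` inverts the line.
    """

    def fit(self, concentration, intensity) -> "IntensityCalibration":
        conc = np.asarray(concentration, dtype=float)
        inten = np.asarray(intensity, dtype=float)
        if conc.size != inten.size or conc.size < 2:
            raise ValueError("need >= 2 paired calibration points")
        reg = stats.linregress(conc, inten)
        if not np.isfinite(reg.slope) or reg.slope <= 0:
            raise ValueError("calibration invalid: fitted slope is not positive")
        self.slope_ = float(reg.slope)
        self.intercept_ = float(reg.intercept)
        self.r_squared_ = float(reg.rvalue**2)
        self.slope_stderr_ = float(reg.stderr) if reg.stderr is not None else np.nan
        return self

    def predict(self, concentration):
        return self.slope_ * np.asarray(concentration, dtype=float) + self.intercept_

    def to_concentration(self, intensity):
        return (np.asarray(intensity, dtype=float) - self.intercept_) / self.slope_

    def transform(self, intensity):
        return self.to_concentration(intensity)


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------


def baseline_correct(trace: PhotometryTrace, bleach_windows: Sequence, **kwargs) -> PhotometryTrace:
    """Fit and apply the cubic-spline baseline correction (see BaselineCorrector)."""
    return BaselineCorrector(exclude_windows=bleach_windows, **kwargs).correct(trace)


def fit_frap(trace: PhotometryTrace, src_sigma: float,
             geo: DetectionGeometry | None = None,
             bleach_event: tuple | None = None, **kwargs) -> FitResult:
    """Fit the recovery model to a trace; see :class:`FrapEstimator`.

    If ``bleach_event = (t0, duration)`` is given, the recovery segment is
    everything after ``t0 + duration`` with time re-zeroed at the bleach end;
    otherwise the whole trace is treated as an aligned recovery.
    """
    radius = geo.radius_r_detect if geo is not None else None
    t, y = trace.time, trace.intensity
    if bleach_event is not None:
        t0, dur = bleach_event
        m = t >= t0 + dur
        t, y = t[m] - (t0 + dur), y[m]
    est = FrapEstimator(sigma_um=src_sigma, radius_um=radius, **kwargs).fit(t, y)
    return est.result_


def fit_clearance(trace: PhotometryTrace, geo: DetectionGeometry | None = None,
                  src_sigma: float = 250.0, **kwargs) -> FitResult:
    """Fit the cleared arrival model to a concentration trace; see ClearanceEstimator."""
    r = geo.distance_r if geo is not None else 3335.0
    est = ClearanceEstimator(distance_r_um=r, sigma_um=src_sigma, **kwargs)
    est.fit(trace.time, trace.intensity)
    return est.result_


def fit_gaussian_profile(profile: HistologyProfile) -> FitResult:
    """Gaussian + baseline fit of a histology profile; see GaussianProfileModel."""
    return GaussianProfileModel().fit(profile.ap_distance, profile.mean_intensity).result_


def calibrate_intensity(known_concentrations, intensities) -> IntensityCalibration:
    """OLS intensity-vs-concentration calibration; see IntensityCalibration."""
    return IntensityCalibration().fit(known_concentrations, intensities)


def apply_calibration(trace: PhotometryTrace, curve: IntensityCalibration) -> PhotometryTrace:
    """Convert a trace from intensity to concentration units via a fitted calibration."""
    return PhotometryTrace(time=trace.time.copy(),
                           intensity=curve.to_concentration(trace.intensity),
                           labels=None if trace.labels is None else trace.labels.copy(),
                           meta={**trace.meta, "calibrated": True})
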