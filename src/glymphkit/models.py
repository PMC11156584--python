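"""Closed-form transport models for dye photobleaching, spread and clearance.

The physical picture: a fluorescent dye is either bleached in, or injected as,
a hemispherical Gaussian volume source of width ``sigma`` sitting at the brain
surface (or deep in tissue for injections).  Subsequent movement is hindered
diffusion with an effective tissue coefficient ``D = D_aq / lambda**2`` where
``lambda`` is the extracellular-space tortuosity.  The module provides

* the spreading Gaussian concentration field ``C(r, t)``,
* the moles of (bleached) dye inside a detection hemisphere of radius ``R``,
  with and without a superimposed bulk flow ``v``,
* the cosine-series solution for dye efflux from a gel slab (the "direct"
  diffusimetry geometry),
* first-order clearance kinetics ``clearance(%) = 100 t / (t + tau)`` and the
  cleared concentration curve,
* unit/temperature helpers (Stokes-Einstein viscosity correction, tortuosity).

Units are fixed internally: micrometres, seconds, um^2/s for diffusion
coefficients, degrees Celsius for temperatures.  Concentrations and
intensities are in arbitrary units; every fitted quantity (D, tau) is
scale-free in the amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.special import erf

__all__ = [
    "GaussianSource",
    "TransportParams",
    "DetectionGeometry",
    "FlowField",
    "SlabGeometry",
    "ClearanceModel",
    "BleachMapping",
    "QuadratureError",
    "concentration_profile",
    "moles_in_hemisphere",
    "moles_with_flow",
    "slab_efflux_concentration",
    "clearance_concentration",
    "clearance_percent",
    "tortuosity",
    "stokes_einstein_correct",
    "water_viscosity_mpa_s",
    "peak_arrival_time",
    "recovery_intensity",
    "bleach_spread_sigma",
]


class QuadratureError(RuntimeError):
    """Raised when an adaptive quadrature fails to converge."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _as_nonneg_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    _require(np.all(np.isfinite(arr)), f"{name} must be finite")
    _require(np.all(arr >= 0.0), f"{name} must be non-negative")
    return arr


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianSource:
    """Hemispherical Gaussian dye distribution.

    Parameters
    ----------
    c_peak : float
        Concentration at the centre of the distribution (arbitrary units).
    sigma : float
        Standard deviation of the Gaussian, in micrometres.
    """

    c_peak: float
    sigma: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.c_peak) and self.c_peak > 0, "c_peak must be > 0")
        _require(np.isfinite(self.sigma) and self.sigma > 0, "sigma must be > 0")


@dataclass(frozen=True)
class TransportParams:
    """Diffusion parameters of the medium.

    ``d_tissue`` is the effective (hindered) coefficient, ``d_aq`` the free
    aqueous/gel coefficient and ``lambda_tort`` the tortuosity.  When all
    three are given they must satisfy ``d_tissue = d_aq / lambda_tort**2``.
    All coefficients in um^2/s; ``temperature`` in Celsius (metadata only).
    """

    d_tissue: float
    d_aq: float | None = None
    lambda_tort: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        _require(np.isfinite(self.d_tissue) and self.d_tissue > 0, "d_tissue must be > 0")
        if self.d_aq is not None:
            _require(self.d_aq > 0, "d_aq must be > 0")
        if self.lambda_tort is not None:
            _require(self.lambda_tort > 0, "lambda_tort must be > 0")
        if self.d_aq is not None and self.lambda_tort is not None:
            implied = self.d_aq / self.lambda_tort**2
            _require(
                abs(implied - self.d_tissue) <= 1e-12 * abs(self.d_tissue),
                "d_tissue, d_aq and lambda_tort are inconsistent "
                "(d_tissue must equal d_aq / lambda_tort**2)",
            )

    @classmethod
    def from_aqueous(cls, d_aq: float, lambda_tort: float, temperature: float | None = None) -> "TransportParams":
        return cls(d_tissue=d_aq / lambda_tort**2, d_aq=d_aq, lambda_tort=lambda_tort, temperature=temperature)


@dataclass(frozen=True)
class DetectionGeometry:
    """Recording geometry: hemisphere radius ``R`` and source-detector distance ``r`` (um)."""

    radius_r_detect: float
    distance_r: float = 0.0

    def __post_init__(self) -> None:
        _require(self.radius_r_detect > 0, "radius_r_detect must be > 0")
        _require(self.distance_r >= 0, "distance_r must be >= 0")

    @classmethod
    def matched(cls, src: GaussianSource, distance_r: float = 0.0) -> "DetectionGeometry":
        """Default geometry with ``R = sigma`` (light penetration for bleaching
        and for recording are assumed comparable)."""
        return cls(radius_r_detect=src.sigma, distance_r=distance_r)


@dataclass(frozen=True)
class FlowField:
    """Bulk flow of speed ``velocity`` um/s directed away from the source."""

    velocity: float

    def __post_init__(self) -> None:
        _require(self.velocity >= 0, "velocity must be >= 0")


@dataclass(frozen=True)
class SlabGeometry:
    """Gel slab of thickness ``L`` with an impermeable face at ``x = 0``.

    The dye starts uniform at concentration ``c0`` and leaves through the
    open face at ``x = L``; the fluorescence is read at depth ``position_x``.
    """

    thickness_l: float
    position_x: float
    c0: float = 1.0

    def __post_init__(self) -> None:
        _require(self.thickness_l > 0, "thickness_l must be > 0")
        _require(0.0 <= self.position_x <= self.thickness_l, "position_x must lie in [0, L]")


@dataclass(frozen=True)
class ClearanceModel:
    """First-order saturating clearance with half-time ``tau`` seconds.

    ``tau = inf`` encodes the no-clearance (gel) limit.
    """

    tau: float

    def __post_init__(self) -> None:
        _require(self.tau > 0, "tau must be > 0")

    def survival(self, t) -> np.ndarray:
        """Fraction of dye remaining at time ``t``: ``1 - t/(t + tau)``."""
        t = _as_nonneg_array(t, "t")
        if np.isinf(self.tau):
            return np.ones_like(t)
        return self.tau / (t + self.tau)


@dataclass(frozen=True)
class BleachMapping:
    """Linear mapping between bleached moles and recorded intensity.

    ``i0`` is the intensity immediately after bleaching, ``i_inf`` the
    pre-bleach/equilibrium intensity, ``m0`` the moles of bleached dye at
    t = 0 (the scale of M(t); it cancels from M(t)/M(0)).
    """

    i0: float
    i_inf: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        _require(self.i_inf > self.i0, "i_inf must exceed i0")
        _require(self.m0 > 0, "m0 must be > 0")


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def concentration_profile(r, t, src: GaussianSource, tp: TransportParams):
    """Concentration of a spreading hemispherical Gaussian source.

    C(r, t) = C(0,0) [1 + 2Dt/sigma^2]^(-3/2) exp(-r^2 / (4Dt + 2 sigma^2))

    At ``t = 0`` this reduces to the initial Gaussian.  ``r`` and ``t`` may be
    arrays (broadcast together).
    """
    r = _as_nonneg_array(r, "r")
    t = _as_nonneg_array(t, "t")
    s2 = src.sigma**2
    denom = 4.0 * tp.d_tissue * t + 2.0 * s2
    out = src.c_peak * (1.0 + 2.0 * tp.d_tissue * t / s2) ** -1.5 * np.exp(-(r**2) / denom)
    return out if out.shape else float(out)


def moles_in_hemisphere(t, src: GaussianSource, tp: TransportParams,
                        geo: DetectionGeometry | None = None):
    """Moles of (bleached) dye inside the detection hemisphere of radius R.

    Closed form obtained by integrating ``2 pi r^2 C(r, t)`` from 0 to R:

    M(t) = 2 pi C(0,0) sigma^3 / sqrt(2Dt + sigma^2)
           * { sqrt(pi (2Dt + sigma^2) / 2) erf(R / sqrt(4Dt + 2 sigma^2))
               - R exp(-R^2 / (4Dt + 2 sigma^2)) }

    Strictly decreasing in ``t`` (the bleached dye dilutes away); tends to 0
    as ``t -> inf``.  Defaults to ``R = sigma``.
    """
    t = _as_nonneg_array(t, "t")
    geo = geo or DetectionGeometry.matched(src)
    R = geo.radius_r_detect
    s2 = src.sigma**2
    u = 2.0 * tp.d_tissue * t + s2
    out = (
        2.0 * np.pi * src.c_peak * src.sigma**3 / np.sqrt(u)
        * (np.sqrt(np.pi * u / 2.0) * erf(R / np.sqrt(2.0 * u)) - R * np.exp(-R**2 / (2.0 * u)))
    )
    return out if out.shape else float(out)


def moles_with_flow(t, src: GaussianSource, tp: TransportParams,
                    geo: DetectionGeometry, flow: FlowField,
                    rtol: float = 1e-9, atol: float = 1e-12):
    """Moles in the detection hemisphere when a bulk flow ``v`` displaces the source.

    M(t) = 2 pi C(0,0) [1 + 2Dt/sigma^2]^(-3/2) exp(-v^2 t^2 / (4Dt + 2 sigma^2))
           * int_0^R r^2 exp(-(r^2 + 2 r v t) / (4Dt + 2 sigma^2)) dr

    The radial integral has no closed form and is evaluated by adaptive
    quadrature (relative tolerance ``rtol``), with a 10^4-point Simpson rule
    as fallback.  At ``v = 0`` this reduces exactly to
    :func:`moles_in_hemisphere`; for fixed ``t > 0`` it is non-increasing in
    ``v`` (flow sweeps bleached dye out of the recording volume).
    """
    t_arr = np.atleast_1d(_as_nonneg_array(t, "t"))
    R = geo.radius_r_detect
    v = flow.velocity
    s2 = src.sigma**2
    D = tp.d_tissue

    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        denom = 4.0 * D * ti + 2.0 * s2
        pref = (
            2.0 * np.pi * src.c_peak
            * (1.0 + 2.0 * D * ti / s2) ** -1.5
            * np.exp(-(v * ti) ** 2 / denom)
        )

        def integrand(r, denom=denom):
            return r**2 * np.exp(-(r**2 + 2.0 * r * v * ti) / denom)

        val, err = integrate.quad(integrand, 0.0, R, epsrel=rtol, epsabs=atol, limit=200)
        if not np.isfinite(val) or (val != 0 and err > max(10 * rtol * abs(val), 10 * atol)):
            # fallback: dense fixed Simpson rule
            r_grid = np.linspace(0.0, R, 10_001)
            val2 = integrate.simpson(integrand(r_grid), x=r_grid)
            if not np.isfinite(val2):
                raise QuadratureError(
                    f"flow integral failed at t={ti}, v={v}: quad value={val}, err={err}"
                )
            val = val2
        out[i] = pref * val
    return out if np.ndim(t) else float(out[0])


def slab_efflux_concentration(t, geo: SlabGeometry, tp: TransportParams,
                              n_terms: int = 200):
    """Concentration in a slab draining through one face (cosine series).

    C(x, t) = (4 C0 / pi) sum_{n>=0} (-1)^n / (2n+1)
              exp(-D (2n+1)^2 pi^2 t / (4 L^2)) cos((2n+1) pi x / (2 L))

    The series is truncated when the next term magnitude falls below
    ``1e-12 * C0`` or after ``n_terms`` terms.  Because of the cosine factor
    the read-out is very insensitive to ``x`` for ``x << L``, which is what
    makes the geometry a practical diffusimeter.
    """
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(_as_nonneg_array(t, "t"))
    L, x, c0 = geo.thickness_l, geo.position_x, geo.c0
    D = tp.d_tissue
    acc = np.zeros_like(t)
    active = np.ones_like(t, dtype=bool)
    for n in range(n_terms):
        k = 2 * n + 1
        term = ((-1.0) ** n / k) * np.exp(-D * k**2 * np.pi**2 * t[active] / (4.0 * L**2)) \
            * np.cos(k * np.pi * x / (2.0 * L))
        acc[active] += term
        done = np.abs(term) < 1e-12 * np.pi / 4.0  # 1e-12 * c0 after the 4 c0/pi prefactor
        still = np.flatnonzero(active)
        active[still[done]] = False
        if not active.any():
            break
    out = 4.0 * c0 / np.pi * acc
    # at t = 0 the alternating series converges too slowly for truncation;
    # use the exact initial condition (uniform c0 inside, 0 at the open face)
    out[t == 0.0] = c0 if x < L else 0.0
    return float(out[0]) if scalar else out


def clearance_concentration(r, t, src: GaussianSource, tp: TransportParams,
                            cl: ClearanceModel):
    """Cleared concentration curve: the Gaussian spread scaled by the surviving fraction.

    C'(r, t) = (1 - t / (t + tau)) * C(r, t)

    Equals :func:`concentration_profile` exactly at t = 0 and in the
    ``tau -> inf`` (gel) limit.
    """
    t = _as_nonneg_array(t, "t")
    out = cl.survival(t) * concentration_profile(r, t, src, tp)
    return out if np.ndim(out) else float(out)


def clearance_percent(t, cl: ClearanceModel):
    """Percentage of dye cleared by time ``t``: ``100 t / (t + tau)``, in [0, 100)."""
    t = _as_nonneg_array(t, "t")
    out = 100.0 * (1.0 - cl.survival(t))
    return out if np.ndim(out) else float(out)


def tortuosity(d_tissue: float, d_aq: float) -> float:
    """Extracellular-space tortuosity ``lambda = sqrt(D_aq / D_tissue)``."""
    _require(d_tissue > 0 and d_aq > 0, "diffusion coefficients must be > 0")
    return float(np.sqrt(d_aq / d_tissue))


# Dynamic viscosity of pure water at 0.1 MPa, mPa s, standard handbook values.
# 37 C is included as an explicit node so physiological corrections use the
# tabulated value rather than an interpolant.
_WATER_VISCOSITY_TABLE_C = np.array(
    [0, 5, 10, 15, 20, 25, 30, 35, 37, 40, 45, 50, 55, 60,
     65, 70, 75, 80, 85, 90, 95, 100], dtype=float)
_WATER_VISCOSITY_TABLE_MPAS = np.array(
    [1.7911, 1.5192, 1.3069, 1.1382, 1.0016, 0.8900, 0.7972, 0.7191, 0.6913,
     0.6527, 0.5958, 0.5465, 0.5036, 0.4660, 0.4329, 0.4035, 0.3774, 0.3540,
     0.3330, 0.3142, 0.2971, 0.2816], dtype=float)


def water_viscosity_mpa_s(temp_c: float) -> float:
    """Viscosity of pure water (mPa s) by linear interpolation in the table above."""
    _require(np.isfinite(temp_c), "temperature must be finite")
    _require(0.0 <= temp_c <= 100.0, "temperature must be within 0-100 C")
    return float(np.interp(temp_c, _WATER_VISCOSITY_TABLE_C, _WATER_VISCOSITY_TABLE_MPAS))


def stokes_einstein_correct(d: float, t_from: float, t_to: float) -> float:
    """Temperature-correct a diffusion coefficient via Stokes-Einstein.

    D ~ T / eta(T), so D(T2) = D(T1) * (T2/T1) * (eta(T1)/eta(T2)) with
    absolute temperatures and the built-in water viscosity table.
    """
    _require(d > 0, "d must be > 0")
    eta_from = water_viscosity_mpa_s(t_from)
    eta_to = water_viscosity_mpa_s(t_to)
    return d * ((t_to + 273.15) / (t_from + 273.15)) * (eta_from / eta_to)


def peak_arrival_time(geo: DetectionGeometry, src: GaussianSource,
                      tp: TransportParams) -> float:
    """Time at which the arrival curve C(r, t) peaks at distance ``r``.

    Setting dC/dt = 0 for the spreading Gaussian gives
    ``sigma^2 + 2 D t = r^2 / 3``, i.e. ``t_peak = (r^2/3 - sigma^2) / (2 D)``.
    Independent of the amplitude.  For ``r^2 <= 3 sigma^2`` the curve is
    monotone decreasing and 0 is returned.
    """
    r = geo.distance_r
    t_pk = (r**2 / 3.0 - src.sigma**2) / (2.0 * tp.d_tissue)
    return float(max(t_pk, 0.0))


def recovery_intensity(t, mapping: BleachMapping, src: GaussianSource,
                       tp: TransportParams, geo: DetectionGeometry | None = None):
    """Post-bleach fluorescence recovery I(t) = I_inf - (I_inf - I0) M(t)/M(0).

    ``M(t)`` is the bleached-dye content of the detection hemisphere; as it
    diffuses away the recorded intensity recovers monotonically to ``I_inf``.
    """
    geo = geo or DetectionGeometry.matched(src)
    m0 = moles_in_hemisphere(0.0, src, tp, geo)
    m = moles_in_hemisphere(t, src, tp, geo)
    out = mapping.i_inf - (mapping.i_inf - mapping.i0) * m / m0
    return out if np.ndim(out) else float(out)


def bleach_spread_sigma(sigma_optical: float, tp: TransportParams,
                        bleach_duration: float, n_times: int = 61,
                        r_max_factor: float = 4.0) -> float:
    """Effective source width after diffusion during the bleach window.

    The bleached-dye distribution keeps spreading during the finite bleach
    (default 30 s).  The concentration profile is time-averaged over the
    bleach window and refit with a hemispherical Gaussian; the fitted sigma
    is the effective width to use in the recovery model.  Always >= the
    optical sigma and bounded above by the end-of-bleach analytic width
    sqrt(sigma^2 + 2 D * duration).
    """
    _require(sigma_optical > 0, "sigma_optical must be > 0")
    _require(bleach_duration >= 0, "bleach_duration must be >= 0")
    if bleach_duration == 0:
        return float(sigma_optical)

    src = GaussianSource(c_peak=1.0, sigma=sigma_optical)
    sigma_end = np.sqrt(sigma_optical**2 + 2.0 * tp.d_tissue * bleach_duration)
    r_grid = np.linspace(0.0, r_max_factor * sigma_end, 200)
    t_grid = np.linspace(0.0, bleach_duration, n_times)
    profiles = concentration_profile(r_grid[None, :], t_grid[:, None], src, tp)
    mean_profile = integrate.simpson(profiles, x=t_grid, axis=0) / bleach_duration

    def gauss(r, a, s):
        return a * np.exp(-(r**2) / (2.0 * s**2))

    try:
        popt, _ = optimize.curve_fit(
            gauss, r_grid, mean_profile,
            p0=[mean_profile[0], sigma_optical],
            bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological parameters
        raise RuntimeError(f"Gaussian fit of time-averaged bleach profile failed: {exc}")
    return float(popt[1])
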