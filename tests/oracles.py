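"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed forms in ``glymphkit.models``: direct
adaptive quadrature of the concentration field, a Crank-Nicolson finite
difference solver for the slab problem, and Monte-Carlo integration of the
advected-source integral.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate
from scipy.linalg import solve_banded

from glymphkit import models


def hemisphere_moles_quadrature(src, tp, radius, t, rtol=1e-11):
    """Moles in the hemisphere by adaptive quadrature of 2 pi r^2 C(r, t)."""
    val, _ = integrate.quad(
        lambda r: 2.0 * np.pi * r**2 * models.concentration_profile(r, t, src, tp),
        0.0, radius, epsrel=rtol, epsabs=0.0, limit=500,
    )
    return val


def total_mass_quadrature(src, tp, t, rtol=1e-10):
    """Total moles 2 pi int_0^inf r^2 C(r, t) dr by adaptive quadrature.

    Split at a multiple of the instantaneous spreading width so the
    infinite-interval transform cannot step over the integrand's peak.
    """
    width = np.sqrt(src.sigma**2 + 2.0 * tp.d_tissue * t)

    def f(r):
        return 2.0 * np.pi * r**2 * models.concentration_profile(r, t, src, tp)

    inner, _ = integrate.quad(f, 0.0, 20.0 * width, epsrel=rtol, epsabs=0.0, limit=500)
    outer, _ = integrate.quad(f, 20.0 * width, np.inf, epsrel=rtol,
                              epsabs=rtol * abs(inner), limit=500)
    return inner + outer


def crank_nicolson_slab(tau_stars, x_over_l, nx=401, dt=5e-5, n_rannacher=20):
    """Slab drain-out solved on the dimensionless problem u_t = u_xx.

    Reflecting boundary at x* = 0, absorbing at x* = 1, u(x, 0) = 1.
    Crank-Nicolson time stepping with a few damped backward-Euler startup
    steps (Rannacher smoothing of the initial boundary discontinuity).
    Returns u(x_over_l, tau*) for each requested dimensionless time.
    """
    tau_stars = np.sort(np.asarray(tau_stars, dtype=float))
    dx = 1.0 / (nx - 1)
    u = np.ones(nx)
    u[-1] = 0.0

    def banded_matrices(theta, step):
        # (I - theta r A) u_new = (I + (1-theta) r A) u_old, A = tridiag Laplacian
        r = step / dx**2
        ab = np.zeros((3, nx))
        lower = np.zeros((3, nx))
        main_new = np.full(nx, 1.0 + 2.0 * theta * r)
        off_new = np.full(nx, -theta * r)
        main_old = np.full(nx, 1.0 - 2.0 * (1 - theta) * r)
        off_old = np.full(nx, (1 - theta) * r)
        return r, main_new, off_new, main_old, off_old

    def step(u, step_dt, theta):
        r = step_dt / dx**2
        a = -theta * r
        b = 1.0 + 2.0 * theta * r
        ab = np.zeros((3, nx))
        ab[0, 1:] = a
        ab[1, :] = b
        ab[2, :-1] = a
        # reflecting (ghost) node at 0: u[-1] = u[1]
        ab[0, 1] = 2.0 * a
        # absorbing at nx-1
        ab[0, -1] = 0.0
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
        rhs = u.copy()
        s = (1 - theta) * r
        rhs[1:-1] = u[1:-1] + s * (u[2:] - 2 * u[1:-1] + u[:-2])
        rhs[0] = u[0] + s * (2 * u[1] - 2 * u[0])
        rhs[-1] = 0.0
        return solve_banded((1, 1), ab, rhs)

    out = []
    t_now = 0.0
    targets = iter(tau_stars)
    target = next(targets, None)
    # startup: backward Euler at dt/10
    for _ in range(n_rannacher):
        u = step(u, dt / 10.0, theta=1.0)
        t_now += dt / 10.0
    while target is not None:
        while t_now + dt <= target + 1e-15:
            u = step(u, dt, theta=0.5)
            t_now += dt
        rem = target - t_now
        if rem > 1e-15:
            u = step(u, rem, theta=0.5)
            t_now = target
        xi = x_over_l / dx
        i0 = int(np.floor(xi))
        w = xi - i0
        out.append((1 - w) * u[i0] + w * u[min(i0 + 1, nx - 1)])
        target = next(targets, None)
    return np.array(out)


def mc_flow_moles(src, tp, radius, velocity, t, n_samples=10_000_000, seed=0):
    """Monte-Carlo estimate of the advected-source hemisphere moles.

    Uniform sampling of the radial integral of the displaced Gaussian
    (the same physical integrand as the flow model, evaluated pointwise,
    estimated stochastically rather than by quadrature).
    """
    rng = np.random.default_rng(seed)
    denom = 4.0 * tp.d_tissue * t + 2.0 * src.sigma**2
    pref = (
        2.0 * np.pi * src.c_peak
        * (1.0 + 2.0 * tp.d_tissue * t / src.sigma**2) ** -1.5
        * np.exp(-((velocity * t) ** 2) / denom)
    )
    r = rng.uniform(0.0, radius, size=n_samples)
    f = r**2 * np.exp(-(r**2 + 2.0 * r * velocity * t) / denom)
    return pref * radius * float(f.mean())
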