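"""Seeded synthetic-data generators.

Each generator is the exact forward model of the matching estimator in
:mod:`glymphkit.fitting` / :mod:`glymphkit.sleep` — the noiseless mean is
produced by the same model code the fitters use — so round-trip parameter
recovery is a meaningful identifiability check.  All randomness flows from
the explicit ``seed`` of each scenario (``numpy.random.default_rng``); there
is no hidden global state.

Default conditions mirror the experimental design the models were built
for: a 150-um bleach width with matched detection radius, 30-s bleach
pulses, 1 Hz recovery sampling, a ~6 %/h baseline decline and 1 % CV
multiplicative photometry noise for recovery traces; a 250-um injected
bolus observed at 3335 um with 0.2 Hz sampling over 8 h and 2 % CV noise
for arrival curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models
from .fitting import HistologyProfile, PhotometryTrace
from .models import (
    BleachMapping,
    ClearanceModel,
    DetectionGeometry,
    GaussianSource,
    TransportParams,
)

__all__ = [
    "FrapScenario",
    "ClearanceScenario",
    "SleepScenario",
    "gen_frap_trace",
    "gen_clearance_trace",
    "gen_histology_profiles",
    "gen_sleep_features",
    "gen_toy_eeg_emg",
    "STATE_FEATURE_MEANS",
]

STATES = ("wake", "nrem", "rem")

FEATURE_COLUMNS = ("delta_power", "theta_power", "theta_delta_ratio", "emg_rms")

# Default per-state feature centroids (delta power, theta power, theta/delta,
# EMG RMS; arbitrary units).  Wake: low delta, high muscle tone; NREM: high
# delta, low tone; REM: theta-dominated, atonia.
STATE_FEATURE_MEANS = {
    "wake": np.array([1.0, 1.3, 1.3, 3.0]),
    "nrem": np.array([4.5, 1.1, 0.24, 0.6]),
    "rem": np.array([0.9, 3.2, 3.6, 0.25]),
}


@dataclass
class FrapScenario:
    """Photobleaching-recovery recording conditions.

    ``bleach_times`` are bleach-pulse start times (s); pulses must be
    separated by at least ``min_separation_s`` so each recovery is
    (near-)complete before the next pulse.
    """

    d_true: float = 136.0
    sigma: float = 150.0
    radius_r_detect: float | None = None  # default: = sigma
    bleach_times: tuple = (3600.0,)
    bleach_duration: float = 30.0
    drift_rate: float = 0.06  # fractional baseline loss per hour
    noise_cv: float = 0.01
    i0: float = 0.2
    i_inf: float = 1.0
    fs: float = 1.0
    duration: float = 7200.0
    min_separation_s: float = 1800.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_true", "sigma", "bleach_duration", "fs", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0 or self.drift_rate < 0:
            raise ValueError("noise_cv and drift_rate must be >= 0")
        times = sorted(self.bleach_times)
        if any(b - a < self.min_separation_s for a, b in zip(times, times[1:])):
            raise ValueError("bleach events must be separated by the recovery horizon")


@dataclass
class ClearanceScenario:
    """Dye-arrival (clearance) recording conditions.

    The default geometry is the deep-injection / cortical-readout pair:
    source width 250 um observed at the coordinate-derived separation of
    3335 um.  ``tau_true = inf`` gives the no-clearance (gel) limit.
    """

    d_true: float = 230.7
    tau_true: float = 1800.0
    sigma: float = 250.0
    distance_r: float = 3335.0
    c_peak: float = 1.0
    duration: float = 28800.0
    dt: float = 5.0
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_true", "tau_true", "sigma", "distance_r", "c_peak", "duration", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass
class SleepScenario:
    """Vigilance-state feature-stream conditions.

    ``state_sequence`` is a per-5-s-bin sequence over {wake, nrem, rem}; if
    None, a bout-structured sequence with roughly 45/40/15 % wake/NREM/REM
    occupancy is generated from the seed.  ``means``/``covariances`` give the
    per-state multivariate-normal feature model for
    (delta_power, theta_power, theta_delta_ratio, emg_rms).
    """

    n_bins: int = 720
    bin_size: float = 5.0
    state_sequence: tuple | None = None
    means: dict = field(default_factory=lambda: {k: v.copy() for k, v in STATE_FEATURE_MEANS.items()})
    covariances: dict | None = None  # default: diagonal, sd = 10 % of each mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariances is None:
            self.covariances = {s: np.diag((0.1 * self.means[s]) ** 2) for s in self.means}
        for s, cov in self.covariances.items():
            cov = np.asarray(cov, dtype=float)
            if not np.allclose(cov, cov.T) or np.any(np.linalg.eigvalsh(cov) < -1e-12):
                raise ValueError(f"covariance for state '{s}' must be positive semi-definite")
        if self.state_sequence is not None:
            if any(s not in STATES for s in self.state_sequence):
                raise ValueError("states must be in {wake, nrem, rem}")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _drift(t: np.ndarray, rate_per_hour: float) -> np.ndarray:
    """Multiplicative baseline drift: (1 - rate)^(t / 1 h), i.e. an exact
    ``rate`` fractional loss over each hour."""
    if rate_per_hour == 0:
        return np.ones_like(t)
    return (1.0 - rate_per_hour) ** (t / 3600.0)


def gen_frap_trace(sc: FrapScenario) -> PhotometryTrace:
    """Simulate a photometry trace with bleach pulses, drift and noise.

    The pre-bleach baseline sits at ``i_inf``; each bleach pulse ramps the
    signal down to ``i0`` over ``bleach_duration`` and the post-bleach
    segment follows :func:`glymphkit.models.recovery_intensity` exactly
    (before drift and noise).  Drift multiplies the whole signal;
    multiplicative Gaussian noise with CV ``noise_cv`` is applied last.
    """
    rng = np.random.default_rng(sc.seed)
    t = np.arange(0.0, sc.duration, 1.0 / sc.fs)
    base = np.full_like(t, sc.i_inf)

    src = GaussianSource(c_peak=1.0, sigma=sc.sigma)
    tp = TransportParams(d_tissue=sc.d_true)
    geo = DetectionGeometry(radius_r_detect=sc.radius_r_detect or sc.sigma)
    mapping = BleachMapping(i0=sc.i0, i_inf=sc.i_inf)

    ends = sorted(sc.bleach_times)
    for j, tb in enumerate(ends):
        te = tb + sc.bleach_duration
        nxt = ends[j + 1] if j + 1 < len(ends) else np.inf
        ramp = (t >= tb) & (t < te)
        base[ramp] = sc.i_inf + (sc.i0 - sc.i_inf) * (t[ramp] - tb) / sc.bleach_duration
        rec = (t >= te) & (t < nxt)
        base[rec] = models.recovery_intensity(t[rec] - te, mapping, src, tp, geo)

    intensity = base * _drift(t, sc.drift_rate)
    if sc.noise_cv > 0:
        intensity = intensity * (1.0 + sc.noise_cv * rng.standard_normal(t.shape))
    return PhotometryTrace(time=t, intensity=intensity,
                           meta={"scenario": "frap", "seed": sc.seed, "d_true": sc.d_true})


def gen_clearance_trace(sc: ClearanceScenario) -> PhotometryTrace:
    """Simulate a dye-arrival curve with first-order clearance and noise.

    The noiseless mean is exactly
    :func:`glymphkit.models.clearance_concentration` evaluated at
    ``distance_r`` over the sampling grid; multiplicative Gaussian noise
    with CV ``noise_cv`` is applied on top.
    """
    rng = np.random.default_rng(sc.seed)
    t = np.arange(0.0, sc.duration + sc.dt / 2, sc.dt)
    src = GaussianSource(c_peak=sc.c_peak, sigma=sc.sigma)
    tp = TransportParams(d_tissue=sc.d_true)
    cl = ClearanceModel(tau=sc.tau_true)
    c = models.clearance_concentration(sc.distance_r, t, src, tp, cl)
    if sc.noise_cv > 0:
        c = c * (1.0 + sc.noise_cv * rng.standard_normal(t.shape))
    return PhotometryTrace(time=t, intensity=c,
                           meta={"scenario": "clearance", "seed": sc.seed,
                                 "d_true": sc.d_true, "tau_true": sc.tau_true})


def gen_histology_profiles(d: float, tau: float, t_kill: float = 3 * 3600.0,
                           noise_cv: float = 0.05, seed: int = 0,
                           sigma: float = 250.0, c_peak: float = 1.0,
                           ap_extent: float = 4080.0,
                           spacing: float = 240.0) -> HistologyProfile:
    """Simulate an anterior-posterior histology intensity profile.

    Samples the cleared spread model along the AP axis at the kill time
    (typically 3 h or 5 h).  The resulting profile is Gaussian in distance
    with standard deviation ``sqrt(sigma^2 + 2 D t_kill)``; its amplitude
    decreases with ``t_kill`` for finite ``tau`` (clearance) and with the
    dilution factor.  Spacing defaults to groups of four 60-um slices.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(-ap_extent, ap_extent + spacing / 2, spacing)
    src = GaussianSource(c_peak=c_peak, sigma=sigma)
    tp = TransportParams(d_tissue=d)
    cl = ClearanceModel(tau=tau)
    y = models.clearance_concentration(np.abs(x), t_kill, src, tp, cl)
    if noise_cv > 0:
        y = y * (1.0 + noise_cv * rng.standard_normal(x.shape))
    return HistologyProfile(ap_distance=x, mean_intensity=np.clip(y, 0.0, None))


def _default_state_sequence(n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Bout-structured state sequence with realistic occupancies."""
    occupancy = {"wake": 0.45, "nrem": 0.40, "rem": 0.15}
    mean_bout = {"wake": 24, "nrem": 18, "rem": 8}  # bins of 5 s
    seq: list[str] = []
    state = "wake"
    while len(seq) < n_bins:
        length = max(1, int(rng.exponential(mean_bout[state])))
        seq.extend([state] * length)
        probs = np.array([occupancy[s] if s != state else 0.0 for s in STATES])
        state = rng.choice(STATES, p=probs / probs.sum())
    return np.array(seq[:n_bins])


def gen_sleep_features(sc: SleepScenario) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a per-bin EEG/EMG feature stream conditioned on state.

    Returns ``(features, labels)`` where ``features`` has columns
    ``bin_start_s, delta_power, theta_power, theta_delta_ratio, emg_rms``
    and ``labels`` are the planted states.  Features are drawn from the
    per-state multivariate normals; with zero covariance they equal the
    state means exactly.
    """
    rng = np.random.default_rng(sc.seed)
    if sc.state_sequence is None:
        labels = _default_state_sequence(sc.n_bins, rng)
    else:
        labels = np.asarray(sc.state_sequence)
    n = labels.size
    feats = np.empty((n, 4))
    for s in STATES:
        idx = np.flatnonzero(labels == s)
        if idx.size == 0:
            continue
        cov = np.asarray(sc.covariances[s], dtype=float)
        if np.allclose(cov, 0.0):
            feats[idx] = sc.means[s]
        else:
            feats[idx] = rng.multivariate_normal(sc.means[s], cov, size=idx.size,
                                                 method="cholesky" if _is_pd(cov) else "svd")
    frame = pd.DataFrame(feats, columns=list(FEATURE_COLUMNS))
    frame.insert(0, "bin_start_s", np.arange(n) * sc.bin_size)
    return frame, labels


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def gen_toy_eeg_emg(labels, fs: float = 200.0, bin_size: float = 5.0,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Toy raw EEG/EMG waveforms for exercising the filter / band-power path.

    Each 5-s bin contains state-dependent sinusoids (delta 2.5 Hz, theta
    7 Hz) plus white noise for the EEG and amplitude-modulated noise for the
    EMG.  This is a band-power test signal, not a physiological waveform
    model.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    n_per_bin = int(round(fs * bin_size))
    amp = {  # (delta amp, theta amp, emg amp)
        "wake": (0.5, 1.0, 2.0),
        "nrem": (3.0, 0.5, 0.4),
        "rem": (0.5, 2.5, 0.15),
    }
    eeg = np.empty(labels.size * n_per_bin)
    emg = np.empty_like(eeg)
    tt = np.arange(n_per_bin) / fs
    for i, s in enumerate(labels):
        a_d, a_t, a_e = amp[s]
        sl = slice(i * n_per_bin, (i + 1) * n_per_bin)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        eeg[sl] = (a_d * np.sin(2 * np.pi * 2.5 * tt + phase[0])
                   + a_t * np.sin(2 * np.pi * 7.0 * tt + phase[1])
                   + 0.1 * rng.standard_normal(n_per_bin))
        emg[sl] = a_e * rng.standard_normal(n_per_bin)
    return eeg, emg
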