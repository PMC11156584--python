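"""Vigilance-state scoring from EEG/EMG signals.

Pipeline: filter the raw signals (EEG high-pass 0.5 Hz; EMG band-pass
1-50 Hz), compute per-5-s-bin features — delta (1-4 Hz) and theta (5-10 Hz)
band powers from a Welch periodogram, their ratio, and the EMG RMS — then
classify bins into wake / NREM / REM with a 3-component full-covariance
Gaussian mixture on standardized log-features.  Mixture components are
mapped to states by a fixed rule: the component with the highest EMG RMS is
wake; of the remaining two, the one with the higher theta/delta ratio is
REM and the other NREM.  There is no temporal model: bins are scored
independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture

__all__ = [
    "DELTA_BAND",
    "THETA_BAND",
    "Hypnogram",
    "compute_features",
    "SleepScorer",
    "gmm_score",
    "confusion_metrics",
    "summarize_hypnogram",
]

STATES = ("wake", "nrem", "rem")
FEATURE_COLUMNS = ("delta_power", "theta_power", "theta_delta_ratio", "emg_rms")

DELTA_BAND = (1.0, 4.0)
# Variant used for depth-of-sleep correlations; pass as delta_band override.
DELTA_BAND_WIDE = (0.5, 4.0)
THETA_BAND = (5.0, 10.0)


@dataclass
class Hypnogram:
    """Per-bin vigilance states on a contiguous, gap-free 5-s grid."""

    states: np.ndarray
    bin_size: float = 5.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        bad = set(np.unique(self.states)) - set(STATES)
        if bad:
            raise ValueError(f"unknown states: {sorted(bad)}")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")

    @property
    def bin_start(self) -> np.ndarray:
        return np.arange(self.states.size) * self.bin_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start_s": self.bin_start, "state": self.states})


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple) -> float:
    """Integrated PSD over a frequency band (trapezoid on the Welch grid)."""
    m = (freqs >= band[0]) & (freqs <= band[1])
    if np.count_nonzero(m) < 2:
        return float(psd[m].sum() * (freqs[1] - freqs[0])) if m.any() else 0.0
    return float(np.trapezoid(psd[m], freqs[m]))


def compute_features(eeg, emg, fs: float, bin_size: float = 5.0,
                     delta_band: tuple = DELTA_BAND,
                     theta_band: tuple = THETA_BAND,
                     welch_window_s: float = 2.0) -> pd.DataFrame:
    """Per-bin EEG band powers, theta/delta ratio and EMG RMS.

    EEG is high-pass filtered at 0.5 Hz and EMG band-pass filtered at
    1-50 Hz (2nd-order Butterworth, zero-phase).  Band powers come from a
    Welch periodogram per bin (Hann windows of ``welch_window_s``, 50 %
    overlap).  Requires ``fs > 100`` Hz so the 50 Hz EMG band edge is
    resolvable.
    """
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if fs <= 100.0:
        raise ValueError("sampling rate must exceed 100 Hz for the 1-50 Hz EMG band")
    n_per_bin = int(round(fs * bin_size))
    if eeg.size < n_per_bin or emg.size < n_per_bin:
        raise ValueError("signals must span at least one bin")

    sos_eeg = signal.butter(2, 0.5, btype="highpass", fs=fs, output="sos")
    sos_emg = signal.butter(2, [1.0, 50.0], btype="bandpass", fs=fs, output="sos")
    eeg_f = signal.sosfiltfilt(sos_eeg, eeg)
    emg_f = signal.sosfiltfilt(sos_emg, emg)

    n_bins = min(eeg_f.size, emg_f.size) // n_per_bin
    nperseg = int(round(fs * welch_window_s))
    rows = []
    for i in range(n_bins):
        sl = slice(i * n_per_bin, (i + 1) * n_per_bin)
        freqs, psd = signal.welch(eeg_f[sl], fs=fs, window="hann",
                                  nperseg=nperseg, noverlap=nperseg // 2)
        delta = _band_power(freqs, psd, delta_band)
        theta = _band_power(freqs, psd, theta_band)
        ratio = theta / delta if delta > 0 else np.nan
        rms = float(np.sqrt(np.mean(emg_f[sl] ** 2)))
        rows.append((i * bin_size, delta, theta, ratio, rms))
    return pd.DataFrame(rows, columns=["bin_start_s", *FEATURE_COLUMNS])


class SleepScorer(BaseEstimator, ClassifierMixin):
    """GMM vigilance-state classifier on standardized log-features.

    A 3-component full-covariance Gaussian mixture is fitted to
    ``log(delta_power, theta_power, theta_delta_ratio, emg_rms)`` after
    z-scoring (band powers are right-skewed, so the log makes the
    per-state clusters roughly Gaussian).  Components are mapped to states
    deterministically from their feature profiles (highest EMG -> wake;
    then higher theta/delta -> REM).  Singular components are refit with
    increased covariance regularization.
    """

    def __init__(self, n_states: int = 3, seed: int = 0, reg_covar: float = 1e-6,
                 min_bins: int = 50):
        self.n_states = n_states
        self.seed = seed
        self.reg_covar = reg_covar
        self.min_bins = min_bins

    @staticmethod
    def _feature_matrix(features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            X = features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        else:
            X = np.asarray(features, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("features must have 4 columns "
                             "(delta_power, theta_power, theta_delta_ratio, emg_rms)")
        return X

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Z = np.log(np.clip(X, 1e-12, None))
        return (Z - self.log_mean_) / self.log_std_

    def fit(self, features, y=None) -> "SleepScorer":
        X = self._feature_matrix(features)
        if X.shape[0] < self.min_bins:
            raise ValueError(f"need at least {self.min_bins} bins to fit the mixture")
        Z = np.log(np.clip(X, 1e-12, None))
        self.log_mean_ = Z.mean(axis=0)
        self.log_std_ = np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
        Zs = (Z - self.log_mean_) / self.log_std_

        reg = self.reg_covar
        for attempt in range(4):
            gmm = GaussianMixture(n_components=self.n_states, covariance_type="full",
                                  reg_covar=reg, n_init=5, random_state=self.seed)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error", RuntimeWarning)
                    gmm.fit(Zs)
                break
            except Exception:
                reg *= 100.0
                warnings.warn(f"singular mixture component; refitting with reg_covar={reg:g}")
        else:  # pragma: no cover
            raise RuntimeError("Gaussian mixture fit failed even with heavy regularization")
        self.gmm_ = gmm

        # component -> state mapping from per-component mean features
        comp = gmm.predict(Zs)
        mean_feat = np.empty((self.n_states, X.shape[1]))
        for k in range(self.n_states):
            members = X[comp == k]
            if members.shape[0] > 0:
                mean_feat[k] = members.mean(axis=0)
            else:  # empty component: fall back to its model mean
                mean_feat[k] = np.exp(gmm.means_[k] * self.log_std_ + self.log_mean_)
        mapping = {}
        wake_k = int(np.argmax(mean_feat[:, 3]))  # highest EMG RMS
        mapping[wake_k] = "wake"
        rest = [k for k in range(self.n_states) if k != wake_k]
        rem_k = rest[int(np.argmax(mean_feat[rest, 2]))]  # higher theta/delta
        mapping[rem_k] = "rem"
        for k in rest:
            mapping.setdefault(k, "nrem")
        self.component_state_ = mapping
        return self

    def predict(self, features) -> np.ndarray:
        X = self._feature_matrix(features)
        comp = self.gmm_.predict(self._transform(X))
        return np.array([self.component_state_[k] for k in comp])

    def predict_proba(self, features) -> pd.DataFrame:
        """Per-bin posterior probability of each state."""
        X = self._feature_matrix(features)
        resp = self.gmm_.predict_proba(self._transform(X))
        out = pd.DataFrame(0.0, index=range(X.shape[0]), columns=list(STATES))
        for k, state in self.component_state_.items():
            out[state] += resp[:, k]
        return out


def gmm_score(features, n_states: int = 3, seed: int = 0) -> tuple[Hypnogram, pd.DataFrame]:
    """Fit the GMM scorer and return (hypnogram, per-bin state posteriors)."""
    scorer = SleepScorer(n_states=n_states, seed=seed).fit(features)
    states = scorer.predict(features)
    return Hypnogram(states=states), scorer.predict_proba(features)


def confusion_metrics(pred: Hypnogram | np.ndarray, truth: Hypnogram | np.ndarray) -> pd.DataFrame:
    """One-vs-rest sensitivity and specificity per state."""
    p = pred.states if isinstance(pred, Hypnogram) else np.asarray(pred)
    t = truth.states if isinstance(truth, Hypnogram) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("hypnograms must have equal length")
    rows = {}
    for s in STATES:
        tp = np.sum((p == s) & (t == s))
        fn = np.sum((p != s) & (t == s))
        fp = np.sum((p == s) & (t != s))
        tn = np.sum((p != s) & (t != s))
        rows[s] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
        }
    return pd.DataFrame(rows).T


def summarize_hypnogram(h: Hypnogram, window: tuple | None = None) -> dict:
    """Fraction of time in each state within ``window = (start_s, end_s)``."""
    starts = h.bin_start
    m = np.ones(starts.shape, dtype=bool)
    if window is not None:
        start, end = window
        if start < 0 or end > starts[-1] + h.bin_size:
            raise ValueError("window outside the record")
        m = (starts >= start) & (starts < end)
    sel = h.states[m]
    n = max(sel.size, 1)
    return {s: float(np.sum(sel == s)) / n for s in STATES}
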