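"""Per-window sEMG features: time-domain, spectral, wavelet, fuzzy entropy.

Ten features per channel, in four families:

* **T** (time domain): IAV — mean absolute amplitude; VAR — mean-square
  power with 1/(N-1) normalisation and *no* mean subtraction (surface EMG
  is approximately zero-mean, and the power reading is the intended
  quantity); ZC — threshold-gated zero-crossing count.
* **F** (frequency domain): mean power frequency (spectral centroid) and
  median frequency (half-power split) of a one-sided PSD estimate.
* **W** (wavelet): mean and singular value of the level-P approximation
  and detail coefficient vectors of a db5 multilevel decomposition
  (default P = 6).  The singular value of a 1-by-M coefficient row is its
  Euclidean norm.
* **S** (complexity): fuzzy entropy, a smooth-membership relative of
  sample entropy.

``extract_features`` assembles the windows-by-features matrix with
channels-major column order and carries the window phase labels through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pywt
from scipy.signal import periodogram, welch
from scipy.spatial.distance import cdist

from .preprocessing import WindowSet

__all__ = [
    "PSD",
    "FuEnParams",
    "FeatureMatrix",
    "FEATURE_ORDER",
    "FAMILY_FEATURES",
    "iav",
    "var_power",
    "zero_crossings",
    "estimate_psd",
    "mean_power_frequency",
    "median_frequency",
    "wavelet_decompose",
    "wavelet_features",
    "fuzzy_entropy",
    "extract_features",
]

#: Fixed within-channel feature order of the assembled matrix.
FEATURE_ORDER = (
    "IAV", "VAR", "ZC", "MPF", "MF",
    "A6_mean", "A6_sv", "D6_mean", "D6_sv", "FuEn",
)
FAMILY_FEATURES = {
    "T": ("IAV", "VAR", "ZC"),
    "F": ("MPF", "MF"),
    "W": ("A6_mean", "A6_sv", "D6_mean", "D6_sv"),
    "S": ("FuEn",),
}


@dataclass(frozen=True)
class PSD:
    """One-sided power spectral density on an ascending frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        f, p = np.asarray(self.freqs, float), np.asarray(self.power, float)
        if f.shape != p.shape:
            raise ValueError("freqs and power must have the same length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class FuEnParams:
    """Fuzzy-entropy parameters.

    ``n`` is the embedding (phase-space) dimension, ``r`` the similarity
    tolerance, ``p`` the membership exponent of exp(-(d/r)^p).  With
    ``r_mode="sd"`` the tolerance is ``r`` times the window's standard
    deviation (floored at ``r_floor`` for degenerate windows).
    """

    n: int = 2
    r: float = 0.15
    p: float = 2.0
    r_mode: str = "sd"  # "sd" (fraction of SD) or "absolute"
    r_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("embedding dimension n must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be positive")
        if self.p <= 0:
            raise ValueError("membership exponent p must be positive")
        if self.r_mode not in ("sd", "absolute"):
            raise ValueError("r_mode must be 'sd' or 'absolute'")


@dataclass
class FeatureMatrix:
    """Windows-by-features table with named columns and per-window labels."""

    values: pd.DataFrame
    labels: np.ndarray
    window_starts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.values) != self.labels.size:
            raise ValueError("labels length must match number of rows")
        if self.window_starts is None:
            self.window_starts = np.arange(len(self.values))
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "window_start", self.window_starts)
        out.insert(1, "label", self.labels)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        starts = df.pop("window_start").to_numpy()
        labels = df.pop("label").to_numpy()
        return cls(df, labels, starts)

    def select_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.iloc[idx].reset_index(drop=True),
            self.labels[idx],
            np.asarray(self.window_starts)[idx],
        )


# ---------------------------------------------------------------------------
# time domain


def iav(window_channel: np.ndarray) -> float:
    """Integral of absolute value: mean |x_k| over the window."""
    x = np.asarray(window_channel, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(x)))


def var_power(window_channel: np.ndarray) -> float:
    """Mean-square power with 1/(N-1) normalisation, no mean subtraction."""
    x = np.asarray(window_channel, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sum(x * x) / (x.size - 1))


def zero_crossings(window_channel: np.ndarray, eps: float = 0.0) -> int:
    """Count of adjacent sign changes with amplitude swing at least ``eps``.

    The threshold guards against counting crossings produced by low-level
    noise around zero.
    """
    x = np.asarray(window_channel, dtype=float)
    if eps < 0:
        raise ValueError("eps must be non-negative")
    a, b = x[:-1], x[1:]
    return int(np.count_nonzero((a * b < 0) & (np.abs(a - b) >= eps)))


# ---------------------------------------------------------------------------
# frequency domain


def estimate_psd(
    window_channel: np.ndarray,
    fs: float,
    method: str = "welch",
    nperseg: int = 128,
    noverlap: int | None = None,
) -> PSD:
    """One-sided PSD on a uniform grid over [0, fs/2].

    ``method="periodogram"`` uses a rectangular window and satisfies the
    discrete Parseval identity (sum P * df equals the mean-square signal
    power); ``method="welch"`` averages Hann-windowed segments with 50 %
    overlap for a lower-variance estimate used in feature extraction.
    """
    x = np.asarray(window_channel, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.size < 8:
        raise ValueError("need at least 8 samples for a PSD estimate")
    if method == "periodogram":
        f, p = periodogram(x, fs=fs, window="boxcar", detrend=False)
    elif method == "welch":
        nper = min(nperseg, x.size)
        f, p = welch(
            x, fs=fs, window="hann", nperseg=nper,
            noverlap=nper // 2 if noverlap is None else noverlap, detrend=False,
        )
    else:
        raise ValueError(f"unknown PSD method: {method!r}")
    return PSD(f, p)


def mean_power_frequency(psd: PSD) -> float:
    """Spectral centroid: sum f*P(f) / sum P(f) over the grid."""
    total = float(np.sum(psd.power))
    if total <= 0:
        raise ValueError("degenerate spectrum: total power is zero")
    return float(np.sum(psd.freqs * psd.power) / total)


def median_frequency(psd: PSD) -> float:
    """Frequency splitting the spectrum into equal-power halves.

    Linear interpolation of the cumulative power between grid points
    removes the grid-resolution bias of a nearest-bin rule.
    """
    p = psd.power
    total = float(np.sum(p))
    if total <= 0:
        raise ValueError("degenerate spectrum: total power is zero")
    cum = np.cumsum(p)
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(psd.freqs[0])
    prev = cum[i - 1]
    frac = (half - prev) / (cum[i] - prev) if cum[i] > prev else 0.0
    return float(psd.freqs[i - 1] + frac * (psd.freqs[i] - psd.freqs[i - 1]))


# ---------------------------------------------------------------------------
# wavelet


def wavelet_decompose(
    window_channel: np.ndarray, wavelet: str = "db5", levels: int = 6
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Multilevel (Mallat) DWT with symmetric extension.

    Returns ``(s_P, [d_1, ..., d_P])`` — the level-P approximation and the
    detail components from finest to coarsest.  The decomposition is
    perfectly invertible: reconstructing from all components returns the
    input to numerical precision.
    """
    x = np.asarray(window_channel, dtype=float)
    flen = pywt.Wavelet(wavelet).dec_len
    if x.size < flen:
        raise ValueError(
            f"signal of length {x.size} too short for wavelet {wavelet}"
        )
    if levels < 1:
        raise ValueError("levels must be >= 1")
    with warnings.catch_warnings():
        # depth beyond dwt_max_level is intentional for short windows
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric")
    approx = coeffs[0]
    details = list(reversed(coeffs[1:]))  # d_1 (finest) .. d_P (coarsest)
    return approx, details


def wavelet_features(
    window_channel: np.ndarray, wavelet: str = "db5", levels: int = 6
) -> tuple[float, float, float, float]:
    """Mean and singular value of the level-P approximation and detail.

    A coefficient vector viewed as a 1-by-M matrix has a single singular
    value equal to its Euclidean norm, which is what is reported.
    Returns ``(A_mean, A_sv, D_mean, D_sv)``.
    """
    approx, details = wavelet_decompose(window_channel, wavelet, levels)
    detail = details[-1]
    return (
        float(np.mean(approx)),
        float(np.linalg.norm(approx)),
        float(np.mean(detail)),
        float(np.linalg.norm(detail)),
    )


# ---------------------------------------------------------------------------
# fuzzy entropy


def _phi(x: np.ndarray, m: int, r: float, p: float) -> float:
    """Mean fuzzy similarity of all pairs of baseline-removed m-templates."""
    n_vec = x.size - m
    idx = np.arange(m) + np.arange(n_vec)[:, None]
    templates = x[idx]
    templates = templates - templates.mean(axis=1, keepdims=True)
    d = cdist(templates, templates, metric="chebyshev")
    sim = np.exp(-((d / r) ** p))
    np.fill_diagonal(sim, 0.0)
    return float(sim.sum() / (n_vec * (n_vec - 1)))


def fuzzy_entropy(window_channel: np.ndarray, params: FuEnParams = FuEnParams()) -> float:
    """Fuzzy entropy FuEn(n, N, r) = ln phi^n - ln phi^(n+1).

    Templates of length n and n+1 have their own mean removed; similarity
    between templates i and j is exp(-(d_ij / r)^p) with d the Chebyshev
    distance; phi^m averages similarity over ordered pairs i != j.  Higher
    values mean lower self-similarity, i.e. a more complex sequence.
    """
    x = np.asarray(window_channel, dtype=float)
    if x.size < params.n + 2:
        raise ValueError(
            f"need at least n + 2 = {params.n + 2} samples, got {x.size}"
        )
    if params.r_mode == "sd":
        r = params.r * float(np.std(x))
        if r < params.r_floor:  # zero-variance window: all templates identical
            return 0.0
    else:
        r = params.r
    phi_n = _phi(x, params.n, r, params.p)
    phi_n1 = _phi(x, params.n + 1, r, params.p)
    if phi_n <= 0 or phi_n1 <= 0:
        return 0.0
    return float(np.log(phi_n) - np.log(phi_n1))


# ---------------------------------------------------------------------------
# assembly


def extract_features(
    windows: WindowSet,
    fs: float | None = None,
    families: Sequence[str] = ("T", "F", "W", "S"),
    zc_eps: float = 0.0,
    psd_method: str = "welch",
    wavelet: str = "db5",
    wavelet_levels: int = 6,
    fuen_params: FuEnParams = FuEnParams(),
    var_subtract_mean: bool = False,
) -> FeatureMatrix:
    """Per-window, per-channel feature matrix for the enabled families.

    Columns are named ``<channel>.<feature>`` and ordered channels-major
    with the fixed feature order IAV, VAR, ZC, MPF, MF, A6_mean, A6_sv,
    D6_mean, D6_sv, FuEn within each channel block.  With all four
    families enabled on 8 channels this yields 80 columns.
    """
    if len(windows) == 0:
        raise ValueError("empty window set")
    for fam in families:
        if fam not in FAMILY_FEATURES:
            raise ValueError(f"unknown feature family: {fam!r}")
    fs = windows.fs if fs is None else fs
    enabled = [f for f in FEATURE_ORDER
               if any(f in FAMILY_FEATURES[fam] for fam in families)]
    names = [f"{ch}.{feat}" for ch in windows.channel_names for feat in enabled]

    rows = np.empty((len(windows), len(names)))
    for w in range(len(windows)):
        col = 0
        for c in range(windows.n_channels):
            x = windows.data[w, :, c]
            vals: dict[str, float] = {}
            if "T" in families:
                vals["IAV"] = iav(x)
                xc = x - x.mean() if var_subtract_mean else x
                vals["VAR"] = var_power(xc)
                vals["ZC"] = float(zero_crossings(x, zc_eps))
            if "F" in families:
                psd = estimate_psd(x, fs, method=psd_method)
                vals["MPF"] = mean_power_frequency(psd)
                vals["MF"] = median_frequency(psd)
            if "W" in families:
                a_m, a_sv, d_m, d_sv = wavelet_features(x, wavelet, wavelet_levels)
                vals["A6_mean"], vals["A6_sv"] = a_m, a_sv
                vals["D6_mean"], vals["D6_sv"] = d_m, d_sv
            if "S" in families:
                vals["FuEn"] = fuzzy_entropy(x, fuen_params)
            for feat in enabled:
                rows[w, col] = vals[feat]
                col += 1
    df = pd.DataFrame(rows, columns=names)
    return FeatureMatrix(df, windows.labels.copy(), windows.starts.copy())
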