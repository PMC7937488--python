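"""Raw-signal conditioning: wavelet denoising and translation-window cutting.

Surface EMG arrives contaminated by broadband instrumentation noise.  The
denoiser here exploits the classic Mallat–Hwang observation that wavelet
modulus maxima produced by genuine signal structure (non-negative Lipschitz
regularity) persist, with non-decreasing magnitude, as the analysis scale
coarsens, whereas maxima produced by noise decay and die out.  Detail
coefficients of an undecimated transform are kept only near maxima that
form such persistent cross-scale chains; everything else is zeroed before
inverse reconstruction.  A plain soft-threshold denoiser is available as a
robust fallback, selected by the ``denoise.method`` config key.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .synthetic import Recording

__all__ = [
    "Window",
    "WindowSet",
    "denoise_modulus_maxima",
    "denoise_soft_threshold",
    "denoise_recording",
    "sliding_windows",
]


@dataclass(frozen=True)
class Window:
    """One labelled analysis window, half-open ``[start, start + n)``."""

    start: int
    data: np.ndarray  # (n, n_channels)
    label: int


@dataclass
class WindowSet:
    """Fixed-length labelled windows cut from one recording."""

    data: np.ndarray  # (n_windows, n, n_channels)
    starts: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def window_length(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def __getitem__(self, i: int) -> Window:
        return Window(int(self.starts[i]), self.data[i], int(self.labels[i]))


def _local_maxima(mag: np.ndarray) -> np.ndarray:
    """Indices of strict-or-plateau local maxima of a non-negative sequence."""
    if mag.size < 3:
        return np.array([], dtype=int)
    idx = np.flatnonzero((mag[1:-1] >= mag[:-2]) & (mag[1:-1] > mag[2:])) + 1
    return idx[mag[idx] > 1e-12 * max(mag.max(), 1e-300)]


def denoise_modulus_maxima(
    signal: np.ndarray,
    wavelet: str = "db5",
    levels: int = 5,
    persistence_min: int = 2,
) -> np.ndarray:
    """Wavelet modulus-maximum denoising of a single channel.

    Computes an undecimated (stationary) wavelet transform to ``levels``
    scales, finds local maxima of the detail-coefficient modulus at every
    scale, and keeps a maximum only if it starts a chain across at least
    ``persistence_min`` adjacent scales whose magnitude does not decrease
    towards coarser scales — the signature of signal rather than noise.
    Detail coefficients within one wavelet support of a retained maximum
    survive; all others are zeroed before inverse reconstruction.

    Output length equals input length.
    """
    x = np.asarray(signal, dtype=float)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if x.size < 2**levels:
        raise ValueError(
            f"signal of length {x.size} too short for {levels} stationary levels"
        )
    if not np.any(x):
        return np.zeros_like(x)

    # SWT needs a length divisible by 2**levels; reflect-pad then crop.
    n = x.size
    block = 2**levels
    pad = (-n) % block
    xp = np.pad(x, (0, pad), mode="symmetric") if pad else x

    coeffs = pywt.swt(xp, wavelet, level=levels, trim_approx=True)
    # coeffs = [cA_L, cD_L, cD_{L-1}, ..., cD_1]
    details = [coeffs[levels - j + 1] for j in range(1, levels + 1)]  # d_1 .. d_L
    mags = [np.abs(d) for d in details]
    maxima = [_local_maxima(m) for m in mags]

    flen = pywt.Wavelet(wavelet).dec_len
    half_support = [max(2, ((flen - 1) * 2 ** (j - 1)) // 2) for j in range(1, levels + 1)]

    masks = [np.zeros(xp.size, dtype=bool) for _ in range(levels)]
    for j0 in range(levels):  # 0-based scale index, finest first
        cand = maxima[j0]
        if cand.size == 0:
            continue
        for t in cand:
            visited = [(j0, t)]
            cur_t, cur_mag = t, mags[j0][t]
            for j in range(j0 + 1, levels):
                w = half_support[j]
                pool = maxima[j]
                if pool.size == 0:
                    break
                lo = np.searchsorted(pool, cur_t - w)
                hi = np.searchsorted(pool, cur_t + w, side="right")
                near = pool[lo:hi]
                ok = near[mags[j][near] >= cur_mag]
                if ok.size == 0:
                    break
                # nearest qualifying maximum is the chain's parent
                nxt = ok[np.argmin(np.abs(ok - cur_t))]
                visited.append((j, nxt))
                cur_t, cur_mag = nxt, mags[j][nxt]
            if len(visited) >= persistence_min:
                for j, tj in visited:
                    # quarter-support neighbourhood: wide enough to keep the
                    # maximum's lobe, narrow enough to reject nearby noise
                    w = max(1, half_support[j] // 4)
                    masks[j][max(0, tj - w) : tj + w + 1] = True

    new_coeffs = [coeffs[0]]  # keep the coarsest approximation untouched
    for j in range(levels, 0, -1):  # cD_L first
        new_coeffs.append(details[j - 1] * masks[j - 1])
    out = pywt.iswt(new_coeffs, wavelet)
    return out[:n]


def denoise_soft_threshold(
    signal: np.ndarray, wavelet: str = "db5", levels: int = 5
) -> np.ndarray:
    """Universal soft-threshold wavelet denoising (VisuShrink)."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2**levels:
        raise ValueError("signal too short for requested decomposition depth")
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="symmetric")
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1)) / 0.6745 if d1.size else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(x.size, 2)))
    new = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    return pywt.waverec(new, wavelet, mode="symmetric")[: x.size]


def denoise_recording(
    recording: Recording,
    method: str = "modulus_maxima",
    wavelet: str = "db5",
    levels: int = 5,
    persistence_min: int = 2,
) -> Recording:
    """Apply the selected denoiser channel-by-channel; labels pass through."""
    if method == "none":
        return recording
    if method == "modulus_maxima":
        cols = [
            denoise_modulus_maxima(recording.samples[:, c], wavelet, levels, persistence_min)
            for c in range(recording.n_channels)
        ]
    elif method == "soft_threshold":
        cols = [
            denoise_soft_threshold(recording.samples[:, c], wavelet, levels)
            for c in range(recording.n_channels)
        ]
    else:
        raise ValueError(f"unknown denoise method: {method!r}")
    return Recording(
        np.column_stack(cols),
        recording.labels,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
    )


def sliding_windows(recording: Recording, n: int = 256, step: int = 64) -> WindowSet:
    """Cut a recording into labelled translation windows.

    Windows of length ``n`` start at 0, step, 2*step, ... — in total
    ``floor((n_samples - n)/step) + 1`` of them, each fully inside the
    recording (half-open indexing).  A window's label is the majority
    phase over its samples; ties break to the earliest phase in cycle
    order.
    """
    if n < 2:
        raise ValueError("window length must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if n > recording.n_samples:
        raise ValueError(
            f"window length {n} exceeds recording length {recording.n_samples}"
        )
    n_win = (recording.n_samples - n) // step + 1
    starts = np.arange(n_win) * step
    data = np.stack([recording.samples[s : s + n] for s in starts])
    labels = np.array(
        [np.bincount(recording.labels[s : s + n], minlength=4).argmax() for s in starts]
    )
    return WindowSet(data, starts, labels, recording.fs, list(recording.channel_names))
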