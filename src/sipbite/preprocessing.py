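"""Stream conditioning: downsampling, low-pass filtering, causal smoothing.

The pipeline order is downsample -> Butterworth low-pass -> half-Gaussian
smoothing.  Every stage is causal (a single forward pass) so the identical
code path can run on a live stream: output sample i depends only on input
samples 0..i.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .core import RunConfig, SensorStream


def downsample(stream: SensorStream, factor: int = 2) -> SensorStream:
    """Keep every ``factor``-th sample starting at index 0; fs' = fs/factor."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return stream
    return SensorStream(
        t0=stream.t0,
        fs=stream.fs / factor,
        acc=stream.acc[::factor].copy(),
        gyro=stream.gyro[::factor].copy(),
    )


def lowpass(stream: SensorStream, cutoff_hz: float, order: int = 4) -> SensorStream:
    """Causal per-channel Butterworth low-pass with unit DC gain."""
    if not 0 < cutoff_hz < stream.fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={stream.fs / 2} Hz)"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=stream.fs, output="sos")
    # zi seeded with the first sample's steady state avoids a startup step
    zi = sps.sosfilt_zi(sos)

    def _filt(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        for c in range(x.shape[1]):
            out[:, c], _ = sps.sosfilt(sos, x[:, c], zi=zi * x[0, c])
        return out

    if stream.n == 0:
        return stream
    return SensorStream(
        t0=stream.t0, fs=stream.fs, acc=_filt(stream.acc), gyro=_filt(stream.gyro)
    )


def half_gaussian_kernel(sigma_s: float, fs: float, trunc: float = 3.0) -> np.ndarray:
    """Past-side half of a Gaussian, normalized to sum 1.

    ``kernel[0]`` weights the current sample, ``kernel[j]`` the sample j
    steps in the past; truncated at ``trunc`` standard deviations.
    """
    if not sigma_s > 0:
        raise ValueError("sigma_s must be > 0")
    sigma = sigma_s * fs
    half = max(1, int(np.ceil(trunc * sigma)))
    lags = np.arange(half + 1, dtype=float)
    k = np.exp(-0.5 * (lags / sigma) ** 2)
    return k / k.sum()


def half_gaussian_smooth(stream: SensorStream, sigma_s: float) -> SensorStream:
    """Causal smoothing by convolution with the past half of a Gaussian.

    The kernel is renormalized over the available history near the stream
    start, so a constant signal is exactly preserved everywhere.
    """
    k = half_gaussian_kernel(sigma_s, stream.fs)

    def _smooth(x: np.ndarray) -> np.ndarray:
        out = np.empty_like(x)
        # cumulative kernel mass actually available at each early index
        norm = np.cumsum(k)
        for c in range(x.shape[1]):
            full = np.convolve(x[:, c], k, mode="full")[: x.shape[0]]
            m = np.minimum(np.arange(x.shape[0]), len(k) - 1)
            out[:, c] = full / norm[m]
        return out

    if stream.n == 0:
        return stream
    return SensorStream(
        t0=stream.t0, fs=stream.fs, acc=_smooth(stream.acc), gyro=_smooth(stream.gyro)
    )


def preprocess(stream: SensorStream, config: RunConfig | None = None) -> SensorStream:
    """Full conditioning pipeline: downsample, low-pass, half-Gaussian smooth."""
    config = config or RunConfig()
    out = downsample(stream, config.downsample_factor)
    out = lowpass(out, config.lowpass_cutoff_hz, config.lowpass_order)
    out = half_gaussian_smooth(out, config.smooth_sigma_s)
    return out
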