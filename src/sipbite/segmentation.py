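"""Windowing of the data stream: FW, DW and DFW.

Three segmentation strategies feed the two recognition branches:

* ``fixed_windows`` (FW) — classic fixed-length windows with fractional
  overlap; used by the eating branch (10 s, 25 % overlap by default).
* ``dynamic_windows`` (DW) — online dynamic segmentation of a 1-D signal:
  the stream is split at the end of every descending run whose drop
  (run maximum minus run minimum) exceeds a dynamic threshold computed
  from the dispersion of the previous N samples.
* ``dynamic_fixed_windows`` (DFW) — a dynamic splitting of fixed-length
  blocks: the dynamic threshold state is reset and a split is forced every
  t seconds, so no window ever exceeds t seconds; used by the drinking
  branch with t matched to the eating-branch window length (10 s).

For wrist data the input signal of the dynamic methods is the magnitude of
the gyroscope, whose sharp drops trail the rotational peaks of a drinking
gesture (grab/raise and put-down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SensorStream, Window


@dataclass(frozen=True)
class DwParams:
    """Dynamic-threshold parameters for DW/DFW.

    threshold(i) = max(floor, scale * std(signal[i-N:i])), where the std is
    over the previous ``N`` input samples (2 s at 50 Hz by default).  Before
    N samples of history exist, the threshold falls back to ``floor``.
    """

    N: int = 100
    scale: float = 2.0
    floor: float = 0.1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")


def gyro_magnitude(stream: SensorStream) -> np.ndarray:
    """Per-sample Euclidean norm of the three gyroscope channels."""
    return np.linalg.norm(stream.gyro, axis=1)


def fixed_windows(
    n: int, fs: float, length_s: float = 10.0, overlap: float = 0.25
) -> list[Window]:
    """Fixed-length windows with fractional overlap; trailing partial dropped."""
    length = int(round(length_s * fs))
    if length < 1:
        raise ValueError("window length must be at least one sample")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    stride = max(1, int(round(length * (1.0 - overlap))))
    out = []
    start = 0
    while start + length <= n:
        out.append(Window(start, start + length, "FW"))
        start += stride
    return out


def _rolling_std(x: np.ndarray, N: int) -> np.ndarray:
    """std of the previous N samples: out[i] = std(x[i-N:i]); NaN while i < N."""
    n = len(x)
    out = np.full(n, np.nan)
    if n <= N:
        return out
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(N, n)
    s1 = c1[i] - c1[i - N]
    s2 = c2[i] - c2[i - N]
    var = np.maximum(s2 / N - (s1 / N) ** 2, 0.0)
    out[N:] = np.sqrt(var)
    return out


def _dw_scan(
    signal: np.ndarray, params: DwParams, offset: int, method: str
) -> list[Window]:
    """Descending-run scan over one contiguous block of ``signal``.

    History for the dynamic threshold starts at the block start; the run
    restarts whenever the signal rises above its running minimum by more
    than ``floor`` (keeps noise from fragmenting runs).  The threshold of
    a run is frozen when the run starts — the drop is judged against the
    dispersion of the signal *before* the change, so a large peak cannot
    mask its own descending flank.  A qualifying run closes a window at
    the end of the drop (just past the run minimum).
    """
    n = len(signal)
    if n == 0:
        return []
    theta = _rolling_std(signal, params.N)

    def thresh(i):
        t = theta[i]
        return params.floor if np.isnan(t) else max(params.floor,
                                                    params.scale * t)

    boundaries = []
    run_max = signal[0]
    run_min = signal[0]
    run_min_idx = 0
    run_theta = thresh(0)
    for i in range(1, n):
        x = signal[i]
        if x > run_min + params.floor:
            # run ended: check whether its drop beats the run's threshold
            if run_max - run_min > run_theta and run_min_idx + 1 < n:
                boundaries.append(run_min_idx + 1)
            run_max = x
            run_min = x
            run_min_idx = i
            run_theta = thresh(i)
        else:
            if x < run_min:
                run_min = x
                run_min_idx = i
            if x > run_max:
                run_max = x
    out = []
    prev = 0
    for b in boundaries:
        if b > prev:
            out.append(Window(offset + prev, offset + b, method))
            prev = b
    if prev < n:
        out.append(Window(offset + prev, offset + n, method))
    return out


def dynamic_windows(signal: np.ndarray, params: DwParams | None = None) -> list[Window]:
    """DW segmentation of a 1-D signal; windows partition the signal."""
    params = params or DwParams()
    signal = np.asarray(signal, dtype=float)
    return _dw_scan(signal, params, 0, "DW")


def dynamic_fixed_windows(
    signal: np.ndarray,
    fs: float,
    t_s: float = 10.0,
    params: DwParams | None = None,
) -> list[Window]:
    """DFW segmentation: DW run independently on consecutive t-second blocks.

    Splits are forced at every multiple of ``t_s * fs`` samples and the
    threshold history resets at each block start, bounding every window to
    at most ``t_s`` seconds.
    """
    params = params or DwParams()
    signal = np.asarray(signal, dtype=float)
    block = int(round(t_s * fs))
    if block < 1:
        raise ValueError("t_s * fs must be at least one sample")
    out: list[Window] = []
    for start in range(0, len(signal), block):
        seg = signal[start : start + block]
        for w in _dw_scan(seg, params, start, "DFW"):
            out.append(w)
    return out
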