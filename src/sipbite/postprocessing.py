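"""Daily-evidence restriction layer applied on top of the branch outputs.

The raw classifier outputs are filtered with simple rules derived from
what is known about meals and drinks in a normal day:

* **E1 — time-of-day meal probability.** The probability of a meal by
  time of day is a sum of three unit-peak Gaussians (breakfast 8:00,
  lunch 12:30, dinner 20:00, sigma 1.5 h), clipped at 1.  Window ``i`` is
  flagged eating only if

      pmeal(i) = sum_{n=0..N} pclass(i-n) * ptime(i-n) / N  >  0.5

  with N = 3 (the printed formula sums N+1 terms over N and is applied
  literally; the boundary pmeal = 0.5 is *not* eating).
* **minute smoothing** — a minute counts as eating only when more than
  three of its six 10-s units are flagged.
* **E2 — minimum meal duration.** Runs of eating minutes shorter than
  5 min are discarded.
* **E3 — pre-meal energy peak** (off by default): a meal must be preceded
  within a lookback horizon by a peak of the acceleration energy signal.
* **D1 — rotational peak.** A positive drinking window must contain at
  least one local maximum of the gyroscope magnitude above a threshold.

Finally the surviving meal intervals and drink events are fused onto the
non-overlapping 10-s unit grid with precedence drink > eat > other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import RunConfig, Window
from .models import PredictionTimeline


@dataclass(frozen=True)
class MealProbabilityProfile:
    """Sum-of-Gaussians meal likelihood by hour of day, clipped to [0, 1]."""

    centers_h: tuple[float, ...] = (8.0, 12.5, 20.0)
    sigma_h: float = 1.5

    def __call__(self, t_hours) -> np.ndarray | float:
        t = np.asarray(t_hours, dtype=float)
        p = np.zeros_like(t)
        for c in self.centers_h:
            p += np.exp(-((t - c) ** 2) / (2.0 * self.sigma_h**2))
        p = np.minimum(p, 1.0)
        return float(p) if np.isscalar(t_hours) else p


def meal_probability(t_hours, profile: MealProbabilityProfile | None = None):
    """Meal probability at ``t_hours`` (hours of day, scalar or array)."""
    return (profile or MealProbabilityProfile())(t_hours)


def meal_evidence(pclass: np.ndarray, ptime: np.ndarray, N: int = 3) -> np.ndarray:
    """Smoothed meal evidence pmeal(i) = sum_{n=0..N} pclass(i-n)*ptime(i-n) / N.

    The printed formula sums N+1 terms over N and is applied literally;
    the first N windows use whatever history exists (still divided by N).
    """
    pclass = np.asarray(pclass, dtype=float)
    ptime = np.asarray(ptime, dtype=float)
    if pclass.shape != ptime.shape:
        raise ValueError("pclass and ptime must be aligned")
    prod = pclass * ptime
    pmeal = np.empty_like(prod)
    for i in range(len(prod)):
        lo = max(0, i - N)
        pmeal[i] = prod[lo : i + 1].sum() / N
    return pmeal


def apply_E1(
    pclass: np.ndarray,
    ptime: np.ndarray,
    N: int = 3,
    threshold: float = 0.5,
) -> np.ndarray:
    """Meal-probability gating on the window grid.

    A window stays flagged as eating only when it is raw-positive
    (pclass > 0.5) *and* the smoothed evidence satisfies pmeal > 0.5 (the
    boundary pmeal = 0.5 is not eating).  E1 is a restriction: it can
    only remove positives, never add them, which keeps the whole layer
    monotone — near a meal-probability peak the smoothed evidence alone
    would otherwise pass windows the classifier itself rejected.
    """
    pclass = np.asarray(pclass, dtype=float)
    pmeal = meal_evidence(pclass, ptime, N)
    return (pclass > 0.5) & (pmeal > threshold)


def minute_smooth(unit_flags: np.ndarray) -> np.ndarray:
    """Collapse 10-s unit flags to minute flags: > 3 of 6 positive units.

    Minute blocks are non-overlapping groups of six consecutive units
    anchored at the stream start; a trailing partial minute uses its
    available units against the same ``> 3`` count.
    """
    flags = np.asarray(unit_flags, dtype=bool)
    n_min = int(np.ceil(len(flags) / 6))
    out = np.zeros(n_min, dtype=bool)
    for m in range(n_min):
        out[m] = flags[6 * m : 6 * m + 6].sum() > 3
    return out


def windows_to_units(
    windows: list[Window], values: np.ndarray, fs: float, n: int, unit_s: float = 10.0
) -> np.ndarray:
    """Resample per-window values onto the non-overlapping unit grid.

    Each unit takes the value of the window whose center is nearest the
    unit center (earlier window on ties); units beyond the last window
    repeat the final value.  Works for boolean flags and probabilities.
    """
    values = np.asarray(values)
    n_units = int(np.ceil(n / (unit_s * fs)))
    if not windows:
        return np.zeros(n_units, dtype=values.dtype)
    centers = np.array([w.mid_idx() / fs for w in windows])
    unit_centers = (np.arange(n_units) + 0.5) * unit_s
    idx = np.searchsorted(centers, unit_centers)
    idx = np.clip(idx, 0, len(centers) - 1)
    left = np.clip(idx - 1, 0, len(centers) - 1)
    use_left = np.abs(unit_centers - centers[left]) <= np.abs(
        unit_centers - centers[idx]
    )
    idx[use_left] = left[use_left]
    return values[idx]


def apply_E2(
    minute_flags: np.ndarray, min_meal_min: int = 5
) -> list[tuple[int, int]]:
    """Keep only runs of eating minutes at least ``min_meal_min`` long.

    Returns half-open minute-index intervals ``[start, end)``.
    """
    flags = np.asarray(minute_flags, dtype=bool)
    out = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_meal_min:
                out.append((start, i))
            start = None
    if start is not None and len(flags) - start >= min_meal_min:
        out.append((start, len(flags)))
    return out


def energy_signal(acc_mag: np.ndarray, fs: float, win_s: float = 5.0,
                  gravity: float = 9.80665) -> np.ndarray:
    """Causal moving-average energy of the gravity-removed acceleration.

    energy[i] = mean over the trailing ``win_s`` of (|a| - g)^2.
    """
    if not win_s > 0:
        raise ValueError("win_s must be > 0")
    dev2 = (np.asarray(acc_mag, dtype=float) - gravity) ** 2
    w = max(1, int(round(win_s * fs)))
    c = np.concatenate([[0.0], np.cumsum(dev2)])
    i = np.arange(1, len(dev2) + 1)
    lo = np.maximum(i - w, 0)
    return (c[i] - c[lo]) / (i - lo)


def apply_E3(
    meal_minutes: list[tuple[int, int]],
    energy: np.ndarray,
    fs: float,
    lookback_s: float = 120.0,
    k: float = 3.0,
) -> list[tuple[int, int]]:
    """Keep meals preceded by an acceleration-energy peak.

    A meal survives iff the maximum energy within ``lookback_s`` before
    its start exceeds ``k`` times the stream's median energy.  Meals
    starting before the lookback horizon evaluate whatever history exists
    (an empty history rejects the meal).
    """
    if not lookback_s > 0:
        raise ValueError("lookback_s must be > 0")
    med = float(np.median(energy)) if len(energy) else 0.0
    out = []
    for start_min, end_min in meal_minutes:
        i1 = int(start_min * 60 * fs)
        i0 = max(0, i1 - int(round(lookback_s * fs)))
        if i1 > i0 and energy[i0:i1].max() > k * med:
            out.append((start_min, end_min))
    return out


def apply_D1(
    windows: list[Window],
    probs: np.ndarray,
    gyro_mag: np.ndarray,
    fs: float,
    peak_thresh: float = 60.0,
    min_sep_s: float = 0.25,
    prob_threshold: float = 0.5,
) -> list[tuple[float, float, float]]:
    """Rotational-peak filter on positive drinking windows.

    A window with probability above ``prob_threshold`` becomes a drink
    event iff it contains at least one local maximum of the gyroscope
    magnitude above ``peak_thresh`` (deg/s).  Returns events as
    ``(start_s, end_s, probability)`` relative to the stream start.
    """
    events = []
    dist = max(1, int(round(min_sep_s * fs)))
    for w, p in zip(windows, probs):
        if p <= prob_threshold:
            continue
        seg = gyro_mag[w.start_idx : w.end_idx]
        peaks, _ = find_peaks(seg, height=peak_thresh, distance=dist)
        if len(peaks):
            events.append((w.start_idx / fs, w.end_idx / fs, float(p)))
    return events


def fuse(
    meal_minutes: list[tuple[int, int]],
    drink_events: list[tuple[float, float, float]],
    n_units: int,
    unit_s: float = 10.0,
) -> list[str]:
    """Fuse meals and drinks onto the 10-s unit grid.

    A unit is ``drink`` when a drink event overlaps it, else ``eat`` when
    inside a meal interval, else ``other``.
    """
    out = np.full(n_units, "other", dtype=object)
    for start_min, end_min in meal_minutes:
        u0 = int(start_min * 60 / unit_s)
        u1 = min(n_units, int(end_min * 60 / unit_s))
        out[u0:u1] = "eat"
    for s, e, _ in drink_events:
        u0 = int(s / unit_s)
        u1 = min(n_units, int(np.ceil(e / unit_s)))
        out[u0:max(u1, u0 + 1)] = "drink"
    return list(out)


@dataclass
class PostProcessResult:
    """Everything the restriction layer produces for one timeline."""

    raw_unit_flags: np.ndarray          # eating flags on the 10-s grid, no E1/E2
    raw_minute_flags: np.ndarray        # minute smoothing only
    gated_minute_flags: np.ndarray      # after E1 + minute smoothing
    meal_minutes: list[tuple[int, int]]
    drink_events: list[tuple[float, float, float]]
    fused_units: list[str]
    unit_s: float = 10.0


def postprocess(
    timeline: PredictionTimeline, config: RunConfig | None = None
) -> PostProcessResult:
    """Full restriction layer: E1 -> minute smoothing -> E2 (+E3), and D1.

    The default pipeline matches the best-performing restriction
    combination: E1 + E2 for eating and D1 for drinking; E3 is available
    but disabled unless ``config.apply_e3``.
    """
    config = config or RunConfig()
    profile = MealProbabilityProfile(config.meal_centers_h, config.meal_sigma_h)
    hours = np.array(
        [(timeline.t0 + w.mid_idx() / timeline.fs) / 3600.0 % 24.0
         for w in timeline.fw_windows]
    )
    ptime = profile(hours)
    gated = apply_E1(timeline.eat_probs, ptime, config.smoothing_N,
                     config.meal_threshold)
    raw_pos = timeline.eat_probs > 0.5

    n_units = int(np.ceil(timeline.n / (10.0 * timeline.fs)))
    raw_units = windows_to_units(timeline.fw_windows, raw_pos, timeline.fs,
                                 timeline.n)
    gated_units = windows_to_units(timeline.fw_windows, gated, timeline.fs,
                                   timeline.n)
    raw_minutes = minute_smooth(raw_units)
    gated_minutes = minute_smooth(gated_units)
    meals = apply_E2(gated_minutes, config.min_meal_min)
    if config.apply_e3:
        energy = energy_signal(timeline.acc_mag, timeline.fs,
                               config.energy_win_s, config.gravity)
        meals = apply_E3(meals, energy, timeline.fs,
                         config.energy_lookback_s, config.energy_k)
    drinks = apply_D1(
        timeline.dfw_windows, timeline.drink_probs, timeline.gyro_mag,
        timeline.fs, config.drink_peak_thresh, config.drink_peak_sep_s,
    )
    fused = fuse(meals, drinks, n_units)
    return PostProcessResult(
        raw_unit_flags=raw_units,
        raw_minute_flags=raw_minutes,
        gated_minute_flags=gated_minutes,
        meal_minutes=meals,
        drink_events=drinks,
        fused_units=fused,
    )
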