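"""Seeded generator of labeled synthetic wrist-IMU days.

The generator emulates a free-living day recorded from the dominant wrist
at 100 Hz, in which eating occupies a few percent of the time and drinking
well under one percent.  The signal model is deliberately additive and
template-based:

    sensor(t) = gravity baseline (slowly wandering orientation)
              + activity template        (per scheduled segment)
              + white noise

Activity templates:

* ``idle`` / ``desk`` — low-variance noise (desk slightly livelier with
  occasional small wrist adjustments).
* ``walk`` — ~2 Hz periodic arm swing on the accelerometer with a weaker
  first harmonic, plus a moderate periodic gyro swing.
* ``eat`` — a quiet manipulative baseline with a periodic low-amplitude
  hand-to-mouth rotation burst (one bite every ``gesture period`` seconds).
* ``drink`` — a 5-8 s gesture whose gyroscope magnitude shows exactly two
  prominent peaks (grab/raise and put-down) separated by a low-rotation
  tilted hold.
* ``table_game`` / ``nail_biting`` — distractor confusers: sparse
  aperiodic manipulation bursts over a table, and small fast repetitive
  wrist rotations near the mouth.

A day plan schedules meals, drink events and background segments; the
generator renders the stream and returns the exactly matching label track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GRAVITY, LabeledInterval, LabelTrack, SensorStream

KINDS = ("eat", "drink", "walk", "desk", "idle", "table_game", "nail_biting")


@dataclass(frozen=True)
class MealSpec:
    """One planned meal."""

    start_h: float
    duration_min: float
    gesture_period_s: float = 8.0
    pre_burst: bool = True

    def __post_init__(self) -> None:
        if self.duration_min < 1:
            raise ValueError("meal duration must be >= 1 min")


@dataclass(frozen=True)
class DrinkSpec:
    """One planned drink event."""

    start_h: float
    duration_s: float = 7.0
    peak_amp: float = 150.0  # deg/s

    def __post_init__(self) -> None:
        if not 2.0 <= self.duration_s <= 15.0:
            raise ValueError("drink duration must be in [2, 15] s")


@dataclass
class DayPlan:
    """Schedule of one synthetic day.

    Defaults approximate a 16-h free-living day: three meals (breakfast
    8:00, lunch 12:30, dinner 20:00) totalling 36.5 min, i.e. 3.8 % of the
    day spent eating, and 34 drinks of 7 s each; drinking thus covers a
    fraction of a percent of the time.  Background alternates walking,
    desk work and idle time plus two distractor blocks.
    """

    day_start_h: float = 6.0
    day_length_h: float = 16.0
    meals: tuple[MealSpec, ...] = (
        MealSpec(8.0, 10.0),
        MealSpec(12.5, 16.5),
        MealSpec(20.0, 10.0),
    )
    drinks: tuple[DrinkSpec, ...] = ()
    n_auto_drinks: int = 34
    background: tuple[tuple[str, float], ...] = ()  # (kind, duration_h)
    #: include distractor confusers (table_game, nail_biting) in the
    #: background — on for evaluation days, off for training days, which
    #: emulates confuser activities being absent from the training data
    distractors: bool = True
    acc_noise: float = 0.08  # m/s^2
    gyro_noise: float = 1.5  # deg/s
    seed: int = 0
    fs: float = 100.0

    def __post_init__(self) -> None:
        end_h = self.day_start_h + self.day_length_h
        for m in self.meals:
            if not (self.day_start_h <= m.start_h
                    and m.start_h + m.duration_min / 60 <= end_h):
                raise ValueError(f"meal at {m.start_h} h outside the day")
        for d in self.drinks:
            if not (self.day_start_h <= d.start_h
                    and d.start_h + d.duration_s / 3600 <= end_h):
                raise ValueError(f"drink at {d.start_h} h outside the day")

    @property
    def t0(self) -> float:
        return self.day_start_h * 3600.0

    def meal_intervals(self) -> list[tuple[float, float]]:
        return [
            (m.start_h * 3600.0, m.start_h * 3600.0 + m.duration_min * 60.0)
            for m in self.meals
        ]


# ---------------------------------------------------------------------------
# activity templates (additive on top of the gravity baseline)


def _smooth_bump(n: int, fs: float, center_s: float, width_s: float) -> np.ndarray:
    """Unit-peak Gaussian bump over n samples."""
    t = np.arange(n) / fs
    return np.exp(-0.5 * ((t - center_s) / width_s) ** 2)


def generate_activity_segment(
    kind: str, duration_s: float, rng: np.random.Generator,
    fs: float = 100.0, params: dict | None = None,
) -> SensorStream:
    """Render one activity segment as a standalone stream (t0 = 0).

    ``params`` tunes template amplitudes; unknown ``kind`` raises.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown activity kind {kind!r}")
    params = params or {}
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    acc = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    acc_noise = params.get("acc_noise", 0.08)
    gyro_noise = params.get("gyro_noise", 1.5)

    if kind == "idle":
        pass  # noise only
    elif kind == "desk":
        # typing / mouse micro-movements
        acc += 0.12 * rng.standard_normal((n, 3))
        gyro += 4.0 * rng.standard_normal((n, 3))
    elif kind == "walk":
        f = params.get("walk_hz", 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        swing = np.sin(2 * np.pi * f * t + phase)
        acc[:, 0] += 3.0 * swing
        acc[:, 2] += 1.2 * np.sin(4 * np.pi * f * t + phase)
        gyro[:, 1] += 35.0 * swing
        gyro[:, 0] += 12.0 * np.cos(2 * np.pi * f * t + phase)
    elif kind == "eat":
        period = params.get("gesture_period_s", 8.0)
        amp = params.get("bite_amp", 85.0)
        # quiet manipulative baseline between bites
        acc += 0.10 * rng.standard_normal((n, 3))
        gyro += 6.0 * rng.standard_normal((n, 3))
        c = rng.uniform(1.0, period)
        while c < duration_s - 1.0:
            # slow, broad hand-to-mouth rotation; mostly flexion (x/z)
            bump = _smooth_bump(n, fs, c, 0.45)
            gyro[:, 0] += amp * bump * rng.uniform(0.8, 1.2)
            gyro[:, 2] += 0.6 * amp * bump
            acc[:, 1] += 1.2 * bump
            c += period * rng.uniform(0.8, 1.2)
    elif kind == "drink":
        amp = params.get("peak_amp", 150.0)
        # grab/raise peak near the start, put-down peak near the end;
        # fast pronation of the forearm dominates both peaks
        c1 = 0.18 * duration_s
        c2 = 0.85 * duration_s
        width = 0.08 * duration_s
        raise_b = _smooth_bump(n, fs, c1, width)
        lower_b = _smooth_bump(n, fs, c2, width)
        gyro[:, 0] += 0.5 * amp * (raise_b + lower_b)
        gyro[:, 1] += amp * (raise_b - lower_b)
        # tilted low-rotation hold between the peaks (container at the mouth)
        hold = np.clip((t - c1) / width, 0, None) * np.clip((c2 - t) / width, 0, None)
        hold = np.minimum(hold, 1.0)
        acc[:, 0] += 2.0 * hold
        acc[:, 2] -= 1.0 * hold
    elif kind == "table_game":
        # manipulation over a table (e.g. domino, cards): bite-shaped but
        # lighter piece-to-board gestures at irregular intervals — the
        # dominant eating confuser (strong gestures overlap the weak end
        # of the bite amplitude range)
        amp = params.get("bite_amp", 85.0)
        acc += 0.10 * rng.standard_normal((n, 3))
        gyro += 6.0 * rng.standard_normal((n, 3))
        c = rng.uniform(0.5, 6.0)
        while c < duration_s - 1.0:
            bump = _smooth_bump(n, fs, c, 0.45)
            g = rng.uniform(0.55, 0.85)
            gyro[:, 0] += amp * bump * g
            gyro[:, 2] += 0.6 * amp * bump * g
            acc[:, 1] += 1.0 * bump
            c += rng.uniform(3.0, 16.0)
    elif kind == "nail_biting":
        # fast small repetitive wrist rotation near the mouth
        f = rng.uniform(2.5, 3.5)
        gate = (np.sin(2 * np.pi * 0.1 * t) > 0).astype(float)
        gyro[:, 0] += 45.0 * np.sin(2 * np.pi * f * t) * gate
        acc[:, 1] += 0.8 * gate

    acc += acc_noise * rng.standard_normal((n, 3))
    gyro += gyro_noise * rng.standard_normal((n, 3))
    return SensorStream(t0=0.0, fs=fs, acc=acc, gyro=gyro)


# ---------------------------------------------------------------------------
# day assembly


#: default daily routine for a 16-h day starting at 6:00 — desk work and
#: errands through the morning, an afternoon leisure block (table game,
#: nail biting) in the post-lunch lull, quiet evening; durations in hours
_DAY_ROUTINE = (
    ("desk", 1.5), ("walk", 0.75), ("desk", 1.75), ("walk", 0.75),
    ("desk", 1.0), ("idle", 0.75), ("desk", 1.0), ("walk", 0.5),
    ("desk", 1.0), ("table_game", 1.5), ("nail_biting", 0.5),
    ("walk", 0.5), ("desk", 1.5), ("idle", 1.0), ("desk", 1.0),
    ("idle", 1.0),
)


def _default_background(plan: DayPlan, rng: np.random.Generator):
    """Background schedule filling the whole day."""
    if plan.background:
        return list(plan.background)
    routine = list(_DAY_ROUTINE)
    if not plan.distractors:
        routine = [("desk" if k in ("table_game", "nail_biting") else k, d)
                   for k, d in routine]
    # scale the 16-h routine onto the plan's day length
    scale = plan.day_length_h / sum(d for _, d in routine)
    return [(k, d * scale) for k, d in routine]


def generate_day(plan: DayPlan) -> tuple[SensorStream, LabelTrack]:
    """Render one synthetic day and its exactly matching label track.

    The stream has ``day_length_h * 3600 * fs`` samples at 100 Hz.  Meals
    overwrite the background with the eating template (preceded, when
    enabled, by a 10-s high-energy accelerometer burst 30-120 s before the
    meal); drink events overwrite their span with the two-peak drinking
    template.  Overlapping drink events are rejected.
    """
    rng = np.random.default_rng(plan.seed)
    fs = plan.fs
    n = int(round(plan.day_length_h * 3600 * fs))
    acc = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    params = {"acc_noise": plan.acc_noise, "gyro_noise": plan.gyro_noise}

    # 1. background
    pos = 0
    for kind, dur_h in _default_background(plan, rng):
        seg_n = min(int(round(dur_h * 3600 * fs)), n - pos)
        if seg_n <= 0:
            break
        seg = generate_activity_segment(kind, seg_n / fs, rng, fs, params)
        acc[pos : pos + seg.n] = seg.acc
        gyro[pos : pos + seg.n] = seg.gyro
        pos += seg.n
    if pos < n:
        seg = generate_activity_segment("idle", (n - pos) / fs, rng, fs, params)
        acc[pos:] = seg.acc
        gyro[pos:] = seg.gyro

    intervals: list[LabeledInterval] = []

    # 2. meals (+ optional pre-meal energy bursts)
    for meal in plan.meals:
        s = meal.start_h * 3600.0
        e = s + meal.duration_min * 60.0
        i0 = int(round((s - plan.t0) * fs))
        i1 = int(round((e - plan.t0) * fs))
        seg = generate_activity_segment(
            "eat", (i1 - i0) / fs, rng, fs,
            {**params, "gesture_period_s": meal.gesture_period_s},
        )
        acc[i0:i1] = seg.acc
        gyro[i0:i1] = seg.gyro
        if meal.pre_burst:
            lead = rng.uniform(30.0, 120.0)
            b0 = max(0, int(round((s - plan.t0 - lead) * fs)))
            b1 = min(i0, b0 + int(round(10.0 * fs)))
            if b1 > b0:
                acc[b0:b1] += 4.0 * rng.standard_normal((b1 - b0, 3))
        intervals.append(LabeledInterval(s, e, "eat"))

    # 3. drink events
    drinks = list(plan.drinks) if plan.drinks else _auto_drinks(plan, rng)
    spans = sorted((d.start_h * 3600.0, d.start_h * 3600.0 + d.duration_s)
                   for d in drinks)
    for (s0, e0), (s1, _) in zip(spans, spans[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping drink events at {s0:.1f}s and {s1:.1f}s")
    for d in drinks:
        s = d.start_h * 3600.0
        e = s + d.duration_s
        i0 = int(round((s - plan.t0) * fs))
        i1 = int(round((e - plan.t0) * fs))
        seg = generate_activity_segment(
            "drink", (i1 - i0) / fs, rng, fs,
            {**params, "peak_amp": d.peak_amp},
        )
        acc[i0:i1] = seg.acc
        gyro[i0:i1] = seg.gyro
        intervals.append(LabeledInterval(s, e, "drink"))

    # 4. gravity baseline with a slowly wandering tilt
    t = np.arange(n) / fs
    tilt = 0.12 * np.sin(2 * np.pi * t / 1800.0 + rng.uniform(0, 2 * np.pi))
    acc[:, 0] += GRAVITY * np.sin(tilt)
    acc[:, 2] += GRAVITY * np.cos(tilt)

    stream = SensorStream(t0=plan.t0, fs=fs, acc=acc, gyro=gyro)
    return stream, LabelTrack(intervals)


def _auto_drinks(plan: DayPlan, rng: np.random.Generator) -> list[DrinkSpec]:
    """Spread ``n_auto_drinks`` 7-s drinks over the day, avoiding collisions.

    About a third of the drinks land inside meals (sips with the meal),
    the rest in background time; pre-meal burst zones are avoided so the
    planted two-peak template is preserved verbatim.
    """
    if plan.n_auto_drinks == 0:
        return []
    meals = plan.meal_intervals()
    end_h = plan.day_start_h + plan.day_length_h
    taken: list[tuple[float, float]] = []

    def collides(s: float, e: float) -> bool:
        for ts, te in taken:
            if s < te and ts < e:
                return True
        # keep clear of 130 s before each meal (pre-burst zone) and edges
        for ms, me in meals:
            if ms - 135.0 < s < ms + 5.0 or me - 10.0 < e < me + 5.0:
                return True
        return False

    n_in_meal = min(plan.n_auto_drinks // 3, len(meals) * 3)
    out: list[DrinkSpec] = []
    guard = 0
    while len(out) < plan.n_auto_drinks and guard < 10000:
        guard += 1
        dur = 7.0
        if len(out) < n_in_meal:
            ms, me = meals[len(out) % len(meals)]
            s = rng.uniform(ms + 30.0, me - 30.0 - dur)
        else:
            s = rng.uniform(plan.day_start_h * 3600 + 60.0,
                            end_h * 3600 - 60.0 - dur)
        if collides(s, s + dur):
            continue
        taken.append((s - 15.0, s + dur + 15.0))
        out.append(DrinkSpec(s / 3600.0, dur))
    return out
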