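"""Time-domain feature extraction and the two-stage feature selection.

The working descriptor of a window is a 33-value vector assembled from ten
low-cost time-domain features, the set that survives the selection
procedure (correlation pruning followed by forest-importance pruning):

* mean and population variance of each of the 6 axes,
* a Haar-like step response (first-half mean minus second-half mean) per axis,
* pairwise axis correlation within each sensor (6 values),
* pairwise axis covariance of the accelerometer (3 values),
* zero-crossing rate of each gyroscope axis (crossings per second),
* manipulation — window mean of (|gx|+|gy|+|gz|) / |a|, an object-handling
  signature,
* linear acceleration — window mean of | |a| - g |,
* RMS of the accelerometer magnitude.

All moments are population moments (ddof = 0); a correlation over a
zero-variance axis is defined as 0.
"""

from __future__ import annotations

import numpy as np

from .core import GRAVITY, SensorStream, Window

_AXES = ["acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"]
_PAIRS = ["xy", "xz", "yz"]

#: Fixed ordering of the 33 features.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"mean_{a}" for a in _AXES]
    + [f"var_{a}" for a in _AXES]
    + [f"haar_{a}" for a in _AXES]
    + [f"corr_acc_{p}" for p in _PAIRS]
    + [f"corr_gyro_{p}" for p in _PAIRS]
    + [f"cov_acc_{p}" for p in _PAIRS]
    + [f"zcr_gyro_{a}" for a in ("x", "y", "z")]
    + ["manipulation", "linear_acceleration", "rms_acc_magnitude"]
)

#: Epsilon guard for the manipulation denominator (m/s^2).
EPS_ACC = 1e-6

# Relative computational cost used to break correlated pairs: the costlier
# member of a highly correlated pair is dropped first.  Larger = costlier.
_COST_BY_KIND = {
    "corr": 6, "cov": 5, "haar": 4, "var": 3, "zcr": 2, "rms": 1,
    "manipulation": 1, "linear": 1, "mean": 0,
}


def feature_cost_rank(names=FEATURE_NAMES) -> dict[str, int]:
    """Default drop-priority of each feature (higher = dropped first)."""
    out = {}
    for name in names:
        kind = name.split("_")[0]
        out[name] = _COST_BY_KIND.get(kind, 0)
    return out


def _pairwise(values: np.ndarray):
    # values: (n, 3) -> pairs (xy, xz, yz)
    yield values[:, 0], values[:, 1]
    yield values[:, 0], values[:, 2]
    yield values[:, 1], values[:, 2]


def _zero_crossings(x: np.ndarray) -> int:
    xc = x - x.mean()
    return int(np.count_nonzero(xc[:-1] * xc[1:] < 0))


def extract_features(
    stream: SensorStream,
    window: Window | None = None,
    gravity: float = GRAVITY,
) -> np.ndarray:
    """Compute the 33-value descriptor of one window of a stream.

    Parameters
    ----------
    stream : SensorStream
        Source stream (already preprocessed).
    window : Window, optional
        Sample span to describe; the whole stream when omitted.
    gravity : float
        Gravity constant used by the linear-acceleration feature (m/s^2).
    """
    if window is None:
        acc, gyro = stream.acc, stream.gyro
    else:
        if window.end_idx > stream.n:
            raise ValueError("window exceeds stream length")
        acc = stream.acc[window.start_idx : window.end_idx]
        gyro = stream.gyro[window.start_idx : window.end_idx]
    n = acc.shape[0]
    if n < 2:
        raise ValueError("window must contain at least 2 samples")
    duration_s = n / stream.fs
    both = np.hstack([acc, gyro])  # (n, 6)

    means = both.mean(axis=0)
    variances = both.var(axis=0)  # population
    half = n // 2
    haar = both[:half].mean(axis=0) - both[half:].mean(axis=0)

    def _corr(a, b):
        va, vb = a.var(), b.var()
        if va == 0.0 or vb == 0.0:
            return 0.0
        return float(((a - a.mean()) * (b - b.mean())).mean() / np.sqrt(va * vb))

    corr = [_corr(a, b) for a, b in _pairwise(acc)]
    corr += [_corr(a, b) for a, b in _pairwise(gyro)]
    cov_acc = [
        float(((a - a.mean()) * (b - b.mean())).mean()) for a, b in _pairwise(acc)
    ]
    zcr = [_zero_crossings(gyro[:, c]) / duration_s for c in range(3)]

    acc_mag = np.linalg.norm(acc, axis=1)
    manipulation = float(
        (np.abs(gyro).sum(axis=1) / np.maximum(acc_mag, EPS_ACC)).mean()
    )
    linear_acceleration = float(np.abs(acc_mag - gravity).mean())
    rms_acc = float(np.sqrt((acc_mag**2).mean()))

    vec = np.concatenate(
        [
            means,
            variances,
            haar,
            corr,
            cov_acc,
            zcr,
            [manipulation, linear_acceleration, rms_acc],
        ]
    )
    assert vec.shape == (33,)
    return vec


def extract_feature_matrix(
    stream: SensorStream, windows, gravity: float = GRAVITY
) -> np.ndarray:
    """Stack :func:`extract_features` over a window list -> (n_windows, 33)."""
    return np.array([extract_features(stream, w, gravity) for w in windows])


# ---------------------------------------------------------------------------
# Feature selection


def correlation_filter(
    feature_matrix: np.ndarray,
    names: list[str],
    cost_rank: dict[str, int] | None = None,
    r_max: float = 0.8,
) -> list[str]:
    """Drop the costlier member of every feature pair with |r| > r_max.

    Pairs are processed in descending |r| (ties broken by name order);
    once a feature is dropped it no longer participates.  Constant columns
    have undefined correlation and are never dropped by this rule.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    if X.shape[1] != len(names):
        raise ValueError("names must match feature_matrix columns")
    cost_rank = cost_rank if cost_rank is not None else feature_cost_rank(names)
    variable = X.std(axis=0) > 0
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    pairs = []
    p = X.shape[1]
    for i in range(p):
        for j in range(i + 1, p):
            if variable[i] and variable[j] and abs(R[i, j]) > r_max:
                pairs.append((-abs(R[i, j]), names[i], names[j], i, j))
    pairs.sort()
    dropped: set[str] = set()
    for _, ni, nj, i, j in pairs:
        if ni in dropped or nj in dropped:
            continue
        ci, cj = cost_rank.get(ni, 0), cost_rank.get(nj, 0)
        if ci > cj:
            dropped.add(ni)
        elif cj > ci:
            dropped.add(nj)
        else:  # equal cost: drop the later name alphabetically
            dropped.add(max(ni, nj))
    return [nm for nm in names if nm not in dropped]


def importance_filter(
    feature_matrix: np.ndarray,
    eat_labels: np.ndarray,
    drink_labels: np.ndarray,
    names: list[str] | None = None,
    threshold: float = 0.01,
    seed: int = 0,
    n_trees: int = 100,
) -> list[str]:
    """Drop features under ``threshold`` impurity importance in either model.

    One forest is trained on eating-vs-rest labels and one on
    drinking-vs-rest; a feature whose normalized Gini importance falls
    below the threshold for at least one of the two activities of interest
    is eliminated.
    """
    from sklearn.ensemble import RandomForestClassifier

    X = np.asarray(feature_matrix, dtype=float)
    names = list(names) if names is not None else list(FEATURE_NAMES[: X.shape[1]])
    keep = np.ones(X.shape[1], dtype=bool)
    for labels in (np.asarray(eat_labels), np.asarray(drink_labels)):
        if len(np.unique(labels)) < 2:
            raise ValueError("label vector must contain both classes")
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(X, labels)
        keep &= clf.feature_importances_ >= threshold
    return [nm for nm, k in zip(names, keep) if k]


def minmax_scale(X: np.ndarray) -> np.ndarray:
    """Optional [0, 1] per-column scaling (off by default in the pipeline)."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng[rng == 0] = 1.0
    return (X - lo) / rng
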