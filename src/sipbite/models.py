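"""Class balancing and the two binary recognition branches.

Training data for both activities of interest is heavily imbalanced (in
free living, eating covers a few percent of the time and drinking well
under one percent), so every branch is balanced with SMOTE followed by
edited-nearest-neighbour (ENN) cleaning before a Random Forest is fit.
SMOTE synthesizes minority samples by interpolating between a minority
sample and one of its k nearest minority neighbours; ENN then removes
samples (of either class) whose own label disagrees with the majority
vote of their k nearest neighbours, cleaning the class border that SMOTE
tends to blur.

Prediction is semi-hierarchical: the eating branch scores fixed-length
windows (10 s, 25 % overlap) and the drinking branch scores dynamic
fixed windows (DFW, t = 10 s) on the gyroscope magnitude; both outputs
are retained for the restriction layer, which is applied separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .core import RunConfig, SensorStream, Window
from .features import FEATURE_NAMES, extract_feature_matrix
from .segmentation import (
    DwParams,
    dynamic_fixed_windows,
    fixed_windows,
    gyro_magnitude,
)

# ---------------------------------------------------------------------------
# SMOTE + ENN


def smote(
    X: np.ndarray, y: np.ndarray, seed: int = 0, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity by k-NN interpolation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote expects a binary label vector")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < k + 1:
        raise ValueError(
            f"minority class has {n_min} samples, need at least k+1={k + 1}; "
            "use a smaller k"
        )
    deficit = n_maj - n_min
    if deficit == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # column 0 is the sample itself
    base = rng.integers(0, len(Xm), size=deficit)
    nbr = idx[base, rng.integers(1, k + 1, size=deficit)]
    gap = rng.random((deficit, 1))
    synth = Xm[base] + gap * (Xm[nbr] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    return X_out, y_out


def enn(
    X: np.ndarray, y: np.ndarray, k: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Edited nearest neighbours: remove samples misvoted by their k-NN.

    A sample is removed when the majority label among its k nearest
    neighbours (excluding itself) differs from its own.  If editing would
    empty a class, that class is left untouched.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) <= k + 1:
        return X.copy(), y.copy()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    nbr_labels = y[idx[:, 1:]]
    agree = (nbr_labels == y[:, None]).sum(axis=1)
    keep = agree * 2 >= k  # majority (ties kept)
    for cls in np.unique(y):
        if not keep[y == cls].any():
            keep[y == cls] = True
    return X[keep], y[keep]


def balance(
    X: np.ndarray, y: np.ndarray, seed: int = 0, smote_k: int = 5, enn_k: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE oversampling of the minority followed by ENN cleaning.

    Deterministic under ``seed``; the output minority:majority ratio is
    strictly closer to 1 than the input's and both classes are preserved.
    """
    X1, y1 = smote(X, y, seed=seed, k=smote_k)
    return enn(X1, y1, k=enn_k)


# ---------------------------------------------------------------------------
# binary branches


@dataclass
class BinaryModel:
    """One trained recognition branch (eating or drinking)."""

    branch: str  # "eat" | "drink"
    classifier: object
    feature_names: tuple[str, ...] = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.branch not in ("eat", "drink"):
            raise ValueError("branch must be 'eat' or 'drink'")


def make_classifier(config: RunConfig):
    """Default classifier for both branches (pluggable: any sklearn-style
    estimator with fit/predict_proba works in its place)."""
    return RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed
    )


def train_branch(
    features: np.ndarray,
    labels: np.ndarray,
    branch: str,
    config: RunConfig | None = None,
    seed: int | None = None,
    classifier=None,
) -> BinaryModel:
    """Balance then fit one binary branch.

    ``labels`` may be boolean (positive = the branch activity) or the
    3-class strings, which are binarized against the branch class.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind in "US":
        y = y == branch
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    before = np.bincount(y, minlength=2)
    Xb, yb = balance(X, y, seed=seed, smote_k=config.smote_k, enn_k=config.enn_k)
    after = np.bincount(yb, minlength=2)
    clf = classifier if classifier is not None else RandomForestClassifier(
        n_estimators=config.n_trees, random_state=seed
    )
    clf.fit(Xb, yb)
    names = (
        FEATURE_NAMES if X.shape[1] == len(FEATURE_NAMES)
        else tuple(f"f{i}" for i in range(X.shape[1]))
    )
    return BinaryModel(
        branch=branch,
        classifier=clf,
        feature_names=names,
        metadata={
            "seed": seed,
            "class_counts_before": before.tolist(),
            "class_counts_after": after.tolist(),
        },
    )


def predict_proba(model: BinaryModel, feature_vectors: np.ndarray) -> np.ndarray:
    """Probability of the positive (branch) class for each feature vector."""
    X = np.atleast_2d(np.asarray(feature_vectors, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    proba = model.classifier.predict_proba(X)
    pos = list(model.classifier.classes_).index(1)
    return proba[:, pos]


# ---------------------------------------------------------------------------
# semi-hierarchical prediction


@dataclass
class PredictionTimeline:
    """Branch outputs plus everything the restriction layer needs."""

    fs: float
    t0: float
    n: int
    fw_windows: list[Window]
    eat_probs: np.ndarray
    dfw_windows: list[Window]
    drink_probs: np.ndarray
    gyro_mag: np.ndarray
    acc_mag: np.ndarray

    @property
    def duration_h(self) -> float:
        return self.n / self.fs / 3600.0


def run_semi_hierarchical(
    stream: SensorStream,
    eat_model: BinaryModel,
    drink_model: BinaryModel,
    config: RunConfig | None = None,
) -> PredictionTimeline:
    """Score both branches over one preprocessed stream.

    The eating branch evaluates fixed windows; the drinking branch
    evaluates DFW windows of the gyroscope magnitude.  No restriction is
    applied here — the raw branch outputs feed the post-processing layer.
    """
    config = config or RunConfig()
    fw = fixed_windows(stream.n, stream.fs, config.fw_length_s, config.fw_overlap)
    if not fw:
        raise ValueError("stream shorter than one fixed window")
    eat_probs = predict_proba(
        eat_model, extract_feature_matrix(stream, fw, config.gravity)
    )
    mag = gyro_magnitude(stream)
    params = DwParams(N=config.dw_N, scale=config.dw_scale, floor=config.dw_floor)
    dfw = [
        w for w in dynamic_fixed_windows(mag, stream.fs, config.dfw_t_s, params)
        if len(w) >= 2
    ]
    drink_probs = (
        predict_proba(
            drink_model, extract_feature_matrix(stream, dfw, config.gravity)
        )
        if dfw
        else np.empty(0)
    )
    return PredictionTimeline(
        fs=stream.fs,
        t0=stream.t0,
        n=stream.n,
        fw_windows=fw,
        eat_probs=eat_probs,
        dfw_windows=dfw,
        drink_probs=drink_probs,
        gyro_mag=mag,
        acc_mag=np.linalg.norm(stream.acc, axis=1),
    )


def label_windows(
    windows: list[Window], unit_labels: list[str], fs: float, unit_s: float
) -> np.ndarray:
    """Assign each window the rasterized label covering its midpoint."""
    out = []
    for w in windows:
        unit = int(w.mid_idx() / fs / unit_s)
        unit = min(unit, len(unit_labels) - 1)
        out.append(unit_labels[unit])
    return np.array(out)


def label_windows_binary(
    windows: list[Window], track, label: str, t0: float, fs: float
) -> np.ndarray:
    """True where a window's midpoint lies inside an interval of ``label``.

    Branch training labels are per-class interval membership, not the
    precedence-rasterized 3-class grid: a sip during a meal is drink time
    for the drinking branch but still meal time for the eating branch.
    """
    spans = [(iv.start_s, iv.end_s) for iv in track.of_label(label)]
    out = np.zeros(len(windows), dtype=bool)
    for k, w in enumerate(windows):
        t = t0 + w.mid_idx() / fs
        out[k] = any(s <= t < e for s, e in spans)
    return out
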