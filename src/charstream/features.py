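"""ERP feature extraction and regularized linear discriminants.

The "standard" decoding pipeline for evoked potentials: a signed-r²
discriminability map over channels and time, heuristic selection of 3–5
class-discriminative time intervals, channel-wise mean amplitudes in those
intervals as features, and a binary LDA classifier whose covariance is
shrunk toward a scaled identity (Ledoit–Wolf). A sparse variant realizes
the discriminant through an l1-penalized optimal-scoring regression.

Accuracies are balanced (mean of per-class recalls) throughout, so chance
level is 0.5 regardless of the heavy 1/29 target:non-target imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf
from sklearn.linear_model import Lasso
from sklearn.model_selection import GroupKFold

from charstream.preprocess import EpochSet


@dataclass(frozen=True)
class DiscriminabilityMap:
    """Signed r² (point-biserial) per channel and time point."""

    values: np.ndarray  # (n_channels, n_times), in [-1, 1]
    channels: tuple[str, ...]
    times: np.ndarray  # ms


@dataclass(frozen=True)
class IntervalSet:
    """3–5 disjoint class-discriminative time intervals, in ms."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self):
        ivs = sorted(self.intervals)
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValueError("intervals must be pairwise disjoint")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass
class LinearModel:
    """A trained linear discriminant: score(x) = w·x + b.

    Positive scores indicate class 1 (target). ``regularization`` holds the
    shrinkage intensity gamma (dense LDA) or the l1 penalty lambda (sparse
    LDA).
    """

    w: np.ndarray
    b: float
    kind: str  # "lda" | "sparse-lda"
    regularization: float
    n_train: tuple[int, int] = (0, 0)  # (n_class0, n_class1)

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "b": self.b,
            "kind": self.kind,
            "regularization": self.regularization,
            "n_train": list(self.n_train),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            w=np.asarray(d["w"], float),
            b=float(d["b"]),
            kind=d["kind"],
            regularization=float(d["regularization"]),
            n_train=tuple(d.get("n_train", (0, 0))),
        )


def signed_r2(epochs: EpochSet, labels: np.ndarray | None = None) -> DiscriminabilityMap:
    """Signed squared point-biserial correlation per (channel, time).

    For each point the value is ``sign(m1 - m0) * r²`` where r is the
    point-biserial correlation between the signal amplitude and the binary
    label. Values are antisymmetric under label swap. Zero-variance points
    yield 0 with a warning.
    """
    y = epochs.labels if labels is None else np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be non-empty")
    X = epochs.data  # (n, ch, t)
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    m1 = X[y == 1].mean(axis=0)
    m0 = X[y == 0].mean(axis=0)
    s = X.std(axis=0)  # population sd over all epochs
    zero = s == 0
    if zero.any():
        warnings.warn("zero-variance points in signed-r2 map set to 0")
        s = np.where(zero, 1.0, s)
    r = (m1 - m0) * np.sqrt(n1 * n0) / (n * s)
    vals = np.sign(m1 - m0) * r**2
    vals[zero] = 0.0
    return DiscriminabilityMap(values=vals, channels=epochs.channels, times=epochs.times)


def select_intervals(
    dmap: DiscriminabilityMap,
    n: int = 5,
    smoothing: float = 30.0,
    min_length: float = 30.0,
    max_length: float = 150.0,
    floor_fraction: float = 0.2,
) -> IntervalSet:
    """Greedy heuristic selection of class-discriminative time intervals.

    The channel-summed absolute signed-r² score is smoothed with a
    ``smoothing``-ms moving average; the heuristic then repeatedly takes
    the highest remaining peak (earliest on ties), grows an interval around
    it while the score stays above ``floor_fraction`` of the global
    maximum (clipped to ``min_length``–``max_length`` ms), masks it out,
    and stops after ``n`` intervals or when no peak clears the floor.
    Fewer than ``n`` intervals are returned with a warning.
    """
    if not 3 <= n <= 5:
        raise ValueError("n must be between 3 and 5")
    times = dmap.times
    dt = float(np.median(np.diff(times)))
    score = np.abs(dmap.values).sum(axis=0)
    k = max(1, int(round(smoothing / dt)))
    kernel = np.ones(k) / k
    smooth = np.convolve(score, kernel, mode="same")

    floor = floor_fraction * smooth.max()
    min_samp = max(1, int(round(min_length / dt)))
    max_samp = max(min_samp, int(round(max_length / dt)))
    avail = smooth.copy()
    picked: list[tuple[int, int]] = []
    for _ in range(n):
        peak = int(np.argmax(avail))  # argmax takes the earliest maximum
        if avail[peak] <= floor:
            break
        lo = hi = peak
        # grow greedily toward the larger neighbour while above floor
        while (hi - lo + 1) < max_samp:
            left = avail[lo - 1] if lo > 0 else -np.inf
            right = avail[hi + 1] if hi < len(avail) - 1 else -np.inf
            best = max(left, right)
            if best <= floor and (hi - lo + 1) >= min_samp:
                break
            if best == -np.inf:
                break
            if left >= right:
                lo -= 1
            else:
                hi += 1
        # enforce minimum length by extension into unmasked territory
        while (hi - lo + 1) < min_samp:
            left_ok = lo > 0 and np.isfinite(avail[lo - 1])
            right_ok = hi < len(avail) - 1 and np.isfinite(avail[hi + 1])
            if left_ok and (not right_ok or avail[lo - 1] >= avail[hi + 1]):
                lo -= 1
            elif right_ok:
                hi += 1
            else:
                break
        picked.append((lo, hi))
        avail[max(0, lo - 1) : hi + 2] = -np.inf  # mask with 1-sample guard
    if len(picked) < 3:
        warnings.warn(
            f"only {len(picked)} interval(s) cleared the selection floor"
        )
    intervals = tuple(
        sorted((float(times[lo]), float(times[hi] + dt)) for lo, hi in picked)
    )
    return IntervalSet(intervals=intervals)


def extract_features(epochs: EpochSet, intervals: IntervalSet) -> np.ndarray:
    """Channel-wise mean amplitudes in each interval.

    Returns an (n_epochs, n_channels * n_intervals) matrix; features are
    ordered interval-major (all channels of interval 1, then interval 2,
    ...).
    """
    times = epochs.times
    cols = []
    for (t0, t1) in intervals:
        mask = (times >= t0) & (times < t1)
        if not mask.any():
            raise ValueError(f"interval [{t0}, {t1}) ms contains no samples")
        cols.append(epochs.data[:, :, mask].mean(axis=2))
    return np.concatenate(cols, axis=1)


def _class_stats(X: np.ndarray, y: np.ndarray):
    y = np.asarray(y).astype(int)
    X1, X0 = X[y == 1], X[y == 0]
    if len(X1) < 2 or len(X0) < 2:
        raise ValueError("need at least 2 samples per class")
    return X0, X1, X0.mean(axis=0), X1.mean(axis=0)


def train_shrinkage_lda(
    X: np.ndarray, y: np.ndarray, gamma: float | None = None
) -> LinearModel:
    """Binary LDA with Ledoit–Wolf shrinkage of the pooled covariance.

    The discriminant is ``w = ((1 - g) S + g v I)^-1 (mu1 - mu0)`` where S
    is the pooled within-class covariance, v its mean eigenvalue, and the
    shrinkage intensity g is computed analytically (Ledoit–Wolf) unless
    given. The bias places the decision boundary at the midpoint of the
    projected class means (ranking, not thresholding, drives the speller).
    """
    X = np.asarray(X, float)
    X0, X1, mu0, mu1 = _class_stats(X, y)
    centered = np.concatenate([X0 - mu0, X1 - mu1], axis=0)
    if gamma is None:
        S, gamma = ledoit_wolf(centered, assume_centered=True)
    else:
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        emp = centered.T @ centered / len(centered)
        nu = np.trace(emp) / emp.shape[0]
        S = (1.0 - gamma) * emp + gamma * nu * np.eye(emp.shape[0])
    diff = mu1 - mu0
    w = np.linalg.solve(S, diff)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return LinearModel(w=w, b=b, kind="lda", regularization=float(gamma),
                       n_train=(len(X0), len(X1)))


def train_sparse_lda(X: np.ndarray, y: np.ndarray, lam: float = 0.01) -> LinearModel:
    """Sparse discriminant via l1-penalized optimal scoring.

    The binary optimal-scoring formulation regresses recoded class labels
    (+n/n1 for targets, -n/n0 otherwise) on the features with a Lasso
    penalty; the OLS limit of this regression is proportional to the LDA
    direction, so ``lam -> 0`` recovers the dense solution up to scale.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    X0, X1, mu0, mu1 = _class_stats(X, y)
    n, n1 = len(y), int(y.sum())
    n0 = n - n1
    t = np.where(y == 1, n / n1, -n / n0).astype(float)
    model = Lasso(alpha=max(lam, 1e-12), fit_intercept=True, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lasso convergence chatter
        model.fit(X, t)
    w = model.coef_.copy()
    if not np.any(w):
        warnings.warn("sparse LDA: penalty zeroed every weight")
    b = -float(w @ (mu0 + mu1) / 2.0)
    return LinearModel(w=w, b=b, kind="sparse-lda", regularization=float(lam),
                       n_train=(n0, n1))


def score(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Real-valued discriminant outputs; positive means target-like."""
    return np.asarray(X, float) @ model.w + model.b


@dataclass
class FittedPipeline:
    """Interval set + discriminant fit together on one training set."""

    intervals: IntervalSet
    model: LinearModel

    def outputs(self, epochs: EpochSet) -> np.ndarray:
        return score(self.model, extract_features(epochs, self.intervals))


def fit_pipeline(
    epochs: EpochSet,
    labels: np.ndarray | None = None,
    n_intervals: int = 5,
    algorithm: str = "lda",
    lam: float = 0.01,
    gamma: float | None = None,
) -> FittedPipeline:
    """Run the standard pipeline: signed-r² map -> intervals -> features -> LDA."""
    y = epochs.labels if labels is None else np.asarray(labels).astype(int)
    dmap = signed_r2(epochs, y)
    intervals = select_intervals(dmap, n=n_intervals)
    X = extract_features(epochs, intervals)
    if algorithm == "lda":
        model = train_shrinkage_lda(X, y, gamma=gamma)
    elif algorithm == "sparse-lda":
        model = train_sparse_lda(X, y, lam=lam)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return FittedPipeline(intervals=intervals, model=model)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class recalls over the classes present in ``y_true``."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    recalls = [
        (y_pred[y_true == c] == c).mean() for c in np.unique(y_true)
    ]
    return float(np.mean(recalls))


def _blocked_folds(groups: np.ndarray, y: np.ndarray, k: int):
    """Trial-blocked folds; re-split if a fold lacks one of the classes."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    # trials that contain each class: a fold can only hold both classes if
    # every fold receives at least one trial carrying each
    trials_c1 = {g for g in uniq if y[groups == g].any()}
    trials_c0 = {g for g in uniq if (y[groups == g] == 0).any()}
    k = min(k, len(uniq), max(2, min(len(trials_c0), len(trials_c1))))
    if k < 2 or len(uniq) < 2:
        raise ValueError("need at least 2 trial groups for cross-validation")
    splitter = GroupKFold(n_splits=k)
    folds = list(splitter.split(np.zeros(len(y)), y, groups))
    if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
           for tr, te in folds):
        return folds
    # stratified re-split: order trials by their target share, deal them
    # round-robin so every fold mixes both classes
    shares = {g: y[groups == g].mean() for g in uniq}
    ordered = sorted(uniq, key=lambda g: (shares[g], g))
    assignment = {g: i % k for i, g in enumerate(ordered)}
    folds = []
    for f in range(k):
        te = np.flatnonzero([assignment[g] == f for g in groups])
        tr = np.flatnonzero([assignment[g] != f for g in groups])
        folds.append((tr, te))
    return folds


def crossval_binary_accuracy(
    epochs: EpochSet,
    labels: np.ndarray | None = None,
    k: int = 5,
    groups: np.ndarray | None = None,
    n_intervals: int = 5,
    algorithm: str = "lda",
    lam: float = 0.01,
) -> float:
    """Trial-blocked k-fold CV of the full standard pipeline.

    Interval selection and the discriminant are re-fit inside every fold,
    so no information leaks from the held-out trials. Returns the mean
    balanced accuracy over folds (chance = 0.5).
    """
    y = epochs.labels if labels is None else np.asarray(labels).astype(int)
    if groups is None:
        groups = epochs.metadata["trial"].to_numpy()
    accs = []
    for tr, te in _blocked_folds(groups, y, k):
        pipe = fit_pipeline(epochs.subset(tr), y[tr],
                            n_intervals=n_intervals, algorithm=algorithm, lam=lam)
        pred = (pipe.outputs(epochs.subset(te)) > 0).astype(int)
        accs.append(balanced_accuracy(y[te], pred))
    return float(np.mean(accs))
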