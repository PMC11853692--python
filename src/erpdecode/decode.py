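"""Time-resolved multivariate decoding of oddball ERPs.

For every time point, channels are used as features of a linear max-margin
(SVM) classifier that discriminates standard from deviant trials, scored
with the ROC area (AUC) under repeated stratified cross-validation.  Two
preprocessing operations are *nested* inside every fold, i.e. fitted on the
training partition and merely applied to the held-out partition:

* z-scoring — per-feature mean/sd estimated on training trials only;
* pseudo-trial ("sample") averaging — within each class, trials are
  randomly partitioned into groups of ``k`` whose means replace the
  original trials, raising the effective SNR at the cost of observations.
  Test trials are grouped independently inside their own fold, so no test
  information ever reaches the training side.

The same cross-validation engine drives the per-time-point curve, the
train-time x test-time temporal-generalization matrix, and the
channel-by-window searchlight; given an identical seed, the matrix diagonal
reproduces the curve bit-for-bit because folds, groupings and regularization
choices are shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as spstats
from sklearn import config_context
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .epochs import EpochSet
from .stats import auc as roc_auc

#: Regularization grid spanning 0.01-100, log-spaced.
DEFAULT_C_GRID = tuple(np.logspace(-2, 2, 7).round(8).tolist())

#: Searchlight windows: the 100 ms pre-stimulus baseline plus 50 ms bins
#: from 50 to 550 ms post-stimulus.
DEFAULT_SEARCHLIGHT_WINDOWS = tuple(
    [(-0.100, 0.0)] + [(0.050 * i, 0.050 * (i + 1)) for i in range(1, 11)]
)


@dataclass(frozen=True)
class DecodingConfig:
    """Cross-validated decoding parameters.

    classifier
        Only ``"svm"`` (linear max-margin) is supported.
    c_grid
        Candidate SVM regularization values; when more than one is given,
        C is selected per training fold by an inner cross-validation.
    n_folds, n_repetitions
        Outer stratified k-fold scheme; repetitions redraw both the fold
        assignment and the pseudo-trial groupings.
    group_size
        Pseudo-trial averaging count ``k`` (5 for superblocks, 2 for
        single blocks, 1 disables averaging).
    inner_folds, inner_max_timepoints
        Inner CV used for C selection: folds of the training trials and
        the maximum number of (evenly subsampled) time points scored.
    """

    classifier: str = "svm"
    c_grid: tuple = DEFAULT_C_GRID
    n_folds: int = 5
    n_repetitions: int = 10
    group_size: int = 5
    metric: str = "auc"
    seed: int = 0
    inner_folds: int = 3
    inner_max_timepoints: int = 40

    def __post_init__(self) -> None:
        if self.classifier != "svm":
            raise ValueError("only the linear SVM classifier is supported")
        if self.metric != "auc":
            raise ValueError("only the AUC metric is supported")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if len(self.c_grid) == 0 or any(c <= 0 for c in self.c_grid):
            raise ValueError("c_grid must be nonempty with positive values")

    def with_(self, **kwargs) -> "DecodingConfig":
        return replace(self, **kwargs)


@dataclass
class DecodingCurve:
    """Per-time-point decoding performance (the Level-1 decoding curve)."""

    times: np.ndarray
    auc: np.ndarray                 # mean AUC across folds x repetitions
    dispersion: np.ndarray          # sd across folds x repetitions
    n_effective_trials: dict        # per-class pseudo-trial count (training)
    config: DecodingConfig

    def peak(self) -> tuple[float, float]:
        """(latency, AUC) of the maximum of the curve."""
        i = int(np.argmax(self.auc))
        return float(self.times[i]), float(self.auc[i])

    def max_in_window(self, window: tuple[float, float]) -> float:
        mask = (self.times >= window[0]) & (self.times <= window[1])
        if not mask.any():
            raise ValueError(f"window {window} outside the time axis")
        return float(self.auc[mask].max())


@dataclass
class TemporalGeneralizationMatrix:
    """Train-time x test-time AUC grid."""

    times: np.ndarray
    auc: np.ndarray  # (n_train_times, n_test_times); y-axis = training time
    config: DecodingConfig

    def diagonal(self) -> np.ndarray:
        return np.diag(self.auc)


@dataclass
class SearchlightMap:
    """Channels x time-window AUC grid."""

    channels: tuple
    windows: tuple
    auc: np.ndarray  # (n_channels, n_windows)
    config: DecodingConfig

    def best_channels(self, window_index: int, top: int = 2) -> list[str]:
        order = np.argsort(self.auc[:, window_index])[::-1]
        return [self.channels[i] for i in order[:top]]


@dataclass
class ZScoreStats:
    """Per-feature normalization statistics estimated on training data."""

    mean: np.ndarray
    sd: np.ndarray  # zero-variance features carry sd 1 (center-only)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ZScoreStats":
        return cls(np.asarray(d["mean"], dtype=float),
                   np.asarray(d["sd"], dtype=float))


def _fit_stats(train: np.ndarray) -> ZScoreStats:
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance training feature(s); "
            "centered but left unscaled", RuntimeWarning, stacklevel=3)
        sd = np.where(zero, 1.0, sd)
    return ZScoreStats(mean, sd)


def zscore_train_apply(train: np.ndarray, test: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray, ZScoreStats]:
    """Z-score features using training statistics only.

    Mean and sample standard deviation (ddof=1) are computed per feature
    over the training rows; both partitions are transformed with those
    training statistics.  Zero-variance features are centered but not
    scaled (with a warning) so that noiseless data remain processable.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need >= 2 training rows to estimate an sd")
    stats = _fit_stats(train)
    return stats.apply(train), stats.apply(test), stats


def average_samples(x: np.ndarray, y: np.ndarray, k: int,
                    seed: int | np.random.Generator = 0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Replace random groups of ``k`` same-class trials by their means.

    Within each class, trials are randomly partitioned into ``floor(n/k)``
    groups of exactly ``k``; remainder trials are dropped.  Averaging k
    i.i.d. trials divides the noise variance by k while preserving the
    class mean, which is why decoding benefits at fixed trial budget.
    """
    if k < 1:
        raise ValueError("group size k must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs, ys = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls!r} has {len(idx)} trials, fewer than group size {k}")
        perm = rng.permutation(idx)
        n_groups = len(idx) // k
        grouped = x[perm[: n_groups * k]].reshape(n_groups, k, *x.shape[1:])
        xs.append(grouped.mean(axis=1))
        ys.append(np.repeat(cls, n_groups))
    return np.concatenate(xs, axis=0), np.concatenate(ys)


# ---------------------------------------------------------------------------
# cross-validation engine
# ---------------------------------------------------------------------------

def _check_input(e: EpochSet, cfg: DecodingConfig) -> tuple[np.ndarray, np.ndarray]:
    y = e.y()
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present for decoding")
    if counts[0] != counts[1]:
        warnings.warn(
            f"unbalanced classes ({counts[0]} standard / {counts[1]} deviant); "
            "consider undersample_balance first", RuntimeWarning, stacklevel=3)
    # each test fold must still contain >= k trials per class
    min_test = counts.min() // cfg.n_folds
    if min_test < cfg.group_size:
        raise ValueError(
            f"too few trials per class ({counts.min()}) for group size "
            f"{cfg.group_size} with {cfg.n_folds} folds")
    return np.asarray(e.data, dtype=float), y


def _group_average(x: np.ndarray, y: np.ndarray, k: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if k == 1:
        return x, y
    return average_samples(x, y, k, rng)


def _fit_linear(x: np.ndarray, y: np.ndarray, c: float) -> tuple[np.ndarray, float]:
    clf = LinearSVC(C=c, tol=1e-4, max_iter=2000, random_state=0)
    clf.fit(x, y)
    return clf.coef_[0], float(clf.intercept_[0])


def stratified_splits(y: np.ndarray, n_folds: int, rng: np.random.Generator,
                      ) -> tuple[list, np.ndarray]:
    """Stratified k-fold assignment driven by one label-blind permutation.

    A single permutation of all trials is drawn; within each class, trials
    are dealt round-robin to folds in permutation order.  Because the
    permutation is drawn independently of the labels and each class is
    dealt separately, the resulting partition is stratified yet invariant
    under relabeling of the classes — swapping the class names yields the
    identical folds, which makes label-flip antisymmetry of the decoding
    curve exact.
    """
    n = len(y)
    perm = rng.permutation(n)
    rank = np.empty(n, dtype=int)
    rank[perm] = np.arange(n)
    fold_of = np.empty(n, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        order = idx[np.argsort(rank[idx])]
        fold_of[order] = np.arange(len(order)) % n_folds
    splits = []
    for f in range(n_folds):
        test = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        splits.append((train, test))
    return splits, rank


def _partition_groups(y: np.ndarray, part_idx: np.ndarray, k: int,
                      rank: np.ndarray) -> list[np.ndarray]:
    """Pseudo-trial groups of k same-class trials within one partition.

    Group membership follows the same label-blind permutation as the fold
    assignment (remainder per class dropped); groups are ordered by the
    permutation rank of their first member so the assembled feature-matrix
    row order does not depend on class names either.
    """
    groups = []
    for cls in np.unique(y[part_idx]):
        idx = part_idx[y[part_idx] == cls]
        order = idx[np.argsort(rank[idx])]
        for g in range(len(idx) // k):
            groups.append(order[g * k:(g + 1) * k])
    groups.sort(key=lambda g: rank[g[0]])
    return groups


def _select_c(x: np.ndarray, y: np.ndarray, cfg: DecodingConfig,
              rng: np.random.Generator) -> float:
    """Pick C on the training partition by inner stratified CV.

    Scores the mean AUC over an evenly subsampled time grid; ties resolve
    to the smaller (more regularized) C.
    """
    if len(cfg.c_grid) == 1:
        return float(cfg.c_grid[0])
    n_t = x.shape[2]
    stride = max(1, int(np.ceil(n_t / cfg.inner_max_timepoints)))
    t_grid = np.arange(0, n_t, stride)
    inner = StratifiedKFold(cfg.inner_folds, shuffle=True,
                            random_state=int(rng.integers(2**31)))
    scores = np.zeros(len(cfg.c_grid))
    for tr, te in inner.split(np.zeros(len(y)), y):
        stats = _fit_stats(x[tr].reshape(len(tr), -1))
        ztr = stats.apply(x[tr].reshape(len(tr), -1)).reshape(x[tr].shape)
        zte = stats.apply(x[te].reshape(len(te), -1)).reshape(x[te].shape)
        gtr, ytr = _group_average(ztr, y[tr], cfg.group_size, rng)
        gte, yte = _group_average(zte, y[te], cfg.group_size, rng)
        if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
            continue
        pos, neg = yte == 1, yte == 0
        for ci, c in enumerate(cfg.c_grid):
            for t in t_grid:
                w, b = _fit_linear(gtr[:, :, t], ytr, c)
                d = gte[:, :, t] @ w + b
                scores[ci] += roc_auc(d[pos], d[neg])
    return float(cfg.c_grid[int(np.argmax(scores))])


def _auc_grid(decisions: np.ndarray, pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Vectorized rank AUC along axis 1 of a (..., n_obs, ...) decision array.

    ``decisions`` has shape (n_train_t, n_obs, n_test_t); returns the
    (n_train_t, n_test_t) AUC grid with ties counted one half.
    """
    ranks = spstats.rankdata(decisions, axis=1)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    rank_sum = ranks[:, pos, :].sum(axis=1)
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _run_cv(e: EpochSet, cfg: DecodingConfig, mode: str):
    """Shared engine for the decoding curve ('diag') and the TGM ('tgm').

    All randomness (fold assignment, C selection, pseudo-trial grouping)
    is drawn from one seeded generator *before* any mode-dependent
    scoring, so both modes see identical folds and classifiers.
    """
    x, y = _check_input(e, cfg)
    n_t = x.shape[2]
    rng = np.random.default_rng(cfg.seed)
    per_split = []  # AUC per (rep, fold): (n_t,) or (n_t, n_t)
    n_eff = {"standard": [], "deviant": []}
    with config_context(assume_finite=True):
        for rep in range(cfg.n_repetitions):
            splits, rank = stratified_splits(y, cfg.n_folds, rng)
            for train_idx, test_idx in splits:
                c = _select_c(x[train_idx], y[train_idx], cfg, rng)
                flat_tr = x[train_idx].reshape(len(train_idx), -1)
                stats = _fit_stats(flat_tr)
                ztr_full = stats.apply(
                    x.reshape(len(y), -1)).reshape(x.shape)
                g_tr = _partition_groups(y, train_idx, cfg.group_size, rank)
                g_te = _partition_groups(y, test_idx, cfg.group_size, rank)
                gtr = np.stack([ztr_full[g].mean(axis=0) for g in g_tr])
                ytr = np.array([y[g[0]] for g in g_tr])
                gte = np.stack([ztr_full[g].mean(axis=0) for g in g_te])
                yte = np.array([y[g[0]] for g in g_te])
                n_eff["standard"].append(int((ytr == 0).sum()))
                n_eff["deviant"].append(int((ytr == 1).sum()))
                pos, neg = yte == 1, yte == 0
                coefs = np.empty((n_t, gtr.shape[1]))
                intercepts = np.empty(n_t)
                for t in range(n_t):
                    coefs[t], intercepts[t] = _fit_linear(gtr[:, :, t], ytr, c)
                if mode == "diag":
                    scores = np.einsum("mct,tc->tm", gte, coefs) + intercepts[:, None]
                    split_auc = _auc_grid(scores[:, :, None], pos, neg)[:, 0]
                else:
                    scores = np.einsum("mcs,tc->tms", gte, coefs) \
                        + intercepts[:, None, None]
                    split_auc = _auc_grid(scores, pos, neg)
                per_split.append(split_auc)
    stacked = np.stack(per_split)  # (n_splits, n_t[, n_t])
    eff = {k: int(np.mean(v)) for k, v in n_eff.items()}
    return stacked, eff


def decode_time_resolved(e: EpochSet, cfg: DecodingConfig | None = None,
                         ) -> DecodingCurve:
    """Cross-validated AUC of a per-time-point linear SVM.

    Returns the mean and sd of the AUC across the
    ``n_folds x n_repetitions`` estimates at every time point.
    """
    cfg = cfg or DecodingConfig()
    stacked, eff = _run_cv(e, cfg, mode="diag")
    return DecodingCurve(
        times=e.times.copy(),
        auc=stacked.mean(axis=0),
        dispersion=stacked.std(axis=0, ddof=1),
        n_effective_trials=eff,
        config=cfg,
    )


def decode_temporal_generalization(e: EpochSet,
                                   cfg: DecodingConfig | None = None,
                                   ) -> TemporalGeneralizationMatrix:
    """Train at every time point, test at every other (and the same) one.

    With the same config/seed the diagonal equals the time-resolved curve,
    because folds, groupings and C choices are shared between the two.
    """
    cfg = cfg or DecodingConfig()
    stacked, _ = _run_cv(e, cfg, mode="tgm")
    return TemporalGeneralizationMatrix(
        times=e.times.copy(), auc=stacked.mean(axis=0), config=cfg)


def searchlight_channels(e: EpochSet, cfg: DecodingConfig | None = None,
                         windows: Sequence[tuple] | None = None,
                         ) -> SearchlightMap:
    """Single-channel decoding per time window.

    For every (channel, window) pair the within-window samples of that one
    channel form the feature vector; the same cross-validation folds and
    pseudo-trial groupings are reused across channels so the map is
    comparable cell-to-cell.
    """
    cfg = cfg or DecodingConfig()
    windows = tuple(windows) if windows is not None else DEFAULT_SEARCHLIGHT_WINDOWS
    prev_end = None
    for (s, t) in windows:
        if prev_end is not None and s < prev_end:
            raise ValueError("searchlight windows must be ordered, non-overlapping")
        prev_end = t
    x, y = _check_input(e, cfg)
    masks = []
    for w in windows:
        m = e.time_mask(w)
        if not m.any():
            raise ValueError(f"window {w} outside epoch support")
        masks.append(m)
    rng = np.random.default_rng(cfg.seed)
    out = np.zeros((e.n_channels, len(windows)))
    n_splits = 0
    c = float(cfg.c_grid[len(cfg.c_grid) // 2])
    with config_context(assume_finite=True):
        for rep in range(cfg.n_repetitions):
            splits, rank = stratified_splits(y, cfg.n_folds, rng)
            for train_idx, test_idx in splits:
                n_splits += 1
                # one grouping per fold, shared across channels/windows
                g_tr = _partition_groups(y, train_idx, cfg.group_size, rank)
                g_te = _partition_groups(y, test_idx, cfg.group_size, rank)
                ytr = np.array([y[g[0]] for g in g_tr])
                yte = np.array([y[g[0]] for g in g_te])
                for wi, mask in enumerate(masks):
                    for ch in range(e.n_channels):
                        feats = x[:, ch][:, mask]
                        stats = _fit_stats(feats[train_idx])
                        z = stats.apply(feats)
                        gtr = np.stack([z[g].mean(axis=0) for g in g_tr])
                        gte = np.stack([z[g].mean(axis=0) for g in g_te])
                        w_, b_ = _fit_linear(gtr, ytr, c)
                        d = gte @ w_ + b_
                        out[ch, wi] += roc_auc(d[yte == 1], d[yte == 0])
    return SearchlightMap(channels=e.channels, windows=windows,
                          auc=out / n_splits, config=cfg)


@dataclass
class MontageComparison:
    """Paired comparison of peak decoding between a full and a reduced montage."""

    max_auc_full: np.ndarray
    max_auc_subset: np.ndarray
    t_statistic: float
    p_value: float
    df: int


def compare_montages(subjects: Sequence[EpochSet], subset: Sequence[str],
                     cfg: DecodingConfig | None = None) -> MontageComparison:
    """Does restricting the montage to ``subset`` change peak decodability?

    For every subject the time-resolved decoding is run twice — on the
    full montage and on the channel subset — and the per-subject maximum
    AUCs are compared with a paired-samples t-test.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("channel subset must be nonempty")
    cfg = cfg or DecodingConfig()
    full, red = [], []
    for e in subjects:
        full.append(decode_time_resolved(e, cfg).peak()[1])
        red.append(decode_time_resolved(e.select_channels(subset), cfg).peak()[1])
    full, red = np.asarray(full), np.asarray(red)
    diffs = full - red
    if np.allclose(diffs, 0):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = spstats.ttest_rel(full, red)
    return MontageComparison(full, red, float(t_stat), float(p), len(full) - 1)
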