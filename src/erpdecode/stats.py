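"""Inference and secondary statistics for single-subject decoding.

Contains the rank-based ROC area, the label-permutation test with
cluster-based multiple-comparison correction over time (Level-1, i.e.
within-subject inference), difference-wave amplitude extraction for the
MMN and P3a components, and the across-subject amplitude-AUC correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as spstats

from .epochs import DEVIANT, STANDARD, EpochSet

#: Component search windows (seconds) and peak-centered averaging spans.
COMPONENT_WINDOWS = {
    "MMN": {"window": (0.080, 0.230), "mean_span": 0.050, "polarity": -1},
    "P3a": {"window": (0.250, 0.350), "mean_span": 0.100, "polarity": +1},
}


def auc(scores_positive: Sequence[float], scores_negative: Sequence[float],
        ) -> float:
    """ROC area: P(random positive scores above random negative), ties 1/2.

    Computed as the normalized Mann-Whitney rank-sum statistic, which is
    exactly the pairwise win count (ties counted one half) divided by the
    number of positive-negative pairs.
    """
    pos = np.asarray(scores_positive, dtype=float)
    neg = np.asarray(scores_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = spstats.rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    return float((rank_sum - pos.size * (pos.size + 1) / 2.0)
                 / (pos.size * neg.size))


@dataclass
class ClusterTestResult:
    """Outcome of the cluster-corrected label-permutation test."""

    clusters: list  # (start_time, end_time, cluster_stat, p_value)
    n_permutations: int
    alpha: float
    cluster_forming_threshold: str
    significant_mask: np.ndarray  # per-time-point bool
    observed_auc: np.ndarray
    times: np.ndarray
    null_max_stat: np.ndarray

    @property
    def any_significant(self) -> bool:
        return bool(self.significant_mask.any())

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {"start": float(s), "end": float(e), "stat": float(c),
                 "p": float(p)} for (s, e, c, p) in self.clusters],
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
            "cluster_forming_threshold": self.cluster_forming_threshold,
            "significant_mask": self.significant_mask.astype(bool).tolist(),
            "times": self.times.tolist(),
            "observed_auc": self.observed_auc.tolist(),
        }


def _clusters_above(values: np.ndarray, thresholds: np.ndarray,
                    stat: str) -> list[tuple[int, int, float]]:
    """Maximal contiguous runs where values exceed the pointwise threshold.

    Returns (start_index, end_index_inclusive, cluster_statistic); the
    "mass" statistic sums (AUC - 0.5) over the run, "size" counts samples.
    """
    above = values > thresholds
    out = []
    i = 0
    n = len(values)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if stat == "mass":
                c = float(np.sum(values[i:j + 1] - 0.5))
            else:
                c = float(j - i + 1)
            out.append((i, j, c))
            i = j + 1
        else:
            i += 1
    return out


def permutation_cluster_test(e: EpochSet, cfg=None, n_permutations: int = 100,
                             alpha: float = 0.05, seed: int = 0,
                             cluster_stat: str = "mass") -> ClusterTestResult:
    """Label-permutation test of the decoding curve, cluster corrected.

    The observed AUC curve is computed once; for each permutation the
    class labels are shuffled and the *entire* decoding analysis is rerun
    with the same fold/seed schedule, so label exchange is the only thing
    that differs.  The pointwise cluster-forming threshold is the
    (1 - alpha) permutation quantile at each time point; clusters are
    contiguous supra-threshold runs scored by their summed (AUC - 0.5)
    mass, and the null distribution is the per-permutation maximum cluster
    statistic.  Cluster p-values include the observed statistic in the
    null (p = (1 + #{null >= obs}) / (n_permutations + 1)), so p > 0.
    """
    from .decode import DecodingConfig, decode_time_resolved

    cfg = cfg or DecodingConfig()
    if n_permutations < 20:
        raise ValueError("need at least 20 permutations")
    if alpha < 1.0 / (n_permutations + 1):
        raise ValueError(
            f"alpha={alpha} unreachable with {n_permutations} permutations "
            f"(minimum attainable p is {1.0 / (n_permutations + 1):.4f})")
    if cluster_stat not in ("mass", "size"):
        raise ValueError("cluster_stat must be 'mass' or 'size'")
    observed = decode_time_resolved(e, cfg)
    rng = np.random.default_rng(seed)
    perm_curves = np.empty((n_permutations, len(observed.auc)))
    shuffled = e.copy()
    for p in range(n_permutations):
        shuffled.labels = e.labels[rng.permutation(e.n_trials)]
        perm_curves[p] = decode_time_resolved(shuffled, cfg).auc
    thresholds = np.quantile(perm_curves, 1.0 - alpha, axis=0)
    obs_clusters = _clusters_above(observed.auc, thresholds, cluster_stat)
    null_max = np.zeros(n_permutations)
    for p in range(n_permutations):
        cl = _clusters_above(perm_curves[p], thresholds, cluster_stat)
        if cl:
            null_max[p] = max(c for (_, _, c) in cl)
    clusters = []
    mask = np.zeros(len(observed.auc), dtype=bool)
    for (i, j, c) in obs_clusters:
        pval = (1.0 + np.sum(null_max >= c)) / (n_permutations + 1.0)
        clusters.append((float(e.times[i]), float(e.times[j]), c, float(pval)))
        if pval <= alpha:
            mask[i:j + 1] = True
    return ClusterTestResult(
        clusters=clusters,
        n_permutations=n_permutations,
        alpha=alpha,
        cluster_forming_threshold=(
            f"pointwise permutation quantile (1 - {alpha})"),
        significant_mask=mask,
        observed_auc=observed.auc,
        times=e.times.copy(),
        null_max_stat=null_max,
    )


@dataclass
class AmplitudeSummary:
    """Peak-centered difference-wave amplitude of one ERP component."""

    component: str
    search_window: tuple
    peak_latency: float
    mean_amplitude: float  # microvolts over the peak-centered span
    max_auc: float | None
    channels: tuple


def extract_component_amplitude(e: EpochSet, component: str = "MMN",
                                channels: Sequence[str] = ("Fz", "Cz"),
                                window: tuple | None = None,
                                mean_span: float | None = None,
                                curve=None) -> AmplitudeSummary:
    """Difference-wave amplitude of the MMN or P3a component.

    The deviant-minus-standard difference wave is averaged over the given
    channel set; the peak is the most negative (MMN) or most positive
    (P3a) point inside the search window, and the reported amplitude is
    the mean over a peak-centered span (50 ms for MMN, 100 ms for P3a)
    clipped to the search window.  When a decoding curve is supplied, its
    maximum inside the search window is attached.
    """
    if component not in COMPONENT_WINDOWS:
        raise ValueError(f"unknown component {component!r}")
    spec = COMPONENT_WINDOWS[component]
    window = window or spec["window"]
    mean_span = mean_span if mean_span is not None else spec["mean_span"]
    polarity = spec["polarity"]
    if window[0] < e.times[0] or window[1] > e.times[-1]:
        raise ValueError(f"search window {window} outside epoch support")
    labels = e.labels.astype(str)
    if DEVIANT not in labels or STANDARD not in labels:
        raise ValueError("both deviant and standard trials required")
    sub = e.select_channels(list(channels))
    diff = (sub.data[labels == DEVIANT].mean(axis=0)
            - sub.data[labels == STANDARD].mean(axis=0)).mean(axis=0)
    mask = e.time_mask(window)
    idx = np.flatnonzero(mask)
    wave = diff[idx]
    peak_i = idx[int(np.argmin(wave) if polarity < 0 else np.argmax(wave))]
    peak_t = float(e.times[peak_i])
    lo = max(window[0], peak_t - mean_span / 2.0)
    hi = min(window[1], peak_t + mean_span / 2.0)
    span_mask = e.time_mask((lo, hi))
    mean_amp = float(diff[span_mask].mean())
    max_auc = None
    if curve is not None:
        max_auc = curve.max_in_window(window)
    return AmplitudeSummary(
        component=component, search_window=tuple(window),
        peak_latency=peak_t, mean_amplitude=mean_amp,
        max_auc=max_auc, channels=tuple(channels))


def correlate_auc_amplitude(summaries: Sequence[AmplitudeSummary],
                            ) -> dict[str, dict]:
    """Pearson correlation of component amplitude vs. peak AUC across subjects.

    Groups the supplied per-subject summaries by component name and
    returns ``{component: {"r": ..., "p": ..., "n": ...}}``.
    """
    by_comp: dict[str, list[AmplitudeSummary]] = {}
    for s in summaries:
        by_comp.setdefault(s.component, []).append(s)
    out = {}
    for name, group in by_comp.items():
        if len(group) < 3:
            raise ValueError(f"component {name!r}: need >= 3 subjects")
        if any(s.max_auc is None for s in group):
            raise ValueError("every summary needs a max_auc (pass curve=...)")
        amps = np.array([s.mean_amplitude for s in group])
        aucs = np.array([s.max_auc for s in group], dtype=float)
        if np.std(amps) == 0 or np.std(aucs) == 0:
            raise ValueError("zero variance in amplitudes or AUCs")
        r, p = spstats.pearsonr(amps, aucs)
        out[name] = {"r": float(r), "p": float(p), "n": len(group)}
    return out
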