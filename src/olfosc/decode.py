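"""Searchlight SVM decoding of binary labels from coherence spectrograms.

The trial-averaged inter-regional coherence spectrogram of each participant
and class is tiled into overlapping searchlight bins (default 12 Hz × 100 ms,
50% stride). Bins near the spectrogram margin with fewer than 10 neighboring
bins (Chebyshev radius 2 on the bin grid, diagonals included) are excluded.
Per bin, a linear SVM (C = 1, features z-scored on training folds only) is
trained with a leave-one-participant-out scheme on one example per
participant per class; group accuracy is compared with a Monte-Carlo null of
label shuffles (class labels swapped within participant), and significant
bin clusters are assessed with the weighted-cluster-mass machinery on
accuracy-derived z maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.random import default_rng
from scipy import stats as sstats

from .masslme import StatMap, ClusterResult, wcm_test
from .tfr import CoherenceMap

__all__ = [
    "SearchlightGrid",
    "DecodingMap",
    "build_searchlight_grid",
    "build_features",
    "loo_decode",
    "shuffle_null_test",
]


@dataclass
class SearchlightBin:
    row: int
    col: int
    freq_slice: slice
    frame_slice: slice
    freq_range: tuple[float, float]
    time_range: tuple[float, float]
    n_neighbors: int


@dataclass
class SearchlightGrid:
    """Overlapping time-frequency bins with the margin-exclusion rule."""

    bins: list[SearchlightBin]
    excluded: list[SearchlightBin]
    grid_shape: tuple[int, int]
    freqs: np.ndarray
    frames: np.ndarray


@dataclass
class DecodingMap:
    """Group decoding accuracies per retained searchlight bin."""

    accuracy: np.ndarray  # (n_bins,)
    per_class: np.ndarray  # (n_bins, 2): [low, high] accuracy
    grid: SearchlightGrid
    null_accuracy: np.ndarray | None = None  # (n_shuffles, n_bins)
    voxel_p: np.ndarray | None = None
    clusters: ClusterResult | None = None

    def __post_init__(self) -> None:
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


def build_searchlight_grid(
    freqs: np.ndarray,
    frames: np.ndarray,
    bin_hz: float = 12.0,
    bin_sec: float = 0.100,
    overlap: float = 0.5,
    min_neighbors: int = 10,
    neighbor_rule: str = "bins",
) -> SearchlightGrid:
    """Tile a freqs × frames grid into overlapping searchlight bins.

    ``neighbor_rule='bins'`` counts neighboring bins within Chebyshev radius
    2 on the bin grid (the default interior-only searchlight);
    ``'cells'`` counts spectrogram cells inside the bin instead (the
    alternative reading of the exclusion rule).
    """
    freqs = np.asarray(freqs, dtype=float)
    frames = np.asarray(frames, dtype=float)
    df = float(np.mean(np.diff(freqs)))
    dt = float(np.mean(np.diff(frames)))
    bh = max(1, int(round(bin_hz / df)))
    bw = max(1, int(round(bin_sec / dt)))
    step_r = max(1, int(round(bh * (1 - overlap))))
    step_c = max(1, int(round(bw * (1 - overlap))))
    row_starts = list(range(0, freqs.size - bh + 1, step_r))
    col_starts = list(range(0, frames.size - bw + 1, step_c))
    if not row_starts or not col_starts:
        raise ValueError("bin size exceeds the spectrogram extent")
    n_rows, n_cols = len(row_starts), len(col_starts)

    all_bins: list[SearchlightBin] = []
    for r, r0 in enumerate(row_starts):
        for c, c0 in enumerate(col_starts):
            fsl = slice(r0, r0 + bh)
            tsl = slice(c0, c0 + bw)
            if neighbor_rule == "bins":
                nr = min(r + 2, n_rows - 1) - max(r - 2, 0) + 1
                nc = min(c + 2, n_cols - 1) - max(c - 2, 0) + 1
                n_neigh = nr * nc - 1
            elif neighbor_rule == "cells":
                n_neigh = bh * bw - 1
            else:
                raise ValueError("neighbor_rule must be 'bins' or 'cells'")
            all_bins.append(
                SearchlightBin(
                    row=r,
                    col=c,
                    freq_slice=fsl,
                    frame_slice=tsl,
                    freq_range=(freqs[r0], freqs[r0 + bh - 1]),
                    time_range=(frames[c0], frames[c0 + bw - 1]),
                    n_neighbors=n_neigh,
                )
            )
    kept = [b for b in all_bins if b.n_neighbors >= min_neighbors]
    excl = [b for b in all_bins if b.n_neighbors < min_neighbors]
    if not kept:
        raise ValueError("neighbor rule excluded every bin")
    return SearchlightGrid(
        bins=kept, excluded=excl, grid_shape=(n_rows, n_cols),
        freqs=freqs, frames=frames,
    )


def build_features(
    coh_by_class: dict[str, dict[str, CoherenceMap]],
    grid: SearchlightGrid,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-participant, per-class feature vectors for every bin.

    ``coh_by_class[participant][class]`` is a trial-averaged coherence map;
    the two classes are 'low' and 'high'. Participants missing a class are
    excluded (with a warning). Returns (features, labels, participants)
    where ``features`` is (n_examples, n_bins, bin_cells), ``labels`` 0/1
    and one example per participant per class.
    """
    feats, labels, parts = [], [], []
    for pid, classes in coh_by_class.items():
        if not {"low", "high"} <= set(classes):
            warnings.warn(f"participant {pid} missing a class; excluded",
                          stacklevel=2)
            continue
        for label, cls in ((0, "low"), (1, "high")):
            cmap = classes[cls]
            vecs = [
                cmap.coh[b.freq_slice, b.frame_slice].ravel() for b in grid.bins
            ]
            feats.append(np.stack(vecs))
            labels.append(label)
            parts.append(pid)
    if not feats:
        raise ValueError("no participant has both classes")
    return np.stack(feats), np.array(labels), np.array(parts)


def _svm_dual_cd(
    G: np.ndarray, Y: np.ndarray, C: float = 1.0, n_passes: int = 60
) -> np.ndarray:
    """Batched dual coordinate descent for the linear SVM (hinge loss).

    Solves min_a 0.5 a'Qa - sum(a), 0 <= a <= C with Q = yy' * G for every
    row of ``Y`` simultaneously (``G`` is the shared training Gram matrix,
    bias handled by feature augmentation). This is the same dual problem
    liblinear solves; the batched solver exists because the shuffle null
    refits the classifier hundreds of thousands of times on tiny folds. It
    is validated against sklearn's SVC in the test suite.
    """
    B, n = Y.shape
    alpha = np.zeros((B, n))
    diag = np.clip(np.diag(G), 1e-12, None)
    AY = alpha * Y  # running (alpha * y)
    for _ in range(n_passes):
        max_delta = 0.0
        for i in range(n):
            margin = Y[:, i] * (AY @ G[:, i]) - 1.0
            new = np.clip(alpha[:, i] - margin / diag[i], 0.0, C)
            delta = new - alpha[:, i]
            md = np.max(np.abs(delta))
            if md > max_delta:
                max_delta = md
            alpha[:, i] = new
            AY[:, i] = new * Y[:, i]
        if max_delta < 1e-8:
            break
    return alpha


def _loo_accuracy_batch(
    Xb: np.ndarray, labels_batch: np.ndarray, parts: np.ndarray,
    unique_parts: np.ndarray, C: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-participant-out linear-SVM accuracy for one bin, batched
    over label assignments.

    ``labels_batch`` is (B, n_examples) of 0/1 labels; features are z-scored
    with training-fold statistics. Returns (accuracy (B,), per_class (B, 2)).
    """
    B, n = labels_batch.shape
    correct = np.zeros((B, 2))
    totals = np.zeros((B, 2))
    Ysigned = 2.0 * labels_batch - 1.0
    for pid in unique_parts:
        test = parts == pid
        train = ~test
        y_tr = Ysigned[:, train]
        if np.any(np.all(y_tr == y_tr[:, :1], axis=1)):
            raise ValueError("degenerate labels in a training fold")
        mu = Xb[train].mean(axis=0)
        sd = Xb[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (Xb[train] - mu) / sd
        Xte = (Xb[test] - mu) / sd
        G = Xtr @ Xtr.T + 1.0  # +1: augmented (regularized) bias feature
        K = Xtr @ Xte.T + 1.0
        alpha = _svm_dual_cd(G, y_tr, C=C)
        scores = (alpha * y_tr) @ K  # (B, n_test)
        pred = np.where(scores >= 0, 1, 0)
        truth = labels_batch[:, test]
        for cls in (0, 1):
            mask = truth == cls
            totals[:, cls] += mask.sum(axis=1)
            correct[:, cls] += ((pred == truth) & mask).sum(axis=1)
    tot = totals.sum(axis=1)
    acc = correct.sum(axis=1) / tot
    with np.errstate(invalid="ignore"):
        per_class = correct / totals
    return acc, per_class


def loo_decode(
    features: np.ndarray, labels: np.ndarray, participants: np.ndarray,
    grid: SearchlightGrid | None = None,
) -> DecodingMap:
    """Group leave-one-participant-out decoding accuracy per bin."""
    unique_parts = np.unique(participants)
    if unique_parts.size < 5:
        raise ValueError("leave-one-out decoding needs >= 5 participants")
    n_bins = features.shape[1]
    acc = np.zeros(n_bins)
    per_class = np.zeros((n_bins, 2))
    lab = np.asarray(labels)[None, :]
    for b in range(n_bins):
        a, pc = _loo_accuracy_batch(
            features[:, b, :], lab, participants, unique_parts
        )
        acc[b], per_class[b] = a[0], pc[0]
    return DecodingMap(accuracy=acc, per_class=per_class, grid=grid)


def shuffle_null_test(
    features: np.ndarray,
    labels: np.ndarray,
    participants: np.ndarray,
    grid: SearchlightGrid,
    n_shuffles: int = 1000,
    seed: int | None = None,
    forming_alpha: float = 0.05,
    weight_exponent: float = 2.0,
) -> DecodingMap:
    """Label-shuffle Monte-Carlo test with WCM cluster correction.

    Shuffles swap the two class labels within participant (preserving one
    example per participant per pseudo-class). Per bin the one-sided p is
    the rank of the observed accuracy among the shuffled accuracies; cluster
    inference converts accuracy p-values to z maps on the bin grid and
    reuses the weighted-cluster-mass machinery, each shuffle's z map being
    ranked against the remaining shuffles.
    """
    if n_shuffles < 100:
        warnings.warn(
            f"only {n_shuffles} shuffles; p-values are coarse", stacklevel=2
        )
    rng = default_rng(seed)
    unique_parts = np.unique(participants)
    observed = loo_decode(features, labels, participants, grid)

    n_bins = features.shape[1]
    # all shuffle label assignments up front (swap labels within participant)
    lab_batch = np.tile(labels, (n_shuffles, 1))
    for pid in unique_parts:
        idx = np.flatnonzero(participants == pid)
        flip = rng.random(n_shuffles) < 0.5
        lab_batch[np.ix_(flip, idx)] = 1 - lab_batch[np.ix_(flip, idx)]
    null = np.zeros((n_shuffles, n_bins))
    for b in range(n_bins):
        null[:, b], _ = _loo_accuracy_batch(
            features[:, b, :], lab_batch, participants, unique_parts
        )

    # one-sided Monte-Carlo p per bin; never below 1/(n_shuffles + 1)
    voxel_p = (1 + np.sum(null >= observed.accuracy[None, :], axis=0)) / (
        n_shuffles + 1
    )

    # accuracy-derived z maps on the bin grid (one-sided: negatives clipped)
    z_obs = np.maximum(sstats.norm.isf(voxel_p), 0.0)
    # each shuffle ranked against all shuffles (its own included: rank >= 1)
    ranks = np.sum(null[None, :, :] >= null[:, None, :], axis=1)
    null_p = ranks / (n_shuffles + 1)
    z_null = np.maximum(sstats.norm.isf(null_p), 0.0)

    def _bin_map(z: np.ndarray) -> np.ndarray:
        out = np.zeros(grid.grid_shape)
        for b, val in zip(grid.bins, z):
            out[b.row, b.col] = val
        return out

    obs_map = StatMap(
        t=_bin_map(z_obs),
        voxel_p=np.ones(grid.grid_shape),
        df=10**6,  # z scale: normal threshold
        beta=_bin_map(z_obs),
        se=np.ones(grid.grid_shape),
        flagged=np.zeros(grid.grid_shape, dtype=bool),
        predictor="accuracy",
    )
    perms = [_bin_map(z_null[s]) for s in range(n_shuffles)]
    # one-sided forming threshold at alpha on the z scale
    clusters = wcm_test(
        obs_map, perms, forming_alpha=2 * forming_alpha,
        weight_exponent=weight_exponent,
    )
    # annotate clusters with bin coordinates
    bin_lookup = {(b.row, b.col): b for b in grid.bins}
    for c in clusters.clusters:
        members = [bin_lookup.get(tuple(cell)) for cell in c["cells"]]
        members = [m for m in members if m is not None]
        if members:
            c["freq_range"] = (
                min(m.freq_range[0] for m in members),
                max(m.freq_range[1] for m in members),
            )
            c["time_range"] = (
                min(m.time_range[0] for m in members),
                max(m.time_range[1] for m in members),
            )
    return DecodingMap(
        accuracy=observed.accuracy,
        per_class=observed.per_class,
        grid=grid,
        null_accuracy=null,
        voxel_p=voxel_p,
        clusters=clusters,
    )
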