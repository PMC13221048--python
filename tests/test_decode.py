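"""Searchlight grid construction, leave-one-out SVM decoding (validated
against sklearn's SVC) and the label-shuffle cluster test."""

import numpy as np
import pytest

from olfosc.decode import (
    _loo_accuracy_batch,
    build_features,
    build_searchlight_grid,
    loo_decode,
    shuffle_null_test,
)
from olfosc.tfr import CoherenceMap

FREQS = np.arange(5.0, 41.0, 3.0)   # 12 rows
FRAMES = np.arange(0.0, 1.0, 0.05)  # 20 cols


def _grid(**kw):
    return build_searchlight_grid(FREQS, FRAMES, bin_hz=12.0, bin_sec=0.2, **kw)


def _toy_features(rng, n_part, n_bins, d=8, offset_bin=None, offset=0.0):
    feats = rng.standard_normal((2 * n_part, n_bins, d))
    labels = np.tile([0, 1], n_part)
    if offset_bin is not None:
        feats[labels == 1, offset_bin, :] += offset
    parts = np.repeat([f"P{i}" for i in range(n_part)], 2)
    return feats, labels, parts


class TestSearchlightGrid:
    def test_margin_bins_excluded_by_neighbor_rule(self):
        grid = _grid()
        assert grid.excluded, "corner bins should fail the 10-neighbor rule"
        assert all(b.n_neighbors >= 10 for b in grid.bins)
        assert all(b.n_neighbors < 10 for b in grid.excluded)
        rows = {b.row for b in grid.bins} | {b.row for b in grid.excluded}
        cols = {b.col for b in grid.bins} | {b.col for b in grid.excluded}
        assert grid.grid_shape == (len(rows), len(cols))

    def test_cells_neighbor_rule_counts_bin_cells(self):
        grid = _grid(neighbor_rule="cells")
        # every bin holds the same number of cells, so none are excluded
        assert not grid.excluded

    def test_bin_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_searchlight_grid(FREQS[:2], FRAMES[:2], bin_hz=50.0,
                                   bin_sec=3.0)


class TestBuildFeatures:
    def _coh_maps(self, rng, n_part, drop_class=None):
        out = {}
        for p in range(n_part):
            pid = f"P{p}"
            out[pid] = {}
            for cls in ("low", "high"):
                if drop_class == (pid, cls):
                    continue
                out[pid][cls] = CoherenceMap(
                    coh=rng.random((FREQS.size, FRAMES.size)),
                    freqs=FREQS, frames=FRAMES, n_trials=10, label=cls,
                )
        return out

    def test_one_example_per_participant_per_class(self, rng):
        grid = _grid()
        feats, labels, parts = build_features(self._coh_maps(rng, 6), grid)
        assert feats.shape[0] == 12 and feats.shape[1] == len(grid.bins)
        assert labels.sum() == 6

    def test_participant_missing_class_excluded(self, rng):
        grid = _grid()
        with pytest.warns(UserWarning, match="missing a class"):
            feats, labels, parts = build_features(
                self._coh_maps(rng, 6, drop_class=("P2", "high")), grid
            )
        assert "P2" not in parts
        assert feats.shape[0] == 10


class TestLooDecode:
    def test_chance_level_on_label_independent_features(self, rng):
        feats, labels, parts = _toy_features(rng, 12, n_bins=15)
        dmap = loo_decode(feats, labels, parts)
        # binomial 99.7% band around 0.5 at 24 folds, averaged over 15 bins
        assert abs(dmap.accuracy.mean() - 0.5) < 3 * np.sqrt(0.25 / 24 / 15) + 0.05

    def test_separable_features_decode_perfectly(self, rng):
        feats, labels, parts = _toy_features(rng, 8, n_bins=3, offset_bin=1,
                                             offset=8.0)
        dmap = loo_decode(feats, labels, parts)
        assert dmap.accuracy[1] == 1.0
        assert np.all(dmap.per_class[1] == 1.0)

    def test_offset_is_local_to_its_bin(self, rng):
        feats, labels, parts = _toy_features(rng, 10, n_bins=6, offset_bin=3,
                                             offset=8.0)
        dmap = loo_decode(feats, labels, parts)
        others = np.delete(dmap.accuracy, 3)
        assert dmap.accuracy[3] == 1.0
        assert np.all(others < 0.9)

    def test_too_few_participants_rejected(self, rng):
        feats, labels, parts = _toy_features(rng, 4, n_bins=2)
        with pytest.raises(ValueError):
            loo_decode(feats, labels, parts)

    def test_agrees_with_sklearn_svc(self, rng):
        """Batched dual-CD solver tracks sklearn's linear SVC accuracies."""
        svm = pytest.importorskip("sklearn.svm")
        n_part = 8
        parts_codes = np.repeat(np.arange(n_part), 2)
        diffs = []
        for rep in range(20):
            X = rng.standard_normal((2 * n_part, 6))
            y = np.tile([0, 1], n_part)
            if rep % 2:
                X[y == 1] += rng.uniform(0.2, 1.2)
            acc, _ = _loo_accuracy_batch(
                X, y[None, :], parts_codes, np.unique(parts_codes)
            )
            correct = 0
            for pid in np.unique(parts_codes):
                te = parts_codes == pid
                tr = ~te
                mu, sd = X[tr].mean(0), X[tr].std(0)
                sd[sd == 0] = 1.0
                clf = svm.SVC(kernel="linear", C=1.0)
                clf.fit((X[tr] - mu) / sd, y[tr])
                correct += (clf.predict((X[te] - mu) / sd) == y[te]).sum()
            diffs.append(abs(acc[0] - correct / (2 * n_part)))
        # identical objective up to the bias convention: accuracies agree on
        # average to within one held-out example
        assert np.mean(diffs) <= 1.0 / (2 * n_part)
        assert np.median(diffs) == 0.0


class TestShuffleNull:
    def test_p_floor_and_determinism(self, rng):
        grid = _grid()
        n_bins = len(grid.bins)
        feats, labels, parts = _toy_features(rng, 8, n_bins=n_bins)
        a = shuffle_null_test(feats, labels, parts, grid, n_shuffles=120,
                              seed=7)
        b = shuffle_null_test(feats, labels, parts, grid, n_shuffles=120,
                              seed=7)
        assert np.all(a.voxel_p >= 1.0 / 121)
        np.testing.assert_array_equal(a.voxel_p, b.voxel_p)
        np.testing.assert_array_equal(a.null_accuracy, b.null_accuracy)

    def test_injected_bin_yields_significant_cluster(self, rng):
        grid = _grid()
        n_bins = len(grid.bins)
        feats, labels, parts = _toy_features(rng, 10, n_bins=n_bins)
        # strong class offset in a 2x2 block of interior bins
        target = [i for i, b in enumerate(grid.bins)
                  if b.row == 1 and b.col in (4, 5)]
        for tb in target:
            feats[labels == 1, tb, :] += 5.0
        dmap = shuffle_null_test(feats, labels, parts, grid, n_shuffles=150,
                                 seed=3)
        sig = dmap.clusters.significant(0.05)
        assert sig
        covered = {tuple(c) for cl in sig for c in cl["cells"]}
        assert all((grid.bins[tb].row, grid.bins[tb].col) in covered
                   for tb in target)
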