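"""Feature encoding geometry, values and the IG/χ² selector."""

import numpy as np
import pytest

from turnklr.features import (
    FeatureMatrix,
    encode_dataset,
    encode_pssm_window,
    encode_ss_block,
    feature_width,
    rank_features,
    scale_pssm,
    select_features,
)
from turnklr.formats import SSPrediction

SOURCES = ("psipred", "jnet", "transec", "proteus")


def make_preds(states_per_source, confs=None):
    L = len(states_per_source[0])
    confs = confs or [[5] * L] * 4
    return [
        SSPrediction("c1", src, st, cf)
        for src, st, cf in zip(SOURCES, states_per_source, confs)
    ]


class TestScalePSSM:
    def test_zero_maps_to_half(self):
        assert scale_pssm(np.zeros((2, 20)))[0, 0] == 0.5

    def test_saturation(self):
        s = scale_pssm(np.array([[100.0, -100.0]]))
        assert s[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert s[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_logistic_value(self):
        assert scale_pssm(np.array([[2.0]]))[0, 0] == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-12
        )

    def test_monotone(self):
        raw = np.linspace(-5, 5, 11)[None, :]
        assert (np.diff(scale_pssm(raw)[0]) > 0).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            scale_pssm(np.array([[np.nan]]))


class TestPSSMWindow:
    def test_length_140_at_window_7(self):
        scaled = np.full((10, 20), 0.3)
        assert encode_pssm_window(scaled, 5, window=7).shape == (140,)

    def test_centered_constant_profile(self):
        scaled = np.full((7, 20), 0.5)
        v = encode_pssm_window(scaled, 3, window=7)
        assert (v == 0.5).all()

    def test_left_edge_padding(self):
        rng = np.random.default_rng(0)
        scaled = rng.uniform(size=(7, 20))
        v = encode_pssm_window(scaled, 0, window=7)
        # three off-chain positions on the left → 60 zeros
        assert (v[:60] == 0).all()
        np.testing.assert_array_equal(v[60:], scaled[:4].ravel())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            encode_pssm_window(np.zeros((5, 20)), 2, window=6)


class TestSSBlock:
    def test_length_76(self):
        preds = make_preds(["HEC"] * 4)
        assert encode_ss_block(preds, 1).shape == (76,)

    def test_central_onehot_layout(self):
        # sources predict H, C, H, H for the central residue
        preds = make_preds(["HHH", "HCH", "HHH", "HHH"])
        v = encode_ss_block(preds, 1)
        expected = [1, 0, 0, 0, 0, 1, 1, 0, 0, 1, 0, 0]
        np.testing.assert_array_equal(v[:12], expected)

    def test_confidence_scaled_by_ten(self):
        preds = make_preds(["CCC"] * 4, confs=[[0, 9, 0]] * 4)
        v = encode_ss_block(preds, 1)
        np.testing.assert_allclose(v[12:16], 0.9)

    def test_all_coil_pattern_and_ratio(self):
        preds = make_preds(["C" * 7] * 4)
        v = encode_ss_block(preds, 3, window=7)
        patterns = v[16:64].reshape(4, 3, 4)  # source × state(H,E,C) × pattern
        for s in range(4):
            np.testing.assert_array_equal(patterns[s, 2], [1, 0, 0, 0])  # CCC
            np.testing.assert_array_equal(patterns[s, :2], 0)
        ratios = v[64:].reshape(4, 3)
        np.testing.assert_allclose(ratios[:, 2], 1.0)
        np.testing.assert_allclose(ratios[:, :2], 0.0)

    def test_boundary_patterns_do_not_fire(self):
        preds = make_preds(["CCC"] * 4)
        v = encode_ss_block(preds, 0)
        assert (v[16:64] == 0).all()

    def test_requires_four_sources(self):
        preds = make_preds(["CCC"] * 4)[:3]
        with pytest.raises(ValueError):
            encode_ss_block(preds, 1)


class TestEncodeDataset:
    def test_geometry_and_provenance(self, small_dataset):
        fm = encode_dataset(small_dataset)
        assert fm.X.shape[1] == feature_width(7) == 216
        assert fm.X.shape[0] == sum(c.length for c in small_dataset.chains)
        # provenance row k maps back to the right chain and position
        k = 37
        cid, pos = fm.provenance[k]
        chain = next(c for c in small_dataset.chains if c.chain_id == cid)
        assert 0 <= pos < chain.length
        offset = 0
        for c in small_dataset.chains:
            if c.chain_id == cid:
                break
            offset += c.length
        assert offset + pos == k

    def test_entries_in_unit_interval(self, small_dataset):
        fm = encode_dataset(small_dataset)
        assert fm.X.min() >= 0.0 and fm.X.max() <= 1.0
        # indicator blocks exactly {0,1}: central one-hot and patterns
        onehot = fm.X[:, 140:152]
        patterns = fm.X[:, 156:204]
        assert set(np.unique(onehot)) <= {0.0, 1.0}
        assert set(np.unique(patterns)) <= {0.0, 1.0}

    def test_width_scales_with_window(self, small_dataset):
        fm9 = encode_dataset(small_dataset, window=9)
        assert fm9.X.shape[1] == 20 * 9 + 76

    def test_encoding_is_position_local(self, small_dataset):
        import copy

        fm = encode_dataset(small_dataset)
        mutated = copy.deepcopy(small_dataset)
        cid = mutated.chains[0].chain_id
        j = 15
        pred = mutated.ss[cid]["jnet"]
        states = list(pred.states)
        states[j] = "H" if states[j] != "H" else "E"
        mutated.ss[cid]["jnet"] = SSPrediction(
            cid, "jnet", "".join(states), list(pred.confidence)
        )
        fm2 = encode_dataset(mutated)
        changed = np.flatnonzero(np.any(fm.X != fm2.X, axis=1))
        positions = [fm.provenance[i] for i in changed]
        assert all(c == cid for c, _ in positions)
        assert all(abs(p - j) <= 3 for _, p in positions)


class TestSelector:
    def _toy(self, n=200, d=8, seed=1):
        rng = np.random.default_rng(seed)
        y = np.where(rng.random(n) < 0.4, 1, -1)
        X = rng.uniform(size=(n, d))
        X[:, 3] = (y > 0).astype(float)  # perfect copy of the class
        X[:, 5] = 0.42  # constant
        return X, y

    def test_class_copy_ranks_first(self):
        X, y = self._toy()
        sel = rank_features(X, y)
        assert sel.ranked_indices[0] == 3
        assert sel.info_gain[3] == max(sel.info_gain)
        assert sel.chi_squared[3] == max(sel.chi_squared)

    def test_constant_feature_scores_zero(self):
        X, y = self._toy()
        sel = rank_features(X, y)
        assert sel.info_gain[5] == pytest.approx(0.0, abs=1e-12)
        assert sel.chi_squared[5] == pytest.approx(0.0, abs=1e-12)

    def test_column_permutation_permutes_ranks(self):
        X, y = self._toy()
        perm = np.array([4, 0, 3, 1, 7, 2, 6, 5])
        sel = rank_features(X, y)
        sel_p = rank_features(X[:, perm], y)
        # feature j in the permuted matrix is original feature perm[j]
        np.testing.assert_array_equal(
            perm[sel_p.ranked_indices], sel.ranked_indices
        )

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).uniform(size=(10, 3))
        with pytest.raises(ValueError):
            rank_features(X, np.ones(10))

    def test_selection_keeps_original_column_order(self):
        X, y = self._toy()
        sel = rank_features(X, y)
        idx = sel.selected_indices(4)
        assert (np.diff(idx) > 0).all()
        np.testing.assert_array_equal(select_features(sel, X, k=4), X[:, idx])

    def test_k_equals_d_is_identity(self):
        X, y = self._toy()
        sel = rank_features(X, y)
        np.testing.assert_array_equal(select_features(sel, X, k=X.shape[1]), X)

    def test_k_larger_than_d_rejected(self):
        X, y = self._toy()
        sel = rank_features(X, y)
        with pytest.raises(ValueError):
            select_features(sel, X, k=X.shape[1] + 1)

    def test_selector_transfers_between_folds(self):
        X, y = self._toy(n=300)
        sel = rank_features(X[:150], y[:150])
        idx_train = select_features(sel, X[:150], k=4)
        idx_test = select_features(sel, X[150:], k=4)
        assert idx_train.shape[1] == idx_test.shape[1] == 4
        np.testing.assert_array_equal(
            sel.selected_indices(4), sel.selected_indices(4)
        )

    def test_no_test_label_leakage(self):
        # selector fitted on training rows only: permuting test labels is a no-op
        X, y = self._toy(n=300)
        sel_a = rank_features(X[:150], y[:150])
        y_perm = y.copy()
        y_perm[150:] = np.random.default_rng(3).permutation(y[150:])
        sel_b = rank_features(X[:150], y_perm[:150])
        np.testing.assert_array_equal(sel_a.ranked_indices, sel_b.ranked_indices)

    def test_selector_json_roundtrip(self, tmp_path):
        from turnklr.features import FeatureSelector

        X, y = self._toy()
        sel = rank_features(X, y)
        p = tmp_path / "sel.json"
        sel.to_json(p)
        back = FeatureSelector.from_json(p)
        np.testing.assert_array_equal(back.ranked_indices, sel.ranked_indices)
        assert back.k == sel.k
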