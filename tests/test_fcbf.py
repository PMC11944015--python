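"""Entropy, MDL discretization, symmetrical uncertainty and FCBF selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytoratio import (entropy, fcbf_select, mdl_discretize,
                       symmetrical_uncertainty)
from cytoratio.fcbf import _encode, _mdl_screen, discretize
from conftest import oracle_fcbf, oracle_su


class TestEntropy:
    @pytest.mark.parametrize("seq,expected", [
        (list("AABB"), 1.0),
        (list("AAAA"), 0.0),
        (list("AAAB"), 0.8112781244591328),  # −¾log₂¾ − ¼log₂¼
    ])
    def test_known_values(self, seq, expected):
        assert entropy(seq) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy([])


class TestMdlDiscretize:
    def test_clear_two_cluster_split(self):
        cuts = mdl_discretize([1, 2, 3, 101, 102, 103], list("AAABBB"))
        assert len(cuts) == 1
        assert 3 < cuts[0] < 101

    def test_constant_labels_no_cuts(self):
        assert mdl_discretize([1, 2, 3, 4, 5, 6], list("AAAAAA")).size == 0

    def test_constant_values_no_cuts(self):
        assert mdl_discretize([5, 5, 5, 5, 5, 5], list("AABBAB")).size == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mdl_discretize([1, 2, 3], list("AB"))

    def test_random_labels_mostly_rejected(self, rng):
        """Pure-noise features rarely earn a cut under the MDL penalty."""
        accepted = 0
        for _ in range(50):
            v = rng.normal(size=30)
            y = rng.integers(0, 2, size=30)
            accepted += mdl_discretize(v, y).size > 0
        assert accepted <= 5

    def test_best_cut_chosen_exhaustively(self, rng):
        """The first accepted cut is the global information-gain maximiser,
        checked against exhaustive search over every boundary."""
        from conftest import oracle_entropy

        for _ in range(20):
            v = np.sort(rng.normal(size=25))
            y = list(rng.choice(list("AB"), size=25))
            cuts = mdl_discretize(v, y)
            if cuts.size == 0:
                continue
            # exhaustive search for the best single binary split
            best_gain, best_mid = -1.0, None
            h = oracle_entropy(y)
            for i in range(24):
                if v[i] == v[i + 1]:
                    continue
                left = [y[j] for j in range(25) if v[j] <= (v[i] + v[i+1]) / 2]
                right = [y[j] for j in range(25) if v[j] > (v[i] + v[i+1]) / 2]
                gain = h - (len(left) * oracle_entropy(left)
                            + len(right) * oracle_entropy(right)) / 25
                if gain > best_gain + 1e-12:
                    best_gain, best_mid = gain, (v[i] + v[i + 1]) / 2
            assert best_mid in [pytest.approx(c) for c in cuts]

    def test_screen_matches_per_feature_recursion(self, rng):
        """The vectorised first-split screen agrees with mdl_discretize on
        which features receive at least one cut."""
        n = 40
        y = rng.integers(0, 2, size=n)
        X = np.column_stack([rng.normal(size=n) for _ in range(30)]
                            + [rng.normal(y * 3.0, 0.5) for _ in range(10)])
        codes, n_classes = _encode(y)
        screened = _mdl_screen(X, codes, n_classes, chunk=7)
        per_feature = np.array(
            [mdl_discretize(X[:, j], y).size > 0 for j in range(X.shape[1])])
        np.testing.assert_array_equal(screened, per_feature)


class TestSymmetricalUncertainty:
    def test_identical_sequences(self):
        assert symmetrical_uncertainty([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_constant_feature(self):
        assert symmetrical_uncertainty([1, 1, 1, 1], list("ABAB")) == 0.0

    def test_independent_feature(self):
        assert symmetrical_uncertainty([0, 0, 1, 1], list("ABAB")) == 0.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 2)),
                    min_size=2, max_size=40))
    def test_symmetry_and_bounds(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        su_xy = symmetrical_uncertainty(x, y)
        su_yx = symmetrical_uncertainty(y, x)
        assert su_xy == pytest.approx(su_yx, abs=1e-12)
        assert 0.0 <= su_xy <= 1.0
        assert su_xy == pytest.approx(oracle_su(x, y), abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        """A strictly increasing transform leaves the induced partition and
        the SU of a feature unchanged."""
        y = rng.integers(0, 2, size=60)
        v = rng.normal(y * 2.0, 1.0)
        cuts_a = mdl_discretize(v, y)
        w = np.exp(3 * v) + 5  # strictly increasing
        cuts_b = mdl_discretize(w, y)
        np.testing.assert_array_equal(discretize(v, cuts_a),
                                      discretize(w, cuts_b))
        su_a = symmetrical_uncertainty(discretize(v, cuts_a), y)
        su_b = symmetrical_uncertainty(discretize(w, cuts_b), y)
        assert su_a == pytest.approx(su_b, abs=1e-12)


class TestFcbfSelect:
    def test_duplicate_feature_deduplicated(self, rng):
        y = rng.integers(0, 2, size=40)
        signal = rng.normal(y * 4.0, 1.0)
        X = pd.DataFrame({"f1": signal, "f2": signal.copy(),
                          "noise": rng.normal(size=40)})
        scores = fcbf_select(X, y)
        by_name = {s.feature: s for s in scores}
        assert by_name["f1"].selected
        assert not by_name["f2"].selected  # perfect redundancy
        assert by_name["f1"].su == pytest.approx(by_name["f2"].su)

    def test_worked_six_sample_table(self):
        """One perfectly predictive feature, one noise feature: the noise
        feature earns no MDL cut, scores SU 0 and is excluded."""
        X = pd.DataFrame({
            "predictive": [1.0, 2.0, 3.0, 101.0, 102.0, 103.0],
            "noise": [5.0, 1.0, 4.0, 2.0, 6.0, 3.0],
        })
        y = list("AAABBB")
        scores = {s.feature: s for s in fcbf_select(X, y)}
        assert scores["predictive"].selected
        assert scores["predictive"].su == 1.0
        assert scores["predictive"].rank == 1
        assert scores["noise"].su == 0.0
        assert not scores["noise"].selected
        assert scores["noise"].rank is None

    def test_su_zero_features_never_selected_ranks_consecutive(self, rng):
        y = rng.integers(0, 2, size=50)
        X = pd.DataFrame({
            **{f"s{i}": rng.normal(y * (2 + i), 1.0) for i in range(3)},
            **{f"n{i}": rng.normal(size=50) for i in range(5)},
        })
        scores = fcbf_select(X, y)
        sus = [s.su for s in scores]
        assert sus == sorted(sus, reverse=True)
        ranks = [s.rank for s in scores if s.selected]
        assert ranks == list(range(1, len(ranks) + 1))
        for s in scores:
            assert 0.0 <= s.su <= 1.0
            if s.selected:
                assert s.su > 0

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fcbf_select(X, ["A", "A", "A"])

    def test_matches_bruteforce_oracle(self, rng):
        """On small random tables the full selector agrees with an
        independent implementation of the predominant-feature definition
        applied to the same discretized bins."""
        for trial in range(25):
            n = int(rng.integers(12, 31))
            n_feat = int(rng.integers(2, 9))
            y = rng.integers(0, 2, size=n)
            cols = {}
            for j in range(n_feat):
                kind = rng.integers(0, 3)
                if kind == 0:
                    cols[f"f{j}"] = rng.normal(size=n)
                elif kind == 1:
                    cols[f"f{j}"] = rng.normal(y * rng.uniform(1, 4), 1.0)
                else:
                    base = cols.get(f"f{rng.integers(0, j)}" if j else "f0")
                    cols[f"f{j}"] = (base + rng.normal(0, 0.2, size=n)
                                     if base is not None
                                     else rng.normal(size=n))
            X = pd.DataFrame(cols)

            scores = fcbf_select(X, y)
            selected = [s.feature for s in scores if s.selected]

            binned = {}
            for f in X.columns:
                cuts = mdl_discretize(X[f].to_numpy(), y)
                if cuts.size:
                    binned[f] = list(discretize(X[f].to_numpy(), cuts))
            kept, su = oracle_fcbf(binned, list(y))
            assert selected == kept, f"trial {trial}"
            for s in scores:
                if s.feature in su:
                    assert s.su == pytest.approx(su[s.feature], abs=1e-9)
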