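"""Correlation, mutual information, CLR and thresholding against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from coexnet import (
    ConfigurationError,
    ScoreMatrix,
    ValidationError,
    clr_z_matrix,
    correlation_matrix,
    mutual_information_matrix,
    network_size_curve,
    read_edge_list,
    threshold_network,
    write_edge_list,
)


def naive_pearson(x, y):
    """Textbook product-moment formula, double loop free."""
    mx, my = sum(x) / len(x), sum(y) / len(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def histogram_mi_nats(x, y, bins):
    """Brute-force equal-width-bin plug-in MI (independent of the implementation)."""

    def discretize(v):
        lo, hi = min(v), max(v)
        if hi == lo:
            return [0] * len(v)
        out = []
        for a in v:
            b = int((a - lo) / (hi - lo) * bins)
            out.append(min(b, bins - 1))
        return out

    dx, dy = discretize(x), discretize(y)
    n = len(x)
    joint = {}
    for a, b in zip(dx, dy):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px = {a: dx.count(a) / n for a in set(dx)}
    py = {b: dy.count(b) / n for b in set(dy)}
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / n
        mi += p * math.log(p / (px[a] * py[b]))
    return max(mi, 0.0)


class TestCorrelation:
    def test_self_correlation_is_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 10)), index=list("abcd"))
        for method in ("pcc", "scc"):
            s = correlation_matrix(m, method)
            np.testing.assert_allclose(np.diag(s.values), 1.0)

    def test_matches_textbook_formula(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 8)), index=list("abcd"))
        s = correlation_matrix(m, "pcc")
        x = m.to_numpy()
        for i, j in itertools.combinations(range(4), 2):
            assert s.values[i, j] == pytest.approx(naive_pearson(x[i], x[j]), abs=1e-12)

    def test_scc_invariant_under_monotone_transform(self, rng):
        m = pd.DataFrame(rng.uniform(1, 5, size=(5, 12)), index=list("abcde"))
        s1 = correlation_matrix(m, "scc")
        s2 = correlation_matrix(np.exp(m) + 3, "scc")
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-12)

    def test_pcc_invariant_under_positive_affine(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 9)), index=list("abcd"))
        s1 = correlation_matrix(m, "pcc")
        s2 = correlation_matrix(m * 2.5 + 7.0, "pcc")
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-10)

    def test_constant_row_zeroed_with_warning(self, caplog):
        m = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["g1", "flat"]
        )
        with caplog.at_level("WARNING"):
            s = correlation_matrix(m, "pcc")
        assert s.values[0, 1] == 0.0
        assert any("flat" in rec.message for rec in caplog.records)


class TestMutualInformation:
    def test_perfect_dependence_is_one_bit(self):
        m = pd.DataFrame([[1, 1, 2, 2], [10, 10, 20, 20]], index=["x", "y"]).astype(float)
        s = mutual_information_matrix(m, estimator="equal_width_bins", bins=2, unit="bits")
        assert s.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        s_nats = mutual_information_matrix(m, estimator="equal_width_bins", bins=2)
        assert s_nats.values[0, 1] == pytest.approx(math.log(2), abs=1e-12)

    def test_exact_independence_is_zero(self):
        m = pd.DataFrame([[1, 1, 2, 2], [1, 2, 1, 2]], index=["x", "y"]).astype(float)
        s = mutual_information_matrix(m, estimator="equal_width_bins", bins=2)
        assert s.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_histogram_oracle(self, rng):
        """100 random 20-sample pairs agree with the joint-histogram oracle to 1e-12."""
        for _ in range(100):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            m = pd.DataFrame([x, y], index=["x", "y"])
            s = mutual_information_matrix(m, estimator="equal_width_bins", bins=5)
            assert s.values[0, 1] == pytest.approx(histogram_mi_nats(x, y, 5), abs=1e-12)

    def test_self_mi_bounds_cross_mi(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 20)), index=list("abcdef"))
        s = mutual_information_matrix(m, estimator="equal_width_bins", bins=4)
        for i in range(6):
            assert s.values[i, i] >= s.values[i].max() - 1e-12

    def test_bspline_order_one_equals_plain_binning(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 20)), index=list("abcde"))
        a = mutual_information_matrix(m, estimator="bspline", bins=6, spline_order=1)
        b = mutual_information_matrix(m, estimator="equal_width_bins", bins=6)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_blocked_equals_unblocked(self, rng):
        m = pd.DataFrame(rng.normal(size=(7, 20)), index=list("abcdefg"))
        a = mutual_information_matrix(m, block_size=2)
        b = mutual_information_matrix(m, block_size=1000)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_bad_configurations_rejected(self, rng):
        m = pd.DataFrame(rng.normal(size=(3, 10)), index=list("abc"))
        with pytest.raises(ConfigurationError):
            mutual_information_matrix(m, bins=1)
        with pytest.raises(ConfigurationError):
            mutual_information_matrix(m, bins=11)  # bins > samples
        with pytest.raises(ConfigurationError):
            mutual_information_matrix(m, bins=4, spline_order=9)


class TestCLR:
    def test_hand_evaluated_toy(self):
        v = np.array([[0.5, 0.8, 0.2], [0.8, 0.5, 0.2], [0.2, 0.2, 0.5]])
        z, bg = clr_z_matrix(ScoreMatrix(("A", "B", "C"), v, "mi"))
        # background of A: off-diagonal (0.8, 0.2) -> mu 0.5, population sd 0.3
        assert bg.mu[0] == pytest.approx(0.5)
        assert bg.sigma[0] == pytest.approx(0.3)
        assert z.values[0, 1] == pytest.approx(math.sqrt(2.0), abs=1e-12)

    def test_low_mi_clamps_to_zero(self, rng):
        v = rng.uniform(0.5, 1.0, size=(5, 5))
        v = (v + v.T) / 2
        v[1, 2] = v[2, 1] = 0.0  # below both backgrounds
        z, _ = clr_z_matrix(ScoreMatrix(tuple("abcde"), v, "mi"))
        assert z.values[1, 2] == 0.0

    def test_symmetric_and_nonnegative_on_random_input(self, rng):
        v = rng.uniform(0, 2, size=(8, 8))
        v = (v + v.T) / 2
        z, _ = clr_z_matrix(ScoreMatrix(tuple("abcdefgh"), v, "mi"))
        np.testing.assert_allclose(z.values, z.values.T, atol=1e-12)
        assert (z.values >= 0).all()

    def test_permutation_equivariance(self, rng):
        v = rng.uniform(0, 2, size=(6, 6))
        v = (v + v.T) / 2
        ids = tuple("abcdef")
        z, _ = clr_z_matrix(ScoreMatrix(ids, v, "mi"))
        perm = rng.permutation(6)
        zp, _ = clr_z_matrix(
            ScoreMatrix(tuple(ids[i] for i in perm), v[np.ix_(perm, perm)], "mi")
        )
        np.testing.assert_allclose(zp.values, z.values[np.ix_(perm, perm)], atol=1e-12)

    def test_wrong_method_rejected(self, rng):
        with pytest.raises(ValidationError):
            clr_z_matrix(ScoreMatrix(("a", "b"), np.eye(2), "pcc"))


class TestThresholding:
    def make_scores(self, rng, n=5):
        v = rng.uniform(-1, 1, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        return ScoreMatrix(tuple(f"g{i}" for i in range(n)), v, "pcc")

    def test_cutoff_above_max_gives_empty_network(self, rng):
        s = self.make_scores(rng)
        net = threshold_network(s, 2.0)
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_minus_infinity_like_cutoff_gives_complete_graph(self, rng):
        s = self.make_scores(rng, n=6)
        net = threshold_network(s, -10.0)
        assert net.n_edges == 6 * 5 // 2

    def test_edges_match_exhaustive_enumeration(self, rng):
        s = self.make_scores(rng)
        for cutoff in (0.0, 0.5):
            net = threshold_network(s, cutoff)
            expected = {
                frozenset((s.gene_ids[i], s.gene_ids[j]))
                for i, j in itertools.combinations(range(5), 2)
                if s.values[i, j] >= cutoff
            }
            got = {frozenset((a, b)) for a, b, _ in net.edges()}
            assert got == expected
            assert all(w >= cutoff for _, _, w in net.edges())

    def test_size_curve_consistent_and_monotone(self, rng):
        s = self.make_scores(rng, n=12)
        cutoffs = np.linspace(-1, 1, 21)
        curve = network_size_curve(s, cutoffs)
        assert (np.diff(curve["nodes"]) <= 0).all()
        assert (np.diff(curve["edges"]) <= 0).all()
        one = network_size_curve(s, [0.3]).iloc[0]
        net = threshold_network(s, 0.3)
        assert one["nodes"] == net.n_nodes and one["edges"] == net.n_edges

    def test_edge_list_round_trip(self, rng, tmp_path):
        s = self.make_scores(rng)
        net = threshold_network(s, 0.2)
        path = tmp_path / "edges.tsv"
        write_edge_list(net, path)
        back = read_edge_list(path)
        assert back.method == "pcc" and back.cutoff == 0.2
        assert {frozenset(e[:2]) for e in back.edges()} == {
            frozenset(e[:2]) for e in net.edges()
        }
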