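"""Clique benchmark construction, p/r/F statistics, and cutoff selection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from coexnet import (
    ComplexBenchmark,
    GeneNetwork,
    OrthologMap,
    ScoreMatrix,
    ValidationError,
    ValidationPoint,
    map_complexes_to_orthologs,
    per_complex_curves,
    performance_curve,
    select_cutoff,
    threshold_network,
    validate_network,
)


def net_from_edges(edges, cutoff=0.5, method="pcc"):
    g = nx.Graph()
    g.add_weighted_edges_from((a, b, 1.0) for a, b in edges)
    return GeneNetwork(g, cutoff, method)


class TestOrthologMapping:
    def test_identity_map_preserves_sets(self):
        genes = {"a", "b", "c"}
        m = OrthologMap(tuple((g, g) for g in sorted(genes)))
        bench = map_complexes_to_orthologs({"cplx": genes}, m)
        assert dict(bench.complexes) == {"cplx": frozenset(genes)}

    def test_unmapped_member_dropped(self):
        m = OrthologMap((("a", "A"), ("b", "B")))
        bench = map_complexes_to_orthologs({"cplx": {"a", "b", "c"}}, m)
        assert dict(bench.complexes) == {"cplx": frozenset({"A", "B"})}
        assert len(bench.true_edges) == 1  # C(2,2)

    def test_shrunken_complex_dropped_with_warning(self, caplog):
        m = OrthologMap((("a", "A"), ("x", "X"), ("y", "Y")))
        with caplog.at_level("WARNING"):
            bench = map_complexes_to_orthologs(
                {"tiny": {"a", "b"}, "ok": {"x", "y"}}, m
            )
        assert [n for n, _ in bench.complexes] == ["ok"]
        assert any("tiny" in r.message for r in caplog.records)

    def test_duplicate_source_or_target_rejected(self):
        with pytest.raises(ValidationError):
            OrthologMap((("a", "A"), ("a", "B")))
        with pytest.raises(ValidationError):
            OrthologMap((("a", "A"), ("b", "A")))


class TestValidateNetwork:
    bench = ComplexBenchmark.from_gene_sets({"c1": {"a", "b", "c"}, "c2": {"d", "e"}})

    def test_exact_clique_union_is_perfect(self):
        net = net_from_edges([("a", "b"), ("a", "c"), ("b", "c"), ("d", "e")])
        pt = validate_network(net, self.bench)
        assert (pt.p, pt.r, pt.F) == (1.0, 1.0, 1.0)

    def test_worked_example(self):
        """{a,b,c}/{d,e}: inferred restricted edges ab, ac, ad -> p=2/3, r=2/4, F=4/7."""
        net = net_from_edges([("a", "b"), ("a", "c"), ("a", "d")])
        pt = validate_network(net, self.bench)
        assert pt.p == pytest.approx(2 / 3)
        assert pt.r == pytest.approx(1 / 2)
        assert pt.F == pytest.approx(4 / 7)

    def test_empty_network_convention(self):
        pt = validate_network(net_from_edges([]), self.bench)
        assert (pt.p, pt.r, pt.F) == (0.0, 0.0, 0.0)

    def test_edges_outside_universe_ignored(self):
        base = net_from_edges([("a", "b"), ("a", "c"), ("a", "d")])
        noisy = net_from_edges(
            [("a", "b"), ("a", "c"), ("a", "d"), ("a", "z1"), ("z1", "z2"), ("e", "z3")]
        )
        assert validate_network(noisy, self.bench) == validate_network(base, self.bench)

    def test_harmonic_mean_bounds_on_random_confusions(self, rng):
        """F between min(p, r) and max(p, r) over 1,000 random confusion settings."""
        universe = [f"g{i}" for i in range(8)]
        bench = ComplexBenchmark.from_gene_sets(
            {"c1": set(universe[:5]), "c2": set(universe[5:])}
        )
        pairs = list(itertools.combinations(universe, 2))
        for _ in range(1000):
            chosen = [pairs[i] for i in rng.choice(len(pairs), size=rng.integers(1, 12), replace=False)]
            pt = validate_network(net_from_edges(chosen), bench)
            assert 0.0 <= pt.p <= 1.0 and 0.0 <= pt.r <= 1.0 and 0.0 <= pt.F <= 1.0
            if pt.p > 0 and pt.r > 0:
                assert min(pt.p, pt.r) - 1e-12 <= pt.F <= max(pt.p, pt.r) + 1e-12


class TestPerformanceCurve:
    def test_single_cutoff_consistent_with_validate(self, rng):
        v = rng.uniform(0, 1, size=(6, 6))
        v = (v + v.T) / 2
        s = ScoreMatrix(tuple("abcdef"), v, "mi")
        bench = ComplexBenchmark.from_gene_sets({"c": {"a", "b", "c"}})
        [pt] = performance_curve(s, bench, [0.5])
        assert pt == validate_network(threshold_network(s, 0.5), bench)

    def test_per_complex_curves_share_global_accuracy(self, rng):
        """Per-complex curves judge accuracy over the union universe: a recovered
        cross-complex edge lowers p for every complex, while r stays local."""
        ids = tuple("abcde")
        v = np.zeros((5, 5))
        pairs = {("a", "b"): 0.9, ("a", "c"): 0.9, ("b", "c"): 0.9,
                 ("d", "e"): 0.9, ("a", "d"): 0.8}  # one cross-complex edge
        idx = {g: i for i, g in enumerate(ids)}
        for (x, y), w in pairs.items():
            v[idx[x], idx[y]] = v[idx[y], idx[x]] = w
        s = ScoreMatrix(ids, v, "mi")
        bench = ComplexBenchmark.from_gene_sets({"c1": {"a", "b", "c"}, "c2": {"d", "e"}})
        curves = per_complex_curves(s, bench, [0.5, 0.85])
        # at 0.5 all five edges survive: p = 4/5 globally for both complexes
        assert curves["c1"][0].p == pytest.approx(4 / 5)
        assert curves["c2"][0].p == pytest.approx(4 / 5)
        assert curves["c1"][0].r == 1.0 and curves["c2"][0].r == 1.0
        # at 0.85 the cross edge is gone: perfect recovery of both cliques
        assert curves["c1"][1].F == 1.0 and curves["c2"][1].F == 1.0
        overall, per = select_cutoff(curves)
        assert overall == 0.85

    def test_coverage_non_increasing(self, rng):
        v = rng.uniform(0, 1, size=(10, 10))
        v = (v + v.T) / 2
        s = ScoreMatrix(tuple(f"g{i}" for i in range(10)), v, "mi")
        bench = ComplexBenchmark.from_gene_sets({"c1": {"g0", "g1", "g2", "g3"}, "c2": {"g4", "g5", "g6"}})
        curve = performance_curve(s, bench, np.linspace(0, 1, 20))
        rs = [pt.r for pt in curve]
        assert all(a >= b - 1e-12 for a, b in zip(rs, rs[1:]))


class TestSelectCutoff:
    @staticmethod
    def curve(points):
        return [ValidationPoint(c, p, r, (2 * p * r / (p + r)) if p + r else 0.0) for c, p, r in points]

    def test_paper_rule_instance(self):
        """Per-complex optima at 77/81/99/86 percent confidence -> overall 77."""
        curves = {}
        for name, best in [("rpl", 77.0), ("rps", 81.0), ("core20s", 99.0), ("reg19s", 86.0)]:
            pts = []
            for c in np.arange(60.0, 100.0, 1.0):
                f_peak = 1.0 if c == best else 0.5
                pts.append(ValidationPoint(c, f_peak, f_peak, f_peak))
            curves[name] = pts
        overall, per_complex = select_cutoff(curves)
        assert per_complex == {"rpl": 77.0, "rps": 81.0, "core20s": 99.0, "reg19s": 86.0}
        assert overall == 77.0

    def test_single_complex_returns_its_optimum(self):
        pts = self.curve([(0.1, 0.2, 1.0), (0.2, 0.8, 0.9), (0.3, 1.0, 0.4)])
        overall, per = select_cutoff({"only": pts})
        best = max(pt.F for pt in pts)
        assert per["only"] == min(p.cutoff for p in pts if p.F == best)
        assert overall == per["only"]

    def test_step_curves_recover_known_optima(self):
        """Plateaus: the smallest cutoff attaining the maximal F is chosen."""
        flat_peak = [ValidationPoint(c, 1, 1, f) for c, f in [(1, 0.4), (2, 0.9), (3, 0.9), (4, 0.2)]]
        overall, per = select_cutoff({"a": flat_peak})
        assert per["a"] == 2

    def test_all_zero_curve_is_an_error(self):
        pts = [ValidationPoint(c, 0, 0, 0.0) for c in (1, 2, 3)]
        with pytest.raises(ValidationError, match="uninformative"):
            select_cutoff({"dead": pts})
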