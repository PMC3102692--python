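"""Protein-complex benchmark: clique expansion, accuracy/coverage/F-score, cutoff selection.

A reference protein complex is treated as a clique of "true" coexpression
edges: every within-complex gene pair is a true positive. An inferred network
is scored against the benchmark by

* accuracy ``p`` — the fraction of inferred edges (restricted to pairs with
  both endpoints in the benchmark universe, where truth is defined) that are
  within-complex;
* coverage ``r`` — the fraction of true edges recovered;
* F-score ``F = 2pr / (p + r)`` (0 when p + r = 0).

The operating cutoff is chosen per complex as the smallest cutoff attaining
that complex's maximal F, and overall as the minimum of the per-complex
optima — the most permissive threshold that is optimal for some complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ValidationError
from .inference import GeneNetwork, ScoreMatrix, threshold_network

__all__ = [
    "OrthologMap",
    "ComplexBenchmark",
    "ValidationPoint",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "map_complexes_to_orthologs",
    "validate_network",
    "performance_curve",
    "per_complex_curves",
    "select_cutoff",
]

log = logging.getLogger(__name__)


def _edge(a, b) -> tuple:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class OrthologMap:
    """One-to-one gene mapping between two species.

    No source and no target identifier may appear twice.
    """

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        sources = [s for s, _ in self.pairs]
        targets = [t for _, t in self.pairs]
        for name, ids in (("source", sources), ("target", targets)):
            seen = set()
            for g in ids:
                if g in seen:
                    raise ValidationError(
                        f"ortholog map is not one-to-one: {name} {g!r} appears twice"
                    )
                seen.add(g)

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    @property
    def sources(self) -> frozenset:
        return frozenset(s for s, _ in self.pairs)

    @property
    def targets(self) -> frozenset:
        return frozenset(t for _, t in self.pairs)


@dataclass(frozen=True)
class ComplexBenchmark:
    """Named gene sets whose within-set pairs are the 'true positive' edges."""

    complexes: tuple[tuple[str, frozenset], ...]

    def __post_init__(self):
        if not self.complexes:
            raise ValidationError("benchmark has no complexes")
        for name, members in self.complexes:
            if len(members) < 2:
                raise ValidationError(
                    f"complex {name!r} has {len(members)} member(s); >= 2 required"
                )

    @classmethod
    def from_gene_sets(cls, sets: dict) -> "ComplexBenchmark":
        return cls(tuple((name, frozenset(m)) for name, m in sets.items()))

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for _, members in self.complexes:
            out |= members
        return frozenset(out)

    @property
    def true_edges(self) -> frozenset:
        """All unordered within-complex pairs (an edge is true if the pair co-occurs in ANY complex)."""
        edges: set = set()
        for _, members in self.complexes:
            mem = sorted(members)
            for i, a in enumerate(mem):
                for b in mem[i + 1 :]:
                    edges.add(_edge(a, b))
        return frozenset(edges)


@dataclass(frozen=True)
class ValidationPoint:
    """(cutoff, accuracy p, coverage r, F-score) of one thresholded network."""

    cutoff: float
    p: float
    r: float
    F: float


def read_gmt(path) -> dict[str, set]:
    """Read a GMT-style gene-set file: name, description, tab-separated members."""
    sets: dict[str, set] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT needs name, description and >= 1 member"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column (source, target) TSV into a one-to-one map."""
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            src, tgt = line.split("\t")[:2]
            pairs.append((src, tgt))
    return OrthologMap(tuple(pairs))


def map_complexes_to_orthologs(complexes: dict, orthologs: OrthologMap) -> ComplexBenchmark:
    """Transfer complexes to the target species through one-to-one orthologs.

    Members without a one-to-one ortholog are dropped; complexes shrinking
    below 2 members are dropped with a warning.
    """
    lut = orthologs.as_dict()
    mapped: dict[str, set] = {}
    for name, members in complexes.items():
        converted = {lut[g] for g in members if g in lut}
        if len(converted) < 2:
            log.warning(
                "complex %r dropped: only %d member(s) have one-to-one orthologs",
                name,
                len(converted),
            )
            continue
        mapped[name] = converted
    if not mapped:
        raise ValidationError("no complex retains >= 2 orthologous members")
    return ComplexBenchmark.from_gene_sets(mapped)


def validate_network(
    net: GeneNetwork, bench: ComplexBenchmark, universe=None
) -> ValidationPoint:
    """Accuracy/coverage/F of an inferred network against the clique benchmark.

    Inferred edges are first restricted to pairs with BOTH endpoints in the
    benchmark universe; pairs with an endpoint outside it have no defined
    truth and enter neither numerator nor denominator. Conventions: p = 0
    when no restricted inferred edge exists, F = 0 when p + r = 0.

    ``universe`` overrides the restriction set. This matters when scoring a
    single complex that was benchmarked alongside others: passing the union
    universe keeps cross-complex pairs in the accuracy denominator (they are
    inferred connections that are not correct), whereas the complex's own
    universe would make every restricted pair true by construction.
    """
    universe = bench.universe if universe is None else frozenset(universe)
    true_edges = bench.true_edges
    restricted = {
        _edge(a, b)
        for a, b, _ in net.edges()
        if a in universe and b in universe
    }
    n_correct = len(restricted & true_edges)
    p = n_correct / len(restricted) if restricted else 0.0
    r = n_correct / len(true_edges)
    f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return ValidationPoint(net.cutoff, p, r, f)


def performance_curve(
    s: ScoreMatrix,
    bench: ComplexBenchmark,
    cutoffs,
    absolute: bool = False,
    universe=None,
) -> list[ValidationPoint]:
    """validate_network of threshold_network at each cutoff (coverage is non-increasing)."""
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValidationError("cutoffs must be non-empty")
    return [
        validate_network(threshold_network(s, c, absolute=absolute), bench, universe=universe)
        for c in cutoffs
    ]


def per_complex_curves(
    s: ScoreMatrix, bench: ComplexBenchmark, cutoffs, absolute: bool = False
) -> dict[str, list[ValidationPoint]]:
    """One validation curve per complex over a shared accuracy baseline.

    At each cutoff, accuracy p is global: inferred edges are restricted to
    the full benchmark universe and an edge is correct when its pair
    co-occurs in any complex (cross-complex pairs count as incorrect).
    Coverage r is per complex — the fraction of THAT complex's within pairs
    recovered — and F combines the global p with the complex's r. Feed the
    result to :func:`select_cutoff`.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValidationError("cutoffs must be non-empty")
    universe = bench.universe
    all_true = bench.true_edges
    per_true = {
        name: ComplexBenchmark.from_gene_sets({name: set(members)}).true_edges
        for name, members in bench.complexes
    }
    curves: dict[str, list[ValidationPoint]] = {name: [] for name, _ in bench.complexes}
    for c in cutoffs:
        net = threshold_network(s, c, absolute=absolute)
        restricted = {
            _edge(a, b)
            for a, b, _ in net.edges()
            if a in universe and b in universe
        }
        p = len(restricted & all_true) / len(restricted) if restricted else 0.0
        for name, true_c in per_true.items():
            r = len(restricted & true_c) / len(true_c)
            f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
            curves[name].append(ValidationPoint(float(c), p, r, f))
    return curves


def select_cutoff(curves: dict) -> tuple[float, dict[str, float]]:
    """Benchmark-driven operating cutoff.

    ``curves`` maps complex name → list of :class:`ValidationPoint`. The
    per-complex optimum is the smallest cutoff attaining that complex's
    maximal F; the overall cutoff is the minimum of the per-complex optima.
    Returns ``(overall, per_complex)``.
    """
    if not curves:
        raise ValidationError("no validation curves supplied")
    per_complex: dict[str, float] = {}
    for name, points in curves.items():
        if not points:
            raise ValidationError(f"empty validation curve for {name!r}")
        best_f = max(pt.F for pt in points)
        if best_f == 0.0:
            raise ValidationError(
                f"benchmark uninformative: F-score is 0 at every cutoff for {name!r}"
            )
        per_complex[name] = min(pt.cutoff for pt in points if pt.F == best_f)
    return min(per_complex.values()), per_complex
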