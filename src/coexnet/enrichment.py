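"""Gene-set term enrichment: one-sided hypergeometric tests with BH-FDR control.

Given a test set (a module, a hub group, a bait-neighbour partner set), each
term with at least one test-set hit is scored by the upper hypergeometric
tail — the probability of drawing at least the observed number of annotated
genes when sampling the test set from the universe without replacement —
and p-values are adjusted across tested terms by the Benjamini–Hochberg
procedure. A term is significant when its adjusted value falls below alpha
(0.05 by default).

Terms are tested exactly as given: no ontology-graph propagation to
ancestor terms is performed, so users supplying real GO annotations should
pre-propagate if they want the usual GO semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["AnnotationMap", "enrich_terms"]


@dataclass(frozen=True)
class AnnotationMap:
    """gene → set-of-terms mapping with optional term descriptions.

    Genes with empty term sets are not stored.
    """

    gene_to_terms: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        cleaned = {
            g: frozenset(terms)
            for g, terms in self.gene_to_terms.items()
            if terms
        }
        object.__setattr__(self, "gene_to_terms", cleaned)

    @property
    def terms(self) -> frozenset:
        out: set = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return frozenset(out)

    def genes_of_term(self, term: str) -> frozenset:
        return frozenset(
            g for g, ts in self.gene_to_terms.items() if term in ts
        )

    @classmethod
    def from_tsv(cls, path) -> "AnnotationMap":
        """Read a two-column (gene, term) TSV; repeated genes accumulate terms."""
        mapping: dict[str, set] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                gene, term = line.split("\t")[:2]
                mapping.setdefault(gene, set()).add(term)
        return cls(mapping)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for gene in sorted(self.gene_to_terms):
                for term in sorted(self.gene_to_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")


def enrich_terms(
    test,
    annotations: AnnotationMap,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation analysis of ``test`` within ``universe``.

    Returns a DataFrame sorted by (fdr, p, term) with columns ``term``,
    ``hits``, ``test_size``, ``universe_hits``, ``universe_size``, ``p``,
    ``fdr`` and ``significant`` (fdr < alpha). Only terms with >= 1 test-set
    hit are tested. Empty test set → empty result; test not a subset of the
    universe → error naming offenders.
    """
    test = set(test)
    universe = set(universe)
    stray = test - universe
    if stray:
        raise ValidationError(
            f"test genes outside the universe: {sorted(stray)[:5]}"
        )
    columns = [
        "term", "hits", "test_size", "universe_hits", "universe_size",
        "p", "fdr", "significant",
    ]
    if not test:
        return pd.DataFrame(columns=columns)

    n_universe = len(universe)
    n_test = len(test)
    term_hits: dict[str, int] = {}
    term_universe: dict[str, int] = {}
    for gene, terms in annotations.gene_to_terms.items():
        in_universe = gene in universe
        in_test = gene in test
        if not in_universe:
            continue
        for term in terms:
            term_universe[term] = term_universe.get(term, 0) + 1
            if in_test:
                term_hits[term] = term_hits.get(term, 0) + 1

    rows = []
    for term in sorted(term_hits):
        k = term_hits[term]
        big_k = term_universe[term]
        # P(X >= k), X ~ Hypergeom(N=universe, K=annotated, n=test size)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_test))
        rows.append(
            {
                "term": term,
                "hits": k,
                "test_size": n_test,
                "universe_hits": big_k,
                "universe_size": n_universe,
                "p": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["fdr"] = fdr
    df["significant"] = df["fdr"] < alpha
    return df.sort_values(["fdr", "p", "term"], kind="stable").reset_index(drop=True)
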