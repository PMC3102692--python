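"""Pairwise association scores and thresholded coexpression networks.

Three scorers are provided for a genes × samples matrix:

* Pearson (``pcc``) and Spearman (``scc``) correlation coefficients;
* mutual information (``mi``), by a B-spline generalised histogram estimator
  (fractional bin membership via a B-spline basis) or a plain equal-width-bin
  plug-in estimator;
* the context likelihood of relatedness (``clr``) Z-score, which normalises
  each MI value against the background MI distribution of both genes:

  .. math::

      z_i(j) = \\max\\left(0, \\frac{I(i,j) - \\mu_i}{\\sigma_i}\\right),
      \\qquad Z(i,j) = \\sqrt{z_i(j)^2 + z_j(i)^2}

  where :math:`\\mu_i, \\sigma_i` are the mean and (population) standard
  deviation of gene *i*'s off-diagonal MI values.

Thresholding a score matrix at a cutoff yields an undirected weighted
network whose nodes are the genes incident to at least one surviving edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import rankdata

from .errors import ConfigurationError, ValidationError

__all__ = [
    "ScoreMatrix",
    "CLRBackground",
    "GeneNetwork",
    "correlation_matrix",
    "mutual_information_matrix",
    "clr_z_matrix",
    "threshold_network",
    "network_size_curve",
    "write_edge_list",
    "read_edge_list",
]

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric pairwise gene-association scores.

    ``method`` is one of ``pcc``, ``scc`` (correlation coefficients in
    [-1, 1]), ``mi`` (mutual information, >= 0) or ``clr`` (CLR Z-score,
    >= 0). The diagonal is never used by downstream edge operations.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    method: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.gene_ids)):
            raise ValidationError("score matrix shape does not match gene_ids")
        if not np.allclose(v, v.T, atol=1e-10, equal_nan=True):
            raise ValidationError("score matrix is not symmetric")
        if self.method == "clr" and (v < 0).any():
            raise ValidationError("CLR Z-scores must be >= 0")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.gene_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, method: str) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(df.index), df.to_numpy(dtype=float), method)


@dataclass(frozen=True)
class CLRBackground:
    """Per-gene background statistics of the off-diagonal MI values."""

    gene_ids: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if len(self.mu) != len(self.gene_ids) or len(self.sigma) != len(self.gene_ids):
            raise ValidationError("background length does not match gene count")
        if (np.asarray(self.sigma) < 0).any():
            raise ValidationError("sigma must be >= 0")


@dataclass
class GeneNetwork:
    """Undirected weighted coexpression network at a fixed score cutoff.

    Nodes are exactly the genes incident to >= 1 edge (which is why the node
    count can be smaller than the number of scored genes); every edge weight
    is >= ``cutoff``; there are no self-edges.
    """

    graph: nx.Graph
    cutoff: float
    method: str

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        """Iterate (gene_a, gene_b, weight) triples."""
        for a, b, d in self.graph.edges(data=True):
            yield a, b, d.get("weight", 1.0)


def correlation_matrix(m: pd.DataFrame, method: str = "pcc") -> ScoreMatrix:
    """Pearson (``pcc``) or Spearman (``scc``) correlation between gene rows.

    Constant-valued rows have undefined variance; their correlations are set
    to 0 with a logged warning rather than raising.
    """
    if method not in ("pcc", "scc"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    if m.shape[1] < 3:
        raise ValidationError("correlation needs >= 3 samples")
    x = m.to_numpy(dtype=float)
    if method == "scc":
        x = rankdata(x, axis=1)  # average ranks: SCC = PCC of ranked data
    constant = x.std(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c = np.corrcoef(x)
    c = np.atleast_2d(c)
    if constant.any():
        names = [g for g, is_c in zip(m.index, constant) if is_c]
        log.warning(
            "constant expression rows, correlations set to 0: %s",
            ", ".join(map(str, names[:10])),
        )
        c[constant, :] = 0.0
        c[:, constant] = 0.0
    np.fill_diagonal(c, 1.0)
    c = np.clip(c, -1.0, 1.0)
    c = (c + c.T) / 2.0
    return ScoreMatrix(tuple(m.index), c, method)


def _bspline_weights(x: np.ndarray, bins: int, spline_order: int) -> np.ndarray:
    """Fractional bin memberships of one sample vector.

    Returns an (n_samples, bins) matrix of non-negative weights, each row
    summing to 1 (partition of unity of the open-uniform B-spline basis).
    ``spline_order`` = 1 reduces to hard equal-width binning.
    """
    degree = spline_order - 1
    domain = bins - degree  # basis count = bins over [0, domain]
    knots = np.concatenate(
        [np.zeros(degree), np.arange(0, domain + 1, dtype=float), np.full(degree, domain)]
    )
    lo, hi = x.min(), x.max()
    if hi > lo:
        z = (x - lo) / (hi - lo) * domain
    else:
        z = np.zeros_like(x)
    z = np.clip(z, 0.0, domain)
    w = BSpline.design_matrix(z, knots, degree, extrapolate=False).toarray()
    return w


def _plugin_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information_matrix(
    m: pd.DataFrame,
    estimator: str = "bspline",
    bins: int = 10,
    spline_order: int = 3,
    unit: str = "nats",
    block_size: int = 64,
) -> ScoreMatrix:
    """Pairwise mutual information between gene expression profiles.

    Parameters
    ----------
    estimator:
        ``"bspline"``: generalised histogram with fractional bin membership
        given by an open-uniform B-spline basis of order ``spline_order``
        (order 1 = indicator functions = plain binning). ``"equal_width_bins"``:
        hard equal-width binning per gene, plug-in joint-histogram MI.
    bins:
        Number of (basis) bins per gene, over that gene's observed range.
    unit:
        ``"nats"`` (natural log) or ``"bits"``.
    block_size:
        Row-block size for the tiled pairwise computation; results are
        identical to the naive double loop, memory stays
        O(block_size × genes × bins²).
    """
    if bins < 2:
        raise ConfigurationError("bins must be >= 2")
    n_genes, n_samples = m.shape
    if bins > n_samples:
        raise ConfigurationError(
            f"bins ({bins}) exceeds the sample count ({n_samples})"
        )
    if estimator == "equal_width_bins":
        spline_order = 1
    elif estimator == "bspline":
        if not 1 <= spline_order <= bins:
            raise ConfigurationError("spline_order must be in [1, bins]")
    else:
        raise ConfigurationError(f"unknown MI estimator {estimator!r}")
    if unit not in ("nats", "bits"):
        raise ConfigurationError(f"unknown MI unit {unit!r}")

    x = m.to_numpy(dtype=float)
    # per-gene membership weights, shape (genes, samples, bins)
    w = np.stack([_bspline_weights(x[i], bins, spline_order) for i in range(n_genes)])
    marg = w.mean(axis=1)  # (genes, bins)
    h_marg = np.array([_plugin_entropy(marg[i]) for i in range(n_genes)])

    mi = np.zeros((n_genes, n_genes))
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        # joint histograms: p_ab(i,j) = mean over samples of w_i(s,a) w_j(s,b)
        joint = np.einsum("isa,jsb->ijab", w[start:stop], w) / n_samples
        joint = np.clip(joint, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            h_joint = -np.where(joint > 0, joint * np.log(joint), 0.0).sum(axis=(2, 3))
        mi[start:stop] = h_marg[start:stop, None] + h_marg[None, :] - h_joint
    mi = np.maximum(mi, 0.0)  # estimator floor
    mi = (mi + mi.T) / 2.0
    if unit == "bits":
        mi /= LN2
    return ScoreMatrix(tuple(m.index), mi, "mi")


def clr_z_matrix(mi: ScoreMatrix) -> tuple[ScoreMatrix, CLRBackground]:
    """Context-likelihood-of-relatedness Z-scores from an MI matrix.

    For each gene *i*, μ_i and σ_i are the mean and population standard
    deviation (divide by n) of its off-diagonal MI values; self-MI never
    enters the background. A gene with σ_i = 0 contributes z_i(·) = 0 with a
    logged warning. Negative z-values are clamped to 0 before combining, so
    any MI(i, j) below both backgrounds gives Z(i, j) = 0.
    """
    if mi.method != "mi":
        raise ValidationError(f"clr_z_matrix expects an MI matrix, got {mi.method!r}")
    v = mi.values
    n = len(mi.gene_ids)
    if n < 3:
        raise ValidationError("CLR needs >= 3 genes for a meaningful background")
    off = ~np.eye(n, dtype=bool)
    rows = [v[i][off[i]] for i in range(n)]
    mu = np.array([r.mean() for r in rows])
    sigma = np.array([r.std() for r in rows])  # population sd (ddof=0)
    zero_sigma = sigma == 0
    if zero_sigma.any():
        names = [g for g, z in zip(mi.gene_ids, zero_sigma) if z]
        log.warning(
            "zero background sd, z-scores set to 0 for: %s",
            ", ".join(map(str, names[:10])),
        )
    safe_sigma = np.where(zero_sigma, 1.0, sigma)
    z_dir = (v - mu[:, None]) / safe_sigma[:, None]  # z_i(j) along rows
    z_dir[zero_sigma, :] = 0.0
    z_dir = np.maximum(z_dir, 0.0)
    z = np.sqrt(z_dir**2 + z_dir.T**2)
    np.fill_diagonal(z, 0.0)
    bg = CLRBackground(mi.gene_ids, mu, sigma)
    return ScoreMatrix(mi.gene_ids, z, "clr"), bg


def threshold_network(s: ScoreMatrix, cutoff: float, absolute: bool = False) -> GeneNetwork:
    """Edges = unordered gene pairs with score >= ``cutoff``; nodes = incident genes.

    ``absolute`` thresholds |score| instead of the signed score (only
    meaningful for correlation matrices; the default follows the signed
    coefficient).
    """
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    v = np.abs(s.values) if absolute else s.values
    n = len(s.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    keep = v[iu, ju] >= cutoff
    g = nx.Graph()
    ids = s.gene_ids
    weights = s.values[iu, ju]
    g.add_weighted_edges_from(
        (ids[i], ids[j], float(wt))
        for i, j, wt in zip(iu[keep], ju[keep], weights[keep])
    )
    return GeneNetwork(g, float(cutoff), s.method)


def network_size_curve(s: ScoreMatrix, cutoffs, absolute: bool = False) -> pd.DataFrame:
    """Node/edge counts (and edge-node density) of the thresholded network per cutoff.

    Both counts are non-increasing in the cutoff; the edge-node ratio is 0
    for an empty network.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValidationError("cutoffs must be non-empty")
    v = np.abs(s.values) if absolute else s.values
    n = len(s.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    pair_scores = v[iu, ju]
    rows = []
    for c in cutoffs:
        keep = pair_scores >= c
        n_edges = int(keep.sum())
        incident = np.zeros(n, dtype=bool)
        incident[iu[keep]] = True
        incident[ju[keep]] = True
        n_nodes = int(incident.sum())
        rows.append(
            {
                "cutoff": float(c),
                "nodes": n_nodes,
                "edges": n_edges,
                "density": (n_edges / n_nodes) if n_nodes else 0.0,
            }
        )
    return pd.DataFrame(rows)


def write_edge_list(net: GeneNetwork, path) -> None:
    """Write ``geneA<TAB>geneB<TAB>weight`` with a header comment recording method/cutoff."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method={net.method}\tcutoff={net.cutoff!r}\n")
        for a, b, wt in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{wt:.10g}\n")


def read_edge_list(path) -> GeneNetwork:
    method, cutoff = "unknown", float("nan")
    g = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("method="):
                        method = tok.split("=", 1)[1]
                    elif tok.startswith("cutoff="):
                        cutoff = float(tok.split("=", 1)[1])
                continue
            a, b, wt = line.split("\t")
            g.add_edge(a, b, weight=float(wt))
    return GeneNetwork(g, cutoff, method)
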