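"""End-to-end pipeline: filter → score → (validate) → threshold → modules → hubs → enrichment.

The pipeline sequences the library stages in the order of the underlying
study design and writes every intermediate artifact plus a JSON manifest
(settings, versions, seed, artifact list) into a run directory, so any
summary table is traceable to its inputs. Identical config + seed yields
byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import networkx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .benchmark import (
    ComplexBenchmark,
    per_complex_curves,
    read_gmt,
    read_ortholog_map,
    select_cutoff,
)
from .enrichment import AnnotationMap, enrich_terms
from .errors import ConfigurationError
from .expression import (
    filter_low_information,
    log2_transform,
    read_expression_matrix,
    write_expression_matrix,
)
from .graphops import degree_table
from .hubs import cluster_hub_profiles, hubs_by_module, select_hubs
from .inference import (
    clr_z_matrix,
    correlation_matrix,
    mutual_information_matrix,
    network_size_curve,
    threshold_network,
    write_edge_list,
)
from .mcl import mcl_cluster, module_summary, write_mcl_clusters
from .synthetic import default_design, generate_annotation_map, generate_complex_benchmark, generate_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; loadable from YAML.

    ``expression`` is a TSV path, or ``"synthetic"`` to draw the default
    design with the run's seed (benchmark and annotations then also come
    from the generator unless paths are given).
    """

    expression: str = "synthetic"
    benchmark: str | None = None         # GMT path (target-species ids)
    orthologs: str | None = None         # two-column TSV; applied to benchmark if given
    annotations: str | None = None       # two-column gene->term TSV
    filter_on: str = "raw"               # raw | log2 | none
    log2: bool = True
    method: str = "clr"                  # pcc | scc | clr
    estimator: str = "bspline"
    bins: int = 10
    spline_order: int = 3
    cutoff: float | None = None          # fixed threshold; None => benchmark-driven
    cutoffs: list = field(default_factory=list)  # validation grid (auto if empty)
    mcl_inflation: float = 1.8
    mcl_prune: float = 1e-5
    mcl_tol: float = 1e-6
    mcl_max_iter: int = 200
    hub_k: int = 60
    hub_groups: int = 6
    enrich_alpha: float = 0.05
    module_min_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("pcc", "scc", "clr"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.filter_on not in ("raw", "log2", "none"):
            raise ConfigurationError(f"unknown filter_on {self.filter_on!r}")
        if self.cutoff is None and self.benchmark is None and self.expression != "synthetic":
            raise ConfigurationError(
                "either a fixed cutoff or a benchmark for cutoff selection is required"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(data) - known
        if stray:
            raise ConfigurationError(f"unknown config keys: {sorted(stray)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _default_grid(method: str, scores) -> list[float]:
    if method in ("pcc", "scc"):
        return [round(c, 2) for c in np.arange(0.60, 1.0001, 0.02)]
    hi = float(np.quantile(scores.values[np.triu_indices(len(scores.gene_ids), k=1)], 0.999))
    hi = max(hi, 1.0)
    return [round(c, 3) for c in np.linspace(0.5, hi, 25)]


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage, write artifacts + manifest into ``outdir``, return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "config": cfg.to_dict(),
        "versions": {
            "coexnet": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
        "artifacts": artifacts,
        "stats": {},
    }
    stats = manifest["stats"]

    def save(name: str, path: Path):
        artifacts[name] = path.name

    # --- inputs -----------------------------------------------------------
    truth = None
    benchmark: ComplexBenchmark | None = None
    annotations: AnnotationMap | None = None
    if cfg.expression == "synthetic":
        design = default_design(seed=cfg.seed)
        raw, truth = generate_dataset(design)
        benchmark = generate_complex_benchmark(truth)
        annotations = generate_annotation_map(truth)
    else:
        raw = read_expression_matrix(cfg.expression)
    if cfg.benchmark:
        sets = read_gmt(cfg.benchmark)
        if cfg.orthologs:
            from .benchmark import map_complexes_to_orthologs

            benchmark = map_complexes_to_orthologs(sets, read_ortholog_map(cfg.orthologs))
        else:
            benchmark = ComplexBenchmark.from_gene_sets(sets)
    if cfg.annotations:
        annotations = AnnotationMap.from_tsv(cfg.annotations)
    stats["genes_input"] = int(raw.shape[0])

    # --- filter + transform ----------------------------------------------
    if cfg.filter_on == "raw":
        filtered, report = filter_low_information(raw)
    elif cfg.filter_on == "log2":
        filtered, report = filter_low_information(log2_transform(raw))
    else:
        filtered, report = raw, None
    m = filtered
    # the synthetic generator emits log2-scale values already
    if cfg.log2 and cfg.filter_on != "log2" and cfg.expression != "synthetic":
        m = log2_transform(filtered)
    if report is not None:
        stats["genes_removed"] = len(report.removed)
        stats["genes_kept"] = len(report.kept)
    path = out / "filtered_matrix.tsv"
    write_expression_matrix(m, path)
    save("filtered_matrix", path)

    # --- scores -----------------------------------------------------------
    if cfg.method in ("pcc", "scc"):
        scores = correlation_matrix(m, cfg.method)
    else:
        mi = mutual_information_matrix(
            m, estimator=cfg.estimator, bins=cfg.bins, spline_order=cfg.spline_order
        )
        scores, _ = clr_z_matrix(mi)
    path = out / "score_matrix.tsv"
    scores.to_tsv(path)
    save("score_matrix", path)

    grid = list(cfg.cutoffs) or _default_grid(cfg.method, scores)
    size_curve = network_size_curve(scores, grid)
    path = out / "network_size_curve.tsv"
    size_curve.to_csv(path, sep="\t", index=False)
    save("network_size_curve", path)

    # --- cutoff selection -------------------------------------------------
    cutoff = cfg.cutoff
    if cutoff is None:
        if benchmark is None:
            raise ConfigurationError("no cutoff given and no benchmark to select one")
        curves = per_complex_curves(scores, benchmark, grid)
        rows = [
            {"complex": name, "cutoff": pt.cutoff, "p": pt.p, "r": pt.r, "F": pt.F}
            for name, pts in curves.items()
            for pt in pts
        ]
        path = out / "validation_curves.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        save("validation_curves", path)
        cutoff, per_complex = select_cutoff(curves)
        stats["per_complex_cutoff"] = per_complex
    stats["cutoff"] = float(cutoff)

    # --- network ----------------------------------------------------------
    net = threshold_network(scores, cutoff)
    stats["nodes"] = net.n_nodes
    stats["edges"] = net.n_edges
    path = out / "network_edges.tsv"
    write_edge_list(net, path)
    save("network_edges", path)

    # --- modules ----------------------------------------------------------
    partition = mcl_cluster(
        net,
        inflation=cfg.mcl_inflation,
        prune_threshold=cfg.mcl_prune,
        max_iter=cfg.mcl_max_iter,
        tol=cfg.mcl_tol,
    )
    stats["modules"] = partition.n_modules
    stats["mcl_converged"] = partition.converged
    path = out / "modules.mcl.txt"
    write_mcl_clusters(partition, path)
    save("modules", path)
    summary = module_summary(partition, annotations, None, min_size=cfg.module_min_size)
    path = out / "module_summary.tsv"
    pd.DataFrame([dataclasses.asdict(r) for r in summary]).to_csv(path, sep="\t", index=False)
    save("module_summary", path)

    # --- hubs -------------------------------------------------------------
    degrees = degree_table(net)
    k = min(cfg.hub_k, len(degrees))
    hubs = select_hubs(degrees, k)
    if cfg.hub_groups <= hubs.k:
        hubs = cluster_hub_profiles(hubs, m, n_groups=cfg.hub_groups)
    path = out / "hubs.tsv"
    hubs.to_frame().to_csv(path, sep="\t", index=False)
    save("hubs", path)
    crosstab = hubs_by_module(hubs, partition)
    path = out / "hub_module_crosstab.tsv"
    crosstab.to_csv(path, sep="\t")
    save("hub_module_crosstab", path)
    stats["hubs"] = hubs.k
    stats["hub_min_degree"] = hubs.min_degree

    # --- enrichment -------------------------------------------------------
    if annotations is not None:
        universe = set(m.index)
        enriched = []
        for name, members in partition.modules:
            if len(members) <= cfg.module_min_size:
                continue
            table = enrich_terms(members & universe, annotations, universe, alpha=cfg.enrich_alpha)
            table.insert(0, "module", name)
            enriched.append(table)
        if enriched:
            path = out / "module_enrichment.tsv"
            pd.concat(enriched, ignore_index=True).to_csv(path, sep="\t", index=False)
            save("module_enrichment", path)
            stats["significant_terms"] = int(
                sum(int(t["significant"].sum()) for t in enriched)
            )

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline finished: %d artifacts in %s", len(artifacts), out)
    return manifest
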