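"""Layer-by-layer construction of the hierarchical network.

For the current bottom layer, backward elimination runs once per bottom gene
against the regulator pool; the per-gene final importances are aggregated
into a unified value per TF; the layer's TFs are retained either by fitting
a Gaussian mixture to the unified values and keeping the top-mean component,
or by a fixed count; edges from retained TFs to bottom genes are emitted
under the edge policy. The retained TFs are removed from the pool and become
the new bottom layer (weights reset to 1), and the procedure repeats until
the designated number of layers is reached, the pool is exhausted, or the
selection comes back empty.

A single-pass baseline (one forest fit per bottom gene, no elimination) is
provided for comparison, with per-layer retention counts matched to a
completed backward-elimination run.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backward_elimination import (
    BwerfParams,
    ImportanceTable,
    aggregate_importance,
    backward_eliminate,
    _round_seed,
)
from .data_model import (
    Edge,
    EdgeList,
    ExpressionMatrix,
    HGRN,
    PathwaySet,
    RegulatorPool,
    ValidationError,
)
from .mixture import em_fit, extract_top_component
from .random_forest import ForestParams, fit_forest, forest_importance

logger = logging.getLogger(__name__)


@dataclass
class BuildConfig:
    """Build settings for one network.

    selection : ``"gmm"`` (mixture top component) or ``"fixed"`` with
        ``fixed_count`` TFs per layer.
    edge_policy : ``"quantile"`` links a retained TF t to bottom gene g when
        t's final importance for g reaches the ``edge_quantile`` quantile of
        all TFs' final importance for g; ``"all_positive"`` links every
        strictly positive importance.
    """

    n_layers: int = 1
    bwerf: BwerfParams = field(default_factory=BwerfParams)
    selection: str = "gmm"
    fixed_count: int | None = None
    edge_policy: str = "quantile"
    edge_quantile: float = 0.9
    gmm_components: int = 2
    gmm_restarts: int = 5

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValidationError("n_layers must be >= 1")
        if self.selection not in ("gmm", "fixed"):
            raise ValidationError(f"unknown selection {self.selection!r}")
        if self.selection == "fixed" and (self.fixed_count or 0) < 1:
            raise ValidationError("fixed selection needs fixed_count >= 1")
        if self.edge_policy not in ("quantile", "all_positive"):
            raise ValidationError(f"unknown edge policy {self.edge_policy!r}")
        if self.edge_policy == "quantile" and not 0 < self.edge_quantile < 1:
            raise ValidationError("edge_quantile must be in (0, 1)")


def _select_tfs(unified: pd.Series, cfg: BuildConfig, pool_size: int) -> list[str]:
    """Retain the layer's TFs from their unified importances.

    Falls back to fixed_count = ceil(sqrt(pool)) when the pool is too small
    for the mixture or the fit degenerates, logged loudly.
    """
    if cfg.selection == "fixed":
        k = min(cfg.fixed_count, len(unified))  # type: ignore[arg-type]
        return _top_k(unified, k)
    values = unified.to_numpy()
    if len(unified) < 2 * cfg.gmm_components or np.ptp(values) == 0:
        k = min(math.ceil(math.sqrt(pool_size)), len(unified))
        logger.warning(
            "GMM selection degenerate (N=%d, K=%d); falling back to fixed top-%d",
            len(unified), cfg.gmm_components, k,
        )
        return _top_k(unified, k)
    result = em_fit(
        values,
        K=cfg.gmm_components,
        restarts=cfg.gmm_restarts,
        seed=cfg.bwerf.seed,
    )
    mask = extract_top_component(values, result.model)
    if not mask.any() or mask.all():
        k = min(math.ceil(math.sqrt(pool_size)), len(unified))
        logger.warning(
            "GMM top component selected %d/%d TFs; falling back to fixed top-%d",
            int(mask.sum()), len(unified), k,
        )
        return _top_k(unified, k)
    if mask.sum() > len(unified) / 2:
        logger.warning(
            "GMM retained %d of %d TFs (more than half the pool)",
            int(mask.sum()), len(unified),
        )
    selected = unified.index[mask]
    return _top_k(unified.loc[selected], len(selected))


def _top_k(unified: pd.Series, k: int) -> list[str]:
    """k highest unified importances, ties broken by gene ID."""
    order = sorted(unified.index, key=lambda t: (-unified[t], t))
    return order[:k]


def assign_edges(
    selected: list[str],
    table: ImportanceTable,
    cfg: BuildConfig,
    layer_index: int,
) -> EdgeList:
    """Emit regulator->target edges for the retained TFs under the policy."""
    vals = table.values
    missing = set(selected) - set(vals.index)
    if missing:
        raise ValidationError(f"selected TFs missing from table: {sorted(missing)}")
    edges: list[Edge] = []
    for gene in vals.columns:
        col = vals[gene]
        if cfg.edge_policy == "quantile":
            thr = float(np.quantile(col.to_numpy(), cfg.edge_quantile))
            keep = lambda v: v >= thr  # noqa: E731
        else:
            keep = lambda v: v > 0  # noqa: E731
        for tf in selected:
            v = float(col[tf])
            if keep(v):
                edges.append(Edge(tf, gene, v, layer_index))
    return EdgeList(edges)


def _elimination_tables(
    expr: ExpressionMatrix,
    bottom_ids: list[str],
    pool_ids: list[str],
    params: BwerfParams,
    layer_index: int,
    single_pass: bool,
) -> ImportanceTable:
    """Final importance per (TF, bottom gene); one elimination run (or one
    plain forest fit for the single-pass baseline) per bottom gene."""
    X = expr.submatrix(pool_ids)
    values = pd.DataFrame(index=pool_ids, columns=bottom_ids, dtype=float)
    prov = pd.DataFrame(0, index=pool_ids, columns=bottom_ids, dtype=int)
    for j, gene in enumerate(bottom_ids):
        y = expr.column(gene)
        gene_key = (layer_index - 1) * 100_000 + j
        if single_pass:
            fp = ForestParams(
                ntree=params.forest.ntree,
                mtry=params.forest.mtry,
                bootstrap_size=params.forest.bootstrap_size,
                seed=_round_seed(params.seed, gene_key, 0),
            )
            imp = forest_importance(fit_forest(X, y, fp, feature_ids=pool_ids))
        else:
            final, trace = backward_eliminate(X, pool_ids, y, params, gene_key=gene_key)
            imp = final
            for i, r in enumerate(trace.rounds):
                for tf in r.eliminated:
                    prov.loc[tf, gene] = i
            last_idx = len(trace.rounds) - 1
            remaining = set(final) - {
                tf for r in trace.rounds for tf in r.eliminated
            }
            for tf in remaining:
                prov.loc[tf, gene] = last_idx
        values[gene] = pd.Series(imp)
    return ImportanceTable(values, prov)


def build_layer(
    expr: ExpressionMatrix,
    bottom: PathwaySet,
    pool: RegulatorPool,
    cfg: BuildConfig,
    layer_index: int = 1,
    single_pass: bool = False,
    forced_count: int | None = None,
) -> tuple[list[str], ImportanceTable, EdgeList]:
    """Construct one regulator layer above the current bottom layer."""
    if not pool.gene_ids:
        raise ValidationError("regulator pool is empty")
    overlap = set(pool.gene_ids) & set(bottom.gene_ids)
    if overlap:
        raise ValidationError(f"pool overlaps the bottom layer: {sorted(overlap)}")
    table = _elimination_tables(
        expr, bottom.gene_ids, pool.gene_ids, cfg.bwerf, layer_index, single_pass
    )
    unified = aggregate_importance(table, bottom.weights)
    if forced_count is not None:
        selected = _top_k(unified, min(forced_count, len(unified)))
    else:
        selected = _select_tfs(unified, cfg, len(pool.gene_ids))
    edges = assign_edges(selected, table, cfg, layer_index)
    logger.info(
        "layer %d: retained %d of %d TFs, %d edges",
        layer_index, len(selected), len(pool.gene_ids), len(edges),
    )
    return selected, table, edges


def _build(
    expr: ExpressionMatrix,
    pathway: PathwaySet,
    pool: RegulatorPool,
    cfg: BuildConfig,
    single_pass: bool,
    layer_counts: list[int] | None,
) -> HGRN:
    if set(pathway.gene_ids) & set(pool.gene_ids):
        raise ValidationError("pathway genes and regulator pool must be disjoint")
    layers: list[list[str]] = [list(pathway.gene_ids)]
    all_edges: list[Edge] = []
    bottom = pathway
    remaining = list(pool.gene_ids)
    for layer_index in range(1, cfg.n_layers + 1):
        if not remaining:
            logger.warning("pool exhausted; stopping at %d layers", layer_index - 1)
            break
        forced = None
        if layer_counts is not None:
            if layer_index - 1 >= len(layer_counts):
                break
            forced = layer_counts[layer_index - 1]
        selected, _table, edges = build_layer(
            expr,
            bottom,
            RegulatorPool(remaining),
            cfg,
            layer_index=layer_index,
            single_pass=single_pass,
            forced_count=forced,
        )
        if not selected:
            logger.warning("no significant TFs; stopping at %d layers", layer_index - 1)
            break
        layers.append(selected)
        all_edges.extend(edges)
        chosen = set(selected)
        remaining = [t for t in remaining if t not in chosen]
        bottom = PathwaySet(selected)  # promoted-layer weights reset to 1
    return HGRN(layers, EdgeList(all_edges))


def build_hgrn(
    expr: ExpressionMatrix,
    pathway: PathwaySet,
    pool: RegulatorPool,
    cfg: BuildConfig,
) -> HGRN:
    """Build the full multilayer network by backward elimination."""
    return _build(expr, pathway, pool, cfg, single_pass=False, layer_counts=None)


def build_genie3_baseline(
    expr: ExpressionMatrix,
    pathway: PathwaySet,
    pool: RegulatorPool,
    cfg: BuildConfig,
    layer_counts: list[int] | None = None,
) -> HGRN:
    """Single-pass baseline: one forest fit per bottom gene, no elimination.

    ``layer_counts`` (usually taken from a completed backward-elimination
    build) fixes the number of TFs retained per layer so the two networks
    are size-matched; without it the configured selection rule applies.
    """
    return _build(expr, pathway, pool, cfg, single_pass=True, layer_counts=layer_counts)
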