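"""Synthetic expression generators with known regulatory ground truth.

Three generators are provided:

* ``generate_toys`` — the single-target benchmark: one pathway gene *y*
  driven additively by six true TFs (three weak, mean 1; three strong,
  mean 3; all variance 1) buried among 1000 independent N(0,1) noise TFs,
  with y = X1 + ... + X6 + z and a small Gaussian residual z, n = 100.
* ``add_noise_genes`` — augments an expression matrix with decoy columns,
  either fresh standard-normal profiles or sample-permuted copies of
  existing columns (association destroyed, marginals preserved).
* ``generate_hierarchical`` — a layered regulator cascade for multilayer
  recovery tests: top-layer profiles are independent Gaussians, each
  lower-layer gene is a positive-coefficient linear combination of 1-3
  parents from the layer above plus noise, and independent decoy TFs are
  appended.

All generators are exactly reproducible from their seed. The second
parameter of every normal law is interpreted as a VARIANCE by default
(matching the N(1,1)/N(3,1) reading); pass ``scale_is_sd=True`` to read the
residual scale as a standard deviation instead.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import Edge, EdgeList, ExpressionMatrix, ValidationError


@dataclass
class ToysConfig:
    n_samples: int = 100
    n_weak_true: int = 3
    n_strong_true: int = 3
    n_noise: int = 1000
    weak_mean: float = 1.0
    strong_mean: float = 3.0
    noise_term_scale: float = 0.1
    scale_is_sd: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_weak_true, self.n_strong_true, self.n_noise) < 0:
            raise ValidationError("counts must be nonnegative")
        if self.noise_term_scale <= 0:
            raise ValidationError("noise_term_scale must be positive")


@dataclass
class SyntheticTruth:
    """Generating ground truth: true edges and their coefficients."""

    edges: EdgeList
    coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    layers: list[list[str]] | None = None

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(e.regulator, e.target) for e in self.edges}


def generate_toys(cfg: ToysConfig | None = None) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the single-pathway-gene benchmark data set.

    Returns an expression matrix whose first column is the pathway gene
    ``y`` followed by TFs ``X1 ... X{p}`` (true TFs first), and the truth
    marking the true TFs as regulators of y.
    """
    cfg = cfg or ToysConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = cfg.n_samples
    p = cfg.n_weak_true + cfg.n_strong_true + cfg.n_noise
    X = np.empty((n, p))
    k = 0
    X[:, k : k + cfg.n_weak_true] = rng.normal(cfg.weak_mean, 1.0, (n, cfg.n_weak_true))
    k += cfg.n_weak_true
    X[:, k : k + cfg.n_strong_true] = rng.normal(cfg.strong_mean, 1.0, (n, cfg.n_strong_true))
    k += cfg.n_strong_true
    X[:, k:] = rng.normal(0.0, 1.0, (n, cfg.n_noise))
    sd = cfg.noise_term_scale if cfg.scale_is_sd else np.sqrt(cfg.noise_term_scale)
    z = rng.normal(0.0, sd, n)
    n_true = cfg.n_weak_true + cfg.n_strong_true
    y = X[:, :n_true].sum(axis=1) + z

    tf_ids = [f"X{j + 1}" for j in range(p)]
    gene_ids = ["y"] + tf_ids
    values = np.column_stack([y, X])
    samples = [f"s{i + 1}" for i in range(n)]
    expr = ExpressionMatrix(samples, gene_ids, values)

    true_ids = tf_ids[:n_true]
    edges = EdgeList([Edge(t, "y", 1.0, 1) for t in true_ids])
    coeff = {(t, "y"): 1.0 for t in true_ids}
    truth = SyntheticTruth(edges, coeff, layers=[["y"], true_ids])
    return expr, truth


def add_noise_genes(
    expr: ExpressionMatrix, count: int, mode: str = "permuted", seed: int = 0
) -> ExpressionMatrix:
    """Append ``count`` decoy gene columns to an expression matrix.

    ``gaussian`` appends fresh standard-normal profiles; ``permuted``
    appends sample-permuted copies of randomly chosen existing columns,
    the download-free analogue of drawing real noise genes from the same
    data set.
    """
    if count < 0:
        raise ValidationError("count must be nonnegative")
    if count == 0:
        return expr
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = expr.n_samples
    if mode == "gaussian":
        noise = rng.normal(0.0, 1.0, (n, count))
    elif mode == "permuted":
        if expr.n_genes == 0:
            raise ValidationError("cannot permute columns of an empty matrix")
        src = rng.integers(0, expr.n_genes, size=count)
        noise = np.empty((n, count))
        for j, s in enumerate(src):
            noise[:, j] = expr.values[rng.permutation(n), s]
    else:
        raise ValueError(f"unknown noise mode {mode!r}")
    noise_ids = [f"noise{j + 1}" for j in range(count)]
    return ExpressionMatrix(
        list(expr.sample_ids),
        list(expr.gene_ids) + noise_ids,
        np.column_stack([expr.values, noise]),
    )


def generate_hierarchical(
    layer_sizes: list[int],
    coeff_scale: float = 1.0,
    noise_scale: float = 1.5,
    n_samples: int = 200,
    n_decoys: int = 0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a layered regulator cascade with known edges.

    ``layer_sizes`` is ordered top layer first; the last entry is the bottom
    (pathway) layer. Layer indices in the returned truth follow the network
    convention: bottom layer 0, regulators above it 1, 2, ... Top-layer
    profiles are i.i.d. N(0,1); each gene below draws 1-3 parents uniformly
    from the layer above and is their positive-coefficient (U(0.5, 1.5) x
    ``coeff_scale``) combination plus N(0, noise_scale^2) noise. Decoys are
    independent N(0,1) columns named ``decoy*``.
    """
    if len(layer_sizes) < 2:
        raise ValidationError("need at least 2 layers")
    if min(layer_sizes) < 1:
        raise ValidationError("all layer sizes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_layers = len(layer_sizes)
    # network-layer index of generator layer i (top first): n_layers - 1 - i
    names: list[list[str]] = []
    for i, size in enumerate(layer_sizes):
        net_layer = n_layers - 1 - i
        names.append([f"L{net_layer}G{j + 1}" for j in range(size)])

    profiles: dict[str, np.ndarray] = {}
    edges: list[Edge] = []
    coeff: dict[tuple[str, str], float] = {}
    for g in names[0]:
        profiles[g] = rng.normal(0.0, 1.0, n_samples)
    for i in range(1, n_layers):
        parents_avail = names[i - 1]
        parent_net_layer = n_layers - i
        for g in names[i]:
            k = int(rng.integers(1, min(3, len(parents_avail)) + 1))
            parents = list(rng.choice(parents_avail, size=k, replace=False))
            x = rng.normal(0.0, noise_scale, n_samples)
            for par in parents:
                c = float(rng.uniform(0.5, 1.5)) * coeff_scale
                x = x + c * profiles[par]
                edges.append(Edge(par, g, c, parent_net_layer))
                coeff[(par, g)] = c
            profiles[g] = x

    decoy_ids = [f"decoy{j + 1}" for j in range(n_decoys)]
    for d in decoy_ids:
        profiles[d] = rng.normal(0.0, 1.0, n_samples)

    gene_ids = [g for layer in names for g in layer] + decoy_ids
    values = np.column_stack([profiles[g] for g in gene_ids])
    samples = [f"s{i + 1}" for i in range(n_samples)]
    expr = ExpressionMatrix(samples, gene_ids, values)
    layers_bottom_up = [names[n_layers - 1 - i] for i in range(n_layers)]
    truth = SyntheticTruth(EdgeList(edges), coeff, layers=layers_bottom_up)
    return expr, truth
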