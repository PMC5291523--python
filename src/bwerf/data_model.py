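"""Core containers and text I/O for expression matrices, gene lists and networks.

The canonical in-memory layout of an expression matrix is samples x genes;
files may store either orientation and are transposed on read. All values are
used as-is (inputs are assumed already normalized, e.g. RMA-scale); gene IDs
are case-sensitive opaque strings.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a container invariant."""


class ParseError(ValueError):
    """A file could not be parsed into a valid container."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass
class ExpressionMatrix:
    """Samples x genes numeric expression table.

    Parameters
    ----------
    sample_ids : ordered sample identifiers (n entries, unique)
    gene_ids : ordered gene identifiers (m entries, unique)
    values : (n, m) float array; finite, no missing entries
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.sample_ids) or m != len(self.gene_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if n < 2:
            raise ValidationError("need at least 2 samples")
        _check_unique(self.sample_ids, "sample IDs")
        _check_unique(self.gene_ids, "gene IDs")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        self._index = {g: j for j, g in enumerate(self.gene_ids)}

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def column(self, gene_id: str) -> np.ndarray:
        """Expression profile of one gene across all samples."""
        try:
            return self.values[:, self._index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene ID {gene_id!r}") from None

    def submatrix(self, gene_ids: Sequence[str]) -> np.ndarray:
        """(n, k) array of the requested genes, in the requested order."""
        idx = [self._index[g] for g in gene_ids]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class PathwaySet:
    """Bottom-layer (pathway) genes with optional per-gene weights.

    Weights bias the aggregation of importance values toward particular
    pathway genes; the default weight 1 treats all genes equally.
    """

    gene_ids: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.gene_ids, "pathway gene IDs")
        if not self.gene_ids:
            raise ValidationError("pathway set is empty")
        if self.weights is None:
            self.weights = np.ones(len(self.gene_ids))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.gene_ids),):
            raise ValidationError("weights length does not match gene count")
        if np.any(self.weights < 0):
            raise ValidationError("pathway weights must be nonnegative")
        if not np.any(self.weights > 0):
            raise ValidationError("at least one pathway weight must be positive")


@dataclass
class RegulatorPool:
    """Candidate regulator (TF) gene IDs."""

    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        _check_unique(self.gene_ids, "regulator IDs")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class Edge:
    regulator: str
    target: str
    importance: float
    layer: int


@dataclass
class EdgeList:
    """Directed regulator -> target edges with importance scores.

    ``layer`` of an edge is the layer index of its regulator (layer 0 is the
    pathway bottom layer, so edges always carry layer >= 1).
    """

    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        pairs = set()
        for e in self.edges:
            if e.importance < 0:
                raise ValidationError(f"negative importance on edge {e}")
            if e.layer < 1:
                raise ValidationError(f"edge layer must be >= 1: {e}")
            key = (e.regulator, e.target)
            if key in pairs:
                raise ValidationError(f"duplicate edge {key}")
            pairs.add(key)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def sorted(self) -> list[Edge]:
        """Deterministic order: layer desc, importance desc, then IDs."""
        return sorted(
            self.edges,
            key=lambda e: (-e.layer, -e.importance, e.regulator, e.target),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.regulator, e.target, e.layer, e.importance) for e in self.sorted()
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "layer", "importance"])


@dataclass
class HGRN:
    """Multilayered hierarchical GRN: ordered layers plus adjacent-layer edges.

    ``layers[0]`` is the bottom (pathway) layer; ``layers[i+1]`` regulates
    ``layers[i]``. Every edge must connect a regulator in layer i+1 to a
    target in layer i, and layers are pairwise disjoint.
    """

    layers: list[list[str]]
    edges: EdgeList

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        all_genes: set[str] = set()
        for i, layer in enumerate(self.layers):
            layer_set = set(layer)
            if len(layer_set) != len(layer):
                raise ValidationError(f"duplicate genes within layer {i}")
            if all_genes & layer_set:
                raise ValidationError(
                    f"layer {i} shares genes with a lower layer: "
                    f"{sorted(all_genes & layer_set)}"
                )
            all_genes |= layer_set
        membership = {g: i for i, layer in enumerate(self.layers) for g in layer}
        for e in self.edges:
            if e.regulator not in membership or e.target not in membership:
                raise ValidationError(f"edge {e} references a gene outside the layers")
            if membership[e.regulator] != membership[e.target] + 1:
                raise ValidationError(
                    f"edge {e.regulator}->{e.target} does not span adjacent layers "
                    f"({membership[e.regulator]} -> {membership[e.target]})"
                )
            if e.layer != membership[e.regulator]:
                raise ValidationError(
                    f"edge {e} layer tag {e.layer} != regulator layer "
                    f"{membership[e.regulator]}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV expression table into canonical samples x genes orientation.

    ``orientation`` describes the *file*: ``genes_in_rows`` (one row per gene,
    one column per sample — the common layout of expression matrices) or
    ``samples_in_rows``.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate row or column IDs")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        if raw.isna().any():
            row = df.index[raw.isna().to_numpy().argmax()]
            raise ParseError(f"{path}: empty cell at row {row!r}, column {col!r}")
        try:
            # float() is correctly rounded, so full-precision values survive
            numeric[col] = raw.to_numpy().astype(float)
        except ValueError:
            for row, cell in raw.items():
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at row {row!r}, "
                        f"column {col!r}"
                    ) from None
            raise
    if orientation == "genes_in_rows":
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, orientation: str = "genes_in_rows"
) -> None:
    """Write an expression matrix as TSV at full float precision."""
    df = expr.to_frame()
    if orientation == "genes_in_rows":
        df = df.T
    elif orientation != "samples_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_list(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a gene list: one ID per line, optional tab-separated weight.

    Returns the IDs in file order and a weight vector (missing weights
    default to 1). Negative weights are rejected.
    """
    ids: list[str] = []
    weights: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            ids.append(parts[0].strip())
            if len(parts) > 1 and parts[1].strip():
                try:
                    w = float(parts[1])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric weight {parts[1]!r}"
                    ) from None
                if w < 0:
                    raise ValidationError(f"{path}:{lineno}: negative weight {w}")
                weights.append(w)
            else:
                weights.append(1.0)
    return ids, np.asarray(weights)


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    """Write edges as 4-column TSV sorted by (layer desc, importance desc, IDs)."""
    df = edges.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_edge_list(path: str | Path) -> EdgeList:
    df = pd.read_csv(path, sep="\t")
    expected = ["regulator", "target", "layer", "importance"]
    if list(df.columns) != expected:
        raise ParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return EdgeList(
        [
            Edge(str(r.regulator), str(r.target), float(r.importance), int(r.layer))
            for r in df.itertuples()
        ]
    )


def export_network(hgrn: HGRN, path: str | Path, format: str = "graphml") -> None:
    """Export an HGRN with layer-annotated nodes and importance-annotated edges.

    ``graphml`` goes through networkx; ``dot`` is written directly (the format
    is a plain text digraph listing).
    """
    path = Path(path)
    if format == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for i, layer in enumerate(hgrn.layers):
            for gene in layer:
                g.add_node(gene, layer=i)
        for e in hgrn.edges.sorted():
            g.add_edge(e.regulator, e.target, importance=e.importance, layer=e.layer)
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["digraph hgrn {"]
        for i, layer in enumerate(hgrn.layers):
            for gene in layer:
                lines.append(f'  "{gene}" [layer={i}];')
        for e in hgrn.edges.sorted():
            lines.append(
                f'  "{e.regulator}" -> "{e.target}" [importance={e.importance:.17g}];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
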