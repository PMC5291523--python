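"""Recursive backward elimination of candidate regulators, per pathway gene.

For one pathway gene, a random forest is fitted on the surviving TF pool, TFs
are ranked by importance, and the least important fraction (default 1/10) is
removed; the survivors are re-fitted, and the loop repeats until a single TF
remains. A TF's *final* importance is its importance in the last round in
which it was modeled — the round of its elimination, or, for the last
survivor, the final fitted round. Final importances across pathway genes are
then combined into one unified value per TF by a weighted sum.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ValidationError
from .random_forest import ForestParams, fit_forest, forest_importance

_SEED_MOD = 2**31 - 1


@dataclass
class BwerfParams:
    """elimination_rate in (0,1): fraction of least important TFs dropped per
    round (at least one is always dropped); ``forest`` holds the per-round
    forest settings; ``seed`` is the master seed from which one independent
    stream per (pathway gene, round) is derived."""

    elimination_rate: float = 0.1
    forest: ForestParams = field(default_factory=ForestParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.elimination_rate < 1:
            raise ValidationError("elimination_rate must be in (0, 1)")


@dataclass
class Round:
    survivors: list[str]
    importance: dict[str, float]
    eliminated: list[str]


@dataclass
class EliminationTrace:
    """Per-round audit trail of one backward-elimination run."""

    rounds: list[Round] = field(default_factory=list)

    def check_partition(self, initial_pool: list[str]) -> None:
        """Eliminated sets plus the final survivor must partition the pool."""
        seen: list[str] = []
        for r in self.rounds:
            seen.extend(r.eliminated)
        final = sorted(set(self.rounds[-1].survivors) - set(self.rounds[-1].eliminated))
        if sorted(seen + final) != sorted(initial_pool):
            raise ValidationError("trace does not partition the initial pool")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.rounds):
            removed = set(r.eliminated)
            for tf in r.survivors:
                rows.append((i, tf, r.importance[tf], tf in removed))
        return pd.DataFrame(rows, columns=["round", "tf", "importance", "eliminated"])


@dataclass
class ImportanceTable:
    """Final backward-elimination importance per (TF, pathway gene).

    ``values``: DataFrame indexed by TF, one column per pathway gene.
    ``provenance``: same shape; the round index at which each value was
    recorded (the TF's elimination round, or the final round).
    """

    values: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values < 0).any().any():
            raise ValidationError("importance values must be nonnegative")


def eliminate_round(
    importance: dict[str, float], rate: float
) -> tuple[list[str], list[str]]:
    """Drop the k = max(1, floor(rate * count)) least important TFs.

    Ties at the cutoff are broken by removing the lexicographically larger
    gene ID, so the retained set is deterministic.
    """
    if len(importance) < 2:
        raise ValidationError("need at least 2 TFs to run an elimination round")
    k = max(1, math.floor(rate * len(importance)))
    # ascending importance; among ties the lexicographically larger ID first
    order = sorted(importance, key=lambda t: (importance[t], _RevStr(t)))
    removed = order[:k]
    removed_set = set(removed)
    retained = [t for t in importance if t not in removed_set]
    return retained, removed


class _RevStr(str):
    """Orders strings in reverse, for 'remove the larger ID first' ties."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)


def _round_seed(master: int, gene_key: int, round_idx: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(gene_key, round_idx))
    return int(ss.generate_state(1)[0]) % _SEED_MOD


def backward_eliminate(
    X_tf: np.ndarray,
    tf_ids: list[str],
    y: np.ndarray,
    params: BwerfParams,
    gene_key: int = 0,
) -> tuple[dict[str, float], EliminationTrace]:
    """Run the elimination loop for one pathway gene.

    Parameters
    ----------
    X_tf : (n, p) expression of the candidate TF pool
    tf_ids : the p TF identifiers (columns of X_tf)
    y : length-n expression profile of the pathway gene
    gene_key : stable integer identifying the pathway gene; together with
        the round index it derives the per-round forest seed, so results do
        not depend on the order in which pathway genes are processed.

    Returns the final importance map (one value per initial TF) and the
    complete per-round trace.
    """
    X_tf = np.asarray(X_tf, dtype=float)
    if len(tf_ids) == 0:
        raise ValidationError("empty TF pool")
    if X_tf.shape != (len(y), len(tf_ids)):
        raise ValidationError("X_tf shape does not match tf_ids / y")

    final: dict[str, float] = {}
    trace = EliminationTrace()
    survivors = list(tf_ids)
    col = {t: j for j, t in enumerate(tf_ids)}
    round_idx = 0
    while True:
        fp = ForestParams(
            ntree=params.forest.ntree,
            mtry=params.forest.mtry,
            bootstrap_size=params.forest.bootstrap_size,
            seed=_round_seed(params.seed, gene_key, round_idx),
        )
        X_round = X_tf[:, [col[t] for t in survivors]]
        forest = fit_forest(X_round, y, fp, feature_ids=survivors)
        imp = forest_importance(forest)
        if len(survivors) == 1:
            final[survivors[0]] = imp[survivors[0]]
            trace.rounds.append(Round(list(survivors), imp, []))
            break
        retained, removed = eliminate_round(imp, params.elimination_rate)
        trace.rounds.append(Round(list(survivors), imp, list(removed)))
        for t in removed:
            final[t] = imp[t]
        survivors = retained
        round_idx += 1
        if len(survivors) == 1:
            final[survivors[0]] = imp[survivors[0]]
            break
    return final, trace


def aggregate_importance(
    table: ImportanceTable, weights: np.ndarray | None = None
) -> pd.Series:
    """Unified importance per TF: weighted sum over pathway genes.

    unified(t) = sum_j weight_j * final_importance(t, gene_j); the default
    weight vector is all ones.
    """
    vals = table.values
    if weights is None:
        weights = np.ones(vals.shape[1])
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (vals.shape[1],):
        raise ValidationError(
            f"weight vector length {weights.shape[0]} != "
            f"{vals.shape[1]} pathway genes"
        )
    return vals @ weights
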