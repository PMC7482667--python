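"""Randomized feature-concordance ranking for grade discrimination.

Every protein is scored on its own: a single-input perceptron predicts the
binary group label (0/1) from that protein's abundances, and the mean
squared test error over Monte-Carlo cross-validation splits ranks the
proteins (lower error = better marker).  The whole ranking is repeated
over randomized iterations (20 by default), and a protein's concordance
is the fraction of iterations in which it lands in the top_k.

Within an iteration the MCCV splits and the weight initializations are
shared by all proteins (a fair comparison that depends only on the
iteration seed and the split index), so no protein's error depends on its
identity or on the order in which proteins are evaluated, and identical
feature vectors receive identical errors — ties are then broken
lexicographically by protein ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactome import MCCVConfig
from .mlp import Hyperparams, predict_mlp, train_mlp_rng


def binary_labels(metadata: pd.Series, group_a: str, group_b: str) -> pd.Series:
    """0/1 labels for a two-group contrast (group_a -> 0, group_b -> 1),
    restricted to samples of those groups."""
    mask = metadata.isin([group_a, group_b])
    if not mask.any():
        raise ValueError(f"no samples in groups {group_a!r}/{group_b!r}")
    sub = metadata[mask]
    labels = (sub == group_b).astype(float)
    if labels.nunique() < 2:
        raise ValueError(f"one of the classes {group_a!r}/{group_b!r} is absent")
    return labels


def single_feature_error(
    x: np.ndarray,
    labels: np.ndarray,
    hyper: Hyperparams | None = None,
    mccv: MCCVConfig | None = None,
    seed: int = 0,
) -> float:
    """Mean squared test error of a 1-input MLP predicting the class.

    ``x`` is one protein's values (min-max scaled internally); ``labels``
    are 0/1.  Split membership, weight initialization and epoch shuffles
    all derive from (``seed``, split index) only, so every feature of one
    iteration is scored under identical randomization.
    """
    hyper = hyper or Hyperparams()
    mccv = mccv or MCCVConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and labels must be 1-D and of equal length")
    if np.any(~np.isfinite(x)):
        raise ValueError("x must be complete")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("labels must contain both classes, coded 0 and 1")
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 samples, got {n}")
    span = x.max() - x.min()
    xs = (x - x.min()) / span if span > 0 else np.full_like(x, 0.5)
    X = xs[:, None]
    n_train = mccv.n_train(n)
    errors = np.empty(mccv.n_splits)
    for split in range(mccv.n_splits):
        rng = np.random.default_rng(np.random.SeedSequence([seed, split]))
        train = rng.choice(n, size=n_train, replace=False)
        test = np.setdiff1d(np.arange(n), train)
        weights = train_mlp_rng(X[train], y[train], hyper, rng)
        pred = predict_mlp(weights, X[test])
        errors[split] = float(np.mean((pred - y[test]) ** 2))
    return float(errors.mean())


@dataclass
class IterationRanking:
    """One randomized iteration: proteins ordered best (lowest test error)
    first, with the per-protein mean test error."""

    iteration: int
    proteins: list[str]
    errors: pd.Series

    def __post_init__(self) -> None:
        if list(self.errors.index) != self.proteins:
            raise ValueError("errors must be indexed by the ranked protein order")
        err = self.errors.to_numpy()
        if np.any(np.diff(err) < 0):
            raise ValueError("ranking order inconsistent with errors")

    def rank_of(self, protein: str) -> int:
        """1-based rank."""
        return self.proteins.index(protein) + 1


def iteration_ranking(
    matrix: pd.DataFrame,
    labels: pd.Series,
    hyper: Hyperparams | None = None,
    mccv: MCCVConfig | None = None,
    iteration_seed: int = 0,
    iteration: int = 0,
) -> IterationRanking:
    """Rank every protein by single-feature MCCV error for one iteration.

    ``matrix`` is proteins x samples (complete, samples matching
    ``labels``).  Ties are broken lexicographically by protein ID.
    Reordering the input proteins does not change any protein's error."""
    if list(matrix.columns) != list(labels.index):
        matrix = matrix.loc[:, labels.index]
    y = labels.to_numpy(dtype=float)
    results = {}
    for pid in matrix.index:
        results[pid] = single_feature_error(
            matrix.loc[pid].to_numpy(),
            y,
            hyper=hyper,
            mccv=mccv,
            seed=iteration_seed,
        )
    errors = pd.Series(results, name="error")
    ordered = errors.reset_index().sort_values(["error", "index"]).set_index("index")
    return IterationRanking(
        iteration=iteration,
        proteins=list(ordered.index),
        errors=ordered["error"],
    )


def concordance_rank(rankings: list[IterationRanking], top_k: int = 10) -> pd.DataFrame:
    """Concordance table over iterations.

    concordance(p) = fraction of iterations with rank(p) <= top_k; the
    table also carries the mean rank and is sorted by concordance
    descending, then mean rank ascending, then protein ID."""
    if not rankings:
        raise ValueError("need at least one iteration")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    protein_set = set(rankings[0].proteins)
    for r in rankings[1:]:
        if set(r.proteins) != protein_set:
            raise ValueError("iterations cover inconsistent protein sets")
    proteins = sorted(protein_set)
    ranks = np.array(
        [[r.rank_of(p) for p in proteins] for r in rankings], dtype=float
    )  # iterations x proteins
    concordance = (ranks <= top_k).mean(axis=0)
    table = pd.DataFrame(
        {
            "protein": proteins,
            "concordance": concordance,
            "mean_rank": ranks.mean(axis=0),
        }
    )
    return (
        table.sort_values(
            ["concordance", "mean_rank", "protein"], ascending=[False, True, True]
        )
        .reset_index(drop=True)
    )


def run_concordance(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_iterations: int = 20,
    top_k: int = 10,
    hyper: Hyperparams | None = None,
    mccv: MCCVConfig | None = None,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, list[IterationRanking]]:
    """Run ``n_iterations`` randomized rankings (iteration seeds =
    master_seed + iteration index) and summarize their concordance."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rankings = [
        iteration_ranking(
            matrix,
            labels,
            hyper=hyper,
            mccv=mccv,
            iteration_seed=master_seed + i,
            iteration=i,
        )
        for i in range(n_iterations)
    ]
    return concordance_rank(rankings, top_k=top_k), rankings
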