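"""ANN-weight interactome inference under Monte-Carlo cross-validation.

For every target protein, a perceptron is trained to predict that protein
from all others over many random train subsets; the summed connection
weights from each input to the output, averaged over splits, score the
directed interaction input -> target.  Edges are then filtered on the
Pearson correlation of the underlying abundance pair (|r| >= 0.7 by
default) and exported as a SIF network.

Seeding is per (target index, split index), so the interaction matrix is
reproducible and identical regardless of the order in which targets are
evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Edge
from .mlp import Hyperparams, MLPWeights, summed_weight_scores, train_mlp_rng


@dataclass
class MCCVConfig:
    """Monte-Carlo cross-validation: ``n_splits`` random train subsets of
    ``train_fraction`` of the samples."""

    n_splits: int = 50
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")

    def n_train(self, n_samples: int) -> int:
        n = int(round(self.train_fraction * n_samples))
        return min(max(n, 1), n_samples - 1)


# ---------------------------------------------------------------------------
# Per-protein min-max scaling
# ---------------------------------------------------------------------------

def minmax_scale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Map each protein row linearly to [0, 1]; constant rows map to 0.5.

    Returns (scaled, row minima, row spans); sigmoid outputs require
    bounded targets.  Inverse: original = scaled * span + min (constant
    rows recover their constant since span is 0)."""
    values = matrix.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("min-max scaling requires a complete matrix")
    lo = values.min(axis=1)
    span = values.max(axis=1) - lo
    scaled = np.empty_like(values)
    const = span == 0
    nz = ~const
    scaled[nz] = (values[nz] - lo[nz, None]) / span[nz, None]
    scaled[const] = 0.5
    return (
        pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns),
        pd.Series(lo, index=matrix.index, name="min"),
        pd.Series(span, index=matrix.index, name="span"),
    )


def inverse_minmax(scaled: pd.DataFrame, lo: pd.Series, span: pd.Series) -> pd.DataFrame:
    return scaled.mul(span, axis=0).add(lo, axis=0)


# ---------------------------------------------------------------------------
# MCCV interactome
# ---------------------------------------------------------------------------

def mccv_target_scores(
    data: np.ndarray,
    target_index: int,
    hyper: Hyperparams,
    mccv: MCCVConfig,
) -> np.ndarray:
    """Mean summed-weight score of every input for one target protein.

    ``data`` is samples x proteins, scaled to [0, 1].  Returns a length
    n_proteins vector with 0 at the target's own position (no self-edges).
    Each split's subsampling, weight init and epoch shuffles are seeded
    from (mccv.seed, target_index, split)."""
    n_samples, n_proteins = data.shape
    input_idx = np.array([j for j in range(n_proteins) if j != target_index])
    X_all = data[:, input_idx]
    y_all = data[:, target_index]
    n_train = mccv.n_train(n_samples)
    acc = np.zeros(len(input_idx))
    for split in range(mccv.n_splits):
        rng = np.random.default_rng(
            np.random.SeedSequence([mccv.seed, target_index, split])
        )
        train = rng.choice(n_samples, size=n_train, replace=False)
        weights = train_mlp_rng(X_all[train], y_all[train], hyper, rng)
        acc += summed_weight_scores(weights)
    scores = np.zeros(n_proteins)
    scores[input_idx] = acc / mccv.n_splits
    return scores


def mccv_interactome(
    matrix: pd.DataFrame,
    hyper: Hyperparams | None = None,
    mccv: MCCVConfig | None = None,
    scale: bool = True,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Directed interaction scores score[source, target] for all targets.

    ``matrix`` is proteins x samples and must be complete; with
    ``scale=True`` (default) rows are min-max scaled to [0, 1] first.
    Scores are averaged (not summed) over MCCV splits so ``n_splits`` does
    not change their scale.  The result is independent of the order of
    ``targets``."""
    hyper = hyper or Hyperparams()
    mccv = mccv or MCCVConfig()
    if len(matrix.index) < 3:
        raise ValueError("need at least 3 proteins to mine an interactome")
    n_samples = len(matrix.columns)
    if n_samples < 5:
        raise ValueError(f"need at least 5 samples, got {n_samples}")
    if matrix.isna().to_numpy().any():
        raise ValueError("interactome mining requires a complete matrix")
    if scale:
        scaled, _, _ = minmax_scale(matrix)
    else:
        vals = matrix.to_numpy()
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("matrix must be scaled to [0, 1] when scale=False")
        scaled = matrix
    data = np.ascontiguousarray(scaled.to_numpy().T)  # samples x proteins
    proteins = list(matrix.index)
    scores = pd.DataFrame(
        np.zeros((len(proteins), len(proteins))), index=proteins, columns=proteins
    )
    scores.index.name = "source"
    scores.columns.name = "target"
    target_names = proteins if targets is None else targets
    for name in target_names:
        t = proteins.index(name)
        scores.iloc[:, t] = mccv_target_scores(data, t, hyper, mccv)
    return scores


# ---------------------------------------------------------------------------
# Pearson filtering and export
# ---------------------------------------------------------------------------

def pearson_filter(
    scores: pd.DataFrame,
    matrix: pd.DataFrame,
    r_cut: float = 0.7,
    top_n: int | None = None,
) -> list[Edge]:
    """Keep edge (i, j) iff |Pearson r(i, j)| >= r_cut on the abundance data
    (boundary inclusive); optionally truncate to the top_n by |score|.

    Constant rows have undefined correlation and never pass.  Each edge
    carries its signed ANN score and the Pearson r."""
    if list(scores.index) != list(matrix.index):
        raise ValueError("scores and data matrix must cover the same proteins")
    values = matrix.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("Pearson filtering requires a complete matrix")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    proteins = list(matrix.index)
    edges = []
    for i, src in enumerate(proteins):
        for j, tgt in enumerate(proteins):
            if i == j:
                continue
            rij = r[i, j]
            if np.isfinite(rij) and abs(rij) >= r_cut:
                edges.append(
                    Edge(source=src, target=tgt, score=float(scores.iloc[i, j]), r=float(rij))
                )
    edges.sort(key=lambda e: (-abs(e.score), e.source, e.target))
    if top_n is not None:
        edges = edges[:top_n]
    return edges
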