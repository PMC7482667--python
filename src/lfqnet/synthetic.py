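"""Synthetic LFQ cohorts with planted ground truth.

Generates protein-by-sample abundance matrices, carrier FASTA files and
spectral-library tables whose structure mimics a label-free meningioma
tissue study — log2 abundances on the ~24-36 scale, group sizes of 10 MGI
/ 11 MGII tumors against 4 dura + 4 arachnoid controls, additive log2
group effects for a planted differential set, a planted directed
interaction network that shapes protein co-variation, and
intensity-dependent (left-censored, MNAR) missingness — so every
downstream stage can be tested against a known answer.

The generative model: for each sample, a protein's log2 abundance is its
base level (Uniform over the base range) plus its group effect (if
planted differential) plus the weighted sum of its regulators'
mean-centered values plus Gaussian noise.  Regulators are centered before
propagation so network edges create covariance without shifting group
means, keeping the differential-abundance truth and the network truth
orthogonal.  Propagation follows the topological order of the planted
graph, which must therefore be acyclic.  An entry is masked missing with
probability logistic((midpoint - log2 value) * steepness), so lower
abundances are more often missing.
"""

from __future__ import annotations

import graphlib
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as qio
from . import srm

DEFAULT_GROUP_SIZES = {"DURA": 4, "ARACH": 4, "MGI": 10, "MGII": 11}

#: Filler alphabet for carrier/decoy segments: no K/R (would add tryptic
#: sites) and no P (would suppress an adjacent cleavage).
_FILLER_ALPHABET = "ACDEFGHILMNQSTVW"


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic cohort.

    ``adjacency`` maps (regulator, target) to a signed weight in [-1, 1]
    (magnitudes bounded away from 0); ``de_set`` maps protein ->
    {group: additive log2 effect}; ``missing_params`` is the (midpoint,
    steepness) of the logistic intensity->missingness curve."""

    protein_ids: tuple[str, ...]
    adjacency: dict[tuple[str, str], float]
    de_set: dict[str, dict[str, float]]
    group_sizes: dict[str, int]
    base_log2_range: tuple[float, float] = (24.0, 36.0)
    noise_sd: float = 0.25
    missing_params: tuple[float, float] = (25.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = set(self.protein_ids)
        if len(ids) != len(self.protein_ids):
            raise ValueError("duplicate protein IDs")
        for (src, tgt), w in self.adjacency.items():
            if src == tgt:
                raise ValueError(f"self-edge on {src!r}")
            if src not in ids or tgt not in ids:
                raise ValueError(f"edge ({src!r}, {tgt!r}) references unknown protein")
            if not np.isfinite(w) or not 0 < abs(w) <= 1:
                raise ValueError(f"edge weight |w| must be in (0, 1], got {w}")
        for pid, effects in self.de_set.items():
            if pid not in ids:
                raise ValueError(f"DE protein {pid!r} not in protein set")
            for group, eff in effects.items():
                if group not in self.group_sizes:
                    raise ValueError(f"DE effect for unknown group {group!r}")
                if not np.isfinite(eff):
                    raise ValueError(f"non-finite DE effect for {pid!r}")
        for group, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {group!r} has size {n}; must be >= 1")
        lo, hi = self.base_log2_range
        if not lo < hi:
            raise ValueError("base_log2_range low must be < high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def protein_names(n_proteins: int) -> tuple[str, ...]:
    return tuple(f"P{i:04d}" for i in range(n_proteins))


def generate_planted_network(
    n_proteins: int,
    n_edges: int,
    weight_low: float = 0.4,
    weight_high: float = 0.9,
    seed: int = 0,
    acyclic: bool = False,
) -> dict[tuple[str, str], float]:
    """Sample a planted directed network with signed weights.

    Draws ``n_edges`` distinct directed edges without self-edges; each
    weight magnitude is Uniform[weight_low, weight_high] with random sign.
    With ``acyclic=True`` the edges form a DAG (edges run from lower to
    higher position in a hidden random topological order), which is what
    :func:`simulate_abundance_matrix` requires.  Reproducible under
    ``seed``."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not 0 < weight_low <= weight_high <= 1:
        raise ValueError("need 0 < weight_low <= weight_high <= 1")
    max_edges = (
        n_proteins * (n_proteins - 1) // 2 if acyclic else n_proteins * (n_proteins - 1)
    )
    if not 0 <= n_edges <= max_edges:
        kind = "acyclic" if acyclic else "directed"
        raise ValueError(
            f"n_edges={n_edges} exceeds the maximum of {max_edges} distinct "
            f"{kind} edges on {n_proteins} proteins"
        )
    names = protein_names(n_proteins)
    rng = np.random.default_rng(seed)
    if acyclic:
        # pick unordered pairs, orient along a hidden random topological order
        order = rng.permutation(n_proteins)
        pairs = [(i, j) for i in range(n_proteins) for j in range(i + 1, n_proteins)]
        chosen = rng.choice(len(pairs), size=n_edges, replace=False)
        edges = []
        for c in chosen:
            i, j = pairs[c]
            edges.append((int(order[i]), int(order[j])))
    else:
        pairs = [
            (i, j) for i in range(n_proteins) for j in range(n_proteins) if i != j
        ]
        chosen = rng.choice(len(pairs), size=n_edges, replace=False)
        edges = [pairs[c] for c in chosen]
    magnitudes = rng.uniform(weight_low, weight_high, size=n_edges)
    signs = rng.choice([-1.0, 1.0], size=n_edges)
    return {
        (names[i], names[j]): float(m * s)
        for (i, j), m, s in zip(edges, magnitudes, signs)
    }


def make_truth(
    n_proteins: int = 30,
    n_edges: int = 40,
    group_sizes: dict[str, int] | None = None,
    n_de: int = 5,
    de_effect: float = 1.5,
    de_groups: tuple[str, ...] = ("MGI", "MGII"),
    weight_low: float = 0.4,
    weight_high: float = 0.9,
    base_log2_range: tuple[float, float] = (24.0, 36.0),
    noise_sd: float = 0.25,
    missing_params: tuple[float, float] = (25.0, 1.0),
    seed: int = 0,
) -> SyntheticTruth:
    """Convenience builder: planted DAG + planted differential set.

    Differential proteins receive ``de_effect`` log2 units in each of
    ``de_groups`` (tumor grades, by default) relative to the controls."""
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    adjacency = generate_planted_network(
        n_proteins, n_edges, weight_low, weight_high, seed=seed, acyclic=True
    )
    names = protein_names(n_proteins)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    de_ids = rng.choice(n_proteins, size=min(n_de, n_proteins), replace=False)
    de_set = {
        names[i]: {g: de_effect for g in de_groups if g in group_sizes}
        for i in sorted(int(i) for i in de_ids)
    }
    return SyntheticTruth(
        protein_ids=names,
        adjacency=adjacency,
        de_set=de_set,
        group_sizes=group_sizes,
        base_log2_range=base_log2_range,
        noise_sd=noise_sd,
        missing_params=missing_params,
        seed=seed,
    )


def _topological_order(truth: SyntheticTruth) -> list[str]:
    graph: dict[str, set[str]] = {pid: set() for pid in truth.protein_ids}
    for (src, tgt) in truth.adjacency:
        graph[tgt].add(src)  # predecessors
    try:
        return list(graphlib.TopologicalSorter(graph).static_order())
    except graphlib.CycleError as exc:
        raise ValueError(
            "planted network contains a cycle; propagation is only defined "
            "for DAGs — generate the network with acyclic=True"
        ) from exc


def sample_names(group_sizes: dict[str, int]) -> tuple[list[str], pd.Series]:
    ids, groups = [], []
    for group, n in group_sizes.items():
        for i in range(1, n + 1):
            ids.append(f"{group}_{i:02d}")
            groups.append(group)
    return ids, pd.Series(groups, index=ids, name="group")


def simulate_abundance_matrix(
    truth: SyntheticTruth,
) -> tuple[qio.AbundanceMatrix, pd.Series]:
    """Simulate (linear-scale AbundanceMatrix with MNAR missingness, sample
    metadata) from the planted truth.  Bitwise deterministic under the
    truth's seed."""
    order = _topological_order(truth)
    names = list(truth.protein_ids)
    n = len(names)
    samples, metadata = sample_names(truth.group_sizes)
    m = len(samples)
    rng = np.random.default_rng(truth.seed)
    # fixed draw order: base levels, noise grid, missingness uniforms, counts
    lo, hi = truth.base_log2_range
    base = rng.uniform(lo, hi, size=n)
    noise = (
        rng.normal(0.0, truth.noise_sd, size=(n, m))
        if truth.noise_sd > 0
        else np.zeros((n, m))
    )
    miss_uniforms = rng.uniform(size=(n, m))
    # unique-peptide counts: ~19% single-peptide IDs, the rest 2 + Poisson;
    # planted (differential or networked) proteins are forced to >= 2 so the
    # confidence filter cannot silently remove the ground truth.
    single = rng.uniform(size=n) < 0.19
    extra = rng.poisson(6, size=n)
    counts = np.where(single, 1, 2 + extra)
    planted = set(truth.de_set) | {p for e in truth.adjacency for p in e}
    for i, pid in enumerate(names):
        if pid in planted:
            counts[i] = max(counts[i], 2)

    group_of = metadata.to_numpy()
    idx = {pid: i for i, pid in enumerate(names)}
    log2 = np.empty((n, m))
    incoming: dict[str, list[tuple[str, float]]] = {pid: [] for pid in names}
    for (src, tgt), w in truth.adjacency.items():
        incoming[tgt].append((src, w))
    for pid in order:
        i = idx[pid]
        row = np.full(m, base[i])
        effects = truth.de_set.get(pid, {})
        if effects:
            row = row + np.array([effects.get(g, 0.0) for g in group_of])
        for src, w in sorted(incoming[pid]):
            parent = log2[idx[src]]
            row = row + w * (parent - parent.mean())
        log2[i] = row + noise[i]

    midpoint, steepness = truth.missing_params
    p_missing = expit((midpoint - log2) * steepness)
    values = np.power(2.0, log2)
    values[miss_uniforms < p_missing] = np.nan
    matrix = qio.AbundanceMatrix(
        pd.DataFrame(values, index=names, columns=samples),
        scale="linear",
        unique_peptide_counts=pd.Series(counts, index=names, name="unique_peptides"),
    )
    return matrix, metadata


# ---------------------------------------------------------------------------
# Truth sidecar (JSON)
# ---------------------------------------------------------------------------

def truth_to_json(truth: SyntheticTruth) -> str:
    payload = {
        "protein_ids": list(truth.protein_ids),
        "adjacency": [
            {"source": s, "target": t, "weight": w}
            for (s, t), w in sorted(truth.adjacency.items())
        ],
        "de_set": truth.de_set,
        "group_sizes": truth.group_sizes,
        "base_log2_range": list(truth.base_log2_range),
        "noise_sd": truth.noise_sd,
        "missing_params": list(truth.missing_params),
        "seed": truth.seed,
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def truth_from_json(text: str) -> SyntheticTruth:
    payload = json.loads(text)
    return SyntheticTruth(
        protein_ids=tuple(payload["protein_ids"]),
        adjacency={
            (e["source"], e["target"]): float(e["weight"])
            for e in payload["adjacency"]
        },
        de_set={
            pid: {g: float(v) for g, v in eff.items()}
            for pid, eff in payload["de_set"].items()
        },
        group_sizes={g: int(v) for g, v in payload["group_sizes"].items()},
        base_log2_range=tuple(payload["base_log2_range"]),
        noise_sd=float(payload["noise_sd"]),
        missing_params=tuple(payload["missing_params"]),
        seed=int(payload["seed"]),
    )


# ---------------------------------------------------------------------------
# Carrier FASTA and spectral library
# ---------------------------------------------------------------------------

def _check_embeddable(peptide: str) -> None:
    bad = set(peptide) - qio.AMINO_ACIDS
    if bad:
        raise ValueError(f"peptide {peptide!r}: non-standard residues {sorted(bad)}")
    for i, aa in enumerate(peptide[:-1]):
        if aa in "KR" and peptide[i + 1] != "P":
            raise ValueError(
                f"peptide {peptide!r} has an internal tryptic site at position "
                f"{i + 1}; it could not survive complete digestion"
            )


def _filler(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_FILLER_ALPHABET), size=length))


def embed_peptides_fasta(
    peptides: list[str], n_decoys: int = 0, seed: int = 0
) -> str:
    """Build FASTA text of synthetic carrier proteins.

    Each target peptide appears exactly once inside its own carrier,
    preceded by K or R (unless placed N-terminal) and not followed by P,
    so that tryptic digestion with 0 missed cleavages releases it intact.
    Decoy proteins contain none of the target peptides.  Deterministic
    under ``seed``."""
    for pep in peptides:
        _check_embeddable(pep)
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    descriptions: dict[str, str] = {}
    targets = set(peptides)

    def contains_target(seq: str) -> bool:
        return any(t in seq for t in targets)

    for i, pep in enumerate(peptides):
        for _ in range(100):
            prefix = _filler(rng, int(rng.integers(8, 16))) + str(rng.choice(["K", "R"]))
            suffix = _filler(rng, int(rng.integers(8, 16)))
            if pep.startswith("P"):
                protein = pep + suffix  # N-terminal placement avoids K/R-P suppression
            elif pep[-1] in "KR":
                protein = prefix + pep + suffix
            else:
                protein = prefix + pep  # C-terminal placement: no cleavage needed after
            digest = srm.digest_trypsin(protein)
            if digest.count(pep) == 1 and not any(
                t in frag for frag in digest for t in targets - {pep}
            ):
                break
        else:  # pragma: no cover - generation is essentially always immediate
            raise RuntimeError(f"could not embed peptide {pep!r}")
        pid = f"SYN{i:03d}"
        records.append((pid, protein))
        descriptions[pid] = f"synthetic carrier for {pep}"
    for d in range(n_decoys):
        for _ in range(100):
            n_segments = int(rng.integers(3, 7))
            parts = []
            for _ in range(n_segments):
                parts.append(_filler(rng, int(rng.integers(6, 14))))
                parts.append(str(rng.choice(["K", "R"])))
            decoy = "".join(parts) + _filler(rng, int(rng.integers(4, 10)))
            if not contains_target(decoy):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not generate a target-free decoy")
        pid = f"DEC{d:03d}"
        records.append((pid, decoy))
        descriptions[pid] = "synthetic decoy"
    return qio.write_fasta(records, descriptions)


def simulate_spectral_library(
    peptides: list[str], seed: int = 0, min_y: int = 2
) -> qio.LibraryType:
    """Spectral-library-like table: a log-normal intensity for every y_n
    fragment (n = min_y .. length-1) at charges 1 and 2, per peptide."""
    rng = np.random.default_rng(seed)
    library: qio.LibraryType = {}
    for pep in peptides:
        frags: dict[tuple[str, int], float] = {}
        for n in range(min_y, len(pep)):
            for z in (1, 2):
                frags[(f"y{n}", z)] = float(rng.lognormal(mean=10.0, sigma=1.0))
        library[pep] = frags
    return library
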