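"""Ant-colony seriation of gene expression profiles.

Genes are ordered into a linear "gene sequence" minimizing the total
squared-Euclidean distance between consecutive genes, so co-varying genes sit
adjacent.  The ordering is computed by a canonical ant system: ants build
permutations edge by edge with probability proportional to
``tau^alpha * (1/(d+eps))^beta``, pheromone evaporates at rate ``rho`` each
iteration, and every ant deposits ``q / length`` on the edges it used.

The screen repeats the optimization with independent seeds, counts for each
gene the number of runs in which it lands within a positional window of the
anchor gene, and retains genes reaching a minimum count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from coherence_screen.dataio import DataIOError, ExpressionMatrix

_HEURISTIC_EPS = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric matrix of squared Euclidean distances between gene profiles."""

    gene_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise DataIOError("duplicate gene ids in distance matrix")
        if self.d.shape != (n, n):
            raise DataIOError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise DataIOError("distance matrix contains non-finite values")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise DataIOError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise DataIOError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise DataIOError("distance matrix has negative entries")
        self.d = np.clip((self.d + self.d.T) / 2.0, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class ACOParams:
    """Ant-system hyperparameters.

    ``n_ants=None`` means one ant per gene with a floor of 20 (tiny
    instances need more ants than genes to search reliably).  ``objective``
    selects an open path (default; a linear gene sequence) or a closed cycle.
    """

    n_ants: int | None = None
    alpha: float = 1.0
    beta: float = 2.0
    rho: float = 0.5
    q: float = 100.0
    n_iterations: int = 200
    tau0: float = 1.0
    objective: str = "open_path"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ants is not None and self.n_ants < 1:
            raise ValueError("n_ants must be >= 1")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.q <= 0 or self.tau0 <= 0:
            raise ValueError("q and tau0 must be > 0")
        if self.objective not in ("open_path", "cycle"):
            raise ValueError(f"unknown objective '{self.objective}'")


@dataclass(frozen=True)
class GeneSequence:
    """One gene ordering: a permutation with its total path length."""

    order: tuple[str, ...]
    length: float
    seed: int
    objective: str = "open_path"

    def positions(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.order)}


@dataclass(frozen=True)
class FrequencyTable:
    """Per-gene count of runs in which the gene fell near the anchor."""

    anchor: str
    window: int
    n_runs: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.anchor in self.counts:
            raise ValueError("anchor must not appear in its own frequency table")
        for g, c in self.counts.items():
            if not (0 <= c <= self.n_runs):
                raise ValueError(f"count {c} for '{g}' outside [0, {self.n_runs}]")


def distance_matrix(
    expr: ExpressionMatrix,
    genes: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
    standardize: bool = True,
) -> DistanceMatrix:
    """Squared Euclidean distances between gene profiles over chosen samples.

    With ``standardize`` (default) each gene profile is z-scored across the
    selected samples first, making the distances scale-free: two genes are
    close when their expression *patterns* co-vary, regardless of absolute
    level.  Constant profiles z-score to all zeros.
    """
    genes = list(genes) if genes is not None else list(expr.gene_ids)
    if len(genes) < 3:
        raise DataIOError(f"need >=3 genes for seriation, got {len(genes)}")
    sub = expr.subset(gene_ids=genes, sample_ids=samples)
    if sub.n_samples < 2:
        raise DataIOError("need >=2 samples to compute profile distances")
    x = sub.values
    if standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    # ||xi - xj||^2 via the Gram expansion
    sq = (x * x).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(genes, np.clip(d, 0.0, None))


def path_length(
    order: Sequence[str], dist: DistanceMatrix, objective: str = "open_path"
) -> float:
    """Total distance along consecutive pairs; cycles add the closing edge."""
    _check_permutation(order, dist.gene_ids)
    idx = {g: i for i, g in enumerate(dist.gene_ids)}
    pos = np.array([idx[g] for g in order])
    total = float(dist.d[pos[:-1], pos[1:]].sum())
    if objective == "cycle":
        total += float(dist.d[pos[-1], pos[0]])
    elif objective != "open_path":
        raise ValueError(f"unknown objective '{objective}'")
    return total


def _check_permutation(order: Sequence[str], universe: Sequence[str]) -> None:
    if sorted(order) != sorted(universe):
        raise DataIOError("order is not a permutation of the gene ids")


def aco_order(dist: DistanceMatrix, params: ACOParams | None = None) -> GeneSequence:
    """One ant-system run; returns the best-so-far sequence after all iterations.

    Deterministic for a fixed ``params.seed``.  Construction, tour-length
    evaluation, and pheromone deposits are vectorized over ants.
    """
    params = params if params is not None else ACOParams()
    n = dist.n
    d = dist.d
    rng = np.random.default_rng(params.seed)
    m = params.n_ants if params.n_ants is not None else max(n, 20)
    cycle = params.objective == "cycle"

    eta = 1.0 / (d + _HEURISTIC_EPS)
    np.fill_diagonal(eta, 0.0)
    eta_b = eta**params.beta
    tau = np.full((n, n), params.tau0)
    ar = np.arange(m)

    best_len = np.inf
    best_tour: np.ndarray | None = None
    for _ in range(params.n_iterations):
        tours = np.empty((m, n), dtype=np.intp)
        current = rng.integers(0, n, size=m)
        visited = np.zeros((m, n), dtype=bool)
        visited[ar, current] = True
        tours[:, 0] = current
        for step in range(1, n):
            w = (tau[current] ** params.alpha) * eta_b[current]
            w[visited] = 0.0
            cw = np.cumsum(w, axis=1)
            total = cw[:, -1]
            u = rng.random(m) * total
            nxt = (cw < u[:, None]).sum(axis=1)
            # guard against zero-weight draws (u == 0 or numerically dead rows)
            bad = (w[ar, np.minimum(nxt, n - 1)] <= 0.0) | (nxt >= n)
            if bad.any():
                nxt[bad] = np.argmax(w[bad], axis=1)
            current = nxt
            visited[ar, nxt] = True
            tours[:, step] = nxt
        lengths = d[tours[:, :-1], tours[:, 1:]].sum(axis=1)
        if cycle:
            lengths = lengths + d[tours[:, -1], tours[:, 0]]
        k = int(np.argmin(lengths))
        if lengths[k] < best_len:
            best_len = float(lengths[k])
            best_tour = tours[k].copy()
        # evaporation then symmetric deposit of q/length on each ant's edges
        tau *= 1.0 - params.rho
        heads, tails = tours[:, :-1], tours[:, 1:]
        if cycle:
            heads = np.concatenate([heads, tours[:, -1:]], axis=1)
            tails = np.concatenate([tails, tours[:, :1]], axis=1)
        deposits = np.repeat(params.q / np.maximum(lengths, _HEURISTIC_EPS),
                             heads.shape[1])
        flat = np.bincount(
            (heads * n + tails).ravel(), weights=deposits, minlength=n * n
        ).reshape(n, n)
        tau += flat + flat.T

    assert best_tour is not None
    order = tuple(dist.gene_ids[i] for i in best_tour)
    return GeneSequence(order=order, length=best_len, seed=params.seed,
                        objective=params.objective)


def brute_force_order(dist: DistanceMatrix, objective: str = "open_path") -> GeneSequence:
    """Exhaustive global optimum (test oracle); refuses n > 10.

    Ties are broken lexicographically on the gene-id order tuple.
    """
    n = dist.n
    if n > 10:
        raise DataIOError(f"brute force refuses n={n} > 10 genes")
    best: tuple[float, tuple[str, ...]] | None = None
    for perm in itertools.permutations(range(n)):
        if objective == "open_path" and perm[0] > perm[-1]:
            continue  # reversal symmetry: canonical direction only
        idx = np.array(perm)
        length = float(dist.d[idx[:-1], idx[1:]].sum())
        if objective == "cycle":
            length += float(dist.d[idx[-1], idx[0]])
        order = tuple(dist.gene_ids[i] for i in perm)
        key = (length, order)
        if best is None or key < best:
            best = key
    assert best is not None
    return GeneSequence(order=best[1], length=best[0], seed=-1, objective=objective)


def repeated_ordering(
    dist: DistanceMatrix,
    params: ACOParams | None = None,
    n_runs: int = 10,
) -> list[GeneSequence]:
    """``n_runs`` independent ant-system runs; run r uses seed ``params.seed + r``."""
    params = params if params is not None else ACOParams()
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return [
        aco_order(dist, replace(params, seed=params.seed + r)) for r in range(n_runs)
    ]


def neighbor_frequency(
    seqs: Sequence[GeneSequence], anchor: str, window: int = 5
) -> FrequencyTable:
    """Count, per gene, the runs in which it lies within ``window`` positions
    of the anchor (reversal-invariant by symmetry of the definition)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if not seqs:
        raise ValueError("need at least one sequence")
    counts: dict[str, int] = {}
    for seq in seqs:
        pos = seq.positions()
        if anchor not in pos:
            raise DataIOError(f"anchor '{anchor}' absent from a sequence")
        a = pos[anchor]
        for g, p in pos.items():
            if g == anchor:
                continue
            counts.setdefault(g, 0)
            if abs(p - a) <= window:
                counts[g] += 1
    return FrequencyTable(anchor=anchor, window=window, n_runs=len(seqs),
                          counts=counts)


def screen_candidates(
    freq: FrequencyTable, min_count: int = 5, strict_gt: bool = False
) -> list[str]:
    """Genes reaching the count threshold, sorted by count desc then gene id.

    The default retains genes with ``count >= min_count``; ``strict_gt``
    switches to a strict ``count > min_count`` rule.
    """
    if not (1 <= min_count <= freq.n_runs):
        raise ValueError(f"min_count must lie in [1, {freq.n_runs}]")
    if strict_gt:
        kept = [(g, c) for g, c in freq.counts.items() if c > min_count]
    else:
        kept = [(g, c) for g, c in freq.counts.items() if c >= min_count]
    kept.sort(key=lambda gc: (-gc[1], gc[0]))
    return [g for g, _ in kept]
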