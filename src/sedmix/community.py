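"""Depth-structured community analytics.

Rarefaction to even sequencing depth, Bray-Curtis dissimilarities,
non-metric multidimensional scaling (NMDS), depth correlations of taxon
relative abundances, tracing of "persister" OTUs present at every
sampled depth, and per-sample top-OTU rankings.

The NMDS here is the classic Kruskal formulation: find a k-dimensional
configuration whose inter-point distances are, as nearly as possible, a
monotone function of the observed dissimilarities.  Each iteration fits
disparities by isotonic (pool-adjacent-violators) regression of the
current distances on the dissimilarity ranks and then moves the
configuration by a Guttman transform; the quality measure is Kruskal
stress-1, sqrt(sum (d - dhat)^2 / sum d^2).  Because only the *ranks*
of the dissimilarities enter, the result is invariant under any
strictly increasing transform of the input dissimilarities.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import braycurtis as _braycurtis, pdist, squareform
from scipy.stats import spearmanr

from .profiles import DepthProfile, OtuTable

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "rarefy",
    "bray_curtis",
    "bray_curtis_matrix",
    "nmds",
    "depth_correlation",
    "adjust_pvalues_bh",
    "trace_persisters",
    "top_otus",
    "PersisterSummary",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric pairwise dissimilarities with sample metadata."""

    matrix: np.ndarray
    sample_ids: tuple[str, ...]
    sample_depth: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if len(self.sample_ids) != m.shape[0] or len(self.sample_depth) != m.shape[0]:
            raise ValueError("sample metadata length mismatch")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "sample_depth", np.asarray(self.sample_depth, dtype=float))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS output: centered sample coordinates, final stress, diagnostics."""

    coordinates: np.ndarray   # (n_samples, k), centered
    stress: float
    converged: bool
    seed: int
    n_restarts: int
    best_start: int           # index of the winning start (0 = metric start)
    stress_history: tuple[float, ...] = ()   # per-iteration stress of the winning run


# ---------------------------------------------------------------------------
# rarefaction & dissimilarity


def rarefy(otus: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Randomly subsample every sample to an even sequencing depth.

    Draws exactly ``depth`` reads per sample *without replacement*
    (multivariate hypergeometric); samples with fewer reads are dropped
    with a warning.  ``depth=None`` uses the smallest sample total.
    """
    totals = otus.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep = np.where(totals >= depth)[0]
    if len(keep) < otus.n_samples:
        dropped = [otus.sample_ids[i] for i in range(otus.n_samples) if i not in set(keep)]
        warnings.warn(f"dropping samples below rarefaction depth {depth}: {dropped}",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    sub = otus.select_samples(keep)
    new_counts = np.empty_like(sub.counts)
    for i in range(sub.n_samples):
        new_counts[i] = rng.multivariate_hypergeometric(sub.counts[i], depth)
    return dc_replace(sub, counts=new_counts)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum |x-y| / sum (x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if x.sum() + y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def bray_curtis_matrix(otus: OtuTable) -> DissimilarityMatrix:
    """All pairwise Bray-Curtis dissimilarities between samples."""
    m = squareform(pdist(otus.counts.astype(float), metric="braycurtis"))
    return DissimilarityMatrix(matrix=m, sample_ids=otus.sample_ids,
                               sample_depth=otus.sample_depth)


# ---------------------------------------------------------------------------
# NMDS


def _kruskal_stress(dist: np.ndarray, disp: np.ndarray) -> float:
    denom = np.sum(dist**2)
    if denom <= 0:
        return 0.0
    return math.sqrt(np.sum((dist - disp) ** 2) / denom)


def _nmds_single(diss_flat: np.ndarray, order: np.ndarray, x0: np.ndarray,
                 max_iter: int, tol: float):
    """One NMDS run from configuration x0; returns (coords, stress, converged)."""
    n, k = x0.shape
    x = x0 - x0.mean(axis=0)
    iu = np.triu_indices(n, 1)
    prev_stress = np.inf
    converged = False
    history: list[float] = []
    for _ in range(max_iter):
        dist = pdist(x)
        # disparities: isotonic regression of distances in dissimilarity order
        dhat = np.empty_like(dist)
        dhat[order] = isotonic_regression(dist[order]).x
        stress = _kruskal_stress(dist, dhat)
        history.append(stress)
        if prev_stress - stress < tol:
            converged = True
            break
        prev_stress = stress
        # Guttman transform toward the disparities, rescaled to the current
        # distance norm so the configuration cannot collapse to the origin
        ss = np.sum(dhat**2)
        dhat_g = dhat * math.sqrt(np.sum(dist**2) / ss) if ss > 0 else dhat
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat_g / dist, 0.0)
        b_flat = -ratio
        b = np.zeros((n, n))
        b[iu] = b_flat
        b += b.T
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
        if np.allclose(x, 0):
            break
    dist = pdist(x)
    dhat = np.empty_like(dist)
    dhat[order] = isotonic_regression(dist[order]).x
    final = _kruskal_stress(dist, dhat)
    history.append(final)
    return x, final, converged, tuple(history)


def _metric_start(diss: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) metric scaling of the dissimilarities."""
    n = diss.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (diss**2) @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    coords = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
    return coords


def nmds(d: DissimilarityMatrix, k: int = 2, seed: int = 0, restarts: int = 20,
         max_iter: int = 500, tol: float = 1e-8) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Runs one metric-scaling start plus ``restarts - 1`` random starts
    (seeded, hence bit-reproducible) and returns the lowest-stress
    configuration, centered.  Non-convergence of the best run is
    reported in ``converged``, never silent.
    """
    n = d.n
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} samples for {k}-D NMDS")
    diss_flat = squareform(d.matrix, checks=False)
    order = np.argsort(diss_flat, kind="stable")
    rng = np.random.default_rng(seed)

    best = None
    for start in range(max(restarts, 1)):
        if start == 0:
            x0 = _metric_start(d.matrix, k)
            if np.allclose(x0, 0):
                x0 = rng.standard_normal((n, k))
        else:
            x0 = rng.standard_normal((n, k)) * np.mean(diss_flat)
        x, stress, conv, hist = _nmds_single(diss_flat, order, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, conv, start, hist)
    x, stress, conv, start, hist = best
    return OrdinationResult(coordinates=x - x.mean(axis=0), stress=stress,
                            converged=conv, seed=seed,
                            n_restarts=max(restarts, 1), best_start=start,
                            stress_history=hist)


# ---------------------------------------------------------------------------
# depth correlations


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rho = spearmanr(x, y).statistic
    return float(rho)


def depth_correlation(taxon_rel_abund: DepthProfile, method: str = "spearman",
                      exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman correlation of a taxon's relative abundance with depth.

    Average-rank tie handling; the p-value uses the t-approximation for
    n above ``exact_max_n`` and an exact two-sided permutation
    distribution of rho for small n.  Constant inputs have no defined
    correlation and raise.
    """
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    mask = np.isfinite(taxon_rel_abund.value)
    x = taxon_rel_abund.midpoint[mask]
    y = taxon_rel_abund.value[mask]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rho = _spearman_rho(x, y)
    if n <= exact_max_n:
        # exact permutation null: all n! orderings of y against fixed x,
        # evaluated on ranks (rank of a permuted vector = permuted ranks)
        from scipy.stats import rankdata
        rx = rankdata(x) - (n + 1) / 2.0
        ry = rankdata(y) - (n + 1) / 2.0
        norm = math.sqrt(float(rx @ rx) * float(ry @ ry))
        perms = np.array(list(itertools.permutations(ry)))
        rho_null = perms @ rx / norm
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        p = float(spearmanr(x, y).pvalue)
    return rho, p


def adjust_pvalues_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for families of depth correlations."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# persisters & rankings


@dataclass(frozen=True)
class PersisterSummary:
    """OTUs present at every sampled depth and their footprint at depth."""

    otu_ids: tuple[str, ...]
    n_persisters: int
    read_share_deepest: float       # persisters' share of reads in the deepest sample
    richness_share_deepest: float   # persisters' share of observed OTUs there
    deepest_sample: str


def trace_persisters(otus: OtuTable, min_count: int = 1) -> PersisterSummary:
    """OTUs with count >= min_count in *every* sample.

    The summary reports the persisters' share of sequencing reads and of
    OTU richness in the deepest sample.
    """
    if otus.n_samples < 2:
        raise ValueError("need at least 2 samples to trace persistence")
    present = otus.counts >= min_count
    persister_mask = present.all(axis=0)
    ids = tuple(o for o, m in zip(otus.otu_ids, persister_mask) if m)
    deep = int(np.argmax(otus.sample_depth))
    deep_counts = otus.counts[deep].astype(float)
    total_reads = deep_counts.sum()
    observed = deep_counts > 0
    return PersisterSummary(
        otu_ids=ids,
        n_persisters=int(persister_mask.sum()),
        read_share_deepest=float(deep_counts[persister_mask].sum() / total_reads)
        if total_reads > 0 else float("nan"),
        richness_share_deepest=float(persister_mask[observed].sum() / observed.sum())
        if observed.any() else float("nan"),
        deepest_sample=otus.sample_ids[deep],
    )


def top_otus(otus: OtuTable, n: int, sample: str) -> list[tuple[str, int, float]]:
    """The n most abundant OTUs in one sample: (otu_id, count, rel_abundance).

    Sorted by count descending, ties broken by OTU id (ascending).
    """
    if n > otus.n_otus:
        raise ValueError(f"n={n} exceeds the {otus.n_otus} OTUs in the table")
    s = otus.sample_index(sample)
    counts = otus.counts[s]
    total = counts.sum()
    ranked = sorted(zip(otus.otu_ids, counts), key=lambda t: (-t[1], t[0]))
    return [(otu, int(c), float(c / total) if total > 0 else float("nan"))
            for otu, c in ranked[:n]]
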