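"""CLR co-expression network inference.

Mutual information (in bits) is estimated between all gene pairs either
with the B-spline estimator (fuzzy bin memberships of a chosen spline
order over ``n_bins`` bins, plug-in entropies) or with hard equal-width
binning. The context-likelihood-of-relatedness step converts the MI matrix
into background-corrected Z-scores; gene pairs whose Z-score reaches a
cutoff (or the top-k pairs) become the edges of an unweighted network.

Two background modes are provided: ``per_gene`` (canonical CLR: each
gene's off-diagonal MI distribution is its background, and the pair score
is the root-sum-square of the two rectified per-gene z-scores) and
``global`` (one background over all off-diagonal MI scores).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.special import erfc

from .config import ClrConfig

__all__ = [
    "CoexpressionScores",
    "mutual_information_matrix",
    "clr_zscores",
    "compute_scores",
    "threshold_network",
    "top_k_network",
    "largest_component",
    "zscore_to_pvalue",
    "powerlaw_fit",
]

log = logging.getLogger(__name__)


@dataclass
class CoexpressionScores:
    """Symmetric MI and CLR Z-score matrices over the retained genes."""

    genes: list[str]
    mi: np.ndarray
    z: np.ndarray | None = None
    excluded: list[str] = field(default_factory=list)


def _bspline_weights(x: np.ndarray, n_bins: int, order: int) -> np.ndarray:
    """Fuzzy bin-membership weights: rows sum to 1 (clamped uniform knots)."""
    degree = order - 1
    lo, hi = x.min(), x.max()
    span = hi - lo
    u = (x - lo) / span if span > 0 else np.zeros_like(x)
    knots = np.concatenate(
        [np.zeros(degree), np.linspace(0.0, 1.0, n_bins - degree + 1), np.ones(degree)]
    )
    return BSpline.design_matrix(u, knots, degree).toarray()


def _hard_bin_weights(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    span = hi - lo
    u = (x - lo) / span if span > 0 else np.zeros_like(x)
    idx = np.minimum((u * n_bins).astype(int), n_bins - 1)
    w = np.zeros((x.size, n_bins))
    w[np.arange(x.size), idx] = 1.0
    return w


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information_matrix(
    expr: pd.DataFrame, config: ClrConfig | None = None
) -> CoexpressionScores:
    """Pairwise MI matrix over genes (rows of ``expr``).

    Genes with zero variance across samples carry no information and are
    excluded (logged), so no NaN ever propagates. With
    ``config.rank_transform`` (default) each gene's profile is replaced by
    its ranks before binning, which stabilizes the estimate against
    outliers and monotone distortions.
    """
    config = config or ClrConfig()
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate mutual information")

    values = expr.to_numpy(float)
    variances = values.var(axis=1)
    keep = variances > 0
    excluded = [g for g, k in zip(expr.index, keep) if not k]
    if excluded:
        log.warning("excluding %d constant gene(s): %s", len(excluded), excluded[:5])
    genes = [str(g) for g, k in zip(expr.index, keep) if k]
    values = values[keep]

    if config.rank_transform:
        values = np.apply_along_axis(stats.rankdata, 1, values)

    n_genes, n_samples = values.shape
    weights = np.empty((n_genes, n_samples, config.n_bins))
    for i in range(n_genes):
        if config.mi_estimator == "bspline":
            weights[i] = _bspline_weights(values[i], config.n_bins, config.spline_order)
        else:
            weights[i] = _hard_bin_weights(values[i], config.n_bins)

    marginal_h = np.array([_entropy(w.mean(axis=0)) for w in weights])
    mi = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        # joint histograms of gene i against all later genes in one pass
        joint = np.einsum("sa,jsb->jab", weights[i], weights[i + 1 :]) / n_samples
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(joint > 0, joint * np.log2(joint), 0.0)
        joint_h = -terms.sum(axis=(1, 2))
        mi_row = marginal_h[i] + marginal_h[i + 1 :] - joint_h
        mi[i, i + 1 :] = mi[i + 1 :, i] = np.maximum(mi_row, 0.0)
    return CoexpressionScores(genes=genes, mi=mi, excluded=excluded)


def clr_zscores(scores: CoexpressionScores, config: ClrConfig | None = None) -> np.ndarray:
    """Background-corrected Z-score matrix from the MI matrix.

    ``per_gene``: z_i(j) = max(0, (MI_ij - mean_i) / sd_i) over row i's
    off-diagonal background, and Z_ij = sqrt(z_i(j)^2 + z_j(i)^2).
    ``global``: Z_ij = (MI_ij - mean) / sd over all off-diagonal scores.
    A zero-variance background contributes zeros (logged).
    """
    config = config or ClrConfig()
    mi = scores.mi
    n = mi.shape[0]
    if n < 2:
        z = np.zeros_like(mi)
        scores.z = z
        return z
    off = ~np.eye(n, dtype=bool)

    if config.background_mode == "global":
        background = mi[off]
        mean, sd = background.mean(), background.std()
        if sd <= 1e-12 * max(1.0, abs(mean)):
            log.warning("flat global MI background; all Z set to 0")
            z = np.zeros_like(mi)
        else:
            z = (mi - mean) / sd
        np.fill_diagonal(z, 0.0)
    else:
        means = (mi.sum(axis=1) - np.diag(mi)) / (n - 1)
        sq = (mi**2).sum(axis=1) - np.diag(mi) ** 2
        var = sq / (n - 1) - means**2
        sds = np.sqrt(np.maximum(var, 0.0))
        flat = sds <= 1e-12 * np.maximum(1.0, np.abs(means))
        if flat.any():
            log.warning("%d gene background(s) with zero spread", int(flat.sum()))
        safe_sd = np.where(flat, 1.0, sds)
        zi = np.maximum((mi - means[:, None]) / safe_sd[:, None], 0.0)
        zi[flat, :] = 0.0
        z = np.sqrt(zi**2 + zi.T**2)
        np.fill_diagonal(z, 0.0)
    scores.z = z
    return z


def compute_scores(expr: pd.DataFrame, config: ClrConfig | None = None) -> CoexpressionScores:
    """MI estimation followed by CLR z-scoring."""
    config = config or ClrConfig()
    scores = mutual_information_matrix(expr, config)
    clr_zscores(scores, config)
    return scores


def _require_z(scores: CoexpressionScores) -> np.ndarray:
    if scores.z is None:
        raise ValueError("Z-scores not computed; call clr_zscores first")
    return scores.z


def threshold_network(scores: CoexpressionScores, z_threshold: float) -> nx.Graph:
    """Unweighted network with an edge wherever Z >= z_threshold (inclusive)."""
    z = _require_z(scores)
    net = nx.Graph(provenance=f"z_threshold={z_threshold:g}")
    genes = scores.genes
    ii, jj = np.nonzero(np.triu(z >= z_threshold, k=1))
    for i, j in zip(ii, jj):
        net.add_edge(genes[i], genes[j])
    return net


def top_k_network(scores: CoexpressionScores, k: int) -> nx.Graph:
    """Network of the k highest-Z gene pairs.

    Boundary ties are broken lexicographically on the sorted gene-id pair.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    z = _require_z(scores)
    genes = scores.genes
    n = len(genes)
    n_pairs = n * (n - 1) // 2
    if k > n_pairs:
        raise ValueError(f"k={k} exceeds the {n_pairs} gene pairs")
    ii, jj = np.triu_indices(n, k=1)
    order = sorted(
        range(n_pairs),
        key=lambda p: (-z[ii[p], jj[p]], genes[ii[p]], genes[jj[p]]),
    )
    net = nx.Graph(provenance=f"top_k={k}")
    for p in order[:k]:
        net.add_edge(genes[ii[p]], genes[jj[p]])
    return net


def largest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the smallest lexicographic node id; an empty
    network yields an empty network with a warning.
    """
    if net.number_of_nodes() == 0:
        log.warning("largest_component of an empty network")
        out = nx.Graph(**net.graph)
        return out
    best = min(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    sub = net.subgraph(best).copy()
    sub.graph.update(net.graph)
    return sub


def zscore_to_pvalue(z: float) -> float:
    """One-sided standard-normal tail P(Z >= z) via the complementary error function."""
    return 0.5 * erfc(z / math.sqrt(2.0))


def powerlaw_fit(net: nx.Graph) -> tuple[float, float]:
    """Least-squares power-law fit to the degree distribution.

    Fits a line to (log10 degree, log10 frequency) over degrees with
    nonzero frequency and returns (exponent, R^2) where the fitted
    frequency is proportional to degree^(-exponent). Requires at least
    three distinct degree values.
    """
    degrees = np.array([d for _, d in net.degree()], dtype=float)
    degrees = degrees[degrees > 0]
    values, counts = np.unique(degrees, return_counts=True)
    if values.size < 3:
        raise ValueError("power-law fit undefined: need >= 3 distinct degree values")
    x = np.log10(values)
    y = np.log10(counts)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-slope), float(r2)
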