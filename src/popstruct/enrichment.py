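"""Signed hypergeometric enrichment/depletion scores and heatmap ordering.

For each (risk allele, population) cell the score asks how surprising the
population's risk-allele count is under sampling without replacement from
the pooled global allele pool: with X ~ Hypergeometric(N, K, n) — N total
alleles in the pool, K risk alleles in the pool, n alleles sampled by the
population — the one-tailed p-value is taken in the direction of the
departure from the expectation nK/N, log10-transformed, and signed:
positive for enrichment, negative for depletion, exactly 0 at the
expectation.  The focal population's alleles are part of the pool.

Rows (risk alleles) and columns (populations) are ordered by average-
linkage (UPGMA) agglomerative clustering on the correlation distance
1 - Pearson r between score vectors, the usual heatmap convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .core_io import FreqTable, InputError, SnpPanel, logger

SCORE_CAP = 300.0  # |score| cap; guards against log10 of denormals


def hypergeom_signed_score(x: int, n: int, K: int, N: int) -> float:
    """Signed -log10 hypergeometric tail probability.

    ``x`` risk alleles observed among the population's ``n`` sampled
    alleles; ``K`` risk alleles among the global pool of ``N``.  Positive
    = enriched (x above the expectation nK/N, p = P(X >= x)); negative =
    depleted (p = P(X <= x)); 0 at the expectation or for a globally
    monomorphic locus (K = 0 or K = N).
    """
    if not (0 <= x <= n <= N and 0 <= x <= K <= N):
        raise InputError(f"inconsistent hypergeometric counts x={x}, n={n}, K={K}, N={N}")
    if K == 0 or K == N:
        return 0.0
    expected = n * K / N
    if x == expected:
        return 0.0
    if x > expected:
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        score = -np.log10(max(p, 10.0 ** (-SCORE_CAP)))
        return float(min(score, SCORE_CAP))
    p = float(stats.hypergeom.cdf(x, N, K, n))
    score = np.log10(max(p, 10.0 ** (-SCORE_CAP)))
    return float(max(score, -SCORE_CAP))


@dataclass
class EnrichmentMatrix:
    """Signed scores (loci x populations) with observed/expected/p companions."""

    scores: pd.DataFrame
    observed: pd.DataFrame
    expected: pd.DataFrame
    pvalues: pd.DataFrame
    monomorphic_loci: list[str]


def enrichment_matrix(
    freq_level: FreqTable, freq_all: FreqTable, snp_panel: SnpPanel
) -> EnrichmentMatrix:
    """Per-population risk-allele enrichment against the pooled sample.

    ``freq_all`` must be the single-population pooled table (level
    ``all``) over the same loci; the risk allele of each locus comes from
    the SNP panel.  Cells where a population has no data (2n = 0) are
    NaN.
    """
    if freq_level.loci != freq_all.loci:
        raise InputError("frequency tables cover different loci")
    if len(freq_all.populations) != 1:
        raise InputError("freq_all must have exactly one pooled population")
    pops = freq_level.populations
    loci = freq_level.loci
    scores = np.zeros((len(loci), len(pops)))
    observed = np.zeros_like(scores)
    expected = np.zeros_like(scores)
    pvals = np.ones_like(scores)
    mono: list[str] = []
    for l, loc in enumerate(loci):
        risk = snp_panel[loc].risk_allele
        try:
            a_idx = freq_level.alleles[l].index(risk)
        except ValueError:
            raise InputError(f"risk allele {risk} absent from allele set of {loc}")
        counts = freq_level.counts[l]
        pool = freq_all.counts[l][0]
        N = int(pool.sum())
        K = int(pool[a_idx])
        if K == 0 or K == N:
            mono.append(loc)
        for p_i in range(len(pops)):
            n = int(counts[p_i].sum())
            x = int(counts[p_i, a_idx])
            if n == 0:
                scores[l, p_i] = np.nan
                observed[l, p_i] = np.nan
                expected[l, p_i] = np.nan
                pvals[l, p_i] = np.nan
                continue
            observed[l, p_i] = x
            expected[l, p_i] = n * K / N if N else np.nan
            scores[l, p_i] = hypergeom_signed_score(x, n, K, N)
            if K not in (0, N):
                if x > expected[l, p_i]:
                    pvals[l, p_i] = float(stats.hypergeom.sf(x - 1, N, K, n))
                elif x < expected[l, p_i]:
                    pvals[l, p_i] = float(stats.hypergeom.cdf(x, N, K, n))
                else:
                    pvals[l, p_i] = 1.0
    idx = pd.Index(loci, name="locus")
    cols = pd.Index(pops, name="population")
    return EnrichmentMatrix(
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        observed=pd.DataFrame(observed, index=idx, columns=cols),
        expected=pd.DataFrame(expected, index=idx, columns=cols),
        pvalues=pd.DataFrame(pvals, index=idx, columns=cols),
        monomorphic_loci=mono,
    )


# ---------------------------------------------------------------------------
# Average-correlation clustering for heatmap ordering
# ---------------------------------------------------------------------------

def correlation_distance_matrix(m: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; zero-variance rows -> max (2)."""
    m = np.asarray(m, dtype=float)
    sd = m.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance vector(s); correlation distance set to 2.0", int(zero_var.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(m)
    d = 1.0 - c
    d[np.isnan(d)] = 2.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Dendrogram leaf order, visiting the lighter subtree first.

    "Lighter" = lower merge height; leaves have height 0.  Ties break on
    the smaller node index, so the order is deterministic.
    """
    heights = {i: 0.0 for i in range(n)}
    children = {}
    for k, (a, b, h, _) in enumerate(Z):
        node = n + k
        heights[node] = h
        children[node] = (int(a), int(b))

    def visit(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = (a, b) if (heights[a], a) <= (heights[b], b) else (b, a)
        return visit(first) + visit(second)

    return visit(n + len(Z) - 1)


def cluster_order(matrix: pd.DataFrame, axis: str = "rows") -> tuple[list[str], np.ndarray]:
    """Order heatmap labels by UPGMA on correlation distance.

    ``axis`` is ``"rows"`` or ``"columns"``.  Returns the ordered labels
    and the scipy linkage matrix (the merge tree).  NaN cells are
    replaced by 0 (no departure) for the purpose of ordering only.
    """
    if axis not in ("rows", "columns"):
        raise InputError("axis must be 'rows' or 'columns'")
    m = matrix.to_numpy(dtype=float)
    labels = list(matrix.index if axis == "rows" else matrix.columns)
    if axis == "columns":
        m = m.T
    if len(labels) < 2:
        raise InputError("need at least 2 vectors to cluster")
    m = np.nan_to_num(m, nan=0.0)
    d = correlation_distance_matrix(m)
    Z = linkage(squareform(d, checks=False), method="average")
    order = _leaf_order(Z, len(labels))
    return [labels[i] for i in order], Z


def heatmap_png(
    matrix: pd.DataFrame, path, row_order: list[str] | None = None, col_order: list[str] | None = None
) -> None:
    """Optional diverging-palette heatmap (blue = depleted, red = enriched)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = matrix
    if row_order is not None:
        m = m.loc[row_order]
    if col_order is not None:
        m = m[col_order]
    vmax = np.nanmax(np.abs(m.to_numpy())) or 1.0
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * m.shape[1] + 2), max(4, 0.22 * m.shape[0] + 1)))
    im = ax.imshow(m.to_numpy(), cmap="bwr", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(m.shape[1]), m.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(m.shape[0]), m.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="signed -log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
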