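"""Interpopulation differentiation statistics.

Three complementary measures of how allele/genotype composition differs
among populations:

* **AMOVA FST** — allele-level analysis of molecular variance.  Each
  diploid individual contributes two alleles; the squared distance
  between two alleles is 0 if identical, 1 otherwise.  Sums of squares
  are partitioned into among- and within-population components with the
  unequal-sample-size coefficient n0, and
  FST = sigma2_among / (sigma2_among + sigma2_within).  Multi-locus FST
  sums the variance components over loci (not a mean of per-locus
  ratios, which would be dominated by low-diversity loci).  Significance
  comes from permuting individuals among populations.  A
  Weir–Cockerham theta estimator is available as an alternative since
  different packages label their "FST from AMOVA" differently.

* **Nei's standard genetic distance** D = -ln( J_XY / sqrt(J_X J_Y) )
  with the identity coefficients averaged over loci.

* **Exact G-tests** of genic (allele x population) and genotypic
  (genotype x population) differentiation: the tail probability, under
  fixed margins, of contingency tables whose log-likelihood-ratio
  statistic G = 2 sum O ln(O/E) is at least the observed one.  Small
  tables are enumerated exactly; larger ones use the Markov-chain Monte
  Carlo walk of Raymond & Rousset (Metropolis moves on 2x2 subtables)
  with batch-mean standard errors.  Per-locus p-values combine across
  loci by Fisher's method (chi2 = -2 sum ln p, df = 2L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    FreqTable,
    GenotypeMatrix,
    InputError,
    LabelledSymmetricMatrix,
    MISSING,
    PopulationHierarchy,
    resolve_level,
)
from .diversity import _group_indices

_TIE_TOL = 1e-12  # G values within this of the observed count as >=


# ---------------------------------------------------------------------------
# Nei's standard genetic distance
# ---------------------------------------------------------------------------

def nei_distance(freq_x: dict[str, np.ndarray], freq_y: dict[str, np.ndarray]) -> float:
    """Nei's standard distance between two per-locus frequency tables.

    ``freq_x`` and ``freq_y`` map locus -> frequency vector over the same
    allele ordering.  Loci undefined in either population (NaN) are
    dropped; fully disjoint allele sets give +inf.
    """
    if set(freq_x) != set(freq_y):
        raise InputError("frequency tables cover different loci")
    jxy = jx = jy = 0.0
    used = 0
    for loc, x in freq_x.items():
        y = freq_y[loc]
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise InputError(f"allele sets differ at {loc}")
        if np.isnan(x).any() or np.isnan(y).any():
            continue
        jxy += float(np.dot(x, y))
        jx += float(np.dot(x, x))
        jy += float(np.dot(y, y))
        used += 1
    if used == 0:
        return float("nan")
    jxy /= used
    jx /= used
    jy /= used
    if jxy <= 0:
        return float("inf")
    return -math.log(jxy / math.sqrt(jx * jy))


def nei_distance_matrix(freq: FreqTable) -> LabelledSymmetricMatrix:
    """Pairwise Nei D between all populations of a frequency table."""
    pops = freq.populations
    tables = {p: freq.pop_frequencies(p) for p in pops}
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nei_distance(tables[pops[i]], tables[pops[j]])
            out[i, j] = out[j, i] = d
    return LabelledSymmetricMatrix(pops, out, kind="nei")


# ---------------------------------------------------------------------------
# AMOVA FST
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Variance components and FST from an allele-level AMOVA."""

    fst: float                 # clamped to [0, 1]
    fst_raw: float             # unclamped estimate (may be negative)
    sigma_among: float
    sigma_within: float
    per_locus_fst: dict[str, float]      # clamped; NaN where undefined
    per_locus_fst_raw: dict[str, float]
    p_value: float | None = None
    n_permutations: int = 0
    excluded_populations: list[str] = field(default_factory=list)


def _locus_matrix(slices: list[slice], m: int) -> np.ndarray:
    """0/1 matrix (m alleles-columns x L loci) mapping columns to loci."""
    L = len(slices)
    lm = np.zeros((m, L))
    for l, sl in enumerate(slices):
        lm[sl, l] = 1.0
    return lm


def _components_from_counts(C: np.ndarray, lmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (sigma_among, sigma_within) from population allele counts.

    ``C`` is (P populations x M allele-columns); ``lmat`` maps columns to
    loci.  With 0/1 allele distances, the sum of squared distances among
    n alleles with per-allele counts c is (n^2 - sum c^2)/2, so every
    AMOVA sum of squares reduces to count algebra.  Loci where the
    design degenerates (fewer than two populations observed, or no
    within-population degrees of freedom) come back NaN.
    """
    n_pl = C @ lmat                      # (P, L) alleles sampled per pop/locus
    s_pl = (C * C) @ lmat                # (P, L) sum of squared counts
    tot = C.sum(axis=0)                  # (M,)
    s_tot = (tot * tot) @ lmat           # (L,)
    N = n_pl.sum(axis=0)                 # (L,)
    P_eff = (n_pl > 0).sum(axis=0)       # (L,)

    with np.errstate(invalid="ignore", divide="ignore"):
        ss_total = (N - s_tot / N) / 2.0
        ss_within = np.where(n_pl > 0, (n_pl - s_pl / np.maximum(n_pl, 1)) / 2.0, 0.0).sum(axis=0)
        ss_among = ss_total - ss_within
        df_a = P_eff - 1.0
        df_w = N - P_eff
        ms_w = ss_within / df_w
        n0 = (N - (n_pl * n_pl).sum(axis=0) / N) / df_a
        sigma_a = (ss_among / df_a - ms_w) / n0
        sigma_w = ms_w

    bad = (P_eff < 2) | (df_w < 1) | ~(n0 > 0)
    sigma_a = np.where(bad, np.nan, sigma_a)
    sigma_w = np.where(bad, np.nan, sigma_w)
    return sigma_a, sigma_w


def _multilocus_fst(sigma_a: np.ndarray, sigma_w: np.ndarray) -> float:
    ok = np.isfinite(sigma_a) & np.isfinite(sigma_w)
    if not ok.any():
        return float("nan")
    num = sigma_a[ok].sum()
    den = (sigma_a[ok] + sigma_w[ok]).sum()
    if den == 0:
        return float("nan")
    return float(num / den)


def amova_fst(
    genotypes: GenotypeMatrix,
    partition: list[str] | np.ndarray,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
    estimator: str = "amova",
) -> AmovaResult:
    """Allele-level AMOVA FST over all loci of the matrix.

    ``partition`` assigns a population label to each sample (aligned with
    ``genotypes.samples``).  With ``n_permutations > 0``, individuals are
    permuted among populations (group sizes fixed) and
    p = (1 + #{FST_perm >= FST_obs}) / (n_permutations + 1).
    ``estimator="wc"`` substitutes the multi-locus Weir–Cockerham theta
    for the point estimates (the permutation machinery is AMOVA-only).
    """
    labels = list(partition)
    if len(labels) != genotypes.n_samples:
        raise InputError("partition length must equal number of samples")
    X, slices = genotypes.allele_count_blocks()
    order: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        order.setdefault(lab, []).append(i)
    excluded = [p for p, idx in order.items() if X[idx].sum() == 0]
    for p in excluded:
        del order[p]
    if len(order) < 2:
        raise InputError("need at least two populations with data")
    pops = list(order)
    groups = [np.asarray(order[p]) for p in pops]
    lmat = _locus_matrix(slices, X.shape[1])

    C = np.vstack([X[g].sum(axis=0) for g in groups])
    sigma_a, sigma_w = _components_from_counts(C, lmat)

    if estimator == "wc":
        fst_raw = weir_cockerham_fst(genotypes, labels)
    elif estimator == "amova":
        fst_raw = _multilocus_fst(sigma_a, sigma_w)
    else:
        raise InputError(f"unknown estimator {estimator!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        per_raw = sigma_a / (sigma_a + sigma_w)
    per_locus_raw = {loc: float(per_raw[l]) for l, loc in enumerate(genotypes.loci)}
    per_locus = {loc: _clamp01(v) for loc, v in per_locus_raw.items()}

    p_value = None
    if n_permutations > 0:
        if rng is None:
            rng = np.random.default_rng()
        amova_obs = _multilocus_fst(sigma_a, sigma_w)
        keep = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        starts = np.cumsum([0] + sizes[:-1])
        Xk = X[keep]
        nk = len(keep)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(nk)
            Cp = np.add.reduceat(Xk[perm], starts, axis=0)
            sa, sw = _components_from_counts(Cp, lmat)
            f = _multilocus_fst(sa, sw)
            if np.isnan(f) or f >= amova_obs - _TIE_TOL:
                hits += 1
        p_value = (1 + hits) / (n_permutations + 1)

    return AmovaResult(
        fst=_clamp01(fst_raw),
        fst_raw=float(fst_raw),
        sigma_among=float(np.nansum(sigma_a)),
        sigma_within=float(np.nansum(sigma_w)),
        per_locus_fst=per_locus,
        per_locus_fst_raw=per_locus_raw,
        p_value=p_value,
        n_permutations=n_permutations,
        excluded_populations=excluded,
    )


def _clamp01(v: float) -> float:
    if np.isnan(v):
        return float("nan")
    return float(min(1.0, max(0.0, v)))


def weir_cockerham_fst(genotypes: GenotypeMatrix, partition: list[str]) -> float:
    """Multi-locus Weir–Cockerham theta (sum of a over sum of a+b+c)."""
    labels = np.asarray(partition)
    pops = list(dict.fromkeys(labels))
    num = den = 0.0
    for l in range(genotypes.n_loci):
        pair = genotypes.codes[:, l, :]
        valid = pair[:, 0] != MISSING
        k = len(genotypes.alleles[l])
        for a in range(k):
            dos = (pair == a).sum(axis=1).astype(float)
            n_i, p_i, h_i = [], [], []
            for pop in pops:
                sel = (labels == pop) & valid
                n = int(sel.sum())
                if n == 0:
                    continue
                n_i.append(n)
                p_i.append(dos[sel].sum() / (2 * n))
                h_i.append((dos[sel] == 1).mean())
            r = len(n_i)
            if r < 2:
                continue
            n_i = np.asarray(n_i, dtype=float)
            p_i = np.asarray(p_i)
            h_i = np.asarray(h_i)
            nsum = n_i.sum()
            nbar = nsum / r
            if nbar <= 1:
                continue
            nc = (nsum - (n_i**2).sum() / nsum) / (r - 1)
            if nc <= 0:
                continue
            pbar = (n_i * p_i).sum() / nsum
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / nsum
            inner = pbar * (1 - pbar) - (r - 1) / r * s2
            a_c = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
            b_c = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
            c_c = hbar / 2
            num += a_c
            den += a_c + b_c + c_c
    if den == 0:
        return float("nan")
    return float(num / den)


def pairwise_fst(
    genotypes: GenotypeMatrix,
    hierarchy: PopulationHierarchy,
    level: str = "superpopulation",
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
    estimator: str = "amova",
) -> tuple[LabelledSymmetricMatrix, pd.DataFrame]:
    """AMOVA FST for every population pair at a hierarchy level.

    Returns the clamped FST matrix and a symmetric permutation-p matrix
    (NaN diagonal; None p-values where permutations were disabled).
    """
    level = resolve_level(level)
    groups = _group_indices(genotypes, hierarchy, level)
    pops = list(groups)
    if len(pops) < 2:
        raise InputError(f"need >= 2 populations at level {level}")
    n = len(pops)
    fst = np.zeros((n, n))
    pmat = np.full((n, n), np.nan)
    if rng is None:
        rng = np.random.default_rng()
    for i in range(n):
        for j in range(i + 1, n):
            idx = np.concatenate([groups[pops[i]], groups[pops[j]]])
            sub = genotypes.subset_samples([genotypes.samples[x] for x in idx])
            labels = [pops[i]] * len(groups[pops[i]]) + [pops[j]] * len(groups[pops[j]])
            res = amova_fst(sub, labels, n_permutations=n_permutations, rng=rng, estimator=estimator)
            fst[i, j] = fst[j, i] = res.fst
            if res.p_value is not None:
                pmat[i, j] = pmat[j, i] = res.p_value
    return (
        LabelledSymmetricMatrix(pops, fst, kind="fst"),
        pd.DataFrame(pmat, index=pops, columns=pops),
    )


def per_locus_global_fst(
    genotypes: GenotypeMatrix,
    hierarchy: PopulationHierarchy,
    level: str = "superpopulation",
) -> dict[str, float]:
    """Single-locus AMOVA FST across all populations at a level.

    NaN marks loci monomorphic across the pooled sample (no variance to
    partition).
    """
    level = resolve_level(level)
    labels = hierarchy.labels(level, genotypes.samples)
    res = amova_fst(genotypes, labels, n_permutations=0)
    return res.per_locus_fst


# ---------------------------------------------------------------------------
# Exact G-test (Markov chain / enumeration)
# ---------------------------------------------------------------------------

@dataclass
class McParams:
    """Markov-chain settings for the exact test (GENEPOP-style defaults)."""

    dememorization: int = 10_000
    batches: int = 100
    iterations_per_batch: int = 5_000
    enumeration_total: int = 30      # exact enumeration below this table total
    enumeration_2x2_total: int = 500  # ... or for 2x2 tables below this total


@dataclass
class ExactTestResult:
    """Per-locus and Fisher-combined exact-test p-values."""

    mode: str                     # genic | genotypic
    per_locus_p: dict[str, float]
    per_locus_se: dict[str, float]
    chi2: float
    df: int
    p: float


def _g_stat_terms(t: np.ndarray) -> float:
    """sum over cells of O ln O (the table-dependent part of G)."""
    x = t[t > 0].astype(float)
    return float((x * np.log(x)).sum())


def g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic G = 2 sum O ln(O/E), E from margins."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    s = _g_stat_terms(t)
    sr = float((rows[rows > 0] * np.log(rows[rows > 0])).sum())
    sc = float((cols[cols > 0] * np.log(cols[cols > 0])).sum())
    return 2.0 * (s - sr - sc + n * math.log(n))


def _enumerate_tail(table: np.ndarray) -> float:
    """Exact P(G >= G_obs) by enumerating all tables with the same margins.

    Table probabilities follow the multivariate hypergeometric
    distribution prod r_i! prod c_j! / (N! prod t_ij!).
    """
    t = np.asarray(table, dtype=np.int64)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    s_obs = _g_stat_terms(t)
    lg = math.lgamma
    log_const = sum(lg(r + 1) for r in rows) + sum(lg(c + 1) for c in cols) - lg(n + 1)

    tail = 0.0
    R, C = t.shape
    cur = np.zeros((R, C), dtype=np.int64)

    def fill_row(i: int, rem_cols: np.ndarray) -> None:
        nonlocal tail
        if i == R - 1:
            cur[i] = rem_cols
            cand = cur
            s = _g_stat_terms(cand)
            if s >= s_obs - _TIE_TOL:
                log_p = log_const - sum(lg(v + 1) for v in cand.ravel())
                tail += math.exp(log_p)
            return
        target = int(rows[i])

        def fill_cell(j: int, left: int, rem: np.ndarray) -> None:
            if j == C - 1:
                if left <= rem[j]:
                    cur[i, j] = left
                    rem2 = rem.copy()
                    rem2[j] -= left
                    fill_row(i + 1, rem2)
                return
            for v in range(min(left, int(rem[j])) + 1):
                cur[i, j] = v
                rem2 = rem.copy()
                rem2[j] -= v
                fill_cell(j + 1, left - v, rem2)

        fill_cell(0, target, rem_cols)

    fill_row(0, cols.copy())
    return min(tail, 1.0)


def _enumerate_tail_2x2(table: np.ndarray) -> float:
    """Fast exact tail for 2x2 tables (single free cell)."""
    t = np.asarray(table, dtype=np.int64)
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    s_obs = _g_stat_terms(t)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    tail = 0.0
    for a in range(lo, hi + 1):
        cand = np.array([[a, r1 - a], [c1 - a, r2 - (c1 - a)]])
        if _g_stat_terms(cand) >= s_obs - _TIE_TOL:
            tail += math.exp(
                math.lgamma(r1 + 1) + math.lgamma(r2 + 1) + math.lgamma(c1 + 1)
                + math.lgamma(n - c1 + 1) - math.lgamma(n + 1)
                - sum(math.lgamma(v + 1) for v in cand.ravel())
            )
    return min(tail, 1.0)


def exact_g_test(
    count_table: np.ndarray,
    mc_params: McParams | None = None,
    rng: np.random.Generator | None = None,
    force_mc: bool = False,
) -> tuple[float, float]:
    """Exact test of homogeneity ordered by the G statistic.

    Returns ``(p, se)``: the probability, under fixed margins, of tables
    with G at least the observed value (ties within 1e-12 counted), and
    the Monte-Carlo standard error (0 for exact enumeration).  A table
    with fewer than two informative rows or columns is undefined:
    ``(nan, nan)``.  ``force_mc`` disables the enumeration shortcut (used
    to validate the chain against enumeration).
    """
    if mc_params is None:
        mc_params = McParams()
    t = np.asarray(count_table, dtype=np.int64)
    if (t < 0).any():
        raise InputError("negative counts in contingency table")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return (float("nan"), float("nan"))
    total = int(t.sum())

    if not force_mc:
        if t.shape == (2, 2) and total <= mc_params.enumeration_2x2_total:
            return (_enumerate_tail_2x2(t), 0.0)
        if total <= mc_params.enumeration_total:
            return (_enumerate_tail(t), 0.0)

    if rng is None:
        rng = np.random.default_rng()
    return _mc_tail(t, mc_params, rng)


def _mc_tail(t: np.ndarray, mc: McParams, rng: np.random.Generator) -> tuple[float, float]:
    """Metropolis walk on tables with fixed margins (2x2 subtable moves)."""
    R, C = t.shape
    state = t.astype(np.int64).copy()
    s_obs = _g_stat_terms(t)
    # relative tie tolerance: distinct tables differ in G by far more than
    # this, and it absorbs drift of the incrementally updated statistic
    thresh = s_obs - 1e-9 * max(1.0, abs(s_obs))
    s_cur = s_obs

    xlogx = np.zeros(int(t.sum()) + 2)
    xs = np.arange(1, len(xlogx))
    xlogx[1:] = xs * np.log(xs)

    n_steps = mc.dememorization + mc.batches * mc.iterations_per_batch
    # pre-draw randomness in blocks to keep the Python loop lean
    rows_a = rng.integers(0, R, size=n_steps)
    rows_b = (rows_a + rng.integers(1, R, size=n_steps)) % R
    cols_a = rng.integers(0, C, size=n_steps)
    cols_b = (cols_a + rng.integers(1, C, size=n_steps)) % C
    direction = rng.integers(0, 2, size=n_steps) * 2 - 1
    unif = rng.random(n_steps)

    st = state  # local alias
    batch_hits = np.zeros(mc.batches)
    hits = 0
    batch = -1
    in_batch = 0
    for step in range(n_steps):
        i1, i2, j1, j2 = rows_a[step], rows_b[step], cols_a[step], cols_b[step]
        d = direction[step]
        a, b, c, e = st[i1, j1], st[i1, j2], st[i2, j1], st[i2, j2]
        na, nb, nc_, ne = a + d, b - d, c - d, e + d
        if na >= 0 and nb >= 0 and nc_ >= 0 and ne >= 0:
            # hypergeometric ratio pi(t')/pi(t) = prod old!/new!
            if d == 1:
                ratio = (b * c) / ((a + 1) * (e + 1))
            else:
                ratio = (a * e) / ((b + 1) * (c + 1))
            if ratio >= 1.0 or unif[step] < ratio:
                s_cur += (
                    xlogx[na] - xlogx[a] + xlogx[nb] - xlogx[b]
                    + xlogx[nc_] - xlogx[c] + xlogx[ne] - xlogx[e]
                )
                st[i1, j1], st[i1, j2], st[i2, j1], st[i2, j2] = na, nb, nc_, ne
        if step >= mc.dememorization:
            if in_batch == 0:
                batch += 1
                hits = 0
                s_cur = _g_stat_terms(st)  # reset accumulated rounding error
            if s_cur >= thresh:
                hits += 1
            in_batch += 1
            if in_batch == mc.iterations_per_batch:
                batch_hits[batch] = hits / mc.iterations_per_batch
                in_batch = 0
    p = float(batch_hits.mean())
    se = float(batch_hits.std(ddof=1) / math.sqrt(mc.batches)) if mc.batches > 1 else float("nan")
    return (p, se)


# ---------------------------------------------------------------------------
# Per-locus contingency tables and the combined test
# ---------------------------------------------------------------------------

def genic_table(gm: GenotypeMatrix, labels: list[str], locus: int) -> np.ndarray:
    """Allele x population count table for one locus (2n per individual)."""
    pops = list(dict.fromkeys(labels))
    lab = np.asarray(labels)
    k = len(gm.alleles[locus])
    out = np.zeros((k, len(pops)), dtype=np.int64)
    pair = gm.codes[:, locus, :]
    for j, pop in enumerate(pops):
        sel = (lab == pop) & (pair[:, 0] != MISSING)
        for col in range(2):
            vals, cnts = np.unique(pair[sel, col], return_counts=True)
            out[vals.astype(int), j] += cnts
    return out


def genotypic_table(gm: GenotypeMatrix, labels: list[str], locus: int) -> np.ndarray:
    """Unordered-genotype x population count table for one locus."""
    pops = list(dict.fromkeys(labels))
    lab = np.asarray(labels)
    k = len(gm.alleles[locus])
    cats = [(a, b) for a in range(k) for b in range(a, k)]
    cat_index = {c: i for i, c in enumerate(cats)}
    out = np.zeros((len(cats), len(pops)), dtype=np.int64)
    pair = gm.codes[:, locus, :]
    for j, pop in enumerate(pops):
        sel = (lab == pop) & (pair[:, 0] != MISSING)
        for a, b in pair[sel]:
            out[cat_index[(int(a), int(b))], j] += 1
    return out


def combine_fisher(per_locus_p: list[float]) -> tuple[float, int, float]:
    """Fisher combination: chi2 = -2 sum ln p_i, df = 2L.

    NaN entries (uninformative loci) are excluded; any exact zero gives
    (+inf, df, 0).
    """
    ps = [p for p in per_locus_p if not (isinstance(p, float) and math.isnan(p))]
    if not ps:
        raise InputError("no defined per-locus p-values to combine")
    df = 2 * len(ps)
    if any(p == 0 for p in ps):
        return (float("inf"), df, 0.0)
    chi2 = -2.0 * sum(math.log(p) for p in ps)
    return (chi2, df, float(stats.chi2.sf(chi2, df)))


def differentiation_exact_tests(
    gm: GenotypeMatrix,
    hierarchy: PopulationHierarchy,
    level: str = "superpopulation",
    mode: str = "genic",
    mc_params: McParams | None = None,
    rng: np.random.Generator | None = None,
) -> ExactTestResult:
    """Per-locus exact G-tests across all populations, Fisher-combined."""
    if mode not in ("genic", "genotypic"):
        raise InputError(f"mode must be genic or genotypic, got {mode!r}")
    level = resolve_level(level)
    labels = hierarchy.labels(level, gm.samples)
    builder = genic_table if mode == "genic" else genotypic_table
    per_p: dict[str, float] = {}
    per_se: dict[str, float] = {}
    for l, loc in enumerate(gm.loci):
        table = builder(gm, labels, l)
        p, se = exact_g_test(table, mc_params=mc_params, rng=rng)
        per_p[loc] = p
        per_se[loc] = se
    chi2, df, p = combine_fisher(list(per_p.values()))
    return ExactTestResult(mode=mode, per_locus_p=per_p, per_locus_se=per_se, chi2=chi2, df=df, p=p)
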