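"""Within-population diversity statistics.

Per (population, locus): allele frequencies, observed heterozygosity
Ho (fraction of heterozygous individuals), Nei's gene diversity
He = 1 - sum p_a^2, Shannon's information index I = -sum p_a ln p_a,
Wright's fixation index F = 1 - Ho/He, and a chi-square goodness-of-fit
test of Hardy-Weinberg genotype proportions with df = k(k-1)/2 for k
observed alleles.  The multi-locus summary reports mean +/- SE over loci
per population, dropping loci where a statistic is undefined (2n = 0,
or He = 0 for F) and reporting how many were dropped.

He is the plain Nei (1973) estimator; the unbiased 2n/(2n-1) variant is
available via ``unbiased=True`` but is not the default.  HWE chi-square
uses no continuity correction.  Raw HWE p-values are reported alongside a
Bonferroni-adjusted column (alpha adjusted across loci x populations);
the adjustment is informational, never used for filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FreqTable, GenotypeMatrix, InputError, MISSING, PopulationHierarchy, resolve_level


def _group_indices(gm: GenotypeMatrix, hierarchy: PopulationHierarchy, level: str) -> dict[str, np.ndarray]:
    labels = hierarchy.labels(level, gm.samples)
    out: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        out.setdefault(lab, []).append(i)
    return {k: np.asarray(v) for k, v in out.items()}


def allele_frequencies(
    gm: GenotypeMatrix, hierarchy: PopulationHierarchy, level: str = "subpopulation"
) -> FreqTable:
    """Allele counts/frequencies per population at the requested level.

    Counts are over non-missing calls only; the per-population total of
    counted alleles (2n) is recorded.  A population with no non-missing
    call at a locus gets NaN frequencies.
    """
    level = resolve_level(level)
    groups = _group_indices(gm, hierarchy, level)
    pops = list(groups)
    X, slices = gm.allele_count_blocks()
    counts = []
    for l, sl in enumerate(slices):
        block = np.vstack([X[groups[p], sl].sum(axis=0) for p in pops])
        counts.append(block)
    return FreqTable(pops, gm.loci, [tuple(a) for a in gm.alleles], counts)


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

def observed_heterozygosity(genotypes_at_locus: np.ndarray) -> float:
    """Fraction of heterozygous individuals among non-missing calls.

    ``genotypes_at_locus`` is an ``(n, 2)`` array of allele codes with
    ``(-1, -1)`` marking a missing call.  NaN when every call is missing.
    """
    g = np.asarray(genotypes_at_locus)
    valid = g[:, 0] != MISSING
    if not valid.any():
        return float("nan")
    g = g[valid]
    return float((g[:, 0] != g[:, 1]).mean())


def expected_heterozygosity(freqs: np.ndarray, two_n: int | None = None, unbiased: bool = False) -> float:
    """Nei's gene diversity He = 1 - sum p_a^2.

    With ``unbiased=True`` the small-sample correction 2n/(2n-1) is
    applied (requires ``two_n``).
    """
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise InputError("empty frequency vector")
    he = 1.0 - float(np.sum(p * p))
    if unbiased:
        if two_n is None or two_n < 2:
            raise InputError("unbiased He requires two_n >= 2")
        he *= two_n / (two_n - 1.0)
    return he


def shannon_index(freqs: np.ndarray) -> float:
    """Shannon's information index I = -sum p_a ln p_a (natural log)."""
    p = np.asarray(freqs, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


def fixation_index(ho: float, he: float) -> float:
    """Wright's fixation index F = 1 - Ho/He; NaN when He = 0."""
    if not (he > 0):
        return float("nan")
    return 1.0 - ho / he


def hwe_chisq(genotype_counts: dict[tuple[str, str], int]) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    ``genotype_counts`` maps unordered genotype pairs, e.g.
    ``{("A","A"): 25, ("A","T"): 50, ("T","T"): 25}``, to individual
    counts.  Expected counts are n p_a^2 (homozygotes) and 2 n p_a p_b
    (heterozygotes) from the observed allele frequencies; the statistic
    sums (O-E)^2/E over all k(k+1)/2 genotype classes and is referred to
    chi-square with k(k-1)/2 degrees of freedom.  A monomorphic sample
    returns ``(nan, 0, nan)`` (test skipped).
    """
    counts = {tuple(sorted(k)): 0 for k in genotype_counts}
    for k, v in genotype_counts.items():
        if v < 0:
            raise InputError("negative genotype count")
        counts[tuple(sorted(k))] += v
    n = sum(counts.values())
    if n < 1:
        raise InputError("at least one individual required")
    allele_counts: dict[str, int] = {}
    for (a, b), v in counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + v
        allele_counts[b] = allele_counts.get(b, 0) + v
    alleles = sorted(allele_counts)
    k = len(alleles)
    if k < 2:
        return (float("nan"), 0, float("nan"))
    p = {a: allele_counts[a] / (2 * n) for a in alleles}
    chi2 = 0.0
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            e = n * (p[a] ** 2 if a == b else 2 * p[a] * p[b])
            o = counts.get((a, b), 0) if a <= b else counts.get((b, a), 0)
            if e > 0:
                chi2 += (o - e) ** 2 / e
    df = k * (k - 1) // 2
    return (chi2, df, float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Per-locus diversity values plus the mean +/- SE multi-locus summary."""

    by_locus: pd.DataFrame  # population, locus, two_n, Ho, He, I, F
    summary: pd.DataFrame   # population, statistic, mean, se, n_loci, n_dropped
    level: str


def _genotype_counts_from_codes(pair: np.ndarray, alleles: tuple[str, ...]) -> dict[tuple[str, str], int]:
    valid = pair[:, 0] != MISSING
    out: dict[tuple[str, str], int] = {}
    for a, b in pair[valid]:
        key = (alleles[a], alleles[b]) if alleles[a] <= alleles[b] else (alleles[b], alleles[a])
        out[key] = out.get(key, 0) + 1
    return out


def diversity_summary(
    gm: GenotypeMatrix,
    hierarchy: PopulationHierarchy,
    level: str = "subpopulation",
    unbiased_he: bool = False,
) -> DiversitySummary:
    """Per-population, per-locus Ho/He/I/F and the multi-locus summary.

    SE = sd/sqrt(L) with L the number of loci where the statistic is
    defined for that population; the count of dropped loci is reported.
    """
    level = resolve_level(level)
    groups = _group_indices(gm, hierarchy, level)
    freq = allele_frequencies(gm, hierarchy, level)
    rows = []
    for p_i, pop in enumerate(freq.populations):
        idx = groups[pop]
        for l, locus in enumerate(gm.loci):
            pair = gm.codes[idx, l, :]
            two_n = int(freq.counts[l][p_i].sum())
            if two_n == 0:
                rows.append((pop, locus, 0, np.nan, np.nan, np.nan, np.nan))
                continue
            ho = observed_heterozygosity(pair)
            f = freq.frequencies(locus)[p_i]
            he = expected_heterozygosity(f, two_n=two_n, unbiased=unbiased_he)
            ii = shannon_index(f)
            rows.append((pop, locus, two_n, ho, he, ii, fixation_index(ho, he)))
    by_locus = pd.DataFrame(rows, columns=["population", "locus", "two_n", "Ho", "He", "I", "F"])

    summ = []
    n_loci = gm.n_loci
    for pop, sub in by_locus.groupby("population", sort=False):
        for stat in ("Ho", "He", "I", "F"):
            vals = sub[stat].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            L = vals.size
            mean = float(vals.mean()) if L else float("nan")
            se = float(vals.std(ddof=1) / math.sqrt(L)) if L > 1 else float("nan")
            summ.append((pop, stat, mean, se, L, n_loci - L))
    summary = pd.DataFrame(summ, columns=["population", "statistic", "mean", "se", "n_loci", "n_dropped"])
    return DiversitySummary(by_locus=by_locus, summary=summary, level=level)


def hwe_table(
    gm: GenotypeMatrix, hierarchy: PopulationHierarchy, level: str = "subpopulation"
) -> pd.DataFrame:
    """HWE chi-square tests for every (population, locus).

    Columns: population, locus, n, chi2, df, p, p_bonferroni (p times
    the number of performed tests, capped at 1).  Monomorphic or empty
    cells carry NaN.
    """
    level = resolve_level(level)
    groups = _group_indices(gm, hierarchy, level)
    rows = []
    for pop, idx in groups.items():
        for l, locus in enumerate(gm.loci):
            pair = gm.codes[idx, l, :]
            counts = _genotype_counts_from_codes(pair, gm.alleles[l])
            n = sum(counts.values())
            if n == 0:
                rows.append((pop, locus, 0, np.nan, 0, np.nan))
                continue
            chi2, df, p = hwe_chisq(counts)
            rows.append((pop, locus, n, chi2, df, p))
    df_out = pd.DataFrame(rows, columns=["population", "locus", "n", "chi2", "df", "p"])
    n_tests = int(df_out["p"].notna().sum())
    df_out["p_bonferroni"] = (df_out["p"] * max(n_tests, 1)).clip(upper=1.0)
    return df_out
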