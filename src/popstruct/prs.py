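"""Polygenic risk scores and their population comparison.

The individual score is the normalized additive aggregate of risk-allele
dosages x_i in {0, 1, 2}: unweighted, score = sum x_i / (2L) over the L
loci with data, so a homozygous-risk individual at every locus scores
exactly 1 and one with no risk alleles scores 0; weighted, the dosages
are weighted by beta_i = |ln OR_i| and normalized by 2 sum beta_i, which
keeps the same [0, 1] range.  The absolute value guards against panels
that list protective-direction odds ratios (< 1) for alleles labelled as
risk.  Missing loci are handled by renormalizing over the non-missing
loci of each individual, never by imputation.

The population-specific score (psPRS) is the mean of its members'
individual scores.  psPRS differences are assessed by one-way ANOVA on
the individual scores followed by Tukey's HSD studentized-range test for
every population pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeMatrix, InputError, PopulationHierarchy, SnpPanel, resolve_level

MODES = ("unweighted", "weighted")


def _weights(panel: SnpPanel, loci: list[str], mode: str) -> np.ndarray:
    if mode not in MODES:
        raise InputError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "unweighted":
        return np.ones(len(loci))
    return np.array([panel[l].beta for l in loci])


def prs_scores(gm: GenotypeMatrix, snp_panel: SnpPanel, mode: str = "unweighted") -> pd.DataFrame:
    """Individual risk scores for every sample.

    Returns columns ``sample``, ``score`` (in [0, 1], NaN when every
    locus is missing) and ``loci_used``.
    """
    risk_of = {l: snp_panel[l].risk_allele for l in gm.loci}
    dosage = gm.dosage(risk_of)            # (n, L), NaN at missing calls
    w = _weights(snp_panel, gm.loci, mode)
    present = ~np.isnan(dosage)
    num = np.nansum(dosage * w, axis=1)
    den = 2.0 * (present * w).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame(
        {"sample": gm.samples, "score": score, "loci_used": present.sum(axis=1)}
    )


def individual_prs(
    calls: list[tuple[str, str] | None], snp_panel: SnpPanel, mode: str = "unweighted"
) -> float:
    """Risk score for a single individual.

    ``calls`` holds one unordered allele pair per panel locus (panel
    order), or None for a missing call.  NaN if every locus is missing.
    """
    if len(calls) != len(snp_panel):
        raise InputError(f"{len(calls)} calls for {len(snp_panel)} panel loci")
    w = _weights(snp_panel, snp_panel.rsids, mode)
    num = den = 0.0
    for wi, rec, call in zip(w, snp_panel, calls):
        if call is None:
            continue
        a, b = (s.upper() for s in call)
        for s in (a, b):
            if s not in rec.alleles:
                raise InputError(f"{rec.rsid}: allele {s} not in panel alleles {rec.alleles}")
        num += wi * ((a == rec.risk_allele) + (b == rec.risk_allele))
        den += 2.0 * wi
    return num / den if den > 0 else float("nan")


@dataclass
class PrsResult:
    """Individual scores plus per-population summaries."""

    mode: str
    level: str
    individual: pd.DataFrame   # sample, population, score, loci_used
    population: pd.DataFrame   # population, psPRS, sd, n
    overall_mean: float
    overall_sd: float


def population_prs(
    gm: GenotypeMatrix,
    hierarchy: PopulationHierarchy,
    snp_panel: SnpPanel,
    level: str = "superpopulation",
    mode: str = "unweighted",
) -> PrsResult:
    """psPRS (mean individual score) per population at a hierarchy level."""
    level = resolve_level(level)
    ind = prs_scores(gm, snp_panel, mode)
    ind["population"] = hierarchy.labels(level, gm.samples)
    rows = []
    for pop, sub in ind.groupby("population", sort=False):
        vals = sub["score"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            from .core_io import logger
            logger.warning("population %s has no scorable individuals; skipped", pop)
            continue
        rows.append((pop, float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0, vals.size))
    popframe = pd.DataFrame(rows, columns=["population", "psPRS", "sd", "n"])
    allvals = ind["score"].to_numpy(dtype=float)
    allvals = allvals[np.isfinite(allvals)]
    return PrsResult(
        mode=mode,
        level=level,
        individual=ind[["sample", "population", "score", "loci_used"]],
        population=popframe,
        overall_mean=float(allvals.mean()) if allvals.size else float("nan"),
        overall_sd=float(allvals.std(ddof=1)) if allvals.size > 1 else float("nan"),
    )


def anova_tukey(scores_by_group: dict[str, np.ndarray]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD pairwise comparison of group means.

    Returns ``(pairwise, summary)``: a symmetric matrix of Tukey
    studentized-range p-values (NaN diagonal) and a one-row-per-group
    summary with the ANOVA F and p attached as frame attributes
    (``summary.attrs['anova_F']``, ``summary.attrs['anova_p']``).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in scores_by_group.items()}
    groups = {k: v[np.isfinite(v)] for k, v in groups.items()}
    if len(groups) < 2:
        raise InputError("need at least two groups")
    for k, v in groups.items():
        if v.size < 2:
            raise InputError(f"group {k!r} has fewer than 2 observations")
    names = list(groups)
    arrays = [groups[k] for k in names]
    f_stat, f_p = stats.f_oneway(*arrays)
    tuk = stats.tukey_hsd(*arrays)
    n = len(names)
    pmat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                pmat[i, j] = tuk.pvalue[i, j]
    pairwise = pd.DataFrame(pmat, index=names, columns=names)
    summary = pd.DataFrame(
        {
            "group": names,
            "mean": [float(a.mean()) for a in arrays],
            "sd": [float(a.std(ddof=1)) for a in arrays],
            "n": [int(a.size) for a in arrays],
        }
    )
    summary.attrs["anova_F"] = float(f_stat)
    summary.attrs["anova_p"] = float(f_p)
    return pairwise, summary
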