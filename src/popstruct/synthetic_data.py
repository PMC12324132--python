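"""Synthetic structured-population genotype generator.

Genotype data are simulated under a two-level island model with
Balding–Nichols divergence: superpopulation allele frequencies are drawn
around a global frequency ``p`` as Beta(p(1-F)/F, (1-p)(1-F)/F) with
``F`` the target FST between superpopulations, and subpopulation
frequencies are drawn the same way around their superpopulation's
frequency with the (smaller) within-superpopulation FST.  Individuals
are then sampled with inbreeding-adjusted genotype probabilities
{p^2 + F p q, 2 p q (1 - F), q^2 + F p q}; the multiallelic
generalisation draws the two alleles identical with probability F and
independently otherwise.  Loci are simulated independently (no LD).

The default study-scale configuration mirrors the structure of the
frontotemporal-dementia risk-locus study this package reanalyses:
26 subpopulations nested in 5 superpopulations with the 1000 Genomes
Phase 3 sample sizes, 32 risk loci (one triallelic), and global
risk-allele frequencies taken from the published panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import (
    GenotypeMatrix,
    InputError,
    MISSING,
    PopulationHierarchy,
    SnpPanel,
    SnpRecord,
)

# (subpopulation, superpopulation, n samples) — the 1000 Genomes Phase 3
# cohorts analysed in the study (N = 2504).
STUDY_HIERARCHY: list[tuple[str, str, int]] = [
    ("ACB", "AFR", 96), ("ASW", "AFR", 61), ("ESN", "AFR", 99), ("GWD", "AFR", 113),
    ("LWK", "AFR", 99), ("MSL", "AFR", 85), ("YRI", "AFR", 108),
    ("CLM", "AMR", 94), ("MXL", "AMR", 64), ("PEL", "AMR", 85), ("PUR", "AMR", 104),
    ("CEU", "EUR", 99), ("FIN", "EUR", 99), ("GBR", "EUR", 91), ("IBS", "EUR", 107),
    ("TSI", "EUR", 107),
    ("CDX", "EAS", 93), ("CHB", "EAS", 103), ("CHS", "EAS", 105), ("JPT", "EAS", 104),
    ("KHV", "EAS", 99),
    ("BEB", "SAS", 86), ("GIH", "SAS", 103), ("ITU", "SAS", 102), ("PJL", "SAS", 96),
    ("STU", "SAS", 102),
]

# The 32-SNP risk panel: rsid, cytoband, risk allele, other allele(s),
# odds ratio, mapped genes, and the global risk-allele frequency implied
# by the published combined-population minor-allele frequency (the risk
# allele is the minor allele where flagged; otherwise 1 - MAF).
STUDY_PANEL: list[tuple[str, str, str, tuple[str, ...], float, tuple[str, ...], tuple[float, ...]]] = [
    ("rs17042852", "2p16.3", "C", ("T",), 2.82, ("LINC01867",), (0.04,)),
    ("rs13393316", "2q33.3", "A", ("G",), 1.89, ("NDUFS1",), (0.90,)),
    ("rs4676496", "3p22.1", "G", ("A",), 1.37, ("RPSA", "MOBP"), (0.60,)),
    ("rs6809184", "3q26.2", "T", ("C",), 0.02, ("TNIK",), (0.07,)),
    ("rs13072484", "3q29", "A", ("G",), 1.51, ("LINC02012", "DLG1-AS1"), (0.21,)),
    ("rs11099660", "4q31.23", "C", ("T",), 1.57, ("LINC02507",), (0.71,)),
    ("rs79095029", "5q21.3", "C", ("G",), 2.56, ("PJA2", "KRT18P42"), (0.95,)),
    ("rs517339", "5q35.1", "C", ("T",), 1.75, ("ERGIC1",), (0.32,)),
    ("rs9268856", "6p21.32", "C", ("A",), 1.24, ("HLA-DRB9",), (0.71,)),
    ("rs62443267", "7p14.1", "C", ("T",), 1.54, ("STARD3NL", "SFRP4"), (0.84,)),
    ("rs7791726", "7p21.3", "G", ("C",), 1.85, ("TMEM106B", "VWDE"), (0.39,)),
    ("rs6962939", "7p21.3", "A", ("T",), 1.27, ("COL28A1",), (0.06,)),
    ("rs2922921", "7q21.3", "A", ("G",), 1.35, ("SEM1", "MARK2P10"), (0.01,)),
    ("rs36196656", "8p21.3", "A", ("C",), 1.55, ("GFRA2",), (0.55,)),
    ("rs10101195", "8p23.1", "C", ("A",), 1.61, ("GATA4", "NEIL2"), (0.71,)),
    ("rs9792144", "8q11.23", "G", ("C",), 0.02, ("ST18",), (0.16,)),
    ("rs3922636", "8q21.13", "A", ("C", "G"), 2.98, ("RPL3P9", "MITA1"), (0.003, 0.17, 0.827)),
    ("rs12554036", "9p21.2", "T", ("G",), 0.09, ("MOB3B",), (0.13,)),
    ("rs10816848", "9q31.3", "T", ("A",), 1.43, ("PALM2", "AKAP2"), (0.66,)),
    ("rs4980079", "10q22.3", "T", ("C",), 1.46, ("ZCCHC24",), (0.28,)),
    ("rs302668", "11q14.2", "T", ("C",), 1.23, ("RAB38",), (0.76,)),
    ("rs10860097", "12q23.1", "T", ("A",), 3.04, ("CFAP54",), (0.04,)),
    ("rs229243", "14q12", "A", ("C",), 1.55, ("G2E3",), (0.52,)),
    ("rs3110643", "17q12", "C", ("T",), 1.65, ("HNF1B",), (0.08,)),
    ("rs906175", "17q25.3", "T", ("C",), 1.58, ("CEP131",), (0.42,)),
    ("rs7240419", "18q23", "A", ("G",), 1.52, ("ATP9B",), (0.32,)),
    ("rs12608932", "19p13.11", "C", ("A",), 1.37, ("UNC13A",), (0.43,)),
    ("rs6857", "19q13.32", "T", ("C",), 1.67, ("NECTIN2",), (0.11,)),
    ("rs6076187", "20p11.21", "A", ("G",), 2.27, ("LINC01721",), (0.12,)),
    ("rs6111609", "20p12.1", "A", ("C",), 2.78, ("RRBP1", "BANF2"), (0.07,)),
    ("rs6108746", "20p12.2", "C", ("T",), 3.24, ("FAT1P1", "LINC02871"), (0.13,)),
    ("rs4810992", "20q13.13", "A", ("G",), 1.2, ("RNF114",), (0.13,)),
]

#: index of the single triallelic locus (rs3922636) in the study panel
STUDY_TRIALLELIC_INDEX = 17 - 1


def study_snp_panel() -> SnpPanel:
    """The fixed 32-SNP risk panel with published odds ratios."""
    return SnpPanel(
        SnpRecord(rsid=r, region=reg, risk_allele=ra, other_alleles=oa, odds_ratio=odds, genes=genes)
        for r, reg, ra, oa, odds, genes, _ in STUDY_PANEL
    )


@dataclass
class SimulationConfig:
    """Parameters of the two-level Balding–Nichols simulation.

    ``global_risk_freqs`` may be a list of per-locus risk-allele
    frequencies, or the string ``"sample uniform(a,b)"`` to draw them.
    ``hierarchy`` optionally overrides the regular
    ``n_superpops x subpops_per_superpop x samples_per_subpop`` grid with
    an explicit (subpop, superpop, size) list such as
    :data:`STUDY_HIERARCHY`.
    """

    n_superpops: int = 5
    subpops_per_superpop: int = 5
    samples_per_subpop: int = 100
    n_loci: int = 32
    global_risk_freqs: Sequence[float] | str = "sample uniform(0.05,0.95)"
    fst_between_superpops: float = 0.08
    fst_within_superpop: float = 0.02
    inbreeding_f: float = 0.0
    missing_rate: float = 0.0
    triallelic_loci: Sequence[int] = ()
    seed: int = 0
    hierarchy: Sequence[tuple[str, str, int]] | None = None
    snp_panel: SnpPanel | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise InputError("n_loci must be >= 1")
        for name in ("fst_between_superpops", "fst_within_superpop"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise InputError(f"{name} must be in [0, 1), got {v}")
        if not (0 <= self.inbreeding_f < 1):
            raise InputError(f"inbreeding_f must be in [0, 1), got {self.inbreeding_f}")
        if not (0 <= self.missing_rate <= 1):
            raise InputError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if isinstance(self.global_risk_freqs, str):
            self._freq_range = _parse_uniform(self.global_risk_freqs)
        else:
            self._freq_range = None
            freqs = list(self.global_risk_freqs)
            if len(freqs) != self.n_loci:
                raise InputError(
                    f"global_risk_freqs has {len(freqs)} entries for {self.n_loci} loci"
                )
            for f in freqs:
                if not (0 < f < 1):
                    raise InputError(f"global risk frequency {f} outside (0, 1)")
        if self.hierarchy is not None:
            subs = [s for s, _, _ in self.hierarchy]
            if len(set(subs)) != len(subs):
                raise InputError("duplicate subpopulation in hierarchy override")
        bad = [i for i in self.triallelic_loci if not (0 <= i < self.n_loci)]
        if bad:
            raise InputError(f"triallelic locus indices out of range: {bad}")


def _parse_uniform(spec: str) -> tuple[float, float]:
    spec = spec.strip()
    prefix, suffix = "sample uniform(", ")"
    if not (spec.startswith(prefix) and spec.endswith(suffix)):
        raise InputError(f"cannot parse frequency spec {spec!r}; expected 'sample uniform(a,b)'")
    a, b = (float(x) for x in spec[len(prefix):-len(suffix)].split(","))
    if not (0 < a < b < 1):
        raise InputError(f"uniform frequency bounds must satisfy 0 < a < b < 1, got ({a}, {b})")
    return a, b


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-scale defaults: Table-of-populations hierarchy, 32 published loci.

    The synthetic odds ratios are replaced by the published panel so the
    weighted risk score uses realistic effect sizes.
    """
    freqs = [f[0] for f in (row[6] for row in STUDY_PANEL)]
    cfg = dict(
        n_superpops=5,
        subpops_per_superpop=0,  # ignored when hierarchy is explicit
        samples_per_subpop=0,
        n_loci=32,
        global_risk_freqs=freqs,
        triallelic_loci=(STUDY_TRIALLELIC_INDEX,),
        hierarchy=list(STUDY_HIERARCHY),
        snp_panel=study_snp_panel(),
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


# ---------------------------------------------------------------------------
# Frequency draws
# ---------------------------------------------------------------------------

def draw_population_frequencies(
    global_freq: float, fst: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding–Nichols draw of per-population risk-allele frequencies.

    Frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) with p the global
    frequency and F the target FST, so E = p and Var = F p (1 - p).
    F = 0 degenerates to every population at p.
    """
    if not (0 < global_freq < 1):
        raise InputError(f"global_freq must be in (0, 1), got {global_freq}")
    if not (0 <= fst < 1):
        raise InputError(f"fst must be in [0, 1), got {fst}")
    if fst == 0:
        return np.full(n_pops, global_freq)
    scale = (1.0 - fst) / fst
    return rng.beta(global_freq * scale, (1.0 - global_freq) * scale, size=n_pops)


def _draw_frequency_vector(
    parent: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiallelic Balding–Nichols: Dirichlet(p * (1-F)/F) around ``parent``.

    Reduces to the Beta draw for two alleles.  Zero components of the
    parent stay (numerically) zero.
    """
    parent = np.asarray(parent, dtype=float)
    if fst == 0:
        return parent.copy()
    alpha = np.maximum(parent, 1e-12) * (1.0 - fst) / fst
    draw = rng.dirichlet(alpha)
    return draw


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _build_hierarchy(config: SimulationConfig) -> list[tuple[str, str, int]]:
    if config.hierarchy is not None:
        return list(config.hierarchy)
    out = []
    for i in range(config.n_superpops):
        sup = f"SUP{i + 1}"
        for j in range(config.subpops_per_superpop):
            out.append((f"{sup}_P{j + 1}", sup, config.samples_per_subpop))
    return out


def _synthetic_panel(config: SimulationConfig, rng: np.random.Generator) -> SnpPanel:
    """Panel with synthetic odds ratios, log-uniform in [1.1, 3.5]."""
    ors = np.exp(rng.uniform(math.log(1.1), math.log(3.5), size=config.n_loci))
    tri = set(config.triallelic_loci)
    records = []
    for l in range(config.n_loci):
        others = ("C", "G") if l in tri else ("G",)
        records.append(
            SnpRecord(
                rsid=f"rs{900000 + l}",
                region=f"{(l % 22) + 1}q{l + 1}",
                risk_allele="A",
                other_alleles=others,
                odds_ratio=float(ors[l]),
                genes=(f"GENE{l + 1}",),
            )
        )
    return SnpPanel(records)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationHierarchy, SnpPanel]:
    """Simulate genotypes under the two-level Balding–Nichols model.

    Reproducible for a fixed ``config.seed``.  With ``missing_rate = 1``
    every call is missing and downstream statistics report undefined
    markers.
    """
    rng = np.random.default_rng(config.seed)
    hier = _build_hierarchy(config)
    panel = config.snp_panel if config.snp_panel is not None else _synthetic_panel(config, rng)
    if len(panel) != config.n_loci:
        raise InputError(f"panel has {len(panel)} loci but config.n_loci = {config.n_loci}")

    # global allele-frequency vectors, risk allele first
    tri = set(config.triallelic_loci)
    if config._freq_range is not None:
        a, b = config._freq_range
        risk = rng.uniform(a, b, size=config.n_loci)
        global_freqs = []
        for l in range(config.n_loci):
            rest = 1.0 - risk[l]
            if l in tri:
                # split the residual mass unevenly between the two other alleles
                w = rng.uniform(0.2, 0.8)
                global_freqs.append(np.array([risk[l], rest * w, rest * (1 - w)]))
            else:
                global_freqs.append(np.array([risk[l], rest]))
    else:
        global_freqs = []
        for l, f in enumerate(config.global_risk_freqs):
            if l in tri:
                # study-style triallelic locus: residual split as published
                rest = 1.0 - f
                if config.snp_panel is not None and l == STUDY_TRIALLELIC_INDEX and len(STUDY_PANEL[l][6]) == 3:
                    global_freqs.append(np.array(STUDY_PANEL[l][6]))
                else:
                    global_freqs.append(np.array([f, rest * 0.5, rest * 0.5]))
            else:
                global_freqs.append(np.array([f, 1.0 - f]))
    for l, (rec, gf) in enumerate(zip(panel, global_freqs)):
        if len(gf) != len(rec.alleles):
            raise InputError(f"locus {rec.rsid}: {len(gf)} frequencies for {len(rec.alleles)} alleles")

    superpops = list(dict.fromkeys(sup for _, sup, _ in hier))
    # per-superpopulation then per-subpopulation frequency vectors
    sup_freqs: dict[str, list[np.ndarray]] = {
        sup: [
            _draw_frequency_vector(global_freqs[l], config.fst_between_superpops, rng)
            for l in range(config.n_loci)
        ]
        for sup in superpops
    }
    sub_freqs: dict[str, list[np.ndarray]] = {
        sub: [
            _draw_frequency_vector(sup_freqs[sup][l], config.fst_within_superpop, rng)
            for l in range(config.n_loci)
        ]
        for sub, sup, _ in hier
    }

    samples: list[str] = []
    subs: list[str] = []
    sups: list[str] = []
    blocks: list[np.ndarray] = []
    f_in = config.inbreeding_f
    for sub, sup, size in hier:
        start = len(samples)
        samples.extend(f"{sub}_{i + 1:04d}" for i in range(size))
        subs.extend([sub] * size)
        sups.extend([sup] * size)
        codes = np.empty((size, config.n_loci, 2), dtype=np.int8)
        for l in range(config.n_loci):
            p = sub_freqs[sub][l]
            cum = np.cumsum(p)
            cum[-1] = 1.0
            a1 = np.searchsorted(cum, rng.random(size), side="right")
            a2 = np.searchsorted(cum, rng.random(size), side="right")
            if f_in > 0:
                ibd = rng.random(size) < f_in
                a2 = np.where(ibd, a1, a2)
            codes[:, l, 0] = a1
            codes[:, l, 1] = a2
        blocks.append(codes)

    codes = np.concatenate(blocks, axis=0)
    if config.missing_rate > 0:
        miss = rng.random(codes.shape[:2]) < config.missing_rate
        codes[miss] = MISSING

    gm = GenotypeMatrix(
        samples, panel.rsids, [rec.alleles for rec in panel], codes
    )
    hierarchy = PopulationHierarchy(samples, subs, sups)
    return gm, hierarchy, panel
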