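"""Domain containers and file I/O.

The analysis operates on three linked objects:

* :class:`SnpPanel` — per-locus metadata for a fixed panel of GWAS risk
  SNPs: the risk allele, the other allele(s) (one locus may be
  triallelic), the published odds ratio and mapped genes.
* :class:`GenotypeMatrix` — samples x loci diploid calls.  A call is an
  *unordered* pair of allele symbols; phasing is ignored everywhere.
  Missing calls are allowed and are excluded locus-wise from every count
  (pairwise deletion), never imputed.
* :class:`PopulationHierarchy` — the two-level sample -> subpopulation ->
  superpopulation mapping of the 1000 Genomes panel file.

Readers cover VCF 4.x (via cyvcf2), the 1000G-style panel TSV and a SNP
panel TSV; writers emit plain VCF and TSV tables with a JSON metadata
sidecar.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("popstruct")

MISSING = -1  # allele code for a missing call

LEVELS = ("subpopulation", "superpopulation", "all")
#: short aliases accepted wherever a hierarchy level is requested
LEVEL_ALIASES = {
    "sub": "subpopulation",
    "super": "superpopulation",
    "subpopulation": "subpopulation",
    "superpopulation": "superpopulation",
    "all": "all",
}


class InputError(ValueError):
    """Raised for malformed or inconsistent input files."""


def resolve_level(level: str) -> str:
    try:
        return LEVEL_ALIASES[level.lower()]
    except KeyError:
        raise InputError(f"unknown hierarchy level {level!r}; expected one of {sorted(LEVEL_ALIASES)}")


# ---------------------------------------------------------------------------
# SNP panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One risk SNP: identity, alleles, effect size and annotation."""

    rsid: str
    region: str
    risk_allele: str
    other_alleles: tuple[str, ...]
    odds_ratio: float
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "risk_allele", self.risk_allele.upper())
        object.__setattr__(self, "other_alleles", tuple(a.upper() for a in self.other_alleles))
        if not self.other_alleles:
            raise InputError(f"{self.rsid}: at least one non-risk allele is required")
        if self.risk_allele in self.other_alleles:
            raise InputError(f"{self.rsid}: risk allele {self.risk_allele} repeated among other alleles")
        if not (self.odds_ratio > 0 and math.isfinite(self.odds_ratio)):
            raise InputError(f"{self.rsid}: odds ratio must be a positive finite number, got {self.odds_ratio}")

    @property
    def alleles(self) -> tuple[str, ...]:
        """All allele symbols at the locus, risk allele first."""
        return (self.risk_allele,) + self.other_alleles

    @property
    def beta(self) -> float:
        """Per-allele weight |ln OR| used by the weighted risk score."""
        return abs(math.log(self.odds_ratio))


class SnpPanel:
    """Ordered collection of :class:`SnpRecord` with unique rsids."""

    def __init__(self, records: Iterable[SnpRecord]):
        self.records: list[SnpRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.rsid in seen:
                raise InputError(f"duplicate rsid in SNP panel: {rec.rsid}")
            seen.add(rec.rsid)
        self._by_rsid = {rec.rsid: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rsid: str) -> SnpRecord:
        return self._by_rsid[rsid]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    @property
    def rsids(self) -> list[str]:
        return [rec.rsid for rec in self.records]

    def subset(self, rsids: Sequence[str]) -> "SnpPanel":
        return SnpPanel(self._by_rsid[r] for r in rsids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.records],
                "region": [r.region for r in self.records],
                "risk_allele": [r.risk_allele for r in self.records],
                "other_alleles": [",".join(r.other_alleles) for r in self.records],
                "odds_ratio": [r.odds_ratio for r in self.records],
                "genes": [",".join(r.genes) for r in self.records],
            }
        )


def read_snp_panel(path: str | Path) -> SnpPanel:
    """Read a SNP panel TSV.

    Expected columns (tab-delimited, one header line): ``rsid``,
    ``region``, ``risk_allele``, ``other_alleles`` (comma-separated,
    so triallelic loci are written e.g. ``C,G``), ``odds_ratio``,
    ``genes`` (comma-separated, optional).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rsid", "region", "risk_allele", "other_alleles", "odds_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"SNP panel {path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            odds = float(row.odds_ratio)
        except ValueError:
            raise InputError(f"SNP panel {path}: non-numeric odds ratio {row.odds_ratio!r} at {row.rsid}")
        genes = tuple(g.strip() for g in str(getattr(row, "genes", "") or "").split(",") if g.strip())
        records.append(
            SnpRecord(
                rsid=row.rsid,
                region=row.region,
                risk_allele=row.risk_allele.strip(),
                other_alleles=tuple(a.strip() for a in row.other_alleles.split(",") if a.strip()),
                odds_ratio=odds,
                genes=genes,
            )
        )
    return SnpPanel(records)


def write_snp_panel(panel: SnpPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Population hierarchy
# ---------------------------------------------------------------------------

class PopulationHierarchy:
    """Sample -> subpopulation -> superpopulation mapping.

    Every sample appears once, and every subpopulation belongs to exactly
    one superpopulation (the 1000 Genomes two-level structure: 26 cohorts
    nested in 5 continental groups).
    """

    def __init__(self, samples: Sequence[str], subpops: Sequence[str], superpops: Sequence[str]):
        if not (len(samples) == len(subpops) == len(superpops)):
            raise InputError("samples, subpops and superpops must have equal length")
        self.samples = list(samples)
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise InputError(f"duplicate sample(s) in panel: {dupes[:5]}")
        self.subpop = dict(zip(self.samples, subpops))
        self.superpop = dict(zip(self.samples, superpops))
        mapping: dict[str, str] = {}
        for sub, sup in zip(subpops, superpops):
            if mapping.setdefault(sub, sup) != sup:
                raise InputError(
                    f"subpopulation {sub!r} mapped to two superpopulations: {mapping[sub]!r} and {sup!r}"
                )
        self.sub_to_super = mapping

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def subpopulations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.subpop[s], None)
        return list(seen)

    @property
    def superpopulations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.superpop[s], None)
        return list(seen)

    def labels(self, level: str, samples: Sequence[str] | None = None) -> list[str]:
        """Group label for each sample at the requested level."""
        level = resolve_level(level)
        samples = self.samples if samples is None else samples
        if level == "subpopulation":
            return [self.subpop[s] for s in samples]
        if level == "superpopulation":
            return [self.superpop[s] for s in samples]
        return ["ALL"] * len(samples)

    def counts(self, level: str = "subpopulation") -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels(level):
            out[lab] = out.get(lab, 0) + 1
        return out

    def subset(self, samples: Sequence[str]) -> "PopulationHierarchy":
        return PopulationHierarchy(
            list(samples), [self.subpop[s] for s in samples], [self.superpop[s] for s in samples]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "pop": [self.subpop[s] for s in self.samples],
                "super_pop": [self.superpop[s] for s in self.samples],
            }
        )


def read_panel_file(path: str | Path) -> PopulationHierarchy:
    """Read a 1000G-style sample panel file.

    Whitespace/tab-delimited columns ``sample pop super_pop [gender]``;
    a header line (first field literally ``sample``) is skipped.
    """
    samples: list[str] = []
    subs: list[str] = []
    supers: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if lineno == 1 and parts[0].lower() == "sample":
                continue
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: expected at least 3 columns, got {len(parts)}")
            samples.append(parts[0])
            subs.append(parts[1])
            supers.append(parts[2])
    if not samples:
        raise InputError(f"{path}: no samples found")
    return PopulationHierarchy(samples, subs, supers)


def write_panel_file(hierarchy: PopulationHierarchy, path: str | Path) -> None:
    hierarchy.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

class GenotypeMatrix:
    """Diploid calls for ``samples x loci``, multiallelic-capable.

    ``codes`` has shape ``(n_samples, n_loci, 2)``; entry ``codes[i, l]``
    holds the two allele indices of sample *i* at locus *l* (indices into
    ``alleles[l]``), or ``(-1, -1)`` for a missing call.  Calls are
    unordered pairs: the internal representation stores the smaller index
    first, and equality is defined on the unordered pair.
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[str],
        alleles: Sequence[Sequence[str]],
        codes: np.ndarray,
        dropped_loci: Sequence[str] = (),
    ):
        self.samples = list(samples)
        self.loci = list(loci)
        self.alleles = [tuple(a.upper() for a in al) for al in alleles]
        codes = np.asarray(codes, dtype=np.int8)
        if codes.shape != (len(self.samples), len(self.loci), 2):
            raise InputError(
                f"codes shape {codes.shape} inconsistent with {len(self.samples)} samples x {len(self.loci)} loci"
            )
        if len(set(self.samples)) != len(self.samples):
            raise InputError("duplicate sample IDs")
        if len(set(self.loci)) != len(self.loci):
            raise InputError("duplicate locus IDs")
        if len(self.alleles) != len(self.loci):
            raise InputError("alleles list length must match loci")
        # canonicalise unordered pairs and missing
        codes = np.sort(codes, axis=2)
        half_missing = (codes[:, :, 0] == MISSING) ^ (codes[:, :, 1] == MISSING)
        if half_missing.any():
            raise InputError("half-missing calls are not supported; a call is missing as a pair")
        self.codes = codes
        self.dropped_loci = list(dropped_loci)
        self._locus_index = {l: i for i, l in enumerate(self.loci)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, rsid: str) -> int:
        return self._locus_index[rsid]

    def missing_mask(self) -> np.ndarray:
        """Boolean (samples x loci) mask, True where the call is missing."""
        return self.codes[:, :, 0] == MISSING

    def calls(self, sample: str, rsid: str) -> tuple[str, str] | None:
        """The unordered allele-symbol pair, or None if missing."""
        i = self.samples.index(sample)
        l = self._locus_index[rsid]
        a, b = self.codes[i, l]
        if a == MISSING:
            return None
        al = self.alleles[l]
        return (al[a], al[b])

    def dosage(self, allele_of: Mapping[str, str]) -> np.ndarray:
        """Count of a chosen allele per (sample, locus); NaN where missing.

        ``allele_of`` maps rsid -> allele symbol (e.g. the risk allele).
        """
        out = np.full((self.n_samples, self.n_loci), np.nan)
        for l, rsid in enumerate(self.loci):
            sym = allele_of[rsid].upper()
            try:
                idx = self.alleles[l].index(sym)
            except ValueError:
                raise InputError(f"allele {sym} not present at locus {rsid}")
            pair = self.codes[:, l, :]
            miss = pair[:, 0] == MISSING
            out[:, l] = (pair == idx).sum(axis=1).astype(float)
            out[miss, l] = np.nan
        return out

    def allele_count_blocks(self) -> tuple[np.ndarray, list[slice]]:
        """Per-sample allele counts, one column block per locus.

        Returns ``(X, slices)`` where ``X`` is ``(n_samples, sum_l k_l)``
        and ``X[i, slices[l]]`` counts each allele of locus *l* carried by
        sample *i* (row block sums to 2, or 0 for a missing call).  This is
        the workhorse representation for frequency and AMOVA computations.
        """
        ks = [len(a) for a in self.alleles]
        X = np.zeros((self.n_samples, sum(ks)))
        slices: list[slice] = []
        off = 0
        for l, k in enumerate(ks):
            sl = slice(off, off + k)
            slices.append(sl)
            pair = self.codes[:, l, :]
            for j in range(2):
                valid = pair[:, j] != MISSING
                np.add.at(X[:, sl], (np.nonzero(valid)[0], pair[valid, j].astype(int)), 1.0)
            off += k
        return X, slices

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in samples]
        return GenotypeMatrix(list(samples), self.loci, self.alleles, self.codes[idx], self.dropped_loci)

    def subset_loci(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._locus_index[r] for r in rsids]
        return GenotypeMatrix(
            self.samples, list(rsids), [self.alleles[i] for i in idx], self.codes[:, idx, :], self.dropped_loci
        )

    def validate_against_panel(self, panel: SnpPanel) -> None:
        """Check every observed allele symbol is declared in the panel."""
        for l, rsid in enumerate(self.loci):
            if rsid not in panel:
                continue
            declared = set(panel[rsid].alleles)
            observed = {
                self.alleles[l][c]
                for c in np.unique(self.codes[:, l, :])
                if c != MISSING
            }
            extra = observed - declared
            if extra:
                raise InputError(f"{rsid}: observed allele(s) {sorted(extra)} not declared in SNP panel")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    snp_panel: SnpPanel,
    sample_subset: Sequence[str] | None = None,
    positions: Mapping[str, tuple[str, int]] | None = None,
) -> GenotypeMatrix:
    """Read panel loci from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Loci are matched by the VCF ID column against panel rsids; when a
    record's ID is missing (``.``) and ``positions`` supplies a
    rsid -> (chrom, pos) mapping, the chrom:pos fallback is used.  Panel
    loci absent from the file are reported as warnings and listed in
    ``dropped_loci``.  Genotypes are decoded as unordered allele pairs;
    ``./.`` becomes a missing call and phasing is ignored.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), samples=list(sample_subset) if sample_subset is not None else None)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise InputError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    pos_lookup = {}
    if positions:
        pos_lookup = {(str(c), int(p)): rsid for rsid, (c, p) in positions.items()}

    wanted = set(snp_panel.rsids)
    found: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for var in vcf:
        rsid = var.ID if var.ID and var.ID != "." else None
        if rsid is None:
            rsid = pos_lookup.get((str(var.CHROM), int(var.POS)))
        if rsid is None or rsid not in wanted:
            continue
        if rsid in found:
            raise InputError(f"duplicate rsid {rsid} in VCF {path}")
        alleles = (var.REF.upper(),) + tuple(a.upper() for a in var.ALT)
        gts = var.genotype.array()  # (n_samples, ploidy+1); last col is phasing
        pair = np.asarray(gts[:, :2], dtype=np.int16)
        pair[pair < 0] = MISSING
        # a half-called genotype is treated as fully missing (pairwise deletion)
        half = (pair == MISSING).any(axis=1)
        pair[half] = MISSING
        found[rsid] = (alleles, pair.astype(np.int8))
    vcf.close()

    matched = [r for r in snp_panel.rsids if r in found]
    dropped = [r for r in snp_panel.rsids if r not in found]
    if not matched:
        raise InputError(f"no panel loci matched in VCF {path}")
    for r in dropped:
        logger.warning("panel locus %s not found in %s; dropped", r, path)

    codes = np.stack([found[r][1] for r in matched], axis=1)
    alleles = [found[r][0] for r in matched]
    return GenotypeMatrix(samples, matched, alleles, codes, dropped_loci=dropped)


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    contig: str = "1",
    start_pos: int = 10_000,
    spacing: int = 10_000,
) -> None:
    """Write the matrix as a minimal plain-text VCF 4.2 file.

    Loci are laid out on a single synthetic contig at evenly spaced
    positions (the analysis never uses coordinates); allele 0 of each
    locus becomes REF.  Calls are written unphased (``a/b``), missing as
    ``./.``.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples) + "\n")
        for l, rsid in enumerate(matrix.loci):
            al = matrix.alleles[l]
            ref, alt = al[0], ",".join(al[1:])
            fields = [contig, str(start_pos + spacing * l), rsid, ref, alt, ".", "PASS", ".", "GT"]
            for i in range(matrix.n_samples):
                a, b = matrix.codes[i, l]
                fields.append("./." if a == MISSING else f"{a}/{b}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Frequency table
# ---------------------------------------------------------------------------

class FreqTable:
    """Allele counts and frequencies per (population, locus).

    ``counts[l]`` is a ``(n_pops, k_l)`` integer array over the allele
    ordering of the source :class:`GenotypeMatrix`; ``two_n[l]`` the
    per-population total of non-missing alleles (2n).  A population with
    2n = 0 at a locus has undefined (NaN) frequencies.
    """

    def __init__(
        self,
        populations: Sequence[str],
        loci: Sequence[str],
        alleles: Sequence[tuple[str, ...]],
        counts: Sequence[np.ndarray],
    ):
        self.populations = list(populations)
        self.loci = list(loci)
        self.alleles = list(alleles)
        self.counts = [np.asarray(c, dtype=float) for c in counts]
        for l, c in enumerate(self.counts):
            if c.shape != (len(self.populations), len(self.alleles[l])):
                raise InputError(f"count block {l} has shape {c.shape}")
        self._pop_index = {p: i for i, p in enumerate(self.populations)}
        self._locus_index = {l: i for i, l in enumerate(self.loci)}

    def two_n(self, locus: str) -> np.ndarray:
        return self.counts[self._locus_index[locus]].sum(axis=1)

    def frequencies(self, locus: str) -> np.ndarray:
        """(n_pops, k) frequency array; NaN rows where 2n = 0."""
        c = self.counts[self._locus_index[locus]]
        tot = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, c / tot, np.nan)
        return f

    def pop_frequencies(self, population: str) -> dict[str, np.ndarray]:
        """Per-locus frequency vectors for one population."""
        i = self._pop_index[population]
        return {loc: self.frequencies(loc)[i] for loc in self.loci}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l, loc in enumerate(self.loci):
            freqs = self.frequencies(loc)
            two_n = self.counts[l].sum(axis=1)
            for p, pop in enumerate(self.populations):
                for a, sym in enumerate(self.alleles[l]):
                    rows.append(
                        {
                            "locus": loc,
                            "population": pop,
                            "allele": sym,
                            "count": int(self.counts[l][p, a]),
                            "frequency": freqs[p, a],
                            "two_n": int(two_n[p]),
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Labelled symmetric matrix
# ---------------------------------------------------------------------------

@dataclass
class LabelledSymmetricMatrix:
    """Pairwise population matrix (Nei D, FST, ...) with a zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InputError(f"matrix shape {self.values.shape} does not match {n} labels")
        v, vt = self.values, self.values.T
        both_nan = np.isnan(v) & np.isnan(vt)
        with np.errstate(invalid="ignore"):
            close = (np.abs(v - vt) <= 1e-12) | (v == vt)  # second test covers +/-inf pairs
        if not np.all(close | both_nan):
            raise InputError("matrix is not symmetric within 1e-12")
        if not np.all(self.values[np.diag_indices(n)] == 0):
            raise InputError("matrix diagonal must be exactly zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: Sequence[str]) -> "LabelledSymmetricMatrix":
        idx = [self.labels.index(l) for l in labels]
        return LabelledSymmetricMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_metadata(path: str | Path, **fields) -> None:
    """JSON run-metadata sidecar (inputs, seed, versions, parameters)."""
    import popstruct

    meta = {
        "popstruct_version": popstruct.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    meta.update(fields)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
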