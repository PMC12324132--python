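"""End-to-end orchestration: diversity -> differentiation -> enrichment
-> PRS -> ordination, at each requested hierarchy level, with seeded
child RNG streams, machine-readable warnings and a run manifest.

One master seed is recorded; every stochastic stage derives its own
generator from (seed, crc32(stage name)), so disabling one stage never
perturbs another's results and two runs with the same seed produce
byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, differentiation, diversity, enrichment, ordination, prs
from .core_io import InputError, logger, write_metadata, write_table

LEVEL_SUFFIX = {"subpopulation": "sub", "superpopulation": "super", "all": "all"}


class StageError(RuntimeError):
    """A pipeline stage failed; partial results were written."""


@dataclass
class RunConfig:
    """Inputs, analysis levels and stochastic-stage parameters for a run."""

    vcf: str | Path
    panel: str | Path
    snps: str | Path
    out_dir: str | Path
    levels: tuple[str, ...] = ("superpopulation", "subpopulation")
    n_permutations: int = 999
    mc_dememorization: int = 10_000
    mc_batches: int = 100
    mc_iterations: int = 5_000
    seed: int = 0
    mode: str = "unweighted"
    distance_for_pcoa: str = "nei"  # or "fst"
    make_plots: bool = False

    def mc_params(self) -> differentiation.McParams:
        return differentiation.McParams(
            dememorization=self.mc_dememorization,
            batches=self.mc_batches,
            iterations_per_batch=self.mc_iterations,
        )


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child RNG stream keyed by stage name (stable across runs)."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.rows: list[dict] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.rows.append({"stage": getattr(record, "stage", ""), "message": record.getMessage()})


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    A stage failure aborts the run after writing a partial-results
    manifest and raises :class:`StageError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    file_handler = logging.FileHandler(out / "run.log", mode="w")
    file_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(collector)
    logger.addHandler(file_handler)
    logger.setLevel(logging.INFO)

    manifest: dict = {"seed": config.seed, "tables": [], "stages": {}, "status": "running"}
    t_all = time.perf_counter()
    current_stage = "load_inputs"

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> None:
        write_table(df, out / name, index=index)
        manifest["tables"].append(name)

    try:
        t0 = time.perf_counter()
        snp_panel = core_io.read_snp_panel(config.snps)
        hierarchy = core_io.read_panel_file(config.panel)
        gm = core_io.read_vcf(config.vcf, snp_panel)
        gm.validate_against_panel(snp_panel)
        hierarchy = hierarchy.subset([s for s in gm.samples if s in set(hierarchy.samples)])
        if set(gm.samples) - set(hierarchy.samples):
            missing = sorted(set(gm.samples) - set(hierarchy.samples))
            raise InputError(f"VCF sample(s) not in panel file: {missing[:5]}")
        manifest["stages"]["load_inputs"] = time.perf_counter() - t0
        logger.info("loaded %d samples x %d loci", gm.n_samples, gm.n_loci)

        for level in config.levels:
            level = core_io.resolve_level(level)
            sfx = LEVEL_SUFFIX[level]

            current_stage = f"diversity_{sfx}"
            t0 = time.perf_counter()
            freq = diversity.allele_frequencies(gm, hierarchy, level)
            freq_all = diversity.allele_frequencies(gm, hierarchy, "all")
            emit(freq.to_frame(), f"freqs_{sfx}.tsv")
            summ = diversity.diversity_summary(gm, hierarchy, level)
            emit(summ.by_locus, f"diversity_by_locus_{sfx}.tsv")
            emit(summ.summary, f"diversity_summary_{sfx}.tsv")
            emit(diversity.hwe_table(gm, hierarchy, level), f"hwe_{sfx}.tsv")
            manifest["stages"][current_stage] = time.perf_counter() - t0

            current_stage = f"differentiation_{sfx}"
            t0 = time.perf_counter()
            rng = stage_rng(config.seed, current_stage)
            fst_mat, fst_p = differentiation.pairwise_fst(
                gm, hierarchy, level, n_permutations=config.n_permutations, rng=rng
            )
            emit(fst_mat.to_frame(), f"pairwise_fst_{sfx}.tsv", index=True)
            emit(fst_p, f"fst_pvalues_{sfx}.tsv", index=True)
            nei = differentiation.nei_distance_matrix(freq)
            emit(nei.to_frame(), f"nei_distance_{sfx}.tsv", index=True)
            plf = differentiation.per_locus_global_fst(gm, hierarchy, level)
            emit(
                pd.DataFrame({"locus": list(plf), "fst": list(plf.values())}),
                f"per_locus_fst_{sfx}.tsv",
            )
            rows = []
            for mode in ("genic", "genotypic"):
                res = differentiation.differentiation_exact_tests(
                    gm, hierarchy, level, mode=mode, mc_params=config.mc_params(), rng=rng
                )
                for loc in res.per_locus_p:
                    rows.append((mode, loc, res.per_locus_p[loc], res.per_locus_se[loc]))
                rows.append((mode, "ALL(Fisher)", res.p, res.chi2))
            emit(pd.DataFrame(rows, columns=["mode", "locus", "p", "se_or_chi2"]), f"exact_tests_{sfx}.tsv")
            manifest["stages"][current_stage] = time.perf_counter() - t0

            current_stage = f"enrichment_{sfx}"
            t0 = time.perf_counter()
            em = enrichment.enrichment_matrix(freq, freq_all, snp_panel)
            emit(em.scores, f"enrichment_scores_{sfx}.tsv", index=True)
            row_order, _ = enrichment.cluster_order(em.scores, axis="rows")
            col_order, _ = enrichment.cluster_order(em.scores, axis="columns")
            (out / f"enrichment_row_order_{sfx}.txt").write_text("\n".join(row_order) + "\n")
            (out / f"enrichment_col_order_{sfx}.txt").write_text("\n".join(col_order) + "\n")
            if config.make_plots:
                enrichment.heatmap_png(em.scores, out / f"heatmap_{sfx}.png", row_order, col_order)
            manifest["stages"][current_stage] = time.perf_counter() - t0

            current_stage = f"prs_{sfx}"
            t0 = time.perf_counter()
            pres = prs.population_prs(gm, hierarchy, snp_panel, level, config.mode)
            emit(pres.individual, f"prs_individual_{sfx}.tsv")
            emit(pres.population, f"prs_population_{sfx}.tsv")
            groups = {
                pop: sub["score"].to_numpy()
                for pop, sub in pres.individual.groupby("population", sort=False)
            }
            try:
                tukey_p, tukey_summary = prs.anova_tukey(groups)
                emit(tukey_p, f"tukey_pvalues_{sfx}.tsv", index=True)
                manifest[f"anova_p_{sfx}"] = tukey_summary.attrs["anova_p"]
            except InputError as exc:
                logger.warning("Tukey comparison skipped at %s: %s", level, exc)
            emit(pres.individual.rename(columns={"score": "psPRS"}), f"prs_long_{sfx}.tsv")
            manifest["stages"][current_stage] = time.perf_counter() - t0

            current_stage = f"pcoa_{sfx}"
            t0 = time.perf_counter()
            dist = nei if config.distance_for_pcoa == "nei" else fst_mat
            dmat = dist.values.copy()
            if not np.isfinite(dmat).all():
                finite_max = np.nanmax(dmat[np.isfinite(dmat)])
                logger.warning("non-finite distances replaced by max finite value for PCoA")
                dmat[~np.isfinite(dmat)] = finite_max
            pres_pcoa = ordination.pcoa(
                core_io.LabelledSymmetricMatrix(dist.labels, dmat, dist.kind)
            )
            emit(pres_pcoa.coordinates, f"pcoa_coordinates_{sfx}.tsv", index=True)
            emit(
                pd.DataFrame(
                    {
                        "axis": [f"Axis{i + 1}" for i in range(len(pres_pcoa.eigenvalues))],
                        "eigenvalue": pres_pcoa.eigenvalues,
                        "percent_explained": list(pres_pcoa.percent_explained)
                        + [np.nan] * (len(pres_pcoa.eigenvalues) - len(pres_pcoa.proportion_explained)),
                    }
                ),
                f"pcoa_eigen_{sfx}.tsv",
            )
            if config.make_plots:
                hue = (
                    hierarchy.sub_to_super if level == "subpopulation" else None
                )
                ordination.scatter_png(pres_pcoa, out / f"pcoa_{sfx}.png", hue=hue)
            manifest["stages"][current_stage] = time.perf_counter() - t0

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed at {current_stage}: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise StageError(f"stage {current_stage} failed: {exc}") from exc
    finally:
        pd.DataFrame(collector.rows, columns=["stage", "message"]).to_csv(
            out / "warnings.tsv", sep="\t", index=False
        )
        logger.removeHandler(collector)
        logger.removeHandler(file_handler)
        file_handler.close()

    manifest["runtime_s"] = time.perf_counter() - t_all
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    write_metadata(
        out / "metadata.json",
        seed=config.seed,
        vcf=str(config.vcf),
        panel=str(config.panel),
        snps=str(config.snps),
        levels=list(config.levels),
        n_permutations=config.n_permutations,
        mc={"dememorization": config.mc_dememorization, "batches": config.mc_batches,
            "iterations_per_batch": config.mc_iterations},
        mode=config.mode,
    )
    return manifest
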