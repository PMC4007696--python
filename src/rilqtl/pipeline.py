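"""End-to-end orchestration: simulate -> QC -> phenotype stats -> QTL report.

A single YAML-serialisable configuration drives the whole pipeline; every
output file carries provenance header comments (package version, seed,
config hash) and reruns with the same seed and config are byte-identical.
"""

from __future__ import annotations

import copy
import logging
import time
from pathlib import Path

import pandas as pd

from . import blup, geno, pheno, qtl, simdata
from ._util import config_hash, provenance_comments, write_csv_with_header

logger = logging.getLogger("rilqtl")

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "n_lines": 118,
        "n_self_generations": 7,
        "markers_per_chromosome": 2000,
        "qtls": [list(q) for q in simdata.DEFAULT_QTL_EFFECTS],
        "heritability": 0.94,
        "replicates": 2,
        "plants_per_plot": 7,
        "baseline": 30.0,
        "missing_rate": 0.20,
        "distorted_chromosome": 10,
        "distortion_allele_freq": 0.25,
    },
    "qc": {
        "max_missing": 0.20,
        "maf": 0.40,
        "maf_chr": {10: 0.30},
        "impute": "knn",
        "window": 10,
        "k": 5,
    },
    "scan": {
        "trait": "rnrg",
        "trait_name": "ALT",
        "alpha": 0.001,
        "epistasis": False,
        "ci": "drop:1.0",
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict | None) -> dict:
    """Merge with defaults and check every threshold before any computation."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    sim, qc, scan = cfg["simulate"], cfg["qc"], cfg["scan"]
    if cfg.get("seed") is None:
        raise ValueError("config: seed is mandatory")
    if sim["n_lines"] < 1 or sim["n_self_generations"] < 1:
        raise ValueError("config: n_lines and n_self_generations must be >= 1")
    if not 0 < sim["heritability"] < 1:
        raise ValueError("config: heritability must be in (0, 1)")
    if not 0 <= sim["missing_rate"] <= 1:
        raise ValueError("config: missing_rate must be in [0, 1]")
    if not 0 <= qc["max_missing"] <= 1:
        raise ValueError("config: qc.max_missing must be in [0, 1]")
    if not 0 <= qc["maf"] <= 0.5:
        raise ValueError("config: qc.maf must be in [0, 0.5]")
    for c, thr in (qc.get("maf_chr") or {}).items():
        if not 0 <= thr <= 0.5:
            raise ValueError(f"config: qc.maf_chr[{c}] must be in [0, 0.5]")
    if not 0 < scan["alpha"] < 1:
        raise ValueError("config: scan.alpha must be in (0, 1)")
    ci = str(scan["ci"])
    mode = ci.split(":")[0]
    if mode not in ("drop", "bootstrap"):
        raise ValueError("config: scan.ci must be 'drop:<units>' or 'bootstrap:<n>'")
    return cfg


def _parse_ci(ci: str) -> tuple[str, float]:
    mode, _, val = str(ci).partition(":")
    return mode, float(val) if val else (1.0 if mode == "drop" else 200)


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.2f s", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.2f s: %s", self.name, dt, exc)
        return False


def run_pipeline(config: dict | None, out_dir) -> dict:
    """Run simulate -> degrade -> impute -> filter -> pheno -> scan -> report.

    Returns a dict with the in-memory results and the artifact paths
    written under ``out_dir``.
    """
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    chash = config_hash(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim, qc, scan_cfg = cfg["simulate"], cfg["qc"], cfg["scan"]

    with _Stage("simulate"):
        gmap = simdata.maize_like_map(sim["markers_per_chromosome"])
        clean = simdata.simulate_ril_genomes(
            gmap, sim["n_lines"], sim["n_self_generations"], seed=seed
        )
        spec = simdata.QtlSpec(
            qtls=[tuple(q) for q in sim["qtls"]],
            heritability=sim["heritability"],
            replicates=sim["replicates"],
            plants_per_plot=sim["plants_per_plot"],
            baseline=sim["baseline"],
        )
        phenotypes = simdata.simulate_phenotypes(clean, spec, seed=seed + 1)
        raw = simdata.degrade_genotypes(
            clean,
            missing_rate=sim["missing_rate"],
            seed=seed + 2,
            distorted_chromosome=sim["distorted_chromosome"],
            distortion_allele_freq=sim["distortion_allele_freq"],
        )
        geno.write_genotypes(raw, out / "genotypes_raw.tsv",
                             header_comments=provenance_comments(seed, chash))
        phenotypes.data.pipe(write_csv_with_header, out / "phenotypes.csv", seed, chash)

    with _Stage("qc"):
        g = raw
        if qc["impute"] == "knn":
            g = geno.impute_missing(g, window_halfwidth=qc["window"], k_neighbors=qc["k"])
        filtered, report = geno.filter_markers(
            g,
            max_missing_fraction=qc["max_missing"],
            maf_default=qc["maf"],
            maf_per_chromosome={int(k): v for k, v in (qc.get("maf_chr") or {}).items()},
        )
        logger.info("qc: %s", report)
        geno.write_genotypes(filtered, out / "genotypes_filtered.tsv",
                             header_comments=provenance_comments(seed, chash))
        write_csv_with_header(report.per_chromosome, out / "filter_report.csv", seed, chash)

    with _Stage("pheno"):
        traits = pheno.line_traits(phenotypes)
        plot = pheno.plot_traits(phenotypes)
        trait_col = scan_cfg["trait"]
        if trait_col not in traits.columns:
            raise ValueError(f"unknown trait {trait_col!r}; have {list(traits.columns)}")
        anova = pheno.anova_crd(plot.rename(columns={trait_col: "value"}))
        summary = pheno.trait_summary(anova)
        write_csv_with_header(traits, out / "line_traits.csv", seed, chash)
        write_csv_with_header(anova.table(), out / "anova.csv", seed, chash)

    with _Stage("scan"):
        trait = traits.rename(columns={trait_col: "value"})[["line", "value"]]
        mode, val = _parse_ci(scan_cfg["ci"])
        model = qtl.StepwiseQtlModel(filtered, trait, alpha=scan_cfg["alpha"])
        results = model.fit(
            epistasis=bool(scan_cfg["epistasis"]),
            ci_method=mode,
            ci_drop=val if mode == "drop" else 1.0,
            n_boot=int(val) if mode == "bootstrap" else 200,
            seed=seed + 3,
        )
        report_df = results.report(scan_cfg["trait_name"])
        write_csv_with_header(results.scan, out / "scan.csv", seed, chash)
        with open(out / "qtl_report.csv", "w") as fh:
            for c in provenance_comments(seed, chash):
                fh.write(f"# {c}\n")
            fh.write(f"# r2_total_pct = {report_df.attrs['r2_total_pct']}\n")
            report_df.to_csv(fh, index=False)

    return {
        "config": cfg,
        "genotypes_clean": clean,
        "genotypes_raw": raw,
        "genotypes_filtered": filtered,
        "filter_report": report,
        "phenotypes": phenotypes,
        "line_traits": traits,
        "anova": anova,
        "trait_summary": summary,
        "qtl_results": results,
        "qtl_report": report_df,
        "out_dir": out,
    }
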