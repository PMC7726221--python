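"""End-to-end pipeline: prep -> blocking -> matrices -> CV -> epistasis -> profiles."""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .genomic_matrices import build_grms, build_model_matrices
from .greml_gblup import greml_fit, per_locus_heritability
from .haploblock import (
    block_statistics,
    blocks_fixed_count,
    blocks_fixed_distance,
    blocks_from_intervals,
    enumerate_haplotypes,
)
from .pheno_prep import boxcox_fit, build_design, remove_outliers
from .synthetic_data import (
    FixedEffectsSpec,
    SimConfig,
    TraitArchitecture,
    simulate_annotations,
    simulate_genotypes,
    simulate_phenotypes,
)
from .validation import ModelSpec, HAPLOTYPE_MODELS, make_folds, model_grid
from .epistasis_heritability import BASELINE_FOR, estimate_epistasis

logger = logging.getLogger("haplopred")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise PipelineError(f"[{name}] {exc}") from exc

        return inner

    return wrap


def load_config(path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:12]


@_stage("data")
def _stage_data(config):
    if "simulate" in config:
        sim = dict(config["simulate"])
        trait = TraitArchitecture(**sim.pop("trait", {}))
        blocking_for_truth = sim.pop("truth_blocking", {"method": "distance", "window_kb": 100})
        chroms = [tuple(c) for c in sim.pop("chromosomes", [("1", 5_000_000)])]
        if "maf_spectrum" in sim:
            sim["maf_spectrum"] = tuple(sim["maf_spectrum"])
        seed = int(config.get("seed", 0))
        sc = SimConfig(chromosomes=chroms, seed=seed, **sim)
        panel = simulate_genotypes(sc)
        intervals = simulate_annotations(chroms, config.get("n_intervals", 0), seed=seed + 1)
        if blocking_for_truth["method"] == "distance":
            truth_blocks = blocks_fixed_distance(panel.snp_map, blocking_for_truth["window_kb"])
        else:
            truth_blocks = blocks_fixed_count(panel.snp_map, blocking_for_truth["s"])
        enumerate_haplotypes(truth_blocks, panel)
        pheno, truth = simulate_phenotypes(
            panel, truth_blocks, trait, FixedEffectsSpec(), seed=seed + 2
        )
        return panel, intervals, pheno, truth
    inputs = config["inputs"]
    panel = hio.read_phased_vcf(inputs["vcf"], strict=inputs.get("strict", True))
    pheno = hio.read_phenotypes(inputs["phenotypes"])
    intervals = hio.read_bed(inputs["bed"]) if "bed" in inputs else pd.DataFrame(
        columns=["chrom", "start", "end", "name", "cls"]
    )
    return panel, intervals, pheno, None


@_stage("prep")
def _stage_prep(config, panel, pheno):
    trait_cfg = config.get("trait", {})
    y = pheno["y"].to_numpy(dtype=float)
    keep = np.isfinite(y)
    pheno = pheno.loc[keep].reset_index(drop=True)
    order = {s: i for i, s in enumerate(panel.samples)}
    individual_idx = pheno["id"].map(order).to_numpy()

    lam = None
    series = pd.Series(pheno["y"].to_numpy())
    if trait_cfg.get("outlier_sd"):
        series, removed = remove_outliers(series, trait_cfg["outlier_sd"])
        if len(removed):
            logger.info("removed %d outliers", len(removed))
            pheno = pheno.loc[series.index].reset_index(drop=True)
            individual_idx = individual_idx[series.index.to_numpy()]
    values = series.to_numpy()
    if trait_cfg.get("transform", False):
        lam, values = boxcox_fit(values, shift=True)
    pheno = pheno.assign(y=values)
    X, x_names = build_design(
        pheno,
        factors=trait_cfg.get("factors", ["sex"]),
        covariates=trait_cfg.get("covariates", ["age"]),
    )
    return pheno, individual_idx, X, x_names, lam


@_stage("blocks")
def _stage_blocks(config, panel, intervals):
    blocksets = {}
    for spec in config.get("blocking", [{"method": "distance", "window_kb": 100}]):
        method = spec["method"]
        if method == "distance":
            label = f"{spec['window_kb']:g}kb"
            bs = blocks_fixed_distance(panel.snp_map, spec["window_kb"])
        elif method == "count":
            label = f"{spec['s']}snp"
            bs = blocks_fixed_count(panel.snp_map, spec["s"])
        elif method == "intervals":
            label = spec.get("cls", "gene")
            bs = blocks_from_intervals(
                panel.snp_map,
                intervals,
                flank_kb=spec.get("flank_kb", 2.0),
                split_kb=spec.get("split_kb", 150.0),
                source=spec.get("cls"),
            )
        else:
            raise ValueError(f"unknown blocking method {method!r}")
        if not bs.blocks:
            raise ValueError(f"blocking {label} produced no blocks")
        enumerate_haplotypes(bs, panel)
        blocksets[label] = bs
    return blocksets


def run_pipeline(config: dict, output_dir=None) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a dict of result tables; when ``output_dir`` (or
    ``config['output_dir']``) is set, every table is also written as TSV
    with provenance headers carrying the config hash and seed.
    """
    seed = int(config.get("seed", 0))
    chash = config_hash(config)
    provenance = {"config_hash": chash, "seed": seed, "haplopred": "0.1.0"}

    panel, intervals, pheno, truth = _stage_data(config)

    maf_min = config.get("maf_min", 0.0)
    if maf_min > 0:
        keep = np.flatnonzero(panel.snp_map["maf"].to_numpy() >= maf_min)
        panel = panel.subset_snps(keep)

    pheno, individual_idx, X, x_names, lam = _stage_prep(config, panel, pheno)
    blocksets = _stage_blocks(config, panel, intervals)

    try:
        mm_snp = build_model_matrices(panel, components=("snp_additive", "snp_dominance"))
        snp_grms = build_grms(mm_snp)
        grm_sets = {}
        hap_mms = {}
        for label, bs in blocksets.items():
            mm_h = build_model_matrices(panel, bs, components=("hap_additive",))
            hap_grm = build_grms(mm_h)
            hap_mms[label] = mm_h
            grms = snp_grms.as_dict() | hap_grm.as_dict()
            sub = np.ix_(individual_idx, individual_idx)
            grm_sets[label] = {k: g[sub] for k, g in grms.items()}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[matrices] {exc}") from exc

    y = pheno["y"].to_numpy(dtype=float)
    try:
        plan = make_folds(pheno["id"], k=config.get("cv", {}).get("k", 10), seed=config.get("cv", {}).get("seed", seed))
        models = config.get("models", [1, 2, 3, 4, 5, 6])
        summary = model_grid(y, X, grm_sets, models, plan, refit_per_fold=config.get("cv", {}).get("refit_per_fold", True))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[cv] {exc}") from exc

    try:
        fit_rows = []
        epi_rows = []
        fits = {}
        for label, grms in grm_sets.items():
            for mid in sorted(set(models) | {BASELINE_FOR[m] for m in models if m in HAPLOTYPE_MODELS}):
                spec = ModelSpec(mid)
                key = (label, mid) if spec.has_haplotypes else ("snp", mid)
                if key in fits:
                    continue
                fit = greml_fit(y, X, {c: grms[c] for c in spec.components})
                fits[key] = fit
                df = fit.to_frame()
                df.insert(0, "model", mid)
                df.insert(0, "blocking", key[0])
                fit_rows.append(df)
            for mid in models:
                if mid not in HAPLOTYPE_MODELS:
                    continue
                est = estimate_epistasis(
                    fits[(label, mid)], fits[("snp", BASELINE_FOR[mid])], mid
                )
                epi_rows.append(
                    (
                        label,
                        mid,
                        est.h_g2,
                        est.h_s2,
                        est.h_e2,
                        est.h_er2_pct,
                        est.haplotype_loss,
                    )
                )
        fit_report = pd.concat(fit_rows, ignore_index=True)
        epistasis_report = pd.DataFrame(
            epi_rows,
            columns=["blocking", "model", "h_g2", "h_s2", "h_e2", "h_er2_pct", "loss_flag"],
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[epistasis] {exc}") from exc

    try:
        profiles = {}
        best = summary.loc[summary["best"]].iloc[0]
        best_label = best["blocking"] if best["blocking"] in blocksets else next(iter(blocksets))
        best_mid = int(best["model"])
        spec = ModelSpec(best_mid)
        mm_full = build_model_matrices(
            panel,
            blocksets[best_label] if spec.has_haplotypes else None,
            components=spec.components,
        )
        key = (best_label, best_mid) if spec.has_haplotypes else ("snp", best_mid)
        sub = np.ix_(individual_idx, individual_idx)
        mm_sub = mm_full
        # restrict model matrices to phenotyped individuals for the profile
        import copy

        mm_sub = copy.copy(mm_full)
        for attr in ("w_alpha", "w_delta", "w_alpha_h"):
            w = getattr(mm_full, attr)
            if w is not None:
                setattr(mm_sub, attr, w[individual_idx])
        profiles = per_locus_heritability(
            fits[key],
            mm_sub,
            grm_sets[best_label],
            y,
            X,
            panel.snp_map,
            blockset=blocksets[best_label] if spec.has_haplotypes else None,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"[profiles] {exc}") from exc

    stats = pd.DataFrame(
        [block_statistics(bs, panel.snp_map).to_series().rename(label) for label, bs in blocksets.items()]
    )

    results = {
        "cv_summary": summary,
        "fit_report": fit_report,
        "epistasis": epistasis_report,
        "block_stats": stats.reset_index(names="blocking"),
        "profiles": profiles,
        "lambda": lam,
        "truth": truth,
    }

    out = output_dir or config.get("output_dir")
    if out:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_table(summary, out / "cv_summary.tsv", provenance)
        hio.write_table(fit_report, out / "fit_report.tsv", provenance)
        hio.write_table(epistasis_report, out / "epistasis.tsv", provenance)
        hio.write_table(results["block_stats"], out / "block_stats.tsv", provenance)
        for comp, df in profiles.items():
            hio.write_table(df, out / f"profile_{comp}.tsv", provenance)
        for label, bs in blocksets.items():
            hio.write_table(bs.to_frame(), out / f"blocks_{label}.tsv", provenance)
    return results
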