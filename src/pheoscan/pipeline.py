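"""Pipeline configuration and sequential orchestration.

One config object is the single source of truth for every threshold used
anywhere in the pipeline; no stage hard-codes a constant.  ``run_pipeline``
executes the enabled stages in method order — simulate (or load) -> QC ->
kinship + mixed-model GWAS -> dominance / epistasis at the candidate loci
-> exhaustive encoding + interaction model search -> prediction on the
held-out cohort — writing tidy TSV outputs and a machine-readable JSON
manifest (inputs, seeds, thresholds, per-stage summaries) from which any
run is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import architecture, color_scale, gwas, io_qc, model_search, simulate
from .predict import predict as apply_model
from .predict import split_cohorts, validation_report

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "save_config"]

log = logging.getLogger("pheoscan")


@dataclass
class PipelineConfig:
    """All thresholds, seeds and stage toggles for one pipeline run."""

    # stage toggles
    do_gwas: bool = True
    do_architecture: bool = True
    do_model_search: bool = True
    do_validate: bool = True
    # simulation (used when genotype_path is unset)
    n_breeds: int = 63
    dogs_per_breed: int = 49
    n_background_markers: int = 2_000
    fst: float = 0.25
    rater_error_rate: float = 0.03
    target_r2: float = 0.73
    residual_sd: float | None = None  # None -> calibrate to target_r2
    # input paths (optional; override simulation)
    genotype_path: str | None = None
    genotype_dialect: str = "tsv"
    phenotype_path: str | None = None
    # QC thresholds
    marker_missingness: float = 0.05
    sample_missingness: float = 0.03
    pi_hat: float = 0.45
    prune_relatedness: bool = False  # quadratic; off by default on large panels
    min_maf: float = 0.001
    # GWAS
    gwas_alpha: float = 0.05
    gwas_mode: str = "quantitative"
    fast_lambda: bool = False  # reuse the null-model variance ratio (approximate)
    # architecture / model search
    epistasis_alpha: float = 0.05
    pre_threshold: float = 1e-3
    response_scale: str = "raw"
    # validation
    train_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("marker_missingness", 0, 1),
            ("sample_missingness", 0, 1),
            ("pi_hat", 0, 1),
            ("min_maf", 0, 0.5),
            ("gwas_alpha", 0, 1),
            ("epistasis_alpha", 0, 1),
            ("rater_error_rate", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return PipelineConfig(**data)


def _stage(name):
    """Halt with the failing stage's name attached."""
    class _ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return False

    return _ctx()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the enabled stages and write outputs + manifest under ``outdir``.

    Returns the manifest dict.  Fully deterministic given the config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    truth = None

    with _stage("input"):
        if config.genotype_path:
            gm = io_qc.read_genotypes(config.genotype_path, config.genotype_dialect)
            import pandas as pd

            ph = pd.read_csv(config.phenotype_path, sep="\t")
            records = [
                io_qc.PhenotypeRecord(
                    sample_id=str(r.sample_id),
                    breed=str(r.breed),
                    phenotype=None if pd.isna(r.phenotype) else int(r.phenotype),
                )
                for r in ph.itertuples(index=False)
            ]
            manifest["stages"]["input"] = {
                "source": config.genotype_path,
                "n_samples": gm.n_samples,
                "n_markers": gm.n_markers,
            }
        else:
            sim_cfg = simulate.SimConfig(
                n_breeds=config.n_breeds,
                dogs_per_breed=config.dogs_per_breed,
                n_background_markers=config.n_background_markers,
                fst=config.fst,
                rater_error_rate=config.rater_error_rate,
                residual_sd=config.residual_sd
                if config.residual_sd is not None
                else simulate.calibrate_residual_sd(
                    simulate.table_shaped_model(),
                    simulate.QTL_FREQS,
                    config.target_r2,
                    mode="recorded",
                    rater_error_rate=config.rater_error_rate,
                    n_sim=20_000,
                    seed=config.seed,
                    fst=config.fst,
                    n_breeds=config.n_breeds,
                ),
                seed=config.seed,
            )
            sim = simulate.simulate_dataset(sim_cfg)
            gm, records, truth = sim.genotypes, sim.samples, sim
            sim.breed_freqs.to_csv(outdir / "true_breed_freqs.tsv", sep="\t")
            manifest["stages"]["input"] = {
                "source": "simulated",
                "residual_sd": sim_cfg.residual_sd,
                "n_samples": gm.n_samples,
                "n_markers": gm.n_markers,
            }

    with _stage("qc"):
        gm, rep_m = io_qc.filter_marker_missingness(gm, config.marker_missingness)
        gm, rep_s = io_qc.filter_sample_missingness(gm, config.sample_missingness)
        removed_rel: list[str] = []
        if config.prune_relatedness:
            retained, rep_r = io_qc.prune_relatives(gm, config.pi_hat)
            removed_rel = rep_r.removed
            keep_idx = [i for i, s in enumerate(gm.sample_ids) if s in set(retained)]
            gm = gm.subset(sample_idx=keep_idx)
        gm, rep_f = io_qc.filter_maf(gm, config.min_maf, config.marker_missingness)
        kept = set(gm.sample_ids)
        records = [r for r in records if r.sample_id in kept]
        manifest["stages"]["qc"] = {
            "markers_removed_missingness": rep_m.n_removed,
            "samples_removed_missingness": rep_s.n_removed,
            "samples_removed_relatedness": len(removed_rel),
            "markers_removed_maf": rep_f.n_removed,
            "n_samples": gm.n_samples,
            "n_markers": gm.n_markers,
        }
        log.info("qc: %s", manifest["stages"]["qc"])

    with _stage("split"):
        discovery, validation = split_cohorts(
            records, config.train_frac, seed=config.seed
        )
        disc_ids = [r.sample_id for r in discovery]
        val_ids = [r.sample_id for r in validation]
        id_index = {s: i for i, s in enumerate(gm.sample_ids)}
        gm_disc = gm.subset(sample_idx=[id_index[s] for s in disc_ids])
        gm_val = gm.subset(sample_idx=[id_index[s] for s in val_ids])
        y_disc = np.array([r.phenotype for r in discovery], dtype=float)
        y_val = np.array([r.phenotype for r in validation], dtype=float)
        manifest["stages"]["split"] = {
            "n_discovery": len(discovery),
            "n_validation": len(validation),
        }

    loci = [l for l in simulate.QTL_LOCI if l in set(gm.markers["marker_id"])]
    dis_dosages = {l: gm_disc.dosage_of(l) for l in loci}
    val_dosages = {l: gm_val.dosage_of(l) for l in loci}

    if config.do_gwas:
        with _stage("gwas"):
            K = gwas.compute_kinship(gm_disc)
            results = gwas.association_scan(
                gm_disc,
                y_disc,
                K,
                mode=config.gwas_mode,
                reuse_null_lambda=config.fast_lambda,
                min_maf=config.min_maf,
                max_missing=config.marker_missingness,
            )
            df = gwas.results_frame(results)
            df.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
            thr = gwas.bonferroni_threshold(len(results), config.gwas_alpha)
            n_sig = int((df["p_wald"] < thr).sum())
            top = df.sort_values("p_wald").iloc[0]
            manifest["stages"]["gwas"] = {
                "n_tests": len(results),
                "bonferroni_p": thr,
                "n_significant": n_sig,
                "top_marker": str(top["marker"]),
                "top_beta": float(top["beta"]),
            }
            log.info("gwas: %s", manifest["stages"]["gwas"])

    if config.do_architecture:
        with _stage("architecture"):
            doms = [
                architecture.estimate_dominance(y_disc, dis_dosages[l], locus=l)
                for l in loci
            ]
            epis = architecture.epistasis_scan(
                y_disc, dis_dosages, alpha=config.epistasis_alpha
            )
            architecture.epistasis_frame(epis).to_csv(
                outdir / "epistasis.tsv", sep="\t", index=False
            )
            manifest["stages"]["architecture"] = {
                "dominance": {e.locus: round(e.d, 6) for e in doms},
                "n_epistasis_significant": sum(e.significant for e in epis),
            }

    best_reduced = None
    if config.do_model_search:
        with _stage("model_search"):
            split_spec = model_search.ModelSpec(
                loci=tuple(loci),
                encodings=(model_search.HET_HOM_SPLIT,) * len(loci),
                response_scale="standardized",
            )
            y_std, _, _ = color_scale.standardize_phenotype(y_disc)
            split_fit = model_search.fit_model(y_std, dis_dosages, split_spec)
            alternatives = {}
            for l in loci:
                b1, b2 = split_fit.coef[f"{l}_1"], split_fit.coef[f"{l}_2"]
                ratio = b1 / b2 if b2 != 0 else np.inf
                dom_alt = (
                    model_search.RED_RECESSIVE
                    if abs(ratio) < abs(ratio - 1)
                    else model_search.RED_DOMINANT
                )
                alternatives[l] = (model_search.ADDITIVE, dom_alt)
            def _fit_all(specs):
                # candidate models that are unidentifiable on this sample
                # (collinear terms, e.g. an interaction duplicating a rare
                # main effect) are dropped from the ranking
                fits = []
                for s in specs:
                    try:
                        fits.append(model_search.fit_model(y_disc, dis_dosages, s))
                    except ValueError:
                        continue
                return fits

            specs = model_search.enumerate_model_space(
                tuple(loci), alternatives, include_base=True,
                response_scale=config.response_scale,
            )
            fits = _fit_all(specs)
            best_dom = model_search.select_best(fits)[0]

            sig_pairs = tuple(
                (e.locus_a, e.locus_b)
                for e in sorted(
                    architecture.epistasis_scan(
                        y_disc, dis_dosages, alpha=config.epistasis_alpha
                    ),
                    key=lambda e: -e.stat,
                )
                if e.significant
            )
            specs2 = model_search.enumerate_model_space(
                tuple(loci), alternatives, sig_pairs, include_base=True,
                response_scale=config.response_scale,
            )
            fits2 = _fit_all(specs2)
            best_full = model_search.select_best(fits2)[0]
            best_reduced = model_search.prune_by_pre(
                best_full, y_disc, dis_dosages, config.pre_threshold
            )
            lrt_p = model_search.likelihood_ratio_test(best_reduced, best_full)
            manifest["stages"]["model_search"] = {
                "n_models_encoding": len(specs),
                "n_models_epistasis": len(specs2),
                "n_models_unfittable": (len(specs) - len(fits))
                + (len(specs2) - len(fits2)),
                "best_dominance_encodings": dict(
                    zip(best_dom.spec.loci, best_dom.spec.encodings)
                ),
                "best_dominance_adj_r2": round(best_dom.adj_r2, 6),
                "best_full_terms": list(best_full.terms),
                "best_full_adj_r2": round(best_full.adj_r2, 6),
                "reduced_terms": list(best_reduced.terms),
                "reduced_adj_r2": round(best_reduced.adj_r2, 6),
                "lrt_reduced_vs_full_p": lrt_p,
            }
            log.info("model_search: %s", manifest["stages"]["model_search"])

    if config.do_validate and best_reduced is not None:
        with _stage("validate"):
            preds = apply_model(best_reduced, val_dosages)
            breeds = [
                r.breed if not r.breed.startswith("mix") else "mixed breed"
                for r in validation
            ]
            report = validation_report(
                preds, y_val, groups=breeds, model_df=best_reduced.n_terms
            )
            import pandas as pd

            pd.DataFrame(
                {
                    "sample_id": val_ids,
                    "breed": breeds,
                    "observed": y_val,
                    "predicted": preds,
                }
            ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
            manifest["stages"]["validate"] = {
                "n": report.n,
                "r2": round(report.r2, 6),
                "adj_r2": round(report.adj_r2, 6),
                "within1_overall": round(report.within1_overall, 6),
            }
            log.info("validate: %s", manifest["stages"]["validate"])

    if truth is not None and best_reduced is not None:
        true_terms = set(truth.config.true_model.term_names())
        manifest["truth_recovery"] = {
            "true_terms": sorted(true_terms),
            "recovered": sorted(true_terms) == sorted(best_reduced.terms)
            or set(best_reduced.terms) >= true_terms,
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
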