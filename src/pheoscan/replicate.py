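"""Refit the candidate-locus models on the original cohort file.

The journal's supplementary data file for the pheomelanin-intensity study
carries, per dog, the breed, six-point phenotype, (optionally) the
discovery/validation cohort label, and genotypes at the five top GWAS
markers.  Given that file this module reproduces the headline
candidate-locus statistics: the additive / best-dominance / epistasis
five-marker model fits, the CFA2-only and two-locus models, the
CFA15 x CFA20 interaction coefficient, the reduced-vs-full likelihood
ratio test, and the held-out validation metrics.

The parser is deliberately tolerant about column naming (the file is a
journal export, not a package-controlled format): marker columns are found
by their published ids, genotypes may be dosages or allele pairs, and a
missing cohort column falls back to the package's own stratified 70:30
split, in which case replication is approximate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import epistasis_scan
from .io_qc import PhenotypeRecord
from .model_search import (
    ADDITIVE,
    RED_DOMINANT,
    RED_RECESSIVE,
    ModelSpec,
    fit_model,
    likelihood_ratio_test,
)
from .predict import predict as apply_model
from .predict import split_cohorts, validation_report

#: Published top markers: array id -> (locus label, red/effect allele).
TOP_MARKERS = {
    "BICF2P1302896": ("CFA2", "A"),
    "BICF2G630433130": ("CFA15", "G"),
    "chr18_12910382": ("CFA18", "G"),
    "BICF2P828524": ("CFA20", "G"),
    "BICF2G630655755": ("CFA21", "A"),
}

LOCI = ("CFA2", "CFA15", "CFA18", "CFA20", "CFA21")
BEST_ENCODINGS = (ADDITIVE, RED_RECESSIVE, RED_DOMINANT, ADDITIVE, RED_DOMINANT)


@dataclass
class ReplicationResult:
    n_discovery: int
    n_validation: int
    has_cohort_labels: bool
    additive_adj_r2: float
    dominance_adj_r2: float
    best_full_adj_r2: float
    reduced_adj_r2: float
    two_locus_adj_r2: float
    cfa2_only_adj_r2: float
    beta3_cfa15_cfa20: float
    lrt_reduced_vs_full_p: float
    lrt_reduced_vs_additive_terms: tuple
    validation_adj_r2: float
    within1_overall: float
    within1_mixed_breed: float | None


def _find_column(columns, *needles) -> str | None:
    for col in columns:
        low = col.lower()
        if any(n.lower() in low for n in needles):
            return col
    return None


def _dosage_from_column(values: pd.Series, red_allele: str) -> np.ndarray:
    """Dosage of the red allele from numeric dosages or allele-pair strings."""
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.notna().mean() > 0.5:
        return numeric.to_numpy(dtype=float)
    out = np.full(len(values), np.nan)
    for i, v in enumerate(values.astype(str)):
        alleles = re.findall(r"[ACGT]", v.upper())
        if len(alleles) == 2:
            out[i] = sum(a == red_allele for a in alleles)
    return out


def load_cohort_table(path) -> tuple[pd.DataFrame, dict, bool]:
    """Read the supplementary cohort file into (table, dosage dict, labeled)."""
    df = pd.read_csv(Path(path), sep=None, engine="python")
    dosages = {}
    for marker_id, (locus, red) in TOP_MARKERS.items():
        col = _find_column(df.columns, marker_id, locus + "_") or _find_column(
            df.columns, locus
        )
        if col is None:
            raise ValueError(f"cannot locate genotype column for {marker_id}")
        dosages[locus] = _dosage_from_column(df[col], red)
    pheno_col = _find_column(df.columns, "phenotype", "intensity", "six")
    breed_col = _find_column(df.columns, "breed")
    if pheno_col is None or breed_col is None:
        raise ValueError("cannot locate phenotype/breed columns")
    cohort_col = _find_column(df.columns, "cohort", "dataset", "partition", "split")
    out = pd.DataFrame(
        {
            "sample_id": df[_find_column(df.columns, "sample", "dog", "id") or df.columns[0]].astype(str),
            "breed": df[breed_col].astype(str),
            "phenotype": pd.to_numeric(df[pheno_col], errors="coerce"),
        }
    )
    if cohort_col is not None:
        lab = df[cohort_col].astype(str).str.lower()
        out["cohort"] = np.where(
            lab.str.contains("disc|train"), "discovery", "validation"
        )
    return out, dosages, cohort_col is not None


def replicate_candidate_models(path, seed: int = 0) -> ReplicationResult:
    """Reproduce the published five-marker model statistics from the file."""
    table, dosages, labeled = load_cohort_table(path)
    ok = table["phenotype"].notna().to_numpy()
    for g in dosages.values():
        ok &= ~np.isnan(g)
    table = table.loc[ok].reset_index(drop=True)
    dosages = {l: g[ok] for l, g in dosages.items()}

    if labeled:
        is_disc = (table["cohort"] == "discovery").to_numpy()
    else:
        records = [
            PhenotypeRecord(
                sample_id=r.sample_id, breed=r.breed, phenotype=int(r.phenotype)
            )
            for r in table.itertuples(index=False)
        ]
        disc, _ = split_cohorts(records, 0.7, seed=seed)
        disc_ids = {r.sample_id for r in disc}
        is_disc = table["sample_id"].isin(disc_ids).to_numpy()

    y = table["phenotype"].to_numpy(dtype=float)
    d_disc = {l: g[is_disc] for l, g in dosages.items()}
    d_val = {l: g[~is_disc] for l, g in dosages.items()}
    y_disc, y_val = y[is_disc], y[~is_disc]

    additive = fit_model(
        y_disc, d_disc, ModelSpec(loci=LOCI, encodings=(ADDITIVE,) * 5)
    )
    dominance = fit_model(
        y_disc, d_disc, ModelSpec(loci=LOCI, encodings=BEST_ENCODINGS)
    )
    full = fit_model(
        y_disc,
        d_disc,
        ModelSpec(
            loci=LOCI,
            encodings=BEST_ENCODINGS,
            interactions=(
                ("CFA15", "CFA20"),
                ("CFA15", "CFA21"),
                ("CFA18", "CFA20"),
                ("CFA18", "CFA21"),
            ),
        ),
    )
    # the published reduced model: drops the CFA21 main effect and both
    # CFA21 interactions from the full model, keeping CFA2, CFA15_2,
    # CFA15_2 x CFA20, CFA18_red_dom, CFA18_red_dom x CFA20 and CFA20
    reduced = fit_model(
        y_disc,
        d_disc,
        ModelSpec(
            loci=LOCI,
            encodings=BEST_ENCODINGS,
            interactions=(("CFA15", "CFA20"), ("CFA18", "CFA20")),
            excluded_terms=frozenset({"CFA21_red_dom"}),
        ),
    )
    two_locus = fit_model(
        y_disc,
        d_disc,
        ModelSpec(
            loci=("CFA15", "CFA20"),
            encodings=(RED_RECESSIVE, ADDITIVE),
            interactions=(("CFA15", "CFA20"),),
        ),
    )
    cfa2_only = fit_model(
        y_disc, d_disc, ModelSpec(loci=("CFA2",), encodings=(ADDITIVE,))
    )
    epi = epistasis_scan(
        y_disc,
        {"CFA15": d_disc["CFA15"], "CFA20": d_disc["CFA20"]},
        pairs=[("CFA15", "CFA20")],
    )[0]

    preds = apply_model(reduced, d_val)
    groups = [
        "mixed breed" if "mix" in b.lower() else b for b in table["breed"][~is_disc]
    ]
    report = validation_report(
        preds, y_val, groups=groups, model_df=reduced.n_terms
    )
    return ReplicationResult(
        n_discovery=int(is_disc.sum()),
        n_validation=int((~is_disc).sum()),
        has_cohort_labels=labeled,
        additive_adj_r2=additive.adj_r2,
        dominance_adj_r2=dominance.adj_r2,
        best_full_adj_r2=full.adj_r2,
        reduced_adj_r2=reduced.adj_r2,
        two_locus_adj_r2=two_locus.adj_r2,
        cfa2_only_adj_r2=cfa2_only.adj_r2,
        beta3_cfa15_cfa20=epi.beta3,
        lrt_reduced_vs_full_p=likelihood_ratio_test(reduced, full),
        lrt_reduced_vs_additive_terms=tuple(additive.terms),
        validation_adj_r2=report.adj_r2,
        within1_overall=report.within1_overall,
        within1_mixed_breed=report.within1_by_group.get("mixed breed"),
    )
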