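"""Cohort partitioning, genotype-based prediction and validation metrics.

The discovery/validation protocol stratifies dogs by breed x six-point
phenotype value, splits each stratum 70:30 (seeded), fits the predictive
model on discovery only, and evaluates on validation with coefficients
frozen: out-of-sample R^2 = 1 - SSE/SST, adjusted by the training model's
parameter count, plus the fraction of dogs whose continuous prediction is
within one point of the observed integer value, overall and per breed
group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import PhenotypeRecord
from .model_search import FitResult

__all__ = [
    "PredictionReport",
    "predict",
    "split_cohorts",
    "validation_report",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_cohorts(
    records: list, train_frac: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Stratified discovery/validation split by (breed, phenotype value).

    Per stratum of size m the discovery share is round(train_frac * m),
    half up; single-member strata therefore go to discovery.  Sampling
    within stratum is seeded and reproducible; record order is preserved
    within each cohort.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault((rec.breed, rec.phenotype), []).append(i)
    train_idx: set[int] = set()
    for key in sorted(strata, key=lambda k: (str(k[0]), str(k[1]))):
        members = strata[key]
        n_train = _round_half_up(train_frac * len(members))
        chosen = rng.choice(len(members), size=n_train, replace=False)
        train_idx.update(members[c] for c in chosen)
    discovery, validation = [], []
    for i, rec in enumerate(records):
        target = discovery if i in train_idx else validation
        cohort = "discovery" if i in train_idx else "validation"
        target.append(
            PhenotypeRecord(
                sample_id=rec.sample_id,
                breed=rec.breed,
                phenotype=rec.phenotype,
                cohort=cohort,
                standardized=rec.standardized,
                imputed=rec.imputed,
            )
        )
    return discovery, validation


def predict(
    model_fit: FitResult, qtl_dosages: dict, clip: bool = False
) -> np.ndarray:
    """Continuous phenotype predictions under a fitted model.

    Samples missing any required locus get NaN (flagged, excluded from
    metrics downstream).  Predictions are not clipped by default; with
    ``clip=True`` they are bounded to the [1, 6] scale.
    """
    X, names = model_fit.spec.design_matrix(qtl_dosages)
    beta = np.array([model_fit.coef[t] for t in names])
    pred = model_fit.intercept + X @ beta
    if clip:
        pred = np.clip(pred, 1.0, 6.0)
    return pred


@dataclass
class PredictionReport:
    """Validation metrics: frozen-coefficient R^2 and within-1 fractions."""

    n: int
    n_excluded: int  # samples with missing predictions
    r2: float
    adj_r2: float
    model_df: int
    within1_overall: float
    within1_by_group: dict
    group_sizes: dict


def validation_report(
    predictions, observations, groups=None, model_df: int = 0, tolerance: float = 1.0
) -> PredictionReport:
    """Score predictions against observed six-point values.

    R^2 = 1 - SSE/SST with the fixed (training) coefficients — it can be
    negative if the model predicts worse than the validation mean.  The
    adjusted value uses ``model_df`` (the training model's term count):
    1 - (1 - R^2)(n - 1)/(n - model_df - 1).  The within-1 fraction is
    mean(|pred - obs| <= tolerance), overall and per group (e.g. breed or
    "mixed breed").
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.size != obs.size:
        raise ValueError("predictions and observations differ in length")
    groups = (
        np.asarray(["all"] * pred.size) if groups is None else np.asarray(groups)
    )
    ok = ~np.isnan(pred) & ~np.isnan(obs)
    n_excl = int((~ok).sum())
    pred, obs, groups = pred[ok], obs[ok], groups[ok]
    n = pred.size
    if n == 0:
        raise ValueError("no scoreable samples")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    denom = n - model_df - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else float("nan")
    hits = np.abs(pred - obs) <= tolerance
    by_group, sizes = {}, {}
    for g in pd.unique(groups):
        mask = groups == g
        by_group[g] = float(hits[mask].mean())
        sizes[g] = int(mask.sum())
    return PredictionReport(
        n=n,
        n_excluded=n_excl,
        r2=r2,
        adj_r2=float(adj),
        model_df=model_df,
        within1_overall=float(hits.mean()),
        within1_by_group=by_group,
        group_sizes=sizes,
    )
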