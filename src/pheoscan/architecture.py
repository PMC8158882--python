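"""Dominance deviation and pairwise epistasis at candidate loci.

Dominance: at a biallelic locus the additive expectation for heterozygotes
is the midpoint m = (mean(hom0) + mean(hom2)) / 2 of the two homozygote
class means.  The dominance deviation d = mean(het) - m is positive when
the red-associated allele is at least partially dominant (heterozygotes
look more like red homozygotes) and negative when it is partially
recessive.  d is called significant when m falls outside the Student-t 95%
confidence interval of the heterozygote mean.  Phenotypes are z-scored by
default, matching the convention of reporting d on the standardized scale.

Epistasis: for a locus pair (A, B) the interaction regression
Y = b0 + b1 gA + b2 gB + b3 gA gB is fit by OLS on additive dosages; the
reported statistic is the squared Wald t of b3 referred to chi-square(1),
and pairs with p < 0.05 are flagged (uncorrected, by design — a Bonferroni
flag over the pair count is available for other uses).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .color_scale import standardize_phenotype
from .model_search import _ols

__all__ = [
    "DominanceEstimate",
    "EpistasisResult",
    "epistasis_frame",
    "epistasis_scan",
    "estimate_dominance",
]


@dataclass
class DominanceEstimate:
    """Dominance deviation at one locus on the (standardized) phenotype."""

    locus: str
    mean_hom0: float
    mean_het: float
    mean_hom2: float
    het_ci: tuple[float, float] | None  # 95% CI on the heterozygote mean
    midpoint: float
    d: float
    significant: bool | None  # None when the CI is undefined (het class of 1)
    class_sizes: tuple[int, int, int]


def estimate_dominance(
    phenotypes, dosages, locus: str = "", standardize: bool = True
) -> DominanceEstimate:
    """Dominance deviation d = mean(het) - midpoint(homozygote means).

    All three genotype classes must be non-empty.  The 95% CI on the
    heterozygote mean is mean +- t_{0.975, n1-1} * sd / sqrt(n1) (sample
    sd); with a single heterozygote d is still returned but significance is
    undefined.  ``standardize=True`` z-scores the phenotype first (the
    scale d is conventionally reported on); d itself is scale-equivariant.
    """
    y = np.asarray(phenotypes, dtype=float)
    g = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(g)
    y, g = y[ok], g[ok]
    if standardize:
        y, _, _ = standardize_phenotype(y)
    classes = [y[g == k] for k in (0, 1, 2)]
    for k, cls in enumerate(classes):
        if cls.size == 0:
            raise ValueError(f"genotype class {k} is empty at locus {locus or '?'}")
    y0, y1, y2 = (float(c.mean()) for c in classes)
    n1 = classes[1].size
    if n1 >= 2:
        se = classes[1].std(ddof=1) / np.sqrt(n1)
        tq = stats.t.ppf(0.975, n1 - 1)
        ci = (y1 - tq * se, y1 + tq * se)
    else:
        ci = None
    m = 0.5 * (y0 + y2)
    return DominanceEstimate(
        locus=locus,
        mean_hom0=y0,
        mean_het=y1,
        mean_hom2=y2,
        het_ci=ci,
        midpoint=m,
        d=y1 - m,
        significant=None if ci is None else not (ci[0] <= m <= ci[1]),
        class_sizes=tuple(c.size for c in classes),
    )


@dataclass
class EpistasisResult:
    """Two-locus interaction regression result."""

    locus_a: str
    locus_b: str
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    stat: float  # squared Wald t of beta3, ~ chi-square(1) under the null
    p_value: float
    significant: bool


def epistasis_scan(
    phenotypes,
    dosage_pairs: dict,
    pairs: list | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list:
    """Interaction regression for each locus pair.

    ``dosage_pairs`` maps locus name -> additive dosage array; ``pairs``
    defaults to all C(L, 2) combinations in name order.  Complete cases per
    pair; both loci must be polymorphic and not perfectly collinear.
    ``bonferroni=True`` divides the significance alpha by the pair count.
    """
    y_all = np.asarray(phenotypes, dtype=float)
    loci = list(dosage_pairs)
    if pairs is None:
        pairs = list(itertools.combinations(loci, 2))
    thresh = alpha / len(pairs) if bonferroni else alpha
    results = []
    for a, b in pairs:
        ga = np.asarray(dosage_pairs[a], dtype=float)
        gb = np.asarray(dosage_pairs[b], dtype=float)
        ok = ~np.isnan(y_all) & ~np.isnan(ga) & ~np.isnan(gb)
        y, xa, xb = y_all[ok], ga[ok], gb[ok]
        for name, x in ((a, xa), (b, xb)):
            if x.std() == 0:
                raise ValueError(f"locus {name!r} is monomorphic in the sample")
        if abs(np.corrcoef(xa, xb)[0, 1]) >= 1.0 - 1e-12:
            raise ValueError(f"loci {a!r} and {b!r} are perfectly collinear")
        X = np.column_stack([np.ones(y.size), xa, xb, xa * xb])
        beta, sse = _ols(X, y)
        dof = y.size - 4
        sigma2 = sse / dof
        cov = np.linalg.inv(X.T @ X) * sigma2
        se3 = float(np.sqrt(cov[3, 3]))
        t3 = beta[3] / se3 if se3 > 0 else 0.0
        stat = float(t3 * t3)
        p = float(stats.chi2.sf(stat, 1))
        results.append(
            EpistasisResult(
                locus_a=a,
                locus_b=b,
                beta0=float(beta[0]),
                beta1=float(beta[1]),
                beta2=float(beta[2]),
                beta3=float(beta[3]),
                stat=stat,
                p_value=p,
                significant=p < thresh,
            )
        )
    return results


def epistasis_frame(results: list) -> pd.DataFrame:
    """Tidy table (interaction, beta3, stat, p) sorted by statistic."""
    df = pd.DataFrame(
        [
            {
                "interaction": f"{r.locus_a} x {r.locus_b}",
                "beta3": r.beta3,
                "stat": r.stat,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
    return df.sort_values("stat", ascending=False).reset_index(drop=True)
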