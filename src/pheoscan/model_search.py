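"""Genotype encodings, exhaustive model enumeration and selection.

A candidate locus with red-allele dosage g in {0, 1, 2} can enter a linear
phenotype model under four encodings:

- ``additive``       one term, value g
- ``red_dominant``   one term, 1 if g >= 1 (red allele dominant)
- ``red_recessive``  one term, 1 if g == 2 (red allele recessive)
- ``het_hom_split``  two indicator terms, ``<locus>_1`` = [g == 1] and
  ``<locus>_2`` = [g == 2]; the ratio of their fitted coefficients
  diagnoses the dominance mode of the locus.

A :class:`ModelSpec` is a per-locus encoding choice plus a set of pairwise
interaction terms (products of the two loci's encoded values).  Models are
fit by ordinary least squares; per-term importance is the proportional
reduction of error (PRE): the increase in residual sum of squares when the
term is removed and the model refit, as a fraction of the total sum of
squares.  The search stage enumerates every combination of encoding toggles
and interaction inclusions (2^(L+I) specs, optionally excluding the
all-baseline model), ranks by adjusted R², prunes terms below a PRE
threshold and compares nested fits by likelihood ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "ENCODINGS",
    "FitResult",
    "ModelSpec",
    "encode_genotype",
    "enumerate_model_space",
    "fit_model",
    "infer_best_encoding",
    "likelihood_ratio_test",
    "prune_by_pre",
    "select_best",
]

ADDITIVE = "additive"
RED_DOMINANT = "red_dominant"
RED_RECESSIVE = "red_recessive"
HET_HOM_SPLIT = "het_hom_split"
ENCODINGS = (ADDITIVE, RED_DOMINANT, RED_RECESSIVE, HET_HOM_SPLIT)

_SINGLE_TERM_SUFFIX = {ADDITIVE: "", RED_DOMINANT: "_red_dom", RED_RECESSIVE: "_2"}


def encode_genotype(dosage, encoding: str):
    """Encode red-allele dosage(s) under one encoding.

    Returns a single array (or scalar) for the one-term encodings and a
    ``(het, hom)`` pair of arrays for ``het_hom_split``.  Missing dosage
    (NaN) propagates to missing term values.
    """
    g = np.asarray(dosage, dtype=float)
    valid = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
    if not np.all(valid):
        raise ValueError(f"dosage must be in {{0,1,2,missing}}; got {g[~valid].flat[0]}")
    nan = np.isnan(g)

    def _mask(values: np.ndarray) -> np.ndarray:
        values = np.where(nan, np.nan, values.astype(float))
        return values if values.shape else float(values)

    if encoding == ADDITIVE:
        return _mask(g.copy())
    if encoding == RED_DOMINANT:
        return _mask(g >= 1)
    if encoding == RED_RECESSIVE:
        return _mask(g == 2)
    if encoding == HET_HOM_SPLIT:
        return _mask(g == 1), _mask(g == 2)
    raise ValueError(f"unknown encoding: {encoding!r}")


def _term_names(locus: str, encoding: str) -> tuple[str, ...]:
    if encoding == HET_HOM_SPLIT:
        return (f"{locus}_1", f"{locus}_2")
    return (locus + _SINGLE_TERM_SUFFIX[encoding],)


@dataclass(frozen=True)
class ModelSpec:
    """Per-locus encodings + interaction pairs (+ optional true coefficients).

    ``interactions`` are (locus_a, locus_b) pairs whose term is the product
    of the two single-column encoded values; loci under ``het_hom_split``
    cannot enter interactions.  ``excluded_terms`` removes individual named
    terms from the design (used by PRE pruning, e.g. dropping a main effect
    while keeping an interaction).  ``intercept``/``coefficients`` carry a
    generative model's true values when the spec is used by the simulator.
    """

    loci: tuple[str, ...]
    encodings: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    excluded_terms: frozenset = frozenset()
    response_scale: str = "raw"  # "raw" six-point | "standardized"
    intercept: float | None = None
    coefficients: dict | None = field(default=None, hash=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.encodings):
            raise ValueError("one encoding per locus required")
        for e in self.encodings:
            if e not in ENCODINGS:
                raise ValueError(f"unknown encoding: {e!r}")
        enc = dict(zip(self.loci, self.encodings))
        for a, b in self.interactions:
            for locus in (a, b):
                if locus not in enc:
                    raise ValueError(f"interaction references unknown locus {locus!r}")
                if enc[locus] == HET_HOM_SPLIT:
                    raise ValueError(
                        f"locus {locus!r} uses het_hom_split and cannot interact"
                    )

    def encoding_of(self, locus: str) -> str:
        return self.encodings[self.loci.index(locus)]

    def term_names(self) -> tuple[str, ...]:
        """Design-column names in spec order, after exclusions."""
        names: list[str] = []
        for locus, enc in zip(self.loci, self.encodings):
            names.extend(_term_names(locus, enc))
        for a, b in self.interactions:
            ta = _term_names(a, self.encoding_of(a))[0]
            tb = _term_names(b, self.encoding_of(b))[0]
            names.append(f"{ta} x {tb}")
        return tuple(n for n in names if n not in self.excluded_terms)

    def key(self) -> str:
        """Deterministic sort key for tie-breaking."""
        return "|".join(self.term_names())

    def design_matrix(
        self, qtl_dosages: dict, n_samples: int | None = None
    ) -> tuple[np.ndarray, tuple[str, ...]]:
        """Build the (n, k) term-value matrix (no intercept column).

        ``qtl_dosages`` maps locus name -> dosage array; NaN dosages yield
        NaN rows for that locus's terms (callers drop incomplete cases).
        ``n_samples`` sizes the matrix for a term-free (intercept-only) spec.
        """
        columns: dict[str, np.ndarray] = {}
        single: dict[str, np.ndarray] = {}
        n = n_samples
        for locus, enc in zip(self.loci, self.encodings):
            g = np.asarray(qtl_dosages[locus], dtype=float)
            n = g.size if n is None else n
            encoded = encode_genotype(g, enc)
            if enc == HET_HOM_SPLIT:
                columns[f"{locus}_1"], columns[f"{locus}_2"] = encoded
            else:
                name = _term_names(locus, enc)[0]
                columns[name] = encoded
                single[locus] = encoded
        for a, b in self.interactions:
            ta = _term_names(a, self.encoding_of(a))[0]
            tb = _term_names(b, self.encoding_of(b))[0]
            columns[f"{ta} x {tb}"] = single[a] * single[b]
        names = self.term_names()
        X = np.column_stack([columns[t] for t in names]) if names else np.empty((n, 0))
        return X, names

    def latent_values(self, qtl_dosages: dict) -> np.ndarray:
        """Linear predictor under the spec's own (true) coefficients."""
        if self.intercept is None or self.coefficients is None:
            raise ValueError("spec carries no coefficients")
        X, names = self.design_matrix(qtl_dosages)
        beta = np.array([self.coefficients[t] for t in names])
        return self.intercept + X @ beta


@dataclass
class FitResult:
    """An OLS fit of a :class:`ModelSpec`.

    ``loglik`` is the Gaussian log-likelihood at the MLE residual variance
    (SSE/n); ``adj_r2`` uses the n-k-1 denominator; ``pre`` maps each term
    to its proportional reduction of error.
    """

    spec: ModelSpec
    terms: tuple[str, ...]
    intercept: float
    coef: dict
    se: dict
    tvalues: dict
    pvalues: dict
    intercept_se: float
    r2: float
    adj_r2: float
    loglik: float
    sse: float
    sst: float
    pre: dict
    n: int

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def predict(self, qtl_dosages: dict) -> np.ndarray:
        """Linear predictor at the fitted coefficients (no clipping)."""
        X, names = self.spec.design_matrix(qtl_dosages)
        beta = np.array([self.coef[t] for t in names])
        return self.intercept + X @ beta


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares solve returning (beta, sse); raises on rank deficiency."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
            "some terms are collinear"
        )
    resid = y - X @ beta
    return beta, float(resid @ resid)


def _gaussian_loglik(sse: float, n: int) -> float:
    sigma2 = max(sse / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def fit_model(phenotype, qtl_dosages: dict, spec: ModelSpec) -> FitResult:
    """OLS fit of ``spec`` on complete cases.

    Samples missing the phenotype or any required locus dosage are dropped.
    Standard errors use the unbiased residual variance SSE/(n-k-1); t tests
    are two-sided with n-k-1 degrees of freedom.  PRE for term j is
    (SSE without term j - SSE full) / SST, each reduced model refit from
    scratch.
    """
    y = np.asarray(phenotype, dtype=float)
    Xterms, names = spec.design_matrix(qtl_dosages, n_samples=y.size)
    ok = ~np.isnan(y)
    if Xterms.shape[1]:
        ok &= ~np.isnan(Xterms).any(axis=1)
    y, Xterms = y[ok], Xterms[ok]
    n, k = y.size, Xterms.shape[1]
    if n <= k + 1:
        raise ValueError(f"too few complete cases (n={n}) for {k} terms")
    X = np.column_stack([np.ones(n), Xterms])
    beta, sse = _ols(X, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    dof = n - k - 1
    sigma2 = sse / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    ses = np.sqrt(np.diag(xtx_inv) * sigma2)
    tvals = np.divide(beta, ses, out=np.zeros_like(beta), where=ses > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    pre: dict[str, float] = {}
    for j, name in enumerate(names):
        Xr = np.delete(X, j + 1, axis=1)
        _, sse_r = _ols(Xr, y)
        pre[name] = (sse_r - sse) / sst if sst > 0 else 0.0
    return FitResult(
        spec=spec,
        terms=names,
        intercept=float(beta[0]),
        coef=dict(zip(names, beta[1:].tolist())),
        se=dict(zip(names, ses[1:].tolist())),
        tvalues=dict(zip(names, tvals[1:].tolist())),
        pvalues=dict(zip(names, pvals[1:].tolist())),
        intercept_se=float(ses[0]),
        r2=r2,
        adj_r2=float(adj_r2),
        loglik=_gaussian_loglik(sse, n),
        sse=sse,
        sst=sst,
        pre=pre,
        n=n,
    )


def infer_best_encoding(het_hom_fit: FitResult, locus: str) -> str:
    """Dominance mode of a locus from its het/hom-split coefficients.

    The ratio beta(_1)/beta(_2) is compared with the three ideal values:
    0.5 (additive), 0 (red allele recessive), 1 (red allele dominant); the
    nearest wins.  This turns the qualitative reading of a split-encoding
    fit into a deterministic rule.
    """
    b1 = het_hom_fit.coef[f"{locus}_1"]
    b2 = het_hom_fit.coef[f"{locus}_2"]
    if b2 == 0:
        return RED_DOMINANT if abs(b1) > 0 else ADDITIVE
    ratio = b1 / b2
    targets = {ADDITIVE: 0.5, RED_RECESSIVE: 0.0, RED_DOMINANT: 1.0}
    return min(targets, key=lambda e: abs(ratio - targets[e]))


def enumerate_model_space(
    loci: tuple[str, ...],
    per_locus_alternatives: dict,
    candidate_interactions: tuple[tuple[str, str], ...] = (),
    include_base: bool = False,
    response_scale: str = "raw",
) -> list[ModelSpec]:
    """Cartesian product of per-locus encoding toggles and interaction sets.

    ``per_locus_alternatives[locus]`` is a (baseline, alternative) encoding
    pair; each interaction is independently in or out.  The all-baseline,
    no-interaction spec is omitted unless ``include_base``; the count is
    then 2^(L'+I) - 1 with L' the number of loci offering two distinct
    encodings.  Interactions use each locus's chosen encoding, so a locus
    toggled to ``het_hom_split`` would be unfittable with an interaction —
    such alternatives are rejected up front.
    """
    choices = []
    for locus in loci:
        alts = tuple(dict.fromkeys(per_locus_alternatives[locus]))  # dedupe, keep order
        choices.append([(locus, e) for e in alts])
    interacting = {l for pair in candidate_interactions for l in pair}
    for locus in interacting:
        if HET_HOM_SPLIT in per_locus_alternatives[locus]:
            raise ValueError(f"interacting locus {locus!r} cannot offer het_hom_split")
    specs = []
    for encoding_combo in itertools.product(*choices):
        encodings = tuple(e for _, e in encoding_combo)
        for r in range(len(candidate_interactions) + 1):
            for inter in itertools.combinations(candidate_interactions, r):
                is_base = all(
                    e == per_locus_alternatives[l][0] for l, e in encoding_combo
                ) and not inter
                if is_base and not include_base:
                    continue
                specs.append(
                    ModelSpec(
                        loci=loci,
                        encodings=encodings,
                        interactions=inter,
                        response_scale=response_scale,
                    )
                )
    return specs


def select_best(fits: list[FitResult]) -> list[FitResult]:
    """Rank fits by adjusted R² (descending); ties prefer fewer terms, then
    the lexicographically smaller spec key.  Deterministic."""
    return sorted(
        fits, key=lambda f: (-round(f.adj_r2, 12), f.n_terms, f.spec.key())
    )


def prune_by_pre(
    fit: FitResult, phenotype, qtl_dosages: dict, threshold: float = 1e-3
) -> FitResult:
    """Drop all terms with PRE <= ``threshold`` simultaneously and refit.

    A single reduction step (not stepwise): every sub-threshold term leaves
    at once.  If nothing is sub-threshold the original fit is returned.
    """
    weak = {t for t in fit.terms if fit.pre[t] <= threshold}
    if not weak:
        return fit
    reduced = replace(fit.spec, excluded_terms=frozenset(fit.spec.excluded_terms | weak))
    return fit_model(phenotype, qtl_dosages, reduced)


def fit_to_dict(fit: FitResult) -> dict:
    """JSON-serializable form of a fitted model (spec + coefficients + fit
    statistics), consumable by the prediction stage."""
    return {
        "loci": list(fit.spec.loci),
        "encodings": list(fit.spec.encodings),
        "interactions": [list(p) for p in fit.spec.interactions],
        "excluded_terms": sorted(fit.spec.excluded_terms),
        "response_scale": fit.spec.response_scale,
        "intercept": fit.intercept,
        "coef": fit.coef,
        "se": fit.se,
        "adj_r2": fit.adj_r2,
        "loglik": fit.loglik,
        "n": fit.n,
    }


def fit_from_dict(data: dict) -> FitResult:
    """Rebuild a fitted model from :func:`fit_to_dict` output.

    Only the quantities prediction needs are restored faithfully; refit on
    data to recover the full inferential statistics.
    """
    spec = ModelSpec(
        loci=tuple(data["loci"]),
        encodings=tuple(data["encodings"]),
        interactions=tuple(tuple(p) for p in data["interactions"]),
        excluded_terms=frozenset(data.get("excluded_terms", ())),
        response_scale=data.get("response_scale", "raw"),
    )
    terms = spec.term_names()
    nanmap = {t: float("nan") for t in terms}
    return FitResult(
        spec=spec,
        terms=terms,
        intercept=float(data["intercept"]),
        coef={t: float(data["coef"][t]) for t in terms},
        se={t: float(data.get("se", {}).get(t, float("nan"))) for t in terms},
        tvalues=dict(nanmap),
        pvalues=dict(nanmap),
        intercept_se=float("nan"),
        r2=float("nan"),
        adj_r2=float(data.get("adj_r2", float("nan"))),
        loglik=float(data.get("loglik", float("nan"))),
        sse=float("nan"),
        sst=float("nan"),
        pre=dict(nanmap),
        n=int(data.get("n", 0)),
    )


def likelihood_ratio_test(fit_reduced: FitResult, fit_full: FitResult) -> float:
    """Chi-squared LRT p-value for nested OLS fits.

    Requires the reduced model's terms to be a subset of the full model's
    and both fits to use the same number of observations; df is the
    difference in term count.  Identical models give p = 1.
    """
    if not set(fit_reduced.terms) <= set(fit_full.terms):
        raise ValueError("models are not nested (reduced terms not a subset)")
    if fit_reduced.n != fit_full.n:
        raise ValueError("fits use different sample sizes; refit on common cases")
    df = fit_full.n_terms - fit_reduced.n_terms
    if df == 0:
        return 1.0
    lr = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    return float(stats.chi2.sf(lr, df))
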