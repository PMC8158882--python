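"""Genotype containers, file I/O and quality control.

The analyses operate on biallelic SNP dosages oriented to a named
"red-associated" (effect) allele per marker: dosage = count of allele1 in
{0, 1, 2}, missing allowed.  Two on-disk dialects are supported:

``tsv``
    A plain-text pair of files: ``<prefix>.geno.tsv`` with a header row
    (``sample_id`` followed by marker ids) and one sample per row, dosages
    as integers with ``NA`` for missing; and ``<prefix>.markers.tsv`` with
    columns ``marker_id  chrom  pos  allele1  allele2`` (1-based positions).

``plink-bed``
    PLINK 1 binary bed/bim/fam triple, variant-major.  The 2-bit codes are
    mapped so that dosage counts the bim A1 allele (00 -> 2, 10 -> 1,
    11 -> 0, 01 -> missing).

QC mirrors standard array practice: marker missingness filter, then sample
missingness across the remaining markers, method-of-moments IBD relatedness
with pi-hat pruning, and a minor-allele-frequency filter.  Phenotype gaps in
breeds fixed for a color can be filled with the breed's modal value.
"""

from __future__ import annotations

import struct
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeRecord",
    "RelatednessEstimate",
    "estimate_relatedness",
    "filter_maf",
    "filter_marker_missingness",
    "filter_sample_missingness",
    "impute_breed_modal_phenotype",
    "prune_relatives",
    "read_genotypes",
    "write_genotypes",
]

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "allele1", "allele2"]


@dataclass
class PhenotypeRecord:
    """One dog: six-point intensity value plus breed/cohort labels."""

    sample_id: str
    breed: str
    phenotype: int | None  # 1..6, None if unphenotyped
    cohort: str | None = None  # "discovery" | "validation" | None
    standardized: float | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.phenotype is not None and not 1 <= int(self.phenotype) <= 6:
            raise ValueError(f"phenotype must be in 1..6, got {self.phenotype}")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic markers, dosages in {0, 1, 2, NaN}.

    ``dosages[i, j]`` counts copies of ``allele1`` (the red-associated /
    effect allele) carried by sample ``i`` at marker ``j``.  ``markers`` is
    a DataFrame with columns ``marker_id, chrom, pos, allele1, allele2``.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.sample_ids)} samples, {len(self.markers)} markers)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        ids = self.markers["marker_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id: {dup!r}")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = self.dosages[~valid].flat[0]
            raise ValueError(f"dosages must be in {{0,1,2,missing}}; got {bad}")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"unknown marker id: {marker_id!r}")
        return int(idx[0])

    def dosage_of(self, marker_id: str) -> np.ndarray:
        return self.dosages[:, self.marker_index(marker_id)]

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def marker_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker frequency of allele1 among non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        sidx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        midx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in sidx],
            markers=self.markers.iloc[midx].reset_index(drop=True),
            dosages=self.dosages[np.ix_(sidx, midx)],
        )


# ---------------------------------------------------------------------------
# I/O: TSV dialect
# ---------------------------------------------------------------------------

def _tsv_paths(path) -> tuple[Path, Path]:
    return Path(str(path) + ".geno.tsv"), Path(str(path) + ".markers.tsv")


def _write_tsv(gm: GenotypeMatrix, path) -> None:
    geno_path, marker_path = _tsv_paths(path)
    gm.markers.to_csv(marker_path, sep="\t", index=False)
    with open(geno_path, "w") as fh:
        fh.write("\t".join(["sample_id", *gm.markers["marker_id"]]) + "\n")
        for i, sid in enumerate(gm.sample_ids):
            cells = ["NA" if np.isnan(d) else str(int(d)) for d in gm.dosages[i]]
            fh.write("\t".join([sid, *cells]) + "\n")


def _read_tsv(path) -> GenotypeMatrix:
    geno_path, marker_path = _tsv_paths(path)
    markers = pd.read_csv(marker_path, sep="\t", dtype={"marker_id": str, "chrom": str})
    missing_cols = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing_cols:
        raise ValueError(f"{marker_path}: missing marker columns {missing_cols}")
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(geno_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "sample_id":
            raise ValueError(f"{geno_path}: line 1: header must start with 'sample_id'")
        marker_ids = header[1:]
        if marker_ids != list(markers["marker_id"]):
            raise ValueError(
                f"{geno_path}: header marker ids do not match {marker_path}"
            )
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(marker_ids) + 1:
                raise ValueError(
                    f"{geno_path}: line {lineno}: expected {len(marker_ids) + 1} "
                    f"fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            try:
                rows.append(
                    np.array(
                        [np.nan if c == "NA" else float(int(c)) for c in parts[1:]]
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{geno_path}: line {lineno}: {exc}") from None
    dosages = (
        np.vstack(rows) if rows else np.empty((0, len(marker_ids)), dtype=float)
    )
    return GenotypeMatrix(sample_ids=sample_ids, markers=markers, dosages=dosages)


# ---------------------------------------------------------------------------
# I/O: PLINK 1 bed/bim/fam (variant-major)
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit PLINK codes -> dosage of the bim A1 allele
_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _write_bed(gm: GenotypeMatrix, path) -> None:
    prefix = Path(path)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in gm.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for rec in gm.markers.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.marker_id}\t0\t{int(rec.pos)}"
                f"\t{rec.allele1}\t{rec.allele2}\n"
            )
    n = gm.n_samples
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(gm.n_markers):
            buf = bytearray(n_bytes)
            col = gm.dosages[:, j]
            for i in range(n):
                d = col[i]
                code = 0b01 if np.isnan(d) else _DOSAGE_TO_CODE[float(d)]
                buf[i >> 2] |= code << ((i & 3) * 2)
            fh.write(bytes(buf))


def _read_bed(path) -> GenotypeMatrix:
    prefix = Path(path)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str
    )
    sample_ids = list(fam[1])
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "marker_id": str, "allele1": str, "allele2": str},
    )
    markers = bim[MARKER_COLUMNS].copy()
    n, m = len(sample_ids), len(markers)
    n_bytes = (n + 3) // 4
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix.with_suffix('.bed')}: not a variant-major PLINK bed file")
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != m * n_bytes:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: expected {m * n_bytes} data bytes, got {body.size}"
        )
    body = body.reshape(m, n_bytes)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, n_bytes * 4)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T  # samples x markers
    return GenotypeMatrix(sample_ids=sample_ids, markers=markers, dosages=dosages)


def write_genotypes(gm: GenotypeMatrix, path, dialect: str = "tsv") -> None:
    """Write a genotype matrix; ``dialect`` is ``"tsv"`` or ``"plink-bed"``."""
    if dialect == "tsv":
        _write_tsv(gm, path)
    elif dialect == "plink-bed":
        _write_bed(gm, path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix written by :func:`write_genotypes`."""
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "plink-bed":
        return _read_bed(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

@dataclass
class RemovalReport:
    """What a filter removed and why."""

    kind: str
    removed: list[str] = field(default_factory=list)
    threshold: float = float("nan")

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_marker_missingness(
    gm: GenotypeMatrix, max_rate: float = 0.05
) -> tuple[GenotypeMatrix, RemovalReport]:
    """Drop markers with missing fraction strictly above ``max_rate``."""
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must be in [0, 1]")
    miss = gm.marker_missingness()
    keep = miss <= max_rate
    report = RemovalReport(
        kind="marker_missingness",
        removed=list(gm.markers["marker_id"][~keep]),
        threshold=max_rate,
    )
    return gm.subset(marker_idx=np.where(keep)[0]), report


def filter_sample_missingness(
    gm: GenotypeMatrix, max_rate: float = 0.03
) -> tuple[GenotypeMatrix, RemovalReport]:
    """Drop samples with missing fraction strictly above ``max_rate``.

    Applied after the marker filter, so "missingness" is across the
    remaining markers.
    """
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must be in [0, 1]")
    miss = gm.sample_missingness()
    keep = miss <= max_rate
    report = RemovalReport(
        kind="sample_missingness",
        removed=[s for s, k in zip(gm.sample_ids, keep) if not k],
        threshold=max_rate,
    )
    return gm.subset(sample_idx=np.where(keep)[0]), report


def filter_maf(
    gm: GenotypeMatrix, min_maf: float = 0.001, max_missing: float = 0.05
) -> tuple[GenotypeMatrix, RemovalReport]:
    """Drop markers with minor allele frequency below ``min_maf`` (MAF ==
    ``min_maf`` is retained) or missingness above ``max_missing``."""
    af = gm.allele_frequencies()
    maf = np.minimum(af, 1.0 - af)
    miss = gm.marker_missingness()
    with np.errstate(invalid="ignore"):
        keep = (maf >= min_maf) & (miss <= max_missing)
    keep &= ~np.isnan(maf)  # all-missing marker -> removed
    report = RemovalReport(
        kind="maf",
        removed=list(gm.markers["marker_id"][~keep]),
        threshold=min_maf,
    )
    return gm.subset(marker_idx=np.where(keep)[0]), report


# ---------------------------------------------------------------------------
# Relatedness (method-of-moments IBD from IBS counts)
# ---------------------------------------------------------------------------

@dataclass
class RelatednessEstimate:
    """Pairwise IBD estimate: P(IBD=0,1,2) and pi_hat = P2 + P1/2."""

    sample_a: str
    sample_b: str
    ibd_probs: tuple[float, float, float]
    pi_hat: float
    n_markers: int


def _ibs_expectations(freqs: np.ndarray) -> tuple[float, float, float, float]:
    """Summed expected IBS-class counts given allele freqs, per IBD state.

    Returns (E[IBS0|IBD0], E[IBS1|IBD0], E[IBS2|IBD0], E[IBS1|IBD1]); the
    remaining expectations follow from normalization (E[IBS2|IBD1] =
    n - E[IBS1|IBD1], E[IBS2|IBD2] = n).
    """
    p = freqs
    q = 1.0 - p
    e0_0 = float(np.sum(2 * p**2 * q**2))
    e1_0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    return e0_0, e1_0, e2_0, e1_1


def estimate_relatedness(
    gm: GenotypeMatrix, pair: tuple[str, str], freqs: np.ndarray | None = None
) -> RelatednessEstimate:
    """Method-of-moments IBD sharing for one sample pair.

    Observed identity-by-state class counts over markers non-missing in both
    samples are compared with their expectations under each IBD state given
    the (sample-estimated, unless provided) allele frequencies; the moment
    solution is projected onto the probability simplex and pi_hat clipped to
    [0, 1].  Monomorphic markers carry no IBD information and are skipped.
    """
    a, b = pair
    ia, ib = gm.sample_ids.index(a), gm.sample_ids.index(b)
    ga, gb = gm.dosages[ia], gm.dosages[ib]
    if freqs is None:
        freqs = gm.allele_frequencies()
    ok = ~np.isnan(ga) & ~np.isnan(gb) & (freqs > 0) & (freqs < 1)
    if not ok.any():
        if not (~np.isnan(ga) & ~np.isnan(gb)).any():
            raise ValueError(f"no overlapping non-missing markers for pair {pair}")
        # overlap exists but is all monomorphic: uninformative
        raise ValueError(f"no polymorphic overlapping markers for pair {pair}")
    ga, gb, p = ga[ok], gb[ok], freqs[ok]
    ibs = 2.0 - np.abs(ga - gb)
    # het/het pairs are IBS 2 under dosage distance but opposite-homozygote
    # pairs must be IBS 0, which |dosage diff| == 2 already captures.
    n = ga.size
    n0 = float(np.sum(ibs == 0))
    n1 = float(np.sum(ibs == 1))
    n2 = float(np.sum(ibs == 2))
    e0_0, e1_0, e2_0, e1_1 = _ibs_expectations(p)
    # sequential moment solution with clipping at each step (as PLINK's
    # --genome constrains out-of-range estimates)
    p0 = min(max(n0 / e0_0 if e0_0 > 0 else 0.0, 0.0), 1.0)
    p1 = (n1 - p0 * e1_0) / e1_1 if e1_1 > 0 else 0.0
    p1 = min(max(p1, 0.0), 1.0)
    p2 = (n2 - p0 * e2_0 - p1 * (n - e1_1)) / n
    p2 = min(max(p2, 0.0), 1.0)
    probs = np.array([p0, p1, p2])
    total = probs.sum()
    probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
    pi_hat = float(np.clip(probs[2] + 0.5 * probs[1], 0.0, 1.0))
    return RelatednessEstimate(
        sample_a=a,
        sample_b=b,
        ibd_probs=tuple(float(x) for x in probs),
        pi_hat=pi_hat,
        n_markers=int(n),
    )


def prune_relatives(
    gm: GenotypeMatrix,
    threshold: float = 0.45,
    pairs: list[RelatednessEstimate] | None = None,
) -> tuple[list[str], RemovalReport]:
    """Retain a subset of samples with no pair at pi_hat >= ``threshold``.

    Iteratively, among flagged pairs the member with the higher genome-wide
    missingness is removed (ties: the lexicographically larger sample id),
    and remaining pairs are re-examined.  If ``pairs`` is omitted every
    sample pair is estimated, which is quadratic — supply a candidate
    superset for large panels.
    """
    if pairs is None:
        freqs = gm.allele_frequencies()
        pairs = []
        for i in range(gm.n_samples):
            for j in range(i + 1, gm.n_samples):
                pairs.append(
                    estimate_relatedness(
                        gm, (gm.sample_ids[i], gm.sample_ids[j]), freqs
                    )
                )
    miss = dict(zip(gm.sample_ids, gm.sample_missingness()))
    flagged = [(e.sample_a, e.sample_b) for e in pairs if e.pi_hat >= threshold]
    removed: list[str] = []
    active = set(gm.sample_ids)
    while True:
        live = [(a, b) for a, b in flagged if a in active and b in active]
        if not live:
            break
        a, b = live[0]
        if miss[a] > miss[b]:
            drop = a
        elif miss[b] > miss[a]:
            drop = b
        else:
            drop = max(a, b)
        active.discard(drop)
        removed.append(drop)
    retained = [s for s in gm.sample_ids if s in active]
    report = RemovalReport(kind="relatedness", removed=removed, threshold=threshold)
    return retained, report


# ---------------------------------------------------------------------------
# Breed-modal phenotype imputation
# ---------------------------------------------------------------------------

def impute_breed_modal_phenotype(
    records: list[PhenotypeRecord], target_samples: list[str]
) -> list[PhenotypeRecord]:
    """Fill missing phenotypes with the modal six-point value of the breed.

    The mode is taken over already-phenotyped dogs of the same breed; a
    modal tie resolves to the higher value.  Returns a new record list in
    the input order with targets marked ``imputed=True``.
    """
    by_breed: dict[str, Counter] = {}
    for rec in records:
        if rec.phenotype is not None and rec.sample_id not in target_samples:
            by_breed.setdefault(rec.breed, Counter())[rec.phenotype] += 1
    targets = set(target_samples)
    out = []
    for rec in records:
        if rec.sample_id in targets:
            counts = by_breed.get(rec.breed)
            if not counts:
                raise ValueError(
                    f"breed {rec.breed!r} has no phenotyped members to impute from"
                )
            top = max(counts.values())
            modal = max(v for v, c in counts.items() if c == top)
            out.append(replace(rec, phenotype=modal, imputed=True))
        else:
            out.append(replace(rec))
    return out
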