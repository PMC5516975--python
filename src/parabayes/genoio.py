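"""Genotype and phenotype I/O, marker quality control, and fixed-effect pre-adjustment.

Genotypes live in a :class:`GenotypeMatrix`: an individuals-by-markers dosage
matrix coded 0/1/2 (count of the A1 allele, PLINK convention) with ``nan`` as
the missing sentinel.  Readers and writers cover the PLINK text (.ped/.map)
and binary (.bed/.bim/.fam, SNP-major) formats.  Quality control applies the
usual marker filters — minor allele frequency, missing-call rate and an exact
Hardy–Weinberg test — and phenotypes are pre-corrected for environmental
fixed effects (farm, month of age, slaughter year) by ordinary least squares,
so that downstream genomic models only see an overall mean plus marker
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeRecord",
    "QCThresholds",
    "read_plink",
    "write_plink",
    "hwe_exact_p",
    "qc_filter",
    "impute_missing",
    "adjust_phenotypes",
    "read_phenotypes",
]

MISSING = np.nan

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with its marker map.

    ``dosages[i, j]`` counts copies of the A1 allele of marker ``j`` carried
    by individual ``i`` (0, 1 or 2; ``nan`` when missing; real-valued after
    mean imputation).
    """

    individual_ids: list[str]
    marker_ids: list[str]
    chromosome: np.ndarray  # per marker
    position: np.ndarray  # base pairs, 1-based
    dosages: np.ndarray  # n x M float
    a1: list[str] | None = None
    a2: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosages")
        if len(self.marker_ids) != m:
            raise ValueError("marker_ids length does not match dosages")
        dup = pd.Index(self.marker_ids)[pd.Index(self.marker_ids).duplicated()]
        if len(dup):
            raise ValueError(f"duplicated marker ids: {sorted(set(dup))}")
        self.chromosome = np.asarray(self.chromosome)
        self.position = np.asarray(self.position)
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)) | (
            (self.dosages >= 0) & (self.dosages <= 2)
        )
        if not ok.all():
            raise ValueError("dosages must lie in [0, 2] or be nan")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def counted_allele_frequency(self) -> np.ndarray:
        """Frequency q_i of the counted (A1) allele, from non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[j] for j in index],
            chromosome=self.chromosome[index],
            position=self.position[index],
            dosages=self.dosages[:, index],
            a1=[self.a1[j] for j in index] if self.a1 else None,
            a2=[self.a2[j] for j in index] if self.a2 else None,
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in index],
            marker_ids=list(self.marker_ids),
            chromosome=self.chromosome.copy(),
            position=self.position.copy(),
            dosages=self.dosages[index, :],
            a1=list(self.a1) if self.a1 else None,
            a2=list(self.a2) if self.a2 else None,
        )


@dataclass(frozen=True)
class PhenotypeRecord:
    """One phenotype observation with its environmental factor levels."""

    individual_id: str
    trait_name: str
    value: float
    farm: str
    month: int  # months after birth at measurement
    year: int  # slaughter year


@dataclass(frozen=True)
class QCThresholds:
    """Marker QC thresholds: retain MAF > maf_min, missing < missing_max, HWE p > hwe_p_min."""

    maf_min: float = 0.05
    missing_max: float = 0.05
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# PLINK readers / writers
# ---------------------------------------------------------------------------


def _read_map(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns (chrom id cM bp)")
    df.columns = ["chrom", "id", "cm", "bp"] + [f"x{i}" for i in range(df.shape[1] - 4)]
    return df


def _read_ped(prefix: Path) -> GenotypeMatrix:
    mapdf = _read_map(prefix.with_suffix(".map"))
    m = len(mapdf)
    if m == 0:
        raise ValueError(f"{prefix}.map: empty marker list")
    ids: list[str] = []
    rows: list[list[str]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            ids.append(fields[1])
            rows.append(fields[6:])
    if not rows:
        raise ValueError(f"{prefix}.ped: no individuals")
    alleles = np.array(rows, dtype="U2").reshape(len(rows), m, 2)
    # Determine A1 per marker: the lexicographically smaller of the observed
    # alleles, unless a .bim-style reference is irrelevant here; dosage counts A1.
    dos = np.full((len(rows), m), np.nan)
    a1_list: list[str] = []
    a2_list: list[str] = []
    for j in range(m):
        col = alleles[:, j, :]
        seen = sorted({a for a in col.ravel() if a not in ("0", "-9")})
        if len(seen) > 2:
            raise ValueError(f"marker {mapdf['id'][j]}: more than two alleles {seen}")
        a1 = seen[0] if seen else "0"
        a2 = seen[1] if len(seen) > 1 else a1
        a1_list.append(a1)
        a2_list.append(a2)
        miss = (col == "0").any(axis=1) | (col == "-9").any(axis=1)
        dos[:, j] = np.where(miss, np.nan, (col == a1).sum(axis=1))
    return GenotypeMatrix(
        individual_ids=ids,
        marker_ids=list(mapdf["id"]),
        chromosome=mapdf["chrom"].to_numpy(),
        position=mapdf["bp"].astype(np.int64).to_numpy(),
        dosages=dos,
        a1=a1_list,
        a2=a2_list,
    )


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "bp", "a1", "a2"],
        dtype=str,
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    n, m = len(fam), len(bim)
    if m == 0:
        raise ValueError(f"{prefix}.bim: empty marker list")
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(
            f"{prefix}.bed: bad magic bytes {raw[:3].hex()} (expected SNP-major 6c1b01)"
        )
    bytes_per_marker = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_marker * m:
        raise ValueError(
            f"{prefix}.bed: size {body.size} bytes inconsistent with "
            f"{n} individuals x {m} markers"
        )
    codes = body.reshape(m, bytes_per_marker)
    # unpack 2-bit genotype codes, individual-minor within byte
    shifts = np.arange(4) * 2
    g2 = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    g2 = g2.reshape(m, bytes_per_marker * 4)[:, :n]
    # PLINK coding: 00 hom A1 (dosage 2), 10 het (1), 11 hom A2 (0), 01 missing
    dos = np.full(g2.shape, np.nan)
    dos[g2 == 0] = 2.0
    dos[g2 == 2] = 1.0
    dos[g2 == 3] = 0.0
    return GenotypeMatrix(
        individual_ids=list(fam[1]),
        marker_ids=list(bim["id"]),
        chromosome=bim["chrom"].to_numpy(),
        position=bim["bp"].astype(np.int64).to_numpy(),
        dosages=dos.T,
        a1=list(bim["a1"]),
        a2=list(bim["a2"]),
    )


def read_plink(prefix: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from PLINK files at ``prefix`` (.ped/.map or .bed/.bim/.fam).

    Dosages count the A1 allele; missing genotypes become ``nan``.  When
    ``format`` is None the binary fileset is preferred if present.
    """
    prefix = Path(prefix)
    if format is None:
        format = "bed" if prefix.with_suffix(".bed").exists() else "ped"
    if format == "ped":
        return _read_ped(prefix)
    if format == "bed":
        return _read_bed(prefix)
    raise ValueError(f"unknown format {format!r} (expected 'ped' or 'bed')")


def write_plink(G: GenotypeMatrix, prefix: str | Path, format: str = "ped") -> None:
    """Write a (complete, unimputed) GenotypeMatrix as PLINK .ped/.map or .bed/.bim/.fam."""
    prefix = Path(prefix)
    a1 = G.a1 or ["A"] * G.n_markers
    a2 = G.a2 or ["G"] * G.n_markers
    if format == "ped":
        with open(prefix.with_suffix(".map"), "w") as fh:
            for j in range(G.n_markers):
                fh.write(f"{G.chromosome[j]} {G.marker_ids[j]} 0 {G.position[j]}\n")
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, iid in enumerate(G.individual_ids):
                parts = [str(iid), str(iid), "0", "0", "0", "-9"]
                for j in range(G.n_markers):
                    d = G.dosages[i, j]
                    if np.isnan(d):
                        parts += ["0", "0"]
                    else:
                        k = int(round(d))
                        parts += [a1[j]] * k + [a2[j]] * (2 - k)
                fh.write(" ".join(parts) + "\n")
    elif format == "bed":
        with open(prefix.with_suffix(".bim"), "w") as fh:
            for j in range(G.n_markers):
                fh.write(
                    f"{G.chromosome[j]}\t{G.marker_ids[j]}\t0\t{G.position[j]}\t{a1[j]}\t{a2[j]}\n"
                )
        with open(prefix.with_suffix(".fam"), "w") as fh:
            for iid in G.individual_ids:
                fh.write(f"{iid} {iid} 0 0 0 -9\n")
        n = G.n_individuals
        bytes_per_marker = (n + 3) // 4
        codes = np.full((G.n_markers, bytes_per_marker * 4), 1, dtype=np.uint8)
        d = G.dosages.T  # markers x individuals
        block = np.where(np.isnan(d), 1, np.where(d == 2, 0, np.where(d == 1, 2, 3)))
        codes[:, :n] = block.astype(np.uint8)
        shifts = np.arange(4) * 2
        packed = (
            (codes.reshape(G.n_markers, bytes_per_marker, 4) << shifts[None, None, :])
            .sum(axis=2)
            .astype(np.uint8)
        )
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(packed.tobytes())
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts and sums the probabilities of all tables no more likely
    than the observed one (the exact test PLINK's --hwe applies; no mid-p).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no individuals (all genotype counts zero)")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0:
        return 1.0
    # probabilities over possible heterozygote counts (same parity as n_rare)
    het_obs = n_Aa
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalized log-probabilities via the standard recurrence
    logp = np.zeros(len(hets))
    for k in range(1, len(hets)):
        h = hets[k]
        hom_r = (n_rare - h) // 2  # rare homozygotes at het count h
        # P(h) / P(h-2) = 4*hom_r_prev*hom_c_prev / (h*(h-1)) with prev at h-2
        hom_r_prev = hom_r + 1
        hom_c_prev = n - (h - 2) - hom_r_prev
        logp[k] = logp[k - 1] + np.log(4.0 * hom_r_prev * hom_c_prev) - np.log(
            float(h) * (h - 1)
        )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hets == het_obs][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filter and imputation
# ---------------------------------------------------------------------------


def _marker_qc_table(G: GenotypeMatrix, t: QCThresholds) -> pd.DataFrame:
    q = G.counted_allele_frequency
    maf = np.minimum(q, 1 - q)
    miss = G.missing_rate
    hwe = np.ones(G.n_markers)
    for j in range(G.n_markers):
        d = G.dosages[:, j]
        d = d[~np.isnan(d)]
        n_aa = int((d == 0).sum())
        n_het = int((d == 1).sum())
        n_AA = int((d == 2).sum())
        if n_AA + n_het + n_aa > 0:
            hwe[j] = hwe_exact_p(n_AA, n_het, n_aa)
    return pd.DataFrame(
        {"marker_id": G.marker_ids, "maf": maf, "missing": miss, "hwe_p": hwe}
    )


def qc_filter(
    G: GenotypeMatrix, t: QCThresholds | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply MAF / missingness / Hardy-Weinberg marker filters.

    Retains markers with MAF > ``maf_min`` and missing proportion <
    ``missing_max`` and HWE exact p > ``hwe_p_min``.  Returns the filtered
    matrix and a report with one row per removed marker (columns
    ``marker_id``, ``reason``, ``value``); a marker failing several filters is
    reported once per failed criterion.
    """
    if G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    t = t or QCThresholds()
    tab = _marker_qc_table(G, t)
    fail_maf = tab["maf"] <= t.maf_min
    fail_miss = tab["missing"] >= t.missing_max
    fail_hwe = tab["hwe_p"] <= t.hwe_p_min
    rows = []
    for j in range(G.n_markers):
        if fail_maf[j]:
            rows.append((G.marker_ids[j], "maf", tab["maf"][j]))
        if fail_miss[j]:
            rows.append((G.marker_ids[j], "missing", tab["missing"][j]))
        if fail_hwe[j]:
            rows.append((G.marker_ids[j], "hwe", tab["hwe_p"][j]))
    report = pd.DataFrame(rows, columns=["marker_id", "reason", "value"])
    keep = ~(fail_maf | fail_miss | fail_hwe)
    if not keep.any():
        raise ValueError(
            "all markers removed by QC "
            f"(maf: {int(fail_maf.sum())}, missing: {int(fail_miss.sum())}, "
            f"hwe: {int(fail_hwe.sum())})"
        )
    return G.subset_markers(np.flatnonzero(keep.to_numpy())), report


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-marker mean of the observed calls."""
    d = G.dosages
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        bad = [G.marker_ids[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"markers with all genotypes missing: {bad}")
    if not np.isnan(d).any():
        return G
    means = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), means[None, :], d)
    out = replace(G)
    out.dosages = filled
    return out


# ---------------------------------------------------------------------------
# Phenotype correction
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype TSV with header ``id trait value farm month year``."""
    df = pd.read_csv(path, sep="\t")
    need = {"id", "trait", "value", "farm", "month", "year"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: phenotype table must have columns {sorted(need)}")
    return [
        PhenotypeRecord(str(r.id), str(r.trait), float(r.value), str(r.farm), int(r.month), int(r.year))
        for r in df.itertuples()
    ]


def adjust_phenotypes(records: Sequence[PhenotypeRecord]) -> pd.Series:
    """Correct phenotypes for farm, month-of-age and slaughter-year effects.

    Fits value ~ intercept + farm + month + year (all factors) by OLS and
    returns the residuals — the corrected phenotypes handed to the genomic
    models — as a Series indexed by individual id, in input order.  The
    residuals have mean zero by construction.
    """
    if not records:
        raise ValueError("no phenotype records")
    if not all(np.isfinite(r.value) for r in records):
        raise ValueError("non-finite phenotype value")
    df = pd.DataFrame(
        {
            "id": [r.individual_id for r in records],
            "value": [r.value for r in records],
            "farm": pd.Categorical([r.farm for r in records]),
            "month": pd.Categorical([r.month for r in records]),
            "year": pd.Categorical([r.year for r in records]),
        }
    )
    X_parts = [np.ones((len(df), 1))]
    cols = ["intercept"]
    for fac in ("farm", "month", "year"):
        dummies = pd.get_dummies(df[fac], prefix=fac, drop_first=True, dtype=float)
        X_parts.append(dummies.to_numpy())
        cols += list(dummies.columns)
    X = np.hstack(X_parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR: pivots beyond the rank
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        aliased = sorted(cols[piv[k]] for k in range(rank, X.shape[1]))
        raise ValueError(f"confounded fixed-effect levels (aliased columns): {aliased}")
    beta, *_ = np.linalg.lstsq(X, df["value"].to_numpy(), rcond=None)
    resid = df["value"].to_numpy() - X @ beta
    return pd.Series(resid, index=df["id"], name="corrected")
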