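"""PLINK I/O, Hardy-Weinberg exact test, QC filtering and phenotype correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import parabayes as pb
from parabayes.genoio import read_plink, write_plink

from _oracles import hwe_exact_brute


@pytest.fixture()
def toy_matrix() -> pb.GenotypeMatrix:
    rng = np.random.default_rng(0)
    d = rng.integers(0, 3, size=(8, 12)).astype(float)
    d[0, 3] = np.nan
    d[2, 3] = np.nan
    return pb.GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(8)],
        marker_ids=[f"m{j}" for j in range(12)],
        chromosome=np.ones(12, int),
        position=np.arange(1, 13) * 1000,
        dosages=d,
    )


# --- PLINK formats --------------------------------------------------------


def test_handwritten_ped_dosages(tmp_path):
    (tmp_path / "toy.map").write_text("1 snp1 0 100\n1 snp2 0 200\n")
    (tmp_path / "toy.ped").write_text(
        "f1 ind1 0 0 0 -9 A A A G\n"
        "f2 ind2 0 0 0 -9 A G G G\n"
    )
    G = read_plink(tmp_path / "toy", format="ped")
    assert G.individual_ids == ["ind1", "ind2"]
    # dosages count the A allele (A1 = lexicographically first observed)
    np.testing.assert_array_equal(G.dosages, [[2, 1], [1, 0]])


def test_ragged_ped_raises(tmp_path):
    (tmp_path / "bad.map").write_text("1 snp1 0 100\n")
    (tmp_path / "bad.ped").write_text("f1 i1 0 0 0 -9 A A\nf2 i2 0 0 0 -9 A\n")
    with pytest.raises(ValueError, match="line 2"):
        read_plink(tmp_path / "bad", format="ped")


def test_empty_marker_list_raises(tmp_path):
    (tmp_path / "e.map").write_text("")
    (tmp_path / "e.ped").write_text("")
    with pytest.raises((ValueError, pd.errors.EmptyDataError)):
        read_plink(tmp_path / "e", format="ped")


def test_bad_bed_magic_raises(tmp_path):
    (tmp_path / "x.bim").write_text("1\tsnp1\t0\t100\tA\tG\n")
    (tmp_path / "x.fam").write_text("f1 i1 0 0 0 -9\n")
    (tmp_path / "x.bed").write_bytes(bytes([0x00, 0x1B, 0x01, 0xFF]))
    with pytest.raises(ValueError, match="magic"):
        read_plink(tmp_path / "x", format="bed")


def test_duplicate_marker_ids_raise():
    with pytest.raises(ValueError, match="duplicated"):
        pb.GenotypeMatrix(
            individual_ids=["i1"],
            marker_ids=["m", "m"],
            chromosome=np.array([1, 1]),
            position=np.array([1, 2]),
            dosages=np.array([[0.0, 1.0]]),
        )


@pytest.mark.parametrize("fmt", ["ped", "bed"])
def test_plink_roundtrip(tmp_path, toy_matrix, fmt):
    write_plink(toy_matrix, tmp_path / "rt", format=fmt)
    back = read_plink(tmp_path / "rt", format=fmt)
    np.testing.assert_allclose(back.dosages, toy_matrix.dosages, equal_nan=True)
    assert back.individual_ids == toy_matrix.individual_ids
    assert back.marker_ids == toy_matrix.marker_ids


# --- Hardy-Weinberg exact test -------------------------------------------


@pytest.mark.parametrize(
    "counts,expected",
    [
        ((25, 50, 25), 1.0),  # perfect HWE proportions are the mode
        ((100, 0, 0), 1.0),  # monomorphic
    ],
)
def test_hwe_exact_known_values(counts, expected):
    assert pb.hwe_exact_p(*counts) == pytest.approx(expected)


def test_hwe_complete_het_deficit_is_extreme():
    assert pb.hwe_exact_p(50, 0, 50) < 1e-6


def test_hwe_invalid_counts():
    with pytest.raises(ValueError):
        pb.hwe_exact_p(0, 0, 0)
    with pytest.raises(ValueError):
        pb.hwe_exact_p(-1, 2, 3)


@settings(deadline=None, max_examples=120, derandomize=True)
@given(
    n_AA=st.integers(0, 50),
    n_Aa=st.integers(0, 50),
    n_aa=st.integers(0, 50),
)
def test_hwe_matches_brute_force_enumeration(n_AA, n_Aa, n_aa):
    if n_AA + n_Aa + n_aa == 0:
        return
    assert pb.hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(
        hwe_exact_brute(n_AA, n_Aa, n_aa), abs=1e-12
    )


# --- QC filter ------------------------------------------------------------


def _matrix_from_columns(cols: dict[str, np.ndarray]) -> pb.GenotypeMatrix:
    names = list(cols)
    d = np.column_stack([cols[m] for m in names]).astype(float)
    return pb.GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(d.shape[0])],
        marker_ids=names,
        chromosome=np.ones(len(names), int),
        position=np.arange(1, len(names) + 1),
        dosages=d,
    )


def test_qc_filter_reasons():
    n = 100
    rng = np.random.default_rng(1)
    good = rng.binomial(2, 0.4, n).astype(float)
    low_maf = np.zeros(n)
    low_maf[:8] = 1.0  # MAF 0.04
    missing = rng.binomial(2, 0.4, n).astype(float)
    missing[:6] = np.nan  # 6% missing
    hwe_bad = np.concatenate([np.zeros(50), np.full(50, 2.0)])  # no hets
    G = _matrix_from_columns(
        {"good": good, "lowmaf": low_maf, "miss": missing, "hwe": hwe_bad}
    )
    kept, report = pb.qc_filter(G, pb.QCThresholds(0.05, 0.05, 1e-6))
    assert kept.marker_ids == ["good"]
    reasons = dict(zip(report["marker_id"], report["reason"]))
    assert reasons["lowmaf"] == "maf"
    assert reasons["miss"] == "missing"
    assert reasons["hwe"] == "hwe"


def test_qc_filter_idempotent():
    rng = np.random.default_rng(2)
    d = rng.binomial(2, rng.uniform(0.1, 0.9, 30), size=(80, 30)).astype(float)
    G = pb.GenotypeMatrix(
        [f"i{k}" for k in range(80)], [f"m{j}" for j in range(30)],
        np.ones(30, int), np.arange(1, 31), d,
    )
    once, _ = pb.qc_filter(G)
    twice, rep2 = pb.qc_filter(once)
    assert twice.marker_ids == once.marker_ids
    assert rep2.empty


def test_qc_all_removed_raises():
    G = _matrix_from_columns({"mono1": np.zeros(50), "mono2": np.full(50, 2.0)})
    with pytest.raises(ValueError, match="all markers removed"):
        pb.qc_filter(G)


# --- imputation -----------------------------------------------------------


def test_impute_mean():
    G = _matrix_from_columns({"m": np.array([0.0, 2.0, np.nan])})
    out = pb.impute_missing(G)
    np.testing.assert_allclose(out.dosages[:, 0], [0.0, 2.0, 1.0])


def test_impute_noop_and_all_missing():
    G = _matrix_from_columns({"m": np.array([0.0, 1.0, 2.0])})
    assert pb.impute_missing(G) is G
    bad = _matrix_from_columns({"m": np.array([np.nan, np.nan])})
    with pytest.raises(ValueError, match="all genotypes missing"):
        pb.impute_missing(bad)


# --- phenotype correction -------------------------------------------------


def _rec(i, value, farm="A", month=20, year=2020):
    return pb.PhenotypeRecord(f"a{i}", "cw", value, farm, month, year)


def test_single_level_model_centers_values():
    recs = [_rec(i, v) for i, v in enumerate([3.0, 5.0, 10.0])]
    corr = pb.adjust_phenotypes(recs)
    np.testing.assert_allclose(corr.to_numpy(), [-3.0, -1.0, 4.0])


def test_exact_farm_offset_removed():
    recs = [_rec(i, 7.0, farm="A") for i in range(5)]
    recs += [_rec(5 + i, 17.0, farm="B") for i in range(5)]
    corr = pb.adjust_phenotypes(recs)
    np.testing.assert_allclose(corr.to_numpy(), np.zeros(10), atol=1e-10)


def test_permutation_invariance_and_orthogonality(rng):
    farms = rng.choice(["A", "B", "C"], 60)
    months = rng.choice([18, 20, 22], 60)
    years = rng.choice([2019, 2020], 60)
    vals = rng.standard_normal(60) + pd.factorize(farms)[0] * 2.0
    recs = [
        pb.PhenotypeRecord(f"a{i}", "t", vals[i], farms[i], months[i], years[i])
        for i in range(60)
    ]
    corr = pb.adjust_phenotypes(recs)
    assert abs(corr.to_numpy().mean()) < 1e-10
    perm = rng.permutation(60)
    corr2 = pb.adjust_phenotypes([recs[i] for i in perm])
    assert corr.sort_index().equals(corr2.sort_index()) or np.allclose(
        corr.sort_index().to_numpy(), corr2.sort_index().to_numpy()
    )
    # residuals orthogonal to every factor's indicator columns
    for fac in (farms, months, years):
        for level in np.unique(fac):
            ind = (fac == level).astype(float)
            assert abs(ind @ corr.to_numpy()) <= 1e-8 * 60


def test_confounded_factors_raise():
    # farm perfectly aliased with year
    recs = [_rec(i, float(i), farm="A", year=2019) for i in range(4)]
    recs += [_rec(4 + i, float(i), farm="B", year=2020) for i in range(4)]
    with pytest.raises(ValueError, match="confounded|aliased"):
        pb.adjust_phenotypes(recs)


def test_nonfinite_value_raises():
    with pytest.raises(ValueError, match="finite"):
        pb.adjust_phenotypes([_rec(0, np.nan)])
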