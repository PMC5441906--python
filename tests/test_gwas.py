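"""Kinship construction, mixed-model scan, FDR, R2 and p_G arithmetic."""

import numpy as np
import pandas as pd
import pytest

from mqtlnet import (
    SimConfig,
    simulate_genotypes,
    simulate_metabolome,
    entry_means_all,
    kinship,
    mlm_scan,
    fdr_adjust,
    variance_explained,
    pg,
)
from mqtlnet.data import GenotypeMatrix
from mqtlnet.trial import Blues


def test_kinship_hand_computed_3x3(toy_geno):
    """VanRaden cross-product for dosages ((0,2),(2,0),(2,2)), p = (2/3, 2/3)."""
    K = kinship(toy_geno, ridge=0.0)
    p = 2.0 / 3.0
    Z = np.array([[0, 2], [2, 0], [2, 2]], dtype=float) - 2 * p
    expected = Z @ Z.T / (2 * 2 * p * (1 - p))
    np.testing.assert_allclose(K.to_numpy(), expected, atol=1e-12)


def test_duplicated_line_offdiagonal_equals_diagonal_average():
    rng = np.random.default_rng(0)
    d = rng.choice([0.0, 2.0], size=(5, 50))
    d[1] = d[0]
    g = GenotypeMatrix([f"L{i}" for i in range(5)], [f"S{j}" for j in range(50)], d)
    K = kinship(g, ridge=0.0).to_numpy()
    assert K[0, 1] == pytest.approx((K[0, 0] + K[1, 1]) / 2, abs=1e-12)


def test_unrelated_lines_have_near_zero_offdiagonals():
    means = []
    for seed in range(3):
        cfg = SimConfig(n_lines=150, n_families=150, n_snps=5000, n_traits=1,
                        missing_rate=0, het_rate=0, seed=seed)
        g = simulate_genotypes(cfg)
        K = kinship(g).to_numpy()
        off = K[np.triu_indices(150, k=1)]
        means.append(off.mean())
    assert abs(np.mean(means)) < 0.02


def test_kinship_rejects_monomorphic_panel():
    g = GenotypeMatrix(["a", "b"], ["s1", "s2"], np.array([[2.0, 2.0], [2.0, 2.0]]))
    with pytest.raises(ValueError):
        kinship(g)


# --- mixed-model scan -------------------------------------------------------

@pytest.fixture(scope="module")
def scan_setup():
    cfg = SimConfig(n_lines=80, n_families=8, n_snps=120, n_traits=1,
                    qtl_map=[("m01", 7, 1.2)], maf_range=(0.2, 0.5),
                    missing_rate=0, het_rate=0, seed=17)
    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_metabolome(geno, cfg)
    em = entry_means_all(pheno)
    K = kinship(geno)
    return geno, pheno, em, K


def test_gamma_zero_reproduces_ols(scan_setup):
    """With the polygenic ratio pinned at zero, the mixed-model Wald F must
    equal the ordinary least-squares F computed independently."""
    geno, pheno, em, K = scan_setup
    mixed0 = mlm_scan(em, geno, K, "m01", fix_gamma_zero=True)
    plain = mlm_scan(em, geno, None, "m01")
    np.testing.assert_allclose(mixed0["wald_F"], plain["wald_F"], rtol=1e-8)

    # independent OLS oracle for a few SNPs
    long = em.stacked("m01")
    y = long["value"].to_numpy()
    E = pd.get_dummies(long["env"]).to_numpy(dtype=float)
    li = {l: i for i, l in enumerate(geno.lines)}
    rows = [li[l] for l in long["line"]]
    for j in [0, 7, 50]:
        x = geno.dosage[:, j].copy()
        x -= x.mean()
        X = np.column_stack([E, x[rows]])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (len(y) - rank)
        se = np.sqrt(s2 * np.linalg.pinv(X.T @ X)[-1, -1])
        f_oracle = (beta[-1] / se) ** 2
        assert plain.loc[j, "wald_F"] == pytest.approx(f_oracle, rel=1e-8)


def test_planted_qtl_is_top_hit_and_invariances(scan_setup):
    geno, pheno, em, K = scan_setup
    res = mlm_scan(em, geno, K, "m01")
    assert int(res["p_snp"].idxmin()) == 7

    # affine rescaling of the trait leaves the Wald p unchanged
    em2 = entry_means_all(pheno)
    em2.means["m01"] = em2.means["m01"] * 5.0 - 3.0
    res2 = mlm_scan(em2, geno, K, "m01")
    np.testing.assert_allclose(res["p_snp"], res2["p_snp"], rtol=1e-6)

    # flipping allele coding 0 <-> 2 flips the effect sign, not the p
    flipped = GenotypeMatrix(
        list(geno.lines), list(geno.snps), 2.0 - geno.dosage, geno.snp_map
    )
    res3 = mlm_scan(em, flipped, K, "m01")
    np.testing.assert_allclose(res["p_snp"], res3["p_snp"], rtol=1e-6)
    assert res3.loc[7, "effect"] == pytest.approx(-res.loc[7, "effect"], rel=1e-6)


def test_snpxe_lrt_reported_for_requested_snps(scan_setup):
    geno, pheno, em, K = scan_setup
    res = mlm_scan(em, geno, K, "m01", snpxe="below_cut", snpxe_pcut=1e-4)
    tested = res["p_snpxe"].notna()
    assert tested.sum() >= 1
    assert ((res.loc[tested, "p_snpxe"] >= 0) & (res.loc[tested, "p_snpxe"] <= 1)).all()
    # the simulated interaction is i.i.d. noise: no strong interaction signal
    assert res.loc[7, "p_snpxe"] > 0.001


def test_non_psd_kinship_rejected(scan_setup):
    geno, pheno, em, K = scan_setup
    bad = K.copy()
    bad.iloc[0, 1] = bad.iloc[1, 0] = 50.0
    with pytest.raises(ValueError, match="positive semi-definite"):
        mlm_scan(em, geno, bad, "m01")


# --- FDR --------------------------------------------------------------------

def test_bh_stepup_hand_example():
    q, flags = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]), 0.20)
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert flags.all()


def test_bh_single_and_degenerate():
    q, _ = fdr_adjust(np.array([0.37]))
    assert q[0] == pytest.approx(0.37)
    q, flags = fdr_adjust(np.array([1.0, 1.0, 1.0]))
    np.testing.assert_allclose(q, 1.0)
    assert not flags.any()
    q, flags = fdr_adjust(np.array([]))
    assert q.size == 0 and flags.size == 0


def test_bh_monotone_and_nested_flags():
    rng = np.random.default_rng(8)
    p = rng.uniform(size=200) ** 2
    q, _ = fdr_adjust(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q >= p - 1e-12).all()
    _, f10 = fdr_adjust(p, 0.10)
    _, f20 = fdr_adjust(p, 0.20)
    assert (f20 | ~f10).all()  # flags at 0.10 are a subset of flags at 0.20


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        fdr_adjust(np.array([0.5, 1.5]))


# --- variance explained and p_G ---------------------------------------------

def _blues_from(y, lines):
    return Blues(pd.DataFrame({"t": y}, index=lines))


def test_exact_linear_relation_gives_full_r2():
    rng = np.random.default_rng(9)
    x = rng.choice([0.0, 2.0], size=40)
    lines = [f"L{i}" for i in range(40)]
    g = GenotypeMatrix(lines, ["s"], x.reshape(-1, 1))
    r2, joint = variance_explained(_blues_from(2.0 * x + 1.0, lines), g, ["s"], "t")
    assert r2["s"] == pytest.approx(100.0)
    assert joint == pytest.approx(100.0)


def test_null_r2_expectation_near_1_over_n():
    rng = np.random.default_rng(10)
    n = 135
    lines = [f"L{i}" for i in range(n)]
    y = rng.normal(size=n)
    vals = []
    for rep in range(300):
        x = rng.choice([0.0, 2.0], size=n)
        g = GenotypeMatrix(lines, ["s"], x.reshape(-1, 1))
        r2, _ = variance_explained(_blues_from(y, lines), g, ["s"], "t")
        vals.append(r2["s"])
    assert np.mean(vals) == pytest.approx(100.0 / (n - 1), rel=0.35)


def test_duplicated_snp_does_not_inflate_joint_r2():
    rng = np.random.default_rng(11)
    x = rng.choice([0.0, 2.0], size=50)
    y = x + rng.normal(size=50)
    lines = [f"L{i}" for i in range(50)]
    g = GenotypeMatrix(lines, ["s1", "s2"], np.column_stack([x, x]))
    _, joint_two = variance_explained(_blues_from(y, lines), g, ["s1", "s2"], "t")
    _, joint_one = variance_explained(_blues_from(y, lines), g, ["s1"], "t")
    assert joint_two == pytest.approx(joint_one, abs=1e-8)


def test_constant_snp_warns_and_zero():
    lines = ["a", "b", "c", "d"]
    g = GenotypeMatrix(lines, ["s"], np.full((4, 1), 2.0))
    with pytest.warns(UserWarning, match="constant"):
        r2, _ = variance_explained(_blues_from(np.arange(4.0), lines), g, ["s"], "t")
    assert r2["s"] == 0.0


@pytest.mark.parametrize(
    "r2,h2,expected",
    [(12.69, 0.737, 17.22), (17.36, 0.364, 47.69), (0.0, 0.5, 0.0)],
)
def test_pg_ratio(r2, h2, expected):
    val, capped = pg(r2, h2)
    assert val == pytest.approx(expected, abs=0.005)
    assert not capped


def test_pg_cap_and_invalid():
    val, capped = pg(80.0, 0.5)
    assert val == 100.0 and capped
    with pytest.warns(UserWarning):
        val, _ = pg(10.0, 0.0)
    assert np.isnan(val)
    with pytest.raises(ValueError):
        pg(150.0, 0.5)
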