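"""Entry means, BLUEs, REML variance components, heritability, repeatability."""

import numpy as np
import pandas as pd
import pytest

from mqtlnet import (
    SimConfig,
    simulate_genotypes,
    simulate_metabolome,
    adjusted_entry_means,
    entry_means_all,
    blues_across_envs,
    reml_varcomp,
    heritability,
    repeatability,
    subgroup_heritability,
)
from mqtlnet.data import PhenotypeTable
from mqtlnet.reml import lrt_variance, reml_fit
from mqtlnet.trial import EntryMeans


def _pheno(rows):
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["line", "env", "rep", "block", "trait", "value"])
    )


# --- adjusted entry means ---------------------------------------------------

def test_balanced_complete_design_reduces_to_line_means():
    rng = np.random.default_rng(1)
    rows = []
    vals = {}
    for line in ["a", "b", "c", "d"]:
        base = rng.normal()
        vals[line] = []
        for rep in ["R1", "R2"]:
            v = base + rng.normal(scale=0.3)
            vals[line].append(v)
            rows.append((line, "E1", rep, "B1", "t", v))
    em = adjusted_entry_means(_pheno(rows), "E1")
    for line in vals:
        assert em.loc[line, "t"] == pytest.approx(np.mean(vals[line]), abs=1e-8)


def test_incomplete_block_effect_absorbed():
    """With a large planted block effect, adjusted means recover the true
    line values far better than raw line means, and match the fixed-effect
    least-squares solution computed independently."""
    true = {"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0}
    b_eff = 10.0
    rows = []
    # rep1 blocks {a,b}, {c,d}; rep2 blocks {b,c}, {d,a}; +b_eff on rep2 block B2
    design = [
        ("R1", "B1", ["a", "b"], 0.0),
        ("R1", "B2", ["c", "d"], 0.0),
        ("R2", "B1", ["b", "c"], 0.0),
        ("R2", "B2", ["d", "a"], b_eff),
    ]
    rng = np.random.default_rng(2)
    for rep, blk, lines, eff in design:
        for line in lines:
            rows.append((line, "E1", rep, blk, "t", true[line] + eff + rng.normal(scale=1e-3)))
    em = adjusted_entry_means(_pheno(rows), "E1")["t"]
    raw = _pheno(rows).frame.groupby("line")["value"].mean()
    truth = pd.Series(true)
    adj_err = (em - em.mean() - (truth - truth.mean())).abs().max()
    raw_err = (raw - raw.mean() - (truth - truth.mean())).abs().max()
    assert adj_err < raw_err
    assert adj_err < 0.6  # block effect largely absorbed (shrinkage leaves a little)


def test_single_replicate_no_blocks_returns_raw_values():
    rows = [("a", "E1", "R1", "B1", "t", 1.5), ("b", "E1", "R1", "B1", "t", -0.5)]
    em = adjusted_entry_means(_pheno(rows), "E1")
    assert em.loc["a", "t"] == pytest.approx(1.5)
    assert em.loc["b", "t"] == pytest.approx(-0.5)


# --- BLUEs ------------------------------------------------------------------

def _em_from_matrix(mat: pd.DataFrame, trait="t") -> EntryMeans:
    em = EntryMeans()
    em.means[trait] = mat
    return em


def test_complete_table_blue_is_row_mean():
    mat = pd.DataFrame(
        np.arange(12, dtype=float).reshape(4, 3),
        index=["a", "b", "c", "d"],
        columns=["E1", "E2", "E3"],
    )
    blues = blues_across_envs(_em_from_matrix(mat))
    np.testing.assert_allclose(blues.values["t"], mat.mean(axis=1))


def test_missing_cell_matches_normal_equations():
    """One line missing an environment: compare against an independently
    assembled two-way least-squares solve."""
    rng = np.random.default_rng(3)
    line_eff = {"a": 0.0, "b": 1.0, "c": -1.0}
    env_eff = {"E1": 5.0, "E2": -5.0, "E3": 0.0}
    mat = pd.DataFrame(
        {e: [line_eff[l] + env_eff[e] for l in line_eff] for e in env_eff},
        index=list(line_eff),
    )
    mat.loc["b", "E2"] = np.nan
    blues = blues_across_envs(_em_from_matrix(mat))

    # oracle: explicit dummy design, env deviation-coded, lstsq
    rows = [(l, e, mat.loc[l, e]) for l in mat.index for e in mat.columns
            if not np.isnan(mat.loc[l, e])]
    lines = list(mat.index)
    envs = list(mat.columns)
    X = np.zeros((len(rows), len(lines) + len(envs) - 1))
    y = np.zeros(len(rows))
    for k, (l, e, v) in enumerate(rows):
        X[k, lines.index(l)] = 1.0
        ei = envs.index(e)
        if ei < len(envs) - 1:
            X[k, len(lines) + ei] = 1.0
        else:
            X[k, len(lines):] = -1.0
        y[k] = v
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(blues.values["t"].to_numpy(), beta[: len(lines)], atol=1e-10)


def test_constant_trait_gives_equal_blues():
    mat = pd.DataFrame(4.2, index=["a", "b"], columns=["E1", "E2"])
    blues = blues_across_envs(_em_from_matrix(mat))
    np.testing.assert_allclose(blues.values["t"], 4.2, atol=1e-9)


def test_blue_invariant_to_environment_order():
    rng = np.random.default_rng(4)
    mat = pd.DataFrame(rng.normal(size=(5, 3)), index=list("abcde"),
                       columns=["E1", "E2", "E3"])
    b1 = blues_across_envs(_em_from_matrix(mat))
    b2 = blues_across_envs(_em_from_matrix(mat[["E3", "E1", "E2"]]))
    np.testing.assert_allclose(b1.values["t"], b2.values["t"], atol=1e-10)


# --- REML variance components ----------------------------------------------

def _balanced_sim(seed, n_lines=60, var_G=1.0, var_GxE=2.0, var_resid=1.0):
    cfg = SimConfig(n_lines=n_lines, n_families=6, n_snps=30, n_traits=1,
                    var_G=var_G, var_GxE=var_GxE, var_resid=var_resid,
                    block_sd=0.0, n_blocks_per_rep=1, polygenic="iid",
                    missing_rate=0, het_rate=0, seed=seed)
    g = simulate_genotypes(cfg)
    p, _ = simulate_metabolome(g, cfg)
    return p


def anova_oracle(frame: pd.DataFrame):
    """Closed-form expected-mean-square estimators for balanced two-way data."""
    cell = frame.groupby(["line", "env"])["value"].mean().unstack()
    r = frame["rep"].nunique()
    e = frame["env"].nunique()
    g = frame["line"].nunique()
    mse = frame.groupby(["line", "env"])["value"].var(ddof=1).mean()
    gm = cell.values.mean()
    ms_ge = (
        r * ((cell.values - cell.values.mean(1, keepdims=True)
              - cell.values.mean(0, keepdims=True) + gm) ** 2).sum()
        / ((g - 1) * (e - 1))
    )
    ms_g = e * r * ((cell.values.mean(1) - gm) ** 2).sum() / (g - 1)
    return (ms_g - ms_ge) / (e * r), (ms_ge - mse) / r, mse


def test_reml_matches_anova_on_balanced_data():
    p = _balanced_sim(seed=13)
    vc = reml_varcomp(p, "m01", include_rep=False, include_block=False, lrt=False)
    s2g, s2ge, s2e = anova_oracle(p.frame)
    assert vc["sigma2_G"] == pytest.approx(s2g, abs=1e-6)
    assert vc["sigma2_GxE"] == pytest.approx(s2ge, abs=1e-6)
    assert vc["sigma2_e"] == pytest.approx(s2e, abs=1e-6)


def test_zero_noise_attributes_all_variance_to_lines():
    cfg = SimConfig(n_lines=20, n_families=2, n_snps=30, n_traits=1,
                    var_GxE=0.0, var_resid=0.0, block_sd=0.0, env_effect_sd=0.0,
                    n_blocks_per_rep=1, polygenic="iid", missing_rate=0,
                    het_rate=0, seed=8)
    g = simulate_genotypes(cfg)
    p, truth = simulate_metabolome(g, cfg)
    vc = reml_varcomp(p, "m01", include_rep=False, include_block=False, lrt=False)
    line_means = p.frame.groupby("line")["value"].mean()
    assert vc["sigma2_GxE"] == pytest.approx(0.0, abs=1e-6)
    assert vc["sigma2_e"] == pytest.approx(0.0, abs=1e-6)
    assert vc["sigma2_G"] == pytest.approx(line_means.var(ddof=1), rel=1e-3)


def test_permuting_lines_within_env_destroys_genotypic_variance():
    ests = []
    for seed in range(6):
        p = _balanced_sim(seed=100 + seed, var_G=1.0)
        rng = np.random.default_rng(seed)
        frame = p.frame.copy()
        for env, idx in frame.groupby("env").groups.items():
            sub = frame.loc[idx]
            lines = sub["line"].unique()
            perm = dict(zip(lines, rng.permutation(lines)))
            # permute line labels jointly across reps within the environment
            frame.loc[idx, "line"] = sub["line"].map(perm)
        vc = reml_varcomp(PhenotypeTable(frame), "m01",
                          include_rep=False, include_block=False, lrt=False)
        ests.append(vc["sigma2_G"])
    assert np.mean(ests) < 0.15  # truth was 1.0 before permutation


def test_one_env_or_one_rep_rejected():
    rows = [("a", "E1", "R1", "B1", "t", 1.0), ("b", "E1", "R1", "B1", "t", 2.0)]
    with pytest.raises(ValueError):
        reml_varcomp(_pheno(rows), "t")


# --- LRT, heritability, repeatability ---------------------------------------

def test_lrt_boundary_mass_and_tail():
    assert lrt_variance(0.0, 0.0) == pytest.approx(0.5)
    assert lrt_variance(1.92, 0.0) == pytest.approx(0.025, abs=5e-4)  # LR = 3.84
    with pytest.raises(ValueError):
        lrt_variance(0.0, 1.0)


@pytest.mark.parametrize(
    "comps,expected",
    [((1.0, 0.0, 0.0), 1.0), ((1.0, 1.0, 1.0), 1 / (1 + 1 / 3 + 1 / 6)), ((0.0, 1.0, 1.0), 0.0)],
)
def test_heritability_closed_form(comps, expected):
    assert heritability(*comps, n_envs=3, n_reps=2) == pytest.approx(expected)


def test_heritability_degenerate_and_invalid():
    assert np.isnan(heritability(0.0, 0.0, 0.0, 3, 2))
    with pytest.raises(ValueError):
        heritability(-1.0, 0.0, 0.0, 3, 2)


@pytest.mark.parametrize("s2g,s2e,n,expected", [(1, 0, 2, 1.0), (1, 2, 2, 0.5)])
def test_repeatability_closed_form(s2g, s2e, n, expected):
    assert repeatability(s2g, s2e, n) == pytest.approx(expected)


def test_repeatability_recovery_single_environment():
    """Truth w2 = 1 / (1 + 2/2) = 0.5 at (s2_G, s2_e) = (1, 2), 2 reps."""
    from mqtlnet.trial import _within_env_varcomp

    ests = []
    for seed in range(50):
        cfg = SimConfig(n_lines=135, n_families=15, n_snps=30, n_traits=1,
                        n_envs=1, var_G=1.0, var_GxE=0.0, var_resid=2.0,
                        block_sd=0.0, n_blocks_per_rep=1, polygenic="iid",
                        missing_rate=0, het_rate=0, seed=300 + seed)
        g = simulate_genotypes(cfg)
        p, _ = simulate_metabolome(g, cfg)
        s2g, s2e = _within_env_varcomp(p.frame)
        ests.append(repeatability(s2g, s2e, 2))
    assert abs(np.mean(ests) - 0.5) < 0.05


def test_h2_and_w2_invariant_to_affine_rescaling():
    p = _balanced_sim(seed=21)
    vc1 = reml_varcomp(p, "m01", include_rep=False, include_block=False, lrt=False)
    frame = p.frame.copy()
    frame["value"] = 3.0 * frame["value"] + 100.0
    vc2 = reml_varcomp(PhenotypeTable(frame), "m01",
                       include_rep=False, include_block=False, lrt=False)
    h1 = heritability(vc1["sigma2_G"], vc1["sigma2_GxE"], vc1["sigma2_e"], 3, 2)
    h2 = heritability(vc2["sigma2_G"], vc2["sigma2_GxE"], vc2["sigma2_e"], 3, 2)
    assert h1 == pytest.approx(h2, abs=1e-5)


# --- maturity subgroups -----------------------------------------------------

def test_subgroup_heritability_null_and_degenerate():
    cfg = SimConfig(n_lines=90, n_families=9, n_snps=30, n_traits=2,
                    block_sd=0.0, n_blocks_per_rep=1, polygenic="iid",
                    missing_rate=0, het_rate=0, seed=77)
    g = simulate_genotypes(cfg)
    p, truth = simulate_metabolome(g, cfg)
    h2 = subgroup_heritability(p, truth.heading_dates)
    assert set(h2.index) == {"early", "intermediate", "late"}
    # heading date independent of traits: groups should look alike
    assert h2.max() - h2.min() < 0.4

    with pytest.warns(UserWarning, match="constant"):
        h2r = subgroup_heritability(p, pd.Series(160.0, index=p.lines))
    assert len(h2r) == 3


def test_subgroup_heritability_ordered_by_planted_residual_scaling():
    """Groups whose residual noise is scaled up must show decreasing H2."""
    frames, dates = [], {}
    for gi, (scale, seed) in enumerate([(0.3, 1), (2.0, 2), (8.0, 3)]):
        cfg = SimConfig(n_lines=45, n_families=5, n_snps=30, n_traits=1,
                        var_G=1.0, var_GxE=0.5, var_resid=scale,
                        block_sd=0.0, n_blocks_per_rep=1, polygenic="iid",
                        missing_rate=0, het_rate=0, seed=seed)
        g = simulate_genotypes(cfg)
        p, _ = simulate_metabolome(g, cfg)
        frame = p.frame.copy()
        frame["line"] = frame["line"] + f"_g{gi}"
        frames.append(frame)
        for line in frame["line"].unique():
            dates[line] = 150.0 + 10 * gi
    pheno = PhenotypeTable(pd.concat(frames, ignore_index=True))
    h2 = subgroup_heritability(pheno, pd.Series(dates))
    assert h2["early"] > h2["intermediate"] > h2["late"]


# --- REML engine edge case --------------------------------------------------

def test_reml_fit_with_no_random_effects_is_ols():
    rng = np.random.default_rng(5)
    X = np.column_stack([np.ones(30), rng.normal(size=30)])
    y = X @ np.array([1.0, 2.0]) + rng.normal(scale=0.1, size=30)
    res = reml_fit(y, X, [], [])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(res.beta, beta, atol=1e-10)
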