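import itertools

import numpy as np
import pandas as pd
import pytest

from tevar import assoc, sim
from tevar.io import GenomeLayout


def _de_inputs(x, y):
    """Expression/genotype/pairs frames putting values x in carriers."""
    n = len(x) + len(y)
    cols = [f"a{i}" for i in range(n)]
    expr = pd.DataFrame([list(x) + list(y)], index=["g1"], columns=cols)
    geno = pd.DataFrame(
        [[1.0] * len(x) + [0.0] * len(y)], index=["v1"], columns=cols
    )
    pairs = pd.DataFrame({"gene_id": ["g1"], "variant_id": ["v1"]})
    return expr, geno, pairs


def _exact_two_sided_p(x, y):
    """Full-enumeration two-sided Mann-Whitney p (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


def test_mannwhitney_exact_small_groups():
    """Groups {1,2,3} vs {4,5,6,7}: exact two-sided p = 2/35."""
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0]
    expr, geno, pairs = _de_inputs(x, y)
    out = assoc.mannwhitney_de(expr, geno, pairs, min_carriers=3)
    assert len(out) == 1
    assert out["p"].iloc[0] == pytest.approx(2 / 35)
    assert out["p"].iloc[0] == pytest.approx(
        _exact_two_sided_p(np.array(x), np.array(y))
    )


def test_mannwhitney_balanced_groups_p_one():
    expr, geno, pairs = _de_inputs([1.0, 4.0], [2.0, 3.0])
    out = assoc.mannwhitney_de(expr, geno, pairs, min_carriers=2)
    assert out["p"].iloc[0] == pytest.approx(1.0)


def test_mannwhitney_exact_agrees_with_enumeration_randomised():
    rng = np.random.default_rng(5)
    for _ in range(5):
        x = rng.normal(size=rng.integers(3, 7))
        y = rng.normal(size=rng.integers(3, 7))
        expr, geno, pairs = _de_inputs(x, y)
        out = assoc.mannwhitney_de(expr, geno, pairs, min_carriers=2)
        assert out["p"].iloc[0] == pytest.approx(_exact_two_sided_p(x, y))


def test_fold_change_gate():
    rng = np.random.default_rng(0)
    x = 30 + rng.normal(0, 0.5, size=10)
    y = 10 + rng.normal(0, 0.5, size=10)
    expr, geno, pairs = _de_inputs(x, y)
    out = assoc.mannwhitney_de(expr, geno, pairs)
    assert out["fold_change"].iloc[0] == pytest.approx(3.0, rel=0.05)
    assert abs(out["log2_fold_change"].iloc[0]) > 1


def test_small_groups_skipped():
    expr, geno, pairs = _de_inputs([1.0, 2.0], [3.0, 4.0])
    out = assoc.mannwhitney_de(expr, geno, pairs, min_carriers=7)
    assert out.empty


def test_te_gene_models_excluded():
    expr, geno, pairs = _de_inputs([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    out = assoc.mannwhitney_de(expr, geno, pairs, min_carriers=3,
                               exclude_genes=["g1"])
    assert out.empty


def test_qvalues_all_ones():
    q = assoc.qvalue_estimate(np.ones(50))
    np.testing.assert_allclose(q, 1.0)


def test_qvalue_pi0_near_one_under_null():
    rng = np.random.default_rng(11)
    p = rng.random(10_000)
    q = assoc.qvalue_estimate(p)
    # q ~= pi0 * p * m / rank; at the largest p, q ~= pi0
    assert abs(np.max(q) - 1.0) < 0.05 or np.max(q) == 1.0
    big = p > 0.95
    assert np.all(q[big] > 0.9)


def test_qvalue_single_value_with_forced_pi0():
    q = assoc.qvalue_estimate(np.array([0.001]), pi0=1.0)
    assert q[0] == pytest.approx(0.001)


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(3)
    p = rng.random(500) ** 2
    q = assoc.qvalue_estimate(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_qvalue_rejects_out_of_range():
    with pytest.raises(ValueError):
        assoc.qvalue_estimate(np.array([0.5, 1.5]))


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------


def test_burden_planted_u_shape_recovered():
    pheno, geno, mapping = sim.simulate_burden_phenotypes(
        n_accessions=150, n_phenotypes=400, mode="u", seed=1
    )
    res = assoc.burden_test(pheno, geno, mapping)
    assert res.curvature > 0
    assert res.r_squared > 0.8
    assert res.counts.sum() == res.n_observations


def test_burden_null_labels_flat():
    pheno, geno, mapping = sim.simulate_burden_phenotypes(
        n_accessions=150, n_phenotypes=400, mode="null", seed=2
    )
    res = assoc.burden_test(pheno, geno, mapping)
    assert res.r_squared < 0.5


def test_burden_permuting_labels_destroys_enrichment():
    pheno, geno, mapping = sim.simulate_burden_phenotypes(
        n_accessions=150, n_phenotypes=400, mode="u", seed=3
    )
    rng = np.random.default_rng(4)
    permuted = geno.copy()
    permuted.columns = list(geno.columns[rng.permutation(len(geno.columns))])
    res_obs = assoc.burden_test(pheno, geno, mapping)
    res_perm = assoc.burden_test(pheno, permuted[geno.columns], mapping)
    assert res_obs.r_squared > 0.8
    assert res_perm.r_squared < 0.3


def test_burden_no_carriers_errors():
    pheno = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 10)),
                         index=["p1", "p2", "p3"],
                         columns=[f"a{i}" for i in range(10)])
    geno = pd.DataFrame(np.zeros((1, 10)), index=["v1"], columns=pheno.columns)
    with pytest.raises(ValueError):
        assoc.burden_test(pheno, geno, {"p1": ["v1"]})


# ---------------------------------------------------------------------------
# DMR correlation / KS
# ---------------------------------------------------------------------------


def _positions(ids, chrom, starts, width=100):
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": [s + width for s in starts]},
        index=ids,
    )


def test_dmr_correlation_perfect_and_constant():
    cols = [f"a{i}" for i in range(8)]
    g = np.array([1, 0, 1, 0, 1, 1, 0, 0], float)
    geno = pd.DataFrame([g], index=["v1"], columns=cols)
    dmr = pd.DataFrame([g, np.full(8, 0.5)], index=["d1", "d2"], columns=cols)
    out = assoc.dmr_te_correlation(
        dmr, geno,
        _positions(["d1", "d2"], "chr1", [1000, 50_000]),
        _positions(["v1"], "chr1", [1500]),
    )
    assert out.loc["d1", "r"] == pytest.approx(1.0)
    assert np.isnan(out.loc["d2", "r"])
    assert out.loc["d1", "group"] == "TE-DMR"
    assert out.loc["d2", "group"] == "non-TE-DMR"


def test_dmr_correlation_matches_direct_formula():
    rng = np.random.default_rng(8)
    cols = [f"a{i}" for i in range(8)]
    g = (rng.random(8) < 0.5).astype(float)
    meth = rng.random(8)
    geno = pd.DataFrame([g], index=["v1"], columns=cols)
    dmr = pd.DataFrame([meth], index=["d1"], columns=cols)
    out = assoc.dmr_te_correlation(
        dmr, geno,
        _positions(["d1"], "chr1", [1000]),
        _positions(["v1"], "chr1", [1200]),
    )
    assert out.loc["d1", "r"] == pytest.approx(np.corrcoef(g, meth)[0, 1])


def test_ks_examples():
    a = [0.1, 0.2, 0.3]
    d, _ = assoc.ks_compare(a, a)
    assert d == 0.0
    d, _ = assoc.ks_compare([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert d == 1.0
    d, _ = assoc.ks_compare([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
    assert d == pytest.approx(1 / 3)


def test_ks_empty_group_errors():
    with pytest.raises(ValueError):
        assoc.ks_compare([], [0.1, 0.2])


# ---------------------------------------------------------------------------
# Flanking methylation profile
# ---------------------------------------------------------------------------


def _methylome(L, m_value, t_value=10):
    m = np.full(L, float(m_value))
    t = np.full(L, float(t_value))
    return m, t


def test_profile_all_methylated_is_one():
    L = 20_000
    layout = GenomeLayout({"chr1": L}, centromeres={"chr1": 0},
                          pericentromere_bp=1)
    variants = pd.DataFrame(
        {"chrom": ["chr1"], "start": [10_000], "end": [10_000]}, index=["v1"]
    )
    geno = pd.DataFrame([[1.0, 0.0]], index=["v1"], columns=["c", "n"])
    methylomes = {
        acc: {"mCG": {"chr1": _methylome(L, 10)}} for acc in ("c", "n")
    }
    prof = assoc.flanking_methylation_profile(variants, geno, methylomes, layout)
    np.testing.assert_allclose(prof["mCG|carrier|arm"].to_numpy(), 1.0)
    np.testing.assert_allclose(prof["mCG|noncarrier|arm"].to_numpy(), 1.0)


def test_profile_no_cytosines_bin_is_nan():
    L = 20_000
    layout = GenomeLayout({"chr1": L})
    variants = pd.DataFrame(
        {"chrom": ["chr1"], "start": [10_000], "end": [10_000]}, index=["v1"]
    )
    geno = pd.DataFrame([[1.0]], index=["v1"], columns=["c"])
    m, t = _methylome(L, 5)
    t[10_000:10_200] = 0  # first bin right of the breakpoint has no calls
    m[10_000:10_200] = 0
    methylomes = {"c": {"mCG": {"chr1": (m, t)}}}
    prof = assoc.flanking_methylation_profile(variants, geno, methylomes, layout)
    col = prof["mCG|carrier|arm"]
    assert np.isnan(col.loc[0])
    assert col.loc[-200] == pytest.approx(0.5)


def test_profile_planted_step_recovered_in_correct_bins():
    """Carriers methylated at 0.8 within 500 bp of the breakpoint and 0.2
    outside; non-carriers flat at 0.2."""
    L = 20_000
    bp = 10_000
    layout = GenomeLayout({"chr1": L})
    variants = pd.DataFrame(
        {"chrom": ["chr1"], "start": [bp], "end": [bp]}, index=["v1"]
    )
    geno = pd.DataFrame([[1.0, 1.0, 0.0, 0.0]], index=["v1"],
                        columns=["c1", "c2", "n1", "n2"])
    methylomes = {}
    for acc, carrier in [("c1", True), ("c2", True), ("n1", False), ("n2", False)]:
        m, t = _methylome(L, 2)
        if carrier:
            m[bp - 500 : bp + 500] = 8
        methylomes[acc] = {"mCHH": {"chr1": (m, t)}}
    prof = assoc.flanking_methylation_profile(variants, geno, methylomes, layout)
    carrier = prof["mCHH|carrier|arm"]
    noncarrier = prof["mCHH|noncarrier|arm"]
    for offset in (-400, -200, 0, 200):
        assert carrier.loc[offset] == pytest.approx(0.8)
    for offset in (-2000, -800, 600, 1800):
        assert carrier.loc[offset] == pytest.approx(0.2)
    np.testing.assert_allclose(noncarrier.to_numpy(), 0.2)


def test_profile_excludes_te_internal_bases():
    L = 20_000
    layout = GenomeLayout({"chr1": L})
    variants = pd.DataFrame(  # absence variant: TE interval 10_000-10_600
        {"chrom": ["chr1"], "start": [10_000], "end": [10_600]}, index=["v1"]
    )
    geno = pd.DataFrame([[1.0]], index=["v1"], columns=["c"])
    m, t = _methylome(L, 2)
    m[10_000:10_600] = 10  # fully methylated inside the TE: must not leak
    methylomes = {"c": {"mCG": {"chr1": (m, t)}}}
    prof = assoc.flanking_methylation_profile(variants, geno, methylomes, layout)
    col = prof["mCG|carrier|arm"]
    # bins fully inside the TE interval have every base excluded -> NaN
    assert np.isnan(col.loc[0]) and np.isnan(col.loc[200]) and np.isnan(col.loc[400])
    assert col.loc[600] == pytest.approx(0.2)   # first bin past the TE
    assert col.loc[-200] == pytest.approx(0.2)  # left flank untouched


# ---------------------------------------------------------------------------
# Permutation scan
# ---------------------------------------------------------------------------


def test_scan_detects_planted_association():
    geno = sim.simulate_genotype_matrix(
        20, 50, seed=5, freqs=np.full(20, 0.3), na_rate=0.0
    )
    meth = sim.simulate_methylation_panel(
        geno, n_dmrs=30, planted={"dmr00003": "v00007"}, seed=6, na_rate=0.02
    )
    result = assoc.permutation_scan(geno, meth, n_perm=200, seed=7)
    assert bool(result.significant.at["v00007", "dmr00003"])
    assert result.p_floor == pytest.approx(1 / 201)
    pairs = result.to_pairs()
    assert pairs["p"].min() >= result.p_floor
    counts = result.per_variant_counts()
    assert counts["v00007"] >= 1


def test_scan_coverage_filter_drops_sparse_dmrs():
    geno = sim.simulate_genotype_matrix(5, 40, seed=8, freqs=np.full(5, 0.4),
                                        na_rate=0.0)
    meth = sim.simulate_methylation_panel(geno, n_dmrs=10, seed=9, na_rate=0.0)
    meth.iloc[0, :20] = np.nan  # 50% missing -> filtered
    result = assoc.permutation_scan(geno, meth, n_perm=10, seed=1)
    assert "dmr00001" not in result.observed_r.columns


def test_scan_rare_variants_excluded():
    freqs = np.array([0.4, 0.01])
    geno = sim.simulate_genotype_matrix(2, 100, seed=10, freqs=freqs, na_rate=0.0)
    meth = sim.simulate_methylation_panel(geno, n_dmrs=5, seed=11, na_rate=0.0)
    result = assoc.permutation_scan(geno, meth, n_perm=10, seed=1)
    assert list(result.observed_r.index) == ["v00001"]


def test_scan_rejects_bad_n_perm():
    geno = sim.simulate_genotype_matrix(3, 30, seed=1, freqs=np.full(3, 0.4))
    meth = sim.simulate_methylation_panel(geno, n_dmrs=3, seed=2)
    with pytest.raises(ValueError):
        assoc.permutation_scan(geno, meth, n_perm=0)


def test_masked_pearson_matches_complete_case_formula():
    rng = np.random.default_rng(13)
    A = rng.normal(size=(6, 25))
    B = rng.normal(size=(4, 25))
    A[rng.random(A.shape) < 0.15] = np.nan
    B[rng.random(B.shape) < 0.15] = np.nan
    R = assoc.masked_pearson(A, B)
    for i in range(6):
        for j in range(4):
            r, n = assoc.pearson_complete(A[i], B[j])
            if np.isnan(r):
                assert np.isnan(R[i, j])
            else:
                assert R[i, j] == pytest.approx(r, abs=1e-10)
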