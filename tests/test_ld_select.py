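"""Clumping and stepwise conditional selection against hand and OLS oracles."""

import numpy as np
import pytest

from trumpetplot.ld_select import (
    LDReference,
    clump,
    ld_from_genotypes,
    read_ld_matrix,
    stepwise_select,
    write_ld_matrix,
)
from trumpetplot.synthetic import (
    SimConfig,
    draw_architecture,
    marginal_sumstats,
    simulate_cohort,
)

from conftest import make_record, make_table

# ---------------------------------------------------------------- LD matrix


def test_duplicated_column_gives_r_one(rng):
    g = rng.binomial(2, 0.3, size=(500, 1)).astype(float)
    G = np.hstack([g, g, rng.binomial(2, 0.4, size=(500, 1))])
    ld = ld_from_genotypes(G, variant_ids=["a", "b", "c"])
    assert ld.r("a", "b") == pytest.approx(1.0)


def test_independent_columns_near_zero_r(rng):
    G = rng.binomial(2, 0.5, size=(5000, 4)).astype(float)
    ld = ld_from_genotypes(G)
    off = ld.R[~np.eye(4, dtype=bool)]
    # sampling sd of r is ~ 1/sqrt(n)
    assert np.all(np.abs(off) < 5 / np.sqrt(5000))


def test_single_variant_matrix(rng):
    ld = ld_from_genotypes(rng.binomial(2, 0.5, size=(100, 1)).astype(float))
    assert ld.R.shape == (1, 1) and ld.R[0, 0] == 1.0


def test_monomorphic_column_error_names_variant(rng):
    G = np.hstack(
        [rng.binomial(2, 0.5, size=(50, 1)).astype(float), np.zeros((50, 1))]
    )
    with pytest.raises(ValueError, match="v1"):
        ld_from_genotypes(G)


def test_ld_matrix_roundtrip(tmp_path, rng):
    G = rng.binomial(2, 0.4, size=(200, 3)).astype(float)
    ld = ld_from_genotypes(G, variant_ids=["x", "y", "z"])
    path = tmp_path / "ld.tsv"
    write_ld_matrix(ld, path)
    back = read_ld_matrix(path)
    assert back.variant_ids == ["x", "y", "z"]
    np.testing.assert_allclose(back.R, ld.R, atol=1e-12)


def test_ld_reference_validation():
    with pytest.raises(ValueError, match="symmetric"):
        LDReference(["a", "b"], [1, 2], np.array([[1.0, 0.5], [0.2, 1.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        LDReference(["a", "b"], [1, 2], np.array([[0.9, 0.2], [0.2, 1.0]]))


# ------------------------------------------------------------------- clump

SIX_IDS = ["v1", "v2", "v3", "v4", "v5", "v6"]
SIX_POS = [100_000, 110_000, 150_000, 400_000, 420_000, 1_000_000]
SIX_P = [1e-9, 1e-12, 1e-8, 1e-9, 5e-9, 1e-10]


def six_variant_fixture():
    R = np.eye(6)
    pairs = {(0, 1): 0.9, (1, 2): 0.2, (0, 2): 0.1, (3, 4): 0.7}
    for (i, j), r in pairs.items():
        R[i, j] = R[j, i] = r
    ld = LDReference(SIX_IDS, SIX_POS, R)
    recs = [
        make_record(variant_id=v, pos_bp=p, pvalue=pv, eaf=0.2)
        for v, p, pv in zip(SIX_IDS, SIX_POS, SIX_P)
    ]
    return make_table(recs), ld


def check_clump_postconditions(result, table, ld, p_thr, r2_thr, window, maf_min):
    """Exhaustive verification of the clumping contract."""
    sig = {
        r.variant_id: r
        for r in table.records
        if r.pvalue < p_thr and min(r.eaf, 1 - r.eaf) >= maf_min
    }
    absorbed = [v for mem in result.membership.values() for v in mem]
    # partition: every significant variant is a lead or absorbed, exactly once
    assert sorted(result.lead_ids + absorbed) == sorted(sig)
    assert not set(result.lead_ids) & set(absorbed)
    by_id = {r.variant_id: r for r in table.records}
    for lead, members in result.membership.items():
        for v in members:
            lr, vr = by_id[lead], by_id[v]
            assert lr.chrom == vr.chrom
            assert abs(lr.pos_bp - vr.pos_bp) <= window
            assert ld.r2(lead, v) >= r2_thr
    # leads pairwise fail the joint (window AND r2) condition
    for i, a in enumerate(result.lead_ids):
        for b in result.lead_ids[i + 1:]:
            ar, br = by_id[a], by_id[b]
            joint = (
                ar.chrom == br.chrom
                and abs(ar.pos_bp - br.pos_bp) <= window
                and ld.r2(a, b) >= r2_thr
            )
            assert not joint


def test_six_variant_toy_matches_hand_execution():
    table, ld = six_variant_fixture()
    res = clump(table, ld, p_threshold=1e-7, r2_threshold=0.1,
                window_bp=100_000, maf_min=0.01)
    # hand-run greedy: v2 leads (absorbs v1; v3 fails r2), then v6, then v4
    # (absorbs v5), then v3
    assert res.lead_ids == ["v2", "v6", "v4", "v3"]
    assert res.membership == {"v2": ["v1"], "v6": [], "v4": ["v5"], "v3": []}
    check_clump_postconditions(res, table, ld, 1e-7, 0.1, 100_000, 0.01)


def test_identity_ld_gives_all_leads():
    table, _ = six_variant_fixture()
    ld = LDReference(SIX_IDS, SIX_POS, np.eye(6))
    res = clump(table, ld, p_threshold=1e-7)
    assert sorted(res.lead_ids) == sorted(SIX_IDS)
    assert all(not m for m in res.membership.values())


def test_strong_pair_absorbed_into_smaller_p():
    ld = LDReference(["a", "b"], [50_000, 60_000],
                     np.array([[1.0, np.sqrt(0.95)], [np.sqrt(0.95), 1.0]]))
    table = make_table(
        [
            make_record(variant_id="a", pos_bp=50_000, pvalue=1e-10),
            make_record(variant_id="b", pos_bp=60_000, pvalue=1e-9),
        ]
    )
    res = clump(table, ld)
    assert res.lead_ids == ["a"] and res.membership["a"] == ["b"]


def test_clump_invariant_under_row_order():
    table, ld = six_variant_fixture()
    res1 = clump(table, ld, p_threshold=1e-7)
    shuffled = make_table(list(reversed(table.records)))
    res2 = clump(shuffled, ld, p_threshold=1e-7)
    assert res1.lead_ids == res2.lead_ids
    assert res1.membership == res2.membership


def test_relaxing_r2_threshold_never_adds_leads():
    table, ld = six_variant_fixture()
    prev = None
    for r2_thr in (0.8, 0.4, 0.1, 0.01):
        k = len(clump(table, ld, p_threshold=1e-7, r2_threshold=r2_thr).lead_ids)
        if prev is not None:
            assert k <= prev
        prev = k


def test_shrinking_window_never_removes_leads():
    table, ld = six_variant_fixture()
    prev = None
    for window in (200_000, 100_000, 15_000, 5_000):
        k = len(clump(table, ld, p_threshold=1e-7, window_bp=window).lead_ids)
        if prev is not None:
            assert k >= prev
        prev = k


def test_empty_candidate_set_is_empty_result_not_error():
    table, ld = six_variant_fixture()
    res = clump(table, ld, p_threshold=1e-20)
    assert res.lead_ids == [] and res.n_candidates == 0


def test_missing_candidate_in_ld_is_error():
    table, _ = six_variant_fixture()
    ld = LDReference(SIX_IDS[:5], SIX_POS[:5], np.eye(5))
    with pytest.raises(KeyError, match="v6"):
        clump(table, ld, p_threshold=1e-7)


def test_maf_filter_excludes_rare_candidates():
    table, ld = six_variant_fixture()
    recs = [r.replace(eaf=0.001) if r.variant_id == "v6" else r
            for r in table.records]
    res = clump(make_table(recs), ld, p_threshold=1e-7, maf_min=0.01)
    assert "v6" not in res.lead_ids


# ---------------------------------------------------------------- stepwise


def consistent_table(pvalues, se=0.02):
    """Records whose (beta, se, pvalue) agree: beta = z(p) * se."""
    from scipy import stats as st

    recs = []
    for vid, pos, p in zip(SIX_IDS, SIX_POS, pvalues):
        z = st.norm.isf(p / 2)
        recs.append(make_record(variant_id=vid, pos_bp=pos, pvalue=p,
                                beta=z * se, se=se, eaf=0.2, n=50_000))
    return make_table(recs)


def test_stepwise_identity_ld_reduces_to_marginal_thresholding():
    table = consistent_table(SIX_P)
    ld = LDReference(SIX_IDS, SIX_POS, np.eye(6))
    res = stepwise_select(table, ld, p_threshold=1e-7)
    expect = [r.variant_id for r in table.records if r.pvalue < 1e-7]
    assert sorted(res.lead_ids) == sorted(expect)
    by_id = {r.variant_id: r for r in table.records}
    for v in res.lead_ids:
        assert res.joint_betas[v] == pytest.approx(by_id[v].beta, rel=1e-9)
        assert res.joint_ses[v] == pytest.approx(by_id[v].se, rel=1e-9)


def test_perfectly_correlated_pair_selects_one():
    R = np.array([[1.0, 1.0], [1.0, 1.0]])
    ld = LDReference(["a", "b"], [1000, 2000], R)
    table = make_table(
        [
            make_record(variant_id="a", pos_bp=1000, pvalue=1e-12, beta=0.2),
            make_record(variant_id="b", pos_bp=2000, pvalue=1e-11, beta=0.2),
        ]
    )
    res = stepwise_select(table, ld, p_threshold=1e-7)
    assert res.lead_ids == ["a"]


def two_causal_cohort(seed):
    cfg = SimConfig(seed=seed, m_common=8, m_rare=0, ld_blocks=((8, 0.5),),
                    n_individuals=2000, common_log10f=(-1.0, -0.3))
    rng = np.random.default_rng(seed)
    arch = draw_architecture(cfg, rng)
    arch.beta_true[:] = 0.0
    arch.causal[:] = False
    arch.beta_true[1], arch.beta_true[5] = 0.3, -0.25
    arch.causal[[1, 5]] = True
    G, y, truth = simulate_cohort(cfg, architecture=arch)
    table = marginal_sumstats(G, y, truth)
    ld = ld_from_genotypes(
        G, variant_ids=list(G.columns),
        pos_bp=truth["pos_bp"].to_numpy(), chrom=list(truth["chrom"]),
    )
    return G, y, table, ld


def test_stepwise_joint_betas_match_multivariate_ols():
    """Joint summary-level estimates vs direct least squares on genotypes."""
    G, y, table, ld = two_causal_cohort(0)
    res = stepwise_select(table, ld, p_threshold=1e-4)
    assert len(res.lead_ids) >= 1
    X = np.column_stack([np.ones(len(y))] + [G[v].to_numpy() for v in res.lead_ids])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    cov = sigma2 * np.linalg.inv(X.T @ X)
    ses = np.sqrt(np.diag(cov))[1:]
    for k, v in enumerate(res.lead_ids):
        assert abs(res.joint_betas[v] - coef[1 + k]) <= 3 * ses[k]


def test_stepwise_requires_ld_coverage():
    table, _ = six_variant_fixture()
    ld = LDReference(SIX_IDS[:4], SIX_POS[:4], np.eye(4))
    with pytest.raises(KeyError):
        stepwise_select(table, ld, p_threshold=1e-7)
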