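"""Differential isoform usage: proportions, the multivariate Welch test,
Shannon diversity, dominance switching and the DIU x DGE overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isoshift as iso
from isoshift.usage import IsoformProportions

from conftest import toy_quant, toy_sheet


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------

def test_proportion_arithmetic():
    sheet = toy_sheet(3)
    quant = toy_quant({"gA": (6.0, 4.0), "gB": (2.0, 2.0, 6.0)}, sheet)
    props = iso.compute_proportions(quant, sheet)
    col = sheet["sample_id"][0]
    assert props.props.loc["gA.i0", col] == pytest.approx(0.6)
    assert props.props.loc["gA.i1", col] == pytest.approx(0.4)
    assert props.props.loc[["gB.i0", "gB.i1", "gB.i2"], col].tolist() == \
        pytest.approx([0.2, 0.2, 0.6])
    sums = props.props.groupby(props.gene_ids).sum()
    assert np.allclose(sums.to_numpy(), 1.0, atol=1e-9)


def test_expression_floor_masks_and_excludes():
    sheet = toy_sheet(3)
    quant = toy_quant({"gZ": (0.0, 0.0)}, sheet)
    props = iso.compute_proportions(quant, sheet, min_gene_tpm=1.0)
    assert props.props.loc["gZ.i0"].isna().all()
    assert "gZ" in set(props.excluded["gene_id"])


def test_single_isoform_gene_excluded_with_reason():
    sheet = toy_sheet(3)
    quant = toy_quant({"gS": (5.0,), "gA": (3.0, 7.0)}, sheet)
    props = iso.compute_proportions(quant, sheet)
    row = props.excluded.set_index("gene_id").loc["gS"]
    assert row["reason"] == "single_isoform"
    assert props.testable_genes == ["gA"]


def test_negative_tpm_rejected():
    sheet = toy_sheet(3)
    quant = toy_quant({"gA": (3.0, 7.0)}, sheet)
    quant.iloc[0, 1] = -1.0
    with pytest.raises(ValueError, match="negative"):
        iso.compute_proportions(quant, sheet)


# ---------------------------------------------------------------------------
# the multivariate Welch-type test
# ---------------------------------------------------------------------------

def test_identical_groups_give_t2_zero():
    rng = np.random.default_rng(0)
    A = rng.dirichlet([2, 3, 4], size=20)
    t2, p = iso.diu_test(A, A.copy())
    assert t2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_k2_reduces_to_welch_t():
    rng = np.random.default_rng(42)
    for _ in range(100):
        na, nb = rng.integers(4, 80, size=2)
        A = rng.dirichlet(rng.uniform(0.5, 8, 2), size=na)
        B = rng.dirichlet(rng.uniform(0.5, 8, 2), size=nb)
        _, p = iso.diu_test(A, B)
        p_welch = stats.ttest_ind(A[:, 0], B[:, 0], equal_var=False).pvalue
        assert p == pytest.approx(p_welch, abs=1e-6)


def test_t2_invariant_under_component_relabeling():
    rng = np.random.default_rng(1)
    A = rng.dirichlet([2, 3, 4, 2], size=30)
    B = rng.dirichlet([3, 3, 3, 3], size=25)
    t2_ref, p_ref = iso.diu_test(A, B)
    for _ in range(5):
        perm = rng.permutation(4)
        t2, p = iso.diu_test(A[:, perm], B[:, perm])
        assert t2 == pytest.approx(t2_ref, rel=1e-6)
        assert p == pytest.approx(p_ref, rel=1e-5)


def test_t2_invariant_under_group_swap():
    rng = np.random.default_rng(2)
    A = rng.dirichlet([2, 5, 3], size=18)
    B = rng.dirichlet([4, 2, 4], size=22)
    t2_ab, p_ab = iso.diu_test(A, B)
    t2_ba, p_ba = iso.diu_test(B, A)
    assert t2_ab == pytest.approx(t2_ba, rel=1e-10)
    assert p_ab == pytest.approx(p_ba, rel=1e-10)


def test_degenerate_constant_proportions():
    A = np.tile([0.5, 0.5], (10, 1))
    B = np.tile([0.5, 0.5], (10, 1))
    t2, p = iso.diu_test(A, B)
    assert (t2, p) == (0.0, 1.0)


def test_approx_vs_permutation_rank_agreement():
    """On null genes the F-approximation must track the permutation oracle."""
    rng = np.random.default_rng(3)
    p_approx, p_perm = [], []
    for _ in range(60):
        alpha = rng.uniform(1, 8, size=3)
        A = rng.dirichlet(alpha, size=30)
        B = rng.dirichlet(alpha, size=30)
        _, pa = iso.diu_test(A, B)
        _, pp = iso.diu_test(A, B, method="permutation", n_permutations=300,
                             seed=int(rng.integers(2**31)))
        p_approx.append(pa)
        p_perm.append(pp)
    rho = stats.spearmanr(p_approx, p_perm).statistic
    assert rho > 0.95


def test_input_validation():
    rng = np.random.default_rng(4)
    with pytest.raises(ValueError, match="3 usable samples"):
        iso.diu_test(rng.dirichlet([1, 1], size=2), rng.dirichlet([1, 1], size=10))
    with pytest.raises(ValueError, match="2 isoforms"):
        iso.diu_test(np.ones((5, 1)), np.ones((5, 1)))


# ---------------------------------------------------------------------------
# diu_table
# ---------------------------------------------------------------------------

def test_diu_table_null_few_discoveries():
    cfg = iso.SimulationConfig(seed=21, n_genes=300, frac_diu=0.0)
    quant, sheet, _ = iso.simulate_isoform_matrix(cfg)
    props = iso.compute_proportions(quant, sheet)
    table = iso.diu_table(props, fdr=0.01)
    assert table["significant"].sum() <= 3  # BH under ~uniform p, 300 genes
    assert (table.sort_values("p_value")["q_value"].diff().dropna() >= -1e-12).all()


def test_diu_table_empty_input():
    sheet = toy_sheet(3)
    quant = toy_quant({"gS": (5.0,)}, sheet)  # only a single-isoform gene
    props = iso.compute_proportions(quant, sheet)
    table = iso.diu_table(props)
    assert table.empty and "q_value" in table.columns


def test_bh_single_gene_q_equals_p():
    # m=1: BH q-value is the p-value itself
    from statsmodels.stats.multitest import multipletests
    assert multipletests([0.5], method="fdr_bh")[1][0] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Shannon diversity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p, expected", [
    ((1.0, 0.0, 0.0), 0.0),
    ((0.25, 0.25, 0.25, 0.25), np.log(4)),
    ((0.5, 0.25, 0.25), 1.0397207708399179),
])
def test_shannon_values(p, expected):
    assert iso.shannon_index(p) == pytest.approx(expected, abs=1e-10)


def test_shannon_rejects_negative():
    with pytest.raises(ValueError):
        iso.shannon_index([-0.1, 1.1])


def test_shannon_bounds_random():
    rng = np.random.default_rng(5)
    for _ in range(50):
        k = rng.integers(2, 9)
        p = rng.dirichlet(np.ones(k))
        h = iso.shannon_index(p)
        assert 0.0 <= h <= np.log(k) + 1e-12


def test_planted_shift_delta_shannon_value():
    # (0.9, 0.1) -> (0.5, 0.5): dH = ln2 - H(0.9, 0.1) = 0.368
    h_before = iso.shannon_index([0.9, 0.1])
    assert np.log(2) - h_before == pytest.approx(0.368, abs=5e-4)


def _props_from_arrays(p_ctl, p_inf, gene="gA"):
    """IsoformProportions with per-sample proportions given as K x n arrays."""
    n = p_ctl.shape[1]
    sheet = toy_sheet(n)
    cols = sheet["sample_id"].tolist()
    K = p_ctl.shape[0]
    data = np.empty((K, 2 * n))
    data[:, 0::2] = p_ctl
    data[:, 1::2] = p_inf
    props = pd.DataFrame(data, index=pd.Index([f"{gene}.i{k}" for k in range(K)]),
                         columns=cols)
    gene_ids = pd.Series([gene] * K, index=props.index)
    gene_tpm = pd.DataFrame(np.ones((1, 2 * n)), index=[gene], columns=cols)
    return IsoformProportions(props=props, gene_tpm=gene_tpm, gene_ids=gene_ids,
                              sheet=sheet, excluded=pd.DataFrame(columns=["gene_id", "reason"]))


def test_delta_shannon_zero_for_identical_conditions():
    rng = np.random.default_rng(6)
    P = rng.dirichlet([2, 3, 4], size=12).T
    props = _props_from_arrays(P, P.copy())
    per_gene, summary = iso.delta_shannon(props, n_permutations=200, seed=0)
    assert per_gene["delta_shannon"].iloc[0] == pytest.approx(0.0, abs=1e-12)


def test_delta_shannon_antisymmetric_under_condition_swap():
    rng = np.random.default_rng(7)
    P1 = rng.dirichlet([5, 1, 1], size=10).T
    P2 = rng.dirichlet([2, 2, 2], size=10).T
    g1, _ = iso.delta_shannon(_props_from_arrays(P1, P2), n_permutations=100, seed=0)
    g2, _ = iso.delta_shannon(_props_from_arrays(P2, P1), n_permutations=100, seed=0)
    assert g1["delta_shannon"].iloc[0] == pytest.approx(-g2["delta_shannon"].iloc[0])


def test_delta_shannon_null_fraction_covers_half():
    """Under exchangeability the permutation null of fraction(dH>0) brackets 0.5."""
    cfg = iso.SimulationConfig(seed=22, n_genes=80, frac_diu=0.0)
    quant, sheet, _ = iso.simulate_isoform_matrix(cfg)
    props = iso.compute_proportions(quant, sheet)
    _, summary = iso.delta_shannon(props, n_permutations=300, seed=1)
    null = summary["null_frac_positive"]
    assert np.quantile(null, 0.05) <= 0.5 <= np.quantile(null, 0.95)


def test_delta_shannon_warns_on_few_permutations():
    rng = np.random.default_rng(8)
    P = rng.dirichlet([2, 2], size=8).T
    with pytest.warns(UserWarning, match="100 permutations"):
        iso.delta_shannon(_props_from_arrays(P, P), n_permutations=10, seed=0)


# ---------------------------------------------------------------------------
# dominance and overlap
# ---------------------------------------------------------------------------

def test_dominant_switch_cases():
    # NI (0.8, 0.2) -> INF (0.3, 0.7): switch
    p_ctl = np.tile([[0.8], [0.2]], (1, 6))
    p_inf = np.tile([[0.3], [0.7]], (1, 6))
    out = iso.dominant_switch(_props_from_arrays(p_ctl, p_inf))
    assert bool(out["switch_flag"].iloc[0]) is True
    # no dominant isoform above 0.5: switch not evaluated
    p_ctl = np.tile([[0.45], [0.30], [0.25]], (1, 6))
    out = iso.dominant_switch(_props_from_arrays(p_ctl, p_ctl.copy()))
    assert out["dominant_ctl"].iloc[0] is None
    assert bool(out["switch_flag"].iloc[0]) is False
    # identical conditions: no switch
    p = np.tile([[0.7], [0.3]], (1, 6))
    out = iso.dominant_switch(_props_from_arrays(p, p.copy()))
    assert bool(out["switch_flag"].iloc[0]) is False


def test_fisher_overlap_independence_and_oracle():
    def flags(n11, n10, n01, n00):
        genes = [f"g{i}" for i in range(n11 + n10 + n01 + n00)]
        a = [True] * (n11 + n10) + [False] * (n01 + n00)
        b = [True] * n11 + [False] * n10 + [True] * n01 + [False] * n00
        return (pd.Series(a, index=genes), pd.Series(b, index=genes))

    odds, p, _ = iso.diu_dge_overlap(*flags(10, 10, 10, 10))
    assert odds == pytest.approx(1.0)
    assert p == pytest.approx(1.0)

    # [[20, 5], [5, 20]] against an exhaustive hypergeometric enumeration
    odds, p, _ = iso.diu_dge_overlap(*flags(20, 5, 5, 20))
    M, n, N = 50, 25, 25
    probs = {k: stats.hypergeom.pmf(k, M, n, N) for k in range(0, 26)}
    p_obs = probs[20]
    p_exact = sum(v for v in probs.values() if v <= p_obs + 1e-12)
    assert p == pytest.approx(p_exact, rel=1e-9)
    assert odds == pytest.approx((20 * 20) / (5 * 5))

    # strong depletion gives OR < 1
    odds, p, _ = iso.diu_dge_overlap(*flags(0, 20, 20, 5))
    assert odds < 1

    # empty margin: flagged
    odds, p, _ = iso.diu_dge_overlap(*flags(0, 0, 20, 20))
    assert np.isnan(odds) and p == 1.0
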