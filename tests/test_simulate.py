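"""Generator contracts: determinism, truth consistency, planted-effect fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isoshift as iso
from isoshift.simulate import ConfigError, default_mirna_set, expected_site_density


def test_same_seed_identical_outputs(small_config):
    q1, s1, t1 = iso.simulate_isoform_matrix(small_config)
    q2, s2, t2 = iso.simulate_isoform_matrix(small_config)
    pd.testing.assert_frame_equal(q1, q2)
    pd.testing.assert_frame_equal(s1, s2)
    e1, a1, _, te1 = iso.simulate_event_counts(small_config)
    e2, a2, _, te2 = iso.simulate_event_counts(small_config)
    pd.testing.assert_frame_equal(e1, e2)
    pd.testing.assert_frame_equal(te1.event_individual, te2.event_individual)


def test_stage_substreams_independent(small_config):
    """Changing event parameters must not perturb the isoform matrix."""
    import dataclasses
    q1, _, _ = iso.simulate_isoform_matrix(small_config)
    other = dataclasses.replace(small_config, read_depth_per_event=999.0)
    q2, _, _ = iso.simulate_isoform_matrix(other)
    pd.testing.assert_frame_equal(q1, q2)


def test_frac_diu_zero_means_no_planted_effects():
    cfg = iso.SimulationConfig(seed=1, n_genes=20, frac_diu=0.0)
    _, _, truth = iso.simulate_isoform_matrix(cfg)
    assert truth.genes["is_diu"].sum() == 0
    assert (truth.genes["effect"] == 0).all()


def test_null_gene_proportions_match_dirichlet_mean():
    # Monte-Carlo check against the stated generative distribution
    cfg = iso.SimulationConfig(seed=3, n_genes=8, frac_diu=0.0, n_individuals=500)
    quant, sheet, truth = iso.simulate_isoform_matrix(cfg)
    props = iso.compute_proportions(quant, sheet, min_gene_tpm=0.0)
    for rec in truth.genes.itertuples(index=False):
        A, B, _ = props.gene_matrices(rec.gene_id)
        for cond_mat in (A, B):
            assert np.abs(cond_mat.mean(axis=0) - np.array(rec.prop_ctl)).max() < 0.02


def test_diu_gene_mean_shift_equals_usage_effect(iso_bundle):
    _, _, truth = iso_bundle
    diu = truth.genes[truth.genes["is_diu"]]
    assert len(diu) > 0
    for rec in diu.itertuples(index=False):
        d = np.abs(np.array(rec.prop_ctl) - np.array(rec.prop_inf))
        assert d.max() == pytest.approx(0.15, abs=1e-12)


def test_event_truth_consistency(event_bundle):
    events, annotations, _, truth = event_bundle
    assert set(truth.events["event_id"]) == set(annotations["event_id"])
    assert set(truth.events["event_id"]) == set(events["event_id"])
    ind = truth.event_individual
    assert ((ind["psi_ni"] >= 0) & (ind["psi_ni"] <= 1)).all()
    assert np.allclose(ind["delta_psi"], ind["psi_inf"] - ind["psi_ni"])


def test_frac_events_shifted_zero():
    cfg = iso.SimulationConfig(seed=2, frac_events_shifted=0.0,
                               n_events_per_category={"SE": 25})
    _, _, _, truth = iso.simulate_event_counts(cfg)
    assert (truth.events["delta_planted"] == 0).all()


def test_tandem_utr_negative_fraction_by_construction():
    cfg = iso.SimulationConfig(seed=4, n_events_per_category={"TandemUTR": 400},
                               frac_events_shifted=0.5)
    _, _, _, truth = iso.simulate_event_counts(cfg)
    shifted = truth.events[truth.events["is_shifted"]]
    frac_neg = (shifted["delta_planted"] < 0).mean()
    # Bernoulli(0.95) over ~200 events: allow 3 binomial sd
    assert abs(frac_neg - 0.95) < 3 * np.sqrt(0.95 * 0.05 / len(shifted))


def test_delta_truncation_recorded():
    cfg = iso.SimulationConfig(seed=5, psi_base_range=(0.85, 0.9),
                               delta_psi_magnitude=0.3, frac_events_shifted=1.0,
                               frac_negative={"SE": 0.0},
                               n_events_per_category={"SE": 10})
    _, _, _, truth = iso.simulate_event_counts(cfg)
    ev = truth.events
    # +0.3 from a 0.85-0.9 base must truncate at 0.99
    assert (ev["psi_base"] + ev["delta_planted"] <= 0.99 + 1e-12).all()
    assert (ev["delta_planted"] < 0.3).all()


def test_delta_psi_recovery_through_estimator():
    cfg = iso.SimulationConfig(seed=6, n_events_per_category={"SE": 100},
                               frac_events_shifted=1.0, delta_psi_magnitude=0.3,
                               frac_negative={"SE": 0.0}, psi_base_range=(0.3, 0.5),
                               read_depth_per_event=200.0)
    events, _, sheet, truth = iso.simulate_event_counts(cfg)
    psi, calls = iso.call_events(events, sheet)
    m = calls.merge(truth.events, on="event_id")
    assert abs(m["mean_delta_psi"].mean() - 0.3) < 0.03


@pytest.mark.parametrize("bad", [
    dict(frac_diu=1.5),
    dict(n_genes=0),
    dict(delta_psi_magnitude=0.0),
    dict(planted_fold=0.5),
    dict(rho_dpsi_fc=0.999),
    dict(isoforms_per_gene=(1, 5), frac_diu=0.2),
    dict(frac_negative={"TandemUTR": -0.1}),
])
def test_config_validation_errors(bad):
    with pytest.raises(ConfigError):
        iso.SimulationConfig(**bad).validate()


# ---------------------------------------------------------------------------
# UTR sequences
# ---------------------------------------------------------------------------

def _utr_calls(n, n_sig):
    return pd.DataFrame({"event_id": [f"TandemUTR_{j:04d}" for j in range(n)],
                         "significant": [j < n_sig for j in range(n)]})


def test_planted_fold_one_gives_flat_ratio():
    cfg = iso.SimulationConfig(seed=8, planted_fold=1.0, utr_ext_len=2000,
                               n_events_per_category={"TandemUTR": 400})
    regions, _ = iso.simulate_utr_sequences(cfg, _utr_calls(400, 200))
    dens, _ = iso.density_by_class(regions, default_mirna_set(cfg))
    sig = dens.loc[dens["sig_class"] == "shortened_significant", "ext_density"].mean()
    unc = dens.loc[dens["sig_class"] == "unchanged", "ext_density"].mean()
    assert 0.8 <= sig / unc <= 1.25


def test_planted_fold_three_realized():
    cfg = iso.SimulationConfig(seed=9, planted_fold=3.0, utr_ext_len=3000,
                               n_events_per_category={"TandemUTR": 900})
    regions, truth = iso.simulate_utr_sequences(cfg, _utr_calls(900, 300))
    mirnas = default_mirna_set(cfg)
    planted = cfg.planted_mirnas[0]
    mature = cfg.mirna_sequences[planted]
    sig = regions[regions["sig_class"] == "shortened_significant"]
    unc = regions[regions["sig_class"] == "unchanged"]

    def density(df):
        counts = sum(iso.count_seed_sites(s, mature)["total"] for s in df["ext_seq"])
        return counts / df["ext_seq"].str.len().sum()

    ratio = density(sig) / density(unc)
    assert 2.5 <= ratio <= 3.5
    assert truth.utrs[f"planted_{planted}"].sum() > 0


def test_zero_length_extensions_are_valid():
    cfg = iso.SimulationConfig(seed=10, utr_ext_len=0,
                               n_events_per_category={"TandemUTR": 5})
    regions, _ = iso.simulate_utr_sequences(cfg, _utr_calls(5, 2))
    assert (regions["ext_seq"].str.len() == 0).all()
    assert (regions["core_seq"].str.len() == cfg.utr_core_len).all()


def test_expected_site_density_matches_counts():
    # analytic background density vs empirical counting on long iid sequence
    cfg = iso.SimulationConfig(seed=11, planted_fold=1.0, utr_ext_len=5000,
                               n_events_per_category={"TandemUTR": 200},
                               gc_strata=(0.5, 0.5))
    regions, _ = iso.simulate_utr_sequences(cfg, _utr_calls(200, 0))
    mature = cfg.mirna_sequences["syn-mir-02"]
    total = sum(iso.count_seed_sites(s, mature)["total"] for s in regions["ext_seq"])
    length = regions["ext_seq"].str.len().sum()
    expected = expected_site_density(mature, 0.5)
    assert total / length == pytest.approx(expected, rel=0.25)


# ---------------------------------------------------------------------------
# expression fold changes
# ---------------------------------------------------------------------------

def test_rho_zero_gives_centered_correlations():
    cfg = iso.SimulationConfig(seed=12, rho_dpsi_fc=0.0,
                               n_events_per_category={"SE": 150}, frac_events_shifted=0.5)
    _, _, _, truth = iso.simulate_event_counts(cfg)
    expr = iso.simulate_expression_changes(cfg, truth)
    wide = truth.event_individual.pivot(index="event_id", columns="individual_id",
                                        values="delta_psi")
    meta = truth.events.set_index("event_id")
    rhos = [stats.spearmanr(row.to_numpy(), expr.loc[meta.loc[e, "gene_id"],
                                                     row.index].to_numpy()).statistic
            for e, row in wide.iterrows()]
    assert abs(np.mean(rhos)) < 0.05


def test_rho_target_calibration():
    cfg = iso.SimulationConfig(seed=13, rho_dpsi_fc=0.6,
                               n_events_per_category={"SE": 200}, frac_events_shifted=1.0)
    _, _, _, truth = iso.simulate_event_counts(cfg)
    expr = iso.simulate_expression_changes(cfg, truth)
    wide = truth.event_individual.pivot(index="event_id", columns="individual_id",
                                        values="delta_psi")
    meta = truth.events.set_index("event_id")
    rhos = [stats.spearmanr(row.to_numpy(), expr.loc[meta.loc[e, "gene_id"],
                                                     row.index].to_numpy()).statistic
            for e, row in wide.iterrows()]
    assert 0.5 <= np.mean(rhos) <= 0.7


# ---------------------------------------------------------------------------
# 3'-end reads
# ---------------------------------------------------------------------------

def _tandem_truth(psi_values, n_ind=4):
    inds = [f"ind{i:03d}" for i in range(n_ind)]
    events = pd.DataFrame({"event_id": [f"TandemUTR_{j:04d}" for j in range(len(psi_values))],
                           "category": "TandemUTR",
                           "gene_id": "g", "is_shifted": False,
                           "psi_base": psi_values, "delta_planted": 0.0})
    rows = [(e, i, p, p, 0.0) for e, p in zip(events["event_id"], psi_values) for i in inds]
    ind = pd.DataFrame(rows, columns=["event_id", "individual_id",
                                      "psi_ni", "psi_inf", "delta_psi"])
    return iso.SyntheticTruth(events=events, event_individual=ind)


def test_threeprime_reads_all_distal_when_psi_one():
    cfg = iso.SimulationConfig(seed=14, jitter_sd=0.0, depth_threeprime=200.0,
                               n_individuals_threeprime=2)
    reads, sites = iso.simulate_threeprime_reads(cfg, _tandem_truth([1.0]))
    assert (reads["start"] == sites.loc[0, "distal"]).all()


def test_threeprime_proximal_fraction_binomial():
    cfg = iso.SimulationConfig(seed=15, jitter_sd=0.0, depth_threeprime=1000.0,
                               n_individuals_threeprime=4)
    reads, sites = iso.simulate_threeprime_reads(cfg, _tandem_truth([0.5]))
    frac_prox = (reads["start"] == sites.loc[0, "proximal"]).mean()
    assert abs(frac_prox - 0.5) < 0.05


def test_threeprime_jitter_tail_bound():
    cfg = iso.SimulationConfig(seed=16, jitter_sd=10.0, depth_threeprime=1000.0,
                               n_individuals_threeprime=4)
    reads, sites = iso.simulate_threeprime_reads(cfg, _tandem_truth([0.5]))
    prox, dist = sites.loc[0, "proximal"], sites.loc[0, "distal"]
    near = (np.abs(reads["start"] - prox) <= 40) | (np.abs(reads["start"] - dist) <= 40)
    assert near.mean() >= 0.99  # 4 sd normal tail
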