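"""Gene-level differential isoform usage (DIU).

Isoform proportions are obtained by dividing isoform TPM by the summed gene
TPM.  The per-gene test is a multivariate generalization of Welch's t-test
(multivariate Behrens-Fisher problem): with one proportion component dropped
to remove the sum-to-one singularity,

    T2 = d' W^-1 d,     W = S_ctl/n_ctl + S_inf/n_inf,

where d is the difference of condition mean proportion vectors and S the
group sample covariances.  P-values come from the Krishnamoorthy-Yu
F-approximation; a condition-label permutation p-value is available as an
exact-mode fallback and oracle.  For K = 2 isoforms the approximation reduces
exactly to the two-sided univariate Welch t-test with Satterthwaite degrees
of freedom.

Also here: Shannon-diversity change with a paired-permutation null,
dominant-isoform switching, and the DIU x DGE Fisher overlap test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IsoformProportions",
    "compute_proportions",
    "diu_test",
    "diu_table",
    "shannon_index",
    "delta_shannon",
    "dominant_switch",
    "diu_dge_overlap",
]


@dataclass
class IsoformProportions:
    """Per-sample isoform proportions plus masking/exclusion bookkeeping.

    ``props`` is isoform x sample (NaN where the gene-sample is masked below
    the expression floor), ``gene_tpm`` is gene x sample, ``gene_ids`` maps
    isoform -> gene, ``excluded`` lists genes removed from testing with a
    reason code.
    """

    props: pd.DataFrame
    gene_tpm: pd.DataFrame
    gene_ids: pd.Series
    sheet: pd.DataFrame
    excluded: pd.DataFrame

    @property
    def testable_genes(self) -> list[str]:
        bad = set(self.excluded["gene_id"])
        return [g for g in self.gene_tpm.index if g not in bad]

    def gene_matrices(self, gene_id: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(control, infected) sample-by-isoform proportion matrices.

        Only samples unmasked for this gene are returned; isoforms are in
        isoform-id order.
        """
        iso = self.gene_ids[self.gene_ids == gene_id].index
        block = self.props.loc[iso]
        ctl_cols = self.sheet.loc[self.sheet["condition"] == "control", "sample_id"]
        inf_cols = self.sheet.loc[self.sheet["condition"] == "infected", "sample_id"]
        A = block[ctl_cols].T.dropna().to_numpy(float)
        B = block[inf_cols].T.dropna().to_numpy(float)
        return A, B, list(iso)


def compute_proportions(quant: pd.DataFrame, sheet: pd.DataFrame,
                        min_gene_tpm: float = 1.0,
                        max_masked_frac: float = 0.20) -> IsoformProportions:
    """Isoform proportions from a TPM matrix.

    Parameters
    ----------
    quant
        Wide matrix indexed by isoform_id with a ``gene_id`` column and one
        non-negative TPM column per sample.
    sheet
        Sample sheet (sample_id, individual_id, condition).
    min_gene_tpm
        Expression floor: gene-samples with summed TPM below it are masked.
    max_masked_frac
        Genes masked in more than this fraction of samples in either
        condition are excluded from testing.
    """
    sample_cols = sheet["sample_id"].tolist()
    missing = [s for s in sample_cols if s not in quant.columns]
    if missing:
        raise ValueError(f"samples missing from TPM matrix: {missing[:5]}")
    tpm = quant[sample_cols].astype(float)
    if (tpm.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    gene_ids = quant["gene_id"]
    gene_tpm = tpm.groupby(gene_ids).sum()
    denom = gene_tpm.reindex(gene_ids).to_numpy()
    masked = denom < min_gene_tpm
    with np.errstate(invalid="ignore", divide="ignore"):
        props = tpm.to_numpy() / np.where(masked, np.nan, denom)
    props = pd.DataFrame(props, index=tpm.index, columns=tpm.columns)

    excluded = []
    iso_count = gene_ids.groupby(gene_ids).size()
    for g, k in iso_count.items():
        if k < 2:
            excluded.append((g, "single_isoform"))
    gene_masked = gene_tpm < min_gene_tpm
    for cond in ("control", "infected"):
        cols = sheet.loc[sheet["condition"] == cond, "sample_id"]
        frac = gene_masked[cols].mean(axis=1)
        for g in frac.index[frac > max_masked_frac]:
            excluded.append((g, f"masked_gt_{int(max_masked_frac * 100)}pct_{cond}"))
    excluded_df = (pd.DataFrame(excluded, columns=["gene_id", "reason"])
                   .drop_duplicates("gene_id").reset_index(drop=True))
    return IsoformProportions(props=props, gene_tpm=gene_tpm, gene_ids=gene_ids,
                              sheet=sheet.reset_index(drop=True), excluded=excluded_df)


# ---------------------------------------------------------------------------
# the multivariate Welch-type test
# ---------------------------------------------------------------------------

def _t2_stat(A: np.ndarray, B: np.ndarray, ridge_scale: float = 1e-8):
    """T2 and its ingredients on the first K-1 components.

    Returns (T2, d, S_A/n_A, S_B/n_B, W_inv) or None when degenerate.
    """
    p = A.shape[1] - 1
    Xa, Xb = A[:, :p], B[:, :p]
    na, nb = Xa.shape[0], Xb.shape[0]
    d = Xa.mean(axis=0) - Xb.mean(axis=0)
    Sa = np.cov(Xa, rowvar=False, ddof=1).reshape(p, p) / na
    Sb = np.cov(Xb, rowvar=False, ddof=1).reshape(p, p) / nb
    W = Sa + Sb
    tr = np.trace(W)
    if not np.isfinite(tr) or tr <= 0:
        return None
    W = W + np.eye(p) * (ridge_scale * tr / p)
    try:
        W_inv = np.linalg.inv(W)
    except np.linalg.LinAlgError:
        return None
    t2 = float(d @ W_inv @ d)
    if not np.isfinite(t2):
        return None
    return t2, d, Sa, Sb, W_inv


def _ky_pvalue(t2: float, Sa, Sb, W_inv, na: int, nb: int) -> float:
    """Krishnamoorthy-Yu F-approximation for the Behrens-Fisher T2."""
    p = Sa.shape[0]
    num = p + p * p
    den = 0.0
    for S, n in ((Sa, na), (Sb, nb)):
        M = S @ W_inv
        den += (np.trace(M @ M) + np.trace(M) ** 2) / (n - 1)
    if den <= 0:
        return float(stats.chi2.sf(t2, p))
    nu = num / den
    if nu <= p - 1 + 1e-9:
        return float(stats.chi2.sf(t2, p))
    f = t2 * (nu - p + 1) / (nu * p)
    return float(stats.f.sf(f, p, nu - p + 1))


def diu_test(props_a: np.ndarray, props_b: np.ndarray, *,
             method: str = "approx", n_permutations: int = 10_000,
             seed: int | None = None, ridge_scale: float = 1e-8):
    """Multivariate Welch-type test on two groups of proportion vectors.

    Parameters
    ----------
    props_a, props_b
        (n_samples, K) arrays of isoform proportions (rows sum to 1).  The
        last component is dropped internally.
    method
        ``"approx"`` for the Krishnamoorthy-Yu F-approximation,
        ``"permutation"`` for a condition-label permutation p-value.

    Returns
    -------
    (T2, p_value).  Degenerate input (singular pooled covariance, constant
    proportions) gives (0.0, 1.0).
    """
    A = np.asarray(props_a, float)
    B = np.asarray(props_b, float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("groups must be 2-d with equal isoform count")
    if A.shape[1] < 2:
        raise ValueError("need at least 2 isoforms")
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 usable samples per group")
    res = _t2_stat(A, B, ridge_scale)
    if res is None:
        return 0.0, 1.0
    t2, d, Sa, Sb, W_inv = res
    if method == "approx":
        return t2, _ky_pvalue(t2, Sa, Sb, W_inv, A.shape[0], B.shape[0])
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    X = np.vstack([A, B])
    na = A.shape[0]
    count = 1
    for _ in range(n_permutations):
        idx = rng.permutation(X.shape[0])
        r = _t2_stat(X[idx[:na]], X[idx[na:]], ridge_scale)
        if r is not None and r[0] >= t2 - 1e-12:
            count += 1
    return t2, count / (n_permutations + 1)


def shannon_index(p) -> float:
    """Shannon entropy H = -sum p_k ln p_k (nats), with 0 ln 0 = 0."""
    p = np.asarray(p, float)
    if (p < 0).any():
        raise ValueError("negative proportion component")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError(f"proportions must sum to 1, got {p.sum():.6f}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _dominant(mean_props: np.ndarray, iso: list[str], threshold: float):
    order = np.argsort(-mean_props, kind="stable")  # isoform-id order breaks ties
    j = order[0]
    tie = bool(mean_props.size > 1 and np.isclose(mean_props[order[0]], mean_props[order[1]]))
    if mean_props[j] > threshold:
        return iso[j], tie
    return None, tie


def diu_table(props: IsoformProportions, *, fdr: float = 0.01,
              dominance_threshold: float = 0.5, min_samples: int = 3,
              method: str = "approx", n_permutations: int = 10_000,
              seed: int | None = None) -> pd.DataFrame:
    """Per-gene DIU results with BH q-values.

    Columns: gene_id, K, n_ctl, n_inf, T2, p_value, q_value, effect_size
    (max over isoforms of |mean proportion difference|), delta_shannon
    (entropy of mean infected minus mean control proportions), dominant_ctl,
    dominant_inf, switch_flag, tie_flag, degenerate, significant.
    """
    rows = []
    for g in props.testable_genes:
        A, B, iso = props.gene_matrices(g)
        if A.shape[0] < min_samples or B.shape[0] < min_samples:
            continue
        t2, p = diu_test(A, B, method=method, n_permutations=n_permutations, seed=seed)
        mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
        effect = float(np.abs(mean_a - mean_b).max())
        d_h = shannon_index(mean_b / mean_b.sum()) - shannon_index(mean_a / mean_a.sum())
        dom_a, tie_a = _dominant(mean_a, iso, dominance_threshold)
        dom_b, tie_b = _dominant(mean_b, iso, dominance_threshold)
        switch = dom_a is not None and dom_b is not None and dom_a != dom_b
        rows.append(dict(gene_id=g, K=len(iso), n_ctl=A.shape[0], n_inf=B.shape[0],
                         T2=t2, p_value=p, effect_size=effect, delta_shannon=d_h,
                         dominant_ctl=dom_a, dominant_inf=dom_b,
                         switch_flag=bool(switch), tie_flag=bool(tie_a or tie_b),
                         degenerate=bool(t2 == 0.0 and p == 1.0)))
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["gene_id", "K", "n_ctl", "n_inf", "T2", "p_value",
                                     "q_value", "effect_size", "delta_shannon",
                                     "dominant_ctl", "dominant_inf", "switch_flag",
                                     "tie_flag", "degenerate", "significant"])
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["q_value"] <= fdr
    cols = ["gene_id", "K", "n_ctl", "n_inf", "T2", "p_value", "q_value",
            "effect_size", "delta_shannon", "dominant_ctl", "dominant_inf",
            "switch_flag", "tie_flag", "degenerate", "significant"]
    return out[cols]


def delta_shannon(props: IsoformProportions, n_permutations: int = 1000,
                  seed: int | None = None, quantiles: tuple[float, float] = (0.025, 0.975)):
    """Per-gene Shannon-diversity change with a paired permutation null.

    delta H = H(mean infected proportions) - H(mean control proportions).
    The null swaps each individual's condition pair independently with
    probability 1/2 (sample permutation across conditions, preserving
    pairing).  Returns ``(per_gene, summary)`` where ``summary`` holds the
    observed global fraction of genes with delta H > 0 and its permutation
    null distribution.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: null quantiles will be coarse")
    rng = np.random.default_rng(seed)
    sheet = props.sheet
    paired = sheet.pivot(index="individual_id", columns="condition", values="sample_id").dropna()
    ctl_cols, inf_cols = paired["control"].tolist(), paired["infected"].tolist()
    n_ind = len(paired)
    swaps = rng.random((n_permutations, n_ind)) < 0.5

    genes, d_obs = [], []
    null_pos = np.zeros(n_permutations)
    null_lo, null_hi = [], []
    n_tested = 0
    for g in props.testable_genes:
        iso = props.gene_ids[props.gene_ids == g].index
        P_ctl = props.props.loc[iso, ctl_cols].to_numpy(float)  # K x n
        P_inf = props.props.loc[iso, inf_cols].to_numpy(float)
        keep = ~(np.isnan(P_ctl).any(axis=0) | np.isnan(P_inf).any(axis=0))
        if keep.sum() < 3:
            continue
        P_ctl, P_inf = P_ctl[:, keep], P_inf[:, keep]
        m = P_ctl.shape[1]
        h_inf = _entropy(P_inf.mean(axis=1))
        h_ctl = _entropy(P_ctl.mean(axis=1))
        dh = h_inf - h_ctl
        Z = swaps[:, :n_ind][:, keep].astype(float)  # B x m, 1 => swap the pair
        mean_inf_b = (P_inf @ (1 - Z).T + P_ctl @ Z.T) / m  # K x B
        mean_ctl_b = (P_ctl @ (1 - Z).T + P_inf @ Z.T) / m
        dh_null = _entropy_cols(mean_inf_b) - _entropy_cols(mean_ctl_b)
        genes.append(g)
        d_obs.append(dh)
        null_pos += dh_null > 0
        null_lo.append(float(np.quantile(dh_null, quantiles[0])))
        null_hi.append(float(np.quantile(dh_null, quantiles[1])))
        n_tested += 1
    per_gene = pd.DataFrame({"gene_id": genes, "delta_shannon": d_obs,
                             "null_q_low": null_lo, "null_q_high": null_hi})
    frac_pos = float(np.mean(np.asarray(d_obs) > 0)) if d_obs else float("nan")
    summary = {"frac_positive": frac_pos,
               "null_frac_positive": null_pos / max(n_tested, 1),
               "n_genes": n_tested}
    return per_gene, summary


def _entropy(p: np.ndarray) -> float:
    p = p / p.sum()
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _entropy_cols(P: np.ndarray) -> np.ndarray:
    P = P / P.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return -terms.sum(axis=0)


def dominant_switch(props: IsoformProportions, dominance_threshold: float = 0.5) -> pd.DataFrame:
    """Dominant isoform per condition and whether it switches.

    The dominant isoform is the argmax of condition-mean proportions,
    declared only when its mean exceeds ``dominance_threshold``; ties are
    broken by isoform-id order and flagged.
    """
    rows = []
    for g in props.testable_genes:
        A, B, iso = props.gene_matrices(g)
        if A.size == 0 or B.size == 0:
            continue
        dom_a, tie_a = _dominant(A.mean(axis=0), iso, dominance_threshold)
        dom_b, tie_b = _dominant(B.mean(axis=0), iso, dominance_threshold)
        switch = dom_a is not None and dom_b is not None and dom_a != dom_b
        rows.append(dict(gene_id=g, dominant_ctl=dom_a, dominant_inf=dom_b,
                         switch_flag=bool(switch), tie_flag=bool(tie_a or tie_b)))
    return pd.DataFrame(rows)


def diu_dge_overlap(diu_flags: pd.Series, dge_flags: pd.Series):
    """Two-sided Fisher's exact test for DIU x DGE membership overlap.

    Flags must be boolean Series indexed by gene over the same universe.
    Returns (odds_ratio, p_value, table); an empty margin gives
    (nan, 1.0, table).
    """
    genes = diu_flags.index.intersection(dge_flags.index)
    a = diu_flags.loc[genes].astype(bool)
    b = dge_flags.loc[genes].astype(bool)
    table = np.array([[int((a & b).sum()), int((a & ~b).sum())],
                      [int((~a & b).sum()), int((~a & ~b).sum())]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), 1.0, table
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table
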