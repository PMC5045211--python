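"""Linking RNA-processing changes to expression changes.

Per gene, the Spearman correlation across individuals between the event's
delta-PSI and the gene's log2 expression fold change; the null permutes the
individual correspondence.  Distribution-level agreement is assessed with a
two-sample Kolmogorov-Smirnov test of observed vs permuted correlations.
A genome-wide variant (the trans-factor scan) correlates every expressed
gene's fold change with the per-individual mean delta-PSI of one category,
to nominate candidate trans-acting regulators at FDR <= 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gene_level_link",
    "GeneLinkResult",
    "individual_level_link",
    "trans_factor_scan",
    "intersect_candidates",
    "log2_fold_changes",
]


def log2_fold_changes(quant: pd.DataFrame, sheet: pd.DataFrame,
                      pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-individual log2((TPM_inf + c)/(TPM_ctl + c)) from a gene TPM matrix.

    ``quant`` may be isoform-level (with a gene_id column, summed per gene)
    or already gene-level (indexed by gene).
    """
    if "gene_id" in quant.columns:
        tpm = quant.drop(columns=["gene_id"]).groupby(quant["gene_id"]).sum()
    else:
        tpm = quant
    paired = sheet.pivot(index="individual_id", columns="condition", values="sample_id").dropna()
    out = {}
    for ind, row in paired.iterrows():
        out[ind] = np.log2((tpm[row["infected"]] + pseudocount)
                           / (tpm[row["control"]] + pseudocount))
    return pd.DataFrame(out)


def _standardized_ranks(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x)
    r = r - r.mean()
    s = np.sqrt((r**2).sum())
    return r / s if s > 0 else r


@dataclass
class GeneLinkResult:
    table: pd.DataFrame
    null_rhos: np.ndarray
    ks_stat: float
    ks_p: float
    frac_positive: float
    masked: pd.DataFrame = field(default_factory=pd.DataFrame)


def gene_level_link(psi_records: pd.DataFrame, events_meta: pd.DataFrame,
                    expr: pd.DataFrame, *, n_permutations: int = 100,
                    seed: int | None = None, min_individuals: int = 10,
                    single_event_only: bool = True,
                    significant_events: set | None = None) -> GeneLinkResult:
    """Per-gene Spearman correlation of delta-PSI with log2 fold change.

    Parameters
    ----------
    psi_records
        Per event x individual PSI table (from :func:`isoshift.call_events`).
    events_meta
        event_id -> gene_id (and category) mapping.
    expr
        Genes x individuals log2 fold-change matrix.
    single_event_only
        Restrict to genes with exactly one event among those supplied
        (the unambiguous event-to-gene linkage mode).
    significant_events
        If given, ``frac_positive`` (fraction of genes with rho > 0) is
        computed over genes whose event is in this set; otherwise over all.

    The null pools ``n_permutations`` per-gene correlations computed after
    permuting which individual's fold change goes with which delta-PSI.
    """
    rng = np.random.default_rng(seed)
    meta = events_meta[["event_id", "gene_id"]].drop_duplicates()
    if single_event_only:
        per_gene = meta.groupby("gene_id")["event_id"].nunique()
        keep_genes = set(per_gene.index[per_gene == 1])
        meta = meta[meta["gene_id"].isin(keep_genes)]
    dpsi = psi_records.pivot(index="event_id", columns="individual_id", values="delta_psi")

    rows, masked, null = [], [], []
    for event_id, gene_id in meta.itertuples(index=False):
        if event_id not in dpsi.index or gene_id not in expr.index:
            continue
        d = dpsi.loc[event_id].dropna()
        shared = d.index.intersection(expr.columns)
        if len(shared) < min_individuals:
            masked.append((gene_id, event_id, "too_few_individuals"))
            continue
        x = d.loc[shared].to_numpy(float)
        y = expr.loc[gene_id, shared].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            masked.append((gene_id, event_id, "constant_values"))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append(dict(gene_id=gene_id, event_id=event_id, spearman_rho=float(rho),
                         p_value=float(p), n_individuals=len(shared)))
        zx = _standardized_ranks(x)
        zy = _standardized_ranks(y)
        perm = np.array([zx @ zy[rng.permutation(len(zy))] for _ in range(n_permutations)])
        null.append(perm)
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    null_rhos = np.concatenate(null) if null else np.array([])
    if len(table) and null_rhos.size:
        ks = stats.ks_2samp(table["spearman_rho"], null_rhos)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat, ks_p = float("nan"), float("nan")
    if significant_events is not None and not table.empty:
        sub = table[table["event_id"].isin(significant_events)]
    else:
        sub = table
    frac_pos = float((sub["spearman_rho"] > 0).mean()) if len(sub) else float("nan")
    return GeneLinkResult(table=table, null_rhos=null_rhos, ks_stat=ks_stat,
                          ks_p=ks_p, frac_positive=frac_pos,
                          masked=pd.DataFrame(masked, columns=["gene_id", "event_id", "reason"]))


def _mean_dpsi_by_individual(psi_records: pd.DataFrame, events_meta: pd.DataFrame,
                             category: str, significant_events: set | None) -> pd.Series:
    meta = events_meta[["event_id", "category"]].drop_duplicates()
    ids = set(meta.loc[meta["category"] == category, "event_id"])
    if significant_events is not None:
        ids &= set(significant_events)
    sub = psi_records[psi_records["event_id"].isin(ids)]
    if sub.empty:
        raise ValueError(f"no events available for category {category!r}")
    return sub.groupby("individual_id")["delta_psi"].mean()


def individual_level_link(psi_records: pd.DataFrame, events_meta: pd.DataFrame,
                          expr: pd.DataFrame, *, significant_events: set | None = None,
                          min_individuals: int = 3) -> pd.DataFrame:
    """Per-category Spearman of individual mean delta-PSI vs mean log2FC.

    Captures whether donors with larger global processing shifts also show
    larger global expression shifts.  Constant inputs are masked.
    """
    mean_fc = expr.mean(axis=0)
    rows = []
    for category in sorted(events_meta["category"].unique()):
        try:
            mean_dpsi = _mean_dpsi_by_individual(psi_records, events_meta,
                                                 category, significant_events)
        except ValueError:
            continue
        shared = mean_dpsi.index.intersection(mean_fc.index)
        if len(shared) < min_individuals:
            continue
        x = mean_dpsi.loc[shared]
        y = mean_fc.loc[shared]
        if x.std() == 0 or y.std() == 0:
            rows.append(dict(category=category, spearman_rho=float("nan"),
                             p_value=float("nan"), n_individuals=len(shared),
                             masked_reason="constant_values"))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append(dict(category=category, spearman_rho=float(rho), p_value=float(p),
                         n_individuals=len(shared), masked_reason=None))
    return pd.DataFrame(rows)


def trans_factor_scan(expr: pd.DataFrame, psi_records: pd.DataFrame,
                      events_meta: pd.DataFrame, category: str, *,
                      significant_events: set | None = None,
                      rbp_list: set | None = None, fdr: float = 0.01,
                      min_individuals: int = 10) -> pd.DataFrame:
    """Genome-wide scan for candidate trans-acting regulators of one category.

    For every gene in ``expr``, the Spearman correlation across individuals
    between its log2 fold change and the per-individual mean delta-PSI of the
    category (significant events by default).  Candidates are BH q <= fdr.
    ``rbp_list`` annotates rows with a known-RNA-binding-protein flag; when
    absent the column is left empty and the scan still runs.
    """
    mean_dpsi = _mean_dpsi_by_individual(psi_records, events_meta, category,
                                         significant_events)
    shared = mean_dpsi.index.intersection(expr.columns)
    if len(shared) < min_individuals:
        raise ValueError("too few shared individuals for the scan")
    x = mean_dpsi.loc[shared].to_numpy(float)
    zx = _standardized_ranks(x)
    Y = expr[shared].to_numpy(float)
    ranks = np.apply_along_axis(stats.rankdata, 1, Y)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    ok = norms > 0
    rho = np.full(Y.shape[0], np.nan)
    rho[ok] = (ranks[ok] / norms[ok, None]) @ zx
    n = len(shared)
    # t-approximation for the Spearman p-value (n >= 10 here)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-12, None))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    out = pd.DataFrame({"gene_id": expr.index, "spearman_rho": rho, "p_value": p,
                        "n_individuals": n})
    out = out.dropna(subset=["spearman_rho"]).reset_index(drop=True)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["candidate"] = out["q_value"] <= fdr
    out["is_rbp"] = (out["gene_id"].isin(rbp_list) if rbp_list is not None
                     else pd.NA)
    return out.sort_values("q_value", kind="stable").reset_index(drop=True)


def intersect_candidates(scan_a: pd.DataFrame, scan_b: pd.DataFrame) -> pd.DataFrame:
    """Candidates significant in BOTH condition datasets (same-sign rho)."""
    a = scan_a[scan_a["candidate"]][["gene_id", "spearman_rho", "q_value"]]
    b = scan_b[scan_b["candidate"]][["gene_id", "spearman_rho", "q_value"]]
    merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
    merged = merged[np.sign(merged["spearman_rho_a"]) == np.sign(merged["spearman_rho_b"])]
    return merged.reset_index(drop=True)
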