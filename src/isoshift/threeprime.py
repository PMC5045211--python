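"""3'-end sequencing validation of tandem-UTR shortening.

Metagene profiles aggregate read 3'-end densities at fixed offsets around the
proximal (upstream) and distal (downstream) polyadenylation sites of tandem
UTRs, with per-event equal weighting; PSI can be recomputed directly from
3'-end counts as the long-isoform share of site-assigned reads.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["metagene", "psi_from_threeprime", "quant_concordance"]


def _offsets(positions: np.ndarray, site: int, strand: str) -> np.ndarray:
    """Strand-aware offsets: positive = downstream (3') of the site."""
    off = positions - site
    return off if strand == "+" else -off


def metagene(reads: pd.DataFrame, sites: pd.DataFrame, *,
             window: int = 500, sheet: pd.DataFrame | None = None):
    """Metagene read-density profiles around the two polyA sites.

    Parameters
    ----------
    reads
        BED-style 3'-end positions (chrom, start, name=sample_id, strand).
    sites
        One row per event: event_id, chrom, proximal, distal, strand and
        (optionally) ``sig_class``.
    window
        Half-width W of the offset grid [-W, +W].
    sheet
        Optional sample sheet; when given, profiles are split by condition.

    Each event's histogram is normalized by the event's total in-window reads
    (across both sites), so per-site profiles integrate to <= 1 and events
    contribute with equal weight.  Events with zero in-window reads are
    excluded and counted.

    Returns ``(profiles, n_excluded)``: a long DataFrame with columns
    sig_class, site_type, condition, offset, density, n_events.
    """
    cond_of = None
    if sheet is not None:
        cond_of = sheet.set_index("sample_id")["condition"].to_dict()
    by_chrom = dict(tuple(reads.groupby("chrom")))
    grid = np.arange(-window, window + 1)
    acc: dict[tuple, list[np.ndarray]] = {}
    n_excluded = 0
    for rec in sites.itertuples(index=False):
        sub = by_chrom.get(rec.chrom)
        if sub is None:
            n_excluded += 1
            continue
        sig_class = getattr(rec, "sig_class", "all")
        pos = sub["start"].to_numpy(int)
        conds = (np.array([cond_of.get(n, "all") for n in sub["name"]])
                 if cond_of is not None else np.repeat("all", len(sub)))
        for cond in np.unique(conds):
            mask = conds == cond
            p = pos[mask]
            hists = {}
            total = 0
            for site_type, site in (("proximal", rec.proximal), ("distal", rec.distal)):
                off = _offsets(p, int(site), rec.strand)
                inwin = off[(off >= -window) & (off <= window)]
                h = np.bincount(inwin + window, minlength=2 * window + 1).astype(float)
                hists[site_type] = h
                total += h.sum()
            if total == 0:
                n_excluded += 1
                continue
            for site_type, h in hists.items():
                acc.setdefault((sig_class, site_type, cond), []).append(h / total)
    rows = []
    for (sig_class, site_type, cond), hlist in sorted(acc.items()):
        mean_h = np.mean(hlist, axis=0)
        rows.append(pd.DataFrame({"sig_class": sig_class, "site_type": site_type,
                                  "condition": cond, "offset": grid,
                                  "density": mean_h, "n_events": len(hlist)}))
    profiles = (pd.concat(rows, ignore_index=True) if rows
                else pd.DataFrame(columns=["sig_class", "site_type", "condition",
                                           "offset", "density", "n_events"]))
    return profiles, n_excluded


def psi_from_threeprime(reads: pd.DataFrame, sites: pd.DataFrame,
                        sheet: pd.DataFrame, *, assignment_radius: int = 100,
                        eps: float = 1.0):
    """PSI (long-isoform usage) per event and sample from 3'-end counts.

    S = reads within +/- radius of the proximal site, L = within the radius
    of the distal site; PSI = (L + eps) / (L + S + 2 eps).  Reads falling in
    neither window are reported as an unassigned fraction.  Delta-PSI is
    paired per individual; when ``sites`` carries a ``sig_class`` column a
    Mann-Whitney comparison of per-event mean delta-PSI between the
    shortened_significant and unchanged classes is returned.

    Returns ``(psi_table, comparison)``.
    """
    gaps = (sites["distal"] - sites["proximal"]).to_numpy()
    if (assignment_radius >= gaps / 2).any():
        raise ValueError("assignment_radius must be < half the proximal-distal distance")
    cond_of = sheet.set_index("sample_id")["condition"]
    by_chrom = dict(tuple(reads.groupby("chrom")))
    rows = []
    n_total = n_unassigned = 0
    for rec in sites.itertuples(index=False):
        sub = by_chrom.get(rec.chrom)
        if sub is None:
            continue
        pos = sub["start"].to_numpy(int)
        near_prox = np.abs(pos - int(rec.proximal)) <= assignment_radius
        near_dist = np.abs(pos - int(rec.distal)) <= assignment_radius
        n_total += len(pos)
        n_unassigned += int((~near_prox & ~near_dist).sum())
        names = sub["name"].to_numpy()
        for sample in np.unique(names):
            m = names == sample
            s = int((near_prox & m).sum())
            l = int((near_dist & m).sum())
            if s + l == 0:
                psi = float("nan")
            else:
                psi = (l + eps) / (l + s + 2 * eps)
            rows.append(dict(event_id=rec.event_id, sample_id=sample,
                             n_proximal=s, n_distal=l, psi=psi))
    psi_long = pd.DataFrame(rows)
    if psi_long.empty:
        return psi_long, {"unassigned_fraction": float("nan")}
    psi_long["individual_id"] = psi_long["sample_id"].map(
        sheet.set_index("sample_id")["individual_id"])
    psi_long["condition"] = psi_long["sample_id"].map(cond_of)
    wide = psi_long.pivot_table(index=["event_id", "individual_id"],
                                columns="condition", values="psi", aggfunc="first")
    wide = wide.reindex(columns=["control", "infected"]).dropna()
    wide["delta_psi"] = wide["infected"] - wide["control"]
    per_event = wide.groupby(level="event_id")["delta_psi"].mean().rename("mean_delta_psi")
    table = (psi_long.merge(wide.reset_index()[["event_id", "individual_id", "delta_psi"]],
                            on=["event_id", "individual_id"], how="left"))
    comparison = {"unassigned_fraction": n_unassigned / n_total if n_total else float("nan")}
    if "sig_class" in sites.columns:
        cls = sites.set_index("event_id")["sig_class"]
        me = per_event.to_frame().join(cls, how="left")
        sig = me.loc[me["sig_class"] == "shortened_significant", "mean_delta_psi"].dropna()
        unc = me.loc[me["sig_class"] == "unchanged", "mean_delta_psi"].dropna()
        if len(sig) >= 2 and len(unc) >= 2:
            u = stats.mannwhitneyu(sig, unc, alternative="two-sided")
            comparison.update(p_value=float(u.pvalue),
                              median_delta_significant=float(sig.median()),
                              median_delta_unchanged=float(unc.median()))
    return table, comparison


def quant_concordance(threeprime_tpm: pd.DataFrame, rnaseq_tpm: pd.DataFrame,
                      min_genes: int = 50) -> pd.DataFrame:
    """Per-sample Pearson correlation of log(TPM + 1) between the two assays.

    Fewer than ``min_genes`` shared genes flags the result underpowered.
    """
    shared_genes = threeprime_tpm.index.intersection(rnaseq_tpm.index)
    shared_samples = threeprime_tpm.columns.intersection(rnaseq_tpm.columns)
    underpowered = len(shared_genes) < min_genes
    rows = []
    for s in shared_samples:
        x = np.log1p(threeprime_tpm.loc[shared_genes, s].to_numpy(float))
        y = np.log1p(rnaseq_tpm.loc[shared_genes, s].to_numpy(float))
        if len(shared_genes) >= 3 and np.std(x) > 0 and np.std(y) > 0:
            r, p = stats.pearsonr(x, y)
        else:
            r, p = float("nan"), float("nan")
        rows.append(dict(sample_id=s, pearson_r=float(r), p_value=float(p),
                         n_genes=len(shared_genes), underpowered=bool(underpowered)))
    return pd.DataFrame(rows)
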