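"""Event-level PSI estimation, Bayes factors, and significance calling.

PSI (percent spliced in) is the proportion of a gene's transcripts carrying
the inclusion isoform of an event (the longer isoform for RI/SE/TandemUTR,
the most distal terminal exon for AFE/ALE).  Counts are first converted to
length-adjusted rates a = inc/l_inc, b = exc/l_exc; the estimator

    PSI = (a + eps) / (a + b + 2 eps),   eps = 1,

is the posterior mean of a uniform-prior beta model on the adjusted rates.

The per-individual Bayes factor compares independent PSI in the two
conditions against a shared PSI under Uniform(0,1) priors:

    BF = B(i1+1, e1+1) B(i2+1, e2+1) / B(i1+i2+1, e1+e2+1)

computed in log space via gammaln, which admits real-valued (length-adjusted)
counts.  An event is called significant when BF >= bf_threshold in at least
ceil(bf_frac * n) individuals AND |mean delta-PSI| >= min_mean_dpsi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "estimate_psi",
    "log_bayes_factor",
    "bayes_factor",
    "call_events",
    "directional_shift",
    "DirectionalShift",
    "dispersion_summary",
    "individual_global_shifts",
]


def estimate_psi(inc_count, exc_count, l_inc=1.0, l_exc=1.0, eps: float = 1.0):
    """Length-adjusted posterior-mean PSI. Vectorized; PSI=0.5 at zero counts."""
    inc = np.asarray(inc_count, float)
    exc = np.asarray(exc_count, float)
    if (inc < 0).any() or (exc < 0).any():
        raise ValueError("counts must be non-negative")
    l_inc = np.asarray(l_inc, float)
    l_exc = np.asarray(l_exc, float)
    if (l_inc <= 0).any() or (l_exc <= 0).any():
        raise ValueError("region lengths must be positive")
    a = inc / l_inc
    b = exc / l_exc
    psi = (a + eps) / (a + b + 2.0 * eps)
    return psi if psi.ndim else float(psi)


def _log_beta(a, b):
    return gammaln(a) + gammaln(b) - gammaln(a + b)


def log_bayes_factor(inc1, exc1, inc2, exc2):
    """Log marginal-likelihood ratio: independent PSI vs shared PSI."""
    i1 = np.asarray(inc1, float)
    e1 = np.asarray(exc1, float)
    i2 = np.asarray(inc2, float)
    e2 = np.asarray(exc2, float)
    if (i1 < 0).any() or (e1 < 0).any() or (i2 < 0).any() or (e2 < 0).any():
        raise ValueError("counts must be non-negative")
    out = (_log_beta(i1 + 1, e1 + 1) + _log_beta(i2 + 1, e2 + 1)
           - _log_beta(i1 + i2 + 1, e1 + e2 + 1))
    return out if np.ndim(out) else float(out)


def bayes_factor(inc1, exc1, inc2, exc2):
    """Bayes factor favoring different PSI in the two conditions (>= 0)."""
    return np.exp(log_bayes_factor(inc1, exc1, inc2, exc2))


def call_events(events: pd.DataFrame, sheet: pd.DataFrame, *,
                bf_threshold: float = 5.0, bf_frac: float = 0.10,
                min_mean_dpsi: float = 0.05, eps: float = 1.0,
                length_adjust_bf: bool = True):
    """Per-individual PSI records and per-event significance calls.

    Parameters
    ----------
    events
        Long counts table: event_id, category, gene_id, sample_id,
        inc_count, exc_count, inc_len, exc_len.
    sheet
        Sample sheet mapping sample_id -> (individual_id, condition).
        Individuals missing one condition for an event are dropped from it.

    Returns
    -------
    (psi_records, calls): per event x individual PSI/delta/BF, and per-event
    calls with mean delta-PSI over all individuals, mean over BF-passing
    individuals, the pass count, the coefficient of variation of delta-PSI
    (sd when the mean is ~0), and the significance flag
    (n_pass >= ceil(bf_frac * n) AND |mean dPSI| >= min_mean_dpsi).
    """
    df = events.merge(sheet, on="sample_id", how="left", validate="many_to_one")
    if df["condition"].isna().any():
        bad = df.loc[df["condition"].isna(), "sample_id"].unique()[:5]
        raise ValueError(f"samples absent from sample sheet: {list(bad)}")
    wide = df.pivot_table(index=["event_id", "individual_id"], columns="condition",
                          values=["inc_count", "exc_count", "inc_len", "exc_len"],
                          aggfunc="first")
    needed = [(v, c) for v in ("inc_count", "exc_count", "inc_len", "exc_len")
              for c in ("control", "infected")]
    for col in needed:
        if col not in wide.columns:
            raise ValueError("both conditions required in the sample sheet")
    complete = wide.dropna()

    i1 = complete[("inc_count", "control")].to_numpy(float)
    e1 = complete[("exc_count", "control")].to_numpy(float)
    i2 = complete[("inc_count", "infected")].to_numpy(float)
    e2 = complete[("exc_count", "infected")].to_numpy(float)
    li = complete[("inc_len", "control")].to_numpy(float)
    le = complete[("exc_len", "control")].to_numpy(float)

    psi_ni = estimate_psi(i1, e1, li, le, eps)
    psi_inf = estimate_psi(i2, e2, li, le, eps)
    if length_adjust_bf:
        lbf = log_bayes_factor(i1 / li, e1 / le, i2 / li, e2 / le)
    else:
        lbf = log_bayes_factor(i1, e1, i2, e2)

    idx = complete.index.to_frame(index=False)
    psi_records = pd.DataFrame({
        "event_id": idx["event_id"],
        "individual_id": idx["individual_id"],
        "psi_ni": psi_ni,
        "psi_inf": psi_inf,
        "delta_psi": psi_inf - psi_ni,
        "log_bf": lbf,
        "bayes_factor": np.exp(np.minimum(lbf, 700.0)),
        "low_info": ((i1 + e1) == 0) | ((i2 + e2) == 0),
    })

    meta = events[["event_id", "category", "gene_id"]].drop_duplicates("event_id")
    grp = psi_records.groupby("event_id", sort=True)
    calls = grp.agg(
        n_individuals=("individual_id", "size"),
        mean_delta_psi=("delta_psi", "mean"),
        sd_delta_psi=("delta_psi", lambda x: x.std(ddof=1)),
        n_individuals_bf_pass=("bayes_factor", lambda x: int((x >= bf_threshold).sum())),
    ).reset_index()
    sig_means = (psi_records[psi_records["bayes_factor"] >= bf_threshold]
                 .groupby("event_id")["delta_psi"].mean().rename("mean_delta_psi_bf_pass"))
    calls = calls.merge(sig_means, on="event_id", how="left")
    need = np.ceil(bf_frac * calls["n_individuals"]).astype(int)
    calls["significant"] = ((calls["n_individuals_bf_pass"] >= need)
                            & (calls["mean_delta_psi"].abs() >= min_mean_dpsi))
    near_zero = calls["mean_delta_psi"].abs() < 1e-8
    calls["cv_delta_psi"] = np.where(
        near_zero, calls["sd_delta_psi"],
        calls["sd_delta_psi"] / calls["mean_delta_psi"].abs())
    calls = calls.merge(meta, on="event_id", how="left")
    cols = ["event_id", "category", "gene_id", "n_individuals", "mean_delta_psi",
            "mean_delta_psi_bf_pass", "sd_delta_psi", "cv_delta_psi",
            "n_individuals_bf_pass", "significant"]
    return psi_records, calls[cols]


@dataclass
class DirectionalShift:
    category: str
    n_significant: int
    n_other: int
    frac_negative: float
    p_two_sample: float
    p_one_sample: float
    underpowered: bool


def directional_shift(calls: pd.DataFrame, category: str,
                      min_events: int = 10) -> DirectionalShift:
    """Directionality of significant mean delta-PSI values in one category.

    frac_negative is the fraction of significant events shifting negative
    (e.g. towards the proximal polyA site for TandemUTRs); p_two_sample is a
    two-sided Mann-Whitney U of significant vs non-significant mean delta-PSI,
    p_one_sample a one-sample t-test of significant mean delta-PSI against 0.
    """
    sub = calls[calls["category"] == category]
    sig = sub.loc[sub["significant"], "mean_delta_psi"].to_numpy(float)
    other = sub.loc[~sub["significant"], "mean_delta_psi"].to_numpy(float)
    underpowered = sig.size < min_events
    frac_neg = float((sig < 0).mean()) if sig.size else float("nan")
    if sig.size >= 2 and other.size >= 2:
        p_two = float(stats.mannwhitneyu(sig, other, alternative="two-sided").pvalue)
    else:
        p_two = float("nan")
    if sig.size >= 2 and np.std(sig) > 0:
        p_one = float(stats.ttest_1samp(sig, 0.0).pvalue)
    else:
        p_one = float("nan")
    return DirectionalShift(category=category, n_significant=int(sig.size),
                            n_other=int(other.size), frac_negative=frac_neg,
                            p_two_sample=p_two, p_one_sample=p_one,
                            underpowered=bool(underpowered))


def dispersion_summary(psi_records: pd.DataFrame, calls: pd.DataFrame):
    """Coefficient of variation of delta-PSI per event, significant vs not.

    CV = sd/|mean| per event (sd reported when the mean is ~0); events with a
    single individual are masked.  Returns ``(per_event, tests)`` where
    ``tests`` maps category -> Mann-Whitney comparison of CV between
    significant and non-significant events.
    """
    g = psi_records.groupby("event_id")["delta_psi"]
    per_event = g.agg(n="size", mean="mean", sd=lambda x: x.std(ddof=1)).reset_index()
    per_event.loc[per_event["n"] < 2, "sd"] = np.nan
    near_zero = per_event["mean"].abs() < 1e-8
    per_event["cv"] = np.where(near_zero, per_event["sd"],
                               per_event["sd"] / per_event["mean"].abs())
    per_event = per_event.merge(calls[["event_id", "category", "significant"]],
                                on="event_id", how="left")
    tests = {}
    for cat, sub in per_event.dropna(subset=["cv"]).groupby("category"):
        sig = sub.loc[sub["significant"].astype(bool), "cv"]
        other = sub.loc[~sub["significant"].astype(bool), "cv"]
        if len(sig) >= 2 and len(other) >= 2:
            u = stats.mannwhitneyu(sig, other, alternative="two-sided")
            tests[cat] = {"median_cv_significant": float(sig.median()),
                          "median_cv_other": float(other.median()),
                          "p_value": float(u.pvalue)}
    return per_event, tests


def individual_global_shifts(psi_records: pd.DataFrame, calls: pd.DataFrame,
                             min_individuals: int = 3):
    """Per-individual mean delta-PSI per category + cross-category Pearson r.

    Returns ``(matrix, pairwise)``: an individuals x categories DataFrame of
    mean delta-PSI, and pairwise Pearson correlations with p-values.
    Categories with no events are dropped.
    """
    merged = psi_records.merge(calls[["event_id", "category"]], on="event_id", how="left")
    matrix = (merged.pivot_table(index="individual_id", columns="category",
                                 values="delta_psi", aggfunc="mean")
              .dropna(axis=1, how="all"))
    if matrix.shape[0] < min_individuals:
        raise ValueError("need at least 3 individuals")
    cats = list(matrix.columns)
    rows = []
    for i, ca in enumerate(cats):
        for cb in cats[i + 1:]:
            sub = matrix[[ca, cb]].dropna()
            if len(sub) < min_individuals:
                continue
            if sub[ca].std() == 0 or sub[cb].std() == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(sub[ca], sub[cb])
            rows.append(dict(category_a=ca, category_b=cb, pearson_r=float(r),
                             p_value=float(p), n=len(sub)))
    return matrix, pd.DataFrame(rows)
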